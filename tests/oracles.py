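"""Independent brute-force oracles used to pin algorithm semantics.

Each oracle is a direct, unoptimized restatement of the definition it checks
(full enumeration / O(n^2) scans) and shares no code with the implementation.
"""

from __future__ import annotations

import math

import numpy as np


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Full enumeration of the conditional heterozygote-count distribution."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n - n_a
    probs = {}
    for het in range(min(n_a, n_A) + 1):
        if (n_a - het) % 2:
            continue
        aa = (n_a - het) // 2
        AA = n - het - aa
        if AA < 0 or aa < 0:
            continue
        # multinomial count of genotype configurations x 2^het orderings
        w = (
            math.factorial(n)
            // (math.factorial(AA) * math.factorial(het) * math.factorial(aa))
            * 2**het
        )
        probs[het] = w
    tot = sum(probs.values())
    p_obs = probs[n_Aa] / tot
    return sum(w for w in probs.values() if w / tot <= p_obs * (1 + 1e-12)) / tot


def roh_brute_force(pos, genotypes, params):
    """Enumerate every sub-run, keep the valid ones, and select runs by the
    leftmost-start / longest-extension rule (one chromosome, one sample)."""
    m = len(pos)
    het = genotypes == 1
    mis = genotypes == -1

    def valid(i, j):
        if het[i] or mis[i] or het[j] or mis[j]:
            return False
        n = j - i + 1
        if n < params.min_consecutive_snps:
            return False
        length = pos[j] - pos[i]
        if length < params.min_length_bp:
            return False
        if sum(het[i:j + 1]) > params.max_het_per_run:
            return False
        if sum(mis[i:j + 1]) > params.max_missing_per_run:
            return False
        if length > 0 and n / length < params.min_density_snps_per_bp:
            return False
        for k in range(i, j):
            if pos[k + 1] - pos[k] > params.max_gap_bp:
                return False
        return True

    out = []
    i = 0
    while i < m:
        best = None
        for j in range(m - 1, i - 1, -1):
            if valid(i, j):
                best = j
                break
        if best is None:
            i += 1
        else:
            out.append((i, best))
            i = best + 1
    return out


def ehh_pair_counting(haps, core, allele, j):
    """EHH at SNP j by explicit distinct-haplotype pair counting."""
    carriers = [h for h in range(haps.shape[0]) if haps[h, core] == allele]
    n = len(carriers)
    lo, hi = min(core, j), max(core, j)
    seen: dict[tuple, int] = {}
    for h in carriers:
        key = tuple(haps[h, lo:hi + 1])
        seen[key] = seen.get(key, 0) + 1
    same = sum(c * (c - 1) // 2 for c in seen.values())
    return same / (n * (n - 1) / 2)


def intersect_brute_force(a, b):
    """O(n^2) interval intersection."""
    out = []
    for ia in a:
        for ib in b:
            if (
                ia.chrom == ib.chrom
                and ia.start_bp <= ib.stop_bp
                and ib.start_bp <= ia.stop_bp
            ):
                out.append(
                    (ia, ib, max(ia.start_bp, ib.start_bp), min(ia.stop_bp, ib.stop_bp))
                )
    return out


def gap_merge_brute_force(positions, gap):
    """Naive left-to-right merge of sorted positions into intervals."""
    if len(positions) == 0:
        return []
    positions = sorted(positions)
    out = [[positions[0], positions[0]]]
    for p in positions[1:]:
        if p - out[-1][1] <= gap:
            out[-1][1] = p
        else:
            out.append([p, p])
    return [tuple(x) for x in out]
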