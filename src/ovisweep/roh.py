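"""Runs of homozygosity: consecutive-method detection, F_ROH, ROH islands.

The consecutive method scans each individual's SNPs in order (no sliding
window): a run grows while every constraint holds — heterozygote and missing
budgets, maximum inter-SNP gap — and a completed run is kept only if it also
meets the minimum SNP count, minimum bp length and minimum SNP density.  Run
selection is deterministic: leftmost feasible start, then the longest
feasible extension, then the scan continues after the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenomicInterval, GenotypeDataset

#: total sheep autosome length used as the F_ROH denominator
AUTOSOME_LENGTH_BP = 2.45e9


@dataclass
class RohParams:
    """Detection thresholds (defaults: 50 SNPs, 1 Mb, <=1 het, <=5 missing,
    >=1 SNP/100 kb, inter-SNP gap <=1 Mb).  ``min_snps_window`` is recorded
    for completeness but is redundant with ``min_consecutive_snps`` under the
    consecutive method."""

    min_snps_window: int = 50
    min_length_bp: float = 1e6
    min_consecutive_snps: int = 50
    max_het_per_run: int = 1
    max_missing_per_run: int = 5
    min_density_snps_per_bp: float = 1.0 / 100_000
    max_gap_bp: float = 1e6

    def __post_init__(self):
        for f in ("min_length_bp", "min_consecutive_snps", "min_density_snps_per_bp",
                  "max_gap_bp"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class RohSegment:
    sample_id: str
    chrom: str
    start_bp: int
    stop_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        # stop - start, matching the size arithmetic of reported regions
        return self.stop_bp - self.start_bp


def _run_valid(pos, het, mis, i, j, params: RohParams) -> bool:
    """Does the SNP run [i..j] satisfy every ROH constraint?"""
    if het[i] or mis[i] or het[j] or mis[j]:
        return False  # runs start/end on a homozygous call
    n = j - i + 1
    if n < params.min_consecutive_snps:
        return False
    length = pos[j] - pos[i]
    if length < params.min_length_bp:
        return False
    if het[i:j + 1].sum() > params.max_het_per_run:
        return False
    if mis[i:j + 1].sum() > params.max_missing_per_run:
        return False
    if length > 0 and n / length < params.min_density_snps_per_bp:
        return False
    if np.any(np.diff(pos[i:j + 1]) > params.max_gap_bp):
        return False
    return True


def _scan_chromosome(pos, het, mis, params: RohParams):
    """Deterministic leftmost-start / longest-extension run selection."""
    m = len(pos)
    # split into blocks at gaps exceeding the maximum
    block = np.zeros(m, dtype=np.int64)
    if m > 1:
        block[1:] = np.cumsum(np.diff(pos) > params.max_gap_bp)
    block_end = np.empty(m, dtype=np.int64)
    for b in np.unique(block):
        idx = np.flatnonzero(block == b)
        block_end[idx] = idx[-1]

    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    het_pos = np.flatnonzero(het)
    mis_pos = np.flatnonzero(mis)

    def budget_limit(i, positions, cum, budget):
        # largest j such that count in [i..j] <= budget
        used_before = cum[i]
        k = used_before + budget  # index (0-based) of first violating event
        if k >= len(positions):
            return m - 1
        return positions[k] - 1

    out = []
    i = 0
    while i < m:
        if het[i] or mis[i]:
            i += 1
            continue
        jmax = min(
            block_end[i],
            budget_limit(i, het_pos, chet, params.max_het_per_run),
            budget_limit(i, mis_pos, cmis, params.max_missing_per_run),
        )
        found = None
        for j in range(jmax, i + params.min_consecutive_snps - 2, -1):
            if _run_valid(pos, het, mis, i, j, params):
                found = j
                break
        if found is None:
            i += 1
        else:
            out.append((i, found))
            i = found + 1
    return out


def detect_roh(ds: GenotypeDataset, params: RohParams | None = None) -> list[RohSegment]:
    """Detect ROH per sample and chromosome with the consecutive method."""
    params = params or RohParams()
    for c in dict.fromkeys(ds.chrom):
        p = ds.pos_bp[ds.chrom == c]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"positions not sorted on chromosome {c}")
    segments: list[RohSegment] = []
    for c in dict.fromkeys(ds.chrom):
        cols = np.flatnonzero(ds.chrom == c)
        pos = ds.pos_bp[cols]
        for s, sid in enumerate(ds.sample_ids):
            g = ds.genotype[s, cols]
            het = g == 1
            mis = g == MISSING
            for i, j in _scan_chromosome(pos, het, mis, params):
                segments.append(
                    RohSegment(
                        sample_id=sid,
                        chrom=str(c),
                        start_bp=int(pos[i]),
                        stop_bp=int(pos[j]),
                        n_snps=int(j - i + 1),
                        n_het=int(het[i:j + 1].sum()),
                        n_missing=int(mis[i:j + 1].sum()),
                    )
                )
    return segments


def froh(segments: list[RohSegment], sample_ids: list[str],
         autosome_length_bp: float = AUTOSOME_LENGTH_BP) -> pd.DataFrame:
    """Per-sample ROH burden and F_ROH = total ROH length / autosome length.

    Samples without segments get F_ROH = 0.
    """
    rows = {s: {"sample_id": s, "n_segments": 0, "total_length_bp": 0.0,
                "mean_length_bp": 0.0} for s in sample_ids}
    for seg in segments:
        r = rows[seg.sample_id]
        r["n_segments"] += 1
        r["total_length_bp"] += seg.length_bp
    df = pd.DataFrame(list(rows.values()))
    df["mean_length_bp"] = np.where(
        df["n_segments"] > 0, df["total_length_bp"] / df["n_segments"].clip(lower=1), 0.0
    )
    df["total_length_mb"] = df["total_length_bp"] / 1e6
    df["f_roh"] = df["total_length_bp"] / autosome_length_bp
    return df


def snp_occupancy(segments: list[RohSegment], group_samples: list[str],
                  ds: GenotypeDataset) -> np.ndarray:
    """Fraction of the group's samples whose ROH cover each SNP of ``ds``."""
    group = [s for s in group_samples if s in set(ds.sample_ids)]
    if not group:
        raise ValueError("empty group")
    cover = np.zeros(ds.n_variants, dtype=np.int64)
    gset = set(group)
    for seg in segments:
        if seg.sample_id not in gset:
            continue
        hit = (ds.chrom == seg.chrom) & (ds.pos_bp >= seg.start_bp) & (ds.pos_bp <= seg.stop_bp)
        cover += hit
    return cover / len(group)


def roh_islands(segments: list[RohSegment], group_samples: list[str],
                ds: GenotypeDataset, freq_threshold: float = 0.5,
                tags=()) -> list[GenomicInterval]:
    """Maximal runs of consecutive SNPs whose ROH occupancy in the group is at
    least ``freq_threshold`` (default: the 50% rule), as bp intervals spanning
    the first..last qualifying SNP."""
    if len(group_samples) < 2:
        raise ValueError("ROH islands need a group of >= 2 samples")
    occ = snp_occupancy(segments, group_samples, ds)
    qual = occ >= freq_threshold
    out: list[GenomicInterval] = []
    for c in dict.fromkeys(ds.chrom):
        cols = np.flatnonzero(ds.chrom == c)
        q = qual[cols]
        j = 0
        while j < len(cols):
            if not q[j]:
                j += 1
                continue
            k = j
            while k + 1 < len(cols) and q[k + 1]:
                k += 1
            out.append(
                GenomicInterval(
                    chrom=str(c),
                    start_bp=int(ds.pos_bp[cols[j]]),
                    stop_bp=int(ds.pos_bp[cols[k]]),
                    tags=frozenset(tags) | {"method=ROH"},
                )
            )
            j = k + 1
    return out


def private_islands(islands_a: list[GenomicInterval],
                    islands_b: list[GenomicInterval]) -> list[GenomicInterval]:
    """Parts of A-islands with zero bp overlap with any B-island.

    Retention kind is recorded in the tags: ``retained=whole`` when an island
    survives untouched, ``retained=segment`` when only a piece does.
    """
    out: list[GenomicInterval] = []
    for a in islands_a:
        pieces = [(a.start_bp, a.stop_bp)]
        for b in islands_b:
            if b.chrom != a.chrom:
                continue
            nxt = []
            for lo, hi in pieces:
                if b.stop_bp < lo or b.start_bp > hi:
                    nxt.append((lo, hi))
                    continue
                if b.start_bp > lo:
                    nxt.append((lo, b.start_bp - 1))
                if b.stop_bp < hi:
                    nxt.append((b.stop_bp + 1, hi))
            pieces = nxt
            if not pieces:
                break
        whole = pieces == [(a.start_bp, a.stop_bp)]
        for lo, hi in pieces:
            out.append(
                GenomicInterval(
                    chrom=a.chrom,
                    start_bp=lo,
                    stop_bp=hi,
                    tags=a.tags | {"retained=whole" if whole else "retained=segment"},
                )
            )
    return out
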