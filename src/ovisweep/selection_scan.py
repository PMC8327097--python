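"""Selection scans: windowed F_ST Z-score outliers and XP-EHH.

Per-SNP F_ST uses the allele-frequency form
``F_ST = 1 - (p1*q1 + p2*q2) / (2 * pr * qr)`` with pr, qr the unweighted
means of the two group frequencies (a sample-size-weighted pooling is
available via ``weighted=True``).  Window statistics are standardized into
ZF_ST over all retained windows of a comparison and the top 0.1% positive
values flagged as candidates.

XP-EHH compares integrated EHH between two populations at each core SNP:
``raw = ln(iHH_A / iHH_B)``, standardized over all scanned SNPs, with
one-sided p-values from the standard normal (positive scores point to longer
haplotypes — recent selection — in population A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotype_io import GenomicInterval, GenotypeDataset, HaplotypeSet


# ---------------------------------------------------------------------------
# per-SNP F_ST
# ---------------------------------------------------------------------------

def pop_allele_freqs(ds: GenotypeDataset, group_a, group_b) -> pd.DataFrame:
    """Per-SNP allele frequencies p1/q1 (group A), p2/q2 (group B) and the
    across-group means pr/qr."""
    idx_a = np.asarray(group_a)
    idx_b = np.asarray(group_b)
    p1 = ds.alt_freq(idx_a)
    p2 = ds.alt_freq(idx_b)
    pr = (p1 + p2) / 2.0
    return pd.DataFrame(
        {
            "variant_id": ds.variant_ids,
            "chrom": ds.chrom,
            "pos_bp": ds.pos_bp,
            "p1": p1,
            "q1": 1 - p1,
            "p2": p2,
            "q2": 1 - p2,
            "pr": pr,
            "qr": 1 - pr,
        }
    )


def snp_fst(p1, p2, weighted: bool = False, n1=None, n2=None):
    """F_ST = 1 - (p1*q1 + p2*q2) / (2 * pr * qr); NaN where pr*qr = 0.

    With ``weighted=True`` pr is the sample-size-weighted pooled frequency.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q1, q2 = 1 - p1, 1 - p2
    if weighted:
        if n1 is None or n2 is None:
            raise ValueError("weighted pooling needs n1 and n2")
        pr = (n1 * p1 + n2 * p2) / (n1 + n2)
    else:
        pr = (p1 + p2) / 2.0
    qr = 1 - pr
    denom = 2 * pr * qr
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = 1.0 - (p1 * q1 + p2 * q2) / denom
    return np.where(denom > 0, fst, np.nan)


@dataclass
class FstScanResult:
    windows: pd.DataFrame  # chrom, start_bp, stop_bp, n_snps, fst_mean, zfst, candidate
    mu_fst: float
    sigma_fst: float
    n_skipped_snps: int

    def candidate_intervals(self, tags=()) -> list[GenomicInterval]:
        return [
            GenomicInterval(
                chrom=str(r.chrom), start_bp=int(r.start_bp), stop_bp=int(r.stop_bp),
                tags=frozenset(tags) | {"method=FST"},
            )
            for r in self.windows[self.windows["candidate"]].itertuples()
        ]


def tile_windows(chrom_length_bp: int, window_bp: int, step_bp: int):
    """Window starts 1, 1+step, ... keeping only windows fully inside the
    chromosome (stop = start + window - 1 <= length)."""
    starts = []
    s = 1
    while s + window_bp - 1 <= chrom_length_bp:
        starts.append(s)
        s += step_bp
    return [(s, s + window_bp - 1) for s in starts]


def window_fst_scan(ds: GenotypeDataset, pop_a: str, pop_b: str,
                    window_bp: int = 200_000, step_bp: int = 60_000,
                    min_snps: int = 3, top_fraction: float = 0.001,
                    weighted: bool = False) -> FstScanResult:
    """Sliding-window F_ST scan with Z-standardization.

    Window statistic = mean per-SNP F_ST; windows with fewer than ``min_snps``
    informative SNPs are dropped; ZF_ST = (F_ST - mu)/sigma over all retained
    windows; candidates are the top ``top_fraction`` (default 0.1%) positive
    ZF_ST values, implemented as the ceil(fraction * n_windows) largest.
    """
    by_pop = ds.samples_by_population()
    if len(by_pop.get(pop_a, ())) < 2 or len(by_pop.get(pop_b, ())) < 2:
        raise ValueError("need >= 2 samples in each group")
    freqs = pop_allele_freqs(ds, by_pop[pop_a], by_pop[pop_b])
    na, nb = len(by_pop[pop_a]), len(by_pop[pop_b])
    fst = snp_fst(freqs["p1"], freqs["p2"], weighted=weighted, n1=na, n2=nb)
    skipped = int(np.isnan(fst).sum())

    rows = []
    for c in dict.fromkeys(ds.chrom):
        on_c = ds.chrom == c
        pos = ds.pos_bp[on_c]
        vals = fst[on_c]
        for start, stop in tile_windows(int(pos.max()), window_bp, step_bp):
            sel = (pos >= start) & (pos <= stop) & ~np.isnan(vals)
            n = int(sel.sum())
            if n < min_snps:
                continue
            rows.append((str(c), start, stop, n, float(vals[sel].mean())))
    win = pd.DataFrame(rows, columns=["chrom", "start_bp", "stop_bp", "n_snps", "fst_mean"])
    if win.empty:
        raise ValueError("no windows retained")
    mu = float(win["fst_mean"].mean())
    sigma = float(win["fst_mean"].std(ddof=0))
    if sigma == 0:
        raise ValueError("degenerate scan: all windows have identical F_ST")
    win["zfst"] = (win["fst_mean"] - mu) / sigma

    k = math.ceil(top_fraction * len(win))
    order = np.argsort(-win["zfst"].to_numpy(), kind="stable")
    cand = np.zeros(len(win), dtype=bool)
    top = [i for i in order[:k] if win["zfst"].iloc[i] > 0]
    cand[top] = True
    win["candidate"] = cand
    return FstScanResult(windows=win, mu_fst=mu, sigma_fst=sigma, n_skipped_snps=skipped)


# ---------------------------------------------------------------------------
# EHH / iHH / XP-EHH
# ---------------------------------------------------------------------------

def _pairs(k: np.ndarray | int):
    k = np.asarray(k, dtype=float)
    return k * (k - 1) / 2.0


def _ehh_walk(haplotypes: np.ndarray, carriers: np.ndarray, core_index: int,
              step: int, stop_below: float):
    """One-directional EHH walk; returns ([snp indices], [ehh values]).

    Haplotype groups are refined SNP by SNP with a bincount-based relabeling
    (no sort); the walk stops once EHH falls below ``stop_below`` or hits 0
    (the first such point is still reported).
    """
    n = carriers.size
    denom = n * (n - 1) / 2.0
    m = haplotypes.shape[1]
    group = np.zeros(n, dtype=np.int64)
    n_groups = 1
    js, vals = [], []
    j = core_index + step
    while 0 <= j < m:
        key = group * 2 + haplotypes[carriers, j]
        counts = np.bincount(key, minlength=2 * n_groups)
        nz = counts > 0
        relabel = np.cumsum(nz) - 1
        group = relabel[key]
        n_groups = int(nz.sum())
        c = counts[nz]
        val = float((c * (c - 1)).sum() / 2.0 / denom)
        js.append(j)
        vals.append(val)
        if val < stop_below or val == 0.0:
            break
        j += step
    return js, vals


def ehh(haplotypes: np.ndarray, core_index: int, core_allele: int,
        stop_below: float = 0.0) -> pd.DataFrame:
    """EHH curve around a core SNP for carriers of ``core_allele``.

    EHH at SNP j = sum_h C(n_h, 2) / C(n, 2) over the distinct extended
    haplotypes spanning core..j among the n carriers; EHH(core) = 1 and the
    curve is non-increasing outward.  With ``stop_below`` > 0 the walk stops
    after the first point falling below it (that point is still reported).

    Returns a DataFrame with columns ``snp_index`` and ``ehh`` ordered left
    to right, including the core.
    """
    carriers = np.flatnonzero(haplotypes[:, core_index] == core_allele)
    if carriers.size < 2:
        raise ValueError("EHH undefined: fewer than 2 carriers of the core allele")
    lj, lv = _ehh_walk(haplotypes, carriers, core_index, -1, stop_below)
    rj, rv = _ehh_walk(haplotypes, carriers, core_index, +1, stop_below)
    rows = list(zip(lj[::-1], lv[::-1])) + [(core_index, 1.0)] + list(zip(rj, rv))
    return pd.DataFrame(rows, columns=["snp_index", "ehh"])


def ihh(curve: pd.DataFrame, map_cm: np.ndarray, core_index: int,
        truncation: float = 0.05) -> float:
    """Trapezoidal integral of an EHH curve over genetic distance (cM).

    Each side is integrated outward from the core until EHH drops below
    ``truncation``; the trapezoid crossing the threshold is included in full,
    points beyond it contribute nothing.  Sides are summed.  Returns 0 when
    the curve decays immediately on both sides.
    """
    snps = curve["snp_index"].to_numpy()
    vals = curve["ehh"].to_numpy()
    core_pos = int(np.flatnonzero(snps == core_index)[0])
    total = 0.0
    for sl in (slice(core_pos, None, 1), slice(core_pos, None, -1)):
        s, v = snps[sl], vals[sl]
        for k in range(1, len(s)):
            dx = abs(map_cm[s[k]] - map_cm[s[k - 1]])
            total += 0.5 * (v[k] + v[k - 1]) * dx
            if v[k] < truncation:
                break
    return total


def _site_ihh(haps: np.ndarray, map_cm: np.ndarray, core: int,
              truncation: float) -> float:
    """Allele-frequency-weighted iHH at a core SNP (site-level statistic):
    each core allele with >= 2 carriers contributes its iHH weighted by its
    frequency among the population's haplotypes."""
    col = haps[:, core]
    n = col.size
    total = 0.0
    for allele in (0, 1):
        k = int(np.sum(col == allele))
        if k < 2:
            continue
        curve = ehh(haps, core, allele, stop_below=truncation)
        total += (k / n) * ihh(curve, map_cm, core, truncation=truncation)
    return total


def xpehh_scan(haps_a: HaplotypeSet, haps_b: HaplotypeSet,
               truncation: float = 0.05, p_threshold: float = 0.001,
               cores: np.ndarray | None = None) -> pd.DataFrame:
    """XP-EHH scan between two populations on the same variant grid.

    Returns one row per scanned SNP with iHH_A, iHH_B, the raw statistic
    ln(iHH_A/iHH_B), its Z-standardization over all defined SNPs, one-sided
    p-values per tail (``p_a`` small: selection in A; ``p_b`` small: in B),
    a significance flag at ``p_threshold`` and the direction.  SNPs where
    either iHH is zero are flagged undefined and excluded from
    standardization.
    """
    if not np.array_equal(haps_a.pos_bp, haps_b.pos_bp) or not np.array_equal(
        haps_a.chrom, haps_b.chrom
    ):
        raise ValueError("populations must share the same variant grid")
    map_cm = haps_a.genetic_map_cm()
    idx = np.arange(haps_a.n_variants) if cores is None else np.asarray(cores)
    ihh_a = np.array([_site_ihh(haps_a.haplotypes, map_cm, j, truncation) for j in idx])
    ihh_b = np.array([_site_ihh(haps_b.haplotypes, map_cm, j, truncation) for j in idx])

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.log(ihh_a / ihh_b)
    defined = np.isfinite(raw)
    df = pd.DataFrame(
        {
            "variant_id": [haps_a.variant_ids[j] for j in idx],
            "chrom": haps_a.chrom[idx],
            "pos_bp": haps_a.pos_bp[idx],
            "ihh_a": ihh_a,
            "ihh_b": ihh_b,
            "raw": np.where(defined, raw, np.nan),
            "defined": defined,
        }
    )
    if defined.sum() < 2:
        raise ValueError("too few defined XP-EHH records to standardize")
    mu = float(df.loc[defined, "raw"].mean())
    sd = float(df.loc[defined, "raw"].std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate XP-EHH scan: zero variance")
    z = (df["raw"] - mu) / sd
    df["z"] = z
    df["p_a"] = norm.sf(z)   # upper tail: selection in A
    df["p_b"] = norm.cdf(z)  # lower tail: selection in B
    df["significant"] = defined & ((df["p_a"] < p_threshold) | (df["p_b"] < p_threshold))
    df["direction"] = np.where(
        df["significant"], np.where(df["z"] > 0, "A", "B"), ""
    )
    return df


def significant_regions(records: pd.DataFrame, merge_gap_bp: int = 200_000,
                        tags=()) -> list[GenomicInterval]:
    """Merge significant SNPs of the same direction into intervals when at
    most ``merge_gap_bp`` apart; intervals are tagged method=XP-EHH plus any
    comparison tags supplied."""
    out: list[GenomicInterval] = []
    sig = records[records["significant"]]
    for (chrom, direction), grp in sig.groupby(["chrom", "direction"], sort=True):
        pos = np.sort(grp["pos_bp"].to_numpy())
        start = prev = int(pos[0])
        for p in pos[1:]:
            if p - prev > merge_gap_bp:
                out.append(_xp_interval(chrom, start, prev, direction, tags))
                start = int(p)
            prev = int(p)
        out.append(_xp_interval(chrom, start, prev, direction, tags))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start_bp))


def _xp_interval(chrom, start, stop, direction, tags):
    return GenomicInterval(
        chrom=str(chrom), start_bp=int(start), stop_bp=int(stop),
        tags=frozenset(tags) | {"method=XP-EHH", f"direction={direction}"},
    )
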