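"""Sample/variant quality control, relatedness (Pi-HAT) pruning, LD pruning.

Filter order in :func:`apply_qc` is samples -> variants -> relatedness; LD
pruning is a separate step applied only for structure analyses (PCA/NJ).
Applying any filter twice is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class QcThresholds:
    """Default thresholds for array QC.

    max_sample_missing: samples with MORE than this missing fraction drop.
    min_snp_call_rate / maf_min / hwe_p_min: variants failing any drop.
    pihat_cutoff 0.1875 = midpoint between the expected Pi-HAT of 2nd-degree
    (0.25) and 3rd-degree (0.125) relatives.
    ld_*: sliding-window LD pruning (window and step in kb, r^2 ceiling).
    """

    max_sample_missing: float = 0.10
    min_snp_call_rate: float = 0.90
    hwe_p_min: float = 1e-10
    maf_min: float = 0.01
    pihat_cutoff: float = 0.1875
    pihat_window: tuple = (0.05, 1.0)
    ld_window_kb: float = 50.0
    ld_step_kb: float = 5.0
    ld_r2_max: float = 0.5

    def __post_init__(self):
        for name in ("max_sample_missing", "min_snp_call_rate", "hwe_p_min",
                     "maf_min", "pihat_cutoff", "ld_r2_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ld_window_kb < self.ld_step_kb:
            raise ValueError("LD window must be >= step")


def pihat_cutoff_midpoint(second_degree: float = 0.25, third_degree: float = 0.125) -> float:
    """Half-way point between expected Pi-HAT of 2nd- and 3rd-degree relatives."""
    return (second_degree + third_degree) / 2.0


@dataclass
class RelatednessMatrix:
    """Symmetric per-pair PI_HAT with unit diagonal."""

    sample_ids: list[str]
    pihat: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        p = np.asarray(self.pihat, float)
        if p.shape[0] != p.shape[1] or not np.allclose(p, p.T, equal_nan=True):
            raise ValueError("PI_HAT matrix must be square and symmetric")
        self.pihat = p

    def clamped_to_window(self, lo: float = 0.05, hi: float = 1.0) -> np.ndarray:
        """Reporting view clipped to the [min, max] window; pruning uses the
        unclamped values."""
        return np.clip(self.pihat, lo, hi)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional HWE test p-value.

    Conditions on the observed allele counts; the p-value is the summed
    probability of all heterozygote counts (same parity) whose conditional
    probability does not exceed the observed one (plain, not mid-p).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("HWE test undefined for zero samples")
    n_a = 2 * n_aa + n_Aa  # copies of one allele; symmetric in the swap
    n_a = min(n_a, 2 * n - n_a)
    hets = np.arange(n_a % 2, n_a + 1, 2)
    n_aa_v = (n_a - hets) // 2
    n_AA_v = n - hets - n_aa_v
    # P(het | allele counts) = n! / (nAA! nAa! naa!) * 2^het / C(2n, n_a)-type constant
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA_v + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa_v + 1)
        + hets * np.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# Sample / variant filters
# ---------------------------------------------------------------------------

def filter_samples(ds: GenotypeDataset, thresholds: QcThresholds | None = None):
    """Drop samples with more than ``max_sample_missing`` missing genotypes."""
    th = thresholds or QcThresholds()
    miss = (ds.genotype == MISSING).mean(axis=1)
    keep = miss <= th.max_sample_missing
    report = {
        "n_input": ds.n_samples,
        "removed_missingness": [s for s, k in zip(ds.sample_ids, keep) if not k],
        "n_kept": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError("all samples removed by missingness filter")
    return ds.take_samples(np.flatnonzero(keep)), report


def filter_variants(ds: GenotypeDataset, thresholds: QcThresholds | None = None):
    """Keep variants with call rate >= 0.90, MAF >= 0.01 and HWE p >= 1e-10."""
    th = thresholds or QcThresholds()
    g = ds.genotype
    called = g != MISSING
    call_rate = called.mean(axis=0)
    freq = ds.alt_freq()
    maf = np.minimum(freq, 1 - freq)
    ok_call = call_rate >= th.min_snp_call_rate
    ok_maf = ~np.isnan(maf) & (maf >= th.maf_min)

    hwe_p = np.ones(ds.n_variants)
    for j in np.flatnonzero(ok_call & ok_maf):  # HWE only where still in play
        col = g[:, j]
        n2 = int(np.sum(col == 2))
        n1 = int(np.sum(col == 1))
        n0 = int(np.sum(col == 0))
        if n0 + n1 + n2 > 0:
            hwe_p[j] = hwe_exact_p(n0, n1, n2)
    ok_hwe = hwe_p >= th.hwe_p_min
    keep = ok_call & ok_maf & ok_hwe
    report = {
        "n_input": ds.n_variants,
        "removed_call_rate": int(np.sum(~ok_call)),
        "removed_maf": int(np.sum(ok_call & ~ok_maf)),
        "removed_hwe": int(np.sum(ok_call & ok_maf & ~ok_hwe)),
        "n_kept": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError("all variants removed by QC filters")
    return ds.take_variants(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Relatedness: method-of-moments IBD from IBS counts
# ---------------------------------------------------------------------------

def pihat_matrix(ds: GenotypeDataset) -> RelatednessMatrix:
    """PI_HAT = P(IBD=2) + 0.5 P(IBD=1) by method of moments.

    Per pair, observed IBS0/IBS1/IBS2 counts over jointly genotyped SNPs are
    equated with their allele-frequency expectations under IBD state 0/1/2;
    the solved probabilities are truncated to [0,1] and renormalized.  Allele
    frequencies come from the full sample set.
    """
    g = ds.genotype
    n, m = g.shape
    p = ds.alt_freq()
    q = 1.0 - p
    G0 = (g == 0).astype(np.float64)
    G1 = (g == 1).astype(np.float64)
    G2 = (g == 2).astype(np.float64)
    M = (g != MISSING).astype(np.float64)

    ibs0 = G0 @ G2.T + G2 @ G0.T
    ibs2 = G0 @ G0.T + G1 @ G1.T + G2 @ G2.T
    nm = M @ M.T
    ibs1 = nm - ibs0 - ibs2

    # per-SNP expectations of IBS states given IBD state (HWE, random pairing)
    e0_ibd0 = 2 * p**2 * q**2
    e2_ibd0 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibd0 = 1.0 - e0_ibd0 - e2_ibd0
    e1_ibd1 = 2 * p * q
    e2_ibd1 = p**2 + q**2
    ok = ~np.isnan(p)

    def pairsum(e):
        e = np.where(ok, e, 0.0)
        return (M * e) @ M.T

    S0_0, S1_0, S2_0 = pairsum(e0_ibd0), pairsum(e1_ibd0), pairsum(e2_ibd0)
    S1_1, S2_1 = pairsum(e1_ibd1), pairsum(e2_ibd1)

    with np.errstate(divide="ignore", invalid="ignore"):
        z0 = ibs0 / S0_0
        z1 = (ibs1 - z0 * S1_0) / S1_1
        z2 = (ibs2 - z0 * S2_0 - z1 * S2_1) / nm
    z = np.stack([z0, z1, z2])
    z = np.clip(z, 0.0, 1.0)
    tot = z.sum(axis=0)
    undefined = (nm == 0) | ~np.isfinite(tot) | (tot == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = z / tot
    pihat = z[2] + 0.5 * z[1]
    pihat[undefined] = np.nan
    np.fill_diagonal(pihat, 1.0)
    pihat = (pihat + pihat.T) / 2.0

    und_pairs = [
        (ds.sample_ids[i], ds.sample_ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if undefined[i, j]
    ]
    return RelatednessMatrix(sample_ids=list(ds.sample_ids), pihat=pihat,
                             undefined_pairs=und_pairs)


def relatedness_prune(rel: RelatednessMatrix, cutoff: float = 0.1875,
                      missingness: np.ndarray | None = None) -> list[str]:
    """Greedy pruning: repeatedly drop, among samples in pairs above the
    cutoff, the one with the most such pairs (ties: higher missingness, then
    later sample order) until no pair exceeds the cutoff.  Returns kept ids."""
    n = len(rel.sample_ids)
    miss = np.zeros(n) if missingness is None else np.asarray(missingness, float)
    p = rel.pihat.copy()
    np.fill_diagonal(p, 0.0)
    exceed = np.nan_to_num(p) > cutoff
    alive = np.ones(n, dtype=bool)
    while True:
        deg = (exceed & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max() == 0:
            break
        worst = np.flatnonzero(deg == deg.max())
        worst = worst[miss[worst] == miss[worst].max()]
        alive[worst[-1]] = False  # later sample order loses the tie
    return [s for s, a in zip(rel.sample_ids, alive) if a]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _dosage_r2(g: np.ndarray, j1: int, j2: int) -> float:
    """Squared Pearson correlation of genotype dosages over joint calls."""
    a, b = g[:, j1].astype(float), g[:, j2].astype(float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(ds: GenotypeDataset, window_kb: float = 50.0, step_kb: float = 5.0,
             r2_max: float = 0.5):
    """Sliding-window dosage-r^2 pruning (windows/steps in kb).

    Within each bp window, while any retained pair exceeds ``r2_max``, the
    member with the lower MAF is removed (tie: later position); windows then
    advance by the step.  Returns (pruned dataset, removed variant ids).
    """
    freq = ds.alt_freq()
    maf = np.minimum(freq, 1 - freq)
    keep = np.ones(ds.n_variants, dtype=bool)
    win, step = int(window_kb * 1000), int(step_kb * 1000)
    g = ds.genotype
    for c in dict.fromkeys(ds.chrom):
        cols = np.flatnonzero(ds.chrom == c)
        pos = ds.pos_bp[cols]
        start = 1
        last = int(pos.max())
        while start <= last:
            in_win = cols[(pos >= start) & (pos < start + win)]
            active = [j for j in in_win if keep[j]]
            changed = True
            while changed and len(active) > 1:
                changed = False
                for ai in range(len(active)):
                    for bi in range(ai + 1, len(active)):
                        j1, j2 = active[ai], active[bi]
                        r2 = _dosage_r2(g, j1, j2)
                        if np.isnan(r2) or r2 <= r2_max:
                            continue
                        # drop lower MAF; tie -> later position
                        if maf[j1] < maf[j2]:
                            drop = j1
                        elif maf[j2] < maf[j1]:
                            drop = j2
                        else:
                            drop = j1 if ds.pos_bp[j1] > ds.pos_bp[j2] else j2
                        keep[drop] = False
                        active.remove(drop)
                        changed = True
                        break
                    if changed:
                        break
            start += step
    removed = [v for v, k in zip(ds.variant_ids, keep) if not k]
    return ds.take_variants(np.flatnonzero(keep)), removed


def apply_qc(ds: GenotypeDataset, thresholds: QcThresholds | None = None):
    """Standard QC chain: samples -> variants -> relatedness pruning.

    Returns (dataset, report).  LD pruning is separate (:func:`ld_prune`) and
    applied only before structure analyses.
    """
    th = thresholds or QcThresholds()
    ds1, rep_s = filter_samples(ds, th)
    ds2, rep_v = filter_variants(ds1, th)
    rel = pihat_matrix(ds2)
    miss = (ds2.genotype == MISSING).mean(axis=1)
    kept_ids = relatedness_prune(rel, th.pihat_cutoff, missingness=miss)
    kept_idx = [i for i, s in enumerate(ds2.sample_ids) if s in set(kept_ids)]
    ds3 = ds2.take_samples(np.asarray(kept_idx, dtype=int))
    report = {
        "samples": rep_s,
        "variants": rep_v,
        "relatedness_removed": sorted(set(ds2.sample_ids) - set(kept_ids)),
        "n_final_samples": ds3.n_samples,
        "n_final_variants": ds3.n_variants,
    }
    return ds3, report
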