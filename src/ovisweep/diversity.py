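"""Heterozygosity, inbreeding, and Weir–Cockerham F_ST with permutation tests.

H_O is the per-individual heterozygous fraction of non-missing calls; H_E is
the per-population mean across SNPs of the unbiased expected heterozygosity
2*p*q*n/(n-1); F is the PLINK-style method-of-moments inbreeding coefficient
(O_hom - E_hom)/(M - E_hom).  Multi-locus theta follows Weir & Cockerham
(1984) as a ratio of averages: sum of per-locus a-components over the sum of
(a + b + c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class DiversityReport:
    per_individual: pd.DataFrame  # sample_id, population, h_o, f
    per_population: pd.DataFrame  # population, n, h_o_mean/sd, h_e_mean/sd, f_mean/sd


@dataclass
class PairwiseFst:
    pop_a: str
    pop_b: str
    theta: float
    p_value: float | None = None
    n_permutations: int = 0


def het_stats(ds: GenotypeDataset) -> DiversityReport:
    """Observed/expected heterozygosity and inbreeding F.

    E_hom for F uses the unbiased per-SNP homozygosity expectation
    1 - 2*p*q*n/(n-1) with allele frequencies from the full sample set,
    summed over each individual's non-missing SNPs.
    """
    g = ds.genotype
    called = g != MISSING
    het = g == 1
    m_i = called.sum(axis=1)
    h_o = np.where(m_i > 0, het.sum(axis=1) / np.maximum(m_i, 1), np.nan)

    n_called = called.sum(axis=0)
    p = ds.alt_freq()
    with np.errstate(invalid="ignore", divide="ignore"):
        e_het_snp = 2 * p * (1 - p) * n_called / np.maximum(n_called - 1, 1)
    e_hom_snp = np.where(n_called > 1, 1.0 - e_het_snp, np.nan)
    usable = called & ~np.isnan(e_hom_snp)[None, :]
    e_hom_i = np.where(usable, np.nan_to_num(e_hom_snp)[None, :], 0.0).sum(axis=1)
    m_use = usable.sum(axis=1)
    o_hom_i = (usable & (g != 1)).sum(axis=1)
    denom = m_use - e_hom_i
    f = np.where(np.abs(denom) > 1e-12, (o_hom_i - e_hom_i) / denom, np.nan)

    per_ind = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "population": ds.population_labels,
            "h_o": h_o,
            "f": f,
        }
    )

    rows = []
    for pop, idx in ds.samples_by_population().items():
        sub = per_ind.iloc[idx]
        row = {
            "population": pop,
            "n": len(idx),
            "h_o_mean": sub["h_o"].mean(),
            "h_o_sd": sub["h_o"].std(ddof=1) if len(idx) > 1 else np.nan,
            "f_mean": sub["f"].mean(),
            "f_sd": sub["f"].std(ddof=1) if len(idx) > 1 else np.nan,
        }
        if len(idx) >= 2:
            gp = g[idx]
            calledp = gp != MISSING
            nn = calledp.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                pp = np.where(nn > 0, np.where(calledp, gp, 0).sum(axis=0) / (2.0 * nn), np.nan)
                he = 2 * pp * (1 - pp) * nn / np.maximum(nn - 1, 1)
            he = he[nn > 1]
            row["h_e_mean"] = float(np.nanmean(he)) if he.size else np.nan
            # SD across SNPs (the paper does not define its SDs; see methods)
            row["h_e_sd"] = float(np.nanstd(he, ddof=1)) if he.size > 1 else np.nan
        else:
            row["h_e_mean"] = np.nan  # H_E undefined for < 2 samples
            row["h_e_sd"] = np.nan
        rows.append(row)
    return DiversityReport(per_individual=per_ind, per_population=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(g: np.ndarray, groups: list[np.ndarray]):
    """Per-locus Weir–Cockerham (1984) a, b, c variance components for r
    populations, from a genotype matrix (missing = -1)."""
    r = len(groups)
    n_i, p_i, h_i = [], [], []
    for idx in groups:
        sub = g[idx].astype(float)
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(called, sub, 0).sum(axis=0) / (2 * n), np.nan)
            h = np.where(n > 0, (called & (sub == 1)).sum(axis=0) / np.maximum(n, 1), np.nan)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)  # (r, m)
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    valid = (n_i >= 1).all(axis=0) & ~np.isnan(p_i).any(axis=0)
    nbar = n_i.mean(axis=0)
    sum_n = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (sum_n - (n_i**2).sum(axis=0) / sum_n) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / sum_n
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / sum_n

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    valid &= (nbar > 1) & (nc > 0) & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    # monomorphic loci contribute nothing to either sum
    poly = valid & (pbar > 0) & (pbar < 1)
    return np.where(poly, a, 0.0), np.where(poly, b, 0.0), np.where(poly, c, 0.0), poly


def wc_theta(ds: GenotypeDataset, groups: dict[str, np.ndarray]) -> float:
    """Multi-locus Weir–Cockerham theta (ratio of averages) over populations."""
    a, b, c, poly = _wc_components(ds.genotype, list(groups.values()))
    denom = (a + b + c).sum()
    if not poly.any() or denom == 0:
        raise ValueError("theta undefined: no polymorphic loci")
    return float(a.sum() / denom)


def wc_fst(ds: GenotypeDataset, pop_a: str, pop_b: str, n_perm: int = 1000,
           seed: int = 0) -> PairwiseFst:
    """Pairwise Weir–Cockerham theta with a label-permutation p-value.

    p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1), permuting population
    labels among the pooled samples of the two groups (seeded).
    """
    by_pop = ds.samples_by_population()
    idx_a, idx_b = by_pop[pop_a], by_pop[pop_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("need >= 2 samples per population")
    theta = wc_theta(ds, {pop_a: idx_a, pop_b: idx_b})
    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([idx_a, idx_b])
        na = len(idx_a)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            try:
                t = wc_theta(ds, {"a": perm[:na], "b": perm[na:]})
            except ValueError:
                continue
            if t >= theta:
                hits += 1
        p_value = (1 + hits) / (n_perm + 1)
    return PairwiseFst(pop_a=pop_a, pop_b=pop_b, theta=theta, p_value=p_value,
                       n_permutations=n_perm)


def fst_matrix(ds: GenotypeDataset, n_perm: int = 0, seed: int = 0) -> pd.DataFrame:
    """Square pairwise theta matrix over all populations (feeds the NJ tree)."""
    pops = list(dict.fromkeys(ds.population_labels))
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            res = wc_fst(ds, a, b, n_perm=n_perm, seed=seed)
            mat.loc[a, b] = mat.loc[b, a] = max(res.theta, 0.0)
    return mat
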