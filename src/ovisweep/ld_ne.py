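"""LD decay curves and effective-population-size trajectories.

r^2 is the squared Pearson correlation of genotype dosages (composite LD,
no haplotyping).  N_E follows Sved's relation N_Et = (1/4c)(1/r2 - 1) with
t = 1/(2c), where c is the genetic distance in Morgans between a SNP pair;
pairs are assigned to a generation bin when their c lies within a relative
tolerance of c* = 1/(2t).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


def pairwise_r2(ds: GenotypeDataset, max_dist_bp: float = 5e6,
                thin_step: int = 1) -> pd.DataFrame:
    """All within-chromosome dosage-r^2 pairs up to ``max_dist_bp`` apart.

    c (Morgans) comes from the dataset's genetic map (default 1 cM/Mb).
    Zero-variance members are skipped and counted in ``df.attrs['skipped']``.
    ``thin_step`` keeps every k-th variant to bound the pair count.
    """
    cm = ds.genetic_map_cm()
    rows = []
    skipped = 0
    for c in dict.fromkeys(ds.chrom):
        cols = np.flatnonzero(ds.chrom == c)[::thin_step]
        g = ds.genotype[:, cols].astype(float)
        g[g == MISSING] = np.nan
        pos = ds.pos_bp[cols]
        gmap = cm[cols]
        mean = np.nanmean(g, axis=0)
        std = np.nanstd(g, axis=0)
        gz = g - mean
        for a in range(len(cols)):
            if std[a] == 0:
                skipped += 1
                continue
            upper = np.searchsorted(pos, pos[a] + max_dist_bp, side="right")
            for b in range(a + 1, upper):
                if std[b] == 0:
                    continue
                ok = ~np.isnan(gz[:, a]) & ~np.isnan(gz[:, b])
                if ok.sum() < 2:
                    skipped += 1
                    continue
                x, y = gz[ok, a], gz[ok, b]
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    skipped += 1
                    continue
                r = float(np.mean(x * y) / (sx * sy))
                rows.append(
                    (
                        ds.variant_ids[cols[a]],
                        ds.variant_ids[cols[b]],
                        int(pos[b] - pos[a]),
                        (gmap[b] - gmap[a]) / 100.0,  # cM -> Morgan
                        min(r * r, 1.0),
                    )
                )
    df = pd.DataFrame(rows, columns=["id1", "id2", "dist_bp", "c_morgan", "r2"])
    df.attrs["skipped"] = skipped
    return df


def ld_decay(pairs: pd.DataFrame, bin_edges_bp) -> pd.DataFrame:
    """Arithmetic mean r^2 per physical-distance bin; empty bins flagged."""
    if pairs.empty:
        raise ValueError("no LD pairs supplied")
    edges = np.asarray(bin_edges_bp, dtype=float)
    idx = np.digitize(pairs["dist_bp"], edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        rows.append(
            {
                "bin_mid_bp": (edges[b] + edges[b + 1]) / 2.0,
                "mean_r2": float(pairs.loc[sel, "r2"].mean()) if sel.any() else np.nan,
                "n_pairs": int(sel.sum()),
                "empty": not sel.any(),
            }
        )
    return pd.DataFrame(rows)


def sved_ne(r2_mean: float, c_morgan: float) -> float:
    """Sved's relation N_Et = (1/4c)(1/r2 - 1)."""
    if c_morgan <= 0:
        raise ValueError("c must be positive")
    if r2_mean >= 1.0:
        return 0.0
    return (1.0 / (4.0 * c_morgan)) * (1.0 / r2_mean - 1.0)


def ne_trajectory(pairs: pd.DataFrame, t_grid, tolerance: float = 0.1,
                  min_pairs: int = 50, sample_size: int | None = None) -> pd.DataFrame:
    """Effective population size t generations ago for each t in ``t_grid``.

    For each t the target genetic distance is c* = 1/(2t); pairs with
    c in c*(1 +/- tolerance) contribute their mean r^2 (optionally reduced by
    the 1/n sampling adjustment when ``sample_size`` is given), and
    N_Et = (1/4c*)(1/r2 - 1).  Bins with fewer than ``min_pairs`` pairs are
    flagged unreliable; r2 <= 0 after adjustment is flagged unstable.
    """
    rows = []
    c_all = pairs["c_morgan"].to_numpy()
    r2_all = pairs["r2"].to_numpy()
    for t in t_grid:
        if t <= 0:
            raise ValueError("t grid must be positive")
        c_star = 1.0 / (2.0 * t)
        sel = (c_all >= c_star * (1 - tolerance)) & (c_all <= c_star * (1 + tolerance))
        n = int(sel.sum())
        row = {"t": int(t), "c_morgan": c_star, "n_pairs": n,
               "reliable": n >= min_pairs, "flag": ""}
        if n == 0:
            row.update(mean_r2=np.nan, ne=np.nan, flag="empty")
        else:
            r2 = float(r2_all[sel].mean())
            row["mean_r2"] = r2
            if sample_size is not None:
                r2 = r2 - 1.0 / sample_size
            if r2 >= 1.0:
                row.update(ne=0.0, flag="r2>=1")
            elif r2 <= 0.0:
                row.update(ne=np.inf, flag="unstable")
            else:
                row["ne"] = sved_ne(r2, c_star)
        rows.append(row)
    return pd.DataFrame(rows)
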