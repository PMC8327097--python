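"""Population structure: genotype PCA and neighbor-joining from F_ST distances."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class PcaResult:
    coordinates: pd.DataFrame     # sample_id, population, pc1..pck
    variance_fraction: np.ndarray  # per component, non-increasing


def pca(ds: GenotypeDataset, k: int = 10, scaling: str = "patterson") -> PcaResult:
    """PCA of the genotype matrix.

    Missing genotypes are mean-imputed per SNP; columns are centered by 2*p
    and, with Patterson scaling (default), divided by sqrt(2p(1-p)).
    ``scaling='center'`` skips the variance normalization.  Variance fractions
    are eigenvalue shares of the full decomposition.
    """
    g = ds.genotype.astype(float)
    g[g == MISSING] = np.nan
    p = ds.alt_freq()
    keep = ~np.isnan(p) & (p > 0) & (p < 1)
    g = g[:, keep]
    p = p[keep]
    mean = 2.0 * p
    g = np.where(np.isnan(g), mean[None, :], g) - mean[None, :]
    if scaling == "patterson":
        g /= np.sqrt(2.0 * p * (1.0 - p))[None, :]
    elif scaling != "center":
        raise ValueError(f"unknown scaling {scaling!r}")

    u, s, _ = np.linalg.svd(g, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds matrix rank {rank}; truncating")
        k = rank
    ev = s**2
    frac = ev / ev.sum()
    coords = u[:, :k] * s[:k]
    df = pd.DataFrame(coords, columns=[f"pc{i + 1}" for i in range(k)])
    df.insert(0, "population", ds.population_labels)
    df.insert(0, "sample_id", ds.sample_ids)
    return PcaResult(coordinates=df, variance_fraction=frac[:k])


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dist: pd.DataFrame) -> str:
    """Saitou–Nei neighbor-joining tree in Newick text.

    Standard Q-matrix pair selection with deterministic tie-breaking by label
    order; negative branch lengths are clamped to zero with the deficit moved
    to the sister branch of the same join.
    """
    labels = list(dist.index)
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(labels) < 3:
        raise ValueError("NJ needs at least 3 taxa")

    nodes = [_Node(label=str(l)) for l in labels]
    active = list(range(len(labels)))
    d = d.copy()

    while len(active) > 2:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, nodes[i].label or "", nodes[j].label or "")
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        # clamp a negative branch; move the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        new.label = min(x for x in (nodes[i].label, nodes[j].label) if x is not None) \
            if (nodes[i].label or nodes[j].label) else None
        # distances from the new node
        dk = {m: 0.5 * (d[i, m] + d[j, m] - d[i, j]) for m in active if m not in (i, j)}
        nodes.append(new)
        d = np.pad(d, ((0, 1), (0, 1)))
        ni = d.shape[0] - 1
        for m, val in dk.items():
            d[ni, m] = d[m, ni] = max(val, 0.0)
        active = [m for m in active if m not in (i, j)] + [ni]

    i, j = active
    root = _Node(children=[(nodes[i], 0.5 * d[i, j]), (nodes[j], 0.5 * d[i, j])])
    return root.newick() + ";"
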