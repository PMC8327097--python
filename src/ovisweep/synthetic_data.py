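"""Seeded genotype/haplotype simulators with known ground truth.

The divergence model is Balding–Nichols: per-population allele frequencies are
Beta-distributed around an ancestral frequency with F_ST as an explicit
parameter, so estimator-recovery tests can compare against the programmed F.
Haplotype LD is produced by building each haplotype as a Markov mosaic over a
finite founder pool per population.  Founder pools carry exact allele counts
(stochastically rounded K*p_k), so the realized population frequency equals
the Balding–Nichols draw and the mosaic adds linkage structure without adding
between-population drift on top of the programmed F.

Every generator is deterministic under its seed and returns its ground truth
(population frequencies, sweep locus, autozygous tracts) alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genotype_io import MISSING, GenotypeDataset, HaplotypeSet


@dataclass
class SweepSpec:
    """A hard/soft sweep: carriers share one donor haplotype over a tract."""

    population: str
    core_bp: int
    carrier_fraction: float = 0.8
    tract_length_bp: int = 1_000_000

    def __post_init__(self):
        if not 0 < self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in (0, 1]")


@dataclass
class SimConfig:
    """Parameters of the two-(or more-)population array simulator."""

    n_pops: int = 2
    n_per_pop: int = 50
    n_variants: int = 2000
    chrom_length_bp: int = 50_000_000
    chrom: str = "1"
    target_fst: float = 0.10
    mosaic_switch_rate: float = 1e-6  # per bp; ~1 Mb founder segments
    founders_per_pop: int | None = 20  # None => unlinked site-iid draws
    missing_rate: float = 0.0
    rng_seed: int = 0
    pop_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mosaic_switch_rate < 0:
            raise ValueError("mosaic_switch_rate must be >= 0")
        if self.rng_seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if not self.pop_names:
            self.pop_names = [f"POP{k + 1}" for k in range(self.n_pops)]


def _balding_nichols_freqs(rng, p_anc: np.ndarray, fst: float, n_pops: int) -> np.ndarray:
    """Per-population frequencies p_k ~ Beta(p(1-F)/F, q(1-F)/F); p_k = p at F=0."""
    if fst == 0.0:
        return np.tile(p_anc, (n_pops, 1))
    ratio = (1.0 - fst) / fst
    a = p_anc * ratio
    b = (1.0 - p_anc) * ratio
    return rng.beta(a, b, size=(n_pops, len(p_anc)))


def _founder_pool(rng, p_k: np.ndarray, k_founders: int) -> np.ndarray:
    """(k_founders, m) binary pool whose column counts are rounded K*p_k."""
    m = len(p_k)
    exact = k_founders * p_k
    counts = np.floor(exact).astype(int)
    counts += (rng.random(m) < (exact - counts)).astype(int)
    pool = np.zeros((k_founders, m), dtype=np.uint8)
    for j in range(m):
        if counts[j]:
            pool[rng.permutation(k_founders)[: counts[j]], j] = 1
    return pool


def _mosaic_haplotypes(rng, pool: np.ndarray, n_haps: int, pos: np.ndarray,
                       switch_rate: float) -> np.ndarray:
    """Markov mosaic: founder index switches between adjacent SNPs with
    probability 1 - exp(-rate * gap)."""
    k, m = pool.shape
    p_switch = 1.0 - np.exp(-switch_rate * np.diff(pos))
    switch = rng.random((n_haps, m - 1)) < p_switch
    seg_id = np.zeros((n_haps, m), dtype=np.int64)
    seg_id[:, 1:] = np.cumsum(switch, axis=1)
    max_seg = int(seg_id[:, -1].max()) + 1
    founders = rng.integers(0, k, size=(n_haps, max_seg))
    fidx = np.take_along_axis(founders, seg_id, axis=1)
    return pool[fidx, np.arange(m)[None, :]]


def simulate_divergent_pops(cfg: SimConfig):
    """Simulate diverged populations; returns (GenotypeDataset, HaplotypeSet, truth).

    truth maps: ``ancestral_freq`` (m,), ``pop_freq`` (n_pops, m) — the
    Balding–Nichols draws whose between-population variance carries the
    programmed F_ST.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    m = cfg.n_variants
    pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length_bp + 1), size=m, replace=False))
    p_anc = rng.uniform(0.05, 0.95, size=m)
    p_pop = _balding_nichols_freqs(rng, p_anc, cfg.target_fst, cfg.n_pops)

    hap_blocks = []
    for kpop in range(cfg.n_pops):
        n_h = 2 * cfg.n_per_pop
        if cfg.founders_per_pop is None:
            haps = (rng.random((n_h, m)) < p_pop[kpop]).astype(np.uint8)
        else:
            pool = _founder_pool(rng, p_pop[kpop], cfg.founders_per_pop)
            haps = _mosaic_haplotypes(rng, pool, n_h, pos, cfg.mosaic_switch_rate)
        hap_blocks.append(haps)
    haplotypes = np.vstack(hap_blocks)

    sample_ids = [
        f"{cfg.pop_names[k]}_{i:03d}" for k in range(cfg.n_pops) for i in range(cfg.n_per_pop)
    ]
    labels = [cfg.pop_names[k] for k in range(cfg.n_pops) for _ in range(cfg.n_per_pop)]
    vids = [f"snp{j + 1}" for j in range(m)]
    chrom = np.array([cfg.chrom] * m, dtype=object)

    hs = HaplotypeSet(
        sample_ids=sample_ids,
        population_labels=labels,
        variant_ids=vids,
        chrom=chrom,
        pos_bp=pos,
        haplotypes=haplotypes,
    )
    geno = hs.genotypes()
    if cfg.missing_rate > 0:
        mask = rng.random(geno.shape) < cfg.missing_rate
        geno = np.where(mask, MISSING, geno).astype(np.int8)
    ds = GenotypeDataset(
        sample_ids=sample_ids,
        population_labels=labels,
        variant_ids=vids,
        chrom=chrom.copy(),
        pos_bp=pos.copy(),
        genotype=geno,
    )
    truth = {"ancestral_freq": p_anc, "pop_freq": p_pop, "pos_bp": pos}
    return ds, hs, truth


def inject_sweep(hs: HaplotypeSet, spec: SweepSpec, rng_seed: int = 0,
                 eroded: bool = False) -> HaplotypeSet:
    """Overwrite a fraction of one population's haplotypes with a shared donor
    haplotype across [core - tract/2, core + tract/2] (an incomplete hard
    sweep: perfect haplotype homozygosity among carriers inside the tract).

    With ``eroded=True`` each carrier's shared extent on each side of the
    core is drawn Exponential(mean = tract/4), truncated at tract/2 so that
    sharing never exceeds the tract bounds: recombination has eroded the
    flanks.  EHH among carriers then decays away from the core and the
    XP-EHH signal peaks at the core instead of being flat across the tract.
    """
    rng = np.random.default_rng(rng_seed)
    chrom_max = int(hs.pos_bp.max())
    lo = spec.core_bp - spec.tract_length_bp // 2
    hi = spec.core_bp + spec.tract_length_bp // 2
    if not 1 <= spec.core_bp <= chrom_max:
        raise ValueError("sweep core outside chromosome")
    if lo < 1 or hi > chrom_max:
        warnings.warn("sweep tract clipped to chromosome bounds")
        lo, hi = max(lo, 1), min(hi, chrom_max)
    in_tract = (hs.pos_bp >= lo) & (hs.pos_bp <= hi)

    hap_pops = np.array(hs.haplotype_population_labels(), dtype=object)
    pop_hap_idx = np.flatnonzero(hap_pops == spec.population)
    if pop_hap_idx.size == 0:
        raise ValueError(f"no haplotypes in population {spec.population!r}")
    n_carriers = max(2, int(round(spec.carrier_fraction * pop_hap_idx.size)))
    carriers = rng.choice(pop_hap_idx, size=min(n_carriers, pop_hap_idx.size), replace=False)
    donor_full = hs.haplotypes[carriers[0]].copy()

    haps = hs.haplotypes.copy()
    if not eroded:
        cols = np.flatnonzero(in_tract)
        haps[np.ix_(carriers, cols)] = donor_full[cols]
    else:
        scale = spec.tract_length_bp / 4.0
        cap = spec.tract_length_bp / 2.0
        for h in carriers:
            left = spec.core_bp - min(rng.exponential(scale), cap)
            right = spec.core_bp + min(rng.exponential(scale), cap)
            cols = np.flatnonzero((hs.pos_bp >= left) & (hs.pos_bp <= right))
            haps[h, cols] = donor_full[cols]
    return replace(hs, haplotypes=haps)


def _merge_tracts(tracts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in sorted(tracts):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(t) for t in merged]


def inject_autozygosity(ds: GenotypeDataset, per_sample_tracts: dict,
                        hs: HaplotypeSet | None = None, rng_seed: int = 0):
    """Force homozygosity inside per-sample (start_bp, stop_bp) tracts.

    With a paired HaplotypeSet the second haplotype is overwritten by the
    first and genotypes recomputed; otherwise heterozygous calls inside the
    tract are resolved to a seeded random homozygote.  Overlapping tracts for
    one sample are merged.  Returns (dataset, haplotypes-or-None, true tracts).
    """
    rng = np.random.default_rng(rng_seed)
    geno = ds.genotype.copy()
    haps = None if hs is None else hs.haplotypes.copy()
    chrom_max = int(ds.pos_bp.max())
    truth: dict[str, list[tuple[int, int]]] = {}
    sidx = {s: i for i, s in enumerate(ds.sample_ids)}
    for sid, tracts in per_sample_tracts.items():
        merged = _merge_tracts([tuple(t) for t in tracts])
        for a, b in merged:
            if a < 1 or b > chrom_max:
                raise ValueError(f"tract ({a}, {b}) outside chromosome bounds")
        truth[sid] = merged
        i = sidx[sid]
        for a, b in merged:
            cols = np.flatnonzero((ds.pos_bp >= a) & (ds.pos_bp <= b))
            if haps is not None:
                haps[2 * i + 1, cols] = haps[2 * i, cols]
                geno[i, cols] = (haps[2 * i, cols] * 2).astype(np.int8)
            else:
                het = cols[geno[i, cols] == 1]
                geno[i, het] = (rng.random(het.size) < 0.5).astype(np.int8) * 2
    out_ds = replace(ds, genotype=geno)
    out_hs = None if hs is None else replace(hs, haplotypes=haps)
    return out_ds, out_hs, truth


def forward_wright_fisher(n_diploid: int, n_generations: int, chrom_length_bp: int,
                          mut_rate: float, recomb_rate: float, seed: int,
                          n_sites: int = 500, init: str = "standing") -> HaplotypeSet:
    """Discrete-generation Wright–Fisher simulation with recombination.

    A fixed grid of ``n_sites`` sites is tracked on one chromosome.  Each
    offspring haplotype is a recombinant of one random parent's two haplotypes
    (crossover count Poisson with mean recomb_rate * chrom_length_bp, uniform
    breakpoints); mutation flips each allele with probability ``mut_rate`` per
    site per generation.  ``init='standing'`` starts from site-independent
    standing variation (frequencies Uniform(0.05, 0.95)); ``'monomorphic'``
    starts all-zero.  LD in the output reflects the constant population size.
    """
    if n_diploid > 200 or n_generations > 2000:
        raise ValueError("desk-scale limits exceeded")
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, chrom_length_bp + 1), size=n_sites, replace=False))
    n_h = 2 * n_diploid
    if init == "standing":
        p0 = rng.uniform(0.05, 0.95, size=n_sites)
        haps = (rng.random((n_h, n_sites)) < p0).astype(np.uint8)
    elif init == "monomorphic":
        haps = np.zeros((n_h, n_sites), dtype=np.uint8)
    else:
        raise ValueError(f"unknown init {init!r}")

    mean_xo = recomb_rate * chrom_length_bp
    for _ in range(n_generations):
        parents = rng.integers(0, n_diploid, size=n_h)
        n_xo = rng.poisson(mean_xo, size=n_h)
        start_hap = rng.integers(0, 2, size=n_h)
        children = np.empty_like(haps)
        for c in range(n_h):
            pa, pb = haps[2 * parents[c]], haps[2 * parents[c] + 1]
            if n_xo[c] == 0:
                children[c] = pa if start_hap[c] == 0 else pb
            else:
                breaks = np.sort(rng.integers(1, chrom_length_bp + 1, size=n_xo[c]))
                seg = np.searchsorted(breaks, pos, side="left")
                use_a = (seg + start_hap[c]) % 2 == 0
                children[c] = np.where(use_a, pa, pb)
        if mut_rate > 0:
            flips = rng.random(children.shape) < mut_rate
            children ^= flips.astype(np.uint8)
        haps = children

    sample_ids = [f"wf_{i:03d}" for i in range(n_diploid)]
    return HaplotypeSet(
        sample_ids=sample_ids,
        population_labels=["WF"] * n_diploid,
        variant_ids=[f"s{j + 1}" for j in range(n_sites)],
        chrom=np.array(["1"] * n_sites, dtype=object),
        pos_bp=pos,
        haplotypes=haps,
        map_cm=pos * recomb_rate * 100.0,
    )
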