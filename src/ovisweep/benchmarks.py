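"""Self-contained evaluation scenarios for the whole pipeline.

Each function sets up a seeded synthetic scenario with known ground truth,
runs the corresponding analysis stage, and returns the recovered quantity.
The scenario parameters are the package's reference study conditions and are
shared between the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .diversity import wc_theta
from .ld_ne import ne_trajectory, pairwise_r2
from .roh import detect_roh, froh
from .selection_scan import window_fst_scan, xpehh_scan
from .synthetic_data import (
    SimConfig,
    SweepSpec,
    forward_wright_fisher,
    inject_autozygosity,
    inject_sweep,
    simulate_divergent_pops,
)


def theta_recovery(base_seed: int = 0, n_seeds: int = 10, target_fst: float = 0.10,
                   n_per_pop: int = 100, n_variants: int = 5000) -> float:
    """Mean multi-locus Weir–Cockerham theta over seeded Balding–Nichols
    replicates with the given programmed F_ST."""
    thetas = []
    for k in range(n_seeds):
        cfg = SimConfig(n_per_pop=n_per_pop, n_variants=n_variants,
                        target_fst=target_fst, rng_seed=base_seed + k)
        ds, _, _ = simulate_divergent_pops(cfg)
        thetas.append(wc_theta(ds, ds.samples_by_population()))
    return float(np.mean(thetas))


def sweep_localization(base_seed: int = 0, n_reps: int = 10,
                       carrier_fraction: float = 0.8,
                       tract_length_bp: int = 1_000_000) -> tuple[int, int]:
    """(hits, reps): how often the top positive XP-EHH SNP falls within
    100 kb of an injected sweep core.

    Scenario: two populations (n=40 each, F=0.02), 2,000 SNPs on a 20 Mb
    chromosome, 100 founder haplotypes per pool, recombination-eroded sweep
    at mid-chromosome in the first population.
    """
    core = 10_000_000
    hits = 0
    for k in range(n_reps):
        cfg = SimConfig(n_per_pop=40, n_variants=2000, chrom_length_bp=20_000_000,
                        target_fst=0.02, founders_per_pop=100,
                        rng_seed=base_seed + k)
        _, hs, _ = simulate_divergent_pops(cfg)
        swept = inject_sweep(
            hs,
            SweepSpec("POP1", core_bp=core, carrier_fraction=carrier_fraction,
                      tract_length_bp=tract_length_bp),
            rng_seed=base_seed + k + 10_000,
            eroded=True,
        )
        rec = xpehh_scan(swept.subset_population("POP1"),
                         swept.subset_population("POP2"))
        top = rec.loc[rec["z"].idxmax()]
        if abs(int(top["pos_bp"]) - core) <= 100_000:
            hits += 1
    return hits, n_reps


def froh_recovery(seed: int = 0) -> tuple[float, float, float]:
    """(estimated F_ROH, true tract ratio, relative error) for one individual
    with programmed autozygous tracts totalling 24.5 Mb (truth F_ROH = 0.01
    against the 2.45 Gb autosome)."""
    cfg = SimConfig(n_per_pop=12, n_variants=4000, chrom_length_bp=60_000_000,
                    target_fst=0.0, rng_seed=seed)
    ds, hs, _ = simulate_divergent_pops(cfg)
    sid = ds.sample_ids[0]
    tracts = [(5_000_000, 17_250_000), (30_000_000, 42_250_000)]  # 24.5 Mb
    ds2, _, truth = inject_autozygosity(ds, {sid: tracts}, hs=hs)
    segs = [s for s in detect_roh(ds2) if s.sample_id == sid]
    est = froh(segs, [sid]).set_index("sample_id").loc[sid, "f_roh"]
    true = sum(b - a for a, b in truth[sid]) / 2.45e9
    return float(est), float(true), float(abs(est - true) / true)


def wf_ne_recovery(base_seed: int = 0, n_seeds: int = 5,
                   t_grid=(20, 25, 33, 50)) -> np.ndarray:
    """Mean Sved N_E per recent generation bin from constant-size (N=50)
    Wright–Fisher simulations (200 generations, 5 Mb, 1 cM/Mb)."""
    nes = []
    for k in range(n_seeds):
        hs = forward_wright_fisher(50, 200, 5_000_000, 5e-4, 1e-8,
                                   seed=base_seed + k, n_sites=600)
        ds = hs.to_genotype_dataset()
        p = ds.alt_freq()
        ds = ds.take_variants(np.flatnonzero((p >= 0.05) & (p <= 0.95)))
        pairs = pairwise_r2(ds, max_dist_bp=5e6)
        nes.append(ne_trajectory(pairs, list(t_grid))["ne"].to_numpy())
    return np.nanmean(np.array(nes, dtype=float), axis=0)


def xpehh_null_tail(base_seed: int = 0, n_seeds: int = 5,
                    p_threshold: float = 0.001) -> tuple[float, float]:
    """(upper-tail, lower-tail) fraction of SNPs significant at the threshold
    under pure neutrality (no sweep, F=0, independent sites)."""
    na = nb = ntot = 0
    for k in range(n_seeds):
        cfg = SimConfig(n_per_pop=40, n_variants=1500, chrom_length_bp=15_000_000,
                        target_fst=0.0, founders_per_pop=None,
                        rng_seed=base_seed + k)
        _, hs, _ = simulate_divergent_pops(cfg)
        rec = xpehh_scan(hs.subset_population("POP1"), hs.subset_population("POP2"),
                         p_threshold=p_threshold)
        d = rec[rec["defined"]]
        na += int((d["p_a"] < p_threshold).sum())
        nb += int((d["p_b"] < p_threshold).sum())
        ntot += len(d)
    return na / ntot, nb / ntot


def zfst_candidate_rule(seed: int = 0) -> tuple[int, int]:
    """(n_candidates, n_windows) from a neutral window scan — the top-0.1%
    rule makes n_candidates = ceil(0.001 * n_windows) by construction."""
    cfg = SimConfig(n_per_pop=40, n_variants=3000, chrom_length_bp=60_000_000,
                    target_fst=0.05, rng_seed=seed)
    ds, _, _ = simulate_divergent_pops(cfg)
    res = window_fst_scan(ds, "POP1", "POP2")
    return int(res.windows["candidate"].sum()), len(res.windows)
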