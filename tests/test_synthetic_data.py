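"""Generator contracts: determinism, ground truth, and recoverable signals."""

import numpy as np
import pytest

from ovisweep.diversity import wc_theta
from ovisweep.roh import RohParams, detect_roh, froh
from ovisweep.selection_scan import ehh
from ovisweep.synthetic_data import (
    SimConfig,
    SweepSpec,
    forward_wright_fisher,
    inject_autozygosity,
    inject_sweep,
    simulate_divergent_pops,
)


class TestDivergentPops:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_per_pop=10, n_variants=200, rng_seed=42, missing_rate=0.02)
        ds1, hs1, t1 = simulate_divergent_pops(cfg)
        ds2, hs2, t2 = simulate_divergent_pops(cfg)
        assert np.array_equal(ds1.genotype, ds2.genotype)
        assert np.array_equal(hs1.haplotypes, hs2.haplotypes)
        assert np.array_equal(t1["pop_freq"], t2["pop_freq"])

    def test_genotype_is_haplotype_sum(self, two_pop_sim):
        ds, hs, _ = two_pop_sim
        assert np.array_equal(ds.genotype, hs.genotypes())

    def test_no_divergence_gives_near_zero_theta(self):
        cfg = SimConfig(n_per_pop=100, n_variants=5000, target_fst=0.0, rng_seed=1)
        ds, _, _ = simulate_divergent_pops(cfg)
        assert abs(wc_theta(ds, ds.samples_by_population())) < 0.02

    def test_theta_recovers_programmed_fst(self):
        cfg = SimConfig(n_per_pop=100, n_variants=5000, target_fst=0.10, rng_seed=2)
        ds, _, _ = simulate_divergent_pops(cfg)
        assert wc_theta(ds, ds.samples_by_population()) == pytest.approx(0.10, abs=0.02)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(target_fst=1.0)


class TestInjectSweep:
    def test_full_sweep_gives_unit_ehh_inside_tract(self, two_pop_sim):
        _, hs, _ = two_pop_sim
        core = 4_000_000
        swept = inject_sweep(
            hs, SweepSpec("POP1", core_bp=core, carrier_fraction=1.0,
                          tract_length_bp=2_000_000), rng_seed=0,
        )
        pop_rows = np.flatnonzero(
            np.array(swept.haplotype_population_labels(), dtype=object) == "POP1"
        )
        sub = swept.haplotypes[pop_rows]
        in_tract = np.flatnonzero(
            (swept.pos_bp >= core - 1_000_000) & (swept.pos_bp <= core + 1_000_000)
        )
        core_j = in_tract[len(in_tract) // 2]
        allele = int(sub[0, core_j])
        curve = ehh(sub, core_j, allele)
        inside = curve[np.isin(curve["snp_index"], in_tract)]
        assert (inside["ehh"] == 1.0).all()

    def test_partial_sweep_ehh_lower_bound(self):
        # 40 identical carriers among 80 haplotypes: at the tract edge the
        # carrier pairs alone guarantee EHH >= C(40,2)/C(80,2)
        rng = np.random.default_rng(0)
        haps = rng.integers(0, 2, size=(80, 21)).astype(np.uint8)
        haps[:40] = haps[0]  # identical block
        n_carriers = int((haps[:, 10] == haps[0, 10]).sum())
        curve = ehh(haps, 10, int(haps[0, 10]))
        bound = (40 * 39 / 2) / (n_carriers * (n_carriers - 1) / 2)
        assert (curve["ehh"] >= min(bound, 1.0) - 1e-12).all()

    def test_tract_clipping_warns(self, two_pop_sim):
        _, hs, _ = two_pop_sim
        with pytest.warns(UserWarning, match="clipped"):
            inject_sweep(
                hs, SweepSpec("POP1", core_bp=100_000, tract_length_bp=1_000_000)
            )


class TestInjectAutozygosity:
    def test_tract_recovered_by_roh_detector(self):
        cfg = SimConfig(n_per_pop=20, n_variants=1200, chrom_length_bp=20_000_000,
                        target_fst=0.0, rng_seed=9)
        ds, hs, _ = simulate_divergent_pops(cfg)
        tract = (5_000_000, 7_000_000)
        sid = ds.sample_ids[0]
        ds2, _, truth = inject_autozygosity(ds, {sid: [tract]}, hs=hs)
        segs = [s for s in detect_roh(ds2) if s.sample_id == sid]
        assert len(segs) >= 1
        cover = sum(
            max(0, min(s.stop_bp, tract[1]) - max(s.start_bp, tract[0]))
            for s in segs
        )
        assert cover >= 0.95 * (tract[1] - tract[0])

    def test_froh_forced_by_ratio(self):
        # total ROH of 24.5 Mb against the 2.45 Gb autosome -> F_ROH = 0.01
        from ovisweep.roh import RohSegment

        seg = RohSegment("s", "1", 1_000_000, 25_500_000, 1000, 0, 0)
        out = froh([seg], ["s"])
        assert out.loc[0, "f_roh"] == pytest.approx(0.01)

    def test_overlapping_tracts_merged(self):
        cfg = SimConfig(n_per_pop=5, n_variants=300, chrom_length_bp=20_000_000,
                        rng_seed=3)
        ds, hs, _ = simulate_divergent_pops(cfg)
        sid = ds.sample_ids[0]
        _, _, truth = inject_autozygosity(
            ds, {sid: [(1_000_000, 3_000_000), (2_500_000, 4_000_000)]}, hs=hs
        )
        assert truth[sid] == [(1_000_000, 4_000_000)]

    def test_outbred_background_has_no_roh(self):
        for seed in range(3):
            cfg = SimConfig(n_per_pop=10, n_variants=2000, chrom_length_bp=20_000_000,
                            target_fst=0.0, founders_per_pop=None, rng_seed=seed)
            ds, _, _ = simulate_divergent_pops(cfg)
            assert detect_roh(ds, RohParams()) == []


class TestWrightFisher:
    def test_monomorphic_start_stays_monomorphic_without_mutation(self):
        hs = forward_wright_fisher(20, 50, 1_000_000, 0.0, 1e-8, seed=1,
                                   n_sites=100, init="monomorphic")
        assert not hs.haplotypes.any()

    def test_same_seed_identical(self):
        a = forward_wright_fisher(20, 30, 1_000_000, 1e-4, 1e-8, seed=5, n_sites=50)
        b = forward_wright_fisher(20, 30, 1_000_000, 1e-4, 1e-8, seed=5, n_sites=50)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_desk_scale_limit_enforced(self):
        with pytest.raises(ValueError):
            forward_wright_fisher(500, 10, 1_000_000, 0, 1e-8, seed=0)
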