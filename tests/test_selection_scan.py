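"""Per-SNP F_ST formula, window tiling/Z-scores, EHH/iHH/XP-EHH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_dataset
from oracles import ehh_pair_counting, gap_merge_brute_force
from ovisweep.selection_scan import (
    ehh,
    ihh,
    significant_regions,
    snp_fst,
    tile_windows,
    window_fst_scan,
    xpehh_scan,
)
from ovisweep.synthetic_data import SimConfig, simulate_divergent_pops


class TestSnpFst:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [(0.5, 0.5, 0.0), (1.0, 0.0, 1.0), (0.8, 0.2, 0.36)],
    )
    def test_printed_formula_values(self, p1, p2, expected):
        assert snp_fst(p1, p2) == pytest.approx(expected)

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=30, deadline=None)
    def test_zero_when_frequencies_equal(self, p):
        assert snp_fst(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_one_only_for_fixed_difference(self):
        assert snp_fst(0.0, 1.0) == pytest.approx(1.0)
        assert snp_fst(0.9, 0.1) < 1.0

    def test_pooled_monomorphic_is_nan(self):
        assert np.isnan(snp_fst(0.0, 0.0))


class TestWindowScan:
    def test_tiling_convention(self):
        wins = tile_windows(1_000_000, 200_000, 60_000)
        assert len(wins) == 14
        assert wins[0] == (1, 200_000)
        assert wins[-1] == (780_001, 980_000)

    def _scan_dataset(self, seed=0, m=600):
        cfg = SimConfig(n_per_pop=40, n_variants=m, chrom_length_bp=6_000_000,
                        target_fst=0.05, rng_seed=seed)
        ds, _, _ = simulate_divergent_pops(cfg)
        return ds

    def test_z_normalization_and_candidate_count(self):
        ds = self._scan_dataset()
        res = window_fst_scan(ds, "POP1", "POP2")
        z = res.windows["zfst"]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert res.windows["candidate"].sum() == int(np.ceil(0.001 * len(res.windows)))

    def test_degenerate_scan_raises(self):
        g = np.tile(np.array([0, 2] * 10)[:, None], (1, 60)).astype(np.int8)
        ds = make_dataset(g, pos=np.arange(1, 61) * 10_000,
                          labels=["A"] * 10 + ["B"] * 10)
        with pytest.raises(ValueError, match="degenerate"):
            window_fst_scan(ds, "A", "B", window_bp=100_000, step_bp=50_000)

    @pytest.mark.parametrize("seed", range(10))
    def test_divergent_locus_top_ranked(self, seed):
        ds = self._scan_dataset(seed=seed)
        # plant a strongly differentiated locus at ~3 Mb
        target = np.flatnonzero(np.abs(ds.pos_bp - 3_000_000) < 100_000)
        pops = np.array(ds.population_labels, dtype=object)
        g = ds.genotype.copy()
        rng = np.random.default_rng(seed + 1000)
        for j in target:
            g[pops == "POP1", j] = (rng.random((pops == "POP1").sum()) < 0.05).astype(np.int8) * 2
            g[pops == "POP2", j] = (rng.random((pops == "POP2").sum()) < 0.95).astype(np.int8) * 2
        ds.genotype = g
        res = window_fst_scan(ds, "POP1", "POP2")
        top = res.windows.sort_values("zfst").iloc[-1]
        assert top["start_bp"] <= 3_100_000 and top["stop_bp"] >= 2_900_000


class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        haps = np.tile(np.array([1, 0, 1, 0, 1], dtype=np.uint8), (6, 1))
        curve = ehh(haps, 2, 1)
        assert (curve["ehh"] == 1.0).all()

    def test_two_two_split(self):
        haps = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], dtype=np.uint8)
        curve = ehh(haps, 0, 1)
        assert curve.set_index("snp_index").loc[1, "ehh"] == pytest.approx(1 / 3)

    def test_non_increasing_outward(self):
        rng = np.random.default_rng(4)
        haps = rng.integers(0, 2, (30, 80)).astype(np.uint8)
        curve = ehh(haps, 40, int(haps[0, 40]))
        vals = curve["ehh"].to_numpy()
        core_pos = int(np.flatnonzero(curve["snp_index"] == 40)[0])
        assert (np.diff(vals[core_pos:]) <= 1e-12).all()
        assert (np.diff(vals[:core_pos + 1]) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, (50, 60)).astype(np.uint8)
        # correlate columns a bit so groups persist
        haps[:, 1::2] = haps[:, 0::2]
        core = 30
        for allele in (0, 1):
            curve = ehh(haps, core, allele).set_index("snp_index")["ehh"]
            for j in curve.index:
                assert curve.loc[j] == pytest.approx(
                    ehh_pair_counting(haps, core, allele, j)
                )

    def test_single_carrier_undefined(self):
        haps = np.zeros((4, 5), dtype=np.uint8)
        haps[0, 2] = 1
        with pytest.raises(ValueError):
            ehh(haps, 2, 1)


class TestIhh:
    def test_flat_curve_rectangle(self):
        # EHH == 1 over 1 cM on each side -> iHH = 2 cM units
        curve = pd.DataFrame({"snp_index": [0, 1, 2, 3, 4],
                              "ehh": [1.0, 1.0, 1.0, 1.0, 1.0]})
        map_cm = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        assert ihh(curve, map_cm, 2) == pytest.approx(2.0)

    def test_truncation_stops_after_crossing(self):
        curve = pd.DataFrame({"snp_index": [0, 1, 2, 3],
                              "ehh": [1.0, 0.5, 0.01, 0.8]})
        map_cm = np.array([0.0, 1.0, 2.0, 3.0])
        # right side only: trapezoids (1+0.5)/2 + (0.5+0.01)/2, nothing past
        assert ihh(curve, map_cm, 0) == pytest.approx(0.75 + 0.255)

    def test_refinement_oracle_on_smooth_curve(self):
        f = lambda x: np.exp(-3 * x)
        coarse_x = np.linspace(0, 1, 12)
        dense_x = np.linspace(0, 1, 111)

        def integral(xs):
            curve = pd.DataFrame({"snp_index": np.arange(len(xs)), "ehh": f(xs)})
            return ihh(curve, xs, 0, truncation=0.0)

        assert integral(coarse_x) == pytest.approx(integral(dense_x), rel=0.05)


class TestXpehh:
    def _pair(self, seed=0, sweep=False):
        import dataclasses

        from ovisweep.synthetic_data import SweepSpec, inject_sweep

        cfg = SimConfig(n_per_pop=20, n_variants=300, chrom_length_bp=6_000_000,
                        target_fst=0.0, rng_seed=seed)
        _, hs, _ = simulate_divergent_pops(cfg)
        if sweep:
            hs = inject_sweep(
                hs, SweepSpec("POP1", core_bp=3_000_000, carrier_fraction=0.8,
                              tract_length_bp=1_000_000), rng_seed=seed,
            )
        hap_pops = np.array(hs.haplotype_population_labels(), dtype=object)

        def sub(pop):
            rows = np.flatnonzero(hap_pops == pop)
            samp = [s for s, p in zip(hs.sample_ids, hs.population_labels) if p == pop]
            return dataclasses.replace(
                hs, sample_ids=samp, population_labels=[pop] * len(samp),
                haplotypes=hs.haplotypes[rows],
            )

        return sub("POP1"), sub("POP2")

    def test_identical_populations_raw_zero(self):
        a, _ = self._pair()
        with pytest.raises(ValueError, match="zero variance"):
            xpehh_scan(a, a)  # raw == 0 everywhere -> degenerate by design

    def test_swap_antisymmetry(self):
        a, b = self._pair(seed=2)
        ab = xpehh_scan(a, b)
        ba = xpehh_scan(b, a)
        d = ab["defined"] & ba["defined"]
        assert np.allclose(ab.loc[d, "raw"], -ba.loc[d, "raw"])
        assert np.allclose(np.abs(ab.loc[d, "z"]), np.abs(ba.loc[d, "z"]), atol=1e-9)

    def test_sweep_produces_positive_scores_at_core(self):
        a, b = self._pair(seed=3, sweep=True)
        rec = xpehh_scan(a, b)
        near = rec[np.abs(rec["pos_bp"] - 3_000_000) < 300_000]
        assert near["z"].mean() > 1.0

    def test_z_standardization(self):
        a, b = self._pair(seed=4)
        rec = xpehh_scan(a, b)
        d = rec[rec["defined"]]
        assert d["z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert d["z"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


class TestSignificantRegions:
    def _records(self, positions, sig, direction="A"):
        return pd.DataFrame(
            {
                "chrom": "1",
                "pos_bp": positions,
                "significant": sig,
                "direction": [direction if s else "" for s in sig],
            }
        )

    def test_no_significant_empty(self):
        assert significant_regions(self._records([100, 200], [False, False])) == []

    def test_two_close_snps_merged(self):
        out = significant_regions(
            self._records([100_000, 150_000], [True, True]), merge_gap_bp=200_000
        )
        assert len(out) == 1
        assert (out[0].start_bp, out[0].stop_bp) == (100_000, 150_000)

    def test_matches_gap_merge_oracle(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(np.arange(1, 10**7), 200, replace=False))
        sig = rng.random(200) < 0.15
        out = significant_regions(self._records(pos, sig), merge_gap_bp=150_000)
        expected = gap_merge_brute_force(pos[sig], 150_000)
        assert [(iv.start_bp, iv.stop_bp) for iv in out] == expected
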