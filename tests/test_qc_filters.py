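"""QC rules, exact HWE test, Pi-HAT relatedness, and LD pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_dataset
from oracles import hwe_exact_enumeration
from ovisweep.genotype_io import MISSING
from ovisweep.qc_filters import (
    QcThresholds,
    RelatednessMatrix,
    filter_samples,
    filter_variants,
    hwe_exact_p,
    ld_prune,
    pihat_cutoff_midpoint,
    pihat_matrix,
    relatedness_prune,
)
from ovisweep.synthetic_data import SimConfig, simulate_divergent_pops


class TestHweExact:
    def test_all_homozygous_is_one(self):
        assert hwe_exact_p(12, 0, 0) == 1.0

    def test_small_full_enumeration(self):
        assert hwe_exact_p(0, 4, 0) == pytest.approx(hwe_exact_enumeration(0, 4, 0))

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        assert hwe_exact_p(aa, ab, bb) == pytest.approx(
            hwe_exact_enumeration(aa, ab, bb), rel=1e-9
        )

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_in_homozygote_swap(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        assert hwe_exact_p(aa, ab, bb) == pytest.approx(hwe_exact_p(bb, ab, aa))

    def test_zero_samples_undefined(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)


class TestVariantFilters:
    def test_low_call_rate_removed(self):
        g = np.ones((20, 2), dtype=np.int8)
        g[:, 1] = np.where(np.arange(20) < 3, MISSING, 1)  # 85% call rate
        g[::2, 0] = 0
        g[::2, 1][g[::2, 1] != MISSING] = 0
        ds = make_dataset(g)
        kept, report = filter_variants(ds)
        assert report["removed_call_rate"] == 1
        assert kept.variant_ids == ["v0"]

    def test_monomorphic_removed_by_maf(self):
        g = np.zeros((30, 2), dtype=np.int8)
        g[:15, 0] = 1  # v0 polymorphic, v1 monomorphic
        kept, report = filter_variants(make_dataset(g))
        assert report["removed_maf"] == 1
        assert kept.variant_ids == ["v0"]

    def test_all_heterozygous_fails_hwe(self):
        g = np.ones((100, 2), dtype=np.int8)
        g[:25, 0] = 0
        g[25:75, 0] = 1
        g[75:, 0] = 2  # v0 at HWE proportions, v1 all-het
        assert hwe_exact_p(0, 100, 0) < 1e-10
        kept, report = filter_variants(make_dataset(g))
        assert report["removed_hwe"] == 1
        assert kept.variant_ids == ["v0"]


class TestSampleFilter:
    def test_boundary_is_more_than_ten_percent(self):
        g = np.zeros((3, 20), dtype=np.int8)
        g[0, :15] = 1
        g[1, :3] = MISSING   # 15% -> removed
        g[2, :2] = MISSING   # exactly 10% -> retained
        kept, report = filter_samples(make_dataset(g))
        assert report["removed_missingness"] == ["s1"]
        assert "s2" in kept.sample_ids

    def test_recount_oracle_on_random_missingness(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(40, 200)).astype(np.int8)
        mask = rng.random(g.shape) < 0.08
        g[mask] = MISSING
        ds = make_dataset(g)
        _, report = filter_samples(ds)
        naive = [
            ds.sample_ids[i]
            for i in range(40)
            if (g[i] == MISSING).mean() > 0.10
        ]
        assert report["removed_missingness"] == naive


@pytest.fixture(scope="module")
def unlinked_big():
    cfg = SimConfig(n_per_pop=30, n_variants=10_000, chrom_length_bp=10**8,
                    target_fst=0.0, founders_per_pop=None, rng_seed=13)
    return simulate_divergent_pops(cfg)[0]


class TestPihat:
    def test_duplicate_sample_near_one(self, unlinked_big):
        ds = unlinked_big.take_samples(np.r_[0, 0, np.arange(1, 10)])
        ds.sample_ids[1] = "dup"
        rel = pihat_matrix(ds)
        assert rel.pihat[0, 1] >= 0.95

    def test_unrelated_near_zero(self, unlinked_big):
        rel = pihat_matrix(unlinked_big.take_samples(np.arange(20)))
        off = rel.pihat[np.triu_indices(20, k=1)]
        assert np.abs(off).max() <= 0.05

    def test_parent_offspring_half(self):
        # child inherits one full haplotype from the parent under HWE
        rng = np.random.default_rng(21)
        m = 10_000
        p = rng.uniform(0.1, 0.9, m)
        parent = (rng.random((2, m)) < p).astype(np.int8)
        others = [(rng.random((2, m)) < p).astype(np.int8).sum(0) for _ in range(8)]
        child = parent[0] + (rng.random(m) < p)
        g = np.vstack([parent.sum(0), child] + others).astype(np.int8)
        rel = pihat_matrix(make_dataset(g, pos=np.arange(1, m + 1) * 100))
        assert rel.pihat[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_cutoff_is_degree_midpoint(self):
        assert pihat_cutoff_midpoint(0.25, 0.125) == 0.1875

    def test_single_pair_prunes_one(self):
        p = np.eye(3)
        p[0, 1] = p[1, 0] = 0.25
        rel = RelatednessMatrix(["a", "b", "c"], p)
        kept = relatedness_prune(rel)
        assert len(kept) == 2 and "c" in kept

    def test_postcondition_no_pair_above_cutoff(self):
        rng = np.random.default_rng(5)
        n = 15
        p = np.zeros((n, n))
        idx = np.triu_indices(n, k=1)
        vals = np.where(rng.random(len(idx[0])) < 0.2, rng.uniform(0.2, 0.6, len(idx[0])), 0.0)
        p[idx] = vals
        p = p + p.T + np.eye(n)
        rel = RelatednessMatrix([f"s{i}" for i in range(n)], p)
        kept = relatedness_prune(rel, 0.1875)
        ki = [i for i, s in enumerate(rel.sample_ids) if s in set(kept)]
        sub = p[np.ix_(ki, ki)]
        np.fill_diagonal(sub, 0)
        assert sub.max() <= 0.1875


class TestLdPrune:
    def test_duplicate_snps_one_removed(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, 50).astype(np.int8)
        g = np.column_stack([col, col])
        ds = make_dataset(g, pos=np.array([1000, 2000]))
        kept, removed = ld_prune(ds)
        assert len(removed) == 1 and kept.n_variants == 1

    def test_independent_snps_untouched(self):
        cfg = SimConfig(n_per_pop=100, n_variants=50, chrom_length_bp=40_000,
                        target_fst=0.0, founders_per_pop=None, rng_seed=3)
        ds, _, _ = simulate_divergent_pops(cfg)
        _, removed = ld_prune(ds)
        assert removed == []

    def test_postcondition_rescan(self, two_pop_sim):
        ds, _, _ = two_pop_sim
        kept, _ = ld_prune(ds, window_kb=50, step_kb=5, r2_max=0.5)
        g = kept.genotype.astype(float)
        for a in range(kept.n_variants):
            for b in range(a + 1, kept.n_variants):
                if kept.pos_bp[b] - kept.pos_bp[a] >= 50_000:
                    break
                if g[:, a].std() == 0 or g[:, b].std() == 0:
                    continue
                r = np.corrcoef(g[:, a], g[:, b])[0, 1]
                assert r * r <= 0.5 + 1e-9
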