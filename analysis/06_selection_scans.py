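#!/usr/bin/env python
"""Selection scans: windowed ZF_ST outliers and XP-EHH.

F_ST in 200 kb windows sliding by 60 kb, Z-standardized with the top 0.1%
positive windows as candidates; XP-EHH per SNP from phased haplotypes with
P < 0.001 significance and gap-merged significant regions.  Reports whether
the injected sweep is recovered.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ovisweep.genotype_io import read_plink_text, read_vcf_phased, write_bed
from ovisweep.selection_scan import significant_regions, window_fst_scan, xpehh_scan

BASE = Path(__file__).resolve().parents[1] / "results"
SWEEP_CORE = 10_000_000


def main():
    ds = read_plink_text(BASE / "qc" / "cohort_qc.ped", BASE / "qc" / "cohort_qc.map")
    out = BASE / "selection"
    out.mkdir(parents=True, exist_ok=True)
    pops = sorted(set(ds.population_labels))
    comp = f"{pops[0]}_vs_{pops[1]}"

    scan = window_fst_scan(ds, pops[0], pops[1])
    scan.windows.to_csv(out / f"zfst_{comp}.tsv", sep="\t", index=False,
                        float_format="%.5g")
    top = scan.windows.sort_values("zfst").iloc[-1]
    print(f"ZF_ST: {len(scan.windows)} windows, mu={scan.mu_fst:.4f}, "
          f"sigma={scan.sigma_fst:.4f}; top window "
          f"{top['start_bp']:,.0f}-{top['stop_bp']:,.0f} (Z={top['zfst']:.2f})")
    write_bed(scan.candidate_intervals(tags={f"comparison={comp}"}),
              out / f"zfst_candidates_{comp}.bed")

    hs = read_vcf_phased(BASE / "data" / "cohort.vcf")
    by_id = dict(zip(ds.sample_ids, ds.population_labels))
    hs.population_labels = [by_id.get(s, ".") for s in hs.sample_ids]
    keep = [j for j, v in enumerate(hs.variant_ids) if v in set(ds.variant_ids)]
    import dataclasses

    hs = dataclasses.replace(
        hs, variant_ids=[hs.variant_ids[j] for j in keep], chrom=hs.chrom[keep],
        pos_bp=hs.pos_bp[keep], haplotypes=hs.haplotypes[:, keep],
    )
    rec = xpehh_scan(hs.subset_population(pops[0]), hs.subset_population(pops[1]))
    rec.drop(columns=["defined"]).to_csv(out / f"xpehh_{comp}.tsv", sep="\t",
                                         index=False, float_format="%.5g")
    regions = significant_regions(rec, tags={f"comparison={comp}"})
    write_bed(regions, out / f"xpehh_regions_{comp}.bed")
    topx = rec.loc[rec["z"].idxmax()]
    print(f"XP-EHH: {int(rec['significant'].sum())} significant SNPs in "
          f"{len(regions)} regions; top SNP at {int(topx['pos_bp']):,} bp "
          f"(Z={topx['z']:.2f}), {abs(int(topx['pos_bp']) - SWEEP_CORE) / 1000:.0f} kb "
          f"from the injected core")


if __name__ == "__main__":
    main()
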