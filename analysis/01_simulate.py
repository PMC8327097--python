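#!/usr/bin/env python
"""Generate the reference synthetic cohort for the downstream analyses.

Two populations diverged to F_ST = 0.05 on one 20 Mb chromosome, with a
recombination-eroded sweep (carrier fraction 0.8, 1 Mb tract) injected at
10 Mb in POP1 and two autozygous tracts (totalling 4 Mb) in the first two
POP2 individuals.  Writes PED/MAP + phased VCF + ground-truth TSVs under
results/data/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ovisweep.genotype_io import write_plink_text, write_vcf_phased
from ovisweep.synthetic_data import (
    SimConfig,
    SweepSpec,
    inject_autozygosity,
    inject_sweep,
    simulate_divergent_pops,
)

SEED = 20
OUT = Path(__file__).resolve().parents[1] / "results" / "data"

CONFIG = SimConfig(
    n_pops=2,
    n_per_pop=40,
    n_variants=2000,
    chrom_length_bp=20_000_000,
    target_fst=0.05,
    founders_per_pop=100,
    rng_seed=SEED,
)
SWEEP = SweepSpec(population="POP1", core_bp=10_000_000,
                  carrier_fraction=0.8, tract_length_bp=1_000_000)
ROH_TRACTS = {"POP2_000": [(2_000_000, 4_000_000)],
              "POP2_001": [(14_000_000, 16_000_000)]}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ds, hs, truth = simulate_divergent_pops(CONFIG)
    hs = inject_sweep(hs, SWEEP, rng_seed=SEED + 1, eroded=True)
    ds = hs.to_genotype_dataset()
    ds, hs, roh_truth = inject_autozygosity(ds, ROH_TRACTS, hs=hs, rng_seed=SEED + 2)

    write_plink_text(ds, OUT / "cohort.ped", OUT / "cohort.map")
    write_vcf_phased(hs, OUT / "cohort.vcf")
    pd.DataFrame(
        {"variant_id": ds.variant_ids, "pos_bp": ds.pos_bp,
         "p_pop1": truth["pop_freq"][0], "p_pop2": truth["pop_freq"][1]}
    ).to_csv(OUT / "truth_freqs.tsv", sep="\t", index=False)
    rows = [
        {"sample_id": s, "start_bp": a, "stop_bp": b}
        for s, tr in roh_truth.items()
        for a, b in tr
    ]
    rows.append({"sample_id": f"sweep:{SWEEP.population}",
                 "start_bp": SWEEP.core_bp - SWEEP.tract_length_bp // 2,
                 "stop_bp": SWEEP.core_bp + SWEEP.tract_length_bp // 2})
    pd.DataFrame(rows).to_csv(OUT / "truth_tracts.tsv", sep="\t", index=False)
    print(f"wrote {ds.n_samples} samples x {ds.n_variants} SNPs to {OUT}")
    print(f"sweep core at {SWEEP.core_bp:,} bp in {SWEEP.population}; "
          f"{len(rows) - 1} autozygous tracts programmed")


if __name__ == "__main__":
    main()
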