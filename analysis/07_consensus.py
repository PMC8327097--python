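#!/usr/bin/env python
"""Multi-evidence consensus candidate regions.

Pools the tagged regions from the ROH-island, ZF_ST and XP-EHH stages,
merges overlapping ones into loci, and keeps loci supported by >= 2 methods
and/or >= 2 comparisons — the evidence rule behind the candidate tables.
"""

from pathlib import Path

from ovisweep.genotype_io import read_bed
from ovisweep.regions import consensus_candidates

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    tagged = []
    for bed in sorted((BASE / "roh").glob("private_islands_*.bed")):
        tagged += read_bed(bed)
    for bed in sorted((BASE / "selection").glob("*.bed")):
        tagged += read_bed(bed)
    tagged = [iv for iv in tagged if any(t.startswith("method=") for t in iv.tags)]
    table = consensus_candidates(tagged, min_methods=2, min_comparisons=2)
    out = BASE / "consensus.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(f"{len(tagged)} tagged regions -> {len(table)} consensus loci")
    if not table.empty:
        print(table.to_string(index=False))


if __name__ == "__main__":
    main()
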