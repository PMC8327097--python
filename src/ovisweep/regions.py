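"""Interval arithmetic and multi-evidence consensus candidate regions.

Candidate regions arriving from the different scans (ROH islands, ZF_ST
windows, XP-EHH regions) carry provenance tags ``method=...`` and
``comparison=...``; overlapping regions are merged into loci (single-linkage
on bp overlap) and a locus is retained when it is supported by at least two
distinct methods and/or at least two distinct comparisons.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genotype_io import GenomicInterval


def intersect_intervals(a: list[GenomicInterval], b: list[GenomicInterval]):
    """All (a_i, b_j) pairs with >= 1 bp overlap, with their overlap span.

    Returns a list of (a_interval, b_interval, overlap GenomicInterval).
    Sorted sweep per chromosome; coordinates are 1-based inclusive.
    """
    out = []
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom_b.values():
        ivs.sort(key=lambda x: (x.start_bp, x.stop_bp))
    for ia in sorted(a, key=lambda x: (x.chrom, x.start_bp, x.stop_bp)):
        for ib in by_chrom_b.get(ia.chrom, ()):
            if ib.start_bp > ia.stop_bp:
                break
            if ib.stop_bp < ia.start_bp:
                continue
            out.append(
                (
                    ia,
                    ib,
                    GenomicInterval(
                        chrom=ia.chrom,
                        start_bp=max(ia.start_bp, ib.start_bp),
                        stop_bp=min(ia.stop_bp, ib.stop_bp),
                        tags=ia.tags | ib.tags,
                    ),
                )
            )
    return out


def interval_length_mb(interval: GenomicInterval) -> float:
    """(stop - start)/1e6 rounded half-away-from-zero to 3 decimals — the
    size convention of the reported candidate-region tables."""
    mb = Decimal(interval.stop_bp - interval.start_bp) / Decimal(10**6)
    return float(mb.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def _parse_tags(iv: GenomicInterval):
    methods = {t.split("=", 1)[1] for t in iv.tags if t.startswith("method=")}
    comps = {t.split("=", 1)[1] for t in iv.tags if t.startswith("comparison=")}
    return methods, comps


def consensus_candidates(tagged_regions: list[GenomicInterval],
                         min_methods: int = 2, min_comparisons: int = 2,
                         mode: str = "or") -> pd.DataFrame:
    """Merge overlapping tagged regions into loci and keep multi-evidence ones.

    A locus is retained when distinct supporting methods >= ``min_methods``
    OR distinct comparisons >= ``min_comparisons`` (``mode='and'`` requires
    both).  Output: one row per retained locus with span, size (Mb), and the
    sorted supporting method/comparison sets.  Order-independent and
    idempotent.
    """
    if mode not in ("or", "and"):
        raise ValueError("mode must be 'or' or 'and'")
    for iv in tagged_regions:
        methods, comps = _parse_tags(iv)
        if not methods or not comps:
            raise ValueError(
                f"untagged region {iv.chrom}:{iv.start_bp}-{iv.stop_bp}: "
                "every region needs method= and comparison= tags"
            )
    loci: list[list[GenomicInterval]] = []
    for iv in sorted(tagged_regions, key=lambda x: (x.chrom, x.start_bp, x.stop_bp)):
        if (
            loci
            and loci[-1][0].chrom == iv.chrom
            and iv.start_bp <= max(m.stop_bp for m in loci[-1])
        ):
            loci[-1].append(iv)
        else:
            loci.append([iv])

    rows = []
    for members in loci:
        methods: set[str] = set()
        comps: set[str] = set()
        for iv in members:
            m, c = _parse_tags(iv)
            methods |= m
            comps |= c
        ok_m = len(methods) >= min_methods
        ok_c = len(comps) >= min_comparisons
        keep = (ok_m or ok_c) if mode == "or" else (ok_m and ok_c)
        if not keep:
            continue
        start = min(iv.start_bp for iv in members)
        stop = max(iv.stop_bp for iv in members)
        span = GenomicInterval(chrom=members[0].chrom, start_bp=start, stop_bp=stop)
        rows.append(
            {
                "chrom": span.chrom,
                "start_bp": start,
                "stop_bp": stop,
                "size_mb": interval_length_mb(span),
                "n_methods": len(methods),
                "methods": ",".join(sorted(methods)),
                "n_comparisons": len(comps),
                "comparisons": ",".join(sorted(comps)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start_bp", "stop_bp", "size_mb", "n_methods",
                 "methods", "n_comparisons", "comparisons"],
    )
    if not df.empty:
        key = df["chrom"].astype(str)
        num = pd.to_numeric(key, errors="coerce")
        df = df.assign(_k=np.where(num.notna(), num, np.inf), _k2=key)
        df = df.sort_values(["_k", "_k2", "start_bp"]).drop(columns=["_k", "_k2"])
        df.insert(0, "region", range(1, len(df) + 1))
        df = df.reset_index(drop=True)
    return df


def annotate_regions(regions: list[GenomicInterval],
                     gene_intervals: list[GenomicInterval]) -> pd.DataFrame:
    """List genes (from a user-supplied BED, already read into intervals) with
    >= 1 bp overlap per region, ordered by gene start.  No network lookups."""
    if gene_intervals is None:
        raise ValueError("gene annotation requires a local gene BED")
    rows = []
    for reg in regions:
        hits = [
            g
            for g in gene_intervals
            if g.chrom == reg.chrom
            and g.start_bp <= reg.stop_bp
            and reg.start_bp <= g.stop_bp
        ]
        hits.sort(key=lambda g: (g.start_bp, g.stop_bp))
        names = [";".join(sorted(g.tags)) or f"{g.chrom}:{g.start_bp}" for g in hits]
        rows.append(
            {
                "chrom": reg.chrom,
                "start_bp": reg.start_bp,
                "stop_bp": reg.stop_bp,
                "n_genes": len(names),
                "genes": ",".join(names),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "stop_bp", "n_genes", "genes"])
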