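"""Core genotype/haplotype data model and plain-text I/O.

Genomic coordinates are 1-based inclusive base pairs throughout the package;
only BED export/import converts to/from the 0-based half-open convention.
Genotypes are stored as counts of the alternate allele (0, 1, 2) with -1 for
missing; by default the alternate allele is the minor allele observed at load
time, with ties broken so that the lexicographically smaller allele letter is
the reference.  All diversity and differentiation statistics downstream are
invariant to that orientation.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1

#: chromosome codes dropped when restricting to autosomes (PLINK sheep files
#: may use either letters or the numeric codes 27+ for X/Y/MT; "0" = unmapped)
NON_AUTOSOMAL = {"X", "Y", "XY", "MT", "M", "0"}


class FormatError(ValueError):
    """Raised when an input file violates the expected text dialect."""


def _as_text_lines(source) -> list[str]:
    """Accept a path, a file-like object, or literal text and return lines."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        raise TypeError(f"cannot read from {type(source)!r}")
    return [ln for ln in text.splitlines() if ln.strip()]


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes for a set of samples.

    Attributes
    ----------
    sample_ids, population_labels : per-sample metadata
    variant_ids, chrom, pos_bp : per-variant metadata (pos strictly
        increasing within a chromosome after loading)
    genotype : int8 array (n_samples, n_variants) of alt-allele counts,
        -1 = missing
    alleles : optional (n_variants, 2) array of (ref, alt) letters so that
        PED output is loss-free
    map_cm : optional per-variant genetic position in centimorgans
    """

    sample_ids: list[str]
    population_labels: list[str]
    variant_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    genotype: np.ndarray
    alleles: np.ndarray | None = None
    map_cm: np.ndarray | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, m = self.genotype.shape
        if len(self.sample_ids) != n or len(self.population_labels) != n:
            raise ValueError("sample metadata length mismatch")
        if not (len(self.variant_ids) == len(self.chrom) == len(self.pos_bp) == m):
            raise ValueError("variant metadata length mismatch")
        bad = ~np.isin(self.genotype, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,missing}")
        if (self.pos_bp <= 0).any():
            raise ValueError("positions must be positive 1-based bp")
        for c in dict.fromkeys(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.genotype.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotype.shape[1]

    # -- subsetting ------------------------------------------------------
    def take_samples(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            population_labels=[self.population_labels[i] for i in idx],
            genotype=self.genotype[idx],
            log=dict(self.log),
        )

    def take_variants(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            variant_ids=[self.variant_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            genotype=self.genotype[:, idx],
            alleles=None if self.alleles is None else self.alleles[idx],
            map_cm=None if self.map_cm is None else self.map_cm[idx],
            log=dict(self.log),
        )

    def samples_by_population(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, p in enumerate(self.population_labels):
            out.setdefault(p, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def alt_freq(self, sample_idx=None) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        g = self.genotype if sample_idx is None else self.genotype[sample_idx]
        called = g != MISSING
        n = called.sum(axis=0)
        tot = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def genetic_map_cm(self) -> np.ndarray:
        """Genetic positions; defaults to 1 cM/Mb where no map was supplied."""
        if self.map_cm is not None and np.any(self.map_cm > 0):
            return np.asarray(self.map_cm, dtype=float)
        return self.pos_bp * 1e-6


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes: two rows per sample, no missing alleles."""

    sample_ids: list[str]
    population_labels: list[str]
    variant_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    haplotypes: np.ndarray  # uint8 (2*n_samples, n_variants)
    map_cm: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.validate()

    def validate(self) -> None:
        h, m = self.haplotypes.shape
        if h != 2 * len(self.sample_ids):
            raise ValueError("haplotype count must be 2 x sample count")
        if not (len(self.variant_ids) == len(self.chrom) == len(self.pos_bp) == m):
            raise ValueError("variant metadata length mismatch")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1 with no missing")
        if self.map_cm is not None:
            for c in dict.fromkeys(self.chrom):
                mm = np.asarray(self.map_cm)[self.chrom == c]
                if np.any(np.diff(mm) < 0):
                    raise ValueError(f"map_cm decreasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self) -> np.ndarray:
        """Per-sample alt-allele counts (sum of the two haplotypes)."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def to_genotype_dataset(self) -> GenotypeDataset:
        return GenotypeDataset(
            sample_ids=list(self.sample_ids),
            population_labels=list(self.population_labels),
            variant_ids=list(self.variant_ids),
            chrom=self.chrom.copy(),
            pos_bp=self.pos_bp.copy(),
            genotype=self.genotypes(),
            map_cm=None if self.map_cm is None else np.asarray(self.map_cm).copy(),
        )

    def genetic_map_cm(self) -> np.ndarray:
        if self.map_cm is not None and np.any(np.asarray(self.map_cm) > 0):
            return np.asarray(self.map_cm, dtype=float)
        return self.pos_bp * 1e-6

    def haplotype_population_labels(self) -> list[str]:
        return [p for p in self.population_labels for _ in range(2)]

    def subset_population(self, pop: str) -> "HaplotypeSet":
        """Haplotypes of one population (both haplotypes of each member)."""
        rows = np.flatnonzero(
            np.array(self.haplotype_population_labels(), dtype=object) == pop
        )
        if rows.size == 0:
            raise ValueError(f"no samples in population {pop!r}")
        samp = [s for s, p in zip(self.sample_ids, self.population_labels) if p == pop]
        from dataclasses import replace

        return replace(
            self,
            sample_ids=samp,
            population_labels=[pop] * len(samp),
            haplotypes=self.haplotypes[rows],
        )


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval with provenance tags (method, comparison)."""

    chrom: str
    start_bp: int
    stop_bp: int
    tags: frozenset = frozenset()

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start_bp > self.stop_bp:
            raise ValueError("start_bp must be <= stop_bp")
        object.__setattr__(self, "tags", frozenset(self.tags))

    def length_bp(self) -> int:
        return self.stop_bp - self.start_bp

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp <= other.stop_bp
            and other.start_bp <= self.stop_bp
        )


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def _sort_variant_order(chrom, pos) -> np.ndarray:
    # numeric chromosomes sort numerically, then lexical ones
    def key(i):
        c = str(chrom[i])
        return (0, int(c), pos[i]) if c.isdigit() else (1, c, pos[i])

    return np.asarray(sorted(range(len(pos)), key=key))


def read_plink_text(ped_source, map_source, autosomes_only: bool = True) -> GenotypeDataset:
    """Read PLINK text PED + MAP into a :class:`GenotypeDataset`.

    Alleles are recoded to alt-allele counts (alt = minor allele; ties broken
    lexicographically), "0 0" becomes missing.  Variants are sorted by
    (chromosome, position).  With ``autosomes_only`` (default) X/Y/MT and
    unmapped variants are dropped and the count logged.
    """
    map_rows = [ln.split() for ln in _as_text_lines(map_source)]
    for r in map_rows:
        if len(r) != 4:
            raise FormatError(f"MAP row needs 4 columns, got {len(r)}: {r[:2]}")
    m = len(map_rows)
    chrom = np.array([r[0] for r in map_rows], dtype=object)
    vids = [r[1] for r in map_rows]
    cm = np.array([float(r[2]) for r in map_rows])
    pos = np.array([int(r[3]) for r in map_rows], dtype=np.int64)

    sample_ids, pops, rows = [], [], []
    for ln in _as_text_lines(ped_source):
        f = ln.split()
        if len(f) != 6 + 2 * m:
            raise FormatError(
                f"PED row for sample {f[1] if len(f) > 1 else '?'} has "
                f"{len(f) - 6} allele fields, MAP defines {m} variants"
            )
        pops.append(f[0])
        sample_ids.append(f[1])
        rows.append(f[6:])
    n = len(sample_ids)
    a1 = np.array([r[0::2] for r in rows], dtype=object).reshape(n, m)
    a2 = np.array([r[1::2] for r in rows], dtype=object).reshape(n, m)

    geno = np.full((n, m), MISSING, dtype=np.int8)
    alleles = np.empty((m, 2), dtype=object)
    for j in range(m):
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = sorted(set(col) - {"0"})
        if len(obs) > 2:
            raise FormatError(f"variant {vids[j]} is not biallelic: alleles {obs}")
        if not obs:
            alleles[j] = ("N", "N")
            continue
        if len(obs) == 1:
            ref, alt = obs[0], "N"
        else:
            counts = {a: int(np.sum(col == a)) for a in obs}
            if counts[obs[0]] == counts[obs[1]]:
                ref, alt = obs[0], obs[1]  # tie: lexicographically smaller = ref
            else:
                ref, alt = max(obs, key=counts.get), min(obs, key=counts.get)
        alleles[j] = (ref, alt)
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        g = (a1[:, j] == alt).astype(np.int8) + (a2[:, j] == alt).astype(np.int8)
        geno[:, j] = np.where(miss, MISSING, g)

    ds = GenotypeDataset(
        sample_ids=sample_ids,
        population_labels=pops,
        variant_ids=vids,
        chrom=chrom,
        pos_bp=pos,
        genotype=geno,
        alleles=alleles,
        map_cm=cm,
    )
    order = _sort_variant_order(ds.chrom, ds.pos_bp)
    ds = ds.take_variants(order)
    if autosomes_only:
        keep = np.array(
            [str(c).upper() not in NON_AUTOSOMAL for c in ds.chrom], dtype=bool
        )
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d non-autosomal/unmapped variants", dropped)
        ds = ds.take_variants(np.flatnonzero(keep))
        ds.log["dropped_non_autosomal"] = dropped
    return ds


def write_plink_text(ds: GenotypeDataset, ped_path, map_path) -> None:
    """Write PED + MAP, loss-free for genotype codes {0,1,2,missing}."""
    if ds.alleles is not None:
        alleles = ds.alleles
    else:
        alleles = np.array([("A", "B")] * ds.n_variants, dtype=object)
    code = {
        0: lambda r, a: f"{r} {r}",
        1: lambda r, a: f"{r} {a}",
        2: lambda r, a: f"{a} {a}",
        MISSING: lambda r, a: "0 0",
    }
    with _open_w(ped_path) as fh:
        for i, sid in enumerate(ds.sample_ids):
            fields = [ds.population_labels[i], sid, "0", "0", "0", "-9"]
            row = ds.genotype[i]
            fields.extend(
                code[int(row[j])](alleles[j][0], alleles[j][1])
                for j in range(ds.n_variants)
            )
            fh.write(" ".join(fields) + "\n")
    with _open_w(map_path) as fh:
        cm = ds.map_cm if ds.map_cm is not None else np.zeros(ds.n_variants)
        for j in range(ds.n_variants):
            fh.write(
                f"{ds.chrom[j]} {ds.variant_ids[j]} {cm[j]:g} {ds.pos_bp[j]}\n"
            )


def _open_w(path_or_buf):
    if hasattr(path_or_buf, "write"):

        class _NoClose:
            def __init__(self, fh):
                self.fh = fh

            def __enter__(self):
                return self.fh

            def __exit__(self, *a):
                return False

        return _NoClose(path_or_buf)
    return open(path_or_buf, "w")


# ---------------------------------------------------------------------------
# Phased VCF (GT-only dialect)
# ---------------------------------------------------------------------------

def read_vcf_phased(vcf_source) -> HaplotypeSet:
    """Read a biallelic, fully phased VCF (GT fields with '|') into haplotypes.

    Raises
    ------
    FormatError
        on an unphased "/" separator or a missing genotype — the haplotype
        scans downstream require complete phased data.
    """
    lines = _as_text_lines(vcf_source)
    samples = None
    chroms, poss, vids, rows = [], [], [], []
    for ln in lines:
        if ln.startswith("##"):
            continue
        if ln.startswith("#CHROM"):
            samples = ln.split("\t")[9:]
            continue
        if samples is None:
            raise FormatError("VCF data before #CHROM header line")
        f = ln.split("\t")
        if len(f) < 10:
            raise FormatError("VCF record with no sample columns")
        if "," in f[4]:
            raise FormatError(f"multi-allelic record at {f[0]}:{f[1]} not supported")
        chroms.append(f[0])
        poss.append(int(f[1]))
        vids.append(f[2] if f[2] != "." else f"{f[0]}:{f[1]}")
        fmt = f[8].split(":")
        if "GT" not in fmt:
            raise FormatError(f"record at {f[0]}:{f[1]} lacks GT")
        gt_i = fmt.index("GT")
        hap_row = np.empty(2 * len(samples), dtype=np.uint8)
        for s, cell in enumerate(f[9:]):
            gt = cell.split(":")[gt_i]
            if "/" in gt:
                raise FormatError(
                    f"unphased genotype {gt!r} at {f[0]}:{f[1]}; phased data required"
                )
            if "." in gt:
                raise FormatError(
                    f"missing genotype at {f[0]}:{f[1]}; haplotype scans require complete data"
                )
            a, b = gt.split("|")
            hap_row[2 * s] = int(a)
            hap_row[2 * s + 1] = int(b)
        rows.append(hap_row)
    if samples is None:
        raise FormatError("no #CHROM header in VCF")
    haps = (
        np.array(rows, dtype=np.uint8).T
        if rows
        else np.empty((2 * len(samples), 0), dtype=np.uint8)
    )
    chrom = np.array(chroms, dtype=object)
    pos = np.array(poss, dtype=np.int64)
    order = _sort_variant_order(chrom, pos)
    return HaplotypeSet(
        sample_ids=list(samples),
        population_labels=["."] * len(samples),
        variant_ids=[vids[i] for i in order],
        chrom=chrom[order],
        pos_bp=pos[order],
        haplotypes=haps[:, order],
    )


def write_vcf_phased(hs: HaplotypeSet, path) -> None:
    with _open_w(path) as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hs.sample_ids)
            + "\n"
        )
        for j in range(hs.n_variants):
            gts = "\t".join(
                f"{hs.haplotypes[2 * s, j]}|{hs.haplotypes[2 * s + 1, j]}"
                for s in range(hs.n_samples)
            )
            fh.write(
                f"{hs.chrom[j]}\t{hs.pos_bp[j]}\t{hs.variant_ids[j]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# BED (0-based half-open interchange)
# ---------------------------------------------------------------------------

def write_bed(intervals, path) -> None:
    """Write intervals as BED3+name: (start_bp-1, stop_bp) half-open."""
    with _open_w(path) as fh:
        for iv in intervals:
            name = ";".join(sorted(iv.tags)) or "."
            fh.write(f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.stop_bp}\t{name}\n")


def read_bed(bed_source) -> list[GenomicInterval]:
    """Read BED3+name back to 1-based inclusive intervals."""
    out = []
    for ln in _as_text_lines(bed_source):
        if ln.startswith(("track", "browser", "#")):
            continue
        f = ln.split()
        if len(f) < 3:
            raise FormatError(f"BED line needs >=3 columns: {ln!r}")
        tags = frozenset() if len(f) < 4 or f[3] == "." else frozenset(f[3].split(";"))
        out.append(
            GenomicInterval(
                chrom=f[0], start_bp=int(f[1]) + 1, stop_bp=int(f[2]), tags=tags
            )
        )
    return out
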