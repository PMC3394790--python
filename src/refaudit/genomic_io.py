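"""Readers, writers and interval indexing for the formats the pipeline touches.

Coordinate conventions, applied everywhere in this package:

* point loci (variants, probe targets, catalog hits) carry **1-based**
  positions, as in VCF;
* spans (structural variants, exons, probe footprints) are **0-based
  half-open**, as in BED.

Conversions happen only inside the readers/writers in this module; no other
module ever adds or subtracts 1. Chromosome names are normalized by stripping
a leading ``chr`` and upper-casing X/Y/MT, so ``chr1`` and ``1`` compare equal.

Genotype calls containing any missing allele (``./.``, ``0/.`` …) are treated
as fully missing; phased ``|`` and unphased ``/`` separators are equivalent.
"""

from __future__ import annotations

import csv
import gzip
import io as _stdio
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "FormatError",
    "ValidationError",
    "GenomeCoordinate",
    "VariantSite",
    "Interval",
    "ProbeRecord",
    "GeneModel",
    "GwasCatalogRow",
    "normalize_chrom",
    "read_vcf",
    "write_vcf",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_gwas_catalog",
    "write_gwas_catalog",
    "IntervalIndex",
    "build_interval_index",
    "query_point",
    "query_window",
    "write_report_tsv",
    "read_report_tsv",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix and upper-case X/Y/MT style names."""
    if not name:
        raise ValidationError("empty chromosome name")
    if name.lower().startswith("chr"):
        name = name[3:]
    if not name:
        raise ValidationError("empty chromosome name after 'chr' prefix")
    if name.upper() in {"X", "Y", "MT", "M"}:
        return "MT" if name.upper() == "M" else name.upper()
    return name


@dataclass(frozen=True, order=True)
class GenomeCoordinate:
    """A single 1-based base position on a chromosome."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")


#: A diploid genotype as a pair of allele indices (0 = REF), or None if missing.
Genotype = Optional[tuple[int, int]]


@dataclass
class VariantSite:
    """One catalog locus: alleles plus per-sample diploid calls.

    ``alts`` keeps the declared ALT alleles in VCF order; an allele of length
    != 1 marks an indel. ``genotypes[k]`` is sample *k*'s unordered pair of
    allele indices into ``[ref] + alts``, or ``None`` when the call is missing
    (including half-calls).
    """

    coord: GenomeCoordinate
    ref: str
    alts: list[str]
    genotypes: list[Genotype] = field(default_factory=list)
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.alts:
            raise ValidationError(f"{self.coord}: alts must be non-empty")
        if self.ref in self.alts:
            raise ValidationError(f"{self.coord}: ref {self.ref!r} listed in alts")
        n_alleles = 1 + len(self.alts)
        for gt in self.genotypes:
            if gt is None:
                continue
            for a in gt:
                if not (0 <= a < n_alleles):
                    raise ValidationError(
                        f"{self.coord}: allele index {a} out of range (<{n_alleles})"
                    )

    @property
    def is_snp(self) -> bool:
        """True when the REF and every ALT allele are single bases."""
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def alleles(self) -> list[str]:
        return [self.ref] + list(self.alts)

    def carried_bases(self) -> set[str]:
        """Alleles actually carried by at least one sample (REF included only
        when some sample carries allele index 0)."""
        carried: set[int] = set()
        for gt in self.genotypes:
            if gt is not None:
                carried.update(gt)
        alleles = self.alleles()
        return {alleles[i] for i in carried}


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open span on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    def contains_pos(self, pos: int) -> bool:
        """Membership of a 1-based point position."""
        return self.start <= pos - 1 < self.end

    def contains_interval(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProbeRecord:
    """One array probe: its targeted locus, designed allele pair, and the
    optional footprint spanned by the hybridization sequence."""

    probe_id: str
    platform: str
    target: GenomeCoordinate
    designed_alleles: frozenset[str]
    footprint: Optional[Interval] = None

    def __post_init__(self) -> None:
        if len(self.designed_alleles) != 2:
            raise ValidationError(
                f"probe {self.probe_id}: designed_alleles must be 2 distinct bases, "
                f"got {sorted(self.designed_alleles)}"
            )
        if self.footprint is not None and not self.footprint.contains_pos(
            self.target.pos
        ):
            raise ValidationError(
                f"probe {self.probe_id}: target {self.target.pos} outside footprint "
                f"[{self.footprint.start}, {self.footprint.end})"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene with ordered, non-overlapping exons and a CDS contained in them."""

    gene_id: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = -1
        for ex in self.exons:
            if ex.start < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        for c in self.cds:
            if not any(ex.contains_interval(c) for ex in self.exons):
                raise ValidationError(
                    f"gene {self.gene_id}: CDS [{c.start},{c.end}) outside exons"
                )

    def intervals(self, region_kind: str) -> tuple[Interval, ...]:
        if region_kind == "exon":
            return self.exons
        if region_kind == "cds":
            return self.cds
        raise ValidationError(f"unknown region_kind {region_kind!r}")


@dataclass(frozen=True)
class GwasCatalogRow:
    """One association-study hit: study, trait, SNP id and its coordinate."""

    study_id: str
    trait: str
    snp_id: str
    coord: GenomeCoordinate

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("empty study_id in GWAS catalog row")
        if not self.snp_id:
            raise ValidationError("empty snp_id in GWAS catalog row")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _open_text(path) -> _stdio.TextIOBase:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_gt(token: str, n_alleles: int, lineno: int) -> Genotype:
    # GT is the first colon-separated field; "." anywhere makes the call missing
    gt = token.split(":", 1)[0]
    sep = "|" if "|" in gt else "/"
    parts = gt.split(sep)
    if len(parts) == 1:
        parts = parts * 2  # haploid call recorded as homozygous diploid
    if len(parts) != 2 or any(p == "." or p == "" for p in parts):
        return None
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: malformed GT field {gt!r}") from exc
    if not (0 <= a < n_alleles and 0 <= b < n_alleles):
        raise FormatError(
            f"line {lineno}: GT allele index out of range in {gt!r} "
            f"({n_alleles - 1} ALT allele(s) declared)"
        )
    return (a, b)


def read_vcf(path) -> tuple[list[str], list[VariantSite]]:
    """Read a VCF v4.x file (plain or gzip) into sample names and sites.

    Multi-allelic records stay one :class:`VariantSite` with several alts.
    Output is sorted by (chrom, pos). Only the GT FORMAT field is interpreted.
    """
    samples: list[str] = []
    sites: list[VariantSite] = []
    saw_header = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if fields[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT",
                    "QUAL", "FILTER", "INFO", "FORMAT",
                ] and fields[:8] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"
                ]:
                    raise FormatError(f"line {lineno}: malformed #CHROM header line")
                samples = fields[9:]
                saw_header = True
                continue
            if line.startswith("#"):
                continue
            if not saw_header:
                raise FormatError(f"line {lineno}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"line {lineno}: fewer than 8 VCF columns")
            chrom, pos_s, vid, ref, alt_s = fields[0], fields[1], fields[2], fields[3], fields[4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer POS {pos_s!r}") from exc
            alts = alt_s.split(",")
            n_alleles = 1 + len(alts)
            gts: list[Genotype]
            if samples:
                if len(fields) < 9 + len(samples):
                    raise FormatError(
                        f"line {lineno}: {len(fields) - 9} genotype columns for "
                        f"{len(samples)} samples"
                    )
                fmt = fields[8].split(":")
                if "GT" not in fmt:
                    raise FormatError(f"line {lineno}: FORMAT lacks GT")
                if fmt[0] != "GT":
                    raise FormatError(f"line {lineno}: GT must be first FORMAT field")
                gts = [
                    _parse_gt(tok, n_alleles, lineno)
                    for tok in fields[9 : 9 + len(samples)]
                ]
            else:
                gts = []
            try:
                site = VariantSite(
                    coord=GenomeCoordinate(chrom, pos),
                    ref=ref,
                    alts=alts,
                    genotypes=gts,
                    id=None if vid in {".", ""} else vid,
                )
            except ValidationError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            sites.append(site)
    if not saw_header:
        raise FormatError("line 0: no #CHROM header found")
    sites.sort(key=lambda s: (s.coord.chrom, s.coord.pos))
    return samples, sites


def write_vcf(samples: Sequence[str], sites: Iterable[VariantSite], path) -> None:
    """Write sites as minimal VCF v4.2 with a GT-only FORMAT column."""
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            cols += ["FORMAT"] + list(samples)
        fh.write("\t".join(cols) + "\n")
        for site in sorted(sites, key=lambda s: (s.coord.chrom, s.coord.pos)):
            row = [
                site.coord.chrom,
                str(site.coord.pos),
                site.id or ".",
                site.ref,
                ",".join(site.alts),
                ".",
                "PASS",
                ".",
            ]
            if samples:
                row.append("GT")
                for gt in site.genotypes:
                    row.append("./." if gt is None else f"{gt[0]}/{gt[1]}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

_PROBE_COLS = ["probe_id", "platform", "chrom", "pos", "allele_a", "allele_b",
               "fp_start", "fp_end"]


def read_probe_manifest(path) -> list[ProbeRecord]:
    """Read the probe-manifest TSV dialect.

    Columns: probe_id, platform, chrom, pos, allele_a, allele_b and optional
    fp_start/fp_end giving the 1-based inclusive footprint, converted here to
    the internal 0-based half-open convention.
    """
    probes: list[ProbeRecord] = []
    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_PROBE_COLS[:6]) <= set(reader.fieldnames):
            raise FormatError(
                f"probe manifest must have columns {_PROBE_COLS[:6]}, "
                f"got {reader.fieldnames}"
            )
        for rowno, row in enumerate(reader, start=2):
            fp = None
            if row.get("fp_start") and row.get("fp_end"):
                fp = Interval(
                    row["chrom"], int(row["fp_start"]) - 1, int(row["fp_end"])
                )
            try:
                probes.append(
                    ProbeRecord(
                        probe_id=row["probe_id"],
                        platform=row["platform"],
                        target=GenomeCoordinate(row["chrom"], int(row["pos"])),
                        designed_alleles=frozenset({row["allele_a"], row["allele_b"]}),
                        footprint=fp,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"probe manifest row {rowno}: {exc}") from exc
    return probes


def write_probe_manifest(probes: Iterable[ProbeRecord], path) -> None:
    with open(path, "wt", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PROBE_COLS)
        for p in probes:
            a, b = sorted(p.designed_alleles)
            fp_start = "" if p.footprint is None else str(p.footprint.start + 1)
            fp_end = "" if p.footprint is None else str(p.footprint.end)
            w.writerow(
                [p.probe_id, p.platform, p.target.chrom, p.target.pos, a, b,
                 fp_start, fp_end]
            )


def read_bed(path) -> list[Interval]:
    """Read BED3 (0-based half-open) intervals in file order."""
    out: list[Interval] = []
    with _open_text(path) as fh:
        for rowno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED row {rowno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"BED row {rowno}: non-integer coordinates") from exc
            try:
                out.append(Interval(fields[0], start, end))
            except ValidationError as exc:
                raise ValidationError(f"BED row {rowno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


_GENE_COLS = ["gene_id", "strand", "feature", "chrom", "start", "end"]


def read_gene_models(path) -> list[GeneModel]:
    """Read the gene-model TSV dialect.

    One row per exon or CDS interval with columns gene_id, strand, feature
    (``exon``/``cds``), chrom, start, end; start/end are 1-based inclusive in
    the file and converted to 0-based half-open here. Rows of one gene must be
    contiguous in the file.
    """
    genes: list[GeneModel] = []
    cur_id = None
    cur_strand = "+"
    exons: list[Interval] = []
    cds: list[Interval] = []

    def _flush():
        if cur_id is not None:
            genes.append(
                GeneModel(cur_id, cur_strand, tuple(sorted(exons)), tuple(sorted(cds)))
            )

    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _GENE_COLS:
            raise FormatError(
                f"gene-model TSV must have columns {_GENE_COLS}, got {reader.fieldnames}"
            )
        for rowno, row in enumerate(reader, start=2):
            if row["gene_id"] != cur_id:
                _flush()
                cur_id, cur_strand = row["gene_id"], row["strand"]
                exons, cds = [], []
            try:
                iv = Interval(row["chrom"], int(row["start"]) - 1, int(row["end"]))
            except ValidationError as exc:
                raise ValidationError(f"gene-model row {rowno}: {exc}") from exc
            if row["feature"] == "exon":
                exons.append(iv)
            elif row["feature"] == "cds":
                cds.append(iv)
            else:
                raise FormatError(
                    f"gene-model row {rowno}: unknown feature {row['feature']!r}"
                )
    _flush()
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "wt", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_GENE_COLS)
        for g in genes:
            for feature, ivs in (("exon", g.exons), ("cds", g.cds)):
                for iv in ivs:
                    w.writerow(
                        [g.gene_id, g.strand, feature, iv.chrom, iv.start + 1, iv.end]
                    )


_GWAS_COLS = ["study_id", "trait", "snp_id", "chrom", "pos"]


def read_gwas_catalog(path) -> list[GwasCatalogRow]:
    """Read the GWAS-catalog TSV dialect (study_id, trait, snp_id, chrom, pos)."""
    rows: list[GwasCatalogRow] = []
    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _GWAS_COLS:
            raise FormatError(
                f"GWAS catalog TSV must have columns {_GWAS_COLS}, got {reader.fieldnames}"
            )
        for rowno, row in enumerate(reader, start=2):
            try:
                rows.append(
                    GwasCatalogRow(
                        study_id=row["study_id"],
                        trait=row["trait"],
                        snp_id=row["snp_id"],
                        coord=GenomeCoordinate(row["chrom"], int(row["pos"])),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"GWAS catalog row {rowno}: {exc}") from exc
    return rows


def write_gwas_catalog(rows: Iterable[GwasCatalogRow], path) -> None:
    with open(path, "wt", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_GWAS_COLS)
        for r in rows:
            w.writerow([r.study_id, r.trait, r.snp_id, r.coord.chrom, r.coord.pos])


# ---------------------------------------------------------------------------
# Interval index
# ---------------------------------------------------------------------------


class IntervalIndex:
    """Per-chromosome interval trees over validated :class:`Interval` spans."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, iv: Interval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def at_point(self, coord: GenomeCoordinate) -> list[Interval]:
        tree = self._trees.get(coord.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.at(coord.pos - 1))

    def overlapping(self, iv: Interval) -> list[Interval]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(iv.start, iv.end))


def build_interval_index(intervals: Iterable[Interval]) -> IntervalIndex:
    index = IntervalIndex()
    for iv in intervals:
        index.add(iv)
    return index


def query_point(index: IntervalIndex, coord: GenomeCoordinate) -> list[Interval]:
    """All indexed intervals containing the 1-based point position."""
    return index.at_point(coord)


def query_window(index: IntervalIndex, window: Interval) -> list[Interval]:
    """All indexed intervals overlapping the 0-based half-open window."""
    return index.overlapping(window)


# ---------------------------------------------------------------------------
# Generic report TSV
# ---------------------------------------------------------------------------


def write_report_tsv(rows: Sequence[dict], path, columns: Optional[Sequence[str]] = None) -> None:
    """Write homogeneous dict rows as TSV with a deterministic column order
    (insertion order of the first row unless ``columns`` is given)."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "wt", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for row in rows:
            w.writerow([row[c] for c in columns])


def read_report_tsv(path) -> list[dict]:
    """Re-read a report TSV; all values come back as strings."""
    with _open_text(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
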