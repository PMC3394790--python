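"""Catalog-level and per-genome variant statistics.

Covers three observations that undercut the biallelic-reference worldview:
polyallelic loci (more than two bases carried across a cohort), heterozygous
dual-non-reference calls (a het where neither allele matches the reference),
and the multi-variant burden of genes and exons (how often a single exon or a
gene's coding region holds two or more variants in one individual).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genomic_io import GeneModel, GenomeCoordinate, ValidationError, VariantSite

__all__ = [
    "BurdenRow",
    "find_polyallelic_sites",
    "count_het_dual_nonref",
    "multi_snp_burden",
    "cohort_summary",
]


@dataclass
class BurdenRow:
    """Multi-variant burden of one sample over a gene-model set."""

    sample: str
    n_genes_multi: int
    n_exons_multi: int
    exon_count_distribution: dict[int, int] = field(default_factory=dict)


def find_polyallelic_sites(sites: Sequence[VariantSite]) -> list[GenomeCoordinate]:
    """Coordinates where more than two distinct bases are carried.

    Site records sharing a coordinate are pooled. An allele counts only when
    at least one sample carries it (the reference base counts when some
    sample carries allele index 0); ALTs declared in the file but absent from
    every genotype are ignored.
    """
    carried_by_coord: dict[GenomeCoordinate, set[str]] = {}
    for site in sites:
        carried_by_coord.setdefault(site.coord, set()).update(site.carried_bases())
    return sorted(
        coord for coord, bases in carried_by_coord.items() if len(bases) > 2
    )


def _resolve_sample(sample: str | int, samples: Optional[Sequence[str]]) -> int:
    if isinstance(sample, int):
        return sample
    if samples is None or sample not in samples:
        raise ValidationError(f"unknown sample id {sample!r}")
    return list(samples).index(sample)


def count_het_dual_nonref(
    sites: Sequence[VariantSite],
    sample: str | int,
    samples: Optional[Sequence[str]] = None,
) -> int:
    """Count sites where ``sample`` is heterozygous with both alleles non-reference.

    ``sample`` is a genotype column index, or a sample name resolved against
    ``samples`` (the VCF sample list); an unknown name is a validation error.
    """
    sample = _resolve_sample(sample, samples)
    count = 0
    for site in sites:
        if sample >= len(site.genotypes):
            raise ValidationError(
                f"sample index {sample} out of range at {site.coord}"
            )
        gt = site.genotypes[sample]
        if gt is None or gt[0] == gt[1]:
            continue
        alleles = site.alleles()
        a, b = alleles[gt[0]], alleles[gt[1]]
        if a != site.ref and b != site.ref:
            count += 1
    return count


def multi_snp_burden(
    sites: Sequence[VariantSite],
    genes: Sequence[GeneModel],
    sample: str | int,
    samples: Optional[Sequence[str]] = None,
    region_kind: str = "exon",
) -> BurdenRow:
    """Count genes and exons holding >= 2 qualifying variants for one sample.

    A variant qualifies iff the sample carries at least one non-reference
    allele there (hom-alt counts once). Variants are assigned to intervals by
    position; ``region_kind`` selects exon or CDS intervals. A gene is
    "multi" when the total over its intervals is >= 2; an interval is "multi"
    when it alone holds >= 2. The distribution tallies intervals by their
    qualifying-variant count (counts >= 2 only).
    """
    sample_name = sample if isinstance(sample, str) else str(sample)
    sample = _resolve_sample(sample, samples)
    qualifying: list[GenomeCoordinate] = []
    for site in sites:
        if sample >= len(site.genotypes):
            raise ValidationError(f"sample index {sample} out of range at {site.coord}")
        gt = site.genotypes[sample]
        if gt is not None and (gt[0] > 0 or gt[1] > 0):
            qualifying.append(site.coord)

    n_genes_multi = 0
    n_exons_multi = 0
    distribution: dict[int, int] = {}
    for gene in genes:
        gene_total = 0
        for iv in gene.intervals(region_kind):
            n_in = sum(
                1
                for c in qualifying
                if c.chrom == iv.chrom and iv.contains_pos(c.pos)
            )
            gene_total += n_in
            if n_in >= 2:
                n_exons_multi += 1
                distribution[n_in] = distribution.get(n_in, 0) + 1
        if gene_total >= 2:
            n_genes_multi += 1
    return BurdenRow(
        sample=sample_name,
        n_genes_multi=n_genes_multi,
        n_exons_multi=n_exons_multi,
        exon_count_distribution=distribution,
    )


def cohort_summary(values: Sequence[float]) -> tuple[float, Optional[float]]:
    """Arithmetic mean and n-1 sample standard deviation of a per-sample
    statistic; sd is None (undefined) for a single sample."""
    if not values:
        raise ValidationError("cohort_summary needs at least one value")
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)
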