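"""Vetting of genotyping-array probes against a population variant catalog.

A probe interrogates one polymorphic base and assumes (i) the flanking
hybridization sequence is invariant and (ii) the target is biallelic with the
two designed alleles. Both assumptions fail often once population-scale
catalogs are consulted. This module flags, per probe:

* ``FLANK_SNP`` / ``FLANK_INDEL`` — an unprobed variant within ``window_bp``
  of the target (offset 0, the target itself, never counts);
* ``SV_OVERLAP`` — the target (or whole footprint) lies inside an annotated
  structural variant;
* ``POLYALLELIC`` — more than two bases are carried at the target across the
  cohort, or some sample is heterozygous with both alleles outside the
  designed pair.

It also builds the per-platform summary table, the signed-offset histogram of
flanking variants, the catalog-subsampling saturation curve, and the
cross-reference marking association studies that rest on flagged probes.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .genomic_io import (
    GwasCatalogRow,
    Interval,
    IntervalIndex,
    ProbeRecord,
    ValidationError,
    VariantSite,
    build_interval_index,
)

__all__ = [
    "AuditConfig",
    "ProbeFlags",
    "AuditSummary",
    "FLAG_FLANK_SNP",
    "FLAG_FLANK_INDEL",
    "FLAG_SV_OVERLAP",
    "FLAG_POLYALLELIC",
    "flag_flanking_variants",
    "flag_sv_overlap",
    "flag_polyallelic_targets",
    "audit_probes",
    "audit_summary",
    "offset_histogram",
    "saturation_curve",
    "flag_gwas_studies",
]

FLAG_FLANK_SNP = "FLANK_SNP"
FLAG_FLANK_INDEL = "FLANK_INDEL"
FLAG_SV_OVERLAP = "SV_OVERLAP"
FLAG_POLYALLELIC = "POLYALLELIC"

ALL_FLAGS = (FLAG_FLANK_SNP, FLAG_FLANK_INDEL, FLAG_SV_OVERLAP, FLAG_POLYALLELIC)


@dataclass(frozen=True)
class AuditConfig:
    """Tuning for the audit.

    window_bp: flanking window; a variant at distance 1..window_bp on either
        side flags the probe (inclusive bound, so the default 10 flags +-10).
    sv_rule: ``target_in_sv`` flags when the target base falls in an SV;
        ``footprint_in_sv`` requires the whole footprint to be contained in
        one SV (probes without footprints fall back to the target rule).
    """

    window_bp: int = 10
    sv_rule: str = "target_in_sv"

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValidationError(f"window_bp must be >= 1, got {self.window_bp}")
        if self.sv_rule not in {"target_in_sv", "footprint_in_sv"}:
            raise ValidationError(f"unknown sv_rule {self.sv_rule!r}")


@dataclass
class ProbeFlags:
    """Audit verdict for one probe."""

    probe_id: str
    flags: set[str] = field(default_factory=set)
    offsets: list[int] = field(default_factory=list)

    def merge(self, other: "ProbeFlags") -> None:
        self.flags |= other.flags
        self.offsets.extend(other.offsets)


@dataclass
class AuditSummary:
    """Per-platform roll-up mirroring the classic audit table layout:
    per-category counts plus the two union columns (SNP-or-indel, any)."""

    platform: str
    n_probes: int
    n_flank_snp: int
    n_flank_indel: int
    n_sv_overlap: int
    n_polyallelic: int
    n_union_snp_indel: int
    n_union_all: int

    def pct(self, count: int) -> float:
        return 100.0 * count / self.n_probes

    def as_row(self) -> dict:
        return {
            "platform": self.platform,
            "n_probes": self.n_probes,
            "flank_snp": self.n_flank_snp,
            "flank_snp_pct": round(self.pct(self.n_flank_snp), 1),
            "flank_indel": self.n_flank_indel,
            "flank_indel_pct": round(self.pct(self.n_flank_indel), 1),
            "sv_overlap": self.n_sv_overlap,
            "sv_overlap_pct": round(self.pct(self.n_sv_overlap), 1),
            "polyallelic": self.n_polyallelic,
            "polyallelic_pct": round(self.pct(self.n_polyallelic), 1),
            "union_snp_indel": self.n_union_snp_indel,
            "union_snp_indel_pct": round(self.pct(self.n_union_snp_indel), 1),
            "union_all": self.n_union_all,
            "union_all_pct": round(self.pct(self.n_union_all), 1),
        }


def _variant_class(site: VariantSite) -> str:
    return FLAG_FLANK_SNP if site.is_snp else FLAG_FLANK_INDEL


def flag_flanking_variants(
    probes: Sequence[ProbeRecord],
    sites: Sequence[VariantSite],
    config: AuditConfig = AuditConfig(),
) -> dict[str, ProbeFlags]:
    """Flag probes with an unprobed variant within the flanking window.

    A variant at position q flags a probe targeting t iff they share a
    chromosome and 1 <= |q - t| <= window_bp; the signed offset q - t is
    recorded. A variant exactly at the target never produces a flanking flag.
    """
    by_chrom: dict[str, list[tuple[int, VariantSite]]] = {}
    for site in sites:
        by_chrom.setdefault(site.coord.chrom, []).append((site.coord.pos, site))
    for entries in by_chrom.values():
        entries.sort(key=lambda e: e[0])

    out: dict[str, ProbeFlags] = {}
    w = config.window_bp
    for probe in probes:
        pf = ProbeFlags(probe.probe_id)
        entries = by_chrom.get(probe.target.chrom, [])
        positions = [e[0] for e in entries]
        t = probe.target.pos
        lo = bisect_left(positions, t - w)
        hi = bisect_right(positions, t + w)
        for pos, site in entries[lo:hi]:
            if pos == t:
                continue
            pf.flags.add(_variant_class(site))
            pf.offsets.append(pos - t)
        out[probe.probe_id] = pf
    return out


def flag_sv_overlap(
    probes: Sequence[ProbeRecord],
    svs: Sequence[Interval] | IntervalIndex,
    config: AuditConfig = AuditConfig(),
) -> dict[str, ProbeFlags]:
    """Flag probes falling inside annotated structural variants."""
    index = svs if isinstance(svs, IntervalIndex) else build_interval_index(svs)
    out: dict[str, ProbeFlags] = {}
    for probe in probes:
        pf = ProbeFlags(probe.probe_id)
        if config.sv_rule == "footprint_in_sv" and probe.footprint is not None:
            hit = any(
                sv.contains_interval(probe.footprint)
                for sv in index.overlapping(probe.footprint)
            )
        else:
            hit = bool(index.at_point(probe.target))
        if hit:
            pf.flags.add(FLAG_SV_OVERLAP)
        out[probe.probe_id] = pf
    return out


def flag_polyallelic_targets(
    probes: Sequence[ProbeRecord],
    sites: Sequence[VariantSite],
) -> dict[str, ProbeFlags]:
    """Flag probes whose target is polyallelic in the cohort.

    A probe is flagged when, pooling every site record at the exact target
    coordinate, (a) more than two distinct bases are carried by at least one
    sample (the reference counts only when some sample carries allele 0), or
    (b) some sample is heterozygous with both called bases outside the probe's
    designed allele pair. Declared-but-uncarried ALT alleles never count.
    """
    by_coord: dict[tuple[str, int], list[VariantSite]] = {}
    for site in sites:
        by_coord.setdefault((site.coord.chrom, site.coord.pos), []).append(site)

    out: dict[str, ProbeFlags] = {}
    for probe in probes:
        pf = ProbeFlags(probe.probe_id)
        here = by_coord.get((probe.target.chrom, probe.target.pos), [])
        carried: set[str] = set()
        off_design_het = False
        for site in here:
            carried |= site.carried_bases()
            alleles = site.alleles()
            for gt in site.genotypes:
                if gt is None or gt[0] == gt[1]:
                    continue
                a, b = alleles[gt[0]], alleles[gt[1]]
                if a not in probe.designed_alleles and b not in probe.designed_alleles:
                    off_design_het = True
        if len(carried) > 2 or off_design_het:
            pf.flags.add(FLAG_POLYALLELIC)
        out[probe.probe_id] = pf
    return out


def audit_probes(
    probes: Sequence[ProbeRecord],
    sites: Sequence[VariantSite],
    svs: Sequence[Interval] | IntervalIndex = (),
    config: AuditConfig = AuditConfig(),
) -> dict[str, ProbeFlags]:
    """Run all three audits and merge verdicts per probe."""
    merged = flag_flanking_variants(probes, sites, config)
    for partial in (
        flag_sv_overlap(probes, svs, config),
        flag_polyallelic_targets(probes, sites),
    ):
        for pid, pf in partial.items():
            merged[pid].merge(pf)
    return merged


def audit_summary(flags: Mapping[str, ProbeFlags], platform: str) -> AuditSummary:
    """Summarize per-probe verdicts into the per-platform table row.

    Union columns deduplicate probes flagged for more than one reason.
    """
    n = len(flags)
    if n == 0:
        raise ValidationError("audit_summary needs at least one probe")
    sets = {f: {pid for pid, pf in flags.items() if f in pf.flags} for f in ALL_FLAGS}
    union_snp_indel = sets[FLAG_FLANK_SNP] | sets[FLAG_FLANK_INDEL]
    union_all = union_snp_indel | sets[FLAG_SV_OVERLAP] | sets[FLAG_POLYALLELIC]
    return AuditSummary(
        platform=platform,
        n_probes=n,
        n_flank_snp=len(sets[FLAG_FLANK_SNP]),
        n_flank_indel=len(sets[FLAG_FLANK_INDEL]),
        n_sv_overlap=len(sets[FLAG_SV_OVERLAP]),
        n_polyallelic=len(sets[FLAG_POLYALLELIC]),
        n_union_snp_indel=len(union_snp_indel),
        n_union_all=len(union_all),
    )


def offset_histogram(
    probes: Sequence[ProbeRecord],
    sites: Sequence[VariantSite],
    config: AuditConfig = AuditConfig(),
) -> dict[int, int]:
    """Histogram of signed offsets of flanking variants around probe targets.

    Bin k (k in [-window_bp, +window_bp], k != 0) counts (probe, variant)
    pairs whose variant sits k bases from the target; the total over bins is
    the total number of in-window pairs.
    """
    w = config.window_bp
    hist = {k: 0 for k in range(-w, w + 1) if k != 0}
    per_probe = flag_flanking_variants(probes, sites, config)
    for pf in per_probe.values():
        for off in pf.offsets:
            hist[off] += 1
    return hist


def saturation_curve(
    probes: Sequence[ProbeRecord],
    sites: Sequence[VariantSite],
    fractions: Sequence[float],
    replicates: int = 50,
    seed: int = 0,
    config: AuditConfig = AuditConfig(),
) -> list[dict]:
    """Flagged-probe count as a function of the sampled catalog fraction.

    For each fraction f, draws ``replicates`` independent uniform subsamples
    (without replacement) of ceil(f * n_sites) sites, re-runs the flanking
    audit, and reports the mean and sd of the flagged-probe count. Each
    (fraction, replicate) cell uses its own RNG stream derived from ``seed``,
    so curves are reproducible and insensitive to evaluation order.
    """
    if any(not (0 < f <= 1) for f in fractions):
        raise ValidationError("fractions must lie in (0, 1]")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    n_sites = len(sites)
    rows = []
    for fi, f in enumerate(fractions):
        k = math.ceil(f * n_sites)
        counts = []
        for rep in range(replicates):
            if k >= n_sites:
                sub = sites
            else:
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(fi, rep))
                )
                idx = rng.choice(n_sites, size=k, replace=False)
                sub = [sites[i] for i in idx]
            flagged = flag_flanking_variants(probes, sub, config)
            counts.append(sum(1 for pf in flagged.values() if pf.offsets))
        mean = float(np.mean(counts)) if counts else 0.0
        sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
        rows.append({"fraction": f, "n_sites": k, "mean_flagged": mean, "sd_flagged": sd})
    return rows


def flag_gwas_studies(
    catalog: Sequence[GwasCatalogRow],
    flagged_probe_ids: set[str],
    probes: Sequence[ProbeRecord],
) -> tuple[dict[str, bool], float]:
    """Mark association studies resting on at least one flagged probe.

    A study is affected iff any of its catalog rows matches a flagged probe,
    by SNP id first and by exact coordinate otherwise. Returns the per-study
    verdict and the affected fraction over distinct studies.
    """
    if not catalog:
        raise ValidationError("empty GWAS catalog")
    by_id: dict[str, ProbeRecord] = {p.probe_id: p for p in probes}
    by_coord: dict[tuple[str, int], list[ProbeRecord]] = {}
    for p in probes:
        by_coord.setdefault((p.target.chrom, p.target.pos), []).append(p)

    affected: dict[str, bool] = {}
    for row in catalog:
        hit = False
        probe = by_id.get(row.snp_id)
        if probe is not None:
            hit = probe.probe_id in flagged_probe_ids
        else:
            for p in by_coord.get((row.coord.chrom, row.coord.pos), []):
                if p.probe_id in flagged_probe_ids:
                    hit = True
                    break
        affected[row.study_id] = affected.get(row.study_id, False) or hit
    fraction = sum(affected.values()) / len(affected)
    return affected, fraction
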