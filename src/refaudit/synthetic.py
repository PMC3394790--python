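"""Synthetic cohorts with planted, fully known ground truth.

Every analysis in this package is validated against data generated here: a
diploid cohort whose LD structure comes from a haplotype-pool block-copy
model (each sample's two haplotypes are drawn per block from a small pool of
block haplotypes, independently across blocks), plus planted probe problems,
polyallelic and dual-non-reference sites, runs of homozygosity, two
discordant caller views of one truth set, and a GWAS catalog with a planted
affected-study set.

The pool model is deliberately simple: it fixes the true block boundaries
exactly (needed for closed-loop recovery tests) and is fast at desk scale.
It does not emulate coalescent genealogies, recombination maps or mutation
spectra; conclusions from it concern the detection machinery, not human
population history.

Determinism: every generator derives its own RNG stream from a master seed
and a fixed label, so adding one generator never perturbs another's output
and every emitted file is byte-identical across runs with the same seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genomic_io import (
    GeneModel,
    GenomeCoordinate,
    GwasCatalogRow,
    Interval,
    ProbeRecord,
    ValidationError,
    VariantSite,
    write_bed,
    write_gene_models,
    write_gwas_catalog,
    write_probe_manifest,
    write_vcf,
)
from .ld_blocks import MISSING, GenotypeMatrix, RohSegment
from .probe_audit import (
    FLAG_FLANK_INDEL,
    FLAG_FLANK_SNP,
    FLAG_POLYALLELIC,
    FLAG_SV_OVERLAP,
)

__all__ = [
    "BlockLayout",
    "CohortSpec",
    "ProbePlant",
    "ViewParams",
    "derive_rng",
    "simulate_cohort",
    "plant_probe_problems",
    "plant_site_anomalies",
    "plant_roh",
    "make_caller_views",
    "make_gwas_catalog",
    "generate_study",
]

_BASES = ("A", "C", "G", "T")


def derive_rng(master_seed: int, label: str) -> np.random.Generator:
    """A child RNG stream keyed by a stable hash of (master seed, label)."""
    digest = hashlib.blake2b(
        f"{master_seed}:{label}".encode(), digest_size=8
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "big") % 2**63)


@dataclass(frozen=True)
class BlockLayout:
    """One haplotype block of the simulated chromosome.

    n_markers consecutive markers spaced spacing_bp apart share a pool of
    pool_size block haplotypes with the given frequencies (default uniform,
    which keeps every marker's minor-allele frequency at or above the
    smallest pool frequency and makes planted blocks identifiable at
    moderate cohort sizes).
    """

    n_markers: int = 10
    spacing_bp: int = 1000
    pool_size: int = 3
    pool_freqs: Optional[tuple[float, ...]] = None

    def freqs(self) -> np.ndarray:
        if self.pool_freqs is not None:
            f = np.asarray(self.pool_freqs, dtype=float)
            if len(f) != self.pool_size or not np.isclose(f.sum(), 1.0):
                raise ValidationError("pool_freqs must match pool_size and sum to 1")
            return f
        return np.full(self.pool_size, 1.0 / self.pool_size)

    def __post_init__(self) -> None:
        if self.n_markers < 1 or self.spacing_bp < 1 or self.pool_size < 1:
            raise ValidationError("block layout fields must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """A simulated diploid cohort: samples, block layout, missingness, seed.

    ``inter_block_retain`` controls LD bleed across block boundaries: each
    haplotype lineage keeps its pool index from the previous block with this
    probability (when pool sizes match) and resamples otherwise; 0 makes
    blocks fully independent.

    ``disruptor_rate`` is the fraction of markers replaced by variants drawn
    independently of the local haplotype background (young variants carried
    on recombined or recurrent-mutation backgrounds). Every disruptor breaks
    the strong-LD fraction around it, so the number of revealed
    "recombination events" grows with marker density while the per-marker
    rate stays fixed — the property that makes sparse panels overestimate
    block length.
    """

    n_samples: int = 100
    blocks: tuple[BlockLayout, ...] = tuple(BlockLayout() for _ in range(10))
    chrom: str = "20"
    start_pos: int = 10_000
    missing_rate: float = 0.0
    inter_block_retain: float = 0.0
    disruptor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.inter_block_retain <= 1.0):
            raise ValidationError("inter_block_retain must be in [0, 1]")
        if not (0.0 <= self.disruptor_rate < 1.0):
            raise ValidationError("disruptor_rate must be in [0, 1)")


def simulate_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, list[tuple[int, int]]]:
    """Generate the cohort dosage matrix and the true block boundaries.

    Returns (matrix, truth_blocks) where truth_blocks lists (first_marker,
    last_marker) index pairs of each planted block.
    """
    rng = derive_rng(spec.seed, "cohort")
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]
    markers: list[tuple[GenomeCoordinate, str, str]] = []
    dosage_rows: list[np.ndarray] = []
    truth_blocks: list[tuple[int, int]] = []
    pos = spec.start_pos
    idx = 0
    prev_choice: Optional[np.ndarray] = None
    prev_pool_size: Optional[int] = None
    for layout in spec.blocks:
        pool = rng.integers(0, 2, size=(layout.pool_size, layout.n_markers))
        if layout.pool_size > 1:
            for m in range(layout.n_markers):
                while pool[:, m].min() == pool[:, m].max():
                    pool[:, m] = rng.integers(0, 2, size=layout.pool_size)
        hap_choice = rng.choice(
            layout.pool_size, size=(2, spec.n_samples), p=layout.freqs()
        )
        if (
            spec.inter_block_retain > 0
            and prev_choice is not None
            and prev_pool_size == layout.pool_size
        ):
            keep = rng.random(size=(2, spec.n_samples)) < spec.inter_block_retain
            hap_choice = np.where(keep, prev_choice, hap_choice)
        prev_choice = hap_choice
        prev_pool_size = layout.pool_size
        block_dosage = pool[hap_choice[0]].T + pool[hap_choice[1]].T  # (m, n)
        for m in range(layout.n_markers):
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            markers.append((GenomeCoordinate(spec.chrom, pos), str(ref), str(alt)))
            dosage_rows.append(block_dosage[m])
            pos += layout.spacing_bp
        truth_blocks.append((idx, idx + layout.n_markers - 1))
        idx += layout.n_markers
    dosage = np.array(dosage_rows, dtype=np.int8)
    if spec.disruptor_rate > 0:
        drng = derive_rng(spec.seed, "disruptors")
        which = np.nonzero(drng.random(len(dosage_rows)) < spec.disruptor_rate)[0]
        for k in which:
            freq = drng.uniform(0.2, 0.5)
            dosage[k] = drng.binomial(2, freq, size=spec.n_samples).astype(np.int8)
    if spec.missing_rate > 0:
        mask = derive_rng(spec.seed, "missing").random(dosage.shape) < spec.missing_rate
        dosage[mask] = MISSING
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage), truth_blocks


# ---------------------------------------------------------------------------
# Probe problems
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbePlant:
    """One planted probe problem: category plus the offset (flanking
    categories) or SV half-width (SV category)."""

    probe_id: str
    category: str  # FLANK_SNP | FLANK_INDEL | SV_OVERLAP | POLYALLELIC
    offset: Optional[int] = None
    sv_halfwidth: int = 25


def _free_position(wanted: int, occupied: set[int]) -> int:
    # deterministic collision handling: probe upward to the next free base
    while wanted in occupied:
        wanted += 1
    return wanted


def _carrier_genotypes(n_samples: int, rng: np.random.Generator) -> list:
    gts = [(0, 0)] * n_samples
    gts[int(rng.integers(n_samples))] = (0, 1)
    return gts


def plant_probe_problems(
    sites: list[VariantSite],
    samples: Sequence[str],
    plants: Sequence[ProbePlant],
    n_clean: int,
    platform: str = "SimArray1",
    seed: int = 0,
    window_bp: int = 10,
    exclude_positions: Optional[set[int]] = None,
) -> tuple[list[ProbeRecord], list[Interval], list[VariantSite], dict, dict]:
    """Build a probe manifest with planted problems against a site catalog.

    Each plant or clean probe targets a distinct existing biallelic site with
    an empty flanking window; FLANK plants insert a new variant at
    target+offset (collisions move upward to the next free base, the realized
    offset is recorded), SV plants write a containing interval, POLYALLELIC
    plants inject a third carried base at the target. Returns (probes, svs,
    augmented sites, truth flags, truth offsets).
    """
    rng = derive_rng(seed, "probes")
    occupied = {int(s.coord.pos) for s in sites}
    exclude = exclude_positions or set()

    sorted_pos = np.array(sorted(occupied), dtype=np.int64)

    def _window_empty(pos: int) -> bool:
        lo = np.searchsorted(sorted_pos, pos - 2 * window_bp)
        hi = np.searchsorted(sorted_pos, pos + 2 * window_bp, side="right")
        return all(sorted_pos[k] == pos for k in range(lo, hi))

    candidates = [
        k
        for k, s in enumerate(sites)
        if len(s.alts) == 1
        and s.is_snp
        and s.coord.pos not in exclude
        and _window_empty(s.coord.pos)
    ]
    need = len(plants) + n_clean
    if len(candidates) < need:
        raise ValidationError(
            f"only {len(candidates)} isolated biallelic target sites for {need} probes"
        )
    chosen = rng.choice(len(candidates), size=need, replace=False)
    targets = [candidates[int(c)] for c in chosen]

    sites = list(sites)
    probes: list[ProbeRecord] = []
    svs: list[Interval] = []
    truth_flags: dict[str, frozenset] = {}
    truth_offsets: dict[str, list[int]] = {}

    for plant, target_idx in zip(plants, targets):
        site = sites[target_idx]
        t = site.coord.pos
        chrom = site.coord.chrom
        designed = frozenset({site.ref, site.alts[0]})
        probes.append(
            ProbeRecord(
                probe_id=plant.probe_id,
                platform=platform,
                target=site.coord,
                designed_alleles=designed,
            )
        )
        offsets: list[int] = []
        if plant.category in {FLAG_FLANK_SNP, FLAG_FLANK_INDEL}:
            if plant.offset is None or not (1 <= abs(plant.offset) <= window_bp):
                raise ValidationError(
                    f"plant {plant.probe_id}: flanking offset must be within the window"
                )
            pos = _free_position(int(t + plant.offset), occupied)
            if abs(pos - t) > window_bp:
                raise ValidationError(
                    f"plant {plant.probe_id}: no free position inside the window"
                )
            occupied.add(pos)
            offsets.append(int(pos - t))
            ref, alt = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
            if plant.category == FLAG_FLANK_INDEL:
                alt = alt + str(rng.choice(_BASES))
            sites.append(
                VariantSite(
                    coord=GenomeCoordinate(chrom, pos),
                    ref=ref,
                    alts=[alt],
                    genotypes=_carrier_genotypes(len(samples), rng),
                )
            )
        elif plant.category == FLAG_SV_OVERLAP:
            svs.append(
                Interval(chrom, t - 1 - plant.sv_halfwidth, t + plant.sv_halfwidth)
            )
        elif plant.category == FLAG_POLYALLELIC:
            third = next(b for b in _BASES if b not in designed)
            new = copy.deepcopy(site)
            new.alts = list(new.alts) + [third]
            k1, k2 = rng.choice(len(samples), size=2, replace=False)
            new.genotypes[int(k1)] = (0, 2)  # carrier of the third base
            new.genotypes[int(k2)] = (0, 1)  # guarantee the designed alt is carried
            sites[target_idx] = new
        else:
            raise ValidationError(f"unknown plant category {plant.category!r}")
        truth_flags[plant.probe_id] = frozenset({plant.category})
        truth_offsets[plant.probe_id] = offsets

    for k, target_idx in enumerate(targets[len(plants):]):
        site = sites[target_idx]
        pid = f"clean{k:04d}"
        probes.append(
            ProbeRecord(
                probe_id=pid,
                platform=platform,
                target=site.coord,
                designed_alleles=frozenset({site.ref, site.alts[0]}),
            )
        )
        truth_flags[pid] = frozenset()
        truth_offsets[pid] = []

    sites.sort(key=lambda s: (s.coord.chrom, s.coord.pos))
    return probes, svs, sites, truth_flags, truth_offsets


def plant_site_anomalies(
    sites: list[VariantSite],
    samples: Sequence[str],
    n_polyallelic: int,
    dual_nonref: Sequence[tuple[str, int]],  # (sample, how many sites)
    seed: int = 0,
    exclude_positions: Optional[set[int]] = None,
) -> tuple[list[VariantSite], list[GenomeCoordinate], dict[str, int]]:
    """Plant polyallelic sites and heterozygous dual-non-reference calls.

    ``dual_nonref`` gives per-sample counts of planted C/T-style het calls in
    which neither base matches the reference. Every planted dual-non-ref site
    is also polyallelic once the rest of the cohort carries the reference.
    Returns (augmented sites, polyallelic truth coordinates, per-sample
    dual-non-ref truth counts).
    """
    rng = derive_rng(seed, "anomalies")
    sites = list(sites)
    exclude = exclude_positions or set()
    candidates = [
        k
        for k, s in enumerate(sites)
        if len(s.alts) == 1 and s.is_snp and s.coord.pos not in exclude
    ]
    need = n_polyallelic + sum(n for _, n in dual_nonref)
    if len(candidates) < need:
        raise ValidationError("not enough biallelic sites for anomaly plants")
    chosen = [candidates[int(c)] for c in rng.choice(len(candidates), need, False)]

    poly_coords: list[GenomeCoordinate] = []
    cursor = 0
    for _ in range(n_polyallelic):
        k = chosen[cursor]
        cursor += 1
        site = copy.deepcopy(sites[k])
        third = next(b for b in _BASES if b != site.ref and b not in site.alts)
        site.alts = list(site.alts) + [third]
        s1, s2 = rng.choice(len(samples), size=2, replace=False)
        site.genotypes[int(s1)] = (0, 2)
        site.genotypes[int(s2)] = (0, 1)
        sites[k] = site
        poly_coords.append(site.coord)

    dual_counts: dict[str, int] = {}
    for sample, n in dual_nonref:
        col = list(samples).index(sample)
        for _ in range(n):
            k = chosen[cursor]
            cursor += 1
            site = copy.deepcopy(sites[k])
            second = next(
                b for b in _BASES if b != site.ref and b not in site.alts
            )
            site.alts = list(site.alts) + [second]
            site.genotypes[col] = (1, 2)  # het, both non-reference
            keep_ref = next(
                c for c in range(len(samples)) if c != col
            )
            site.genotypes[keep_ref] = (0, 0)
            sites[k] = site
            poly_coords.append(site.coord)
        dual_counts[sample] = dual_counts.get(sample, 0) + n
    return sites, sorted(poly_coords), dual_counts


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------


def plant_roh(
    matrix: GenotypeMatrix,
    plants: Sequence[tuple[str, int, int]],  # (sample, first_marker, last_marker)
    flank_hets: int = 2,
) -> tuple[GenotypeMatrix, list[RohSegment]]:
    """Force homozygosity for the major allele over planted marker ranges.

    ``flank_hets`` markers on each side of a planted range are set
    heterozygous for the sample so the run's boundaries are identifiable
    under the detector's embedded-het allowance. Overlapping ranges for one
    sample are a validation error. Returns (matrix, truth segments).
    """
    by_sample: dict[str, list[tuple[int, int]]] = {}
    for sample, lo, hi in plants:
        if lo > hi:
            raise ValidationError("ROH plant range reversed")
        for plo, phi in by_sample.get(sample, []):
            if lo <= phi and plo <= hi:
                raise ValidationError(
                    f"overlapping ROH plants for sample {sample}"
                )
        by_sample.setdefault(sample, []).append((lo, hi))

    dosage = matrix.dosage.copy()
    maf_major = np.where(
        np.where(dosage == MISSING, 0, dosage).sum(axis=1)
        <= (dosage != MISSING).sum(axis=1),
        0,
        2,
    ).astype(np.int8)
    positions = matrix.positions()
    chrom_labels = [c.chrom for c, _, _ in matrix.markers]
    truth: list[RohSegment] = []
    for sample, lo, hi in plants:
        col = matrix.samples.index(sample)
        if chrom_labels[lo] != chrom_labels[hi]:
            raise ValidationError("ROH plant must stay on one chromosome")
        dosage[lo : hi + 1, col] = maf_major[lo : hi + 1]
        for k in range(max(0, lo - flank_hets), lo):
            if chrom_labels[k] == chrom_labels[lo]:
                dosage[k, col] = 1
        for k in range(hi + 1, min(matrix.n_markers, hi + 1 + flank_hets)):
            if chrom_labels[k] == chrom_labels[hi]:
                dosage[k, col] = 1
        truth.append(
            RohSegment(
                sample=sample,
                chrom=chrom_labels[lo],
                start_pos=int(positions[lo]),
                end_pos=int(positions[hi]),
                n_markers=hi - lo + 1,
                n_het_allowed_used=0,
            )
        )
    out = GenotypeMatrix(
        samples=list(matrix.samples), markers=list(matrix.markers), dosage=dosage
    )
    return out, sorted(truth, key=lambda s: (s.sample, s.chrom, s.start_pos))


# ---------------------------------------------------------------------------
# Caller views
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViewParams:
    """Per-view corruption rates for the two caller views of one truth set."""

    miss_rate_a: float = 0.1
    miss_rate_b: float = 0.1
    slip_prob: float = 0.2
    extra_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("miss_rate_a", "miss_rate_b", "slip_prob", "extra_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")


def make_caller_views(
    sites: Sequence[VariantSite],
    params: ViewParams = ViewParams(),
    seed: int = 0,
) -> tuple[list[VariantSite], list[VariantSite], dict]:
    """Derive two discordant caller views from one truth site list.

    View A drops each truth site with miss_rate_a, view B with miss_rate_b
    (independently); sites retained in both may have view B's coordinate
    slipped by +-1 bp; each view gains private invented sites at extra_rate
    per truth site. A slip is only applied when the shifted coordinate stays
    >= 2 bp away from every other site, keeping the truth partition the
    unique optimal matching. Truth records every site's fate.
    """
    rng = derive_rng(seed, "views")
    positions = sorted(s.coord.pos for s in sites)
    pos_set = set(positions)
    n_samples = len(sites[0].genotypes) if sites else 0

    view_a: list[VariantSite] = []
    view_b: list[VariantSite] = []
    truth = {"shared": [], "unique_a": [], "unique_b": [], "dropped": []}

    for site in sorted(sites, key=lambda s: (s.coord.chrom, s.coord.pos)):
        in_a = rng.random() >= params.miss_rate_a
        in_b = rng.random() >= params.miss_rate_b
        do_slip = rng.random() < params.slip_prob
        pos_b = site.coord.pos
        if in_a and in_b and do_slip:
            shift = int(rng.choice([-1, 1]))
            cand = site.coord.pos + shift
            clash = any(
                (cand + d in pos_set and cand + d != site.coord.pos)
                for d in (-1, 0, 1)
            )
            if not clash and cand >= 1:
                pos_b = cand
        if in_a:
            view_a.append(copy.deepcopy(site))
        if in_b:
            b_site = copy.deepcopy(site)
            if pos_b != site.coord.pos:
                b_site.coord = GenomeCoordinate(site.coord.chrom, pos_b)
            view_b.append(b_site)
        if in_a and in_b:
            truth["shared"].append([site.coord.pos, pos_b])
        elif in_a:
            truth["unique_a"].append(site.coord.pos)
        elif in_b:
            truth["unique_b"].append(pos_b)
        else:
            truth["dropped"].append(site.coord.pos)

    # private invented sites, kept >= 2 bp from everything in either view
    chrom = sites[0].coord.chrom if sites else "1"
    taken = set(pos_set)
    taken.update(s.coord.pos for s in view_b)
    n_extra = int(round(params.extra_rate * len(sites)))
    for label, view, bucket in (("a", view_a, "unique_a"), ("b", view_b, "unique_b")):
        made = 0
        lo = min(positions) if positions else 100
        hi = max(positions) if positions else 10_000
        while made < n_extra:
            cand = int(rng.integers(lo, hi + 1))
            if any(cand + d in taken for d in (-2, -1, 0, 1, 2)):
                continue
            taken.add(cand)
            gts = [(0, 0)] * n_samples
            if n_samples:
                gts[int(rng.integers(n_samples))] = (0, 1)
            ref, alt = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
            view.append(
                VariantSite(
                    coord=GenomeCoordinate(chrom, cand),
                    ref=ref,
                    alts=[alt],
                    genotypes=gts,
                )
            )
            truth[bucket].append(cand)
            made += 1

    view_a.sort(key=lambda s: (s.coord.chrom, s.coord.pos))
    view_b.sort(key=lambda s: (s.coord.chrom, s.coord.pos))
    for bucket in ("unique_a", "unique_b", "dropped"):
        truth[bucket].sort()
    truth["shared"].sort()
    return view_a, view_b, truth


# ---------------------------------------------------------------------------
# GWAS catalog
# ---------------------------------------------------------------------------

_TRAITS = (
    "height", "type 2 diabetes", "LDL cholesterol", "asthma", "hypertension",
    "rheumatoid arthritis", "breast cancer", "Crohn disease",
)


def make_gwas_catalog(
    probes: Sequence[ProbeRecord],
    flagged_probe_ids: set[str],
    n_studies: int = 100,
    hits_per_study: int = 3,
    affected_fraction: float = 0.34,
    seed: int = 0,
) -> tuple[list[GwasCatalogRow], set[str]]:
    """A synthetic association catalog with a planted affected-study set.

    Exactly round(affected_fraction * n_studies) studies receive >= 1 hit on
    a flagged probe; all other hits land on clean probes. SNP ids are probe
    ids. Returns (catalog rows, truth affected study ids).
    """
    if not (0.0 <= affected_fraction <= 1.0):
        raise ValidationError("affected_fraction must be in [0,1]")
    rng = derive_rng(seed, "gwas")
    flagged = sorted(p.probe_id for p in probes if p.probe_id in flagged_probe_ids)
    clean = sorted(p.probe_id for p in probes if p.probe_id not in flagged_probe_ids)
    n_affected = int(round(affected_fraction * n_studies))
    if n_affected > 0 and not flagged:
        raise ValidationError("no flagged probes available for affected studies")
    if (n_studies > 0 and not clean) or (hits_per_study > 1 and not clean):
        raise ValidationError("no clean probes available for clean hits")
    by_id = {p.probe_id: p for p in probes}

    rows: list[GwasCatalogRow] = []
    affected: set[str] = set()
    for k in range(n_studies):
        study = f"study{k:04d}"
        is_affected = k < n_affected
        if is_affected:
            affected.add(study)
        picks: list[str] = []
        if is_affected:
            picks.append(flagged[int(rng.integers(len(flagged)))])
        while len(picks) < hits_per_study:
            picks.append(clean[int(rng.integers(len(clean)))])
        for snp_id in picks:
            probe = by_id[snp_id]
            rows.append(
                GwasCatalogRow(
                    study_id=study,
                    trait=str(rng.choice(_TRAITS)),
                    snp_id=snp_id,
                    coord=probe.target,
                )
            )
    return rows, affected


# ---------------------------------------------------------------------------
# One-shot study generation
# ---------------------------------------------------------------------------


@dataclass
class StudySpec:
    """Desk-scale study conditions for the end-to-end demo pipeline."""

    n_samples: int = 100
    n_blocks: int = 100
    markers_per_block: int = 10
    spacing_bp: int = 1000
    pool_size: int = 3
    missing_rate: float = 0.002
    n_flank_snp: int = 12
    n_flank_indel: int = 10
    n_sv: int = 10
    n_poly_probe: int = 8
    n_clean_probes: int = 160
    n_polyallelic_sites: int = 6
    dual_nonref_per_sample: tuple[tuple[str, int], ...] = (
        ("S0000", 4),
        ("S0001", 3),
        ("S0002", 5),
    )
    roh_plants: tuple[tuple[str, int, int], ...] = (
        ("S0000", 40, 239),
        ("S0001", 300, 499),
    )
    view_params: ViewParams = field(default_factory=ViewParams)
    n_studies: int = 100
    hits_per_study: int = 3
    affected_fraction: float = 0.34
    window_bp: int = 10


def _gene_models_over(matrix: GenotypeMatrix, seed: int, n_genes: int = 40) -> list[GeneModel]:
    """Gene models tiling the simulated chromosome: each gene gets 2-4 exons
    of a few markers each, with the CDS equal to the interior exons."""
    rng = derive_rng(seed, "genes")
    positions = matrix.positions()
    chrom = matrix.markers[0][0].chrom
    genes: list[GeneModel] = []
    n = matrix.n_markers
    starts = np.sort(rng.choice(max(n - 12, 1), size=min(n_genes, max(n // 14, 1)), replace=False))
    for g, s in enumerate(starts):
        n_exons = int(rng.integers(2, 5))
        exons = []
        k = int(s)
        for _ in range(n_exons):
            width = int(rng.integers(2, 4))
            if k + width > n:
                break
            exons.append(
                Interval(chrom, int(positions[k]) - 1, int(positions[k + width - 1]))
            )
            k += width + 1
        if len(exons) < 2:
            continue
        cds = tuple(exons[1:-1]) or (exons[0],)
        genes.append(
            GeneModel(
                gene_id=f"gene{g:03d}",
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple(exons),
                cds=cds,
            )
        )
    return genes


def generate_study(out_dir, seed: int = 0, spec: StudySpec = StudySpec()) -> dict:
    """Generate the full synthetic study and emit every input file + truth.

    Writes cohort.vcf, probes.tsv, svs.bed, genes.tsv, gwas.tsv, view_a.vcf,
    view_b.vcf and truth.json under ``out_dir``; returns the truth dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort_spec = CohortSpec(
        n_samples=spec.n_samples,
        blocks=tuple(
            BlockLayout(spec.markers_per_block, spec.spacing_bp, spec.pool_size)
            for _ in range(spec.n_blocks)
        ),
        missing_rate=spec.missing_rate,
        seed=seed,
    )
    matrix, truth_blocks = simulate_cohort(cohort_spec)

    # ROH plants first; all later plants avoid the affected marker ranges
    matrix, truth_roh = plant_roh(matrix, list(spec.roh_plants))
    positions = matrix.positions()
    roh_positions: set[int] = set()
    for _, lo, hi in spec.roh_plants:
        roh_positions.update(
            int(p) for p in positions[max(0, lo - 3) : min(matrix.n_markers, hi + 4)]
        )

    base_sites = matrix.to_sites()

    # caller views come from the clean cohort catalog (well-spaced positions)
    view_a, view_b, truth_partition = make_caller_views(
        base_sites, spec.view_params, seed=seed
    )

    sites, poly_coords, dual_counts = plant_site_anomalies(
        base_sites,
        matrix.samples,
        n_polyallelic=spec.n_polyallelic_sites,
        dual_nonref=list(spec.dual_nonref_per_sample),
        seed=seed,
        exclude_positions=roh_positions,
    )
    anomaly_positions = {c.pos for c in poly_coords}

    plants = (
        [
            ProbePlant(f"psnp{k:03d}", FLAG_FLANK_SNP, offset=int(o))
            for k, o in enumerate(
                derive_rng(seed, "offsets-snp").choice(
                    [o for o in range(-spec.window_bp, spec.window_bp + 1) if o],
                    size=spec.n_flank_snp,
                )
            )
        ]
        + [
            ProbePlant(f"pind{k:03d}", FLAG_FLANK_INDEL, offset=int(o))
            for k, o in enumerate(
                derive_rng(seed, "offsets-indel").choice(
                    [o for o in range(-spec.window_bp, spec.window_bp + 1) if o],
                    size=spec.n_flank_indel,
                )
            )
        ]
        + [ProbePlant(f"psv{k:03d}", FLAG_SV_OVERLAP) for k in range(spec.n_sv)]
        + [ProbePlant(f"ppoly{k:03d}", FLAG_POLYALLELIC) for k in range(spec.n_poly_probe)]
    )
    probes, svs, sites, truth_flags, truth_offsets = plant_probe_problems(
        sites,
        matrix.samples,
        plants,
        n_clean=spec.n_clean_probes,
        seed=seed,
        window_bp=spec.window_bp,
        exclude_positions=roh_positions | anomaly_positions,
    )
    poly_probe_coords = [
        p.target for p in probes if truth_flags[p.probe_id] == {FLAG_POLYALLELIC}
    ]

    flagged_ids = {pid for pid, fl in truth_flags.items() if fl}
    catalog, truth_affected = make_gwas_catalog(
        probes,
        flagged_ids,
        n_studies=spec.n_studies,
        hits_per_study=spec.hits_per_study,
        affected_fraction=spec.affected_fraction,
        seed=seed,
    )

    genes = _gene_models_over(matrix, seed)

    write_vcf(matrix.samples, sites, out_dir / "cohort.vcf")
    write_probe_manifest(probes, out_dir / "probes.tsv")
    write_bed(svs, out_dir / "svs.bed")
    write_gene_models(genes, out_dir / "genes.tsv")
    write_gwas_catalog(catalog, out_dir / "gwas.tsv")
    write_vcf(matrix.samples, view_a, out_dir / "view_a.vcf")
    write_vcf(matrix.samples, view_b, out_dir / "view_b.vcf")

    truth = {
        "seed": seed,
        "probe_flags": {pid: sorted(fl) for pid, fl in truth_flags.items()},
        "probe_offsets": truth_offsets,
        "block_boundaries": [
            {
                "first_marker": lo,
                "last_marker": hi,
                "start_pos": int(positions[lo]),
                "end_pos": int(positions[hi]),
            }
            for lo, hi in truth_blocks
        ],
        "roh": [
            {
                "sample": s.sample,
                "chrom": s.chrom,
                "start_pos": s.start_pos,
                "end_pos": s.end_pos,
                "n_markers": s.n_markers,
            }
            for s in truth_roh
        ],
        "polyallelic_sites": sorted(
            {c.pos for c in poly_coords} | {c.pos for c in poly_probe_coords}
        ),
        "dual_nonref_counts": dual_counts,
        "concordance": truth_partition,
        "affected_studies": sorted(truth_affected),
    }
    with open(out_dir / "truth.json", "wt") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
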