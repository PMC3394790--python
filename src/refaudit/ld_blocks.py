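"""Linkage-disequilibrium machinery: call-rate trimming, two-locus EM
haplotype frequencies, |D'| with profile-likelihood confidence intervals,
Gabriel-style haplotype block partitioning, marker/sample subsampling
experiments, and runs-of-homozygosity detection.

The block definition follows the confidence-interval criteria popularized by
Gabriel et al. and implemented by Haploview/PLINK ``--blocks``: a marker pair
is in *strong LD* when the one-sided 90% CI on |D'| has lower bound >= 0.70
and upper bound >= 0.98, shows *strong evidence of recombination* when the
upper bound < 0.90, and is *uninformative* otherwise; a span of markers is a
block when its end pair is in strong LD and >= 95% of its informative pairs
are. All thresholds live in :class:`LdConfig` so runs are self-describing.

Haplotype frequencies for unphased genotype pairs come from the standard
two-locus EM in which the double heterozygote is the single ambiguous class.
The |D'| confidence interval is a profile over |D'| in [0, 1] on a fixed
grid, with allele frequencies held at their MLEs: the exponentiated profile
log-likelihood is normalized to unit mass and the 5th/95th cumulative
percentiles are read off, as in Haploview.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .genomic_io import GenomeCoordinate, ValidationError, VariantSite

__all__ = [
    "GenotypeMatrix",
    "PairwiseLD",
    "HaplotypeBlock",
    "RohSegment",
    "LdConfig",
    "RohConfig",
    "STRONG_LD",
    "RECOMB",
    "UNINFORMATIVE",
    "matrix_from_sites",
    "trim_by_call_rate",
    "em_haplotype_freqs",
    "dprime_ci",
    "gabriel_blocks",
    "block_summary",
    "ld_subsample_experiment",
    "find_roh",
    "roh_total",
]

MISSING = -1

STRONG_LD = "STRONG_LD"
RECOMB = "RECOMB"
UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class LdConfig:
    """Block-detection tuning constants (Gabriel/Haploview-style defaults).

    ci_strong_low/ci_strong_high: strong-LD requires CI lower bound >= 0.70
        and upper bound >= 0.98. ci_recomb_high: recombination evidence when
        the upper bound < 0.90. strong_fraction: >= 95% of informative pairs
        inside a block must be strong. maf_min: markers below this minor
        allele frequency are not classified (they may still sit inside a
        block's span). max_block_span_bp: longest candidate span considered.
    dprime_grid_step / em_tol / em_max_iter: numerical knobs.
    """

    ci_strong_low: float = 0.70
    ci_strong_high: float = 0.98
    ci_recomb_high: float = 0.90
    strong_fraction: float = 0.95
    maf_min: float = 0.05
    max_block_span_bp: int = 500_000
    dprime_grid_step: float = 0.001
    em_tol: float = 1e-8
    em_max_iter: int = 100

    def __post_init__(self) -> None:
        for name in ("ci_strong_low", "ci_strong_high", "ci_recomb_high",
                     "strong_fraction", "maf_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.dprime_grid_step <= 0:
            raise ValidationError("dprime_grid_step must be > 0")


@dataclass(frozen=True)
class RohConfig:
    """Runs-of-homozygosity tuning: a reported run needs >= min_markers
    markers spanning >= min_span_bp, may contain <= max_het embedded
    heterozygous calls, and no adjacent-marker gap above max_gap_bp.
    Missing calls terminate a run."""

    min_markers: int = 25
    min_span_bp: int = 500_000
    max_het: int = 1
    max_gap_bp: int = 100_000

    def __post_init__(self) -> None:
        if min(self.min_markers, self.min_span_bp, self.max_het, self.max_gap_bp) < 0:
            raise ValidationError("RohConfig fields must be >= 0")


@dataclass
class GenotypeMatrix:
    """Biallelic marker-by-sample alt-allele dosage matrix.

    ``dosage`` has shape (n_markers, n_samples) with entries 0/1/2 or -1 for
    missing. Markers are sorted with strictly increasing positions within a
    chromosome.
    """

    samples: list[str]
    markers: list[tuple[GenomeCoordinate, str, str]]  # (coord, ref, alt)
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.markers), len(self.samples)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.markers)}, {len(self.samples)})"
            )
        prev: Optional[GenomeCoordinate] = None
        for coord, _, _ in self.markers:
            if prev is not None and coord.chrom == prev.chrom and coord.pos <= prev.pos:
                raise ValidationError(
                    f"markers not strictly increasing at {coord.chrom}:{coord.pos}"
                )
            prev = coord

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def positions(self) -> np.ndarray:
        return np.array([c.pos for c, _, _ in self.markers], dtype=np.int64)

    def chroms(self) -> list[str]:
        seen: list[str] = []
        for c, _, _ in self.markers:
            if not seen or seen[-1] != c.chrom:
                seen.append(c.chrom)
        return seen

    def subset(
        self,
        marker_idx: Optional[Sequence[int]] = None,
        sample_idx: Optional[Sequence[int]] = None,
    ) -> "GenotypeMatrix":
        mi = np.arange(self.n_markers) if marker_idx is None else np.sort(np.asarray(marker_idx))
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            markers=[self.markers[i] for i in mi],
            dosage=self.dosage[np.ix_(mi, si)].copy(),
        )

    def call_rate(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker over non-missing calls."""
        d = self.dosage.astype(np.float64)
        obs = d != MISSING
        n = obs.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, d, 0.0).sum(axis=1) / (2 * n)
        p = np.where(n > 0, p, 0.0)
        return np.minimum(p, 1 - p)

    def to_sites(self) -> list[VariantSite]:
        sites = []
        for k, (coord, ref, alt) in enumerate(self.markers):
            gts = []
            for dose in self.dosage[k]:
                if dose == MISSING:
                    gts.append(None)
                else:
                    gts.append({0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(dose)])
            sites.append(VariantSite(coord=coord, ref=ref, alts=[alt], genotypes=gts))
        return sites


def matrix_from_sites(
    samples: Sequence[str], sites: Sequence[VariantSite]
) -> GenotypeMatrix:
    """Build a dosage matrix from biallelic single-base sites.

    Multi-allelic sites and indels are skipped (they are audit material, not
    LD markers); duplicate positions keep the first record.
    """
    markers: list[tuple[GenomeCoordinate, str, str]] = []
    rows: list[list[int]] = []
    seen: set[tuple[str, int]] = set()
    for site in sorted(sites, key=lambda s: (s.coord.chrom, s.coord.pos)):
        if len(site.alts) != 1 or not site.is_snp:
            continue
        key = (site.coord.chrom, site.coord.pos)
        if key in seen:
            continue
        seen.add(key)
        row = []
        for gt in site.genotypes:
            if gt is None:
                row.append(MISSING)
            else:
                row.append(int(gt[0] > 0) + int(gt[1] > 0))
        markers.append((site.coord, site.ref, site.alts[0]))
        rows.append(row)
    dosage = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(samples=list(samples), markers=markers, dosage=dosage)


def trim_by_call_rate(
    matrix: GenotypeMatrix, min_call_rate: float = 0.99
) -> GenotypeMatrix:
    """Keep markers whose non-missing genotype fraction is >= min_call_rate."""
    keep = np.nonzero(matrix.call_rate() >= min_call_rate)[0]
    return matrix.subset(marker_idx=keep)


# ---------------------------------------------------------------------------
# Two-locus EM and |D'| confidence intervals
# ---------------------------------------------------------------------------


@dataclass
class PairwiseLD:
    """Two-locus LD summary for one marker pair."""

    i: int
    j: int
    D: float
    Dprime: float
    r2: float
    ci_low: float
    ci_high: float
    status: str


def _pair_tables(
    dosage: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray
) -> np.ndarray:
    """3x3 genotype-count tables, flattened to (n_pairs, 9) with cell a*3+b."""
    di = dosage[idx_i]
    dj = dosage[idx_j]
    ok = (di != MISSING) & (dj != MISSING)
    counts = np.zeros((len(idx_i), 9), dtype=np.float64)
    for a in range(3):
        for b in range(3):
            counts[:, a * 3 + b] = ((di == a) & (dj == b) & ok).sum(axis=1)
    return counts


def _em_from_tables(
    counts: np.ndarray, tol: float, max_iter: int
) -> np.ndarray:
    """Vectorized two-locus EM: (n_pairs, 9) genotype tables -> (n_pairs, 4)
    haplotype frequencies in order (00, 01, 10, 11)."""
    n = counts  # aliases per flattened cell index a*3+b
    known = np.empty((counts.shape[0], 4))
    known[:, 0] = 2 * n[:, 0] + n[:, 1] + n[:, 3]  # h00
    known[:, 1] = 2 * n[:, 2] + n[:, 1] + n[:, 5]  # h01
    known[:, 2] = 2 * n[:, 6] + n[:, 3] + n[:, 7]  # h10
    known[:, 3] = 2 * n[:, 8] + n[:, 5] + n[:, 7]  # h11
    ndh = n[:, 4]  # double heterozygotes
    total = counts.sum(axis=1)
    gametes = np.maximum(2 * total, 1e-12)

    p = (known[:, 2] + known[:, 3] + ndh) / gametes  # alt freq, locus i
    q = (known[:, 1] + known[:, 3] + ndh) / gametes  # alt freq, locus j
    f = np.stack(
        [(1 - p) * (1 - q), (1 - p) * q, p * (1 - q), p * q], axis=1
    )
    f = np.maximum(f, 1e-12)
    f /= f.sum(axis=1, keepdims=True)

    for _ in range(max_iter):
        coupling = f[:, 0] * f[:, 3]
        repulsion = f[:, 1] * f[:, 2]
        denom = coupling + repulsion
        w = np.where(denom > 0, coupling / np.maximum(denom, 1e-300), 0.5)
        new = known.copy()
        new[:, 0] += ndh * w
        new[:, 3] += ndh * w
        new[:, 1] += ndh * (1 - w)
        new[:, 2] += ndh * (1 - w)
        new /= gametes[:, None]
        delta = np.abs(new - f).max(axis=1)
        f = new
        if float(delta.max(initial=0.0)) < tol:
            break
    return f


def em_haplotype_freqs(
    dosages_i: Sequence[int] | np.ndarray,
    dosages_j: Sequence[int] | np.ndarray,
    config: LdConfig = LdConfig(),
) -> np.ndarray:
    """Two-locus haplotype frequencies (00, 01, 10, 11) for one marker pair.

    Pairs with a missing call at either locus are dropped. Deterministic:
    initialized at linkage equilibrium of the observed allele frequencies and
    iterated to ``config.em_tol``. When no double heterozygotes exist the EM
    has no latent data and equals direct haplotype counting.
    """
    di = np.asarray(dosages_i, dtype=np.int8)[None, :]
    dj = np.asarray(dosages_j, dtype=np.int8)[None, :]
    counts = _pair_tables(np.vstack([di, dj]), np.array([0]), np.array([1]))
    if counts.sum() < 2:
        raise ValidationError("fewer than 2 informative samples for EM")
    return _em_from_tables(counts, config.em_tol, config.em_max_iter)[0]


def _dprime_stats(freqs: np.ndarray) -> tuple[np.ndarray, ...]:
    """D, |D'|, r2, allele freqs p, q from (n, 4) haplotype frequencies."""
    p = freqs[:, 2] + freqs[:, 3]
    q = freqs[:, 1] + freqs[:, 3]
    D = freqs[:, 3] - p * q
    dmax_pos = np.minimum(p * (1 - q), (1 - p) * q)
    dmax_neg = np.minimum(p * q, (1 - p) * (1 - q))
    dmax = np.where(D >= 0, dmax_pos, dmax_neg)
    with np.errstate(invalid="ignore", divide="ignore"):
        dprime = np.where(dmax > 0, np.abs(D) / np.maximum(dmax, 1e-300), 0.0)
        r2 = np.where(
            (p > 0) & (p < 1) & (q > 0) & (q < 1),
            D * D / np.maximum(p * (1 - p) * q * (1 - q), 1e-300),
            0.0,
        )
    return D, np.clip(dprime, 0, 1), np.clip(r2, 0, 1), p, q


def _ci_grid(
    counts: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    sign_pos: np.ndarray,
    config: LdConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Profile-likelihood CI bounds on |D'| for a chunk of pairs.

    For each pair, |D'| runs over a fixed grid with allele frequencies held
    at their MLEs and D signed like the MLE; the exponentiated log-likelihood
    profile is normalized to unit mass and the 5%/95% cumulative points are
    returned.
    """
    grid = np.arange(0.0, 1.0 + config.dprime_grid_step / 2, config.dprime_grid_step)
    dmax_pos = np.minimum(p * (1 - q), (1 - p) * q)
    dmax_neg = np.minimum(p * q, (1 - p) * (1 - q))
    dmax = np.where(sign_pos, dmax_pos, dmax_neg)
    sign = np.where(sign_pos, 1.0, -1.0)

    Dg = (sign * dmax)[:, None] * grid[None, :]  # (P, G)
    pq = (p * q)[:, None]
    f11 = pq + Dg
    f10 = p[:, None] - f11
    f01 = q[:, None] - f11
    f00 = 1 - p[:, None] - q[:, None] + f11
    tiny = 1e-300
    f00, f01 = np.maximum(f00, 0.0), np.maximum(f01, 0.0)
    f10, f11 = np.maximum(f10, 0.0), np.maximum(f11, 0.0)

    cell_probs = (
        f00 * f00,            # (0,0)
        2 * f00 * f01,        # (0,1)
        f01 * f01,            # (0,2)
        2 * f00 * f10,        # (1,0)
        2 * (f00 * f11 + f01 * f10),  # (1,1)
        2 * f01 * f11,        # (1,2)
        f10 * f10,            # (2,0)
        2 * f10 * f11,        # (2,1)
        f11 * f11,            # (2,2)
    )
    ll = np.zeros_like(Dg)
    for cell, prob in enumerate(cell_probs):
        nc = counts[:, cell]
        mask = nc > 0
        if mask.any():
            ll[mask] += nc[mask, None] * np.log(np.maximum(prob[mask], tiny))

    ll -= ll.max(axis=1, keepdims=True)
    w = np.exp(ll)
    cum = np.cumsum(w, axis=1)
    cum /= cum[:, -1:]
    lo_idx = np.argmax(cum >= 0.05, axis=1)
    hi_idx = np.argmax(cum >= 0.95, axis=1)
    return grid[lo_idx], grid[hi_idx]


def _classify_pairs(
    matrix: GenotypeMatrix,
    idx_i: np.ndarray,
    idx_j: np.ndarray,
    config: LdConfig,
    chunk: int = 4096,
) -> list[PairwiseLD]:
    """Vectorized EM + CI classification for many marker pairs."""
    out: list[PairwiseLD] = []
    for lo in range(0, len(idx_i), chunk):
        ii = idx_i[lo : lo + chunk]
        jj = idx_j[lo : lo + chunk]
        counts = _pair_tables(matrix.dosage, ii, jj)
        freqs = _em_from_tables(counts, config.em_tol, config.em_max_iter)
        D, dprime, r2, p, q = _dprime_stats(freqs)
        informative = (
            (counts.sum(axis=1) >= 2)
            & (p > 0) & (p < 1) & (q > 0) & (q < 1)
        )
        ci_low = np.zeros(len(ii))
        ci_high = np.ones(len(ii))
        if informative.any():
            sub = np.nonzero(informative)[0]
            ci_low[sub], ci_high[sub] = _ci_grid(
                counts[sub], p[sub], q[sub], D[sub] >= 0, config
            )
        for k in range(len(ii)):
            if not informative[k]:
                status = UNINFORMATIVE
            elif (
                ci_low[k] >= config.ci_strong_low
                and ci_high[k] >= config.ci_strong_high
            ):
                status = STRONG_LD
            elif ci_high[k] < config.ci_recomb_high:
                status = RECOMB
            else:
                status = UNINFORMATIVE
            out.append(
                PairwiseLD(
                    i=int(ii[k]),
                    j=int(jj[k]),
                    D=float(D[k]),
                    Dprime=float(dprime[k]),
                    r2=float(r2[k]),
                    ci_low=float(ci_low[k]) if informative[k] else 0.0,
                    ci_high=float(ci_high[k]) if informative[k] else 1.0,
                    status=status,
                )
            )
    return out


def dprime_ci(
    dosages_i: Sequence[int] | np.ndarray,
    dosages_j: Sequence[int] | np.ndarray,
    config: LdConfig = LdConfig(),
    i: int = 0,
    j: int = 1,
) -> PairwiseLD:
    """Full two-locus LD summary (D, |D'|, r2, 90% CI, status) for one pair.

    Monomorphic loci or fewer than two informative samples yield status
    ``UNINFORMATIVE`` with a vacuous [0, 1] interval.
    """
    di = np.asarray(dosages_i, dtype=np.int8)
    dj = np.asarray(dosages_j, dtype=np.int8)
    tiny = GenotypeMatrix(
        samples=[f"s{k}" for k in range(len(di))],
        markers=[
            (GenomeCoordinate("1", 1), "A", "C"),
            (GenomeCoordinate("1", 2), "A", "C"),
        ],
        dosage=np.vstack([di, dj]),
    )
    result = _classify_pairs(tiny, np.array([0]), np.array([1]), config)[0]
    return replace(result, i=i, j=j)


# ---------------------------------------------------------------------------
# Gabriel-style blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplotypeBlock:
    """A contiguous marker run declared a haplotype block. Marker indices
    refer to the full matrix; span is end-position minus start-position + 1."""

    chrom: str
    first_marker: int
    last_marker: int
    span_bp: int

    def __post_init__(self) -> None:
        if self.first_marker >= self.last_marker:
            raise ValidationError("a block needs >= 2 markers")


def gabriel_blocks(
    matrix: GenotypeMatrix, config: LdConfig = LdConfig()
) -> list[HaplotypeBlock]:
    """Partition markers into haplotype blocks by the CI criteria.

    Markers below ``maf_min`` are not classified (but may fall inside an
    accepted block's span). Candidate spans (i, j) must span at most
    ``max_block_span_bp``, have a strong-LD end pair, and have >=
    ``strong_fraction`` of their informative pairs strong; candidates are
    accepted greedily by decreasing bp span (ties leftmost), skipping spans
    that overlap accepted blocks.
    """
    if matrix.n_markers < 2:
        return []
    blocks: list[HaplotypeBlock] = []
    positions = matrix.positions()
    maf = matrix.maf()
    chrom_labels = np.array([c.chrom for c, _, _ in matrix.markers])
    for chrom in matrix.chroms():
        on_chrom = np.nonzero(chrom_labels == chrom)[0]
        eligible = on_chrom[maf[on_chrom] >= config.maf_min]
        m = len(eligible)
        if m < 2:
            continue
        pos = positions[eligible]

        pair_i: list[int] = []
        pair_j: list[int] = []
        for a in range(m - 1):
            hi = np.searchsorted(
                pos, pos[a] + config.max_block_span_bp - 1, side="right"
            )
            for b in range(a + 1, hi):
                pair_i.append(a)
                pair_j.append(b)
        if not pair_i:
            continue
        pi = np.asarray(pair_i)
        pj = np.asarray(pair_j)
        pairs = _classify_pairs(matrix, eligible[pi], eligible[pj], config)

        strong = np.zeros((m, m))
        informative = np.zeros((m, m))
        for k, pr in enumerate(pairs):
            a, b = pi[k], pj[k]
            if pr.status == STRONG_LD:
                strong[a, b] = 1
                informative[a, b] = 1
            elif pr.status == RECOMB:
                informative[a, b] = 1
        strong_cum = strong.cumsum(0).cumsum(1)
        info_cum = informative.cumsum(0).cumsum(1)

        def _rect(cum: np.ndarray, a: int, b: int) -> float:
            total = cum[b, b]
            if a > 0:
                total -= cum[a - 1, b] + cum[b, a - 1] - cum[a - 1, a - 1]
            return total

        candidates: list[tuple[int, int, int]] = []  # (span_bp, a, b)
        for k, pr in enumerate(pairs):
            if pr.status != STRONG_LD:
                continue
            a, b = int(pi[k]), int(pj[k])
            n_info = _rect(info_cum, a, b)
            n_strong = _rect(strong_cum, a, b)
            if n_info > 0 and n_strong / n_info >= config.strong_fraction:
                candidates.append((int(pos[b] - pos[a]) + 1, a, b))

        candidates.sort(key=lambda t: (-t[0], pos[t[1]]))
        occupied = np.zeros(m, dtype=bool)
        for span_bp, a, b in candidates:
            if occupied[a : b + 1].any():
                continue
            occupied[a : b + 1] = True
            blocks.append(
                HaplotypeBlock(
                    chrom=chrom,
                    first_marker=int(eligible[a]),
                    last_marker=int(eligible[b]),
                    span_bp=span_bp,
                )
            )
    blocks.sort(key=lambda blk: (blk.chrom, blk.first_marker))
    return blocks


def block_summary(blocks: Sequence[HaplotypeBlock]) -> dict:
    """n_blocks, total bp, mean bp and n-1 sd of block spans."""
    spans = [b.span_bp for b in blocks]
    if not spans:
        return {"n_blocks": 0, "total_bp": 0, "mean_bp": 0.0, "sd_bp": None}
    mean = float(np.mean(spans))
    sd = float(np.std(spans, ddof=1)) if len(spans) > 1 else None
    return {
        "n_blocks": len(spans),
        "total_bp": int(np.sum(spans)),
        "mean_bp": mean,
        "sd_bp": sd,
    }


def ld_subsample_experiment(
    matrix: GenotypeMatrix,
    marker_fractions: Sequence[float],
    sample_fractions: Sequence[float],
    replicates: int = 1,
    seed: int = 0,
    config: LdConfig = LdConfig(),
) -> list[dict]:
    """Mean block span over a marker-fraction x sample-fraction grid.

    Each grid cell draws ``replicates`` seeded uniform subsamples of markers
    and/or samples, recomputes blocks, and averages the mean block span over
    replicates where it is defined (cells whose every replicate yields no
    block, or fewer than 2 markers, report None).
    """
    if any(not (0 < f <= 1) for f in list(marker_fractions) + list(sample_fractions)):
        raise ValidationError("fractions must lie in (0, 1]")
    rows: list[dict] = []
    for mi, mf in enumerate(marker_fractions):
        for si, sf in enumerate(sample_fractions):
            means: list[float] = []
            n_blocks: list[int] = []
            for rep in range(replicates):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(mi, si, rep))
                )
                n_mark = int(np.ceil(mf * matrix.n_markers))
                n_samp = int(np.ceil(sf * matrix.n_samples))
                marker_idx = (
                    np.arange(matrix.n_markers)
                    if n_mark >= matrix.n_markers
                    else rng.choice(matrix.n_markers, n_mark, replace=False)
                )
                sample_idx = (
                    np.arange(matrix.n_samples)
                    if n_samp >= matrix.n_samples
                    else rng.choice(matrix.n_samples, n_samp, replace=False)
                )
                sub = matrix.subset(marker_idx=marker_idx, sample_idx=sample_idx)
                if sub.n_markers < 2:
                    continue
                summary = block_summary(gabriel_blocks(sub, config))
                n_blocks.append(summary["n_blocks"])
                if summary["n_blocks"] > 0:
                    means.append(summary["mean_bp"])
            rows.append(
                {
                    "marker_fraction": mf,
                    "sample_fraction": sf,
                    "replicates": replicates,
                    "mean_block_bp": float(np.mean(means)) if means else None,
                    "mean_n_blocks": float(np.mean(n_blocks)) if n_blocks else None,
                }
            )
    return rows


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RohSegment:
    """One maximal homozygous run for one sample (1-based inclusive span)."""

    sample: str
    chrom: str
    start_pos: int
    end_pos: int
    n_markers: int
    n_het_allowed_used: int

    def __post_init__(self) -> None:
        if self.end_pos < self.start_pos:
            raise ValidationError("ROH end before start")

    @property
    def span_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


def find_roh(
    matrix: GenotypeMatrix,
    sample: str | int,
    config: RohConfig = RohConfig(),
) -> list[RohSegment]:
    """Maximal homozygous runs for one sample.

    A run is a stretch of consecutive markers with homozygous non-missing
    calls, allowing up to ``max_het`` embedded heterozygotes (never at the
    endpoints) and no adjacent-marker gap above ``max_gap_bp``; missing calls
    terminate runs. Runs shorter than ``min_markers`` markers or
    ``min_span_bp`` bases are dropped. With max_het > 0, reported maximal
    runs may overlap.
    """
    if isinstance(sample, str):
        if sample not in matrix.samples:
            raise ValidationError(f"unknown sample id {sample!r}")
        col = matrix.samples.index(sample)
        name = sample
    else:
        col = sample
        name = matrix.samples[col]

    dosage = matrix.dosage[:, col]
    positions = matrix.positions()
    chrom_labels = [c.chrom for c, _, _ in matrix.markers]

    segments: list[RohSegment] = []
    # chunks: maximal index ranges with no missing call and no oversized gap
    chunk_start = None
    boundaries: list[tuple[int, int]] = []
    for k in range(matrix.n_markers + 1):
        end_chunk = (
            k == matrix.n_markers
            or dosage[k] == MISSING
            or (
                chunk_start is not None
                and k > chunk_start
                and (
                    chrom_labels[k] != chrom_labels[k - 1]
                    or positions[k] - positions[k - 1] > config.max_gap_bp
                )
            )
        )
        if end_chunk:
            if chunk_start is not None and k > chunk_start:
                boundaries.append((chunk_start, k))
            chunk_start = None
            if k < matrix.n_markers and dosage[k] != MISSING:
                chunk_start = k
        elif chunk_start is None:
            chunk_start = k

    for lo, hi in boundaries:
        hets = [k for k in range(lo, hi) if dosage[k] == 1]
        windows: list[tuple[int, int, int]] = []  # (start, end_exclusive, hets used)
        t = config.max_het
        if len(hets) <= t:
            windows.append((lo, hi, len(hets)))
        else:
            for first in range(len(hets) - t + 1):
                left = lo if first == 0 else hets[first - 1] + 1
                right = hi if first + t == len(hets) else hets[first + t]
                windows.append((left, right, t))
        for start, end, used in windows:
            # trim het endpoints (embedded hets only)
            while start < end and dosage[start] == 1:
                start += 1
                used -= 1
            while end > start and dosage[end - 1] == 1:
                end -= 1
                used -= 1
            n = end - start
            if n < max(config.min_markers, 1):
                continue
            span = int(positions[end - 1] - positions[start]) + 1
            if span < config.min_span_bp:
                continue
            segments.append(
                RohSegment(
                    sample=name,
                    chrom=chrom_labels[start],
                    start_pos=int(positions[start]),
                    end_pos=int(positions[end - 1]),
                    n_markers=n,
                    n_het_allowed_used=max(used, 0),
                )
            )
    # windows sharing all their homozygous content after trimming collapse
    uniq = sorted(set((s.chrom, s.start_pos, s.end_pos) for s in segments))
    out = []
    for chrom, start, end in uniq:
        match = next(
            s
            for s in segments
            if (s.chrom, s.start_pos, s.end_pos) == (chrom, start, end)
        )
        out.append(match)
    # drop windows nested inside a larger reported window
    out = [
        s
        for s in out
        if not any(
            o is not s
            and o.chrom == s.chrom
            and o.start_pos <= s.start_pos
            and s.end_pos <= o.end_pos
            for o in out
        )
    ]
    return sorted(out, key=lambda s: (s.chrom, s.start_pos))


def roh_total(segments: Iterable[RohSegment]) -> int:
    """Total base pairs covered by the reported runs (overlaps not merged)."""
    return sum(s.span_bp for s in segments)
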