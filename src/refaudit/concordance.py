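"""Slippage-tolerant concordance between two variant call sets.

Two sequencing projects calling the same genomes rarely report identical
variant lists: sites are missed, and reported coordinates can slip by a base
through alignment ambiguity or 0/1-based bookkeeping. This module partitions
two call sets into shared and set-unique variants while tolerating a bounded
coordinate slippage.

Matching is one-to-one and exact-preferring: within each chromosome the two
position lists are split into independent runs (separated by gaps larger than
the slippage bound) and each run is matched by a dynamic program over the two
sorted lists that maximises, lexicographically, (number of pairs, number of
exact-position pairs). For this banded compatibility structure (|a - b| <=
slip_bp) some maximum matching is always non-crossing, so the DP attains the
true maximum cardinality; preferring exact pairs picks the canonical one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .genomic_io import ValidationError, VariantSite

__all__ = [
    "ConcordanceConfig",
    "ConcordanceResult",
    "restrict_to_shared_samples",
    "match_with_slippage",
    "match_positions",
    "venn_counts",
]


@dataclass(frozen=True)
class ConcordanceConfig:
    """slip_bp: maximum tolerated coordinate offset for a pair (default 1);
    require_allele_match: pairs must additionally share >= 1 ALT allele."""

    slip_bp: int = 1
    require_allele_match: bool = False

    def __post_init__(self) -> None:
        if self.slip_bp < 0:
            raise ValidationError(f"slip_bp must be >= 0, got {self.slip_bp}")


@dataclass
class ConcordanceResult:
    """Partition of two call sets into matched pairs and set-unique variants.

    Positions are (chrom, pos) tuples; ``pairs`` maps set-A positions to their
    set-B partners.
    """

    n_shared: int
    n_unique_a: int
    n_unique_b: int
    pairs: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)
    unique_a: list[tuple[str, int]] = field(default_factory=list)
    unique_b: list[tuple[str, int]] = field(default_factory=list)

    @property
    def pct_unique(self) -> float:
        total = self.n_shared + self.n_unique_a + self.n_unique_b
        if total == 0:
            raise ValidationError("empty concordance universe")
        return 100.0 * (self.n_unique_a + self.n_unique_b) / total


def restrict_to_shared_samples(
    samples_a: Sequence[str],
    sites_a: Sequence[VariantSite],
    samples_b: Sequence[str],
    sites_b: Sequence[VariantSite],
) -> tuple[list[VariantSite], list[VariantSite]]:
    """Keep only sites carried by at least one sample present in both sets.

    A sample "carries" a site when its call is non-missing with >= 1
    non-reference allele. Comparing the genomes the two projects actually
    share removes sampling differences from the unique fractions.
    """
    shared = [s for s in samples_a if s in set(samples_b)]
    if not shared:
        raise ValidationError("call sets share no samples")

    def _restrict(samples: Sequence[str], sites: Sequence[VariantSite]) -> list[VariantSite]:
        cols = [list(samples).index(s) for s in shared]
        kept = [
            site
            for site in sites
            if any(
                site.genotypes[c] is not None
                and (site.genotypes[c][0] > 0 or site.genotypes[c][1] > 0)
                for c in cols
                if c < len(site.genotypes)
            )
        ]
        kept.sort(key=lambda s: (s.coord.chrom, s.coord.pos))
        return kept

    return _restrict(samples_a, sites_a), _restrict(samples_b, sites_b)


def _match_run(
    a: list[int], b: list[int], slip: int
) -> list[tuple[int, int]]:
    """Optimal non-crossing matching of two sorted position lists.

    dp[i][j] holds (pairs, exact pairs) achievable using a[i:], b[j:];
    lexicographic maximum. Reconstruction prefers matching over skipping and
    skips the A side first, which yields a deterministic pair list.
    """
    na, nb = len(a), len(b)
    dp = [[(0, 0)] * (nb + 1) for _ in range(na + 1)]
    for i in range(na - 1, -1, -1):
        row = dp[i]
        nxt = dp[i + 1]
        for j in range(nb - 1, -1, -1):
            best = nxt[j] if nxt[j] >= row[j + 1] else row[j + 1]
            if abs(a[i] - b[j]) <= slip:
                cand = nxt[j + 1]
                cand = (cand[0] + 1, cand[1] + (1 if a[i] == b[j] else 0))
                if cand > best:
                    best = cand
            row[j] = best
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < na and j < nb:
        here = dp[i][j]
        if abs(a[i] - b[j]) <= slip:
            down = dp[i + 1][j + 1]
            cand = (down[0] + 1, down[1] + (1 if a[i] == b[j] else 0))
            if cand == here:
                pairs.append((a[i], b[j]))
                i += 1
                j += 1
                continue
        if dp[i + 1][j] == here:
            i += 1
        else:
            j += 1
    return pairs


def match_positions(
    positions_a: Sequence[tuple[str, int]],
    positions_b: Sequence[tuple[str, int]],
    config: ConcordanceConfig = ConcordanceConfig(),
) -> ConcordanceResult:
    """Partition two (chrom, pos) collections into shared and unique calls.

    Within-set duplicate positions are collapsed before matching. With
    slip_bp = 0 this reduces to exact set intersection.
    """
    set_a = sorted(set(positions_a))
    set_b = sorted(set(positions_b))
    by_chrom_a: dict[str, list[int]] = {}
    by_chrom_b: dict[str, list[int]] = {}
    for chrom, pos in set_a:
        by_chrom_a.setdefault(chrom, []).append(pos)
    for chrom, pos in set_b:
        by_chrom_b.setdefault(chrom, []).append(pos)

    pairs: list[tuple[tuple[str, int], tuple[str, int]]] = []
    slip = config.slip_bp
    for chrom in sorted(set(by_chrom_a) | set(by_chrom_b)):
        a = by_chrom_a.get(chrom, [])
        b = by_chrom_b.get(chrom, [])
        if not a or not b:
            continue
        # split into runs separated by > slip so the DP works on small pieces
        merged = sorted([(p, 0) for p in a] + [(p, 1) for p in b])
        run_a: list[int] = []
        run_b: list[int] = []
        prev = None
        for pos, which in merged:
            if prev is not None and pos - prev > slip:
                for pa, pb in _match_run(run_a, run_b, slip):
                    pairs.append(((chrom, pa), (chrom, pb)))
                run_a, run_b = [], []
            (run_a if which == 0 else run_b).append(pos)
            prev = pos
        for pa, pb in _match_run(run_a, run_b, slip):
            pairs.append(((chrom, pa), (chrom, pb)))

    matched_a = {p for p, _ in pairs}
    matched_b = {p for _, p in pairs}
    unique_a = [p for p in set_a if p not in matched_a]
    unique_b = [p for p in set_b if p not in matched_b]
    return ConcordanceResult(
        n_shared=len(pairs),
        n_unique_a=len(unique_a),
        n_unique_b=len(unique_b),
        pairs=sorted(pairs),
        unique_a=unique_a,
        unique_b=unique_b,
    )


def match_with_slippage(
    sites_a: Sequence[VariantSite],
    sites_b: Sequence[VariantSite],
    config: ConcordanceConfig = ConcordanceConfig(),
) -> ConcordanceResult:
    """Site-level wrapper around :func:`match_positions`.

    With ``require_allele_match``, positional pairs are additionally required
    to share >= 1 ALT allele; pairs failing the allele check are dissolved
    back into the unique partitions.
    """
    if not config.require_allele_match:
        return match_positions(
            [(s.coord.chrom, s.coord.pos) for s in sites_a],
            [(s.coord.chrom, s.coord.pos) for s in sites_b],
            config,
        )

    alts_a: dict[tuple[str, int], set[str]] = {}
    alts_b: dict[tuple[str, int], set[str]] = {}
    for site in sites_a:
        alts_a.setdefault((site.coord.chrom, site.coord.pos), set()).update(site.alts)
    for site in sites_b:
        alts_b.setdefault((site.coord.chrom, site.coord.pos), set()).update(site.alts)

    base = match_positions(list(alts_a), list(alts_b), config)
    kept = [
        (pa, pb) for pa, pb in base.pairs if alts_a[pa] & alts_b[pb]
    ]
    matched_a = {p for p, _ in kept}
    matched_b = {p for _, p in kept}
    unique_a = sorted(p for p in alts_a if p not in matched_a)
    unique_b = sorted(p for p in alts_b if p not in matched_b)
    return ConcordanceResult(
        n_shared=len(kept),
        n_unique_a=len(unique_a),
        n_unique_b=len(unique_b),
        pairs=sorted(kept),
        unique_a=unique_a,
        unique_b=unique_b,
    )


def venn_counts(result: ConcordanceResult) -> dict:
    """Three-way partition summary with the unique percentage."""
    total = result.n_shared + result.n_unique_a + result.n_unique_b
    if total == 0:
        raise ValidationError("empty concordance universe")
    return {
        "n_unique_a": result.n_unique_a,
        "n_shared": result.n_shared,
        "n_unique_b": result.n_unique_b,
        "n_total": total,
        "pct_unique": result.pct_unique,
    }
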