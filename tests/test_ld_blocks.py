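"""ld_blocks: EM, |D'| CIs, Gabriel blocks, subsampling, ROH."""

import itertools

import numpy as np
import pytest

from refaudit.genomic_io import GenomeCoordinate, ValidationError
from refaudit.ld_blocks import (
    MISSING,
    RECOMB,
    STRONG_LD,
    UNINFORMATIVE,
    GenotypeMatrix,
    HaplotypeBlock,
    LdConfig,
    RohConfig,
    block_summary,
    dprime_ci,
    em_haplotype_freqs,
    find_roh,
    gabriel_blocks,
    ld_subsample_experiment,
    matrix_from_sites,
    roh_total,
    trim_by_call_rate,
)
from refaudit.synthetic import BlockLayout, CohortSpec, simulate_cohort
from tests.conftest import make_site, random_matrix


def loglik(freqs, counts):
    """Multinomial genotype log-likelihood at given haplotype freqs."""
    f00, f01, f10, f11 = freqs
    probs = np.array([
        f00 * f00, 2 * f00 * f01, f01 * f01,
        2 * f00 * f10, 2 * (f00 * f11 + f01 * f10), 2 * f01 * f11,
        f10 * f10, 2 * f10 * f11, f11 * f11,
    ])
    with np.errstate(divide="ignore"):
        logp = np.where(probs > 0, np.log(np.maximum(probs, 1e-300)), -np.inf)
    return float(np.where(counts > 0, counts * logp, 0.0).sum())


def genotype_counts(di, dj):
    counts = np.zeros(9)
    for a, b in zip(di, dj):
        if a != MISSING and b != MISSING:
            counts[a * 3 + b] += 1
    return counts


class TestTrim:
    def test_two_missing_of_100_dropped_at_99pct(self, rng):
        m = random_matrix(rng, n_markers=3, n_samples=100)
        m.dosage[1, :2] = MISSING  # call rate 0.98
        trimmed = trim_by_call_rate(m, 0.99)
        assert trimmed.n_markers == 2
        assert trimmed.markers == [m.markers[0], m.markers[2]]

    def test_no_missing_kept(self, rng):
        m = random_matrix(rng, n_markers=5)
        assert trim_by_call_rate(m, 0.99).n_markers == 5

    def test_threshold_zero_identity(self, rng):
        m = random_matrix(rng, n_markers=5, missing_rate=0.5)
        assert trim_by_call_rate(m, 0.0).n_markers == 5

    def test_never_increases_markers(self, rng):
        m = random_matrix(rng, n_markers=30, missing_rate=0.1)
        for thr in (0.0, 0.5, 0.9, 1.0):
            assert trim_by_call_rate(m, thr).n_markers <= m.n_markers


class TestEm:
    def test_all_hom_ref(self):
        f = em_haplotype_freqs([0, 0, 0], [0, 0, 0])
        assert f[0] == pytest.approx(1.0)

    def test_no_double_het_equals_direct_counting(self, rng):
        for _ in range(20):
            n = 40
            di = rng.integers(0, 3, n)
            dj = rng.integers(0, 3, n)
            dj[di == 1] = rng.choice([0, 2], size=(di == 1).sum())  # kill double hets
            f = em_haplotype_freqs(di, dj)
            # direct gamete counting (unambiguous when no double hets)
            counts = np.zeros(4)
            for a, b in zip(di, dj):
                ga = [0] * (2 - a) + [1] * a
                gb = [0] * (2 - b) + [1] * b
                if a == 1 and b == 1:
                    raise AssertionError("double het not removed")
                # without double hets every gamete pairing yields the same
                # multiset of haplotypes
                for x in range(2):
                    counts[ga[x] * 2 + gb[x]] += 1
            counts /= counts.sum()
            assert np.allclose(f, counts, atol=1e-9)

    def test_frequencies_sum_to_one_and_nonnegative(self, rng):
        for _ in range(30):
            di = rng.integers(0, 3, 30)
            dj = rng.integers(0, 3, 30)
            f = em_haplotype_freqs(di, dj)
            assert f.min() >= 0
            assert abs(f.sum() - 1) < 1e-9

    def test_sample_order_invariance(self, rng):
        di = rng.integers(0, 3, 50)
        dj = rng.integers(0, 3, 50)
        perm = rng.permutation(50)
        assert np.allclose(
            em_haplotype_freqs(di, dj), em_haplotype_freqs(di[perm], dj[perm])
        )

    def test_missing_pairs_dropped(self):
        f_full = em_haplotype_freqs([0, 2, 0, 2], [0, 2, 0, 2])
        f_miss = em_haplotype_freqs([0, 2, 0, 2, MISSING], [0, 2, 0, 2, 1])
        assert np.allclose(f_full, f_miss)

    def test_fixed_point_beats_random_simplex(self, rng):
        """EM fixed-point likelihood >= 2000 random simplex points."""
        for _ in range(10):
            di = rng.integers(0, 3, 50)
            dj = rng.integers(0, 3, 50)
            counts = genotype_counts(di, dj)
            f = em_haplotype_freqs(di, dj)
            best = loglik(f, counts)
            rand = rng.dirichlet(np.ones(4), size=2000)
            rand_ll = max(loglik(r, counts) for r in rand)
            assert best >= rand_ll - 1e-7


class TestDprime:
    def test_perfect_coupling(self):
        di = np.array([0] * 50 + [2] * 50)
        r = dprime_ci(di, di.copy())
        assert r.Dprime == pytest.approx(1.0)
        assert r.r2 == pytest.approx(1.0)
        assert r.status == STRONG_LD

    def test_equilibrium_quarter_table(self):
        # dosages built from independent haplotype draws at exact equilibrium
        haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
        di, dj = [], []
        for (a1, b1), (a2, b2) in itertools.product(haps, repeat=2):
            di.append(a1 + a2)
            dj.append(b1 + b2)
        r = dprime_ci(np.array(di), np.array(dj))
        assert r.D == pytest.approx(0.0, abs=1e-9)
        assert r.r2 == pytest.approx(0.0, abs=1e-9)

    def test_independent_loci_recomb(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            di = rng.binomial(1, 0.5, 500) + rng.binomial(1, 0.5, 500)
            dj = rng.binomial(1, 0.5, 500) + rng.binomial(1, 0.5, 500)
            r = dprime_ci(di, dj)
            assert r.Dprime < 0.3
            hits += r.status == RECOMB
        assert hits >= 18  # overwhelmingly classified as recombination

    def test_monomorphic_uninformative(self):
        r = dprime_ci([0] * 30, [0, 1, 2] * 10)
        assert r.status == UNINFORMATIVE
        assert (r.ci_low, r.ci_high) == (0.0, 1.0)

    def test_bounds_and_r2_implication(self, rng):
        for _ in range(40):
            di = rng.integers(0, 3, 40)
            dj = rng.integers(0, 3, 40)
            r = dprime_ci(di, dj)
            assert 0 <= r.Dprime <= 1
            assert 0 <= r.r2 <= 1
            assert 0 <= r.ci_low <= r.ci_high <= 1
            if r.r2 > 1 - 1e-9:
                assert r.Dprime == pytest.approx(1.0)


def exhaustive_blocks(matrix, config):
    """Literal re-derivation of the block partition: classify every pair via
    the scalar path, enumerate all candidate spans, apply the same greedy."""
    maf = matrix.maf()
    eligible = [k for k in range(matrix.n_markers) if maf[k] >= config.maf_min]
    pos = matrix.positions()
    status = {}
    for a, b in itertools.combinations(range(len(eligible)), 2):
        i, j = eligible[a], eligible[b]
        if pos[j] - pos[i] + 1 > config.max_block_span_bp:
            continue
        status[(a, b)] = dprime_ci(matrix.dosage[i], matrix.dosage[j], config).status
    candidates = []
    for (a, b), st in status.items():
        if st != STRONG_LD:
            continue
        inner = [
            status[(x, y)]
            for x, y in itertools.combinations(range(a, b + 1), 2)
            if (x, y) in status
        ]
        informative = [s for s in inner if s in (STRONG_LD, RECOMB)]
        if informative and sum(
            s == STRONG_LD for s in informative
        ) / len(informative) >= config.strong_fraction:
            span = int(pos[eligible[b]] - pos[eligible[a]]) + 1
            candidates.append((span, a, b))
    candidates.sort(key=lambda t: (-t[0], pos[eligible[t[1]]]))
    taken = set()
    blocks = []
    for span, a, b in candidates:
        if any(k in taken for k in range(a, b + 1)):
            continue
        taken.update(range(a, b + 1))
        blocks.append(
            HaplotypeBlock(matrix.markers[0][0].chrom, eligible[a], eligible[b], span)
        )
    return sorted(blocks, key=lambda blk: blk.first_marker)


class TestGabrielBlocks:
    def test_single_marker_no_blocks(self, rng):
        m = random_matrix(rng, n_markers=1)
        assert gabriel_blocks(m) == []

    def test_planted_two_blocks_recovered(self, small_cohort):
        matrix, truth = small_cohort
        blocks = gabriel_blocks(matrix)
        assert [(b.first_marker, b.last_marker) for b in blocks] == truth

    def test_output_non_overlapping_and_sorted(self, rng):
        m = random_matrix(rng, n_markers=15, n_samples=60)
        blocks = gabriel_blocks(m)
        for b1, b2 in zip(blocks, blocks[1:]):
            assert b1.last_marker < b2.first_marker

    def test_matches_exhaustive_enumeration_small(self):
        """Windowed/prefix-sum implementation equals the literal O(n^4)
        re-derivation on small seeded instances."""
        cfg = LdConfig(max_block_span_bp=100_000)
        for seed in range(8):
            spec = CohortSpec(
                n_samples=60,
                blocks=(BlockLayout(n_markers=4, spacing_bp=500),
                        BlockLayout(n_markers=4, spacing_bp=500)),
                seed=seed,
            )
            matrix, _ = simulate_cohort(spec)
            assert gabriel_blocks(matrix, cfg) == exhaustive_blocks(matrix, cfg)

    def test_invariant_to_marker_relabeling(self, small_cohort):
        matrix, _ = small_cohort
        renamed = GenotypeMatrix(
            samples=matrix.samples,
            markers=[
                (GenomeCoordinate(c.chrom, c.pos), alt, ref)  # swap allele labels
                for (c, ref, alt) in matrix.markers
            ],
            dosage=(2 - matrix.dosage).astype(np.int8),  # relabel ref<->alt
        )
        a = [(b.first_marker, b.last_marker) for b in gabriel_blocks(matrix)]
        b = [(b.first_marker, b.last_marker) for b in gabriel_blocks(renamed)]
        assert a == b


class TestBlockSummary:
    def test_two_blocks(self):
        blocks = [
            HaplotypeBlock("1", 0, 5, 10_000),
            HaplotypeBlock("1", 6, 9, 20_000),
        ]
        s = block_summary(blocks)
        assert (s["n_blocks"], s["total_bp"], s["mean_bp"]) == (2, 30_000, 15_000)

    def test_single_block_sd_undefined(self):
        s = block_summary([HaplotypeBlock("1", 0, 2, 5000)])
        assert s["sd_bp"] is None

    def test_empty(self):
        s = block_summary([])
        assert (s["n_blocks"], s["total_bp"], s["sd_bp"]) == (0, 0, None)

    def test_totals_fuzzed(self, rng):
        spans = [int(x) for x in rng.integers(2, 10_000, size=25)]
        blocks = [
            HaplotypeBlock("1", 2 * k, 2 * k + 1, s) for k, s in enumerate(spans)
        ]
        assert block_summary(blocks)["total_bp"] == sum(spans)


class TestSubsampleExperiment:
    def test_full_fractions_equal_full_data(self, small_cohort):
        matrix, _ = small_cohort
        grid = ld_subsample_experiment(matrix, [1.0], [1.0], replicates=2, seed=3)
        full = block_summary(gabriel_blocks(matrix))
        assert grid[0]["mean_block_bp"] == pytest.approx(full["mean_bp"])

    def test_same_seed_identical(self, small_cohort):
        matrix, _ = small_cohort
        g1 = ld_subsample_experiment(matrix, [0.5], [0.5], replicates=2, seed=9)
        g2 = ld_subsample_experiment(matrix, [0.5], [0.5], replicates=2, seed=9)
        assert g1 == g2

    def test_tiny_subsample_undefined(self, rng):
        m = random_matrix(rng, n_markers=3)
        grid = ld_subsample_experiment(m, [0.1], [1.0], replicates=1, seed=0)
        assert grid[0]["mean_block_bp"] is None


def brute_force_roh(matrix, col, cfg):
    """Quadratic oracle: all maximal valid windows, then filters."""
    dosage = matrix.dosage[:, col]
    pos = matrix.positions()
    chroms = [c.chrom for c, _, _ in matrix.markers]
    n = matrix.n_markers

    def valid(i, j):
        if dosage[i] == 1 or dosage[j] == 1:
            return False
        for k in range(i, j + 1):
            if dosage[k] == MISSING:
                return False
            if k > i and (chroms[k] != chroms[k - 1]
                          or pos[k] - pos[k - 1] > cfg.max_gap_bp):
                return False
        return sum(dosage[k] == 1 for k in range(i, j + 1)) <= cfg.max_het

    wins = [(i, j) for i in range(n) for j in range(i, n) if valid(i, j)]
    maximal = [
        (i, j)
        for i, j in wins
        if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in wins)
    ]
    out = set()
    for i, j in maximal:
        if j - i + 1 >= max(cfg.min_markers, 1) and pos[j] - pos[i] + 1 >= cfg.min_span_bp:
            out.add((int(pos[i]), int(pos[j])))
    return out


class TestRoh:
    CFG = RohConfig(min_markers=5, min_span_bp=400, max_het=1, max_gap_bp=1000)

    def matrix_for(self, dosages, spacing=100):
        d = np.array([dosages], dtype=np.int8).T
        markers = [
            (GenomeCoordinate("1", 1000 + spacing * k), "A", "G")
            for k in range(len(dosages))
        ]
        return GenotypeMatrix(samples=["s"], markers=markers, dosage=d)

    def test_all_het_no_segments(self):
        m = self.matrix_for([1] * 30)
        assert find_roh(m, "s", self.CFG) == []

    def test_simple_run_recovered(self):
        m = self.matrix_for([1, 1] + [0] * 10 + [1, 1])
        segs = find_roh(m, "s", self.CFG)
        assert len(segs) == 1
        assert (segs[0].start_pos, segs[0].end_pos) == (1200, 2100)
        assert segs[0].n_markers == 10

    def test_embedded_het_allowed_then_split(self):
        calls = [1, 1] + [0] * 5 + [1] + [0] * 5 + [1, 1]
        m = self.matrix_for(calls)
        keep = find_roh(m, "s", self.CFG)
        assert len(keep) == 1
        assert keep[0].n_markers == 11
        strict = find_roh(m, "s", RohConfig(min_markers=5, min_span_bp=400,
                                            max_het=0, max_gap_bp=1000))
        assert len(strict) == 2  # split at the embedded het

    def test_missing_breaks_run(self):
        calls = [0] * 6 + [MISSING] + [0] * 6
        m = self.matrix_for(calls)
        segs = find_roh(m, "s", self.CFG)
        assert len(segs) == 2

    def test_gap_breaks_run(self):
        m = self.matrix_for([0] * 12, spacing=100)
        wide = GenotypeMatrix(
            samples=["s"],
            markers=[(GenomeCoordinate("1", p), "A", "G")
                     for p in list(range(1000, 1600, 100)) + list(range(9000, 9600, 100))],
            dosage=m.dosage,
        )
        segs = find_roh(wide, "s", self.CFG)
        assert len(segs) == 2

    def test_unknown_sample_is_error(self, rng):
        m = random_matrix(rng, n_markers=5)
        with pytest.raises(ValidationError):
            find_roh(m, "nobody")

    def test_matches_brute_force(self, rng):
        cfg = self.CFG
        for _ in range(25):
            n = int(rng.integers(10, 120))
            dosages = rng.choice([0, 1, 2, MISSING], size=n,
                                 p=[0.45, 0.2, 0.3, 0.05])
            m = self.matrix_for(list(dosages))
            got = {(s.start_pos, s.end_pos) for s in find_roh(m, "s", cfg)}
            assert got == brute_force_roh(m, 0, cfg)

    def test_roh_total(self):
        m = self.matrix_for([0] * 10)
        segs = find_roh(m, "s", self.CFG)
        assert roh_total(segs) == sum(s.span_bp for s in segs) == 901


class TestMatrixFromSites:
    def test_indels_and_multiallelics_skipped(self):
        sites = [
            make_site(100, genotypes=[(0, 1)]),
            make_site(200, alts=("CT",), genotypes=[(0, 1)]),
            make_site(300, alts=("C", "T"), genotypes=[(0, 1)]),
        ]
        m = matrix_from_sites(["s1"], sites)
        assert m.n_markers == 1
        assert m.dosage[0, 0] == 1

    def test_dosage_and_missing(self):
        sites = [make_site(100, genotypes=[(0, 0), (0, 1), (1, 1), None])]
        m = matrix_from_sites(["a", "b", "c", "d"], sites)
        assert list(m.dosage[0]) == [0, 1, 2, MISSING]
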