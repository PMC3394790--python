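# Methods

This note records the models, numerical choices and open design decisions
behind `refaudit`, in the order the pipeline runs them.

## Coordinate and genotype conventions

Point loci (variants, probe targets, catalog hits) are 1-based, as in VCF;
spans (structural variants, exons, probe footprints) are 0-based half-open,
as in BED. Conversions happen only inside `genomic_io` readers/writers —
mixing the two conventions is itself a known source of off-by-one errors in
call-set comparisons, which is one reason the concordance stage tolerates
±1 bp slippage. Chromosome names are normalized (`chr1` ≡ `1`). Any
genotype containing a missing allele (`./.`, `0/.`) is treated as fully
missing; phased and unphased separators are equivalent, and phase is never
used (the two-locus EM works from unphased dosages).

## Probe audit

A probe is modeled as a target coordinate plus a designed allele pair and an
optional footprint. Three failure modes are flagged:

* **Flanking variants** (`FLANK_SNP`/`FLANK_INDEL`): any catalog variant at
  distance 1..`window_bp` from the target on the same chromosome. The
  window is inclusive at ±`window_bp` (default 10), so offsets ±1..±10 flag
  and ±11 does not; a variant exactly at the target never produces a
  flanking flag — its allele content is the polyallelic check's business.
  A variant is an indel iff any of its alleles has length ≠ 1.
* **Structural-variant containment** (`SV_OVERLAP`): by default the target
  base falls inside an SV interval (`target_in_sv`); the stricter
  `footprint_in_sv` rule requires the whole footprint to be contained in a
  single SV and falls back to the target rule for probes without footprints.
  The default is the target rule because real vendor manifests often omit
  footprints.
* **Polyallelic target** (`POLYALLELIC`): pooling all catalog records at the
  target coordinate, more than two distinct bases are *carried* (an allele
  counts only if ≥ 1 sample carries it; the reference counts only when some
  sample carries allele 0), or some sample is heterozygous with both bases
  outside the designed pair. Declared-but-uncarried ALT alleles never count.

The per-platform summary keeps the four categories plus two union columns
(SNP-or-indel, and all categories), deduplicating probes flagged for more
than one reason. Percentages are exact counts divided by probe number,
rounded only for display.

The saturation curve redraws, for each catalog fraction *f*, `replicates`
uniform subsamples without replacement of ⌈f·V⌉ variants and averages the
flanking-flagged probe count. Each (fraction, replicate) cell derives its
own RNG stream from the master seed, so the curve is reproducible and
independent of evaluation order; at *f* = 1 the subsample is the full
catalog and the curve is deterministic.

GWAS matching prefers SNP id and falls back to exact coordinate; no slippage
is applied because catalog and manifest share one genome build. A study is
affected iff ≥ 1 of its rows matches a flagged probe.

## Variant statistics

Polyallelic sites use the same carried-alleles rule as the probe audit. A
"heterozygous dual non-reference" call is a het whose two bases are both ≠
the reference base. Burden counts are per sample: a variant qualifies iff
the sample carries ≥ 1 alternate allele there (hom-alt counts once);
variants are assigned to exon/CDS intervals by point position (indels by
their anchor base); an exon is multi-variant at ≥ 2 qualifying variants, a
gene at ≥ 2 summed over its intervals. Overlapping transcript exons are
modeled as distinct genomic intervals counted once each.

## Concordance

Within-set duplicate positions collapse first; matching is per chromosome.
Two calls are compatible iff their positions differ by ≤ `slip_bp`
(default 1). The matcher must be one-to-one and well defined; a naive
"expand each position by ±1 and intersect" can double-match. We use an
optimal non-crossing dynamic program over the two sorted position lists
(split into independent runs separated by gaps > `slip_bp`): it maximizes,
lexicographically, (number of pairs, number of exact-position pairs), and
reconstruction is deterministic. For this banded compatibility structure an
uncrossing argument shows some maximum matching is always non-crossing, so
the DP attains true maximum cardinality — a property we verify against
brute-force maximum bipartite matching in the tests — while the secondary
objective keeps exact pairs preferred (e.g. A={100,101}, B={100} pairs
100/100 and leaves 101 unique). A simpler two-pass greedy (exact matches
first, then nearest-neighbor) was rejected because it is not
maximum-cardinality: for A={101,102}, B={100,101} it strands two matchable
calls. With `slip_bp = 0` the DP reduces to exact set intersection.
`require_allele_match` additionally dissolves pairs that share no ALT
allele. Restricting to shared samples keeps sites carried (≥ 1 alt allele,
non-missing) by at least one sample present in both sets.

## LD machinery

**Call-rate trim.** Markers with a non-missing genotype fraction below the
threshold (default 0.99) are dropped before any LD computation, because the
EM and CI computations degrade with missingness.

**Two-locus EM.** For a marker pair the 3×3 genotype table has one ambiguous
cell, the double heterozygote, which is either coupling (00/11) or repulsion
(01/10). The EM starts at linkage equilibrium of the observed allele
frequencies and iterates the standard update to `em_tol` = 1e-8 (max 100
iterations); with no double heterozygotes it equals direct gamete counting
in one step. Pairs with missing calls at either locus are dropped;
frequencies always sum to 1 and the result is independent of sample order.

**|D′| confidence interval.** The multinomial log-likelihood of the genotype
table is profiled over |D′| ∈ [0,1] on a grid (step 0.001), with allele
frequencies fixed at their MLEs and D signed like the MLE. The exponentiated
profile is normalized to unit mass and the 5th/95th cumulative points are
the interval — the same construction Haploview uses. Pair classification:
strong LD iff CI lower ≥ 0.70 and upper ≥ 0.98; strong evidence of
recombination iff upper < 0.90; otherwise uninformative. Monomorphic loci or
fewer than two informative samples are uninformative with a vacuous [0,1]
interval. Cells with zero counts contribute nothing, so zero-probability
cells only penalize when observed.

**Blocks.** Markers below `maf_min` = 0.05 are not classified but remain in
coordinates (they can sit inside a block's span). Candidate spans must (i)
span ≤ `max_block_span_bp`, (ii) have a strong-LD end pair, and (iii) have
≥ `strong_fraction` = 0.95 of their informative pairs strong. Candidates
are accepted greedily by decreasing bp span, ties broken leftmost, skipping
spans that overlap an accepted block; the output is sorted and
non-overlapping. The windowed/prefix-sum implementation is checked against
a literal re-derivation (classify all pairs, enumerate all spans) on small
instances. The library default for `max_block_span_bp` is 500 kb; the
analysis scripts and the end-to-end demo pass 50 kb because on a ~1 Mb
synthetic chromosome with ~10 kb true blocks no longer span can satisfy the
strong-fraction criterion, and the cap bounds the number of classified
pairs.

**Subsampling experiment.** Each (marker fraction, sample fraction,
replicate) cell draws a seeded subsample, recomputes blocks, and averages
the mean span over replicates where blocks exist; cells with < 2 markers or
no blocks are undefined rather than zero.

**Runs of homozygosity.** A run is a maximal stretch of consecutive
homozygous non-missing calls for one sample, allowing ≤ `max_het` embedded
heterozygotes (never at the endpoints) and no adjacent-marker gap >
`max_gap_bp`; missing calls terminate runs. Runs with < `min_markers`
markers or spanning < `min_span_bp` are dropped. With `max_het` > 0,
distinct maximal runs can overlap (they share homozygous stretches around
different embedded hets); nested runs are suppressed. The defaults
(25 markers, 500 kb, 1 het, 100 kb gap) correspond to array-density marker
maps; the vendor tool the field historically used for this does not publish
its defaults, so ours are explicit and echoed in run metadata. The
synthetic demo uses `min_span_bp` = 100 kb because its 1 Mb chromosome
cannot hold a 500 kb run.

## Synthetic cohort generator

The generator's job is to produce inputs whose correct analysis output is
known exactly.

**LD model.** Each block has a pool of `pool_size` haplotypes (default 3)
over its markers; each sample draws two haplotypes per block. This
block-copy model was chosen over a coalescent simulator because it makes
the true block boundaries exact and is fast; it does not emulate
genealogies, recombination maps, mutation spectra or allele-frequency
ascertainment, so passing tests demonstrate correct *detection machinery*,
not population-genetic realism. Pool frequencies default to uniform: every
marker's MAF is then ≥ 1/pool_size, which keeps endpoint pairs of a
planted block informative enough (CI lower bound ≥ 0.70 at n = 100) for the
planted boundaries to be identifiable — with strongly skewed pools the
block definition itself (correctly) refuses to certify low-frequency
endpoint pairs and planted-truth recovery is not a well-posed test.

Two optional features shape between-block structure:

* `inter_block_retain` — each haplotype lineage keeps its pool index from
  the previous block with this probability (Markov retention), emulating
  partial LD across historical recombination breakpoints; 0 (default)
  makes blocks independent, which is what exact boundary-recovery tests
  use.
* `disruptor_rate` — this fraction of markers is replaced by variants drawn
  independently of the local haplotype background (allele frequency
  uniform in 0.2–0.5), emulating young variants carried on recombined or
  recurrent-mutation backgrounds. Disruptors are what make the
  marker-density experiment behave like real data: pair classification is
  density-independent, so with purely block-uniform LD a sparser panel can
  only shorten detected spans (detected endpoints move inward). What
  shrinks blocks in dense real panels is that each additional marker is
  another chance to reveal recombination evidence *inside* a span; the
  number of revealing markers in a span scales with density while the
  per-marker rate is fixed, which is exactly what a constant
  `disruptor_rate` provides. At 0.1 on a 20×50-marker backbone the
  detected mean span at one-quarter density is ~2.5–3× the full-density
  mean, matching the magnitude of the published HapMap-vs-sequencing
  contrast.

**Plants.** Probe plants target existing biallelic sites whose 2×window
neighborhood is empty, so planted flags are the only flags; flanking plants
insert a new variant at target+offset (coordinate collisions probe upward
to the next free base, and the realized offset is recorded in the truth);
SV plants write a containing interval; polyallelic plants inject a third
carried base plus a guaranteed carrier of the designed alternate.
Dual-non-reference plants give one sample a het of two non-reference bases
(such sites are, by construction, also polyallelic once the rest of the
cohort carries the reference, and the truth accounts for that). ROH plants
force the major allele over a marker range and set the two flanking markers
on each side heterozygous, so the planted boundary is identifiable under
the detector's embedded-het allowance (one accidental boundary crossing
would need more hets than `max_het` = 1 permits). Caller views drop truth
sites at per-view miss rates, slip view B's coordinate by ±1 with
probability `slip_prob` (only when the shifted coordinate stays ≥ 2 bp from
every other site, keeping the truth partition the unique optimal matching),
and add isolated private sites at `extra_rate`. The GWAS catalog gives
exactly round(`affected_fraction`·n) studies one hit on a flagged probe and
fills everything else with clean-probe hits.

**Determinism.** Every generator derives its RNG stream from
(master seed, label) via a stable hash, so adding a generator never
perturbs another's output, and all emitted files are byte-identical across
runs with one seed.

## Study conditions used by the demo and acceptance runs

One hundred 10-marker blocks at 1 kb spacing (1,000 markers, ~1 Mb), 100
samples, 0.2% missing calls; 200 probes of which 40 carry planted problems
(12/10/10/8 across the four categories); 26 planted polyallelic sites
(6 standalone + 12 via dual-non-reference plants + 8 via probe plants); two
200-marker ROH plants; caller views at miss rates 0.1/0.1, slip 0.2,
extras 0.05; 100 GWAS studies at affected fraction 0.34. The density
experiment uses a separate 1,000-marker cohort (20×50 markers,
`disruptor_rate` 0.1) at full and quarter density. These sizes keep a full
run around one to two minutes while leaving every planted artifact
unambiguous.

## Known limitations

* The generator's LD is haplotype-pool-based; quantities that depend on
  fine-scale recombination-rate variation or allele-frequency spectra
  (e.g. absolute block-size distributions) are not comparable to real
  cohorts, only the qualitative density dependence is.
* Indels are point-anchored; no left-alignment/normalization is performed
  before concordance matching.
* Genotype-level (dosage) concordance, symbolic ALT alleles, liftover
  between builds, and vendor-native manifest formats are out of scope;
  structural variants enter only as BED intervals.
* The |D′| CI fixes allele frequencies at their MLEs (profile, not joint,
  likelihood), the standard shortcut; intervals are slightly narrow for
  rare alleles.
* `audit_summary` keeps flanking-SNP and flanking-indel categories disjoint
  by variant class and provides both unions; whether a historical audit
  table would have counted an indel-flagged probe under its SNP column is
  not recoverable from the published layouts.
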