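# refaudit

Population-scale variant catalogs (thousands of sequenced genomes) break
several quiet assumptions baked into reference-genome-based tools: that the
sequence around an assayed SNP is invariant, that polymorphic sites are
biallelic, that haplotype-block maps and runs of homozygosity estimated from
sparse marker panels describe the genome rather than the panel, and that two
pipelines calling variants on the same genomes will agree. `refaudit` is an
analysis pipeline that quantifies each of these failure modes:

* **probe audit** — flag genotyping-array probes confounded by unprobed
  SNPs/indels within a flanking window of the target, by containment in an
  annotated structural variant, or by a polyallelic target (more than two
  bases carried across the cohort, or a heterozygote with both alleles
  outside the designed pair); summarize per platform, histogram the flanking
  offsets, and measure how the flagged count grows as the variant catalog is
  subsampled (saturation);
* **variant statistics** — polyallelic site detection, per-genome
  "heterozygous, dual non-reference" call counts, and the multi-variant
  burden of genes and exons;
* **call-set concordance** — one-to-one matching of two call sets with ±1 bp
  coordinate-slippage tolerance, partitioning calls into shared and
  set-unique;
* **LD machinery** — 99% call-rate trimming, two-locus EM haplotype
  frequencies from unphased genotypes, |D′| with profile-likelihood 90%
  confidence intervals, Gabriel-style haplotype-block partitioning
  (strong LD: CI bounds ≥ 0.70/0.98; recombination: upper bound < 0.90;
  ≥ 95% of informative pairs strong), block-size response to marker density,
  and runs-of-homozygosity detection;
* **GWAS cross-reference** — the fraction of association studies whose
  reported hits rest on at least one flagged probe.

Because the original data sources are multi-gigabyte consortium downloads,
everything here runs against a **synthetic cohort generator with planted
ground truth**: block-structured diploid haplotypes with configurable LD,
planted probe problems of every category, planted polyallelic and
dual-non-reference sites, planted homozygous runs, two corrupted "caller
views" of one truth set, and a catalog with a planted affected-study set.
Every analysis is validated by recovering exactly what was planted, or by
agreement with an independent brute-force oracle.

## Core statistics

For two biallelic loci with alt-allele frequencies *p*, *q* and haplotype
frequency *f₁₁* (alt at both), the disequilibrium coefficient is
*D = f₁₁ − pq*, normalized to *D′ = D / D_max* with the usual sign-dependent
*D_max*, and *r² = D² / p(1−p)q(1−q)*. Haplotype frequencies for unphased
genotype pairs come from the standard EM over the single ambiguous class
(double heterozygotes). The 90% CI on |D′| is a normalized profile
likelihood over |D′| ∈ [0,1] on a 0.001 grid with allele frequencies held at
their MLEs; blocks are spans whose end pair is in strong LD and whose
informative pairs are ≥ 95% strong, accepted greedily by decreasing span.

## Worked example

The numbered scripts under `analysis/` run the full study against the
generated data in `results/data/`:

```
$ python analysis/01_simulate.py --seed 1
wrote synthetic study to results/data (seed 1)
  cohort: 100 samples, 1000 markers in 100 true blocks
  probes: 200 (40 with planted problems)
  ...

$ python analysis/02_probe_audit.py
probe audit summary (counts of probes confounded by unprobed variation):
         flank_snp:   12 (6.0%)
       flank_indel:   10 (5.0%)
        sv_overlap:   10 (5.0%)
       polyallelic:    8 (4.0%)
   union_snp_indel:   22 (11.0%)
         union_all:   40 (20.0%)
planted-flag recovery: 200/200 probes exact
saturation curve (catalog fraction -> mean flagged probes):
  0.2 -> 4.6
  0.4 -> 9.3
  0.6 -> 13.2
  0.8 -> 17.6
  1.0 -> 22.0

$ python analysis/05_ld_blocks.py --seed 1
haplotype blocks: 100 blocks, mean span 8.9 kb, total 888 kb
  (cohort has 100 planted blocks)
marker-density experiment (mean detected block span):
  100% of markers: 8.5 kb
   25% of markers: 22.0 kb (2.6x longer at the sparse density)
...

$ python analysis/06_gwas_xref.py
GWAS cross-reference: 34/100 studies (34%) have a hit on a flagged probe
```

The audit table mirrors the per-platform layout used for real array
platforms; the union columns deduplicate probes that are problematic for
more than one reason. The saturation curve rising without flattening means
the flagged-probe count is limited by the catalog, not the array. The
density experiment shows the central LD finding: block maps built from
sparse panels overestimate block length (here 2.6× at one-quarter density),
because each added marker is another chance to reveal a recombination
event. The 34% affected-study figure is recovered exactly from the planted
truth.

The same stages are available as a CLI (`refaudit simulate|audit|stats|
burden|concord|blocks|blocks-subsample|roh|gwas-xref|run|report`); `refaudit
run --config cfg.yaml` executes the whole pipeline from one YAML snapshot
and writes a manifest plus a planted-truth recovery report.

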