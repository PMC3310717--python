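# Methods

## Model and procedure

`hapcon` classifies phased chromosomes by *congruence*: repeated, fuzzy
agreement with a consensus string derived over a SNP span. The algorithm
alternates consensus derivation and survivor filtering:

- survivors ← all chromosomes passing the missingness cap; consensus ← empty;
  p ← span start;
- repeat until the consensus covers the span:
  1. derivation window = `[p, p+W)` clipped to the span end; append the
     first `min(N, remaining)` alleles of the window's *modal string*
     (most frequent complete allele string among survivors) to the
     consensus;
  2. evaluate every filter window of length F starting on the lattice
     `span_start + k·O` whose end now lies within the built consensus and
     which was not evaluated before; a survivor is removed when its
     mismatch count in any such window exceeds F − M (missing alleles
     never count as mismatches);
  3. p ← p + N;
- short tail windows at the span end are evaluated with the same F − M
  budget (a window of length < F passes unless mismatches > F − M).

Chromosomes surviving to the end are congruent. Because eliminated
chromosomes stop contributing to the modal string, the consensus is
self-reinforcing around the dominant shared haplotype; the look-ahead
(W > N) biases selection toward strings that stay identical beyond the
recorded prefix, emphasising long haplotypes. The consensus is built from
survivors, so it need not equal any single chromosome, and results depend
on the chosen start site — the start index is therefore an explicit
parameter rather than an implicit convention.

### Assumptions

- Input chromosomes are phased; phase uncertainty is represented as a
  single MISSING state (missing and unphased are not distinguished).
- SNP order and physical bp positions are given; the algorithm itself is
  index-driven and uses no genetic distance.
- Alleles are symbols from a finite alphabet; multi-allelic sites
  participate as symbols, not as biallelic dosages.

## Parameters

| parameter | meaning | unit | default | rationale |
| --- | --- | --- | --- | --- |
| `derivation_window` (W) | look-ahead window | SNPs | 30 | long-haplotype emphasis |
| `record_length` (N) | consensus alleles appended per iteration | SNPs | 10 | W/N = 3 look-ahead |
| `filter_window` (F) | fuzzy-matching window | SNPs | 30 | one LD-scale unit of dense panels |
| `min_matches` (M) | required matches per window | SNPs | 20 | tolerates ~1-in-3 mismatch locally while overlapping windows keep global identity high |
| `filter_offset` (O) | spacing of filter-window starts | SNPs | 1 | every window checked |
| `max_missing_fraction` | eligibility cap on a chromosome's MISSING share | fraction | 1.0 | exclusion is opt-in; no principled universal cap exists |
| scan `window_snps` | rolling-window width | SNPs | 250 | candidate regions ≥ 300 SNPs |
| scan `offset_snps` | rolling-window spacing | SNPs | 50 | 5× overlap smooths the profile |
| region `percentile` | cohort-wide threshold | percentile | 99 | calls ~1% of windows genome-wide |
| region `min_contiguous` | windows per region | count | 2 | one isolated window is not a region |

A stricter rule (e.g. 28 of 30) is appropriate when point mutations on a
specific haplotype are of interest; parameters should track SNP density
and the feature under study.

## Numerical and procedural conventions

- **Tie-breaking.** The modal string (and the per-column modal allele in
  the fallback) breaks ties to the lexicographically smallest candidate
  under the sorted allele alphabet. This makes results deterministic and
  invariant to chromosome order and duplication.
- **Missing data in derivation.** A survivor with a MISSING cell inside a
  derivation window is left out of that window's frequency count but
  remains a survivor. If no survivor is complete in the window, the modal
  allele is taken per column; a column with no non-missing survivor allele
  raises an error naming the column.
- **Matching rule as a budget.** "M of F must match" is implemented as
  *fail iff mismatches > F − M*, which is equivalent for full windows
  (missing counts as non-mismatch) and extends naturally to tail windows.
- **Window scheduling.** Filter windows are anchored to the span start on
  the `k·O` lattice and each is evaluated exactly once, as soon as the
  consensus covers it; removals within an iteration take effect before the
  next modal-string computation.
- **Degenerate inputs.** A single chromosome is congruent by construction
  with 100% identity. If every survivor is eliminated before the consensus
  covers the span (possible only on unstructured inputs), a
  `ConsensusDepletedError` is raised rather than returning a truncated
  consensus.
- **Identity.** Allele identity is computed over non-missing positions
  only and reported as NaN for a chromosome with no non-missing allele in
  the span, and for excluded chromosomes.
- **Percentiles.** Thresholds use linear interpolation between order
  statistics (the numpy default); "exceeds the threshold" is strict (>).
- **Scan lattice.** Rolling windows start at SNP 1, 1+offset, 1+2·offset …
  per chromosome; partial tail windows are not emitted so every
  observation summarises the same SNP count. (For a 2,837-SNP panel the
  250/50 lattice yields 52 observations.)
- **Region geometry.** A merged run of n contiguous windows spans
  `window + (n−1)·offset` SNPs — hence the 300-SNP minimum for two
  250/50 windows. Region bp bounds are the first window's start and the
  last window's end; BED output converts to 0-based half-open starts.
- **Wilcoxon comparison.** Paired, two-sided; zero differences are dropped
  (Wilcoxon's convention); the exact null distribution is used when at
  most 25 nonzero differences remain, otherwise the normal approximation
  with continuity correction (scipy). All-zero differences return p = 1
  with a warning. Windows of an overlapping lattice are not independent,
  so a profile p-value is descriptive, not a calibrated genome-wide test —
  this caveat is inherent to comparing overlapping windows and is
  deliberately not "corrected".
- **Coordinates.** 1-based inclusive bp everywhere internally and in
  reports; Python APIs take 0-based half-open SNP index spans; BED output
  is 0-based half-open.

## Design choices where the design was open

- **Survivors-only consensus.** The modal string is computed from current
  survivors rather than all chromosomes: once eliminated, a chromosome no
  longer drags the consensus toward its own haplotype. The alternative
  (all-chromosome counting) can be emulated by computing the consensus
  once and scoring with `window_mismatches` directly.
- **Half-missing phased genotypes** (e.g. `0|.`) set both haplotypes to
  MISSING — a site that is partially unresolved is treated as unresolved.
- **Unphased homozygotes** (`0/0`) also become MISSING: the `/` separator
  is taken at face value as "phase not established".
- **Founder restriction for VCF input.** A VCF carries no pedigree, so
  founder status cannot be derived from it; callers may pass an explicit
  founder-ID list, otherwise all samples are used and marked as founders.
- **Group size floor.** Groups under 10 chromosomes are skipped; identity
  summaries are over congruent chromosomes only.
- **Quadrant classification.** Windows are flagged when congruence exceeds
  its 90th percentile *and* recombination exceeds its 10th percentile —
  the joint-high quadrant where low haplotype diversity cannot be
  explained by suppressed recombination.

## The simulator

`simulate_matrix` emulates the data the method targets: a planted founder
haplotype carried by `carrier_fraction` of chromosomes over a configurable
span, a pool of `n_background` background founder haplotypes from which
non-carriers (and carriers outside the planted span) are drawn, per-allele
error flips to a uniformly random different symbol, per-cell missingness,
and Poisson-distributed single-crossover breakpoints after which a carrier
continues on a background haplotype. Defaults (binary alphabet, 60%
carriers, 1% error, 8 backgrounds, 1 kb marker spacing) describe a dense
panel over a region with one common extended haplotype.

What the simulator does **not** emulate: coalescent genealogies and
realistic LD decay, allele-frequency spectra, mutation/recombination-rate
heterogeneity, phasing-error correlation along a chromosome, and
ascertainment of tag SNPs. Passing tests therefore demonstrate the
*mechanics* of the classifier (recovery of planted sharing under
independent noise), not calibrated performance on real cohort data.

Problem sizes in the test-suite and acceptance runs (e.g. 100 × 2,000
long-range classification over 20 seeds; 60 × 1,200 rolling scans; 1,000
randomized oracle-equivalence cases up to 8 × 40 plus all 4,096 binary
3 × 4 matrices) were chosen as the smallest scales at which the binomial
tolerances and lattice arithmetic being checked are meaningful.

## Known limitations

- Results depend on the span's start site; the suggested strategy is a
  rolling scan first, then long-range analysis over the identified range.
- Extended haplotypes shorter than the rolling window (250 SNPs by
  default) are likely missed.
- In a matrix with little structure only one chromosome may be congruent;
  percent congruence has a floor of 1/n by construction.
- The consensus is a point estimate with no uncertainty; bootstrap over
  chromosomes would be required for one.
- Physical distance only; genetic-map input is used solely for the
  recombination join, not for windowing.
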