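# Methods

## The detection model

`rohscan` implements the rule-based scanning-window ROH detector used
throughout livestock genetics (the `--homozyg` algorithm family).  Its
assumptions are worth stating plainly:

- A run of homozygosity is an observational object — a stretch of
  homozygous genotype calls — not a probabilistic statement about
  identity by descent.  Length, SNP-count and density thresholds are
  what separate "homozygous by descent" from "homozygous by chance".
- Genotypes are unphased diploid calls in {hom-A, het, hom-B,
  missing}; which allele is labelled A is irrelevant to the algorithm,
  which only distinguishes homozygous / heterozygous / missing.
- All coordinates are 1-based base pairs from a PLINK `.map`; every
  length is a base-pair difference.  A segment's length is the
  *inclusive* span `(end_bp − start_bp + 1)/1000` kb.  The +1 is
  immaterial at kb scale but is fixed so that exact (segment-for-
  segment) tests are well defined.

The three stages, per individual and chromosome:

1. **Window scan.** Every run of `window_snp` consecutive markers is a
   window; a window is homozygous iff it has ≤ `window_het`
   heterozygous and ≤ `window_missing` missing calls.  Each SNP's hit
   rate is (homozygous windows containing it) / (windows containing
   it).  Near chromosome ends a SNP sits in fewer windows; the
   denominator counts only windows that exist.  A chromosome shorter
   than the window has zero windows and all-zero hit rates.
2. **Segment calling.** Maximal runs of SNPs with hit rate ≥
   `window_threshold` become candidates.  The comparison is `>=` (a
   window of 100 at threshold 0.05 requires *at least five* homozygous
   windows) with an absolute tolerance of 1e-9, so a rate of exactly
   k/n meets an equal printed threshold despite floating point.
   Candidate ends are trimmed inward to the outermost homozygous
   non-missing call: a ROH bounded by a heterozygous or missing call
   is not defensible.
3. **Final constraints.** Candidates are split at adjacent-marker
   intervals > `max_gap_kb`; then any piece with more than `max_het`
   heterozygous calls is split at its *leftmost* heterozygous SNP
   (the het call is excised — it belongs to neither flank) until every
   piece complies; piece ends are re-trimmed; pieces failing
   `length/n_snp ≤ max_density`, `length ≥ min_kb` or `n_snp ≥
   min_snp` are dropped.  Split order is gap-first, then
   heterozygosity; after the het split, gaps are not re-checked.  The
   order is observable only in rare composite cases and is fixed so
   that the brute-force oracle and the vectorized implementation agree
   bit-for-bit.  Splitting can produce final ROH shorter than the
   scanning window; no window-length floor is imposed.  Missing calls
   inside a final segment are tolerated without limit — only
   `window_missing` constrains them.

Exact PLINK bit-compatibility at chromosome ends is not promised; the
normative definition is the exhaustive-enumeration reference in the
test suite, against which the implementation is checked
segment-for-segment on hundreds of random instances.

## Coverage and the two F_ROH denominators

`covered_length` simulates an individual homozygous at every marker of
the map and runs the detector on it with *exactly* the parameters
under evaluation (not relaxed ones).  The summed ROH length is the
maximal detectable ROH length; genome coverage is its percentage of
`L_aut`.  `L_aut` is computed per chromosome as last-SNP minus
first-SNP position, on the post-QC, pre-pruning map (pruning arms
evaluate coverage on their own pruned map, so the comparison is
internally consistent).  Because each segment's inclusive span can
exceed the first-to-last difference by 1 bp, covered length is clamped
to `L_aut`, making 100% exact in the limiting case.

`f_roh_aut = L_ROH / L_aut` and `f_roh_cov = L_ROH / covered`.  The
inequality `f_roh_cov ≥ f_roh_aut` is exact (covered ≤ L_aut); with
zero coverage `f_roh_cov` is NaN rather than a number.

Coverage of the all-homozygous probe is invariant to
`window_threshold` and (for windows no longer than the chromosome)
`window_snp` — the probe's hit rates are identically 1 — while real
individuals' F_ROH falls as either rises.  Both behaviors are asserted
in the suite.

## Closed-form rules

- **Minimum SNP count** (`lencz_min_snp`):
  `L = ln(α/(n_s·n_i)) / ln(1 − het)`, with `n_s` SNPs per individual,
  `n_i` individuals, `α` the tolerated expected number of
  false-positive ROH (0.05 by convention) and `het` the mean
  heterozygosity across SNPs.  The real-valued L is *ceiled* (a
  "minimal number of SNPs" must be integral; ceiling is the
  conservative closure) with a floor of 1.  When a dataset's observed
  heterozygosity is 0 the formula is undefined and the package returns
  1: without heterozygous calls, chance runs cannot occur at all.
- **Window threshold** (`window_threshold`):
  `t = floor((N_out + 1)/L, 3)` — flooring to three decimals, computed
  in exact rational arithmetic so 0.05 comes out as 0.05.  `N_out` is
  the number of outer SNPs per segment side that should not enter the
  final ROH (outer SNPs are the ones most likely homozygous merely by
  chance).  A threshold that floors to 0.000 is rejected with advice
  rather than returned.

## Pruning

MAF is `min(f, 1−f)` of the A-allele frequency over non-missing calls;
`maf_filter` removes SNPs strictly below the threshold (equality is
kept, as with `--maf`) and removes undefined-MAF (all-missing) SNPs
whenever the threshold is positive.  LD is the squared Pearson
correlation of 0/1/2 dosages over pairwise-complete individuals
(composite LD — the right statistic for unphased data); pairs with <2
complete observations or a constant member are undefined and never
trigger pruning.  `indep_pairwise` slides a window of
`ld_window_snps` *kept* SNPs by `ld_step_snps`, removes one member of
each violating pair, and repeats whole passes to a fixpoint, which
guarantees the post-condition that no surviving within-window pair
exceeds the threshold.  The victim rule — remove the smaller-MAF
member, ties remove the later SNP — approximates PLINK 1.9's
keep-the-more-informative-marker behavior; the literature does not pin
down a victim rule, any deterministic one preserves the qualitative
findings, and this one is fixed and tested against an all-pairs
reference.

## Synthetic data

The generator emulates a medium-density array: by default 3
chromosomes × 1000 SNPs at a mean spacing of 50 kb (uniform grid, or
Gamma-distributed spacings with shape 4 for realistic density
fluctuation and occasional gaps), 20 individuals, 1% missing calls,
and background heterozygosity 0.35 — an intentionally demanding level
that makes chance homozygous runs short.  Planted segments are
specified in SNP indices and converted to bp via the realized map, so
truth is exact under any spacing model.  Outside segments, genotypes
are independent Hardy–Weinberg draws: either at per-SNP MAFs drawn
uniformly from `maf_range`, or (default) at the single frequency whose
Hardy–Weinberg heterozygosity equals `background_het`, so the
requested background het rate holds exactly in expectation.  Inside a
segment one allele is drawn per SNP and doubled.  Missingness is
applied independently everywhere, including inside planted segments.

`ld_block_map` adds block LD for pruning experiments: block members
copy a latent template genotype with probability `p` and are redrawn
from Hardy–Weinberg otherwise, giving member–member r² = p⁴; `p` is
set to the fourth root of the requested within-block r².

What the generator does **not** emulate: coalescent haplotype
structure, background LD outside explicit blocks, allele-frequency
correlation along the genome, genotyping-error hets inside real ROH,
and array ascertainment bias.  Passing tests therefore demonstrate
algorithmic correctness and the internal consistency of the coverage /
F_ROH machinery — not that any particular parameter set is optimal for
a given real population, which must be checked per dataset with the
coverage statistic.

## Problem sizes and numerical choices

The test suite runs entirely on generated data: random-instance
equivalence uses ≤ 3 chromosomes × ≤ 200 SNPs (225 instances against
the brute-force reference), and the recovery study uses the default
20 × (3 × 1000) population — sizes chosen so the whole suite completes
in seconds while exercising every code path; the algorithms are linear
in markers × individuals and scale to real 50K panels directly.
Hit-rate threshold comparisons carry a 1e-9 absolute tolerance
(distinct exact rates differ by ≥ 1/(1000·n_windows), far larger);
all other comparisons are exact.  Ties and degenerate inputs are
resolved as documented above: first-observed allele labelling,
leftmost-het splitting, later-SNP pruning victim, single-SNP
chromosomes contribute 0 kb with a warning, empty filter results are
errors rather than empty datasets.

## Known limitations

- Text `.ped`/`.map` only (no binary PLINK, no VCF); sex chromosomes
  and pedigree fields beyond IDs are ignored.
- No consensus/overlap ROH across individuals, no ROH-island
  significance testing, no model-based (HMM) homozygosity-by-descent
  comparator.
- The LD pruner is O(window² · passes) per chromosome — fine for array
  panels, not intended for sequence-density data.
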