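# Methods

## Clonotype identity and repertoire model

A clonotype is one unique TCRα rearrangement; its template count is treated
as the number of cells carrying it. Identity defaults to the tuple
(CDR3 nucleotide sequence, V gene, J gene) at gene-level resolution —
allele suffixes (`*01`) are stripped before keying, because gene-level
calls are the common denominator across export dialects, and
nucleotide-level identity is what makes nonproductive-sequence sharing a
clonal-origin signal. The key is configurable (any subset of
cdr3_nt/v_gene/j_gene/cdr3_aa containing a CDR3 field). Rows sharing a key
are merged by summing counts — exports often split one clonotype across
rows — so reading is invariant to row order. Template counts are the
preferred abundance column; read-count columns are accepted with a logged
warning.

Records whose productivity flag is missing can be resolved by a fallback
rule: productive iff the CDR3 length is divisible by 3 and its translation
contains no stop codon. The fallback is logged, never silent; with the
fallback disabled, unknown-frame records are routed to the nonproductive
fraction (conservative for clonal-origin analyses).

## Diversity and overlap statistics

Simpson's diversity D = Σ nᵢ(nᵢ−1)/(N(N−1)) and clonality √D; Jaccard
J = |A∩B|/|A∪B| on unique key sets, abundance ignored. Both statistics
depend on depth, so comparisons are normalized by subsampling every larger
repertoire to k = the unique-clonotype count of the smallest one, and
averaging over n_iter iterations (default 100 000; the analysis scripts
use 1 000–2 000, which keeps Monte-Carlo error well below the
between-subset differences at the default scales while staying at desk
scale). Choices that the definitions leave open, fixed here:

- the subsampling unit is **unique clonotypes**, drawn uniformly without
  replacement, retaining template counts — not count-weighted read
  rarefaction, which is a different estimator and is deliberately not
  implemented;
- the smallest repertoire in a comparison is used as-is, not jackknifed;
- the standard deviation across iterations is reported alongside the mean
  as uncertainty provenance.

Randomness: one master seed; each repertoire's subsampling stream is
derived deterministically from (operation name, repertoire label) via
SHA-256 into a `numpy` SeedSequence. A repertoire's stream therefore never
depends on argument order, which makes the resampled Jaccard exactly
symmetric under swapping its inputs and makes whole runs reproducible
regardless of evaluation order. When a repertoire is compared against
itself the second side receives a distinct sub-stream.

Degenerate inputs raise typed errors rather than returning NaN: N < 2 for
Simpson, empty sets for Jaccard, k outside [1, R] for subsampling.

## Phenotyping

The analysis scheme discriminates on CD45RA, CCR7, CD95 only; CD95 is
consulted only inside the CD45RA⁺CCR7⁺ quadrant. CD27/CD28 are
descriptive: they are heterogeneous in EM and implied by the quadrant
elsewhere, and making them discriminating would create unclassifiable
cells. Consequently the scheme is exhaustive and exclusive over the
2³ = 8 marker combinations (verified by enumeration). The sorting scheme
additionally requires CD62L concordant with CCR7; discordant cells are
"unassigned" and excluded from frequency tables with a logged count — the
treatment of such cells during sorting is this package's choice.

Frequency tables drop (donor, tissue, compartment) groups under
`min_cells` (default 100) and log the exclusion. Ki67 tables instead keep
small *subset* groups and flag them `low_confidence`: turnover estimates
in rare subsets warrant caution, not removal.

## Cohort statistics

Spearman rho (midranks, two-sided asymptotic p), Kruskal–Wallis H (tie
corrected, chi-square approximation on #groups − 1 df), and percentiles by
linear interpolation, all delegated to scipy/numpy; each result row
records its convention string. Exact (permutation) p-values are not
implemented; at the cohort sizes involved (n ≈ 9–27) the asymptotic
approximations are adequate and the convention is recorded in the output.
No multiple-testing correction is applied by default, matching the
marginal p < 0.05 reading of such cohort analyses; Benjamini–Hochberg is
available as a flag. CMV serostatus is carried as a stratification column
but no CMV-adjusted model is fitted.

## Synthetic data: what it emulates

The generator provides ground truth for every stage; its defaults are the
study conditions the tests and the acceptance script run under.

**Repertoires.** CDR3s are random sense-codon strings (8–15 codons,
in-frame, stop-free for productive records); nonproductive partners are
frameshifted or carry a premature stop. Clone sizes follow a zipf law
(default), heavy-tailed like real repertoires; the exponent is per subset.
A clone carries a paired nonproductive rearrangement with probability 0.15
(the true rate is unknown biology and configurable — only the *sharing
pattern* of partners, not the rate, carries meaning in tests). With a
template target set, counts are 1 + multinomial(target − R, law weights),
hitting the target exactly with every clone ≥ 1.

**Subset families.** Default unique-clonotype scales mirror the study's
sequencing yields: CD4 naive 40 000, CM 30 000, EM 20 000, SCM 500 (CD8:
30 000 / — / 6 000 / 300 plus EMRA 2 500), with memory subsets given
smaller zipf exponents (EM most clonal). Sharing is *constructed*, not
sampled: each subset pair receives a dedicated common pool sized
round(fraction × smaller R), so full-set overlap ground truth is
noiseless and all estimator noise comes from the pipeline's own
subsampling. Shared clones carry identical nonproductive partners in both
subsets; private clones never do. Default planted fractions order the
pairs as CM–EM (0.30) > SCM–CM (0.15) > SCM–EM (0.08) > naive–memory
(0.01), i.e. resting and effector memory share most, naive shares almost
nothing.

**Cohorts.** 12 donors, ages uniform on 0.1–67 y, four tissues, both
compartments, 2 000 cells per (donor, tissue, compartment). Subset
mixtures interpolate linearly between an age-0 and an age-67 composition
per (tissue, compartment) — naive declining, memory rising, ileum
EM-dominated — multiplied by a per-(donor, compartment, subset) log-normal
random effect (σ = 0.35) that produces realistic between-donor scatter
around the trend, then renormalized. Marker vectors are the canonical
subset profiles with independent per-marker flips at probability 0.02
(EM's CD27/CD28 drawn 50/50). Ki67 rates are per subset (naive 0.01,
SCM 0.08, CM 0.05, EM 0.03, EMRA 0.02) scaled per tissue (higher in ileum
and blood, lower in lymphoid tissue). The CD21⁺ fraction of naive cells
declines with age and reaches zero after age 50 in the CD4 compartment
(the thymic-involution signature); the CD21⁺ memory fraction is fixed per
(tissue, compartment), 0.227 for splenic CD8 — the one published summary
value used directly as a generator parameter.

**What passing tests do not show.** The generator makes no attempt at
V(D)J recombination biology, realistic gene usage, doublet/viability
artefacts, fluorescence spillover, batch effects, or donor-level
covariance between tissues beyond the shared subset random effect.
Recovery of planted structure demonstrates that the estimators and the
pipeline plumbing are correct at realistic scales — not that the
biological conclusions would survive real measurement noise.

## Verification strategy

Every estimator is checked against an independent oracle: Simpson's D
against brute-force enumeration of same-clone ordered cell pairs (exact to
1e-12 on 1 000 random repertoires with N ≤ 30); resampled clonality at
k = 5 against the exact expectation over all C(10,5) = 252 subsets;
resampled Jaccard against the exact mean over all 400 subsample pairs of a
6-vs-6 configuration; Spearman and Kruskal–Wallis against hand-computed
rank formulas; percentiles against a sorted-array interpolation oracle.
Monte-Carlo agreement is asserted within 3 standard errors at
n_iter = 10 000, and the 1/√n_iter shrinkage of the resampling error is
itself a test. The integration test regenerates the default family across
100 seeds (overlap ordering recovered in ≥ 99) and 200 twelve-donor
cohorts (naive age decline detected at p < 0.05 in ≥ 95%); these rates are
computed by the test, not asserted from prior expectation.

## Known limitations

- Whether the original resampling drew with or without replacement is not
  derivable from the definitions; without replacement is implemented, as
  subsampling a finite clonotype set to a smaller size implies.
- The clonotype identity behind published unique-clonotype counts is not
  stated anywhere authoritative; the default key is a design choice and
  configurable.
- Simpson/Jaccard at very small k are biased relative to their full-sample
  values (normalization trades bias for comparability); the package
  reports both the point value and the resampled mean so users can see the
  gap.
- The per-iteration resampling loop is pure Python over numpy draws;
  100 000 iterations on a 40 000-clonotype repertoire takes minutes, not
  seconds. The analysis scripts default to 1 000–2 000 iterations.
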