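# Methods

`phenoscape` implements the computational phenotyping toolkit for
whole-embryo single-cell RNA-seq screens of mouse developmental mutants:
given cohorts of replicate embryos per genotype, it quantifies where mutant
cells sit in expression space relative to wild type, which cell types change
in proportion, which embryos resemble each other, and whether a mutant is
developmentally delayed. All statistics are validated on synthetic cohorts
whose generative structure mirrors the study design they were developed for.

## Neighbourhood enrichment (lochNESS)

For a co-embedding of one mutant's cells with a pooled wild type (N cells in
total, m of them mutant), each cell's score is

    lochNESS = (mutant cells among k nearest neighbours / k) / (m / N) − 1,

with neighbours found by exact Euclidean search in the supplied embedding
and cells of the *same embryo* excluded from every neighbourhood (so
within-embryo batch structure cannot masquerade as enrichment). The
neighbourhood size k = round(√N / 2) (round-half-even, floored at 1) scales
with the dataset. A score of 0 means the neighbourhood mutant fraction
matches the dataset-wide fraction; −1 means no mutant neighbours; the
maximum is 1/(m/N) − 1. The expected fraction deliberately uses the
whole-dataset m/N even though own-embryo cells are excluded — this matches
the score's definition and introduces only a small bias of order
(embryo size)/N, which the permutation null shares and therefore absorbs.

**Null and deviance.** The null permutes genotype labels over cells; the
neighbour graph does not depend on labels and is reused. Under permutation
each label is marginally mutant with probability m/N, so the null scores
have mean exactly 0 — the acceptance suite verifies the grand mean to within
three Monte-Carlo standard errors. The deviance of a score vector is the
average over permutations of the Euclidean distance between observed and
permuted scores, divided by √(n_cells) (a per-cell RMS). The normalization
is a deliberate choice: the screening heat-map compares sub-trajectories of
very different sizes, and an unnormalized distance would scale as √n. A
cell-level permutation is the default; users worried about within-embryo
correlation can permute at embryo level instead.

**Screening.** Per sub-trajectory the package reports the median score, the
RMS deviance against the null, and a two-sample KS statistic of observed
versus pooled permuted scores, sorted by deviance. Because neighbourhoods
overlap, scores are positively correlated across cells and the KS statistic
is larger than iid sampling would suggest; calibration checks therefore use
the permutation envelope, not an absolute KS threshold. Groups under
20 cells are flagged low-confidence.

**Gene association.** Genes whose expression tracks the score are found by
per-gene quasi-Poisson regression (log link, Pearson-χ² scale, log size
factor as offset), Wald test on the score coefficient, and
Benjamini–Hochberg adjustment across genes. Quasi-Poisson was chosen as the
overdispersed count model because the per-cell counts the generator produces
(and sparse scRNA-seq counts generally) are over-dispersed relative to
Poisson; a misspecified pure-Poisson Wald test would be anti-conservative.

**LISI comparison.** The local inverse Simpson index is computed with
Gaussian-kernel weights tuned per cell to a target perplexity
floor(0.5·√(N/3)) over K = 3·perplexity neighbours (the dynamic-perplexity
reading of the published formula; the alternative floor(0.5·√N/3) parsing is
available by passing `perplexity` explicitly). For two labels LISI ranges
from 1 (separated) to 2 (perfectly mixed); on separated synthetic data it
anti-correlates with |lochNESS|, but carries no sign and no baseline
adjustment, which is exactly what the enrichment score adds.

## Composition testing

Cells are cross-tabulated by embryo × annotation; counts are size-factor
normalized (total / geometric mean of totals, so log factors sum to zero)
and rounded back to integers, since the regression needs counts. For each
mutant genotype within a background strain, each cell type is tested against
the pooled reference of all other same-background embryos by beta-binomial
regression: logit-linear mean (intercept + genotype) with one shared
overdispersion ρ ∈ [0, 1). The variance of a proportion k/n is inflated by
1 + (n−1)ρ over binomial, which is what replicate embryos show: with ~15,000
cells per embryo the binomial noise is tiny and embryo-to-embryo scatter
dominates.

The fit is maximum likelihood (L-BFGS-B on (intercept, coef, logit ρ)) with
restarts from the binomial solution and from ρ ∈ {0.001, 0.01, 0.1}. The
ρ → 0 boundary is handled explicitly: when the binomial fit attains a higher
likelihood than any interior point, the fit is reported at the boundary and
the genotype Wald test uses the profile (2×2) observed information — the
logit-ρ axis is flat there and the full 3×3 Hessian is singular. Elsewhere
the Wald z-test (normal reference, as the standard vector-GLM
implementations use) comes from the inverted observed information, with a
likelihood-ratio fallback when the Hessian cannot be inverted. With four
embryos per group the normal-reference Wald test is mildly anti-conservative
(a t reference with ~5 degrees of freedom would be exact under normality);
the calibration suite measures the realized type-I rate on null cohorts and
finds it within binomial error of the nominal 5%.

Cell types whose normalized mean count per embryo is below 10 are reported
untested. Effect summaries are log2 ratios of merged-count proportions with
a pseudocount of 0.5 guarding zeros, clipped to ±2 for display (the raw
value is also reported). Significance is nominal (uncorrected); no
multiple-testing correction is applied across types, by design.

## Power simulation

Power is estimated by simulation at each (cell type, effect size, replicate
count) grid point: cohorts are drawn from the composition generator, the
same beta-binomial test is run for the shifted type, and power is the
fraction of simulations with p < α (0.05). "Sufficient to detect" is
quantified as power > 0.8 — the conventional threshold; it is configurable.
The acceptance grid uses types pinned at 1%, 10% and 20% abundance, effects
{0.01, 0.10, 0.25} and {4, 16} replicates at 100 simulations per point, and
reproduces the design conclusions: a 25% shift is detectable even for a
1%-abundance type with four replicates per group; a 10% shift only for
abundant types; a 1% shift is indistinguishable from the null at four
replicates, and power is monotone along every axis within Monte-Carlo slack.

## Synthetic cohorts

`simulate_composition_cohort` draws per-embryo totals from a normal law
(mean 15,000, sd 3,000, floored at 100 cells — non-positive totals are
impossible by construction), per-embryo proportions from
Dirichlet(c · base), and applies mutant shifts multiplicatively to counts
(an effect of 0.1 is a 10% count reduction) before rounding. The default
base proportions are twenty cell types spanning 0.5–20% abundance.

The Dirichlet concentration c controls replicate-to-replicate scatter: the
per-embryo sd of a type at proportion p is √(p(1−p)/(c+1)). The default
c = 2·10⁴ is derived, before any simulation, from the design constraint
above: detecting a 25% shift of a 1%-abundance type with 4 + 4 embryos at
α = 0.05 and power 0.8 needs a standardized shift of ≈ 2.8, i.e. a
per-embryo sd ≤ 1.2·10⁻³ at p = 0.01; subtracting the binomial component at
n ≈ 15,000 leaves c ≳ 1.2·10⁴. Smaller concentrations (say c = 500, CV ≈ 45%
at p = 0.01) make that regime unreachable for any test, so they cannot
describe replicate embryos of an inbred strain, where abundant-type CVs are
a few percent. Similarly, the total-cell sd uses within-genotype replicate
scatter (CV 20%), not the across-strain spread of a whole atlas: an sd of
~9,000 around 15,000 truncates a substantial mass near the floor and the
resulting E[1/n] term alone would exceed the variance budget.

`simulate_embedding_cohort` draws a Gaussian mixture whose component weights
differ by genotype, giving a localized mutant enrichment with a known ground
truth. `simulate_expression` adds gamma–Poisson counts (dispersion 0.5) with
a three-fold library-size spread and log-mean shifts slope × covariate for
linked genes. `simulate_reference_timecourse` drifts along one axis at
`drift_per_day` with isotropic noise, playing the role of a staged E9.5–E13.5
reference atlas. What the generators do *not* emulate: gene–gene correlation
structure, ambient RNA, doublets with real expression profiles, batch
effects in the embedding, or curved developmental manifolds. Passing tests
therefore demonstrate correctness of the statistics under their stated
assumptions, not robustness to every artefact of real data.

## Similarity and delay

The similarity score of cell n toward embryo j is the observed/expected
fraction of embryo-j cells among n's k nearest neighbours (k as in
lochNESS); only the cell itself is excluded — own-embryo neighbours count,
which is what makes the diagonal informative. Averaging over the cells of
embryo i gives a directional embryo × embryo matrix whose rows satisfy an
exact conservation identity (the n_j/N-weighted row mean is 1, asserted on
every run). Genotype-level scores average embryo-level entries within
genotype pairs, excluding same-embryo self-pairs; embryo-first averaging is
the default, cell-count weighting optional.

Time scores place query cells on a staged reference: the score is the mean
developmental time of the k = 10 nearest reference cells (k is not dictated
by theory; 10 keeps the estimate local while averaging label noise, and is
configurable). Scores are bounded by the reference time range and shift by
exactly δ when all reference times shift by δ. Delay is tested by a
two-sided Welch t-test on cell-level scores by default, matching how such
comparisons are usually reported; because cells within an embryo are not
independent, an embryo-level aggregation mode is provided and recommended
when replicate counts allow.

## Label transfer and staging

Query cells take the majority label among their k = 15 nearest reference
cells in the chosen embedding, with the vote fraction as the assigned score
(so scores lie in [1/k, 1]). Ties are broken by smaller mean neighbour
distance, then lexicographically — the tie-break is not scientifically
meaningful, only deterministic. No score threshold is enforced; rows at or
below 0.8 are flagged for review.

Staging uses per-embryo pseudobulk (summed counts), size-factor
normalization, log2(x+1) (pseudocount 1), and centered, unscaled PCA. Query
profiles are projected with size factors computed against the *training*
geometric-mean depth, so single-embryo queries are normalized consistently;
features missing from a query are imputed at the training center (zero after
centering) with a warning, and projection is refused below 50% feature
overlap. On drifting timecourses PC1 tracks developmental age, and held-out
embryos project in stage order.

## Trajectory matching

Aggregate profiles (sum of log-transformed normalized counts over a
trajectory's cells) from two atlases are matched by reciprocal NNLS: each
target trajectory is predicted from all trajectories of the other atlas on
the union of its 3,000 most expressed and 3,000 most specific genes
(specificity = the gene's share of its cross-trajectory total; "most
specific" admits several readings, and a share is scale-free and cheap). The intercept is kept unconstrained by fitting slopes on
mean-centered data. Directional coefficients combine as
2(β_ab + 0.001)(β_ba + 0.001); the 0.001 offset is retained verbatim rather
than rescaled to the coefficient magnitude, since only the ranking matters
and the offset's role is to keep one-directional predictivity from zeroing
the product.

## Numerical and reproducibility choices

- Neighbour search is exact (chunked pairwise distances); ties at equal
  distance keep the lower cell index everywhere, and the test suite verifies
  bit-level agreement with exhaustive per-cell oracles on random datasets of
  up to 500 cells.
- All generators and permutations are driven by `numpy.random.default_rng`
  with explicit seeds; pipeline stages derive their streams from the single
  config seed plus fixed offsets, so full runs are bit-reproducible.
- Problem sizes in the test and acceptance suites (cohorts of 2,400–6,000
  cells for neighbourhood statistics, 100 simulations per power grid point,
  1,000 genes × 5,000 cells for the gene-regression recovery) were chosen as
  the smallest sizes at which the Monte-Carlo error of each check is well
  below its decision margin.

## Known limitations

- The Wald test with four replicates per group leans on asymptotics; its
  realized type-I error is verified empirically but not guaranteed outside
  the simulated design.
- lochNESS and similarity scores inherit the geometry of the supplied
  embedding; a distorted embedding distorts the scores, and no correction is
  attempted.
- The doublet-subcluster rule consumes externally computed doublet scores
  and subcluster labels; the package does not recompute either, and the
  marker-based manual curation step of real pipelines is out of scope.
- Gene-level association assumes a log-linear score effect; non-monotone
  expression patterns along the enrichment gradient will be missed.
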