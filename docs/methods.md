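# Methods

This note records the models implemented in `growthmap`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generators do and do not emulate.

## Growth phenotyping

Specific growth rate is the least-squares slope of ln OD600 against time,
i.e. the exponent of OD600(t) = e^{kt}, in 1/h.  When no window is given the
log-linear region is auto-detected: among all contiguous windows of ≥4
points, the fit uses the longest (earliest on ties) whose R² is within 10⁻³
of the best achievable window.  A pure exponential therefore uses every
point, while lag or stationary phases are excluded.  Negative slopes are
reported as-is; no lag/stationary modeling (logistic, Gompertz) is attempted.

Fitness comparisons between backgrounds use a two-sided Welch test at
α = 0.05 (both knobs exposed).  The original analyses behind this design used
per-figure ANOVA with Dunnett's post test; a two-group unequal-variance test
is the reusable primitive and is documented as a deviation.  Synthetic-rescue
classification evaluates, per medium, the forward conditions
(i) F(WT+Δ) < F(WT), (ii) F(WT+Δ+AE) > F(WT+Δ), (iii) F(WT+AE) not
significantly greater than F(WT); "neutral at best" is encoded as
NOT(significantly greater), so significantly deleterious rescue alleles
qualify.  The reverse direction treats the evolved strain as the starting
point with the mutations applied in reverse order: (i) F(WT+Δ) < F(WT+Δ+AE)
(reverting the evolved alleles is deleterious), (ii) F(WT) > F(WT+Δ)
(restoring the deletion afterwards is beneficial), (iii) F(WT+AE) not
significantly greater than F(WT+Δ+AE).

## Contrast statistics

Contrasts are computed on log2(x+1) values (pseudocount 1 keeps zeros
finite): log2 fold change is the difference of group means; the p-value is a
two-group unequal-variance comparison.  By default the per-gene variances
are moderated before the statistic is formed: each group's sample variances
are modeled as scaled chi-square draws around a common prior variance whose
scale and prior degrees of freedom are fitted by the method of moments on
log s², and the posterior variance is the df-weighted blend.  At triplicate
sample sizes a raw per-gene variance has two degrees of freedom and the
unmoderated test is erratic; pooling dispersion information across genes is
what the field's count-based differential-expression models do, and the
moderated test keeps its null calibration (≈5% of null genes at p < 0.05 in
simulation).  `moderate=False` restores the plain Welch test.  Multiple
testing is controlled by Benjamini–Hochberg.  An optional per-batch
mean-centering of log2 values (off by default) absorbs day-of-collection
offsets.  Significance calls use |fold change| > 1.5 (linear scale) and
adjusted p < 0.01.

## Gene Change Score

Per gene and per threshold pair (fc in log2 units, p-value threshold):
P = deletion contrast significant; Q = |lfc_del| > fc; R = evolution (AE)
contrast significant; S = |lfc_ae| > fc; T = opposite signs and
|lfc_del + lfc_ae| ≤ fc; U = same signs and WT-vs-sup significant.  T's
"equal magnitude and opposite sign" is threshold-relative — exact float
equality would hold with probability zero; a net WT→sup change below the
current fold-change threshold is the operational meaning of restoration.
T and U are mutually exclusive by construction.  Genes with neither P nor R
score 0; otherwise the score is (P+Q+R+S+T+U)/5, signed by the fold-change
product (positive = restorative).  A zero product (either lfc exactly zero)
gets sign 0.

Threshold grids: 5 evenly spaced percentiles from the 95th to the 99th of
(a) |log2fc| pooled over the deletion and AE contrasts and (b) −log10 p
pooled the same way (converted back to p-values), recomputed per deletion
family; the 25 scores are averaged.  Raw p-values feed the percentile axis
by default (adjusted available via config); whether U needs a fold-change
condition in addition to significance is unspecified in the source design —
significance-only is implemented.  Strong-response sets use score > 0.4 and
score < −0.2 (strict), intersected across the sup strains of a family.

A property of the percentile rule worth knowing: if more than ~5% of genes
carry true signal, the thresholds land inside the signal cluster by
construction and partial scores result.  The planted-truth benchmarks
therefore use a ~2% planted fraction, consistent with the few-percent
differentially expressed fractions typical of deletion-strain comparisons.

## Eigengene space

The basis is built from the compendium after quantile normalization (each
sample's sorted vector becomes the across-sample mean of sorted vectors;
ties get mean ranks) and log2(x+1).  Zero-variance genes are dropped
(correlation undefined) and recorded.  The gene-gene Pearson correlation
matrix is decomposed by SVD; the eigenvalue sum equals the retained gene
count (trace of a correlation matrix) and at most N (profiles) eigenvalues
are nonzero.  Projection centers a profile at the compendium per-gene mean
before dotting with the eigenvectors — centering is what makes the
full-basis reconstruction identity hold; whether the original analyses
centered is unknown, so this convention is flagged as a potential deviation.
New samples are normalized against the frozen training reference
distribution (rank-mapped onto the stored sorted mean column) so single
profiles project consistently.

A limitation inherited from rank-based normalization: an expression shift in
a gene already at the very top of a sample's distribution cannot change its
rank and is invisible after quantile normalization.  Planted-response
benchmarks place responses below the ~90th expression percentile for this
reason.

## KNN growth model

Weights are inverse squared Euclidean distance, normalized to sum to one; a
zero-distance neighbor takes all the weight (the limit of the rule, and it
avoids division by zero), with ties broken by training index for
determinism.  The prediction is the weighted mean of the k = 8 neighbor
growth rates and always lies within their range.

Pseudo-profiles: per real training profile, four noisy copies drawn per gene
from Gaussian(mean = observed value, variance = μ(1+β) + αμ²), floored at
zero, inheriting the parent's growth rate (they are noise replicates of a
measured state).  Pseudo-counts: the center of mass ḡ and radius
d = max pairwise distance define a spherical shell; ⌊m(m−1)/16⌋ distinct
random point pairs are drawn and both intersections of each pair's line with
the shell are emitted, all with growth 0 — they damp extrapolation toward
non-physical expression states.

Cross-validation is stratified five-fold: samples are ranked by growth rate
and dealt to folds in consecutive rank-blocks (shuffled within block), so
every fold shares the growth distribution.  Pseudo-profiles train only when
their parent trains (no leakage); pseudo-counts are rebuilt per fold from
the training coordinates; test folds contain real samples only.

Forward selection greedily adds the eigengene that minimizes the
cross-validated residual r (sum of squared errors over real samples) and
stops when the objective r(n) − λL(n), λ = 0.1, stops decreasing.  The
log-occupation ratio uses N_f = 13 equal-count growth bins and decile
projection bins per selected eigengene, merging adjacent deciles whose mean
projections differ by less than 10% of the mean absolute projection on that
eigengene (the "10% of their mean projection" rule is ambiguous about its
referent; this quantification is isolated in one function).  The summation
bound of the ratio is read with the growth axis as the (n+1)-th binning
dimension, giving L = 2 ln N_o − 2 ln N_f − Σᵢ ln N_i; the literal
alternative is a one-line change in `log_occupation_ratio`.

## Response transfer

The transcriptional response to a mutation set is the replicate-averaged
difference between final and initial states on the log2 quantile-normalized
scale (replicates paired by index; they are day-batched, so pairing cancels
shared batch offsets).  A linear-scale option is deliberately not the
default.  Hypothetical states add the response to each replicate of another
background, floored at zero (the log2 image of zero expression), and are
projected and predicted per replicate; results are reported as mean percent
change versus the background's measured rate with its standard error.  A
response applied in its source background is flagged as a self-pair; when
the model reproduces the background's measured rate exactly (e.g. the
background is a training point), a zero response yields exactly 0% — any
other value exposes the model's self-consistency gap.

## Synthetic data: what it emulates, and what it does not

The compendium generator draws per-gene baseline means log-uniform on
[1, 10⁴] (the marginal distribution of means in real compendia is not
standardized; this choice is documented as arbitrary), adds a
latent-dimensional signal through Gaussian loadings in log2 units, and
applies heteroscedastic noise obeying σ² = μ(1+β) + αμ² with the
study-estimated defaults α = 0.217, β = 0.539.  The noise draw is a
moment-matched lognormal: values stay positive by construction, so the
mean-variance law holds exactly instead of being distorted by truncation at
zero (a Gaussian clipped at zero loses ~2% of its mass at these dispersion
levels at every mean, which visibly biases a re-fit of the law).  Growth is
max(0, c₀ + cᵀz + ε), ε ~ N(0, 0.02): an affine link with clamping to keep
rates physical — the real study measured rates rather than positing a
generative model, so this link is the package's own choice.  Default sizes
(500 genes, 300 profiles, 150 with growth, 3 latent factors) keep the
planted-truth benchmarks tractable on one CPU while preserving the
m < N < G ordering of the real corpus.

Strain triplets plant two response classes on a baseline: restored genes
shift by the effect size (log2) in the deletion and revert in the
suppressor; compensated genes shift by the effect size in the deletion and
by a further equal shift in the suppressor, ending distinct from both WT and
deletion.  The fully compensatory pattern requires same-sign significant
changes in both the deletion and the evolution contrast — a gene that
differs only between WT and suppressor is classified as neither restorative
nor compensatory by the Venn logic and scores 0, so planting such genes
would test nothing.  Replicate noise is 0.25 log2 sd within condition
(≈15–20% CV, typical of within-condition RNA-seq triplicates — deliberately
smaller than the compendium-level dispersion hyper-parameters, which
describe variation across heterogeneous datasets) plus an additive per-day
batch offset of 0.15 log2 sd shared across genes and strains.  Setting both
to zero gives exact planted fold changes, which the tests exploit.

OD curves are exp(rate·t)·(1+ε) with relative Gaussian noise.  The packaged
mutation and rescue tables are plain-TSV transcriptions of the study's
strain/lesion and rescue-combination tables.

What passing the planted-truth tests shows: the pipeline recovers structure
it is designed to detect, under its own noise model.  What it does not show:
robustness to features of real RNA-seq the generators omit — count
discreteness and library-size variation, correlated gene modules beyond the
latent factors, condition-dependent dispersion, unbalanced replication, or
growth determined by anything other than expression.

## Benchmark problem sizes

The acceptance checks use: 2,000–3,000 genes × 50 replicates for the
mean-variance re-fit (iterated weighted least squares of per-gene sample
variance on mean and mean², weights 1/fitted-variance², excluding genes with
mean < 2 where the mean estimate is noise-dominated and is known to bias the
linear coefficient upward); the default compendium for model training with
15 candidate eigengenes; and a 2,000-gene triplet benchmark with 24 restored
and 16 compensated genes at effect size 2.  These sizes were chosen so the
full suite runs in well under a minute of compute per benchmark on a single
CPU while leaving the statistical conclusions stable across seeds.

## Known limitations

- The contrast stand-in is a moderated t on log2 pseudocounted values, not a
  count GLM; genes with very low counts are better served by the latter.
- Quantile normalization cannot represent shifts of top-of-distribution
  genes (see above).
- The KNN model assumes growth rate is uniquely determined by expression;
  contradictory training data (identical coordinates, different growth)
  average by distance weighting rather than raising an error.
- Percent-change transfer predictions require a positive measured background
  rate; zero-growth backgrounds are rejected rather than silently divided.
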