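# Methods

This note documents the models and procedures implemented in `terraomics`,
the choices made where the design was genuinely open, and what the bundled
synthetic-data generator does and does not emulate.

## Problem setting

Cross-environment surveys profile the same samples with shotgun
metagenomics (microbial taxon counts) and untargeted LC-MS/MS
(metabolite intensities), with samples organised under a four-level
EMPO-style environment ontology (host association → salinity → habitat
group → habitat). The package answers four linked questions: which
metabolite features are of microbial origin; how microbial and metabolite
composition turn over across environments (ordination, PERMANOVA, Mantel,
nestedness); which features characterise each environment (differential
ranking); and which microbes and metabolites co-occur, integrated across
all of the above.

## Microbial-origin annotation

Features with a spectral-library or dereplicator annotation that matches a
microbial secondary-metabolite reference database (Natural Products Atlas,
MIBiG) seed a "microbially related" label. The label is propagated through
molecular families — connected components of the spectral-similarity
molecular network — because structurally related metabolites share
biosynthetic provenance. Edge weights are ignored: family membership alone
decides, and propagation is idempotent and monotone in the seed set.
Dereplicator hits without database membership do not seed.

Two control-based filters precede annotation:

* **Blank (gap-fill) filter.** The qualitative rule "present in universal
  negative controls at relatively low per-sample intensity" is made concrete
  as a max-intensity ratio: a feature is kept only if its maximum intensity
  across real samples strictly exceeds `ratio_threshold` (default 3) times
  its maximum across blanks. At the boundary the feature is removed.
* **Device filter.** A feature detected in a sampling device's positive
  control is zeroed in samples collected with that device only (controls
  are scoped per device type), then globally empty features are dropped.

## Robust Aitchison ordination (RPCA)

Compositional tables carry information only in ratios and are sparse. The
robust centred log-ratio transform (rclr) maps each observed entry to
`ln x − mean(ln x over the sample's nonzero entries)` and treats zeros as
missing rather than imputing them. The observed entries are completed at a
fixed low rank (default 3) by alternating least squares with a spectral
initialisation (OptSpace family); the completed matrix is double-centred
and decomposed by SVD. The robust Aitchison distance between samples is the
Euclidean distance between rows of `scores × singular values`, i.e. over
the retained rank only. Numerical choices: convergence when the relative
objective change falls below 1e-8 (or the residual reaches the numerical
floor relative to the observed mass), iteration cap 1000, a 1e-9 ridge in
the least-squares solves, deterministic axis signs (largest-magnitude
loading positive). Sparsity filters default to 500 nonzero features per
sample and 10% feature prevalence; both are configuration-exposed because
appropriate values are table-dependent (the synthetic studies use a
5-feature sample threshold).

## Multinomial differential ranking

Abundances are modelled as `y_n ~ Multinomial(softmax(b0 + B[:, env(n)]))`
with a one-hot environment design (reference level dropped) and a Gaussian
prior (sd 0.5) on the environment coefficients; environments with fewer
than 10 samples are excluded and an 80/20 split stratified by environment
selects the training samples. Intensities are treated identically to
counts after per-sample closure: every sample is normalised to proportions
and given a fixed total weight (`closure_depth` = 1000), an approximation
that (a) makes the fit exactly invariant to per-sample scaling and (b)
keeps the prior weak relative to the data. The penalised likelihood is
maximised with a full-batch quasi-Newton optimiser (L-BFGS) run to
convergence; because all samples of an environment share one logit vector,
the likelihood collapses to per-environment aggregates and the fit takes
seconds. `epochs` caps the iteration count; the conventional stochastic
hyperparameters (learning rate 1e-5, batch size 400) are accepted and
recorded for provenance but do not influence the deterministic optimiser.

Identifiability and gauge fixing: softmax leaves coefficients identified
only up to an additive constant per environment (across features), and the
choice of reference shifts all environment columns by a per-feature vector.
After fitting, coefficients are therefore centred per feature across
environments — which cancels the reference choice exactly at the optimum,
making within-environment feature ranks reference-robust — and then per
environment across features. The reference column is kept (it is generally
nonzero after centring). `reference_consistency` verifies the robustness
empirically; comparisons against generating truth apply the same centring
to the true coefficients, since differentials are only identified up to
these gauges. Only relative orderings ("ranks") of the resulting
differentials are interpretable. When summarising log fold changes for a
group of features, the reported spread is the standard deviation across
features in the group.

## Microbe-metabolite co-occurrence model

Metabolite proportions are modelled conditionally on microbial composition:
`p_n(j) = Σ_i q_ni softmax_j(U_i·V_j + b_j)`, with `q_n` the sample's
microbial relative abundances and Gaussian priors (sd 1.0, unstated in
common usage and therefore configuration-exposed) on the latent factors
`U` (microbes × k) and `V` (metabolites × k); default latent dimension 10
and a minimum feature prevalence of 10 samples. The mixture is evaluated in
its deterministic expectation form — every microbe contributes with weight
`q_ni` at every step — rather than drawing microbes stochastically per
gradient step; this makes the fit reproducible bit-for-bit under a seed and
converges quickly at desk scale with L-BFGS. Training uses an
environment-balanced 80/20 split.

`L[i, j] = U_i·V_j + b_j` is the log conditional probability of metabolite
j given microbe i up to a per-microbe constant; the reported "co-occurrence
strength" removes that constant (per-row log-sum-exp). Model skill is the
cross-validated pseudo-Q²: one minus the held-out per-observation
multinomial negative log-likelihood of the model over that of a baseline
predicting the pooled training metabolite proportions; at most 1, zero for
baseline-equivalent models, negative for worse.

The metabolite ordination in microbe space double-centres `L` and takes an
SVD, splitting the singular values evenly between the two factor sets
(each side scaled by the square root of the singular values) so neither
microbes nor metabolites absorb all of the variance — the "equalised
biplot" convention adopted here.

## Nestedness

NODF quantifies the degree to which less diverse communities are subsets of
more diverse ones. For every ordered pair of rows with `fill(i) > fill(j) >
0` the contribution is `100·|ones(i)∩ones(j)|/fill(j)` (pairs with equal
fills contribute 0), likewise over columns, normalised by `r(r−1)/2 +
c(c−1)/2`. Contributions are defined directly by the strict fill
inequality — equivalent to the classical sorted formulation but free of
tie-ordering ambiguity — and accumulated with correctly rounded summation
so the value is independent of pair visit order. Samples are rows and
(optionally hierarchy-collapsed, presence-thresholded) features are
columns.

Significance uses an equiprobable-rows / fixed-columns null model: each
draw keeps every column total and scatters that column's presences
uniformly across rows without replacement (10,000 iterations by default).
The standardized effect size is `(observed − null mean)/null sd`; the
p-value is upper-tail with the add-one convention, since nestedness is a
directional hypothesis here. When the null distribution is degenerate the
SES is reported as undefined while the p-value remains valid.

## Diversity and the test battery

Phylogenetic metrics share a branch × tip incidence machinery. Faith's PD
sums branch lengths subtending at least one observed tip, including the
path to the root. Weighted Faith's PD weights each branch by the *mean*
relative abundance of its descendant tips; an alternative convention
weights by the branch-wise *sum* of descendant abundances — the mean form
is implemented. Weighted UniFrac is
`Σ_branches length·|p_A − p_B|` with `p` the summed relative abundance of
descendant tips.

PERMANOVA computes the pseudo-F from squared distances (between-group over
within-group dispersion) with label-permutation p-values; Mantel correlates
upper-triangle distances with Spearman's rho, permuting one matrix's sample
labels (two-sided). Both use `p = (1 + #{perm ≥ obs})/(1 + n_perm)` and
explicit seeds. The "random-effect" Spearman correlation is realised as
within-group rank centring — ranks are computed within each study group and
centred at the group mean before pooling — a rank analogue of a random
intercept rather than a full mixed model; groups of size 1 drop out.
Group comparisons of per-sample log-ratios use Welch's (unequal-variance)
t-test, chosen over the pooled form because group variances are not
assumed equal. Benjamini-Hochberg adjustment is applied within a
caller-declared family of tests (e.g. one correlation grid).

## Multi-omics integration

Per-metabolite summaries from the three layers — co-occurrence PC loadings,
per-environment differentials, global-ordination loadings and their overall
magnitude (Euclidean norm over the first three axes) — are inner-joined and
cross-correlated (Spearman, BH over the full grid). Focal/reference
metabolite groups, selected manually in practice, are made reproducible
here as: focal = features above an LFC quantile (default 0.9) *and* inside
a window on the chosen co-occurrence axis; reference = the mirrored
selection. Explicit id lists remain possible. Validation computes the
per-sample log-ratio of focal over reference metabolites, and of the top-k
(default 10, or top 10%) co-occurring microbes of each group, comparing the
focal environment against all others with Welch t-tests.

## Synthetic-data generator

The generator plants known structure for every stage: a consistent 4-level
environment hierarchy over `n_environments` leaves; microbial counts from a
multinomial with baseline log-abundances N(0,1), per-environment effects
N(0, `differential_scale`) (reference environment pinned at zero), and
per-sample overdispersion N(0, 1.5); Poisson sequencing depths (mean
5,000); metabolite proportions from the co-occurrence mixture with latent
factors `U ~ N(0, 2.5)`, `V ~ N(0,1)`, rank 3; per-sample intensity scales
log-normal(ln 10⁶, 0.5), multiplicative intensity noise (σ = 0.5) and 10%
zero inflation; molecular families from truncated-geometric sizes (so
singletons exist) wired as random trees; database-hit seeds on every
microbially derived family; contaminant features spiked into blanks and
device controls. Defaults (three environments × 20 samples, 50 microbes,
80 metabolites in 20 families) keep a full pipeline run in seconds.

Two calibration choices matter. The per-sample overdispersion (1.5) and
latent scale (2.5) were set so that the planted co-occurrence signal has
realistic strength: with much smaller values the mixture over ~50 microbes
averages the conditional distributions so strongly that even the *true*
generating parameters score a pseudo-Q² near zero, i.e. no estimator could
detect the coupling. At the chosen values the oracle pseudo-Q² is ≈ 0.1,
the same order as values reported for real coupled surveys, and the
calibration was done against that oracle rather than against any fitted
model. The block-coupled variant plants two disjoint microbe→metabolite
driver blocks with inner products elevated by 6.0 over a 0.3 background so
that "true driver" is unambiguous.

What the generator does **not** emulate: real spectral noise and adduct
structure, taxon phylogenetic correlation, batch effects beyond study-level
assignment, compositional interactions between metabolites, or realistic
feature counts (real tables are 100× larger). Passing tests therefore
demonstrate correctness of the statistics and recoverability of planted
structure at desk scale, not performance on real survey data.

## Problem sizes used in validation

The bundled validation suite runs the default study (60 samples), a
recovery study (3 × 50 samples, 100 microbes), 20-seed simulation studies
for pseudo-Q², 200-replicate calibration checks for the permutation tests
and the nestedness null model, and exact-oracle comparisons on small random
instances (≤ 6×6 matrices, 5-tip trees). These sizes were chosen so the
whole suite runs in a few minutes on one CPU while every statistical claim
is still testable.

## Known limitations

* The differential and co-occurrence optimisers are full-batch; they are
  exact and fast at desk scale but would need mini-batching for tables with
  tens of thousands of features.
* The multilevel Spearman correlation removes group location shifts only —
  it is not a full random-slope mixed model.
* Rarefaction subsamples without replacement (multivariate hypergeometric);
  with-replacement resampling is not offered.
* The co-occurrence model offers no covariate adjustment.
* BIOM-HDF5 writing and remote accession fetching are out of scope; all
  formats are plain text.
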