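# Methods

This note documents the statistical procedures implemented in `tmrnet`, the
defaults chosen where the methodology leaves a decision open, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## The TMR model categories

All associations are ordinary least squares with an intercept.  Let `T` be
the matrix of treatment covariates — here binary indicators for house-dust-mite
sensitization (HDM), cholera-toxin adjuvant (CT) and NO2-OA treatment, plus
final weight and percent weight gain as continuous obesity measures — entered
*jointly* in every model.  For measured (omics) variables `m` and response
(lung-function) variables `r`, the scan fits:

* category 1: `m ~ 1 + T`, one edge per covariate and measured variable;
* category 2: `v ~ 1 + u + T` for every ordered pair `(u, v)` of variables in
  *different* measured groups (within-group pairs are deliberately outside
  the framework: within-compartment correlation is expected and uninformative
  for integration);
* category 3: `r ~ 1 + u + T` for every measured variable and response.

Inference is Wald: `t = β/SE`, two-sided p from Student's t with
`n − p − 1` residual degrees of freedom.  Residual df follows the standard
OLS formula; the built-in published coefficient table is checked at 10
residual df, the only value consistent with its printed t→p pairs.

**Bidirectional resolution.** When both directions of a cross-omics pair are
significant at the working cutoff, the direction with the smaller p-value is
kept; exact ties go to the larger |t|, then to the lexicographically smaller
labelling.  "Stronger" is defined by p because p is the significance currency
of the whole procedure; the chosen orientation is a heuristic and is treated
as such when recovery is scored (matching is on unordered endpoint pairs).

**Covariate-surfaced edges.** When a covariate stays significant in a
category-2/3 model, its edge is emitted flagged `covariate_surfaced`.  These
are annotations of individual models: the same (covariate, response) pair is
re-tested once per measured predictor, so the full table may contain many
near-duplicate rows for one pair.  Recovery scoring therefore counts primary
association edges only.

**Networks.** `build_network` keeps edges with `p < α` (strict), the default
α = 0.005 matching the reference analyses.  No multiple-testing correction is
applied by default (a Benjamini–Hochberg helper is provided); at ~1,700
candidate models per default-sized study, roughly `0.005 × #tests` chance
edges are expected in the network and the planted-recovery results below
should be read with that in mind.

**Vectorized OLS core.** A scan fits one design per measured predictor
against all eligible response columns simultaneously (a multi-response
least-squares solve), which keeps a full scan under 100 ms at study scale.
The core is verified against statsmodels and closed-form normal equations in
the test suite.

## Compositional 16S handling

Counts are closed per sample; the top `n = 10` taxa by mean relative
abundance are kept and the rest pooled into `Remainder` (ties at the boundary
break lexicographically).  ALR uses the natural log with an additive
pseudocount (default 1e-6 on the relative-abundance scale; 0 is allowed for
strictly positive tables).  The reference component defaults to `Remainder`
when present — it is always positive after pooling and keeps all named taxa
in the output — otherwise to the taxon with minimal log-abundance variance.
Reference and pseudocount are recorded in the output metadata because the
choice defines the coordinate system.  A consequence worth knowing: every ALR
coordinate shares the reference's own variation, which induces positive
correlation within a layer and mildly attenuates regressions on 16S
predictors.

## Variable selection

Each variable is Shapiro–Wilk tested; when raw normality is rejected at 0.05
(gating; `always_compare` disables it), square-root (requires min ≥ 0) and
natural-log transforms are tried and the largest W wins ("improved
normality" is operationalized as a larger W statistic — p and W rank
identically at fixed n).  Log of a variable containing zeros uses an offset
of half its smallest positive value; variables with negatives skip both
transforms.  PCA runs on the correlation matrix of the transformed block;
components contributing strictly more than 1% of total variance are
retained; proxies are assigned greedily in component order among
not-yet-selected variables by |Pearson r| with the component scores, so the
selected set is non-redundant.  When a block has little correlation
structure, every component clears 1% and selection is lossless by design.

## Group structure

Distances are Euclidean over each group's variables, computed on per-variable
z-scores by default because groups mix units (ALR coordinates, relative
amounts, expression ratios); `standardize=False` restores raw distances.
The Mantel statistic is the Pearson correlation of the strictly upper
triangles (no permutation test — the statistic is used only as a similarity),
and groups are clustered on `1 − |cor|` with Ward's minimum-variance
criterion via the Lance–Williams recurrence.  The default variant applies the
recurrence to the dissimilarities as given (the classic "Ward.D" update,
matching R's `hclust(..., "ward.D")`); `ward.d2` squares them first and
reports square-root heights (scipy's `linkage(method="ward")`).  The variant
is recorded in the output.  Newick branch lengths are parent merge height
minus child merge height.

## Ordination and PERMANOVA

Classical MDS double-centers `−½D²`, eigen-decomposes, and scales the top
axes by √eigenvalue; negative eigenvalues are reported but contribute no
axes.  PERMANOVA partitions `tr(H G)` of the Gower-centered matrix `G` with
sequential (type-I) sums of squares in the user-given covariate order
(marginal SS is a flag); permutations are unrestricted and the p-value uses
the add-one estimator `(1 + #{F* ≥ F})/(1 + n_perm)`, so the smallest
attainable p is `1/(n_perm + 1)`.  Deterministic given (data, n_perm, seed).

## The synthetic study generator

The generator emulates the study design statistically: 4 arms × 10 mice
(Naive, Control, AAD-Vehicle, AAD-NO2-OA encoded as HDM/CT/NO2-OA
indicators, plus correlated final-weight and weight-gain covariates), two
12-taxon 16S layers drawn as multinomial counts (depth 5·10⁴) from
softmax-composed log abundances, three 4-metabolite and two 3-gene
compartments drawn log-normally, and five flexiVent parameters (H, G, Rn,
Ers, Rrs) emitted as dose series over 0–50 mg/mL methacholine,
reconstructed from baseline and slope features.  Every variable carries a
latent Gaussian signal with sd 0.5 (the noise scale); planted effects add
`β · source` to the target's latent signal, so the ground truth is exact on
the modeling scale: ALR for taxa (the softmax normalization cancels), log
scale for metabolites/expression, feature scale for responses.  Response
features are reduced from the dose series by baseline = value at the lowest
dose and slope = OLS slope over raw dose (dose 0 included; a log-dose option
excludes it) — raw dose is the default because no convention is universal.

The default planted design is a chain-free DAG of 33 effects (18
treatment→omics, 5 cross-omics, 10 omics→response) with a single source per
target, so no mediated marginal associations exist beyond the planted list.
Effects touching a 16S variable use β = 1.6 and all others β = 1.3: the ALR
reference variation attenuates regressions on 16S sources, and the larger β
keeps the per-test power of every planted edge above 0.99 at α = 0.005 so
that recovery measures the pipeline, not the noise floor.

What the generator does **not** emulate: real taxon identities or abundance
distributions, overdispersion beyond multinomial sampling, within-block
biological correlation (metabolite pathways, co-regulated genes),
missingness, batch effects, or nonlinear dose-response shapes.  Passing
recovery tests therefore demonstrate that the machinery finds linear planted
structure at realistic sizes and calibrated error rates — not that the
framework's modeling assumptions hold on any particular real dataset.

## Problem sizes used in validation

Recovery is scored over 10 generated studies (n = 40 each) pooled; null
calibration uses 5 global-null studies (~3,900 deduplicated category-1/2
tests; each unordered category-2 pair is counted once because its two fitted
directions are near-duplicate tests); PERMANOVA null uniformity uses 120
replicates at 199 permutations; dendrogram structure recovery uses 10 seeded
three-group studies sharing one latent factor.  These sizes make the whole
validation run in seconds while keeping binomial/KS checks well-powered.

## Numerical notes and degenerate inputs

Rank deficiency raises a collinearity error naming dependent columns (QR
pivoting); constant variables are rejected before standardization, PCA and
Shapiro–Wilk; all-zero taxa rows are rejected by closure with the sample
named; alignment is strict string matching on sample ids, dropping
incomplete samples per group before intersecting, and is idempotent.
Retention thresholds are strict inequalities.  Ties (top-taxa boundary,
proxy correlation, Ward merges, bidirectional resolution) break
deterministically as documented above, so identical configurations and seeds
reproduce byte-identical outputs.

## Known limitations

Only OLS associations: no mixed effects, no penalization, no robust errors,
no causal orientation beyond the p-value heuristic.  PERMANOVA has no strata
/ restricted permutations.  The ALR reference choice changes coordinates and
is configuration, not inference.  Published study-specific quantities that
depend on the original cohort's raw data cannot be recomputed here; the
package validates those pathways on synthetic data and on internal-consistency
checks of the published coefficient table instead.
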