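# Methods

## The problem and the overall model

The package ranks gene variants by the severity of the metabolic phenotype
they induce in an isogenic cell background, from a targeted-metabolomics
concentration matrix. Severity is never supplied as a label to the models:
an unsupervised PCA of the variant-carrying samples defines a latent axis
(the first score vector, t1), and the claim that this axis *is* a severity
axis rests on (i) the wild-type-allele control and the most severe variant
sitting at opposite ends, (ii) an OPLS model on t1 that generalizes under
cross-validation and collapses under permutation, and (iii) monotone
behavior of biochemically interpretable indices along t1.

## Preprocessing

The cleaning chain is fixed in order and each stage is a pure function
returning its transformed table plus a report:

1. **LOD filter.** Metabolite *j* is dropped iff
   `#(values < LOD_j) / n > 0.20` (strict inequality, so exactly 20% is
   retained). Sub-LOD values of retained metabolites are kept as reported —
   no imputation. The downstream methods are variance- and rank-based, and
   inventing values below the detection limit would add structure that was
   never measured. The filter is idempotent.
2. **Bridge-sample batch normalization.** One bridge sample measured in
   every batch (by default the lexicographically first such sample,
   overridable) supplies per-metabolite factors
   `f_bj = value(bridge, reference batch, j) / value(bridge, b, j)` that
   multiply all values of batch *b*. The factor is per metabolite, not a
   scalar, because batch effects in flow-injection/LC-MS are
   analyte-specific. The consumed bridge run is removed in *every* batch
   (reference included), so the remaining bridge replicates stay available
   to verify, via PCA, that the batch direction shrank.
3. **Bridge-replicate collapse.** Remaining multi-batch samples are
   reduced to their reference-batch run and rows are re-keyed by sample id:
   the analysis table is one row per biological sample (34 samples in the
   default design: the normalizer is consumed, 4 wild type + 5 knock-out +
   25 transfected remain).
4. **Row (total-sum) normalization.** Each row is divided by its total and
   multiplied by the grand mean of the original totals, removing
   cell-input differences while keeping µM-like magnitudes; afterwards all
   row totals are equal. The rescaling is cosmetic and recorded.
5. **Autoscaling.** Per-metabolite centering and unit-variance scaling,
   with the n−1 standard deviation (either convention is defensible; one
   must be fixed and recorded — it is, in the stage report, together with
   centers and scales for the inverse transform). Scaling is applied per
   analysis subset, and *recomputed inside every cross-validation training
   fold* so held-out samples never influence the model that predicts them.

## Latent-variable models

**PCA** is computed by NIPALS with deflation: per component, iterate
`p = X't/t't` (normalized), `t = Xp` until the relative change of `t` is
below 1e−12 (iteration cap 20000 — power iteration at this tolerance needs
many iterations when eigenvalue gaps are small), then deflate
`X ← X − tp'`. The start vector is the column of maximal variance and the
component sign makes the largest-magnitude loading positive, so fits are
fully deterministic. Explained variance is
`R²X_a = ||t_a p_a'||²_F / ||X_0||²_F`; over the full rank the shares sum
to 1. NIPALS is the reference implementation because it is the
chemometrics standard and is comfortable in the small-n/large-J regime; an
SVD oracle checks it in the tests to 1e−8. Hotelling's
`T²_i = Σ_a t²_ia / var(t_a)` with the F-based limit
`A(n−1)(n+1)/(n(n−A)) · F_{1−α}(A, n−A)` flags outliers.

**OPLS** (single response, single predictive component): `w ∝ X'y`
(unit norm), `t = Xw`, `p = X't/t't`. Each orthogonal component takes
`w_o ∝ p − (w'p)w`, `t_o = Xw_o`, `p_o = X't_o/t_o't_o`, deflates
`X ← X − t_o p_o'`, and the predictive component is recomputed on the
filtered matrix. Two exact identities follow from the algebra and are
asserted, not approximated: deflating a y-orthogonal component leaves
`X'y` unchanged, so the predictive weight vector is invariant under the
orthogonal deflations (`w'w_o = 0` exactly), and every orthogonal score
satisfies `t_o'y = 0`. The regression is `b = t'y/t't`;
`R²Y = 1 − ||y − bt||²/||y||²` is non-decreasing in the number of
orthogonal components on training data. **OPLS-DA** encodes two classes as
0/1 (wild type 0, knock-out 1 in analysis A, so negative loadings mean
"decreased in the knock-out") and decodes predictions to the nearest
encoded value. **VIP** with one predictive component is
`VIP_j = √J · |w_j|`, so the mean squared VIP is exactly 1 and VIP ≥ 1 is
the conventional importance cut.

Multi-class discrimination, multiple predictive components, O2PLS and
missing-data NIPALS are out of scope.

## Validation

- **Q²Y_cum** uses venetian-blind folds (sample *i* → fold *i* mod k after
  ordering by sample id), k = 7 by default — the de-facto chemometrics
  default. PRESS accumulates out-of-fold squared errors; SSY is total
  variation about the grand mean; Q² = 1 − PRESS/SSY. Under the null Q² is
  negatively biased, which is the point.
- **Orthogonal-component count** is chosen as the smallest A whose CV gain
  `Q²(A+1) − Q²(A)` falls below 0.01, scanned up to 5. If the full-data
  matrix supports fewer orthogonal directions than the CV scan suggested
  (e.g. when y is exactly a principal component of X, as in analysis B,
  where the predictive loading then carries no orthogonal remainder), the
  fit backs off to the largest feasible count.
- **Permutation null**: the response is randomly permuted (seeded), the
  entire cross-validation refitted, and Q²Y_cum-perm reported as the mean
  of the permuted Q² values (the summary convention is a choice; mean is
  used and recorded, 200 permutations by default). The identity
  permutation may occur by chance and is kept.
- **CV-ANOVA**: `F = ((SSY − PRESS)/d1)/(PRESS/d2)` with d1 = number of
  latent components (predictive + orthogonal) and d2 = n − d1 − 1, upper
  tail of F(d1, d2). This follows the published components-as-degrees-of-
  freedom approximation; under the null it is *conservative* (PRESS
  typically exceeds SSY, clipping F at 0), which simulations in the test
  suite confirm (~1% false positives at nominal 5%).
- **Verdict**: Q²Y_cum > 0.5 and mean permuted Q² < 0 and CV-ANOVA
  p < 0.05.
- **Univariate**: Mann–Whitney–Wilcoxon (exact when the pooled sample is
  ≤ 12 and tie-free, otherwise normal approximation with tie and
  continuity corrections; the reported statistic is min(U₁, U₂)) and
  Spearman ρ (Pearson correlation of average ranks; NaN for constant
  input, propagated as missing). Both delegate to scipy behind the module
  surface; independent enumeration and rank-Pearson oracles check them in
  the tests. No multiplicity correction is applied across metabolites —
  selection is VIP-based, not p-value based.

## Signatures, indices, regressions

A signature is the set of metabolites with VIP ≥ 1 (threshold
configurable), ranked by |loading| (analysis A) or |ρ| (analysis B), with
direction = the sign of that association; an optional top-fraction cut
exists because "high loading" has no canonical numeric value. Signature
overlap reports the shared count and the fraction of *each* signature,
since either denominator is defensible.

The derived indices are computed on the cleaned, row-normalized table
*before* autoscaling (ratios of autoscaled values would be meaningless).
PUFA/MUFA/SFA are defined on the total double-bond count of the
sum-composition shorthand (≥ 2 / = 1 / = 0) within the diacyl and
acyl-alkyl phosphatidylcholine subclasses — the panel does not resolve
individual chains, so saturation classes can only be read from the summed
composition. Missing analytes yield missing indices with a warning, never
infinities. Each index is regressed on t1 by ordinary least squares with
R² = squared Pearson correlation.

Because t1 in analysis B is oriented so the declared most-severe group has
the maximal mean score, signs are comparable across runs: "up" means
"rises toward the severe end".

## The synthetic-data generator

Concentrations are log-normal:

    log c_ij = μ_j + slope_j·severity(group_i) + τ_j·transfected_i
               + β_{batch(i),j} + ε_ij + η_mj

- μ_j log-uniform over [0.01, 100] µM, fixed by a panel-level seed so the
  dynamic range belongs to the panel, not the replicate seed.
- The severity gradient is linear in the group's ordinal severity rank
  (0 for wild type and the wild-type allele, 5 for the knock-out), carried
  by a random `signal_fraction` (default 0.8) of each affected class:
  amino acids (−0.12 per rank), biogenic amines (−0.08), diacyl and
  acyl-alkyl phosphatidylcholines (−0.10/−0.08), sphingomyelins (+0.10,
  hydroxylated +0.14), with named overrides (spermine up, spermidine and
  putrescine down, trans-4-hydroxyproline down, glutamine up against the
  amino-acid pool, a +0.15/+0.04 differential between SM 18:0 and SM 16:0)
  and a per-double-bond differential (−0.02, centered within subclass) on
  the phosphatidylcholine classes so saturation ratios trend too. Slope
  magnitudes are on log concentration per severity-rank unit; none are
  estimates of the real study, which published no effect sizes — they are
  chosen once as a plausible moderate gradient (roughly half the replicate
  noise per rank step).
- τ_j ~ N(0, 0.30) is a per-metabolite offset shared by all transfected
  groups: it separates transfected from non-transfected lines on the
  second principal component without touching the severity axis.
- β ~ N(0, batch_sd) per (batch, metabolite), default 0.15.
- Noise is split into biological replicate scatter ε ~ N(0, 0.20) per
  *sample* and technical injection scatter η ~ N(0, 0.05) per *measurement
  row*. The split matters: the bridge sample's two batch runs share ε, so
  the bridge factor estimates the batch effect with only technical noise.
  With a single noise term the factor would inject √2 × replicate noise
  into every batch and bridge normalization would be counterproductive at
  realistic batch effects — contradicting the observable fact that the
  normalization is verifiable by PCA.
- LODs: a fixed count (`round(lod_quantile·188)` = 59 by default) of
  metabolites receive an LOD near the middle of their observed range and
  reliably fail the 20% rule; the rest get an LOD below their minimum. The
  failing set is drawn from metabolites that carry no planted signal and
  are not needed by the derived indices, emulating a study in which the
  signature analytes were all quantifiable. Default attrition is therefore
  129/188 retained (68.6%).
- The default design runs replicates 1–3 of every non-bridge group in
  batch 1 and 4–5 in batch 2, so batch composition is identical across
  groups and batch effects cannot confound the severity ordering; the five
  wild-type samples are measured in both batches as bridges (40
  measurement rows).

What the generator does *not* emulate: correlated metabolite blocks within
pathways, heteroscedastic (intensity-dependent) technical noise,
within-batch drift, non-linear severity responses, and missing values from
instrument dropouts. Passing tests therefore show that the chain recovers
planted log-linear structure under realistic noise, batches and censoring
— not that it would rank variants correctly under arbitrary real-data
pathologies.

## Numerical and design choices

- Missing token "NA"; NaN internally; 0 is never used for "absent".
- Canonical orientation samples-as-rows; identifiers case-sensitive,
  end-trimmed only (panel ids contain internal spaces and parentheses).
- Lipid shorthand grammar `<token> C<carbons>:<double bonds>` with tokens
  `PC aa`, `PC ae`, `lysoPC a`, `SM`, `SM (OH)`; parsing is total over the
  bundled panel.
- Table round-trips hold to 12 significant digits (`%.12g`).
- All fits deterministic; every stochastic step (generator, permutations)
  takes an explicit seed; the end-to-end report is byte-identical across
  reruns, with the wall-clock timestamp isolated in one JSON field.
- Problem sizes used in the consistency checks: verdict behavior on
  effect-free data over 50 replicate simulations with 30 permutations
  each; severity-ordering recovery over 100 replicates; bridge
  normalization over 50 replicates at batch_sd 0.5. These sizes give the
  fractions being asserted (≥ 90%, ≥ 95/100, ≥ 80%) a few percentage
  points of Monte-Carlo resolution, which is what the thresholds require.
- t1 enters the analysis-B OPLS as raw (centered) scores; scaling a
  single response only rescales the regression coefficient.

## Known limitations

- Single predictive component throughout; two-class discrimination only.
- CV-ANOVA degrees of freedom are approximate; the test is conservative
  under the null.
- VIP-based selection has no error control across metabolites; with a
  high fraction of truly affected metabolites, VIP ≥ 1 necessarily misses
  some carriers (the mean squared VIP is pinned at 1), so recall against
  the planted ground truth is bounded well below 1 at the default,
  realistic effect sizes.
- Under total-sum normalization the data are compositional: a metabolite's
  apparent trend is its trend relative to the weighted total, which can
  attenuate (or flip) weak absolute trends. Ratio indices are immune;
  single-analyte indices are not.
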