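# Methods

This note documents the statistical model behind `ifnsig`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not establish.

## Per-study differential expression

Each stimulation study is modelled separately on the log2 scale.  For gene
*g* with expression x, the response is y = log2(x + 1) (the +1 pseudocount
matches the scoring convention log2(TPM + 1); it compresses effects slightly
for genes with baseline log2 expression near the pseudocount, which is why
the synthetic baselines start at 5).  The design contains an intercept
(control baseline), one indicator per non-control condition, and centered
numeric dose/time covariates.  A covariate enters only when the study has
more than one distinct value among stimulated samples: with a single dose
level the dose column is an exact linear combination of the treatment
indicators, and with controls recorded at dose 0 a dose covariate in a
dose-ranging design absorbs a linearly dose-dependent treatment effect —
the covariate is meaningful exactly when it varies within arms.  Conditions
outside the IFN panel ("other", e.g. IFN-λ or TNF arms) are modelled, which
stabilises the residual variance, but never contrasted.

Residual variances are moderated with the standard hierarchical F-model:
s² | σ² ~ σ²·χ²_d/d and σ² ~ s₀²·d₀/χ²_d₀, giving the posterior
s̃² = (d₀ s₀² + d s²)/(d₀ + d).  The hyperparameters come from moment
matching on e = log s² − ψ(d/2) + log(d/2): the prior location s₀²(A) is a
locally weighted linear fit of e on mean log2 expression A (span 0.5,
**no robustifying iterations** — e is left-skewed, and robust reweighting
biases the prior upward by several percent, which measurably deflates
downstream discovery rates), and d₀ solves
ψ′(d₀/2) = Var(e − fit) − ψ′(d/2).  When the excess variance is
non-positive, d₀ = ∞ and the prior is the trend fit itself (or mean(s²)
in the constant-prior case, where that is exact for identical variances).
The constant-prior path agrees with an independent implementation of the
same moment equations to ~1e-14 (verified in the test suite against R's
Bioconductor implementation); the trended path differs in the smoother
(lowess here, spline there), which only shifts the prior location, never
the squeeze algebra.

Each study emits, for every condition pair present, a contrast: effect =
coefficient difference (log2), SE = sqrt(c′(X′X)⁻¹c · s̃²), moderated t
with d₀ + d df.  The sign convention is expression in A minus expression
in B.

## Network meta-analysis

Per gene, the contrasts form a network: nodes are conditions, edges are
per-study estimates with variances.  Contrasts from a study with ≥3 arms
are reduced to the treatment-vs-control basis (the dropped
treatment–treatment contrasts are exact linear combinations of the retained
ones), and the covariance between two vs-control edges — they share the
control arm — is recovered from the flat contrast table by variance
triangulation, cov(a,b) = (v_a + v_b − v_ab)/2.  This matters: treating the
edges as independent inflates treatment–treatment SEs by ~30% in the
default five-study design and destroys p-value calibration.

The consistent effects solve the generalized least-squares problem on the
node-difference (incidence) design.  With block weight matrix W the normal
matrix X′WX is the weighted graph Laplacian; its Moore–Penrose
pseudoinverse yields node potentials, all pairwise effects θ̂(i,j) (exactly
antisymmetric and path-consistent by construction), and their SEs from
L⁺_ii + L⁺_jj − 2L⁺_ij.  Connectivity is required; genes with disconnected
networks are skipped with a warning rather than imputed.

Heterogeneity uses the generalized DerSimonian–Laird moment estimator:
τ² = max(0, (Q − df)/C) with Q the fixed-effect weighted residual sum of
squares, df = m − (n − 1), and C = tr(W) − tr(W X L⁺ X′W); it reduces to
the classical scalar estimator for a single replicated comparison.  The
random-effects model adds τ² to each edge variance (independent
heterogeneity per edge, matching the generator, which draws one deviation
per gene×study×treatment) and refits.  p-values are Wald/normal — the
effects are meta-analytic aggregates — and Benjamini–Hochberg correction is
applied across genes separately for each of the six comparisons.

A known property worth stating: under *exact* homogeneity (τ² = 0 truly),
the clamp at zero makes τ̂² strictly nonnegative on average, so
random-effects p-values are conservative (observed discovery fractions
0.025–0.043 at nominal 0.05).  The null-calibration checks therefore use
the common-effect model, which is the correct model for that scenario;
discovery under heterogeneous defaults uses the random-effects model.

## Signature derivation

Six directional pairwise DEG lists (|FC| > 2.5, FDR < 0.05) and three
vs-control lists (FC > 3, FDR < 0.05, upregulation only); per IFN X,
S_X = (∪ up-in-X pairwise) ∩ (up in X vs control), then
S_IFNb := S_IFNb \ S_IFNa.  Two deliberately configurable readings:

* **Threshold scale.** Fold-change cutoffs are interpreted on the linear
  scale by default (a cutoff c tests 2^|logFC| > c); `effect_scale="log2"`
  gives the literal log2 reading.  The linear reading is the conventional
  meaning of "fold change > 3", and the log2 reading is degenerate whenever
  true effects sit near the cutoff — an estimate centred on its own
  threshold passes with probability ½ regardless of sample size.
* **FDR direction.** The vs-control criterion is applied as FDR < 0.05
  ("significantly high FC"); `fdr_direction="literal"` reproduces a
  published FDR > 0.05 reading that is almost certainly a typographical
  slip, flagged rather than silently fixed.

Gene symbols are uppercased before matching; no alias resolution.

## Scoring and evaluation

The mean signature score of a sample is the mean over present signature
genes of the across-sample z-score (sample SD, n−1) of log2(x+1); constant
genes contribute 0, missing genes are dropped with a warning above 50%
missingness, and scores of a fully present signature sum to zero across
samples — which is also why scores are cohort-dependent and not comparable
across datasets.  Coherence is the mean Pearson correlation over all gene
pairs of the signature (≥3 samples, ≥2 non-constant genes); d_mean is the
difference in mean score between a stimulated arm and the controls.
Severity association uses Spearman ρ with average-rank ties; correlation
distributions are compared after Fisher z = atanh(r) with pooled-variance
Student t-tests (Welch available); responder ROC/AUC fits a
single-predictor logistic regression by IRLS and computes the tie-aware
trapezoidal AUC of predicted probabilities, which equals the Mann–Whitney
rank AUC whenever the fitted slope is positive (asserted at run time; on
perfect separation the rank AUC is used with a warning).  Covariance
ranking sorts signatures by sample covariance with a reference signature,
ties broken by name.

## The synthetic study system

The generator emulates the discovery design: five studies with incomplete
treatment coverage ({IFNa, IFNg}, {IFNa, IFNb, IFNg}, {IFNg}, {IFNa},
{IFNb}), three replicates per arm, one dose/time level per study by
default.  Four planted programs of 30 genes each (shared ISG; type-I
specific = IFNa+IFNb; IFN-b only; type-II specific = IFNg) with log2 effect
3, between-study heterogeneity SD τ = 0.2 on every treated gene×study×
treatment cell, residual SD σ = 0.5, per-study×gene baseline offsets
SD 0.5 (which is what makes naive cross-study pooling inappropriate and
the network synthesis necessary), baselines uniform on log2 ∈ [5, 12],
matrices returned on the linear scale 2^x.  Dose/time modifiers scale the
true effect by dose/max(dose) · time/max(time); they are exercised in unit
tests, not in the default design, because replicate-level dose ranges plus
a linear dose response make the treatment indicator and the dose covariate
fight over the same signal — a real identifiability issue, not an artifact.
The zero-effect configuration also sets τ = 0: random per-study deviations
around a zero mean are genuine treatment effects, not a null.

Clinical cohorts are generated from a latent activity z ~ N(0, latent_sd)
that shifts the driver signature's genes by 1·z log2 units over independent
gene noise (SD 0.5); severity = round(4 + 3z + N(0,1)) clipped at 0 (a
nonnegative integer score in the SLEDAI tradition), response ~
Bernoulli(logistic(0 + 2z)).

What passing these checks shows: the inferential chain (moderation →
network GLS → FDR → set logic → scoring → evaluation) is calibrated under
its assumptions and recovers planted structure with realistic
heterogeneity and incomplete designs.  What it does not show: robustness to
count noise (the generator is Gaussian on the log scale, by design — the
pipeline consumes normalized expression), batch effects, platform
differences, scRNA-seq sparsity, or misannotated arms; and the generator's
distributions are stand-ins, not calibrated to any public dataset.

## Numerical notes and limitations

* Pseudoinverse cutoff 1e-12 on the Laplacian; a connected network has
  exactly one zero eigenvalue (the reference-level nullspace), anything
  more raises.
* Reconstructed multi-arm covariance blocks are checked for positive
  definiteness and fall back to their diagonal if violated (can happen with
  inconsistent hand-made inputs, not with model-generated contrasts).
* Variance floor 1e-12×min positive s² before logs, for noiseless fixtures.
* HVG rank ties use average ranks; rank-sum ties break alphabetically;
  both for determinism.
* trigamma inversion by Newton from x₀ = 0.5 + 1/y, 50 iterations, exact to
  ~1e-10 — degenerate y ≤ 0 maps to d₀ = ∞.
* Scores, coherence and AUC are undefined for degenerate inputs (single
  sample, constant vectors, single-class labels); these raise or return
  missing values with warnings rather than fabricating numbers.
* Runtime: one full discovery run (2000 genes × 5 studies) takes ~20 s on
  one CPU; the validation batches use three seeds per scenario.
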