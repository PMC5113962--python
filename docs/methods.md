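# Methods

This note documents the models, the defaults and the reasoning behind the
design choices in `csfmet`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

The central object is a samples × metabolites table of GC-MS peak heights
(relative quantification). Missing cells are censored non-detects, encoded
as NaN and kept distinct from zero, which is a legitimate reported
measurement; files use empty cells for missingness. IDs are case-sensitive
strings matched exactly across the three tables (matrix, sample annotation,
metabolite annotation), so metabolite-name aliasing fails loudly instead of
silently. Sample annotations carry a closed group vocabulary (CTRL, MS,
NMOSD, ITM), a status (NONE for controls, REMISSION/RELAPSE for patients), a
`pre_treatment` flag, and the clinical covariates EDSS (0–10 in half
points), OCB (binary), CSF protein (mg/dL), WBC and IgG index.

## Preprocessing

1. **Sum normalisation** divides each sample by its total present intensity
   and rescales to the cohort-median total, preserving magnitudes. It is
   idempotent. This matches the convention of normalising each chromatogram
   to the summed intensity of identified peaks.
2. **Occurrence filter**: a metabolite is kept iff present in ≥ 50% of the
   samples of at least one design group. Presence means non-missing; zero
   counts as present.
3. **Imputation**: half the per-metabolite minimum replaces missing values
   (the standard stand-in for below-LOD censoring); `none` is available for
   stages that tolerate missingness (univariate tests use present values
   only).
4. **Scaling**: natural-log transform, then unit-variance (UV) autoscaling,
   the de-facto default of the commercial chemometrics packages; Pareto and
   centering-only are available. The scaling state (per-metabolite centre
   and dispersion) is stored so held-out samples are scaled with training
   moments, never their own.

Univariate statistics run on the sum-normalised, *unlogged* scale because
fold changes are ratios of relative abundances; multivariate models run on
the log/UV scale.

## Univariate contrasts

Two-sided pooled-variance Student *t*-tests on present values (Welch behind
a flag), fold change = arithmetic mean(case)/mean(reference). Group unions
are allowed (all-diseases vs. control). No multiple-testing correction by
default — significance is raw p < 0.05, mirroring standard univariate
screens in this literature — with Benjamini–Hochberg behind a flag; the
result object records which was used. A side with fewer than two present
values makes the metabolite untestable; it is flagged and excluded from the
significance list rather than silently dropped.

## Latent models

### NIPALS PLS2

With X (n × p, centred) and response matrix Y (centred), each component
iterates w = Xᵀu/(uᵀu) (normalised), t = Xw, c = Yᵀt/(tᵀt), u = Yc/(cᵀc) to
convergence (relative score change ≤ 1e-9, ≤ 2000 iterations), then
deflates X by t pᵀ with p = Xᵀt/(tᵀt) and Y by t cᵀ. Scores of distinct
components are exactly orthogonal. R²Y(cum) = 1 − ‖Y − Ŷ‖²/‖Y‖²; per
component SSY_a = (tᵀt)(cᵀc).

**Dummy coding.** Discriminant responses are one-hot dummies, centred *and
unit-variance scaled* per column. Scaling is the convention of the standard
chemometrics software and matters here: with 12 controls among 145 samples
a centred-only control column carries ~11% of the response variance, and
control-vs-disease markers — the core of any diagnostic panel — would be
structurally buried in the SSY-weighted VIP. Predictions are mapped back to
the 0/1 dummy scale; class assignment is the largest predicted dummy.

**Sign convention.** Every component is flipped so its largest-|weight|
variable is positive, making scores and loadings reproducible across runs.

### OPLS

For each orthogonal component the X-loading p of the current predictive
direction is projected onto the orthogonal complement of the span of the
current XᵀY columns (orthonormalised by QR), normalised to give w_o, and X
is deflated by t_o p_oᵀ with t_o = X w_o. Because w_o ⊥ XᵀY, every
orthogonal score has exactly zero sample covariance with every response
column (asserted to 1e-8 in tests). For a single response this reduces to
the classical w_o = p − (wᵀp/wᵀw)w. With zero orthogonal components OPLS
equals PLS-DA exactly. Predictive components are then fitted by NIPALS on
the filtered X; prediction on new samples removes the fitted orthogonal
variation first.

The default 4-class model uses 3 predictive components (classes − 1) and 2
orthogonal components; component counts are configurable, and a forward
rule (add while cross-validated Q² improves by > 0.01) is provided.

### Cross-validated Q²

Q² = 1 − PRESS/SSY, with PRESS accumulated over held-out folds and SSY the
held-out deviation from the training-fold response mean (the null model).
7-fold by default, stratified by class; fold assignment keys samples by
sorted sample ID before a seeded shuffle, so the value is invariant to row
order. Column scaling of X is re-estimated inside each training fold. A
fold that would remove an entire class from training raises.

### VIP and p(corr)

VIP_j = √( p · Σ_a SSY_a ŵ²_ja / Σ_a SSY_a ) over predictive components
(ŵ unit-norm per component); the mean squared VIP is exactly 1, which is
asserted as an algebraic identity. p(corr)_j is the Pearson correlation of
the (scaled) column j with the first predictive score, defined only for
one-predictive-component models.

### EDSS profile and PCA

The response-related profile regresses the scaled metabolite block on EDSS
with a one-predictive-component OPLS (one orthogonal component by default)
and reports predictive weights plus p(corr); the profile can be re-ordered
by a structural-class map for display. PCA scores come from the
eigen-decomposition of the covariance matrix with the same sign convention.

## Biomarker panels

The panel ranking is the VIP of the 4-class OPLS-DA model (3 predictive + 2
orthogonal) — the model whose discrimination the panel must serve; ties
break by ascending metabolite name. For each one-vs-rest contrast the panel
columns are transformed to a single component: a two-class one-component
PLS-DA T1, oriented so the positive class has the higher mean. One PLS-DA
per contrast (rather than a single shared T1) keeps each AUC well defined;
the midrank Mann–Whitney AUC is returned unflipped. Confidence intervals
are stratified percentile bootstrap (500 replicates, 95%), deterministic
given a seed; BCa is deliberately not the default. The panel-size sweep
evaluates top-k panels for k = 2…20 and reports the arg-max of the mean
one-vs-rest AUC plus the plateau (all k within 0.005 of the maximum).

Joint panels append clinical covariates as columns: numeric covariates are
UV-scaled like metabolites; binary OCB is centred but not variance-scaled
(unit-variance scaling of a rare binary inflates its leverage). VIP is
recomputed on the augmented 4-class model and the top-10 features form the
joint panel; samples missing a selected covariate are excluded with a
logged count. The published panel compositions ship as named presets
(`fig3a` metabolite-only, `fig3b` joint).

## SUS relapse screening

Two one-predictive-component OPLS-DA models share the control class:
control vs. remission (X axis) and control vs. relapse (Y axis), restricted
to pre-treatment samples when the annotation flag is present (with a
warning otherwise). Coordinates are p(corr) values, each oriented so the
disease class has the positive mean score. Region calls are a deterministic
function of the coordinates:

* `relapse_specific` iff |x| < c_axis and y ≥ c_contrib (and symmetrically
  `remission_specific`),
* `shared_up_gradual` iff x > c_axis and y > x + c_diag,
* `shared_up` iff both ≥ c_contrib and |y − x| ≤ c_diag,
* `shared_down` iff both ≤ −c_contrib, else `null`.

The thresholds are configuration, not biology: the defaults
(c_contrib = 0.3, c_axis = c_diag = 0.08) were chosen once so that the
synthetic generator's designed gradient structure is recovered with ≥ 90%
sensitivity at the study's sample sizes, and every output records the
thresholds used. The merged screen pools remission/relapse across diseases,
keeps the `shared_up_gradual` metabolites and confirms each by the
univariate relapse-vs-remission test (p < 0.05 and FC > 1). K-means
confirmation clusters candidate metabolites on per-metabolite z-scored
profiles (pattern, not magnitude) with 20 seeded restarts, and reports
per-cluster status means plus whether control < remission < relapse holds.
Heatmap ordering uses average-linkage agglomeration on 1 − Spearman ρ;
constant profiles (undefined ρ) are flagged and placed last.

## Networks and pathways

Chemical-similarity edges connect metabolite pairs with Tanimoto
coefficient |A∩B|/|A∪B| ≥ 0.7 over binary fingerprints; reaction-pair
(substrate–product) edges are overlaid regardless of similarity, and a pair
satisfying both is typed `both`. A pair of all-zero fingerprints is
undefined and skipped; reaction pairs naming unknown metabolites are
skipped with a warning. Nodes annotated from a contrast carry direction
(up/down for significant, `ns` otherwise — retained in the data model,
flagged for display filtering) and size |log₂ FC|, which makes halving and
doubling symmetric. Export is Cytoscape SIF plus a node-attribute TSV in
deterministic lexicographic order. Fingerprints and reaction pairs are
input data, never fetched live.

Over-representation of a hit set in a pathway is the upper-tail
hypergeometric probability P(X ≥ k); pathway impact is the sum of
relative-betweenness centrality over hit members divided by the sum over
all pathway members, on the pathway graph built from reaction pairs
restricted to members (0 when the pathway carries no centrality mass). No
correction across pathways by default (a BH flag exists).

## The synthetic cohort generator

The generator is the package's testbed: it produces cohorts in which every
downstream claim has a known ground truth. The default design emulates the
study conditions: 145 samples (12 CTRL / 54 MS / 49 NMOSD / 30 ITM), 57
remission + 61 relapse pre-treatment patient samples (the remaining 15
patients are flagged post-treatment; statuses split proportionally per
disease since per-disease counts are not published), and 85 named
metabolites in realistic chemical-class proportions (12% sugars, 12%
polyols, 28% amino acids, 15% fatty acids, 15% organic acids, 2% amines,
1% phosphates, 14% miscellaneous).

**Abundance model.** Log-normal per metabolite with multiplicative effects:
log x_ij = μ_j + log f(group_i, j) + log g(status_i, j) + σ_j ε_ij. Every
published (metabolite, disease, fold-change) univariate entry is designed
exactly (controls are the reference). The per-metabolite dispersion σ_j is
back-calculated from the published p-value of the same entry by inverting
the pooled t-test at the study group sizes: the printed p gives the t
statistic, hence the standardised effect d, and σ_j = |ln FC|/d (the
smallest implied σ when a metabolite appears in several contrasts). This
reproduces not only the published effect sizes but their published
*evidence*: a large fold change with a marginal p (butane-2,3-diol, 0.22 at
p ≈ 0.03) is designed as a noisy marker, a modest fold change with a tiny p
(1-monostearin, 1.72 at p ≈ 3e-9) as a strong one. Unlisted metabolites get
σ = 0.45; gradient metabolites 0.50; threitol 0.30; 1-monopalmitin uses
0.19 (slightly below its implied 0.216), a design-stage power-calibration
choice.

**Designed panel.** The eight published panel metabolites are the designed
multi-class ground truth. Where the published per-disease tables are silent
about a panel member, the design adds complementary between-disease effects
(threitol 0.70/0.48/1.05 across MS/NMOSD/ITM; phenylalanine 1.18 in NMOSD
and 0.82 in ITM; lactic acid 0.85 in MS) at magnitudes whose detection
power at the published group sizes is ~50–70%, so their absence from a
single univariate table is unsurprising. These complements encode the
between-disease discriminative structure that a published VIP-selected
panel must have carried but a per-disease significance table cannot show.

**Baseline abundances.** Chromatogram totals are dominated by abundant,
stable peaks — urea, glucose, creatinine, myo-inositol, lactate are the
canonical CSF majors — so those receive large log-abundance boosts and
tight dispersions, class-level offsets put sugars/organic acids high and
fatty acids/amines low, and baseline log-abundance anti-correlates with
dispersion. Without this structure, sum normalisation would be driven by a
few wildly fluctuating trace peaks, which real profiles do not show, and
compositional artefacts would distort every designed effect.

**Correlation structure.** Metabolites of one chemical class share a
per-sample latent factor (noise correlation 0.35; 0.1 for fatty acids so
that block-level estimation errors decorrelate), and the amino-acid block's
designed effects scale with a per-sample log-normal severity factor
(sd 0.75): one systemic mechanism drives the block, so a severely affected
patient shifts all its members together. Both features mimic the
co-regulation observed in real metabolomes and are what makes surplus
markers partially redundant.

**Relapse gradient.** Sixteen metabolites — the full 13-member fatty-acid
block plus putrescine, oxoproline and β-hydroxybutyrate — carry status
multipliers 1.6 (remission) and 3.5 (relapse) against control. The
multipliers were chosen once, by a design-stage power analysis, as the
weakest monotone gradient whose SUS signature (remission p(corr) ≈ 0.3,
relapse ≈ 0.6) is recoverable with ≥ 90% per-metabolite sensitivity at 12
controls; the implied relapse/remission ratio of ≈ 2.2 matches the strong,
significant univariate relapse elevation the screen must confirm.

**Clinical covariates.** EDSS is 0 for healthy controls; patients draw a
group/status base (NMOSD attacks more disabling than MS relapses) plus
N(0, 0.9) noise plus the designed metabolite coupling — sign · strength ·
z(log abundance) with strengths +1.3/+1.1 for 1-monostearin/1-monopalmitin
and −0.5…−0.6 for ethanolamine, threose and 1,5-anhydroglucitol — then
rounds to the half-point grid with a minimal-disability floor (0.5
remission, 1.0 relapse). OCB is Bernoulli with MS-enriched rates
(0.85 vs 0.15–0.20 in other diseases, 0.02 in controls); protein is
log-normal with disease-specific elevation (strongest in NMOSD/ITM); WBC is
Poisson with status-dependent rates; IgG index is MS-elevated.

**Censoring.** Cells go missing at rate 0.02, doubled below the
per-metabolite 10% abundance quantile (missing-not-at-random, as in GC-MS
non-detects).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chromatographic drift and batch effects, the
~900 unidentified signals, non-log-normal heavy tails, inter-class
correlation beyond the class factors, treatment effects on the metabolome
(post-treatment samples differ only by flag), and any relationship among
covariates beyond their designed couplings.

## Numerical choices

* NIPALS convergence: relative score change ≤ 1e-9, max 2000 iterations
  (near-degenerate eigenvalue pairs under correlated blocks converge
  slowly); non-convergence raises with the component index.
* Orthogonality contracts are asserted to 1e-8; round-trip file I/O uses
  `%.17g` and round-trip float parsing, so datasets survive write/read
  bit-faithfully.
* AUC uses midranks, so tied scores contribute exactly 1/2; AUC(s) +
  AUC(−s) = 1 exactly.
* VIP ties break by ascending metabolite name; component signs follow the
  largest-|weight| convention; K-means uses 20 seeded restarts.
* Degenerate inputs fail loudly: all-missing samples or metabolites,
  zero-variance columns under scaling or p(corr), constant panel columns,
  empty classes in AUC or bootstrap, exhausted X-rank in OPLS.

## Known limitations

* The SSY-weighted VIP of a 4-class model intrinsically favours
  between-disease contrasts; uniform control-vs-disease markers rank high
  only through the response scaling described above, and their ranks remain
  the noisiest part of panel recovery.
* With ~35 genuinely informative metabolites in the designed cohort, the
  panel-size sweep's mean AUC keeps improving slowly past k = 8, so the
  strict 0.005 plateau typically starts near k ≈ 16–20 rather than at the
  designed panel size; the sweep, arg-max and plateau are reported as
  computed.
* Fold changes use arithmetic means (ratios of relative abundances); for
  very high-dispersion metabolites the sample mean ratio is a poor
  estimator of the designed multiplier, which is a property of the
  statistic, not a bug.
* Percentile bootstrap intervals undercover slightly near AUC = 1 (every
  resample separable); coverage is verified at AUC = 0.8.
* The pathway catalogue bundled with the generator is a small toy; real
  analyses should supply their own fingerprint/pathway/reaction-pair
  tables (documented input schema, never fetched live).
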