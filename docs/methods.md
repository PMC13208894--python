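# Methods

This note records the models, defaults and design choices behind each stage
of the pipeline, and what the synthetic validation does and does not show.

## Data model and statistical unit

An MSI section is a set of 0-based (row, col) pixels, each with a full
positive-mode spectrum on a shared m/z axis (acquisition window m/z 70–1000;
peaks outside it are dropped on load with a logged count). Missing peaks are
stored as 0, never NaN; a pseudo-count downstream handles zeros.

The statistical unit of every group comparison is the **ROI-averaged
spectrum**: the arithmetic mean spectrum over the pixels of one region in
one section. Testing at pixel level would treat thousands of strongly
correlated pixels as independent observations and inflate n by orders of
magnitude; ROI-level n (one observation per section and region) is the
conservative choice, and it is the only mode offered. The price is power:
with only three liver-metastasis sections, the LT-vs-LN screen often calls
nothing at ROI level, which the package reports honestly rather than
hiding. Necrotic and background pixel labels are representable in masks but
never enter group statistics.

## Normalization

Per-pixel total-ion-current (TIC) normalization is the default, with
median-intensity normalization as an option; both are idempotent and
invariant to per-pixel rescaling. The pipeline's default TIC target is 1e4
(a counts-like scale) because the fold-change pseudo-count of 1 must stay
negligible relative to per-feature means; normalizing to total 1 would let
the pseudo-count dominate and shrink every log₂FC toward 0.

TIC normalization measures *relative* abundance. When a large fraction of
the signal changes asymmetrically between regions, the closure constraint
shifts all other ions in the opposite direction (compositional effect).
With the synthetic generator's small ion panels this is visible: null
metabolites acquire genuine relative changes and are correctly—in the
relative sense—flagged. Calibration of the screen itself (FDR, recall) is
therefore assessed on matrix-level simulations without closure; the
end-to-end tests assert recovery of strongly planted effects, not
precision against absolute ground truth.

## Peak alignment

Peaks from all ROI spectra are pooled, sorted by m/z, and split into
clusters wherever the gap between consecutive peaks exceeds the tolerance
(default 5 ppm, relative to the lower m/z). For points on a line this gap
rule is exactly single-linkage clustering at the ppm threshold; it is
deterministic and independent of input order. Consensus m/z is the
intensity-weighted mean of a cluster; a spectrum contributing several peaks
to one cluster has them summed (total intensity is conserved); absent peaks
are 0. Clusters whose span exceeds 2× the tolerance (chain effect) are kept
but logged for manual exclusion.

## Adduct annotation

Theoretical m/z = neutral monoisotopic mass + adduct shift, with shifts
computed from CODATA monoisotopic masses (proton 1.007276466621 Da,
electron 5.48579909e-4 Da, Na, K, NH₄, H₂O), e.g. [M]⁺ subtracts one
electron mass and [M−H₂O+H]⁺ is −17.002670 Da. Matching keeps **every**
(metabolite, adduct) pair within tolerance (default 5 ppm), ranked by
|ppm error| with ties broken by adduct priority
[M+H]⁺ > [M+NH₄]⁺ > [M+Na]⁺ > [M+K]⁺ > [M−H₂O+H]⁺ > [M]⁺ (ordering
rationale: protonated and ammoniated species dominate in acetonitrile
sprays). All matches are
retained because MS1 accuracy alone cannot resolve isobars; rank 1 encodes
preference and downstream stages use the rank-1 metabolite.

A systematic instrument shift is estimated as the median signed ppm error
of unique best matches at a widened tolerance (10 ppm), requiring at least
5 confident matches, and—when correction is enabled (off by default)—
removed by dividing observed m/z by (1 + shift·10⁻⁶) before final
matching. The median is robust to the minority of wrong matches at the
widened tolerance.

## Differential screening

Default test: two-sided Mann–Whitney U with normal approximation and tie
correction, chosen for robustness to the heavy right skew of MSI
intensities. Welch's t on log₂(x + 1) is the alternative; the default
pipeline applies it to the small-arm comparisons (LT vs PT and LT vs LN at
3 sections, metastatic vs metastasis-free at 5 vs 5), where the discrete
rank statistic's attainable p floor (≈0.009 at 5 vs 5) makes BH discovery
arithmetically impossible. All-tied features get p = 1.

log₂FC = log₂((mean_B + c)/(mean_A + c)) on linear-scale group means,
pseudo-count c = 1 (configurable). BH adjustment is applied within each
comparison separately. Calls require q < 0.05 **and** |log₂FC| > 0.25.

Venn integration counts significant sets, their intersection/union and
sign concordance; trend labels over (N, PT, LT) map the two
consecutive-comparison directions: (up, up) → monotone increase,
(up, down) → up-then-down, (down, up) → down-then-up, (down, down) →
monotone decrease, (ns, ns) → flat, anything else → mixed.

## PCA and OPLS-DA

PCA is an SVD of the centered (and scaled) matrix with a deterministic
sign convention (largest-|loading| positive per component). Scaling
options: unit variance (default for OPLS-DA), Pareto (÷√sd), none;
constant columns are centered and left unscaled.

OPLS-DA follows the orthogonal-signal-correction scheme: repeatedly
extract the component of X orthogonal to the (centered 0/1) response and
deflate, then fit one predictive PLS component to the filtered matrix.
R²Y is 1 − SS(residual)/SS(y) on the training fit. Q² uses venetian-blind
k-fold CV (row i → fold i mod k, k = 7, the customary layout in
commercial PLS software), with
centering, scaling and the full orthogonal filtering refitted on each
training portion. Prediction of new rows applies the stored orthogonal
filters before projecting.

The permutation test refits the model under n (default 200) label
permutations with identical settings and reports per-permutation
(|corr(y_perm, y)|, R²Y, Q²) plus the least-squares intercepts of the R²
and Q² lines at correlation 0, the original model included at correlation
1. Verdict "no overfitting" requires all permuted Q² below the original
and Q² intercept < 0.05. The four-region view is handled as PLS-DA with a
one-hot response for scores plots only — orthogonal PLS is single-response
by construction, so the permutation machinery is binary-only.

## Pathway over-representation

Plain hypergeometric upper tail, P(X ≥ k), with pathways intersected with
an **explicit** universe (the annotated metabolites of the run) before
testing; zero overlap gives p = 1. No topology/impact weighting and no
multiple-testing correction across pathways; significance is raw p < 0.05.
Pathway sets come from a tab-separated file or from the `pathways` column
of the metabolite database.

## Signature panels

Univariate AUC uses midranks (ties count ½), with orientation recorded and
tiers at oriented AUC ≥ 0.75 and ≥ 0.85. The logistic panel is fitted by
damped Newton/IRLS on standardized members with an L2 penalty (default
1e-6) on the non-intercept coefficients — enough to keep quasi-separated
panels finite while leaving well-conditioned fits numerically identical to
the unpenalized maximum likelihood (verified against statsmodels).
Convergence: max |penalized score| < 1e-8 within 100 iterations, with a
stall detector that accepts machine-precision convergence when the line
search can no longer move β and the score is already < 1e-5; genuine
non-convergence raises with the iteration trace. Cross-validation uses
stratified folds (class proportions preserved) assigned deterministically
from a seed, refitting the panel on each training portion; the reported CV
AUC is the mean ± sample sd over folds. Panels are user-specified member
lists or the automatic top-k by univariate AUC; when a screen yields fewer
than two annotated significant markers the pipeline ranks all annotated
features instead and records `marker_pool: all_annotated`.

## Synthetic study generator

The generator emulates the target study design: 10 normal-colorectal
sections (region N), 10 primary-tumor sections (regions N + PT; 5 patients
metastatic, 5 metastasis-free) and 3 liver-metastasis sections (LT + LN),
23 sections total. Each of n metabolites (default 150; neutral mass
uniform on 100–900 Da) expresses 1–3 adducts with Dirichlet weights;
observed m/z per (section, peak) carries Gaussian mass error (sd 1.5 ppm
by default, small enough that true matches stay inside the 5 ppm window)
plus an optional planted systematic shift. Pixel intensity is

    lognormal baseline (meanlog 10, sdlog 1)
    × per-(section, metabolite) biological factor (lognormal, sdlog 0.3)
    × 2^(region log₂ effect) × adduct weight
    × mean-1 multiplicative noise (CV 0.3) × Bernoulli(1 − dropout).

A configured fraction of metabolites (default 0.3) is differential: each
stage transition (N→PT, PT→LT) changes with probability 0.8 and magnitude
uniform on ±[0.5, 2.0] log₂ units — spanning both sides of the screening
cutoffs. A further subset (default 0.15) carries an extra PT-only effect
(|log₂| ∈ [1, 2]) in the metastatic arm. The database contains the true
metabolites plus decoys (default 50) rejection-sampled so every decoy
adduct m/z is ≥ 20 ppm from every true adduct m/z: any decoy hit is an
unambiguous annotation error. All draws flow from one integer seed;
identical seeds give identical studies.

What the generator does **not** emulate: chromatography, isotope
envelopes, MS/MS spectra, spatially smooth within-region texture (noise is
i.i.d. across pixels), patient-level pairing between primary and
metastatic sections, and realistic metabolite mass clustering. Passing the
recovery suites therefore demonstrates correctness of the statistical
machinery under the stated generative model, not performance on real
tissue data.

## Validation problem sizes

The test and acceptance suites use: spike-in screens at 1000 features with
100 planted effects (|log₂FC| ≥ 1) at n = 10 vs 10; null calibration over
200 replicates of 1000 all-null features; mass-shift recovery on a
23-section study with 60 metabolites; OPLS-DA permutation runs of 200
permutations at 40 × 60; panel CV at n = 60 with a planted binormal AUC of
0.95, averaged over 10 replicate draws to tighten the Monte-Carlo estimate
of the CV mean. These sizes give stable pass/fail behaviour at seeded
randomness while keeping the full suite in the tens of seconds.

## Numerical choices and degenerate inputs

- All-zero pixels pass through normalization unchanged (counted, logged).
- Consensus m/z ties from duplicated peaks are broken by nextafter-nudging
  to preserve strict monotonicity of the feature axis.
- Mann–Whitney on an all-tied feature returns p = 1 (zero tie-corrected
  variance), not NaN.
- BH adjustment delegates to the standard step-up implementation and is
  oracle-checked against the definition on exhaustive small vectors.
- PCA/OPLS sign conventions are deterministic; permutation tests,
  CV folds and the generator are seeded, so reruns are byte-identical.
- Logistic ridge 1e-6 is a stability floor, not a tuning parameter; it is
  recorded in every panel model.

## Known limitations

- Annotation is MS1-only ("putative"); isobaric metabolites within the ppm
  window are all reported and ranked, never resolved.
- No image registration, spatial segmentation, or spatial autocorrelation
  correction; ROI masks are taken as given.
- ORA ignores pathway topology; results depend on the declared universe.
- The ROI-level unit gives little power in 3-section arms (by design);
  interpret empty LT screens as insufficient n, not absence of biology.
- imzML support covers reading (continuous and processed modes); writing
  uses the package's own CSV dialects.
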