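# Methods

This note documents the models implemented in `phytoplex`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Assay calibration

Standard curves are ordinary least squares lines `signal = b₀ + b₁·c`
through (concentration, signal) pairs, with a free intercept: blanks are
non-zero in practice and forcing the origin would bias low-concentration
readings. A curve is invertible only when `b₁ > 0`.

TEAC conversion: for a well absorbance `A`, the Trolox-equivalent
concentration in the diluted extract is `(A − b₀)/b₁` (mM). With powder
extracted in `v` volumes of solvent (ml per g) and the extract diluted by a
factor `d` before plating, the activity per kg of material is

    TEAC [mmol TE/kg] = (A − b₀)/b₁ × d × v

— the powder mass cancels, which is also the package's invariance test
(TEAC depends only on the extract concentration). Replicates below the
blank clamp to 0 and raise a flag rather than an error: small negative
readings are routine plate noise. The canonical internal unit is
mmol TE/kg; `TEACResult.unit` records it explicitly because the field
mixes "/g" and "/kg" conventions.

HPLC quantification maps peak areas through per-analyte curves to mg per
100 g fresh weight; several analytes may share one curve (the "equivalents"
convention, e.g. glycosides quantified as cyanidin-3-O-glucoside
equivalents), and the curve actually used is recorded per analyte.
Ascorbic acid is treated as just another analyte/curve pair; the detection
wavelength is stored as metadata only.

## Preprocessing

Median fold change normalization removes per-sample global intensity
differences. The reference profile is the feature-wise median across all
samples (symmetric in the samples; the method's name fixes the statistic
but not the reference). The per-sample factor is the median of
value/reference over features positive in both; zeros are excluded rather
than pseudo-counted so the factor stays scale-free. The pseudo-count
(default 1 area unit) applies only at the log step.

One numerical property worth knowing: re-running the normalization on its
own output with a *recomputed* reference does not return factors of exactly
1 — the median reference does not transform multiplicatively under
per-sample scaling, and the fixed-point iteration can oscillate. Because
the median of ratios is exactly scale-equivariant, re-applying the
normalization **with the reference it returned** yields factors identically
1; the function therefore returns its reference and accepts one, and that
is the form in which idempotence is guaranteed and tested.

Feature matrices are natural-log transformed (base is irrelevant after
centering) and column mean-centered; unit-variance scaling is available but
off by default (mean-centering only). Targeted concentration tables are
centered without log transform by default (`log=False`), and the response
may be modelled as log₁₀(TEAC) via `response_transform="log10"` — the
convention for FRAP responses.

## PLS1, VIP, cross-validation

For a single response the NIPALS weight vector is closed-form per
component: `w_a ∝ X_aᵀy`, `t_a = X_a w_a`, `p_a = X_aᵀt_a/(t_aᵀt_a)`,
`q_a = yᵀt_a/(t_aᵀt_a)`, deflating X only. Coefficients are
`b = W(PᵀW)⁻¹q`. Requests beyond `min(n−1, p)` components raise an error;
a rank-deficient X is handled by stopping when the deflated matrix retains
no covariance with y (warning, truncated model). With full components the
fitted values equal OLS, the package's oracle test.

VIP: `vip_j = sqrt(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a)` with
`SSY_a = q_a² t_aᵀt_a`; mean VIP² = 1 by construction, so VIP ≈ 1 is an
averagely influential variable.

Cross-validation uses seven-fold random partitions (seeded and recorded);
when cultivar labels exist, samples of each cultivar are spread round-robin
across folds so no fold loses a whole cultivar by chance. Centering is
re-estimated inside each training fold — the training-fold mean is the
null prediction — so `Q² = 1 − PRESS/TSS` with TSS about training-fold
means, and `SDECV = sqrt(PRESS/n)` (divisor n, not n−1; both appear in the
literature and the choice is exposed only through this documented default).
Because PLS1 components are nested, each training fold is decomposed once
at the largest component count and truncated coefficient vectors serve all
smaller counts — one CV pass yields the whole Q² path.

The component count A maximizes Q² over A = 1..min(5, n−1, p), with the
smallest A attaining the maximum kept; a fixed-A override exists.

VIP-threshold selection: candidate thresholds are 0 plus the sorted unique
VIPs of the full model; each refit (on variables with VIP strictly above
the threshold) re-chooses A by Q²; the best-Q² threshold wins and ties
break toward the sparser model (thresholds are scanned from sparsest to
densest and a strictly better Q² is required to switch). If every candidate
is degenerate the full model is returned with a warning flag.

The permutation test permutes y, recomputes Q² at the observed component
count, and reports `p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1)` — the +1
correction keeps p > 0. Under the null the test is exact: with 99
permutations the rejection rate at α = 0.05 is exactly 5%.

Post-transformation: the predictive score is `t_p = X_c b/‖b‖` (computed as
`T q/‖b‖` via the NIPALS identity `X_c b = T q`), perfectly correlated with
the fitted values; the remaining score directions are orthogonalized
against it. Only the contract is guaranteed — prediction invariance and a
single predictive component — not a specific rotation matrix.

PCA is an SVD of the centered matrix; explained fractions are
non-increasing and sum to ≤ 1; requests beyond the rank truncate with a
warning.

## Monte-Carlo stability selection

Each of `n_subsamples` (default 1000) draws includes every sample
independently with probability `inclusion_prob` (default 0.70) — the
"prior probability" reading of Monte-Carlo subsampling; a fixed-quota mode
is deliberately not the default. Draws whose training set cannot support a
model (fewer than max(folds, A_max + 2) samples) are redrawn, with a hard
failure after 100 attempts. Per subsample, VIP-based PLS selection runs on
the included samples; SDEP = sqrt(Σ(ŷ−y)²/n_excluded) is scored on the
excluded samples using the selected-variable refit (the full-model
alternative is a documented assumption, not the default). Variables
selected in strictly more than 50% of the subsample models are "relevant".

A per-subsample permutation gate guards against over-fit subsample models:
a model whose response permutation test gives p > 0.05 contributes an empty
selection. The gate uses 19 permutations by default — the smallest count
whose minimum attainable p (1/20 = 0.05) still passes the strict p > 0.05
rule, keeping the cost of 1000 gated subsamples practical. Under a null
response this gate empties ~95% of selections, which is what makes the
null-calibration property (empty relevant set in ≥ 90% of seeds) hold.

The SLR analogue fits univariate OLS of y on each variable per subsample
(vectorized closed form; slope t-test with n−2 df) and records r², the
out-of-subsample SDEP and the slope p-value; "selected" within a subsample
means p < 0.05 — the criterion is an assumption since only the strategy,
not the rule, is conventionally stated. Variables constant in a subsample
are skipped; globally constant variables are excluded and reported.

All subsample seeds derive from one master seed through a counter, so every
result is exactly reproducible.

## Synergy classification

For a class C with conditions full, depleted(C) and isolated(C):

    loss  = TEAC_full − TEAC_depleted
    index = loss − TEAC_component          (mmol TE/kg)
    ratio = loss / TEAC_component

Uncertainty: each condition mean is resampled as
Normal(mean, sd²/n) — a parametric bootstrap, because with n = 3
replicates a nonparametric bootstrap is degenerate. The central 95%
interval of the index drives a three-way call: synergistic if the lower
bound is above 0, antagonistic if the upper bound is below 0, additive
otherwise (antagonism is included because the sign structure of the rule
forces it, even where only additive/synergistic outcomes are discussed).
A numerical guard (10⁻⁹ relative to the full-mixture TEAC) prevents
rounding residue from registering as an interaction in exact zero-noise
data. The p-value is the +1-corrected two-sided bootstrap probability of a
sign reversal.

Two properties of this rule worth knowing. First, plugging 3-replicate
standard deviations into Normal draws ignores their sampling error, so the
intervals undercover slightly (measured ≈ 91–92% at nominal 95%); the
calibration test asserts an honest band. Second, a truly additive class is
miscalled at the interval's miscoverage rate *regardless of the assay noise
level* (the interval scales with the noise), so a four-class panel is fully
correct only ≈ 85–90% of the time even when every call is made exactly as
designed — accuracy statements are therefore made per class call, not per
panel.

`run_depletion_panel` assesses every (full, depleted:C, isolated:C) triple
of each design against that design's own full condition, so a design whose
baseline is itself a depleted mixture (nested depletion, e.g. an
anthocyanin-free reconstitution further depleted of quercetins) is handled
like any other. `coverage_fraction` reports the reconstituted mixture's
share of the natural extract's activity with a bootstrap interval on the
ratio. Conditions are treated as independent (separate wells); no pairing
is assumed.

## MS/MS annotation

Neutral losses use monoisotopic masses (pentose 132.0423, deoxyhexose
146.0579, hexose 162.0528 Da) and are evaluated on every parent→child edge
of the fragment tree (precursor→MS² and MS²→MS³), not only from the
precursor — the more permissive and, for glycoconjugates, chemically
sensible reading. The default mass tolerance is 0.5 Da (ion-trap, unit
resolution). Hydroxycinnamic-acid classes match an MS² fragment with the
required MS³ child; ferulic derivatives accept *any* of 134/149/178 by
default (the three children are listed without conjunction semantics; an
"all" mode exists). Widening the tolerance never removes an annotation.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes:

* **Design** 18 cultivars × 2 vintages × 3 replicate pools (configurable).
* **Concentrations** cultivar mean × shared per-class vintage multiplier ×
  unit-mean lognormal replicate noise, truncated at 0. Replicate noise is
  multiplicative because concentrations are positive and skewed; the
  vintage effect is a weak shared shift (default 5% relative SD) so
  cultivar dominates the variance hierarchy, which is what makes PCA
  cluster samples by cultivar rather than vintage.
* **Default ranges** per-cultivar class totals: anthocyanins 14–114,
  hydroxycinnamic acids 10–65, quercetins 1–7, ascorbic acid 7–15 mg/100 g
  fresh weight, split among class members at fixed proportions with
  rutinosides dominant.
* **Responses** TEAC = intercept + Σβ·c + Σγ·c·c + Gaussian noise. Unit
  activities put cyanidin-3-O-rutinoside highest, then ascorbate and
  cyanidin-3-O-glucoside. Default interaction terms pair an anthocyanin
  with quercetin and with ascorbate; because interactions are pairwise
  products, removing the anthocyanin partner extinguishes them — the
  mechanism behind the "synergy vanishes without anthocyanins" simulations.
  Pairwise terms only: the minimal model expressing the
  additive-versus-synergistic dichotomy. Per-sample assay responses are
  simulated because no per-sample assay data is available to emulate; the
  response defaults are calibrated to plausible TEAC ranges
  (≈ 5–40 mmol TE/kg), not to any particular dataset.
* **Features** each metabolite expands into a monoisotopic feature, a +1
  isotope at a fixed fraction (default 0.12) and an adduct (default 0.25),
  all scaled by a per-sample lognormal global intensity factor (σ = 0.3)
  plus multiplicative measurement noise; 104 noise features (default)
  carry no cultivar effect. Feature counts and fractions are configurable.
* **Plates** absorbance = curve(concentration) + Gaussian noise, with
  Trolox standard wells at serial dilutions.

Not emulated: chromatogram/spectrum-level data (no mzML, no peak shapes),
missing values and detector saturation, drift within a batch, correlated
assay errors between conditions, NMR data, and any real cultivar's actual
composition — the phytocomplex compositions shipped in examples are
synthetic stand-ins, not a published recipe. Passing tests therefore
demonstrate the *statistical machinery* (calibration arithmetic, selection
operating characteristics, classification logic), not that any real
cultivar exhibits synergy.

## Problem sizes and numerical defaults

The test suite and the acceptance script run the study-scale design
(n = 108) but scale iteration counts to what the properties need:
200 Monte-Carlo subsamples for planted-model recovery, 400 simulated
datasets × 99 permutations for the null calibration of the permutation
test (99 keeps the nominal 5% level exactly attainable), 40–50 subsamples
per seed for the null-stability check, 2000 bootstrap draws per synergy
assessment (25–100 seeded panels), and 1000 noisy plates for the assay
round trip. Tolerances: exact algebraic identities at 1e-8–1e-10;
stochastic calibrations at the width justified by their own Monte-Carlo
error. The pseudo-count, tie-break, degenerate-input and truncation rules
are described above where each operation is defined.
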