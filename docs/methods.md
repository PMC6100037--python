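# Methods

This note records the models, conventions and design choices behind
`grapearoma`, in the order the pipeline applies them.

## Aroma chemistry layer

**Odor activity values.** OAV = concentration / odor threshold, computed
per replicate; a not-detected compound is stored as concentration 0 and
therefore OAV 0, so every downstream sum is defined. Thresholds are
strictly positive by library invariant, which keeps all OAVs finite.
Compound *activity* uses the strict inequality OAV > 1; series *activity*
uses value ≥ 1 in at least one sample (values below 1 everywhere mean "no
active aroma"). The two cutoffs deliberately differ in strictness because
they are used in different roles: the compound rule filters individual
odorants, the series rule grays out whole wheel sectors.

**Aromatic series.** Each descriptor maps to exactly one of ten primary
series; descriptors under fruity/floral/sweet may additionally map to
secondary series (14/13/5 of them). A compound joins the union of its
descriptors' series and contributes its *full* OAV to each — a compound
with three fruity descriptors feeds three secondary series undiminished.
This double counting is intentional: series values are perceptual-salience
scores per aroma note, not a partition of chemical mass. Consequence:
series totals are conserved (Σ primary series = Σ OAV) only when every
compound carries a single descriptor, which the test suite checks on
exactly that restriction. Descriptor tokens are case-folded and
whitespace-trimmed before lookup; descriptors absent from the taxonomy
produce warnings, never errors, because literature descriptor coverage is
incomplete. The shipped default taxonomy names the series the literature
names (eight fruity, five floral, two sweet secondary series) and fills the
remaining slots with `*_x*` placeholder series so the stated 14/13/5 counts
hold; a study-specific taxonomy file replaces it transparently.

**Whole-berry blending.** Whole = f·skin + (1−f)·pulp per compound and
replicate, with skin mass fraction f = 0.2 by default (configurable). The
blend is a declared stand-in: published whole-berry values rarely state
their aggregation rule, and a convex mass-weighted combination is the
simplest physically interpretable choice. Ripeness screening flags
cultivars below 16 °Brix TSS (the OIV table-grape rule) but never removes
them; removal is a pipeline option.

## Chemometrics

**Scaling.** Unit-variance (UV) scaling throughout: column mean 0, SD 1,
with SD computed with ddof = 1. The response is UV-scaled alongside X;
RMSEE and RMSECV are reported back on the 1–5 sensory scale by multiplying
scaled residuals by the fitted y SD. Zero-variance columns are dropped at
fit time with a recorded list and the same columns are dropped at apply
time; applying scaling parameters to data missing a fitted column is an
error that names the column.

**OPLS.** Single-response orthogonal PLS with the orthogonal-filtering
recursion: w ∝ X′y (unit norm, computed once); per orthogonal component,
p = X′t/t′t with t = Xw, w_o ∝ p − (w′p)w, t_o = Xw_o, deflate
X ← X − t_o p_o′; finally t = Xw, q = y′t/t′t. With zero orthogonal
components the model is exactly one-component PLS1, which the tests verify
against scikit-learn's implementation at 1e-10. Orthogonality assertions
(w′w_o, t′t_o) use tolerance 1e-10. R²X is the cumulative X-variance of
all components; R²Y the explained response variance; RMSEE uses the
degrees-of-freedom convention √(SS_res/(N − 1 − A)) with A the total
component count (the convention of the chemometrics software lineage this
follows; switching to 1/N is a one-line change). Prediction removes the
orthogonal components from new data with the stored (w_o, p_o) pairs
before projecting on w — predictions are therefore invariant to adding
any multiple of a fitted orthogonal direction to a new sample, which is
tested by construction.

**Component selection.** Seven-fold cross-validation with deterministic,
response-balanced folds: samples are sorted by y and fold labels are a
seeded permutation within each consecutive block of seven, so every fold
spans the response range. Scaling and the model are refitted per fold on
the training part only. Q²Y = 1 − PRESS/SS(y); RMSECV = √(PRESS/N) in raw
units. The orthogonal-component count grows while Q²Y improves by more
than 0.01 (cap 9, configurable). The 0.01 rule is a declared stand-in for
the proprietary component-acceptance rules of commercial packages, which
are not published.

**Hotelling's T² screening.** PCA on the UV-scaled matrix; the score space
uses the smallest number of components reaching cumulative R²X ≥ 0.8,
capped at 5 (the source analyses state only "Hotelling's T² (99%)", so the
component rule is a package choice). T²ᵢ = Σ t²ᵢₐ/λₐ; the control limit is
A(N−1)/(N−A)·F₀.₉₉(A, N−A); screening is a single pass: flag, remove,
refit once. The limit requires N > A + 1. On clean spherical Gaussian data
the empirical flag rate sits slightly below the nominal 1% (top
eigenvalues of sample PCA are biased upward), which the test suite brackets
at 0.2–2.5%.

**Permutation test.** n = 200 permutations of y with the component and
fold counts frozen; each permutation refits and cross-validates. The R²
and Q² regression lines pass through the permuted points at |corr(y_perm,
y)| plus the unpermuted model at correlation 1; their values at
correlation 0 are the reported intercepts. A negative Q² intercept is the
validity signature; with a pure-noise response the original Q²Y is not
separated from its permutation null.

**VIP.** VIPⱼ = √(K·Σₐ SSYₐ(wₐⱼ/‖wₐ‖)²/Σₐ SSYₐ) over the predictive and
orthogonal components, SSYₐ being the response sum of squares captured by
component a. The mean of squared VIPs is 1 by construction (tolerance
1e-8 in the tests), which grounds the VIP > 1 selection rule. Whether
total or predictive-only VIP is "the" VIP differs between software
lineages; total VIP is the default here with `kind="pred"` as the switch —
for a single predictive component the orthogonal SSYₐ are near zero, so
the two variants differ little in practice.

## Liking pipeline conventions

Training uses cultivar-mean whole-berry features; prediction is made per
replicate and averaged per cultivar (predict-then-average; the alternative
average-then-predict is identical for the linear model on matched
replicate counts). Quality bins close the half-open published ranges
deterministically: poor < 3.5 ≤ average < 4.0 ≤ good ≤ 4.5 < excellent,
with 4.5 belonging to "good". Models with cross-validated Q²Y ≤ 0.5 are
flagged ineffective and block key-compound selection unless explicitly
overridden. Aroma combinations partition cultivars by seeded k-means on
the UV-scaled (positive-key total, negative-key total) plane, labelled
I, II, ... in increasing order of total key-compound content — a declared
interpretation of a grouping that the source material describes only
pictorially. HCA uses Ward linkage on Euclidean distances of UV-scaled
series values (neither linkage nor metric is stated in the source
analyses; both are configurable).

## Synthetic cohorts

The generator's defaults are the study conditions: 20 scored + 19 unscored
cultivars, triplicate pulp and skin profiles, 100 compounds in 8 chemical
classes (terpenes 30%, esters 20%, aldehydes 13%, alcohols 11%, C₆ 7%,
acids 5%, norisoprenoids 3%, ketones 2%, other 9%), odor thresholds
log-uniform over 0.1–10⁴ μg/kg, 17 positively and 9 negatively
liking-related key compounds, liking noise SD 0.2 on the 1–5 scale, three
y-orthogonal latent factors.

Concentrations are log-normal: per-compound base abundances span orders of
magnitude with class-typical ranges (C₆ compounds highest, forming the
background), class-level cultivar effects (ln-SD 0.1), compound-level
idiosyncratic variation (ln-SD 0.25; 0.08 for key compounds), additive
ln-space tissue bias (esters pulp-heavy, terpenes skin-heavy, C₆ high in
both) and multiplicative replicate noise with CV 10%. Non-key compounds
drop out (concentration 0) in 8% of cultivar × tissue cells, emulating
zero-inflated detection.

Key compounds load on two latent cultivar factors — one for the liked
group, one for the disliked group, ln-loadings U(0.55, 0.7) — mimicking
the co-regulation of biosynthetically related volatiles (terpene pathways,
ester pathways); this low-dimensional structure is what makes coefficient
signs identifiable from a 20-cultivar training set. Liking is a linear
function of the UV-scaled whole-berry cultivar means of the key compounds
with mixed-sign coefficients, the two sign groups balanced to contribute
equal variance (preference is modelled as a trade-off between liked and
disliked volatiles, not a head count), scaled to SD 0.6 around a center of
3.5, plus Gaussian noise, then clipped to [1, 5] (clipping after noise).
The latent factors are standardized and decorrelated within the scored
block: a sensory-panel training set is assembled to span the preference
space, so the generator enforces that by construction. Y-orthogonal
factors are random cultivar scores orthogonalized exactly against the
liking signal, multiplied into all compounds' concentrations through
ln-space loadings (SD 0.12) — structured variation an OPLS model should
route into its orthogonal components.

What the generator does **not** emulate: chromatographic artifacts,
co-elution, detection limits beyond zero-inflation, nonlinear or
interactive (masking/synergy) psychophysics, and matrix effects. Passing
tests therefore demonstrate that the pipeline recovers linear mixed-sign
structure from realistically scaled, tissue-structured, log-normal data —
not that real sensory panels are linear in volatile content.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded from
explicit seed parameters; generation, fold assignment, permutations and
k-means are reproducible bit-for-bit (tests assert identical serialized
reports across repeated runs, and value-level determinism at 1e-12). The
test suite runs on cohorts of the default size (234 samples × 100
compounds); the parameter-recovery properties are measured across 20
seeds, and Monte-Carlo rates (Hotelling false-positive rate) across 30
datasets of 200 samples — sizes at which the whole suite completes in a
few seconds on one core.

## Known limitations

- The OPLS implementation is single-response by design; no O2-PLS, kernel
  or multi-block variants.
- RMSEE/RMSECV conventions and the component-acceptance rule follow one
  software lineage; numbers from other packages can differ in the second
  decimal for the same data.
- The default taxonomy's placeholder secondary series make counts, not
  chemistry; studies should supply their own descriptor table.
- Hotelling screening is a single pass by design; iterated screening can
  remove more points than intended on small N.
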