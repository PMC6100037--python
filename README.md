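# grapearoma

Volatile aroma profiling and consumer-liking prediction for table grapes.

Breeding programmes sit on many unfamiliar grape cultivars whose market
appeal is unknown: they are grown in plantings too small for consumer
panels. `grapearoma` implements the chemometric route around that problem —
train a regression model on cultivars whose liking scores *are* known, then
predict the liking of the unfamiliar ones from their GC-MS volatile
profiles alone — together with the aroma-chemistry layer (odor activity
values and aromatic series) needed to interpret the result.

## What it computes

**Odor activity values.** For compound *i* in a sample, OAVᵢ = cᵢ / tᵢ,
the concentration (μg/kg) over the odor threshold. Compounds with OAV > 1
are perceptible ("aroma-active").

**Aromatic series.** Odor descriptors map onto ten primary series
(herbaceous, floral, fruity, sweet, spicy, roasty, fatty, earthy, balsamic,
solvent); fruity, floral and sweet subdivide into 14 / 13 / 5 secondary
series (apple, rose, honey, ...). A series' value in a sample is the sum of
its member compounds' OAVs; a compound with several descriptors feeds every
matching series at full OAV. Per-cultivar fingerprints and Ward/HCA
clusterings of the series profiles summarize the aroma landscape.

**OPLS liking regression.** With X the UV-scaled whole-berry volatile
matrix and y the UV-scaled liking score (1–5 scale), a single-response
orthogonal PLS model separates one predictive component (w ∝ X′y, t = Xw,
q = y′t/t′t) from A orthogonal components that carry X-variation
uncorrelated with y ("1 + A + 0" models). The component count is chosen by
seven-fold cross-validation (Q²Y = 1 − PRESS/SS, RMSECV = √(PRESS/N));
strong outliers are screened beforehand with Hotelling's T² at the 99%
limit on PCA scores; a Y-permutation test (n = 200) guards against
overfitting (a valid model has a negative Q² intercept); and VIP scores
(mean of squares ≡ 1) with the coefficient sign select the key compounds
(VIP > 1) that drive liking up or down. Predicted cultivars are binned
(poor < 3.5 ≤ average < 4.0 ≤ good ≤ 4.5 < excellent) and grouped into
aroma combinations by the joint content of positively and negatively
liking-related key volatiles.

**Synthetic cohorts.** Because concentration tables of this kind are rarely
deposited, the package ships a seeded generator
(`grapearoma.synthetic_data`) that emulates the study structure: ~100
compounds in 8 chemical classes, log-normal concentrations with
tissue bias (esters in pulp, terpenes in skin, a C₆ background), thresholds
spanning 0.1–10⁴ μg/kg, liking as a noisy mixed-sign linear function of key
compounds, plus y-orthogonal structured variation. Every downstream stage
is tested against its known ground truth.

## Worked example

```bash
grapearoma simulate --seed 7 --out demo
grapearoma fit --samples demo/samples.csv --library demo/library.csv \
    --scores demo/scores.csv --permutations 200 --seed 7 --out demo/model.json
```

```
fitted 1 + 1 + 0: R2X=0.291 R2Y=0.965 Q2Y=0.765 RMSEE=0.113 RMSECV=0.272
```

One predictive plus one orthogonal component explain 96.5% of the liking
variance on the 20 scored cultivars; the cross-validated Q²Y of 0.765
clears the Q²Y > 0.5 adequacy criterion, and the held-out error (RMSECV
0.272) is about 5% of the sensory scale. The permutation test stored in
`model.json` reports a Q² intercept of −0.66: permuted responses cannot be
cross-validated, so the fit is not an overfitting artifact.

```bash
grapearoma predict --model demo/model.json --samples demo/samples.csv \
    --library demo/library.csv --out demo/predictions.csv
# U01: 3.97 (average)   U02: 3.38 (poor)   U03: 2.96 (poor) ...
grapearoma keys --model demo/model.json --samples demo/samples.csv \
    --library demo/library.csv --out demo/keys.csv
# 34 key compounds written to demo/keys.csv
```

The key-compound table ranks volatiles by VIP with the sign of their
regression coefficient (for this seed the 34 selected compounds include
all 26 that the generator actually wired to liking). The same stages are
available as library calls (`grapearoma.train`, `predict_liking`,
`select_key_compounds`, `assign_aroma_combinations`, `hca_clusters`,
`build_fingerprint`); see the module docstrings.

## Layout

- `src/grapearoma/compound_library.py` — compound panels, descriptor →
  series taxonomy, membership resolution
- `src/grapearoma/profiles.py` — concentration tables, ripeness screening
  (TSS ≥ 16 °Brix), pulp/skin → whole-berry blending
- `src/grapearoma/synthetic_data.py` — seeded cohort generator with ground
  truth
- `src/grapearoma/oav_series.py` — OAVs, activity cutoffs, series values,
  fingerprints
- `src/grapearoma/chemometrics.py` — UV scaling, PCA/Hotelling T², OPLS,
  cross-validation, permutation test, VIP
- `src/grapearoma/liking_pipeline.py` — end-to-end training, prediction,
  key-compound selection, quality bins, aroma combinations, HCA
- `docs/methods.md` — model assumptions, numerical conventions and known
  limitations
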