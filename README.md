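# metacontrol

Meta-analysis of **control arms from large-animal myocardial-infarction (MI)
studies**: random-effects pooling of raw-mean percentage outcomes,
uni-/multivariable meta-regression on study-design moderators with post-hoc
Wald contrasts, weighted analysis of peri- and post-procedural mortality
proportions, and prediction of expected outcomes for named experimental
designs. A synthetic study-level data generator with known ground truth makes
every stage of the pipeline testable end to end.

## Who this is for

Researchers designing or appraising large-animal MI experiments (pig, dog,
sheep) who want to know how methodological choices — species, sex, permanent
vs temporary coronary occlusion, occluded vessel, surgical approach,
co-medication, quantification method, ischemia and follow-up duration — shift
the standard endpoints: infarct size as % of the area at risk (IS/AAR),
infarct size as % of the left ventricle (IS/LV), and ejection fraction (EF),
plus expected animal mortality for power calculations.

## The model

Each control arm *i* contributes its raw mean outcome
*y<sub>i</sub>* (a percentage) with sampling variance
*v<sub>i</sub> = sd<sub>i</sub>² / n<sub>i</sub>*. The random-effects model is

> *y<sub>i</sub> = x<sub>i</sub>ᵀβ + u<sub>i</sub> + e<sub>i</sub>*,  
> *u<sub>i</sub> ~ N(0, τ²)*, *e<sub>i</sub> ~ N(0, v<sub>i</sub>)*

with the between-study variance τ² estimated by **restricted maximum
likelihood (REML)** and weights *w<sub>i</sub> = 1/(v<sub>i</sub> + τ²)*.
Inference is z-based (no Knapp–Hartung adjustment). Heterogeneity is
summarized by Cochran's Q and *I² = max(0, (Q − (k−1))/Q)*; a moderator
model's explained heterogeneity is *R² = 1 − τ²<sub>residual</sub> /
τ²<sub>null</sub>*. Categorical moderators are dummy-coded against a
reference level; moderators with more than two levels get post-hoc pairwise
Wald contrasts (unadjusted by default), and post-hoc testing is skipped
whenever the multivariable omnibus test is non-significant (p ≥ 0.05).

Mortality is analyzed as per-phase death fractions. Two sequential
measurements in the same setting combine multiplicatively on the survival
scale, *1 − p<sub>total</sub> = (1 − p₁)(1 − p₂)*, with effective sample size
*(n₁ + n₂)/2*. The classic "1/√n" weighting phrase is ambiguous, so both
readings are implemented: weight ∝ n (standard error ∝ 1/√n; the default) and
the literal weight = 1/√n. Every output records the convention used.

## Worked example

```python
from metacontrol import *

cfg = SyntheticConfig(
    seed=42,
    true_betas={"species:pig": 21.6, "follow_up_hours": -0.03},
    tau2_true=25.0,
    level_probabilities={**SyntheticConfig().level_probabilities,
                         "species": {"dog": 0.6, "pig": 0.4, "sheep": 0.0}},
    follow_up_choices=(24., 72., 168., 336., 672.),
)
ds = generate_dataset(cfg)

fit = pool_random_effects(effects_from_dataset(ds, "IS_AAR"))
spec = DesignSpec(moderators=["species", "follow_up_hours"], add_separately=[])
report = analyze_outcome(ds, "IS_AAR", spec)
```

prints (via the obvious format calls):

```
IS/AAR: 50.3% (95% CI 48.1-52.5%), tau2=189.6, I2=91%, k=165
  intercept          beta= +49.60  se=0.95
  pig (vs dog)       beta= +21.08  se=1.12
  follow_up_hours    beta=  -0.03  se=0.00
omnibus p=1.35e-111, residual tau2=31.4, R2=83%
  post hoc dog vs pig: -21.08 (p=2.22e-79)
peri-procedural mortality: 16.3% (95% CI 15.1-17.6%), k=165
Pig I/R (60 min) LAD model @ 1 week: 65.3% (95% CI 63.6-67.1%)
```

Reading this: the pooled infarct size across 165 simulated control arms is
50.3% of the area at risk with very high heterogeneity (I² = 91%), most of
which the two moderators explain (R² = 83%). The meta-regression recovers the
simulated ground truth — pigs infarct about 21 percentage points more than
dogs, and each hour of follow-up shrinks measured infarct size by 0.03
points — and the prediction module turns the fitted model into an expected
IS/AAR of ~65% for a pig 60-minute ischemia/reperfusion LAD design at one
week.

The same pipeline is available from the shell:

```bash
metacontrol simulate --seed 42 --out sim.csv
metacontrol pool sim.csv --outcome IS_AAR --forest forest.svg
metacontrol regress sim.csv --outcome IS_AAR
metacontrol mortality sim.csv --phase peri
metacontrol predict sim.csv
```

## Layout

- `src/metacontrol/data_io.py` — data model, CSV interchange (see
  `docs/column_dictionary.md`), validation, sensitivity-subset filtering
- `src/metacontrol/synthetic.py` — ground-truth synthetic data generator
- `src/metacontrol/meta_core.py` — REML τ², random-effects pooling, Q/I²,
  forest tables/plots
- `src/metacontrol/meta_regression.py` — design matrices, uni-/multivariable
  meta-regression, omnibus tests, pairwise Wald contrasts, significance gate
- `src/metacontrol/mortality.py` — sequential proportion combination, 1/√n
  weighting conventions, weighted pooling and meta-regression of death
  fractions
- `src/metacontrol/prediction.py` — scenario prediction grids, OLS
  association checks
- `docs/methods.md` — modelling assumptions, defaults and limitations
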