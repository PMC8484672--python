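# manatee-bci

Body-condition analysis for Antillean manatees (*Trichechus manatus
manatus*) from field morphometrics: robust allometric fitting of three
body condition indices (BCIs), per-individual scoring, habitat/sex/locality
inference, and allometric weight prediction — plus a synthetic-population
generator so the whole pipeline can be exercised and validated end to end.

## Who this is for

Wildlife veterinarians and sirenian researchers who capture manatees and
record straight-line total length (SL, m), umbilical girth (UG, m) and,
when logistics allow, body mass (W, kg). From such records the package
estimates population-level allometry and turns it into per-animal
condition scores that are comparable across habitats, sexes and capture
localities.

## The model

Three ratio-type indices relate the measurements, each with a power-law
exponent *b* estimated from data rather than fixed at its geometric-
similarity value:

    BCI1 = UG / SL^b1            (similarity: b1 = 1)
    BCI2 = W  / SL^b2            (similarity: b2 = 3)
    BCI3 = W  / (SL * UG^b3)     (similarity: b3 = 2)

Fitting uses the generative form (e.g. `UG = BCI1 * SL^b1`) with
M-estimation on raw-scale residuals by iteratively reweighted nonlinear
least squares (Huber weights, k = 1.345), because gross measurement
outliers are common in field data. Habitat (coastal vs riverine) and sex
enter as additive offsets on both the coefficient and the exponent:

    UG = (BCI1 + r·Riverine + m·Male) * SL^(b1 + br·Riverine + bm·Male)

Per-individual scores computed with the fitted, group-specific exponents
feed two inference tools: a high-breakdown MM-type robust linear model
`BCI = a + c·Country + h·Habitat + s·Sex + f·FieldCondition`, and
pairwise Wilcoxon rank-sum comparisons between localities with
Bonferroni adjustment. Body mass can be predicted from length and girth
by inverting the third index; the average-animal constants are
`W = 37.67 · SL · UG^1.893`.

## Worked example

```python
import manateebci as mb
from manateebci.records import filter_analysis_set, measurement_subsets

cfg = mb.default_config(seed=0)          # study-condition synthetic population
pop = mb.generate_population(cfg)
retained, report = filter_analysis_set(pop)   # drop thin/obese/late-pregnant
subsets = measurement_subsets(retained)
res = mb.fit_robust_allometry(subsets["bci1"], model="bci1",
                              factors=("habitat", "sex"))
print(res.summary())
```

prints

```
Robust allometric fit: bci1  (loss=huber, tuning=1.345)
n = 338, iterations = 14, converged = True, robust scale = 0.0987643

parameter     estimate          SE         t         p
bci1            0.7782      0.0210         -         -
r1             -0.0813      0.0312    -2.604    0.0096
m1             -0.0311      0.0267    -1.163    0.2457
b1              0.9083      0.0303     3.026    0.0027
br1             0.0147      0.0490     0.300    0.7645
bm1            -0.0613      0.0396    -1.549    0.1223

Geometric-similarity contrasts:
  1-b1 (Female, Coastal)          0.0917    0.0303     3.026    0.0027
  b1 (Coastal-Riverine)          -0.0147    0.0490    -0.300    0.7645
  b1 (Female-Male)                0.0613    0.0396     1.549    0.1223
```

Reading the output: the reference (female, coastal) girth-length level is
`bci1 = 0.778`; riverine animals sit `r1 = -0.081` lower (p = 0.0096),
i.e. proportionally slimmer girths in riverine habitat, while the sex
difference is not significant. The exponent `b1 = 0.908` is below 1
(the `1-b1` contrast has p = 0.0027): longer animals are proportionally
thinner than geometric similarity would imply. These recover the
generator's stratified truth (coastal level 0.76, riverine 0.69).

Predicting mass for an animal with SL = 2.6 m and UG = 1.9 m:

```python
>>> round(mb.estimate_weight(2.6, 1.9), 1)
330.1
```

The same steps are available from a shell via the `manatee-bci` CLI
(`simulate`, `fit`, `score`, `predict-weight`, `compare`, `run`); see
`manatee-bci --help`.

## Layout

- `manateebci.records` — CSV reading/validation, age classes, field-score
  grouping, analysis filtering with full exclusion accounting
- `manateebci.simulate` — synthetic populations and recovery experiments
- `manateebci.allometry` — `AllometricModel` / `AllometricResults`
- `manateebci.scoring` — per-individual indices, weight prediction
- `manateebci.inference` — MM robust linear model, pairwise Wilcoxon
- `manateebci.tables`, `manateebci.pipeline`, `manateebci.cli` — report
  tables, end-to-end runs with manifests, command-line interface

See `docs/methods.md` for the statistical details and design choices.
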