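# ringphys

Retrospective dendro-physiological analysis of mountain Norway spruce
(*Picea abies*) under moderate acid air pollution: a tested, reusable Python
implementation of the full chain from raw tree-ring measurements to
period-wise mixed-model contrasts.

## The problem

Sulfate and reactive-nitrogen deposition peaked in central Europe in the
1970s–1980s. In moderately polluted areas (unlike the heavily damaged "Black
Triangle") trees show no obvious growth decline, so the physiological imprint
of pollution must be read from subtler signals preserved in tree rings:

* **Carbon isotope discrimination** Δ¹³C — how strongly the canopy
  discriminated against ¹³C, an integrator of stomatal supply vs.
  photosynthetic demand for CO₂;
* **intercellular CO₂** (Ci) and **intrinsic water-use efficiency**
  (iWUE = A/g_w);
* **whole-tree biomass increment**, its inter-annual variability, and its
  correlation with monthly climate (temperature, cloud cover, precipitation,
  PDSI drought index).

Each quantity is averaged per tree over four pollution-defined periods —
before (1900–1935), during (1971–1989) and after (1998–2005, 2006–2011) the
deposition peak — and the periods are contrasted with linear mixed models.

## The models

**Isotope physiology.** Wood δ¹³C is mapped to foliage via the empirical
relation δ¹³C_foliage = 1.0523·δ¹³C_wood − 0.205, then

    Δ¹³C = (δ¹³C_air − δ¹³C_foliage) / (1 + δ¹³C_foliage/1000)
    Ci   = Ca · (Δ¹³C − a) / (b − a),   a = 4.4‰, b = 27‰
    iWUE = (Ca − Ci) · 0.625

with δ¹³C_air and Ca interpolated from an annual (ice-core-style)
atmospheric record at each segment's midpoint year.

**Biomass allometry.** Per-year over-bark diameter
D(t) = 1.096·(2·Σwidths + 2·pith offset); site-specific height polynomials,
a crown-length power law and cambial age feed five log-linear biomass
component models (needles, branches, dry branches, stem, roots); the annual
increment is the first difference of total biomass.

**Detrending.** Increment series are variance-stabilized by an adaptive
power transform x → x^p with p = 1 − m, where m is the slope of log₁₀(IQR)
on log₁₀(median) over non-overlapping 10-year segments, then a cubic
smoothing spline with a 50% frequency cutoff at 30 years is subtracted.
Inter-annual variability uses the mean-sensitivity statistic
2|xᵢ − xᵢ₋₁|/(xᵢ + xᵢ₋₁).

**Inference.** Tree × period means are modelled as
`value ~ period (+ catchment ± interaction) + (1 | tree)`, selected by ML
AIC and reported from a REML refit, with Tukey-style single-step pairwise
period comparisons, compact letter displays and Nakagawa–Schielzeth
marginal/conditional pseudo-R². A companion model regresses biomass
increment on Δ¹³C × period to test whether the growth–discrimination link
broke down during the pollution peak.

Because the original field data are not deposited, a first-class synthetic
generator reproduces the statistical structure of every input (atmosphere,
monthly climate, age-trended AR(1) ring widths with a shared growing-season
temperature signal, and isotope segments with configurable period effects),
so the whole pipeline runs and is validated end to end.

## Worked example

```python
from ringphys import (SimulationConfig, simulate_dataset, physiology_series,
                      PeriodMixedModel, period_means_segments)

data = simulate_dataset(SimulationConfig(seed=7))
physio = physiology_series(data["isotopes"], data["atmosphere"])
means = period_means_segments(physio.rename(columns={"delta13C": "value"}))
result = PeriodMixedModel(means, response_name="delta13C").fit(structure="period")
print(result.fe_params.round(3))
print("pseudo-R2 (marginal, conditional):",
      tuple(round(v, 2) for v in result.pseudo_r2()))
```

prints

```
intercept            19.723
period[pollution]    -1.810
period[post1]        -0.746
period[post2]        -0.483
dtype: float64
pseudo-R2 (marginal, conditional): (0.43, 0.88)
```

i.e. from synthetic wood-δ¹³C segments generated with a −1.876‰ pollution
effect, the pipeline recovers a ~1.8‰ transient drop in discrimination
during 1971–1989 with partial recovery afterwards, and the random tree
intercepts absorb most of the remaining variance. `result.tukey()` returns
the pairwise period contrasts with adjusted p-values and letter groupings;
`result.summary()` prints the full coefficient table.

The same analysis is available from the shell:

```sh
ringphys run-all --out results/demo --seed 7
ringphys report --response iwue --from pollution --to post2 --mode absolute
# {"response": "iwue", ..., "value": -3.8}
```

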