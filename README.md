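# flightbn

Bayesian-network prediction of hourly forest-insect flight activity from
meteorological and temporal covariates.

## The problem

Bark beetles (*Hylurgus ligniperda*, *Hylastes ater*) and the burnt-pine
longhorn (*Arhopalus ferus*) colonize freshly harvested *Pinus radiata*
logs, so knowing **when they fly** matters for phytosanitary risk
management of wood exports.  Flight is driven by interacting abiotic
factors — temperature, wind, humidity, light — and by time of day relative
to sunrise and sunset.  `flightbn` models the probability that a species is
in flight during a given hour as a probabilistic classifier over
discretized covariates, with an emphasis on the biosecurity-critical
**false negative** (Type II) error: predicting no flight when flight
occurred.

## The model

Each site-hour is a case with nine covariates (day of year, signed minutes
since sunrise/sunset, maximum hourly temperature, temperature range, mean
wind speed, relative humidity, photon flux density, rainfall) and a binary
flight target per species (trap catch ≥ 1).  The classifier is a
**tree-augmented naive Bayes (TAN)** network:

- covariates are discretized by supervised recursive entropy splitting with
  the Fayyad–Irani MDL stopping rule; variables with no accepted split are
  excluded as uninformative;
- every predictor X_i is a child of the class C, and the predictors are
  additionally joined by the maximum-weight spanning tree under the
  conditional mutual information I(X_i; X_j | C);
- conditional probability tables are learnt by EM (Dirichlet α = 1),
  which on complete data reduces to Laplace-smoothed frequencies and
  marginalizes missing covariates otherwise;
- inference is exact message passing over the predictor tree.

Model quality is assessed by five calibration indices (logarithmic loss,
quadratic/Brier loss, spherical payoff, Gini coefficient, AUC), by Type I /
Type II / total error rates at no-flight thresholds τ ∈ {0.50, 0.90, 0.95,
0.99} (predict "no flight" iff P(no flight) ≥ τ), by a modified ROC curve
of true-negative prediction rate against Type II error, and by 100 × 4-fold
cross-validation with full re-learning per training split.  Sensitivity
(mutual information, percent of class entropy, variance of beliefs) and
single-variable influence runs (tornado diagrams) rank the predictors.

Upper-bound response curves supplement the classifier: interval maxima of
catch against temperature are fitted with a Gaussian
Y = k·exp(−(T−μ)²/(2σ²)), against wind with a negative exponential
Y = y0·exp(w/b) or a gamma GAM (inverse link), with Cook's-distance
outlier screening (D > 1) and Wherry's adjusted R².

Because the original field trap data are not public, the package ships a
first-class synthetic generator that emulates the study conditions: ~7,500
site-hours over 78 days at 4 sites in three spring/summer windows,
positive-hour rates ≈ 11% / 2% / 3% by species, wind–temperature
correlation ≈ +0.27, humidity–temperature correlation ≈ −0.66, crepuscular
vs nocturnal diel activity, and rare container-carryover anomalies.

## Worked example

```python
from flightbn import (
    GeneratorConfig, generate_casefile, exclude_fault_days, flag_anomalies,
    FlightActivityModel,
)

cf = generate_casefile(GeneratorConfig(), seed=1)
cf = exclude_fault_days(cf)          # drop whole site-days with trap faults
cf, report = flag_anomalies(cf)      # zero implausible catches in the modelling view
print(f"{len(cf)} modelling hours; {len(report)} anomalous catches flagged")

results = FlightActivityModel(cf, "hylurgus").fit()
print(results.summary())
```

Output:

```
7128 modelling hours; 7 anomalous catches flagged
Flight-activity Bayesian network: hylurgus
======================================================
Cases: 7128   positive hours: 787 (11.0%)
Structure: 7 predictors, 6 tree edges (8 nodes, 13 linkages, 372 probabilities)

Calibration scores
------------------------------------------------------
  logarithmic_loss        0.257
  quadratic_loss          0.157
  spherical_payoff        0.913
  gini                    0.715
  auc                     0.858

Errors by no-flight threshold (%)
------------------------------------------------------
    tau   Type I  Type II    Total
   0.50      1.4     85.5     10.7
   0.90     27.0     14.6     25.6
   0.95     37.7      7.4     34.4
   0.99     58.7      2.4     52.5

Sensitivity (variance of beliefs, descending)
------------------------------------------------------
  t_sunset_min     MI=0.07451 bits   14.9%  VB=0.010860
  t_sunrise_min    MI=0.06549 bits   13.1%  VB=0.008230
  max_temp_c       MI=0.04135 bits    8.2%  VB=0.004797
  par_umol         MI=0.02937 bits    5.9%  VB=0.004465
  wind_ms          MI=0.01024 bits    2.0%  VB=0.001078
  day_of_year      MI=0.00598 bits    1.2%  VB=0.000844
  rh_pct           MI=0.00323 bits    0.6%  VB=0.000387
```

Reading the table: at τ = 0.50 the model rarely cries wolf (Type I 1.4%)
but misses most flight hours (Type II 85.5%); raising the threshold to
τ = 0.99 cuts Type II to 2.4% at the cost of predicting flight for more
than half of the quiet hours — the trade-off that drives threshold choice
in a biosecurity setting.  Times relative to sunset/sunrise and maximum
hourly temperature carry most of the predictive information for this
crepuscular species.

`results.crossval(k=4, iterations=100, seed=0)` produces the per-threshold
mean/SD/min/max error envelopes and the SD-distance diagnostic between the
calibration and cross-validated curves.  The same analysis is scriptable
end-to-end:

```sh
flightbn all --out runs/demo --seed 1
flightbn simulate --seed 1 --out cases.csv
flightbn learn cases.csv --species arhopalus --out model.json
```

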