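# itsmeta

Bayesian interrupted-time-series (ITS) hierarchical meta-regression for
aggregated school-level test scores.

When a community-wide event — a mine fire, a flood, an epidemic — disrupts
schooling, its effect on educational attainment is hard to measure:
individual student records are slow and costly to obtain after a disaster.
Publicly released *aggregated* school results (a mean score and its standard
error per school, grade, year and testing domain) are enough, if they are
modelled properly: each school mean is an estimate with known sampling
variance, so the analysis is a meta-regression, weighting each cell by its
precision, rather than an ordinary regression on means. This package
implements that estimator for epidemiologists and education researchers,
together with a synthetic-study generator with known ground truth so the
whole chain is testable without any restricted data.

## Model

Scores are first *centred*: each school-cell mean has the regional average
for the same year, grade and domain subtracted, making grades and domains
comparable without standardizing away real progression. The centred mean
`y_sgc` of school *s*, grade *g*, cohort *c* (a cohort is the set of
students progressing together, e.g. Grade 3 in 2014 → Grade 5 in 2016) is
modelled as

    y_sgc ~ Normal( X_sg β + θ_sc + θ_s ,  τ_sgc² + σ_e² )

where `τ_sgc` is the known standard error of the cell mean, `θ_s ~ N(0, σ_s²)`
and `θ_sc ~ N(0, σ_sc²)` are school and cohort-within-school random
intercepts, and a per-cell residual with variance `σ_e²` is marginalized
into the observation variance. The fixed effects `X_sg β` contain the
confounders (ICSEA socio-educational index, enrolments, proportion of
girls, sector, grade level) and the seven ITS terms

    β_t·T + β_m,pre·E_m + β_m,int·E_m·I_post + β_m,trend·E_m·I_post·T_post
          + β_h,pre·E_h + β_h,int·E_h·I_post + β_h,trend·E_h·I_post·T_post

with `T` counting years from the study start, `I_post` switching on in the
event year, `T_post` counting years since the event, and `E_m`, `E_h`
indicating moderate and high exposure against a no/low-exposure control
group. `β_·,int` is the immediate level shift at the event (the
*interruption effect*), `β_·,trend` the change in annual slope afterwards.

Priors are weakly informative — `N(0, 50²)` on each fixed effect,
`TN(10, 5²)` on `(0, ∞)` for each SD — and inference is by MCMC: blocked
Gibbs with exact Gaussian conditionals for `β` and the random intercepts,
collapsed slice-sampling updates for the three SDs, and interweaving moves
that decorrelate school-level fixed effects from the school intercepts.
Fits report posterior means, 95% credible intervals, `P(β<0)`/`P(β>0)`,
split R-hat and effective sample sizes.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (69 schools split 34/28/7 across no/low, moderate and high exposure;
years 2008–2018; event in 2014; generating truth: −10-point high-exposure
interruption, +2 points/year recovery, 5-point school/cohort/residual SDs):

```bash
python analysis/01_simulate_study.py      # writes results/study/
python analysis/02_validate_and_centre.py # writes results/centred.csv
python analysis/03_fit_models.py          # one fit per testing domain
python analysis/04_sensitivity.py         # prior/cohort/exclusion variants
python analysis/05_parameter_recovery.py  # replicate recovery study
```

`03_fit_models.py` prints, per domain, the high-exposure interruption
estimate and its months-of-learning equivalent (scores grow ~27 points per
school year, so −10 points ≈ 4.4 months):

```
grammar    high interruption  -9.65 [-14.17, -5.15]  P(b<0)=1.000  ~4.3 months of learning  (max R-hat 1.003)
numeracy   high interruption -10.40 [-14.91, -5.70]  P(b<0)=1.000  ~4.6 months of learning  (max R-hat 1.006)
reading    high interruption  -8.64 [-13.13, -4.14]  P(b<0)=1.000  ~3.8 months of learning  (max R-hat 1.003)
spelling   high interruption  -8.48 [-13.18, -3.89]  P(b<0)=1.000  ~3.8 months of learning  (max R-hat 1.010)
writing    high interruption -13.03 [-17.61, -8.56]  P(b<0)=1.000  ~5.8 months of learning  (max R-hat 1.004)
```

Every domain recovers the −10-point generating truth within its credible
interval, and the posterior leaves essentially no mass above zero. The
library surface behind these scripts:

```python
from itsmeta import (SimulationConfig, generate_study, center_scores,
                     build_design, fit_model, summarize, predicted_margins)

obs, profiles, reference, truth = generate_study(SimulationConfig(seed=1))
centred = center_scores(obs, reference)
design = build_design(centred, profiles, domain="reading", event_year=2014)
fit = fit_model(design)                     # 4 chains x 2000 iterations
table = summarize(fit)                      # Table-style coefficient summary
margins = predicted_margins(fit, range(2008, 2019))
```

`run_pipeline(RunConfig(...))` chains all stages per domain and writes
coefficient tables, margins, diagnostics, trend plots and a hash manifest.

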