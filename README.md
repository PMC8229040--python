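# isosub

Isotemporal and compositional isotemporal substitution modelling of daily
sitting, standing and stepping time against cardiometabolic outcomes.

## The problem

Waking time is finite: a day splits exhaustively into sitting, standing and
stepping, so "more stepping" necessarily means "less of something else".
Epidemiologists estimate the health consequence of *reallocating* time
between behaviours with two competing regression strategies, and this
package implements both so they can be compared on the same data:

* **ISM (isotemporal substitution model).** Ordinary least squares of a
  standardised outcome on waking wear hours, standing hours and stepping
  hours (sitting omitted), plus covariates. With total time held fixed, the
  standing/stepping coefficient β is the effect of substituting one hour of
  sitting with that behaviour. Estimates for *t* minutes are `β·t/60` —
  exactly linear in *t* and exactly antisymmetric under reversing the swap.

* **CISM (compositional isotemporal substitution model).** The behaviour
  composition **x** = (sit, stand, step) carries only relative information,
  so it is mapped to isometric log-ratio (ILR) coordinates
  `z = V·ln(x)` (V an orthonormal log-contrast matrix from a sequential
  binary partition) and the outcome regressed on `z` plus covariates. A
  reallocation effect is the predicted difference
  `γ·[ilr(x*) − ilr(x₀)]` between a perturbed composition **x\*** and the
  cohort mean composition **x₀**, with a delta-method 95% CI. Estimates are
  non-linear in *t*, asymmetric between directions, and invariant to the
  choice of ILR basis.

The package is for biostatisticians and physical-behaviour researchers who
want the two methods behind one interface, together with the supporting
pipeline: wear-day quality control for thigh-worn monitor data, outcome
standardisation, clustered cardiometabolic risk scores (CCRS), and a
synthetic cohort generator whose known ground truth lets every estimator be
validated end to end.

## Worked example

```python
from isosub import (AnalysisConfig, default_params, generate_cohort,
                    run_full_analysis, run_incremental_grid,
                    symmetry_linearity_report)

cohort = generate_cohort(default_params(seed=1))   # n=1524 synthetic participants
est = run_full_analysis(cohort, AnalysisConfig(outcomes=("bmi", "triglycerides")))
print(est[["method", "outcome", "from", "to", "minutes",
           "estimate", "ci_low", "ci_high", "significant"]].round(3))
```

```
method       outcome from    to  minutes  estimate  ci_low  ci_high  significant
   ISM           bmi  sit stand     60.0    -0.284  -0.312   -0.255         True
  CISM           bmi  sit stand     60.0    -0.262  -0.288   -0.237         True
   ISM           bmi  sit  step     60.0    -0.245  -0.314   -0.177         True
  CISM           bmi  sit  step     60.0    -0.216  -0.273   -0.159         True
   ISM triglycerides  sit stand     60.0    -0.110  -0.142   -0.078         True
  CISM triglycerides  sit stand     60.0    -0.101  -0.130   -0.072         True
   ISM triglycerides  sit  step     60.0    -0.144  -0.222   -0.067         True
  CISM triglycerides  sit  step     60.0    -0.131  -0.196   -0.066         True
```

Each row is the estimated change, in standard deviations of the outcome,
from moving 60 min/day out of sitting: e.g. reallocating an hour of sitting
to stepping is associated with a BMI 0.25 SD lower under ISM and 0.22 SD
lower under CISM — same direction, similar magnitude, both significant at
α = 0.05. The methods diverge in *shape*, which the 5–60-minute grid
quantifies:

```python
grid = run_incremental_grid(cohort, AnalysisConfig(), "bmi")
print(symmetry_linearity_report(grid).round(4))
```

```
method  symmetry_defect  linearity_defect
  CISM           0.0817            0.0200
   ISM           0.0000            0.0000
```

ISM's defects are zero by algebra; CISM's mirror-symmetry defect (the gap
between sit→step and step→sit magnitudes) and its departure from linear
scaling in *t* are real consequences of the simplex geometry.

## Command line

```bash
isosub simulate --seed 1 --out participants.csv --days-out days.csv
isosub qc --days days.csv --out screened.csv --exclusions excluded.csv
isosub analyze --input participants.csv --out estimates.csv
isosub curve --input participants.csv --outcome bmi --out grid.csv
isosub report --grid grid.csv
```

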