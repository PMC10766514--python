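# dagoat

Dynamic moving-window risk scoring for severe acute graft-versus-host
disease (aGVHD) after allogeneic hematopoietic stem cell transplantation
(allo-HSCT), from irregular multidimensional clinical time series.

## The problem

After allo-HSCT, patients are monitored through a mix of near-daily vital
signs and sporadic labs, immune-cell profiles and inflammatory markers.
Severe (grade III–IV) aGVHD strikes a minority of patients, mostly in the
first post-transplant month, and early warning would allow pre-emptive
immunosuppression. The data are "spotty": most feature–day cells are
missing, and a value's clinical meaning shifts as immune reconstitution
progresses. This package implements a probabilistic model built for exactly
that regime, plus the benchmarking, evaluation and synthetic-data machinery
needed to study it.

## The model

For patient *i* with static peri-transplantation covariates **z**ᵢ and
dynamic features *x*ᵢₖ(τ) (availability indicator *I*ᵢₖτ), the daily risk
score for onset within the next δ days (default δ = 14) is

φᵢ(t) = ρ(**z**ᵢ) + Σ_{τ ∈ [t−δ+1, t]} Σₖ *I*ᵢₖτ · θₖ(xᵢₖ(τ), τ)

- ρ(**z**) is the log-odds of a categorical Naive Bayes fit on the static
  covariates.
- Each dynamic feature is discretized into low / middle / high bins via
  thresholds (lₖ, uₖ): per-day cutoffs maximizing the mutual information
  between the binarized feature and the moving-window outcome are pooled
  across days, and lₖ, uₖ are their 25th/75th percentiles.
- Per-day class-conditional bin probabilities ρ⁽ᴸ⁾/ρ⁽ᴴ⁾ (given onset /
  no onset in (t, t+δ]) are smoothed along time with a GCV-selected cubic
  smoothing spline; θₖ(x, t) is the log-ratio of the γ-floored (γ = 0.1),
  zero-clamped smoothed probabilities of the bin containing *x*.
- Missing cells contribute exactly zero — no raw-value imputation beyond an
  optional 3-day sample-and-hold at the data layer.

Fitting is deterministic. The estimator follows scikit-learn conventions
(`DaGOAT(delta=14, gamma=0.1, smoothing=True, horizon=100)`, `.fit`,
fitted attributes with trailing underscores), but consumes a
`CohortDataset` — a patient × feature × day panel with mask, a peri table
and an outcome table — rather than a flat matrix.

## Worked example

```python
import numpy as np
from dagoat import DaGOAT, ModelConfig
from dagoat.simulation import generate_clinical_fixture
from dagoat.evaluation import daily_metrics, pooled_cv_trajectories, temporal_cv

cohort, truth = generate_clinical_fixture(n_patients=500, seed=1)
cfg = ModelConfig()                      # delta=14, gamma=0.1, horizon=100
traj = pooled_cv_trajectories(cohort, cfg, temporal_cv(cohort, 5))
dm = daily_metrics(traj, cohort, cfg)
rich = dm[dm.day.between(8, 40)]
best = rich.loc[rich.auroc.idxmax()]
print(f"peak daily AUROC {best.auroc:.3f} on day {int(best.day)} "
      f"({int(best.n_positive)} onsets in window, {int(best.n_at_risk)} at risk)")
```

Output:

```
peak daily AUROC 0.709 on day 40 (6 onsets in window, 358 at risk)
```

The synthetic cohort has 500 patients, one strong and two weaker effector
labs among 8 dynamic features, ~14% cumulative incidence with onset
concentrated in weeks 3–5, and irregular feature-specific sampling. The
number printed is the pooled out-of-fold discrimination between patients who
do and do not start aGVHD treatment within the next 14 days, at the best day
in the onset-rich window — i.e., honest internal validation, not resubstitution.

A command-line interface mirrors the library:

```bash
dagoat fixture --out-prefix demo --n 200 --seed 1
dagoat fit   --measurements demo_measurements.csv --peri demo_peri.csv \
             --outcomes demo_outcomes.csv --out model.json
dagoat score --model model.json --measurements demo_measurements.csv \
             --peri demo_peri.csv --outcomes demo_outcomes.csv --out traj.csv
dagoat simulate --out grid.csv --reps 5 --seed 1   # 2x2x2 scenario grid
```

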