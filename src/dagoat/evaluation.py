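"""Time-varying discrimination metrics and model-inspection experiments.

Daily AUROC / AUPRC over the moving-window labels, percentile-bootstrap
confidence intervals, top-sextile hazard ratios, leave-one-feature-out
importance timelines, expanding-window temporal cross-validation, the
2x2 chi-square comparison, smoothing ablation and top-N feature-subset
curves.  Metrics are undefined (NaN) wherever only one outcome class is
present — no convention is silently substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .io import CohortDataset
from .model import DaGOAT, ModelConfig, RiskTrajectory, _window_labels_all

INCALCULABLE = "incalculable"


def auroc(scores, labels) -> float:
    """Area under the ROC curve with midrank tie handling; NaN if one class."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        return np.nan
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Average precision (step-interpolated PR area); NaN if one class."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        return np.nan
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def bootstrap_ci(metric, scores, labels, B: int = 1000, level: float = 0.95,
                 seed: int = 0):
    """Percentile bootstrap CI over patients; single-class resamples skipped."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(B):
        idx = rng.integers(0, y.size, y.size)
        v = metric(scores[idx], y[idx])
        if np.isfinite(v):
            vals.append(v)
    if not vals:
        return (np.nan, np.nan)
    alpha = (1 - level) / 2
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def daily_metrics(trajectory: RiskTrajectory, cohort: CohortDataset,
                  config: ModelConfig, with_ci: bool = False, B: int = 1000,
                  seed: int = 0) -> pd.DataFrame:
    """Per-day AUROC / AUPRC over risk-set patients with moving-window labels."""
    at_risk, ywin = _window_labels_all(cohort, config.delta, config.horizon)
    rows = []
    for d in range(config.horizon):
        sel = at_risk[:, d] & trajectory.valid[:, d]
        s, y = trajectory.scores[sel, d], ywin[sel, d]
        row = {
            "day": d + 1,
            "n_at_risk": int(sel.sum()),
            "n_positive": int(y.sum()),
            "auroc": auroc(s, y),
            "auprc": auprc(s, y),
        }
        if with_ci and np.isfinite(row["auroc"]):
            row["auroc_lo"], row["auroc_hi"] = bootstrap_ci(auroc, s, y, B, seed=seed)
            row["auprc_lo"], row["auprc_hi"] = bootstrap_ci(auprc, s, y, B, seed=seed)
        rows.append(row)
    return pd.DataFrame(rows)


def sextile_hazard_ratio(scores, cohort: CohortDataset, t: int,
                         config: ModelConfig):
    """Hazard ratio: top-1/6 vs bottom-5/6 risk groups over (t, t+delta].

    Proportional-hazards comparison of onset within the window, censoring at
    window end or loss to follow-up.  Returns (hr, (lo, hi)) or the string
    ``"incalculable"`` when a group has zero events or the fit fails.
    """
    from .model import window_labels

    at_risk, _ = window_labels(cohort, t, config.delta, config.horizon)
    idx = np.nonzero(at_risk)[0]
    if idx.size < 6:
        return INCALCULABLE
    s = np.asarray(scores, dtype=float)[idx]
    thr = np.quantile(s, 5 / 6)
    high = s > thr  # ties at the threshold stay low-risk
    onset = cohort.onset_array()[idx]
    last = cohort.last_observed_array()[idx]
    end = np.minimum(np.minimum(onset, last), t + config.delta)
    event = (onset >= t + 1) & (onset <= np.minimum(t + config.delta, last))
    duration = np.maximum(end - t, 0.5)
    if event[high].sum() == 0 or event[~high].sum() == 0:
        return INCALCULABLE
    try:
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"duration": duration, "event": event.astype(int),
                           "high": high.astype(int)})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="duration", event_col="event")
        hr = float(np.exp(cph.params_["high"]))
        ci = cph.confidence_intervals_
        lo = float(np.exp(ci.loc["high"].iloc[0]))
        hi = float(np.exp(ci.loc["high"].iloc[1]))
        return hr, (lo, hi)
    except Exception:
        return INCALCULABLE


@dataclass
class ImportanceTimeline:
    """(feature x day) leave-one-out importance plus summaries."""

    scores: np.ndarray
    feature_names: list
    density: np.ndarray | None = None

    def max_over(self, day_lo: int = 8, day_hi: int = 30) -> pd.Series:
        window = self.scores[:, day_lo - 1 : day_hi]
        with np.errstate(all="ignore"):
            m = np.nanmax(window, axis=1)
        return pd.Series(m, index=self.feature_names)


def temporal_cv(cohort: CohortDataset, n_folds: int = 5):
    """Expanding-window splits over patients in temporal (index) order.

    The cohort is partitioned into ``n_folds`` consecutive blocks; fold j
    trains on blocks 1..j and validates on block j+1, so validation blocks
    partition everything after the seed block.
    """
    n = cohort.n_patients
    if n < n_folds:
        raise ValueError("fewer patients than folds")
    blocks = np.array_split(np.arange(n), n_folds)
    folds = []
    for j in range(1, n_folds):
        train = np.concatenate(blocks[:j])
        folds.append((train, blocks[j]))
    return folds


def pooled_cv_trajectories(cohort: CohortDataset, config: ModelConfig,
                           cv_plan=None, feature_subset=None) -> RiskTrajectory:
    """Pooled out-of-fold risk trajectories for internal validation.

    Each validation block is scored by a model fit on the preceding blocks;
    the seed block (never validated) gets invalid flags everywhere.
    """
    if cv_plan is None:
        cv_plan = temporal_cv(cohort)
    work = cohort if feature_subset is None else cohort.select_features(feature_subset)
    n, H = work.n_patients, config.horizon
    scores = np.full((n, H), np.nan)
    valid = np.zeros((n, H), dtype=bool)
    for train_idx, val_idx in cv_plan:
        model = DaGOAT(config.delta, config.gamma, config.smoothing, config.horizon)
        model.fit(work.subset_patients(train_idx))
        traj = model.predict_trajectories(work.subset_patients(val_idx))
        scores[val_idx] = traj.scores
        valid[val_idx] = traj.valid
    scores[~valid] = 0.0
    return RiskTrajectory(scores, valid, list(work.panel.patients))


def feature_importance(cohort: CohortDataset, config: ModelConfig,
                       cv_plan=None, day_range=(1, 30)) -> ImportanceTimeline:
    """Leave-one-feature-out AUPRC decrement, per feature and day.

    importance_k(t) = AUPRC_full(t) - AUPRC_without_k(t), computed on pooled
    out-of-fold internal-validation scores with feature k removed from both
    fitting and scoring.
    """
    if cv_plan is None:
        cv_plan = temporal_cv(cohort)
    names = list(cohort.panel.feature_names)
    full = daily_metrics(
        pooled_cv_trajectories(cohort, config, cv_plan), cohort, config
    )["auprc"].to_numpy()
    imp = np.full((len(names), config.horizon), np.nan)
    for k, name in enumerate(names):
        rest = [n for n in names if n != name]
        wo = daily_metrics(
            pooled_cv_trajectories(cohort, config, cv_plan, feature_subset=rest),
            cohort, config,
        )["auprc"].to_numpy()
        imp[k] = full - wo
    density = data_density(cohort.panel, day_range).to_numpy()
    return ImportanceTimeline(imp, names, density)


def rank_features(importance: ImportanceTimeline, day_lo: int = 8,
                  day_hi: int = 30) -> list:
    """Features by descending max importance over the day range; ties by name."""
    m = importance.max_over(day_lo, day_hi)
    key = m.fillna(-np.inf)
    order = sorted(importance.feature_names, key=lambda n: (-key[n], n))
    return order


def data_density(panel, day_range=(1, 30)) -> pd.Series:
    """Per-feature fraction of available (patient, day) cells in the range."""
    lo, hi = day_range
    m = panel.mask[:, :, lo - 1 : hi]
    denom = panel.n_patients * (hi - lo + 1)
    return pd.Series(m.sum(axis=(0, 2)) / denom, index=panel.feature_names)


def two_by_two_chisq(a: int, b: int, c: int, d: int, continuity: bool = True):
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]].

    The continuity correction moves each observed count 0.5 toward its
    expected value (never past it); p comes from the chi2(1) tail.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    res = stats.chi2_contingency(table, correction=continuity)
    return float(res[0]), float(res[1])


def ablation_run(cohort: CohortDataset, config: ModelConfig, cv_plan=None):
    """Paired daily metrics with the smoothing component on vs off."""
    out = {}
    for flag in (True, False):
        cfg = ModelConfig(config.delta, config.gamma, flag, config.horizon)
        traj = pooled_cv_trajectories(cohort, cfg, cv_plan)
        out["smoothing" if flag else "no_smoothing"] = daily_metrics(traj, cohort, cfg)
    return out


def subset_curve(cohort: CohortDataset, config: ModelConfig, ranked: list,
                 fractions=(0.2, 0.4, 0.6, 0.8, 1.0), cv_plan=None) -> pd.DataFrame:
    """Daily metrics using only the top-N ranked features, per fraction.

    fraction 0 gives the prior-only model (no dynamic features).
    """
    rows = []
    for frac in fractions:
        n_top = int(round(frac * len(ranked)))
        subset = ranked[:n_top]
        if n_top == 0:
            cfg = config
            work = cohort.select_features([])
            traj = pooled_cv_trajectories(work, cfg, cv_plan)
            dm = daily_metrics(traj, work, cfg)
        else:
            dm = daily_metrics(
                pooled_cv_trajectories(cohort, config, cv_plan, feature_subset=subset),
                cohort, config,
            )
        dm = dm.assign(fraction=frac, n_features=n_top)
        rows.append(dm)
    return pd.concat(rows, ignore_index=True)
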