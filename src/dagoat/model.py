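"""Dynamic moving-window risk model for severe acute GVHD onset.

The model produces, for every patient i and post-transplant day t, a relative
risk score for event onset within the next ``delta`` days::

    phi_i(t) = rho(z_i) + sum_{tau in [t-delta+1, t]} sum_k I_{ik,tau} *
               theta_k(x_ik(tau), tau)

``rho(z)`` is the Naive Bayes log-odds of the static peri-transplantation
covariates; ``theta_k(x, t)`` is the time-varying log relative-risk
contribution of dynamic feature k, obtained by discretizing the feature into
low / middle / high bins via mutual-information-optimal cutoffs and comparing
the smoothed class-conditional bin probabilities.  Missing cells (I = 0)
contribute exactly zero: absence of data is treated as absence of evidence,
never imputed on the raw-value scale.

Fitting is fully deterministic given the cohort and configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator

from .io import CohortDataset, DynamicPanel
from .baselines import NBParams, fit_nb, nb_log_odds_batch

# bins of the discretized dynamic feature
LOW, MID, HIGH = 0, 1, 2

# GCV smoothing splines need at least this many knots; sparser probability
# curves fall back to a constant extension of their mean
MIN_SPLINE_POINTS = 5


@dataclass
class ModelConfig:
    """Hyperparameters of the risk model.

    delta : length of the moving prediction window, days (default 14)
    gamma : additive floor on bin probabilities inside the log-ratio;
        larger gamma shrinks all contributions toward zero (default 0.1)
    smoothing : smooth the per-day bin probabilities along time with a
        GCV-selected cubic smoothing spline (default True)
    horizon : last post-transplant day modeled (default 100)
    """

    delta: int = 14
    gamma: float = 0.1
    smoothing: bool = True
    horizon: int = 100

    def __post_init__(self):
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class DynamicFeatureParams:
    """Fitted per-feature parameters.

    ``raw_probs`` / ``smooth_probs`` are (4, horizon) arrays ordered as
    (rho1_low, rho1_high, rho0_low, rho0_high); undefined entries are NaN.
    ``informative`` is False when no day produced a defined cutoff, in which
    case the feature contributes zero everywhere.
    """

    l: float
    u: float
    per_day_cutoffs: np.ndarray
    raw_probs: np.ndarray
    smooth_probs: np.ndarray | None
    informative: bool = True


@dataclass
class RiskTrajectory:
    """phi_i(t) for each patient over days 1..horizon plus risk-set flags."""

    scores: np.ndarray  # (n_patients, horizon)
    valid: np.ndarray   # (n_patients, horizon) bool
    patients: list
    days: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.days is None:
            self.days = np.arange(1, self.scores.shape[1] + 1)


def window_labels(cohort: CohortDataset, t: int, delta: int, horizon: int | None = None):
    """Risk set and moving-window outcome at day ``t``.

    A patient is at risk at t iff onset has not yet occurred (onset absent or
    > t) and the patient is still observed (last_observed_day >= t).  The
    binary label is onset within [t+1, min(t+delta, horizon)].
    """
    onset = cohort.onset_array()
    last = cohort.last_observed_array()
    if horizon is None:
        horizon = cohort.panel.horizon
    at_risk = (onset > t) & (last >= t)
    hi = min(t + delta, horizon)
    y = (onset >= t + 1) & (onset <= hi)
    return at_risk, y & at_risk


def _window_labels_all(cohort: CohortDataset, delta: int, horizon: int):
    """Vectorized window_labels for t = 1..horizon -> (n, horizon) arrays."""
    onset = cohort.onset_array()[:, None]
    last = cohort.last_observed_array()[:, None]
    t = np.arange(1, horizon + 1)[None, :]
    at_risk = (onset > t) & (last >= t)
    hi = np.minimum(t + delta, horizon)
    y = (onset >= t + 1) & (onset <= hi) & at_risk
    return at_risk, y


def _binary_mi(n11, n10, n01, n00):
    """Mutual information (nats) of a 2x2 contingency table, vectorized.

    Arguments are cell counts; each may be an array of candidate splits.
    """
    n = n11 + n10 + n01 + n00
    out = np.zeros(np.broadcast(n11, n00).shape, dtype=float)
    for a, row, col in (
        (n11, n11 + n10, n11 + n01),
        (n10, n11 + n10, n10 + n00),
        (n01, n01 + n00, n11 + n01),
        (n00, n01 + n00, n10 + n00),
    ):
        nz = a > 0
        out += np.where(nz, a * np.log(np.where(nz, a * n / np.maximum(row * col, 1), 1.0)), 0.0)
    return out / n


def best_cutoff(values, labels):
    """Cutoff maximizing mutual information between 1{x > c} and the label.

    Candidates are midpoints between consecutive sorted distinct values; ties
    go to the smallest candidate.  Returns NaN when the labels are
    single-class or there are fewer than two distinct values.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.size == 0 or y.all() or not y.any():
        return np.nan
    order = np.argsort(v, kind="stable")
    v, y = v[order], y[order]
    boundary = np.nonzero(np.diff(v) > 0)[0]
    if boundary.size == 0:
        return np.nan
    cand = (v[boundary] + v[boundary + 1]) / 2.0
    cum1 = np.cumsum(y)[boundary].astype(float)   # positives with x < c
    n_le = (boundary + 1).astype(float)           # all with x < c
    n1 = float(y.sum())
    n = float(v.size)
    mi = _binary_mi(n1 - cum1, n - n1 - (n_le - cum1), cum1, n_le - cum1)
    # ties (exact up to float noise) go to the smallest candidate
    top = mi.max()
    idx = int(np.nonzero(mi >= top - 1e-12 * max(1.0, abs(top)))[0][0])
    return float(cand[idx])


def fit_thresholds(cutoffs):
    """(l, u) = 25th / 75th percentile of the defined per-day cutoffs.

    Linear-interpolation percentile convention.  Returns (nan, nan) when no
    day has a defined cutoff (the feature is then uninformative).
    """
    c = np.asarray(cutoffs, dtype=float)
    c = c[np.isfinite(c)]
    if c.size == 0:
        return np.nan, np.nan
    l, u = np.percentile(c, [25, 75])
    return float(l), float(u)


def fit_bin_probs(values, mask, at_risk, y, l, u):
    """Raw per-day class-conditional bin probabilities for one feature.

    values, mask : (n_patients, horizon) for the feature; at_risk, y likewise.
    Returns a (4, horizon) array (rho1_low, rho1_high, rho0_low, rho0_high);
    a day with no observed patient of a class leaves that class's entries NaN.
    """
    horizon = values.shape[1]
    out = np.full((4, horizon), np.nan)
    obs = mask & at_risk
    below = obs & (values < l)
    above = obs & (values > u)
    for cls, (lo_row, hi_row) in ((1, (0, 1)), (0, (2, 3))):
        in_cls = y if cls == 1 else (at_risk & ~y)
        denom = (obs & in_cls).sum(axis=0).astype(float)
        ok = denom > 0
        out[lo_row, ok] = (below & in_cls).sum(axis=0)[ok] / denom[ok]
        out[hi_row, ok] = (above & in_cls).sum(axis=0)[ok] / denom[ok]
    return out


def smooth_probs(raw, horizon=None):
    """Smooth a per-day probability series along time.

    A GCV-selected cubic smoothing spline is fit over the days where ``raw``
    is defined and evaluated at every integer day 1..horizon (extrapolating
    beyond the defined range); output may stray outside [0, 1] — clamping is
    the contribution function's job.  With fewer than ``MIN_SPLINE_POINTS``
    defined days the series is extended as the constant mean of the defined
    values; with none, all-NaN is returned.
    """
    raw = np.asarray(raw, dtype=float)
    if horizon is None:
        horizon = raw.shape[-1]
    days = np.arange(1, raw.shape[-1] + 1, dtype=float)
    ok = np.isfinite(raw)
    grid = np.arange(1, horizon + 1, dtype=float)
    if ok.sum() == 0:
        return np.full(horizon, np.nan)
    if ok.sum() < MIN_SPLINE_POINTS:
        return np.full(horizon, float(raw[ok].mean()))
    yv = raw[ok]
    if np.ptp(yv) == 0:  # constant series: spline is exact, skip GCV
        return np.full(horizon, float(yv[0]))
    spl = make_smoothing_spline(days[ok], yv)
    return np.asarray(spl(grid), dtype=float)


def _theta_bins(p1_low, p1_high, p0_low, p0_high, gamma):
    """theta for the three bins at one day given the four curve values.

    Any NaN among the values a bin needs yields zero for that bin (no
    information, no contribution).
    """

    def ratio(a, b):
        if not (np.isfinite(a) and np.isfinite(b)):
            return 0.0
        return float(np.log((max(0.0, a) + gamma) / (max(0.0, b) + gamma)))

    th = np.zeros(3)
    th[LOW] = ratio(p1_low, p0_low)
    th[HIGH] = ratio(p1_high, p0_high)
    if all(np.isfinite(v) for v in (p1_low, p1_high, p0_low, p0_high)):
        th[MID] = float(
            np.log(
                (max(0.0, 1.0 - p1_low - p1_high) + gamma)
                / (max(0.0, 1.0 - p0_low - p0_high) + gamma)
            )
        )
    return th


def theta(x, t, params: DynamicFeatureParams, gamma: float, smoothing: bool = True):
    """Contribution of one feature value on day ``t`` (1-based)."""
    if not params.informative:
        return 0.0
    probs = params.smooth_probs if smoothing else params.raw_probs
    p1l, p1h, p0l, p0h = probs[:, t - 1]
    th = _theta_bins(p1l, p1h, p0l, p0h, gamma)
    if x < params.l:
        return float(th[LOW])
    if x > params.u:
        return float(th[HIGH])
    return float(th[MID])


def theta_table(params: DynamicFeatureParams, gamma: float, smoothing: bool, horizon: int):
    """(horizon, 3) table of bin contributions for fast batch scoring."""
    tab = np.zeros((horizon, 3))
    if not params.informative:
        return tab
    probs = params.smooth_probs if smoothing else params.raw_probs
    for d in range(horizon):
        tab[d] = _theta_bins(*probs[:, d], gamma)
    return tab


class DaGOAT(BaseEstimator):
    """Daily-updated moving-window risk score for severe acute GVHD onset.

    Estimator-style interface: hyperparameters in ``__init__``, fitted state
    in trailing-underscore attributes.  ``fit`` consumes a
    :class:`~dagoat.io.CohortDataset` (the input is intrinsically a 3-way
    patient x feature x day panel plus static covariates and outcomes).

    Parameters
    ----------
    delta : moving-window length in days.
    gamma : probability floor inside the log-ratio contributions.
    smoothing : smooth per-day bin probabilities along time.
    horizon : last modeled day.
    nb_pseudocount : additive smoothing for the peri-covariate Naive Bayes
        prior.

    Attributes
    ----------
    feature_names_ : dynamic features seen during fit.
    features_ : dict of per-feature :class:`DynamicFeatureParams`.
    peri_prior_ : fitted :class:`~dagoat.baselines.NBParams`, or None when the
        cohort carries no peri covariates (the prior then reduces to the
        class-prior log-odds).
    class_prior_log_odds_ : log(n1 / n0) of the static outcome.
    theta_table_ : (n_features, horizon, 3) contribution lookup.
    """

    def __init__(self, delta=14, gamma=0.1, smoothing=True, horizon=100,
                 nb_pseudocount=1.0):
        self.delta = delta
        self.gamma = gamma
        self.smoothing = smoothing
        self.horizon = horizon
        self.nb_pseudocount = nb_pseudocount

    # -- fitting ------------------------------------------------------------

    def fit(self, cohort: CohortDataset, y=None):
        cfg = ModelConfig(self.delta, self.gamma, self.smoothing, self.horizon)
        onset = cohort.onset_array()
        static_y = onset <= cfg.horizon
        n1 = int(static_y.sum())
        n0 = int((~static_y).sum())
        if n1 == 0 or n0 == 0:
            raise ValueError("cohort must contain both event and event-free patients")
        self.class_prior_log_odds_ = float(np.log(n1 / n0))
        if cohort.peri.shape[1] > 0:
            self.peri_prior_ = fit_nb(cohort.peri, static_y, pseudocount=self.nb_pseudocount)
        else:
            self.peri_prior_ = None

        at_risk, ywin = _window_labels_all(cohort, cfg.delta, cfg.horizon)
        panel = cohort.panel
        if panel.horizon < cfg.horizon:
            raise ValueError("panel horizon shorter than model horizon")
        self.feature_names_ = list(panel.feature_names)
        self.features_ = {}
        for k, name in enumerate(self.feature_names_):
            vals = panel.values[:, k, : cfg.horizon]
            mask = panel.mask[:, k, : cfg.horizon]
            cutoffs = np.full(cfg.horizon, np.nan)
            for d in range(cfg.horizon):
                sel = mask[:, d] & at_risk[:, d]
                if sel.any():
                    cutoffs[d] = best_cutoff(vals[sel, d], ywin[sel, d])
            l, u = fit_thresholds(cutoffs)
            if not np.isfinite(l):
                self.features_[name] = DynamicFeatureParams(
                    np.nan, np.nan, cutoffs, np.full((4, cfg.horizon), np.nan),
                    None, informative=False,
                )
                continue
            raw = fit_bin_probs(vals, mask, at_risk, ywin, l, u)
            smooth = None
            if cfg.smoothing:
                smooth = np.vstack([smooth_probs(raw[r], cfg.horizon) for r in range(4)])
            self.features_[name] = DynamicFeatureParams(l, u, cutoffs, raw, smooth)

        self.theta_table_ = _stack_tables(self.features_, self.feature_names_, cfg)
        self.config_ = cfg
        return self

    # -- scoring ------------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "features_"):
            raise ValueError("model is not fitted")

    def _prior(self, cohort: CohortDataset) -> np.ndarray:
        if self.peri_prior_ is not None:
            return nb_log_odds_batch(self.peri_prior_, cohort.peri)
        return np.full(cohort.n_patients, self.class_prior_log_odds_)

    def _daily_contributions(self, panel: DynamicPanel) -> np.ndarray:
        """(n_patients, horizon) sum over features of I * theta per day."""
        if list(panel.feature_names) != self.feature_names_:
            raise ValueError("feature names of panel do not match fitted model")
        H = self.config_.horizon
        vals = panel.values[:, :, :H]
        mask = panel.mask[:, :, :H]
        ls = np.array([self.features_[n].l for n in self.feature_names_])
        us = np.array([self.features_[n].u for n in self.feature_names_])
        with np.errstate(invalid="ignore"):
            bins = np.where(
                vals < ls[None, :, None], LOW,
                np.where(vals > us[None, :, None], HIGH, MID),
            )
        # theta_table_ is (p, H, 3); gather per cell then zero out missing
        th = np.take_along_axis(
            self.theta_table_[None, :, :, :],
            bins[:, :, :, None],
            axis=3,
        )[:, :, :, 0]
        return np.where(mask, th, 0.0).sum(axis=1)

    def predict_score(self, cohort: CohortDataset, t: int) -> np.ndarray:
        """phi_i(t) for every patient in ``cohort``."""
        self._check_fitted()
        daily = self._daily_contributions(cohort.panel)
        lo = max(1, t - self.config_.delta + 1)
        window = daily[:, lo - 1 : t].sum(axis=1)
        return self._prior(cohort) + window

    def predict_trajectories(self, cohort: CohortDataset) -> RiskTrajectory:
        """phi_i(t) for all patients and all days 1..horizon."""
        self._check_fitted()
        H, delta = self.config_.horizon, self.config_.delta
        daily = self._daily_contributions(cohort.panel)
        cum = np.concatenate(
            [np.zeros((daily.shape[0], 1)), np.cumsum(daily, axis=1)], axis=1
        )
        t = np.arange(1, H + 1)
        lo = np.maximum(1, t - delta + 1)
        window = cum[:, t] - cum[:, lo - 1]
        scores = self._prior(cohort)[:, None] + window
        at_risk, _ = _window_labels_all(cohort, delta, H)
        return RiskTrajectory(scores, at_risk, list(cohort.panel.patients))

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        self._check_fitted()

        def arr(a):
            return None if a is None else np.where(np.isfinite(a), a, None).tolist()

        payload = {
            "config": asdict(self.config_),
            "nb_pseudocount": self.nb_pseudocount,
            "class_prior_log_odds": self.class_prior_log_odds_,
            "peri_prior": None if self.peri_prior_ is None else self.peri_prior_.to_dict(),
            "features": {
                name: {
                    "l": None if not np.isfinite(p.l) else p.l,
                    "u": None if not np.isfinite(p.u) else p.u,
                    "informative": p.informative,
                    "per_day_cutoffs": arr(p.per_day_cutoffs),
                    "raw_probs": arr(p.raw_probs),
                    "smooth_probs": arr(p.smooth_probs),
                }
                for name, p in self.features_.items()
            },
            "feature_names": self.feature_names_,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "DaGOAT":
        payload = json.loads(text)
        cfg = ModelConfig(**payload["config"])
        model = cls(cfg.delta, cfg.gamma, cfg.smoothing, cfg.horizon,
                    payload.get("nb_pseudocount", 1.0))
        model.config_ = cfg
        model.class_prior_log_odds_ = payload["class_prior_log_odds"]
        model.peri_prior_ = (
            None if payload["peri_prior"] is None
            else NBParams.from_dict(payload["peri_prior"])
        )
        model.feature_names_ = list(payload["feature_names"])

        def arr(a):
            return None if a is None else np.array(
                [[np.nan if v is None else v for v in row] for row in a]
                if a and isinstance(a[0], list)
                else [np.nan if v is None else v for v in a],
                dtype=float,
            )

        model.features_ = {}
        for name in model.feature_names_:
            d = payload["features"][name]
            model.features_[name] = DynamicFeatureParams(
                np.nan if d["l"] is None else d["l"],
                np.nan if d["u"] is None else d["u"],
                arr(d["per_day_cutoffs"]),
                arr(d["raw_probs"]),
                arr(d["smooth_probs"]),
                d["informative"],
            )
        model.theta_table_ = _stack_tables(model.features_, model.feature_names_, cfg)
        return model


def _stack_tables(features, names, cfg):
    if not names:
        return np.zeros((0, cfg.horizon, 3))
    return np.stack(
        [theta_table(features[n], cfg.gamma, cfg.smoothing, cfg.horizon) for n in names]
    )


# thin functional wrappers -------------------------------------------------

def fit(cohort: CohortDataset, config: ModelConfig | None = None) -> DaGOAT:
    cfg = config or ModelConfig()
    return DaGOAT(cfg.delta, cfg.gamma, cfg.smoothing, cfg.horizon).fit(cohort)


def score(model: DaGOAT, cohort: CohortDataset, t: int) -> np.ndarray:
    return model.predict_score(cohort, t)


def score_trajectories(model: DaGOAT, cohort: CohortDataset) -> RiskTrajectory:
    return model.predict_trajectories(cohort)
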