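"""Static-covariate Naive Bayes prior and benchmark model harness.

The risk model anchors every trajectory at rho(z), the log-odds of the
outcome given the categorical peri-transplantation covariates under a
standard categorical Naive Bayes with additive smoothing.  The same module
hosts the day-wise benchmark scorers the model is compared against:
Naive Bayes and Random Forest on peri covariates only ("PeriHSCT" variants)
and XGBoost on the flattened dynamic window with native missing-value
handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortDataset


@dataclass
class NBParams:
    """Fitted categorical Naive Bayes parameters.

    ``cond_tables[feature][category]`` is a (p_cat_given_y0, p_cat_given_y1)
    pair computed with additive pseudocount smoothing over the training
    vocabulary; categories unseen in training get pseudocount mass
    ps / (n_y + ps * V) so scoring stays finite.
    """

    class_counts: tuple
    pseudocount: float
    cond_tables: dict

    @property
    def class_log_prior_odds(self) -> float:
        n0, n1 = self.class_counts
        return float(np.log(n1 / n0))

    def feature_log_ratio(self, feature: str, category) -> float:
        if feature not in self.cond_tables:
            raise KeyError(f"unknown peri feature {feature!r}")
        table = self.cond_tables[feature]
        n0, n1 = self.class_counts
        ps = self.pseudocount
        V = len(table)
        if category in table:
            p0, p1 = table[category]
        else:  # unseen category: pure pseudocount mass
            p0 = ps / (n0 + ps * V)
            p1 = ps / (n1 + ps * V)
        return float(np.log(p1) - np.log(p0))

    def to_dict(self) -> dict:
        return {
            "class_counts": list(self.class_counts),
            "pseudocount": self.pseudocount,
            "cond_tables": {
                f: {str(c): list(pv) for c, pv in tab.items()}
                for f, tab in self.cond_tables.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NBParams":
        return cls(
            tuple(d["class_counts"]),
            d["pseudocount"],
            {f: {c: tuple(pv) for c, pv in tab.items()} for f, tab in d["cond_tables"].items()},
        )


def fit_nb(peri: pd.DataFrame, labels, pseudocount: float = 1.0) -> NBParams:
    """Fit a categorical Naive Bayes on the peri-covariate table.

    ``labels`` is a binary vector aligned with the table's rows.  Both
    classes must be present.
    """
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present to fit the prior")
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    tables = {}
    for feat in peri.columns:
        col = peri[feat].astype(str)
        vocab = sorted(col.unique())
        V = len(vocab)
        tab = {}
        for cat in vocab:
            c1 = int(((col == cat) & y).sum())
            c0 = int(((col == cat) & ~y).sum())
            tab[cat] = (
                (c0 + pseudocount) / (n0 + pseudocount * V),
                (c1 + pseudocount) / (n1 + pseudocount * V),
            )
        tables[feat] = tab
    return NBParams((n0, n1), float(pseudocount), tables)


def nb_log_odds(params: NBParams, z) -> float:
    """log P(Y=1 | z) / P(Y=0 | z) under conditional independence.

    ``z`` maps peri feature name -> category (dict, Series or DataFrame row).
    """
    total = params.class_log_prior_odds
    for feat in params.cond_tables:
        total += params.feature_log_ratio(feat, str(z[feat]))
    return float(total)


def nb_log_odds_batch(params: NBParams, peri: pd.DataFrame) -> np.ndarray:
    return np.array([nb_log_odds(params, row) for _, row in peri.iterrows()])


# -- benchmark harness ------------------------------------------------------

@dataclass
class BenchmarkSpec:
    """Benchmark request: name in {nb, rf, xgboost} plus hyperparameters."""

    name: str
    hyperparameters: dict = None

    def __post_init__(self):
        if self.name not in ("nb", "rf", "xgboost"):
            raise ValueError(f"unknown benchmark {self.name!r}")
        self.hyperparameters = dict(self.hyperparameters or {})


def flatten_window(cohort: CohortDataset, t: int, delta: int) -> np.ndarray:
    """Dynamic values in [t-delta+1, t] as one column per (feature, lag).

    Missing cells become NaN (native missing markers for tree boosters).
    """
    lo = max(1, t - delta + 1)
    vals = cohort.panel.values[:, :, lo - 1 : t]
    mask = cohort.panel.mask[:, :, lo - 1 : t]
    X = np.where(mask, vals, np.nan)
    return X.reshape(X.shape[0], -1)


def fit_benchmark(spec: BenchmarkSpec, cohort: CohortDataset, t: int, delta: int,
                  horizon: int | None = None, seed: int = 0):
    """Fit a benchmark at day ``t`` and return a scorer over cohorts.

    nb / rf use the peri covariates only; xgboost uses the flattened dynamic
    window with NaN missing markers.  The returned callable maps a cohort to
    one score per patient (higher = riskier).
    """
    at_risk, y = _labels(cohort, t, delta, horizon)
    if spec.name == "nb":
        params = fit_nb(cohort.peri.iloc[_idx(at_risk)], np.asarray(y)[_idx(at_risk)],
                        **({"pseudocount": spec.hyperparameters.get("pseudocount", 1.0)}))

        def scorer(c: CohortDataset) -> np.ndarray:
            return nb_log_odds_batch(params, c.peri)

        return scorer

    if spec.name == "rf":
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.preprocessing import OneHotEncoder

        enc = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
        Xtr = enc.fit_transform(cohort.peri.astype(str).iloc[_idx(at_risk)])
        clf = RandomForestClassifier(
            random_state=seed, **spec.hyperparameters
        ).fit(Xtr, np.asarray(y)[_idx(at_risk)])

        def scorer(c: CohortDataset) -> np.ndarray:
            return clf.predict_proba(enc.transform(c.peri.astype(str)))[:, 1]

        return scorer

    # xgboost on the flattened dynamic window
    try:
        from xgboost import XGBClassifier
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("xgboost backend is not available") from exc

    Xtr = flatten_window(cohort, t, delta)[_idx(at_risk)]
    clf = XGBClassifier(
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        **spec.hyperparameters,
    ).fit(Xtr, np.asarray(y)[_idx(at_risk)].astype(int))

    def scorer(c: CohortDataset) -> np.ndarray:
        return clf.predict_proba(flatten_window(c, t, delta))[:, 1]

    return scorer


def _labels(cohort, t, delta, horizon):
    from .model import window_labels

    return window_labels(cohort, t, delta, horizon)


def _idx(boolean):
    return np.nonzero(np.asarray(boolean))[0]
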