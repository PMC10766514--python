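"""Panel assembly for irregular post-transplant clinical time series.

Clinical measurements arrive as long-format records (patient, day, feature,
value) sampled at wildly different frequencies per feature.  This module
cleans them (plausibility blanking), collapses repeated same-day measurements
to a daily mean, densifies with a time-limited sample-and-hold, and packs the
result into a dense (patient x feature x day) panel with an availability mask.
No other imputation is performed: absent cells stay absent and are skipped by
the risk model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["patient_id", "day", "feature", "value"]


class RawMeasurement(NamedTuple):
    """One measurement of one dynamic variable on one post-transplant day."""

    patient_id: str
    day: int  # 1-based day post-transplant
    feature: str
    value: float


class ConfigError(ValueError):
    """Malformed configuration (e.g. a plausibility range with min > max)."""


class AssemblyError(ValueError):
    """Patient id sets disagree between panel, peri table and outcomes."""


@dataclass
class DynamicPanel:
    """Dense (patient, feature, day) array of daily values plus mask.

    ``values[i, k, d]`` is the value of feature ``k`` for patient ``i`` on day
    ``d + 1``; ``mask`` is 1 where a value exists.  Days are 1-based and run
    from 1 to ``horizon`` inclusive.
    """

    values: np.ndarray
    mask: np.ndarray
    patients: list
    feature_names: list
    horizon: int = field(default=0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.ndim != 3:
            raise ValueError("panel must be 3-dimensional (patient, feature, day)")
        if self.horizon == 0:
            self.horizon = self.values.shape[2]
        if self.horizon != self.values.shape[2]:
            raise ValueError("horizon does not match day axis length")
        bad = self.mask & ~np.isfinite(self.values)
        if bad.any():
            raise ValueError("non-finite value under mask=1")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "DynamicPanel":
        return DynamicPanel(
            self.values.copy(), self.mask.copy(), list(self.patients),
            list(self.feature_names), self.horizon,
        )

    def select_features(self, names: Sequence[str]) -> "DynamicPanel":
        idx = [self.feature_names.index(n) for n in names]
        return DynamicPanel(
            self.values[:, idx, :], self.mask[:, idx, :], list(self.patients),
            list(names), self.horizon,
        )


@dataclass
class CohortDataset:
    """Aligned bundle of dynamic panel, peri-transplant table and outcomes.

    ``peri`` is a per-patient DataFrame of categorical covariates known at
    transplant; ``outcomes`` has nullable integer ``onset_day`` (day severe
    aGVHD treatment started) and ``last_observed_day``.
    """

    panel: DynamicPanel
    peri: pd.DataFrame
    outcomes: pd.DataFrame

    def __post_init__(self):
        pts = list(self.panel.patients)
        for name, df in (("peri", self.peri), ("outcomes", self.outcomes)):
            if list(df.index) != pts:
                raise AssemblyError(f"{name} index not aligned with panel patients")
        onset = self.outcomes["onset_day"]
        last = self.outcomes["last_observed_day"]
        has = onset.notna()
        if has.any():
            o = onset[has].astype(float)
            if (o < 1).any() or (o > last[has].astype(float)).any():
                raise ValueError("onset_day must satisfy 1 <= onset <= last_observed_day")

    @property
    def n_patients(self) -> int:
        return self.panel.n_patients

    def onset_array(self) -> np.ndarray:
        """Onset days as float with +inf for event-free patients."""
        o = self.outcomes["onset_day"].to_numpy(dtype=float)
        return np.where(np.isnan(o), np.inf, o)

    def last_observed_array(self) -> np.ndarray:
        return self.outcomes["last_observed_day"].to_numpy(dtype=float)

    def subset_patients(self, indices: Sequence[int]) -> "CohortDataset":
        idx = np.asarray(indices, dtype=int)
        panel = DynamicPanel(
            self.panel.values[idx], self.panel.mask[idx],
            [self.panel.patients[i] for i in idx],
            list(self.panel.feature_names), self.panel.horizon,
        )
        return CohortDataset(panel, self.peri.iloc[idx], self.outcomes.iloc[idx])

    def select_features(self, names: Sequence[str]) -> "CohortDataset":
        return CohortDataset(self.panel.select_features(names), self.peri, self.outcomes)


def blank_outliers(
    measurements: Iterable[RawMeasurement],
    plausibility: Mapping[str, tuple] | None = None,
) -> list:
    """Drop measurements outside the declared plausibility range of their feature.

    Features without a declared range pass through unchanged.  Idempotent.
    """
    plausibility = dict(plausibility or {})
    for feat, (lo, hi) in plausibility.items():
        if lo > hi:
            raise ConfigError(f"plausibility range for {feat!r} has min > max")
    kept = []
    n_blanked = 0
    for m in measurements:
        rng = plausibility.get(m.feature)
        if rng is not None and not (rng[0] <= m.value <= rng[1]):
            n_blanked += 1
            continue
        kept.append(m)
    if n_blanked:
        logger.info("blank_outliers: removed %d out-of-range records", n_blanked)
    return kept


def aggregate_daily(
    measurements: Iterable[RawMeasurement],
    horizon: int = 100,
    patients: Sequence | None = None,
    feature_names: Sequence[str] | None = None,
) -> DynamicPanel:
    """Collapse repeated same-day measurements to their arithmetic mean.

    Patient and feature order default to sorted order of appearance; pass
    explicit lists to pin the axes (extra ids yield all-missing rows).
    """
    rows = [m for m in measurements if 1 <= m.day <= horizon]
    for m in rows:
        if not np.isfinite(float(m.value)):
            raise ValueError(f"non-numeric value in record {m!r}")
    if patients is None:
        patients = sorted({m.patient_id for m in rows})
    if feature_names is None:
        feature_names = sorted({m.feature for m in rows})
    p_idx = {p: i for i, p in enumerate(patients)}
    f_idx = {f: i for i, f in enumerate(feature_names)}
    sums = np.zeros((len(patients), len(feature_names), horizon))
    counts = np.zeros_like(sums)
    for m in rows:
        if m.patient_id in p_idx and m.feature in f_idx:
            sums[p_idx[m.patient_id], f_idx[m.feature], m.day - 1] += float(m.value)
            counts[p_idx[m.patient_id], f_idx[m.feature], m.day - 1] += 1
    mask = counts > 0
    values = np.where(mask, sums / np.where(mask, counts, 1), 0.0)
    return DynamicPanel(values, mask, list(patients), list(feature_names), horizon)


def sample_and_hold(
    panel: DynamicPanel,
    hold_days: int = 3,
    last_observed: Mapping | pd.Series | None = None,
) -> DynamicPanel:
    """Carry each observation forward up to ``hold_days`` days.

    A newer observation overwrites a held value; original observations are
    never altered.  If ``last_observed`` maps patients to their last day under
    observation, held values never cross it.
    """
    if hold_days < 0:
        raise ValueError("hold_days must be >= 0")
    out = panel.copy()
    if hold_days == 0:
        return out
    values, mask = out.values, out.mask
    obs = panel.mask
    for d in range(1, panel.horizon):
        # fill day d+1 from the most recent original observation at most
        # hold_days back; a same-day observation takes precedence
        lo = max(0, d - hold_days)
        recent = obs[:, :, lo : d + 1]
        fill = recent.any(axis=2) & ~obs[:, :, d]
        if fill.any():
            last_idx = lo + (recent.shape[2] - 1 - np.argmax(recent[:, :, ::-1], axis=2))
            vals_src = np.take_along_axis(panel.values, last_idx[:, :, None], axis=2)[:, :, 0]
            values[:, :, d] = np.where(fill, vals_src, values[:, :, d])
            mask[:, :, d] = mask[:, :, d] | fill
    if last_observed is not None:
        last = np.asarray([float(last_observed[p]) for p in panel.patients])
        days = np.arange(1, panel.horizon + 1)
        beyond = days[None, None, :] > last[:, None, None]
        introduced = mask & ~obs
        mask[introduced & beyond] = False
    values[~mask] = 0.0
    return DynamicPanel(values, mask, out.patients, out.feature_names, out.horizon)


def assemble_cohort(
    panel: DynamicPanel, peri: pd.DataFrame, outcomes: pd.DataFrame
) -> CohortDataset:
    """Align peri and outcome tables to the panel's patient order."""
    pts = list(panel.patients)
    for name, df in (("peri", peri), ("outcomes", outcomes)):
        missing = sorted(set(pts) - set(df.index))
        if missing:
            raise AssemblyError(f"patients missing from {name}: {missing}")
        extra = sorted(set(df.index) - set(pts))
        if extra:
            raise AssemblyError(f"patients in {name} but not in panel: {extra}")
    return CohortDataset(panel, peri.loc[pts], outcomes.loc[pts])


# ---------------------------------------------------------------------------
# CSV round-trips.  Long format is canonical for dynamic data; peri and
# outcome tables are one row per patient.

def read_measurements_csv(path) -> list:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV lacks columns {sorted(missing)}")
    return [
        RawMeasurement(str(r.patient_id), int(r.day), str(r.feature), float(r.value))
        for r in df.itertuples()
    ]


def write_measurements_csv(measurements: Iterable[RawMeasurement], path) -> None:
    pd.DataFrame(measurements, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def panel_to_long(panel: DynamicPanel) -> pd.DataFrame:
    i, k, d = np.nonzero(panel.mask)
    return pd.DataFrame(
        {
            "patient_id": [panel.patients[j] for j in i],
            "day": d + 1,
            "feature": [panel.feature_names[j] for j in k],
            "value": panel.values[i, k, d],
        }
    )


def long_to_panel(
    df: pd.DataFrame,
    horizon: int = 100,
    patients: Sequence | None = None,
    feature_names: Sequence[str] | None = None,
) -> DynamicPanel:
    ms = [
        RawMeasurement(str(r.patient_id), int(r.day), str(r.feature), float(r.value))
        for r in df.itertuples()
    ]
    return aggregate_daily(ms, horizon=horizon, patients=patients, feature_names=feature_names)


def read_peri_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).set_index("patient_id")
    return df


def write_peri_csv(peri: pd.DataFrame, path) -> None:
    peri.to_csv(path, index_label="patient_id")


def read_outcomes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("patient_id")
    df.index = df.index.map(str)
    df["onset_day"] = df["onset_day"].astype("Int64")
    df["last_observed_day"] = df["last_observed_day"].astype(int)
    return df


def write_outcomes_csv(outcomes: pd.DataFrame, path) -> None:
    outcomes.to_csv(path, index_label="patient_id")


def load_config(path) -> dict:
    """Load the hierarchical YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg
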