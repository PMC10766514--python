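"""Adapter for the UCI smartphone activities / postural-transitions dataset.

Converts the published feature windows (step 1.28 s, 561 features, 12-class
activity labels, pre-partitioned 70:30 by subject) into pseudo-cohorts the
risk model can consume: every run of 7 consecutive sitting windows (8.96 s)
becomes a segment, labeled '+' when a sit-to-stand transition begins within
the following 4 windows (5.12 s).  Segments are enumerated at stride 1 over
all offsets; a segment whose 4-window lookahead crosses the end of a
subject's recording is labeled from the available lookahead.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortDataset, DynamicPanel

N_FEATURES = 561
SEGMENT_WINDOWS = 7   # 8.96 s / 1.28 s
LOOKAHEAD_WINDOWS = 4  # 5.12 s / 1.28 s
SITTING = 4
SIT_TO_STAND = 8


class HAPTLoadError(RuntimeError):
    pass


@dataclass
class ActivitySeries:
    """Ordered windows of one subject within one partition."""

    subject: int
    partition: str  # 'train' or 'test'
    features: np.ndarray  # (n_windows, 561)
    labels: np.ndarray    # (n_windows,)

    def __post_init__(self):
        if self.features.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features per window")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("feature/label row counts differ")


@dataclass
class Segment:
    subject: int
    partition: str
    start: int               # window index of the first sitting window
    features: np.ndarray     # (7, 561)
    positive: bool


def load_hapt(directory) -> list:
    """Load both partitions into per-subject ordered ActivitySeries.

    Expects the dataset layout ``Train/X_train.txt``, ``Train/y_train.txt``,
    ``Train/subject_id_train.txt`` (and the Test equivalents) with
    whitespace-separated values; row order within each file is preserved.
    """
    series = []
    for part, sub in (("train", "Train"), ("test", "Test")):
        paths = {
            kind: _find(directory, sub, f"{kind}_{part}.txt")
            for kind in ("X", "y", "subject_id")
        }
        X = np.loadtxt(paths["X"])
        y = np.loadtxt(paths["y"], dtype=int)
        subj = np.loadtxt(paths["subject_id"], dtype=int)
        if not (X.shape[0] == y.shape[0] == subj.shape[0]):
            raise HAPTLoadError(
                f"row-count mismatch in {part}: X={X.shape[0]} y={y.shape[0]} "
                f"subject={subj.shape[0]}"
            )
        for s in np.unique(subj):
            sel = subj == s
            series.append(ActivitySeries(int(s), part, X[sel], y[sel]))
    train_subj = {s.subject for s in series if s.partition == "train"}
    test_subj = {s.subject for s in series if s.partition == "test"}
    if train_subj & test_subj:
        raise HAPTLoadError("subjects appear in both partitions")
    return series


def _find(directory, sub, fname):
    for cand in (os.path.join(directory, sub, fname),
                 os.path.join(directory, fname)):
        if os.path.exists(cand):
            return cand
    raise HAPTLoadError(f"missing file {fname} under {directory}")


def extract_segments(series) -> list:
    """All stride-1 sitting segments with their stand-up lookahead labels."""
    if isinstance(series, ActivitySeries):
        series = [series]
    segments = []
    for s in series:
        labels = s.labels
        n = labels.shape[0]
        sitting = labels == SITTING
        for i in range(n - SEGMENT_WINDOWS + 1):
            if not sitting[i : i + SEGMENT_WINDOWS].all():
                continue
            look = labels[i + SEGMENT_WINDOWS : i + SEGMENT_WINDOWS + LOOKAHEAD_WINDOWS]
            positive = bool((look == SIT_TO_STAND).any())
            segments.append(
                Segment(s.subject, s.partition, i,
                        s.features[i : i + SEGMENT_WINDOWS], positive)
            )
    return segments


def segment_counts(segments) -> dict:
    """Totals and '+' counts per partition."""
    out = {}
    for part in ("train", "test"):
        sub = [g for g in segments if g.partition == part]
        out[part] = {"total": len(sub), "positive": sum(g.positive for g in sub)}
    return out


def to_cohort(segments) -> CohortDataset:
    """Segments as a pseudo-cohort: 7 'days', 561 features, no peri table.

    '+' segments get a nominal onset immediately after day 7, so a model with
    delta = 7 scored at t = 7 spans the full segment and its moving-window
    label equals the segment label.
    """
    segments = list(segments)
    n = len(segments)
    T = SEGMENT_WINDOWS
    values = np.zeros((n, N_FEATURES, T + 1))
    mask = np.zeros((n, N_FEATURES, T + 1), dtype=bool)
    for j, g in enumerate(segments):
        values[j, :, :T] = g.features.T
        mask[j, :, :T] = True
    patients = [f"{g.partition}-s{g.subject}-w{g.start}" for g in segments]
    feats = [f"v{k}" for k in range(N_FEATURES)]
    panel = DynamicPanel(values, mask, patients, feats, T + 1)
    peri = pd.DataFrame(index=patients)
    outcomes = pd.DataFrame(
        {
            "onset_day": pd.array(
                [T + 1 if g.positive else pd.NA for g in segments], dtype="Int64"
            ),
            "last_observed_day": T + 1,
        },
        index=patients,
    )
    return CohortDataset(panel, peri, outcomes)
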