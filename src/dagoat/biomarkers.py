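"""Landmark plasma-biomarker comparator scores.

Two published linear scores on log-transformed plasma biomarkers measured at
a fixed post-transplant landmark: the two-biomarker MAGIC score (ST2,
Reg3a; base-10 logs) and the three-biomarker Ann Arbor score (TNFR1, Reg3a,
ST2; base-2 logs).  Assay units are unspecified in the source reports; any
consistent unit per analyte is accepted — a common rescaling of one analyte
shifts the score by a constant, so rank-based metrics (AUROC / AUPRC) are
unit-invariant while absolute score values are not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _check_positive(name, x):
    x = np.asarray(x, dtype=float)
    if (x <= 0).any() or not np.isfinite(x).all():
        raise ValueError(f"{name} must be strictly positive and finite")
    return x


def magic_score(st2, reg3a):
    """MAGIC score: -11.263 + 1.844*log10(ST2) + 0.577*log10(Reg3a)."""
    st2 = _check_positive("st2", st2)
    reg3a = _check_positive("reg3a", reg3a)
    return -11.263 + 1.844 * np.log10(st2) + 0.577 * np.log10(reg3a)


def ann_arbor_score(tnfr1, reg3a, st2):
    """Ann Arbor score: -9.169 + 0.598*log2(TNFR1) - 0.028*log2(Reg3a) + 0.189*log2(ST2)."""
    tnfr1 = _check_positive("tnfr1", tnfr1)
    reg3a = _check_positive("reg3a", reg3a)
    st2 = _check_positive("st2", st2)
    return -9.169 + 0.598 * np.log2(tnfr1) - 0.028 * np.log2(reg3a) + 0.189 * np.log2(st2)


def score_panel(df: pd.DataFrame) -> pd.DataFrame:
    """Score a (patient, st2, reg3a, tnfr1) table -> (patient, magic, annarbor)."""
    return pd.DataFrame(
        {
            "magic": magic_score(df["st2"], df["reg3a"]),
            "annarbor": ann_arbor_score(df["tnfr1"], df["reg3a"], df["st2"]),
        },
        index=df.index,
    )
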