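"""Fast-spiking vs regular-spiking classification.

The rule is a conjunction of four strict inequalities on single-cell
features: a cell is fast-spiking (FS) iff

* AP half-width < 0.5 ms, and
* maximum firing frequency > 50 Hz, and
* fAHP amplitude > 14 mV, and
* spike-frequency accommodation (SFA) < 2;

otherwise it is regular-spiking (RS).  Boundary values classify RS.
A cell with any required feature undefined (NaN) is *unclassifiable* —
a third outcome, never silently RS, because a missing SFA (fewer than
three spikes) must not masquerade as regular spiking.

:class:`FastSpikingClassifier` wraps the rule as a scikit-learn style
estimator so it composes with pandas/sklearn workflows; the plain
functions :func:`classify` and :func:`cohort_summary` remain the
lightweight interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intrinsic import IntrinsicProfile

__all__ = [
    "DEFAULT_THRESHOLDS",
    "PhysClass",
    "classify",
    "cohort_summary",
    "FastSpikingClassifier",
]

#: Cutoffs of the conjunctive rule. Keys name the feature, values the cutoff;
#: direction is fixed (half_width and sfa must be below, max_freq and fahp above).
DEFAULT_THRESHOLDS = {
    "half_width": 0.5,  # ms, FS requires <
    "max_freq": 50.0,   # Hz, FS requires >
    "fahp": 14.0,       # mV, FS requires >
    "sfa": 2.0,         # ratio, FS requires <
}

FEATURE_COLUMNS = {
    "half_width": "half_width_ms",
    "max_freq": "max_freq_hz",
    "fahp": "fahp_mv",
    "sfa": "sfa",
}


@dataclass
class PhysClass:
    """Classification outcome for one cell.

    ``label`` is ``"FS"``, ``"RS"`` or ``"unclassifiable"``; ``criteria``
    records the per-criterion booleans, and ``thresholds_used`` the four
    cutoffs that produced them.
    """

    label: str
    criteria: dict
    thresholds_used: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    cell_id: str = ""


def _extract_features(p) -> dict:
    if isinstance(p, IntrinsicProfile):
        return {
            "half_width": p.ap.half_width,
            "max_freq": p.max_freq,
            "fahp": p.ap.fahp,
            "sfa": p.sfa,
            "cell_id": p.cell_id,
        }
    d = dict(p)
    d.setdefault("cell_id", "")
    return d


def classify(profile, thresholds: dict | None = None) -> PhysClass:
    """Apply the four-criterion FS rule to one cell.

    ``profile`` is an :class:`~fastspike.intrinsic.IntrinsicProfile` or a
    mapping with keys ``half_width`` (ms), ``max_freq`` (Hz), ``fahp``
    (mV) and ``sfa``.  ``thresholds`` overrides any subset of the
    default cutoffs.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        unknown = set(thresholds) - set(thr)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        thr.update(thresholds)
    f = _extract_features(profile)
    missing = [k for k in DEFAULT_THRESHOLDS if k not in f or f[k] is None
               or (isinstance(f[k], float) and math.isnan(f[k]))]
    if missing:
        return PhysClass(
            label="unclassifiable",
            criteria={k: None for k in DEFAULT_THRESHOLDS},
            thresholds_used=thr,
            cell_id=f.get("cell_id", ""),
        )
    criteria = {
        "half_width": f["half_width"] < thr["half_width"],
        "max_freq": f["max_freq"] > thr["max_freq"],
        "fahp": f["fahp"] > thr["fahp"],
        "sfa": f["sfa"] < thr["sfa"],
    }
    label = "FS" if all(criteria.values()) else "RS"
    return PhysClass(label=label, criteria=criteria, thresholds_used=thr,
                     cell_id=f.get("cell_id", ""))


def cohort_summary(classes, group_labels=None) -> pd.DataFrame:
    """FS fraction and counts per group.

    ``classes`` is a sequence of :class:`PhysClass`; ``group_labels`` an
    optional parallel sequence of group names (one group if omitted).
    Unclassifiable cells are counted separately and excluded from the
    FS-fraction denominator.
    """
    classes = list(classes)
    if group_labels is None:
        group_labels = ["all"] * len(classes)
    group_labels = list(group_labels)
    if len(group_labels) != len(classes):
        raise ValueError("group_labels must match classes in length")
    if not classes:
        raise ValueError("no classified cells")
    rows = []
    for group in dict.fromkeys(group_labels):  # preserve first-seen order
        members = [c for c, g in zip(classes, group_labels) if g == group]
        n_fs = sum(c.label == "FS" for c in members)
        n_rs = sum(c.label == "RS" for c in members)
        n_uncl = sum(c.label == "unclassifiable" for c in members)
        n_cls = n_fs + n_rs
        rows.append(
            {
                "group": group,
                "n_cells": len(members),
                "n_fs": n_fs,
                "n_rs": n_rs,
                "n_unclassifiable": n_uncl,
                "fs_fraction": n_fs / n_cls if n_cls else float("nan"),
            }
        )
    return pd.DataFrame(rows)


class FastSpikingClassifier:
    """Rule-based FS/RS classifier with a scikit-learn estimator surface.

    The rule has no free parameters to learn; :meth:`fit` validates the
    configured cutoffs and freezes them as ``thresholds_``.  ``predict``
    accepts a DataFrame with columns ``half_width_ms``, ``max_freq_hz``,
    ``fahp_mv`` and ``sfa`` (the column dictionary of the feature table
    written by the extraction pipeline) and returns an array of labels
    in {"FS", "RS", "unclassifiable"}.

    Parameters
    ----------
    half_width_ms, max_freq_hz, fahp_mv, sfa : float
        The four cutoffs; FS requires half-width and SFA strictly below,
        maximum frequency and fAHP strictly above, their cutoffs.
    """

    def __init__(self, half_width_ms: float = 0.5, max_freq_hz: float = 50.0,
                 fahp_mv: float = 14.0, sfa: float = 2.0):
        self.half_width_ms = half_width_ms
        self.max_freq_hz = max_freq_hz
        self.fahp_mv = fahp_mv
        self.sfa = sfa

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "half_width_ms": self.half_width_ms,
            "max_freq_hz": self.max_freq_hz,
            "fahp_mv": self.fahp_mv,
            "sfa": self.sfa,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r} for FastSpikingClassifier")
            setattr(self, k, v)
        return self

    @property
    def _thresholds(self) -> dict:
        return {
            "half_width": self.half_width_ms,
            "max_freq": self.max_freq_hz,
            "fahp": self.fahp_mv,
            "sfa": self.sfa,
        }

    def fit(self, X=None, y=None):
        """Validate and freeze the cutoffs; no parameters are estimated."""
        for k, v in self._thresholds.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"cutoff {k} must be finite and positive, got {v}")
        self.thresholds_ = dict(self._thresholds)
        self.classes_ = np.array(["FS", "RS", "unclassifiable"])
        return self

    def _check_fitted(self):
        if not hasattr(self, "thresholds_"):
            self.fit()

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in FEATURE_COLUMNS.values() if c not in X.columns]
            if missing:
                raise ValueError(f"feature table missing columns: {missing}")
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError(
                "array input must be (n_cells, 4): half_width_ms, max_freq_hz, fahp_mv, sfa"
            )
        return pd.DataFrame(X, columns=list(FEATURE_COLUMNS.values()))

    # -- prediction ---------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Labels for a feature table: 'FS', 'RS' or 'unclassifiable'."""
        self._check_fitted()
        df = self._as_frame(X)
        out = np.empty(len(df), dtype=object)
        for i, (_, row) in enumerate(df.iterrows()):
            out[i] = classify(
                {k: row[col] for k, col in FEATURE_COLUMNS.items()},
                thresholds=self.thresholds_,
            ).label
        return out

    def criteria_frame(self, X) -> pd.DataFrame:
        """Per-criterion booleans plus the final label, one row per cell."""
        self._check_fitted()
        df = self._as_frame(X)
        rows = []
        for _, row in df.iterrows():
            pc = classify({k: row[col] for k, col in FEATURE_COLUMNS.items()},
                          thresholds=self.thresholds_)
            rows.append({**{f"crit_{k}": v for k, v in pc.criteria.items()},
                         "label": pc.label})
        return pd.DataFrame(rows, index=df.index)

    def score(self, X, y) -> float:
        """Fraction of cells whose label matches ``y``."""
        return float(np.mean(self.predict(X) == np.asarray(y)))
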