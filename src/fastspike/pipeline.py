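"""Cell-level pipeline: sweep families in, feature/label tables out.

:class:`IntrinsicFeatureExtractor` exposes feature extraction with a
scikit-learn transformer surface so it chains naturally with
:class:`~fastspike.classify.FastSpikingClassifier`:

>>> features = IntrinsicFeatureExtractor().fit_transform(sweep_sets)
>>> labels = FastSpikingClassifier().fit().predict(features)
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd

from .classify import FastSpikingClassifier
from .intrinsic import FeatureConfig, FeatureUndefinedError, extract_profile
from .traces import SweepSet

__all__ = ["IntrinsicFeatureExtractor", "extract_feature_table"]

log = logging.getLogger("fastspike")


class IntrinsicFeatureExtractor:
    """Transformer mapping current-clamp sweep families to a feature table.

    Parameters are the extraction knobs of
    :class:`~fastspike.intrinsic.FeatureConfig` (all overridable as
    keyword arguments).  ``transform`` returns one row per cell with the
    documented column dictionary (``rmp_mv``, ``r_in_mohm``,
    ``rheobase_pa``, ``max_freq_hz``, ``sfa``, ``cv_isi``,
    ``ap_threshold_mv``, ``ap_amplitude_mv``, ``half_width_ms``,
    ``max_dvdt_mv_per_ms``, ``fahp_mv``, ``ap_sweep_pa``, ``sag_ratio``,
    ``rebound_mv``).  Cells whose extraction fails are skipped with a
    logged warning and collected in ``failures_``.
    """

    def __init__(self, **feature_params):
        valid = {f.name for f in dataclasses.fields(FeatureConfig)}
        unknown = set(feature_params) - valid
        if unknown:
            raise ValueError(f"unknown feature parameters: {sorted(unknown)}")
        self.feature_params = feature_params

    def get_params(self, deep: bool = True) -> dict:
        return {"feature_params": dict(self.feature_params)}

    def set_params(self, **params):
        if "feature_params" in params:
            self.feature_params = dict(params.pop("feature_params"))
        self.feature_params.update(params)
        return self

    def fit(self, X=None, y=None):
        """Freeze the configuration; nothing is estimated from data."""
        self.config_ = FeatureConfig(**self.feature_params)
        return self

    def transform(self, sweep_sets) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit()
        rows = []
        self.failures_: list[tuple[str, str]] = []
        for ss in sweep_sets:
            if not isinstance(ss, SweepSet):
                raise TypeError(f"expected SweepSet, got {type(ss).__name__}")
            try:
                rows.append(extract_profile(ss, self.config_).feature_row())
            except (FeatureUndefinedError, ValueError) as e:
                log.warning("cell %s: extraction failed: %s", ss.cell_id, e)
                self.failures_.append((ss.cell_id, str(e)))
        return pd.DataFrame(rows)

    def fit_transform(self, sweep_sets, y=None) -> pd.DataFrame:
        return self.fit().transform(sweep_sets)


def extract_feature_table(
    sweep_sets,
    feature_config: FeatureConfig | None = None,
    classifier: FastSpikingClassifier | None = None,
) -> pd.DataFrame:
    """Feature table with FS/RS classification appended.

    Thin functional wrapper over :class:`IntrinsicFeatureExtractor` and
    :class:`~fastspike.classify.FastSpikingClassifier`.
    """
    params = dataclasses.asdict(feature_config) if feature_config else {}
    extractor = IntrinsicFeatureExtractor(**params)
    table = extractor.fit_transform(sweep_sets)
    clf = classifier or FastSpikingClassifier()
    if len(table):
        table = table.copy()
        table["label"] = clf.fit().predict(table)
    return table
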