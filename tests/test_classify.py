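"""The conjunctive FS/RS rule and its estimator surface."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fastspike.classify import (
    DEFAULT_THRESHOLDS,
    FastSpikingClassifier,
    classify,
    cohort_summary,
)


def brute_force_label(hw, freq, fahp, sfa_v):
    """Literal reapplication of the four printed inequalities."""
    return "FS" if (hw < 0.5 and freq > 50.0 and fahp > 14.0 and sfa_v < 2.0) else "RS"


class TestRule:
    @pytest.mark.parametrize(
        "features,expected",
        [
            ((0.4, 80.0, 16.0, 1.5), "FS"),
            ((0.5, 80.0, 16.0, 1.5), "RS"),  # strict inequality at the boundary
            ((0.8, 20.0, 6.0, 4.0), "RS"),
            ((0.4, 50.0, 16.0, 1.5), "RS"),  # boundary on frequency
            ((0.4, 80.0, 14.0, 1.5), "RS"),  # boundary on fAHP
            ((0.4, 80.0, 16.0, 2.0), "RS"),  # boundary on SFA
        ],
    )
    def test_examples(self, features, expected):
        hw, freq, fahp, sfa_v = features
        pc = classify({"half_width": hw, "max_freq": freq, "fahp": fahp, "sfa": sfa_v})
        assert pc.label == expected

    def test_boundary_grid_matches_brute_force(self):
        """3^4 grid of feature vectors straddling every cutoff."""
        grids = {
            "half_width": [0.4, 0.5, 0.6],
            "max_freq": [40.0, 50.0, 60.0],
            "fahp": [13.0, 14.0, 15.0],
            "sfa": [1.5, 2.0, 2.5],
        }
        for hw in grids["half_width"]:
            for fr in grids["max_freq"]:
                for fa in grids["fahp"]:
                    for sf in grids["sfa"]:
                        got = classify({"half_width": hw, "max_freq": fr,
                                        "fahp": fa, "sfa": sf}).label
                        assert got == brute_force_label(hw, fr, fa, sf)

    def test_criteria_record_and_thresholds_returned(self):
        pc = classify({"half_width": 0.4, "max_freq": 30.0, "fahp": 16.0, "sfa": 1.0})
        assert pc.label == "RS"
        assert pc.criteria == {"half_width": True, "max_freq": False,
                               "fahp": True, "sfa": True}
        assert pc.thresholds_used == DEFAULT_THRESHOLDS

    def test_missing_feature_is_unclassifiable_not_rs(self):
        pc = classify({"half_width": 0.4, "max_freq": 80.0, "fahp": 16.0,
                       "sfa": float("nan")})
        assert pc.label == "unclassifiable"

    def test_threshold_overrides(self):
        pc = classify({"half_width": 0.6, "max_freq": 80.0, "fahp": 16.0, "sfa": 1.5},
                      thresholds={"half_width": 0.7})
        assert pc.label == "FS"
        with pytest.raises(ValueError, match="unknown threshold"):
            classify({"half_width": 0.4, "max_freq": 80.0, "fahp": 16.0, "sfa": 1.5},
                     thresholds={"spikiness": 1.0})

    @settings(max_examples=200, derandomize=True)
    @given(
        hw=st.floats(0.1, 1.5), freq=st.floats(0.0, 200.0),
        fahp=st.floats(0.0, 30.0), sfa_v=st.floats(0.1, 10.0),
        d=st.floats(0.0, 0.5),
    )
    def test_monotonicity(self, hw, freq, fahp, sfa_v, d):
        """Moving every feature toward the FS side never flips FS -> RS."""
        before = classify({"half_width": hw, "max_freq": freq,
                           "fahp": fahp, "sfa": sfa_v}).label
        after = classify({"half_width": hw - d * hw, "max_freq": freq + d * 10,
                          "fahp": fahp + d * 5, "sfa": sfa_v - d * sfa_v}).label
        assert not (before == "FS" and after == "RS")


class TestCohortSummary:
    def _mk(self, labels):
        return [classify({"half_width": 0.4 if l == "FS" else 0.8,
                          "max_freq": 80.0, "fahp": 16.0, "sfa": 1.5})
                for l in labels]

    def test_fraction(self):
        classes = self._mk(["FS"] * 10 + ["RS"] * 20)
        df = cohort_summary(classes)
        assert df.loc[0, "fs_fraction"] == pytest.approx(1.0 / 3.0)
        assert df.loc[0, "n_fs"] == 10

    def test_all_rs(self):
        df = cohort_summary(self._mk(["RS"] * 5))
        assert df.loc[0, "fs_fraction"] == 0.0

    def test_unclassifiable_counted_separately(self):
        classes = self._mk(["FS", "RS"])
        classes.append(classify({"half_width": 0.4, "max_freq": 80.0,
                                 "fahp": 16.0, "sfa": None}))
        df = cohort_summary(classes)
        assert df.loc[0, "n_unclassifiable"] == 1
        assert df.loc[0, "fs_fraction"] == pytest.approx(0.5)

    def test_groups_and_empty_rejected(self):
        classes = self._mk(["FS", "RS", "RS", "FS"])
        df = cohort_summary(classes, ["a", "a", "b", "b"])
        assert list(df["group"]) == ["a", "b"]
        with pytest.raises(ValueError):
            cohort_summary([])


class TestEstimatorSurface:
    def test_get_set_params_roundtrip(self):
        clf = FastSpikingClassifier()
        params = clf.get_params()
        assert params["half_width_ms"] == 0.5
        clf.set_params(fahp_mv=10.0)
        assert clf.get_params()["fahp_mv"] == 10.0
        with pytest.raises(ValueError, match="invalid parameter"):
            clf.set_params(bogus=1)

    def test_predict_on_dataframe(self):
        df = pd.DataFrame({
            "half_width_ms": [0.4, 0.8, np.nan],
            "max_freq_hz": [80.0, 20.0, 80.0],
            "fahp_mv": [16.0, 6.0, 16.0],
            "sfa": [1.5, 4.0, 1.5],
        })
        labels = FastSpikingClassifier().fit().predict(df)
        assert list(labels) == ["FS", "RS", "unclassifiable"]

    def test_predict_on_array_and_score(self):
        X = np.array([[0.4, 80.0, 16.0, 1.5], [0.8, 20.0, 6.0, 4.0]])
        clf = FastSpikingClassifier().fit()
        assert clf.score(X, ["FS", "RS"]) == 1.0

    def test_random_vectors_match_brute_force(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame({
            "half_width_ms": rng.uniform(0.1, 1.2, 500),
            "max_freq_hz": rng.uniform(0.0, 150.0, 500),
            "fahp_mv": rng.uniform(0.0, 30.0, 500),
            "sfa": rng.uniform(0.2, 6.0, 500),
        })
        labels = FastSpikingClassifier().fit().predict(X)
        for i, row in X.iterrows():
            assert labels[i] == brute_force_label(
                row.half_width_ms, row.max_freq_hz, row.fahp_mv, row.sfa)

    def test_fit_rejects_nonsense_cutoffs(self):
        with pytest.raises(ValueError, match="cutoff"):
            FastSpikingClassifier(fahp_mv=-1.0).fit()
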