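import numpy as np
import pandas as pd
import pytest

from spinsense.features import (
    FEATURE_SCHEMA,
    SchemaError,
    SelectionReport,
    apply_selection,
    extract_feature_matrix,
    extract_features,
    fit_selection,
)
from spinsense.io import ValidationError
from spinsense.segmentation import Segment


def _segment(data, label="non_spinning"):
    return Segment(subject_id="dog00", start_sample=0, data=np.asarray(data, float), label=label)


def _brute_periodogram_peak(x, rate):
    """Independent oracle: O(n^2) DFT, largest non-DC power bin."""
    n = len(x)
    freqs = [k * rate / n for k in range(n // 2 + 1)]
    power = []
    for k in range(n // 2 + 1):
        re = sum(x[t] * np.cos(2 * np.pi * k * t / n) for t in range(n))
        im = sum(x[t] * np.sin(2 * np.pi * k * t / n) for t in range(n))
        power.append(re**2 + im**2)
    k_star = 1 + int(np.argmax(power[1:]))
    return freqs[k_star]


class TestExtractFeatures:
    def test_schema_is_48_stable_names(self):
        assert len(FEATURE_SCHEMA) == 48
        assert FEATURE_SCHEMA[0] == "Accel_LN_X__mean"
        assert FEATURE_SCHEMA[-1] == "Gyro_Mag__spec_entropy"

    def test_constant_trace_degenerates_cleanly(self):
        data = np.zeros((130, 6))
        data[:, 0] = 5.0
        feats = extract_features(_segment(data), 50.0)
        assert feats["Accel_LN_X__mean"] == 5.0
        assert feats["Accel_LN_X__std"] == 0.0
        assert feats["Accel_LN_X__range"] == 0.0
        assert feats["Accel_LN_X__dom_freq"] == 0.0
        assert feats["Accel_LN_X__spec_entropy"] == 0.0
        assert not any(np.isnan(v) for v in feats.values())

    def test_gyro_magnitude_of_3_4_0_axes_is_5(self):
        data = np.zeros((130, 6))
        data[:, 3] = 3.0
        data[:, 4] = 4.0
        feats = extract_features(_segment(data), 50.0)
        assert feats["Gyro_Mag__mean"] == pytest.approx(5.0)

    def test_sinusoid_dominant_frequency_matches_brute_dft(self):
        rate, n = 50.0, 130
        t = np.arange(n) / rate
        data = np.zeros((n, 6))
        data[:, 1] = np.sin(2 * np.pi * 2.0 * t)
        feats = extract_features(_segment(data), rate)
        oracle = _brute_periodogram_peak(data[:, 1], rate)
        assert feats["Accel_LN_Y__dom_freq"] == pytest.approx(oracle)
        # nearest bin to 2 Hz at bin width 50/130
        assert feats["Accel_LN_Y__dom_freq"] == pytest.approx(2.0, abs=50 / 130 / 2)

    def test_entropy_bounded_by_log2_bins(self, rng):
        data = rng.normal(size=(130, 6))
        feats = extract_features(_segment(data), 50.0)
        n_bins = 130 // 2  # non-DC rfft bins
        for trace in ("Accel_LN_X", "Gyro_Mag"):
            assert 0.0 <= feats[f"{trace}__spec_entropy"] <= np.log2(n_bins)
            assert feats[f"{trace}__range"] >= 0.0

    def test_matrix_has_no_missing_values(self, small_segments):
        segs = list(small_segments.values())[0][:40]
        X, y, meta = extract_feature_matrix(segs, 50.0)
        assert list(X.columns) == list(FEATURE_SCHEMA)
        assert not X.isna().any().any()
        assert len(X) == len(y) == len(meta)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValidationError):
            extract_features(_segment(np.zeros((130, 5))), 50.0)


def _toy_matrix(rng, n=60):
    """Crafted matrix: informative, constant, duplicated and noise columns."""
    y = np.array([0, 1] * (n // 2))
    cols = {
        "informative": y * 3.0 + rng.normal(0, 0.3, n),
        "constant": np.full(n, 7.0),
        "noise_a": rng.normal(0, 2.0, n),
    }
    cols["dup_of_noise_a"] = cols["noise_a"] * 1.0
    cols["weak"] = y * 0.5 + rng.normal(0, 1.0, n)
    return pd.DataFrame(cols), y


class TestSelection:
    def test_constant_column_dropped_at_stage_1(self, rng):
        X, y = _toy_matrix(rng)
        report = fit_selection(X, y, k=3)
        assert "constant" in report.dropped_low_variance

    def test_duplicate_column_dropped_at_stage_2_keeping_earlier(self, rng):
        X, y = _toy_matrix(rng)
        report = fit_selection(X, y, k=5)
        assert ("dup_of_noise_a", "noise_a") in report.dropped_collinear
        assert "noise_a" not in [d for d, _ in report.dropped_collinear]

    def test_defaults_select_20_of_48(self, small_segments):
        segs = [s for lst in small_segments.values() for s in lst]
        X, y, _ = extract_feature_matrix(segs, 50.0)
        report = fit_selection(X, y)
        survivors = 48 - len(report.dropped_low_variance) - len(report.dropped_collinear)
        assert survivors >= 20
        assert len(report.selected) == 20

    def test_f_statistic_matches_direct_anova(self, small_segments):
        """Implementation F vs the between/within mean-square formula."""
        segs = [s for lst in small_segments.values() for s in lst]
        X, y, _ = extract_feature_matrix(segs, 50.0)
        report = fit_selection(X, y)
        for name in report.selected:
            x = X[name].to_numpy()
            groups = [x[y == 0], x[y == 1]]
            grand = x.mean()
            ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
            df_b, df_w = len(groups) - 1, len(x) - len(groups)
            f_direct = (ss_between / df_b) / (ss_within / df_w)
            assert report.f_statistic[name] == pytest.approx(f_direct, rel=1e-9)

    def test_refit_is_pure_function_of_inputs(self, rng):
        X, y = _toy_matrix(rng)
        a = fit_selection(X, y, k=3)
        b = fit_selection(X, y, k=3)
        assert a == b

    def test_stage_order_matters(self, rng):
        """Variance-then-correlation differs from correlation-then-variance:
        a low-variance column correlated with a high-variance one changes
        which partner survives depending on ordering."""
        n = 40
        y = np.array([0, 1] * (n // 2))
        base = rng.normal(0, 1.0, n)
        X = pd.DataFrame(
            {
                "tiny": base * 0.01,  # variance ~1e-4 < 0.1, |r|=1 with 'big'
                "big": base * 5.0,
                "other": rng.normal(0, 1.0, n),
            }
        )
        report = fit_selection(X, y, k=3)
        # pipeline order: stage 1 removes 'tiny' first, so 'big' is never
        # examined against it and survives stage 2
        assert "tiny" in report.dropped_low_variance
        assert report.dropped_collinear == []
        assert "big" in report.f_statistic
        # reversed order would have dropped 'big' as the later collinear
        # partner of 'tiny'; assert the crafted matrix really discriminates
        corr = abs(np.corrcoef(X["tiny"], X["big"])[0, 1])
        assert corr > 0.95

    def test_all_features_dropped_raises_with_attrition(self):
        X = pd.DataFrame({"c1": np.full(10, 1.0), "c2": np.full(10, 2.0)})
        y = np.array([0, 1] * 5)
        with pytest.raises(ValidationError, match="stage"):
            fit_selection(X, y)

    def test_single_class_labels_rejected(self, rng):
        X, _ = _toy_matrix(rng)
        with pytest.raises(ValidationError):
            fit_selection(X, np.zeros(len(X), dtype=int))


class TestApplySelection:
    def test_apply_restricts_and_orders(self, small_segments):
        segs = [s for lst in small_segments.values() for s in lst]
        X, y, _ = extract_feature_matrix(segs, 50.0)
        report = fit_selection(X, y)
        out = apply_selection(report, X)
        assert list(out.columns) == report.selected
        assert out.shape == (len(X), 20)

    def test_apply_to_single_segment(self, small_segments):
        segs = [s for lst in small_segments.values() for s in lst]
        X, y, _ = extract_feature_matrix(segs, 50.0)
        report = fit_selection(X, y)
        single = apply_selection(report, X.iloc[[0]])
        assert single.shape == (1, 20)

    def test_missing_column_is_schema_error(self, rng):
        X, y = _toy_matrix(rng)
        report = fit_selection(X, y, k=2)
        with pytest.raises(SchemaError, match=report.selected[0]):
            apply_selection(report, X.drop(columns=[report.selected[0]]))

    def test_report_round_trips_through_json(self, rng, tmp_path):
        X, y = _toy_matrix(rng)
        report = fit_selection(X, y, k=3)
        path = tmp_path / "sel.json"
        report.to_json(path)
        back = SelectionReport.from_json(path)
        assert back == report
        pd.testing.assert_frame_equal(apply_selection(back, X), apply_selection(report, X))
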