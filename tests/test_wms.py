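"""The WMS index, sigmoid score, 1-4 scale, and the cohort refitting paths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sixmwt.wms import (
    WMSModel,
    fit_sigmoid,
    fit_wms_line,
    published_model,
    wms_index,
    wms_scale,
    wms_sigmoid,
)

# published cohort group means (SL, SC, 6MWEE)
FRAIL_MEANS = (0.52, 1.88, 11.10)
NON_FRAIL_MEANS = (0.67, 2.12, 21.48)


def _index_reference(sl, sc, ee):
    return 0.064 * sl + 0.189 * sc + 0.859 * ee + 1.554


class TestPublishedModel:
    def test_validates_and_carries_published_constants(self):
        m = published_model()
        assert m.w_ee == 0.859
        assert (m.w_sl, m.w_sc, m.intercept) == (0.064, 0.189, 1.554)
        assert (m.a, m.b) == (1.198, 18.388)
        assert m.scale_bounds == (0.01, 0.50, 0.95)
        assert m.input_convention == "raw" and m.provenance == "published"

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            WMSModel(w_sl=1, w_sc=1, w_ee=1, intercept=0, a=-1.0, b=0.0)
        with pytest.raises(ValueError, match="scale_bounds"):
            WMSModel(w_sl=1, w_sc=1, w_ee=1, intercept=0,
                     scale_bounds=(0.5, 0.2, 0.9))


class TestIndexAndSigmoid:
    def test_frail_group_mean_index(self):
        m = published_model()
        got = wms_index(m, *FRAIL_MEANS)
        assert got == pytest.approx(_index_reference(*FRAIL_MEANS), abs=1e-12)
        assert got == pytest.approx(11.48, abs=0.005)

    def test_zero_inputs_give_intercept(self):
        assert wms_index(published_model(), 0, 0, 0) == pytest.approx(1.554)

    def test_linearity_about_intercept(self):
        m = published_model()
        x = np.array([0.6, 2.0, 20.0])
        lhs = wms_index(m, *(2.5 * x)) - m.intercept
        rhs = 2.5 * (wms_index(m, *x) - m.intercept)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_score_at_center_is_exactly_half(self):
        m = published_model()
        assert wms_sigmoid(m, m.b) == 0.5

    def test_frail_mean_scores_below_weakest_boundary(self):
        m = published_model()
        s = wms_sigmoid(m, wms_index(m, *FRAIL_MEANS))
        assert s < 0.01

    def test_strictly_increasing(self):
        m = published_model()
        grid = np.linspace(10, 26, 200)
        assert np.all(np.diff(wms_sigmoid(m, grid)) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            wms_sigmoid(published_model(), float("nan"))


class TestScale:
    @pytest.mark.parametrize("s,level", [
        (0.005, 1), (0.3, 2), (0.7, 3), (0.97, 4),
        (0.50, 3), (0.95, 3), (0.01, 2),
    ])
    def test_levels_and_boundaries(self, s, level):
        assert wms_scale(s) == level

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.1, 1.1])
    def test_scores_outside_open_interval_rejected(self, s):
        with pytest.raises(ValueError):
            wms_scale(s)

    @settings(max_examples=200, derandomize=True)
    @given(w=st.floats(0, 30), dw=st.floats(0, 5))
    def test_scale_of_sigmoid_monotone(self, w, dw):
        m = published_model()
        assert wms_scale(wms_sigmoid(m, w + dw)) >= wms_scale(wms_sigmoid(m, w))


MEANS = np.array([0.6, 2.0, 18.0])


def _cloud(seed, n=60, r_target=0.85, v=None):
    """Points on a line in mean-normalized space plus isotropic noise chosen
    so that sqrt(variance explained) matches r_target in expectation."""
    rng = np.random.default_rng(seed)
    if v is None:
        v = np.abs(rng.normal(size=3))
    v = v / np.linalg.norm(v)
    s2 = (1 - r_target**2) / (3 * r_target**2 - 1)
    t = rng.normal(0, 1, n)
    Z = 1.0 + np.outer(t, v) + rng.normal(0, np.sqrt(s2), (n, 3))
    return Z * MEANS, v


def _fitted_axis(model):
    v = np.array([model.w_sl, model.w_sc, model.w_ee]) * np.array(model.means)
    return v / np.linalg.norm(v)


def _truth_axis(v, model):
    u = (v * MEANS) / np.array(model.means)
    return u / np.linalg.norm(u)


class TestFitWmsLine:
    def test_exact_line_recovered(self):
        rng = np.random.default_rng(0)
        v = np.array([0.5, 0.6, 0.62])
        v /= np.linalg.norm(v)
        X = (1.0 + np.outer(rng.normal(0, 1, 60), v)) * MEANS
        m = fit_wms_line(X[:, 0], X[:, 1], X[:, 2])
        assert abs(_fitted_axis(m) @ _truth_axis(v, m)) > 1 - 1e-9
        assert m.r == pytest.approx(1.0, abs=1e-9)

    def test_r_recovered_within_tolerance_over_seeds(self):
        rs = []
        for seed in range(100):
            X, _ = _cloud(1000 + seed)
            rs.append(fit_wms_line(X[:, 0], X[:, 1], X[:, 2]).r)
        assert np.mean(rs) == pytest.approx(0.85, abs=0.05)

    def test_axis_direction_unbiased(self):
        # parameter-recovery: the mean fitted axis over 100 seeds points
        # within 5 degrees of the generating axis
        v = np.array([0.55, 0.6, 0.58])
        v /= np.linalg.norm(v)
        dirs = []
        for seed in range(100):
            X, _ = _cloud(1000 + seed, v=v)
            m = fit_wms_line(X[:, 0], X[:, 1], X[:, 2])
            vh = _fitted_axis(m)
            vt = _truth_axis(v, m)
            dirs.append(vh if vh @ vt >= 0 else -vh)
        mean_dir = np.mean(dirs, axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        vt = v / np.linalg.norm(v)  # sample means converge to MEANS, so spaces agree
        angle = np.degrees(np.arccos(min(1.0, abs(mean_dir @ vt))))
        assert angle < 5.0

    def test_projection_matches_direct_svd(self):
        X, _ = _cloud(7)
        m = fit_wms_line(X[:, 0], X[:, 1], X[:, 2])
        # independent projection oracle: SVD of the centered normalized cloud
        Z = X / X.mean(axis=0) - 1.0
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        axis = vt[0] if vt[0].sum() > 0 else -vt[0]
        got = wms_index(m, X[:, 0], X[:, 1], X[:, 2])
        np.testing.assert_allclose(got, Z @ axis, atol=1e-9)

    def test_degenerate_cloud_rejected(self):
        X = np.tile(MEANS, (10, 1))
        with pytest.raises(ValueError):
            fit_wms_line(X[:, 0], X[:, 1], X[:, 2])
        with pytest.raises(ValueError, match="4 subjects"):
            fit_wms_line([0.5, 0.6], [2.0, 2.1], [15.0, 16.0])

    def test_ols_variant_needs_and_uses_response(self):
        X, v = _cloud(11)
        with pytest.raises(ValueError, match="response"):
            fit_wms_line(X[:, 0], X[:, 1], X[:, 2], method="ols")
        y = X @ np.array([1.0, 2.0, 3.0]) + 5.0
        m = fit_wms_line(X[:, 0], X[:, 1], X[:, 2], method="ols", response=y)
        assert m.r == pytest.approx(1.0, abs=1e-9)
        assert m.provenance == "refit"


class TestFitSigmoid:
    @staticmethod
    def _cohort(seed, a=1.198, b=18.388, n=200):
        rng = np.random.default_rng(seed)
        w = rng.uniform(b - 4, b + 4, n)
        p = 1.0 / (1.0 + np.exp(-a * (w - b)))
        labels = rng.uniform(size=n) < p
        six_mwd = np.where(labels, 450.0, 350.0)  # encode labels as distances
        return w, six_mwd

    def test_parameters_recovered_within_10pct(self):
        a_hat, b_hat = [], []
        for seed in range(20):
            w, d = self._cohort(2000 + seed)
            a, b = fit_sigmoid(w, d)
            a_hat.append(a)
            b_hat.append(b)
        assert abs(np.median(a_hat) - 1.198) / 1.198 < 0.10
        assert abs(np.median(b_hat) - 18.388) / 18.388 < 0.10

    def test_separated_gap_puts_center_in_gap(self):
        w = np.r_[np.linspace(10, 14, 30), np.linspace(20, 24, 30)]
        d = np.r_[np.full(30, 300.0), np.full(30, 450.0)]
        _, b = fit_sigmoid(w, d)
        assert 14 < b < 20

    def test_center_scores_exactly_half(self):
        w, d = self._cohort(5)
        a, b = fit_sigmoid(w, d)
        model = WMSModel(w_sl=0, w_sc=0, w_ee=0, intercept=0, a=a, b=b)
        assert wms_sigmoid(model, b) == 0.5

    def test_shift_equivariance(self):
        w, d = self._cohort(9)
        a0, b0 = fit_sigmoid(w, d)
        a1, b1 = fit_sigmoid(w + 3.5, d)
        assert a1 == pytest.approx(a0, rel=1e-4)
        assert b1 == pytest.approx(b0 + 3.5, rel=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both label classes"):
            fit_sigmoid(np.linspace(10, 20, 50), np.full(50, 500.0))
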