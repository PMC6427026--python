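"""Worm-like-chain mechanics: trace measurement, the closed form, the fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibrilmetrics as fm
from fibrilmetrics.exceptions import ParameterError
from fibrilmetrics.mechanics import P_MAX_UM
from fibrilmetrics.scales import BOLTZMANN_JK


class TestMeasureTrace:
    @pytest.mark.parametrize("vertices, L, D", [
        ([(0, 0), (1, 0), (2, 0)], 2.0, 2.0),
        ([(0, 0), (1, 0), (1, 1)], 2.0, np.sqrt(2)),
        ([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)], 4.0, 0.0),  # closed square
    ])
    def test_contour_and_end_to_end(self, vertices, L, D):
        got_L, got_D = fm.measure_trace(fm.FibrilTrace(np.array(vertices, float)))
        assert got_L == pytest.approx(L)
        assert got_D == pytest.approx(D)

    def test_short_or_degenerate_traces_rejected(self):
        with pytest.raises(ParameterError):
            fm.FibrilTrace(np.array([[0.0, 0.0]]))
        with pytest.raises(ParameterError):
            fm.FibrilTrace(np.array([[0.0, 0.0], [0.0, 0.0]]))


class TestClosedForm:
    def test_frozen_values(self):
        # rigid, intermediate and flexible regimes of the 2D chain
        assert fm.wlc_expected_sq_end_to_end(0.01, 6.7) == pytest.approx(
            9.99751e-5, rel=1e-5)
        assert fm.wlc_expected_sq_end_to_end(6.7, 6.7) == pytest.approx(
            38.2573, rel=1e-5)
        assert fm.wlc_expected_sq_end_to_end(670.0, 6.7) == pytest.approx(
            17596.88, rel=1e-6)

    def test_rigid_limit_series(self):
        # D^2 -> L^2 - L^3/(6P) for L << P
        L, P = 0.01, 6.7
        assert fm.wlc_expected_sq_end_to_end(L, P) == pytest.approx(
            L**2 - L**3 / (6 * P), rel=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(L=st.floats(0.01, 100.0), P=st.floats(0.01, 100.0),
           bump=st.floats(0.01, 1.0))
    def test_monotone_in_both_arguments_and_bounded(self, L, P, bump):
        base = fm.wlc_expected_sq_end_to_end(L, P)
        assert 0.0 < base < L**2
        assert fm.wlc_expected_sq_end_to_end(L + bump, P) > base
        assert fm.wlc_expected_sq_end_to_end(L, P + bump) > base

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ParameterError):
            fm.wlc_expected_sq_end_to_end(0.0, 6.7)
        with pytest.raises(ParameterError):
            fm.wlc_expected_sq_end_to_end(1.0, -1.0)


class TestBendingRigidity:
    def test_reference_values(self):
        assert fm.bending_rigidity(6.7, 300.0) == pytest.approx(2.775e-26, rel=2e-4)
        assert fm.bending_rigidity(0.0, 300.0) == 0.0
        assert fm.bending_rigidity(1.0, 300.0) == pytest.approx(
            BOLTZMANN_JK * 300 * 1e-6, rel=1e-12)

    def test_linear_in_both_arguments(self):
        b = fm.bending_rigidity(2.0, 150.0)
        assert fm.bending_rigidity(4.0, 150.0) == pytest.approx(2 * b)
        assert fm.bending_rigidity(2.0, 300.0) == pytest.approx(2 * b)

    def test_negative_persistence_rejected(self):
        with pytest.raises(ParameterError):
            fm.bending_rigidity(-1.0, 300.0)


class TestFit:
    @pytest.mark.parametrize("P", [0.5, 6.7, 50.0])
    def test_exact_model_recovery(self, P):
        L = np.linspace(0.5, 10.0, 30)
        D = np.sqrt(fm.wlc_expected_sq_end_to_end(L, P))
        res = fm.fit_persistence_length(np.column_stack([L, D]), n_bootstrap=0)
        assert res.persistence_length_um == pytest.approx(P, rel=1e-6)
        # rigidity identity holds exactly
        assert res.bending_rigidity_nm2 == pytest.approx(
            res.persistence_length_um * 1e-6 * BOLTZMANN_JK * 300.0, rel=1e-12)

    def test_straight_fibrils_hit_documented_cap(self):
        L = np.linspace(1.0, 8.0, 20)
        with pytest.warns(UserWarning, match="rigid-limit cap"):
            res = fm.fit_persistence_length(np.column_stack([L, L]), n_bootstrap=0)
        assert res.at_upper_bound
        assert res.persistence_length_um >= 0.99 * P_MAX_UM

    def test_too_few_observations_rejected(self):
        with pytest.raises(ParameterError):
            fm.fit_persistence_length([(1.0, 0.9)])

    def test_end_to_end_exceeding_contour_rejected(self):
        with pytest.raises(ParameterError):
            fm.fit_persistence_length([(1.0, 1.1), (2.0, 1.5)])

    def test_bootstrap_is_seeded_and_plausible(self):
        traces = fm.generate_trace_ensemble(6.7, 124, (1.0, 8.0), seed=7)
        model = fm.WormLikeChainModel.from_traces(traces)
        a = model.fit(n_bootstrap=50, seed=3)
        b = model.fit(n_bootstrap=50, seed=3)
        np.testing.assert_array_equal(a.bootstrap_samples, b.bootstrap_samples)
        assert 0.05 < a.bootstrap_se_um < 5.0

    def test_estimator_bias_small_over_replicates(self):
        """Mean fitted P over 200 seeded ensembles (n = 124 fibrils) stays
        within 2% of the true 6.7 um when fibrils span a couple of
        persistence lengths (contour lengths 2-12 um)."""
        fits = []
        for s in range(200):
            traces = fm.generate_trace_ensemble(6.7, 124, (2.0, 12.0), seed=s)
            model = fm.WormLikeChainModel.from_traces(traces)
            fits.append(model.fit(n_bootstrap=0).persistence_length_um)
        assert np.mean(fits) == pytest.approx(6.7, rel=0.02)

    def test_summary_and_prediction_consistency(self):
        traces = fm.generate_trace_ensemble(6.7, 60, (1.0, 8.0), seed=5)
        res = fm.WormLikeChainModel.from_traces(traces).fit(n_bootstrap=30, seed=0)
        text = res.summary()
        assert "persistence length" in text and "bending rigidity" in text
        assert res.predict(1.0) == pytest.approx(fm.wlc_expected_sq_end_to_end(
            1.0, res.persistence_length_um))
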