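"""Signal-model, truncation, joint-fit, reference-fit, and SD-map tests."""

import math
import warnings

import numpy as np
import pytest

from saturn import (
    FitParams,
    SignalSeries,
    TissueParams,
    build_saturn_protocol,
    compute_sd,
    eval_signal_model,
    fit_maps,
    fit_sasha,
    fit_saturn,
    fit_t2prep,
    fit_t2star_multiecho,
    truncate_echoes,
)
from saturn.fitting import DegenerateSeriesError, FitResult


def series_from_model(protocol, params: FitParams) -> SignalSeries:
    coords = protocol.sample_coordinates()
    mags = eval_signal_model(coords[:, 1], coords[:, 2], coords[:, 3], params)
    return SignalSeries(coords[:, 0], coords[:, 1], coords[:, 2], coords[:, 3], mags)


class TestEvalSignalModel:
    def test_all_exponentials_collapse(self):
        p = FitParams(A=1.0, B=0.1, T1=1500, T2=40, T2star=25)
        assert eval_signal_model(math.inf, 0.0, 0.0, p) == pytest.approx(1.1)

    def test_zero_recovery_leaves_only_offset(self):
        p = FitParams(A=1.0, B=0.1, T1=1500, T2=40, T2star=25)
        assert eval_signal_model(0.0, 0.0, 2.0, p) == pytest.approx(
            0.1 * math.exp(-2.0 / 25.0)
        )

    def test_hand_computed_value(self):
        # (1 - e^-0.4) e^-0.04 + 0.1 e^-0.04, verified independently
        p = FitParams(A=1.0, B=0.1, T1=1500, T2=40, T2star=25)
        assert eval_signal_model(600.0, 0.0, 1.0, p) == pytest.approx(
            0.41283196198441413, abs=1e-12
        )


class TestTruncation:
    def _series(self, mags):
        n = len(mags)
        return SignalSeries(
            contrast_index=np.ones(n),
            TS=np.full(n, math.inf),
            T2p=np.zeros(n),
            TE=np.arange(1.0, n + 1.0),
            magnitude=np.asarray(mags, float),
        )

    def test_trailing_noise_floor_dropped(self):
        reduced, n = truncate_echoes(self._series([10, 8, 6, 1.5, 1.0]), 1.0, k=2)
        assert n == 2 and len(reduced) == 3

    def test_zero_noise_leaves_series_unchanged(self, clean_series):
        reduced, n = truncate_echoes(clean_series, 0.0)
        assert n == 0 and len(reduced) == len(clean_series)

    def test_suffix_only_semantics(self):
        # an interior dip below threshold is kept because a later echo is above
        reduced, n = truncate_echoes(self._series([10, 8, 1.5, 6, 1.0]), 1.0, k=2)
        assert len(reduced) == 4 and n == 1

    def test_minimum_three_echoes_retained(self):
        reduced, _ = truncate_echoes(self._series([0.1, 0.1, 0.1, 0.1, 0.1]), 1.0, k=2)
        assert len(reduced) == 3


class TestJointFit:
    def test_exact_model_round_trip(self, baseline_protocol):
        truth = FitParams(A=1.0, B=0.05, T1=1500, T2=40, T2star=30)
        fit = fit_saturn(series_from_model(baseline_protocol, truth))
        assert fit.converged
        for name in ("A", "B", "T1", "T2", "T2star"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-3
            )

    def test_exact_model_round_trip_random_draws(self, baseline_protocol):
        rng = np.random.default_rng(42)
        for _ in range(50):
            truth = FitParams(
                A=rng.uniform(0.5, 2.0),
                B=rng.uniform(0.0, 0.2),
                T1=rng.uniform(800, 2200),
                T2=rng.uniform(20, 120),
                T2star=rng.uniform(5, 80),
            )
            fit = fit_saturn(series_from_model(baseline_protocol, truth))
            assert fit.params.T1 == pytest.approx(truth.T1, rel=1e-3)
            assert fit.params.T2 == pytest.approx(truth.T2, rel=1e-3)
            assert fit.params.T2star == pytest.approx(truth.T2star, rel=1e-3)

    def test_degenerate_series_raises(self, baseline_protocol):
        coords = baseline_protocol.sample_coordinates()
        zero = SignalSeries(
            coords[:, 0], coords[:, 1], coords[:, 2], coords[:, 3],
            np.zeros(len(coords)),
        )
        with pytest.raises(DegenerateSeriesError):
            fit_saturn(zero)

    def test_insufficient_coordinates_rejected(self):
        n = 6
        series = SignalSeries(
            contrast_index=np.repeat([1, 2], 3),
            TS=np.full(n, 100.0),
            T2p=np.zeros(n),
            TE=np.tile([1.0, 2.0, 3.0], 2),
            magnitude=np.linspace(1, 0.5, n),
        )
        with pytest.raises(ValueError):
            fit_saturn(series)


class TestReferenceFits:
    def test_sasha_round_trip(self):
        TS = np.array([103.0, 300.0, 600.0, math.inf])
        S = 1.0 * (1 - 1.0 * np.exp(-TS / 1000.0))
        S[np.isinf(TS)] = 1.0
        T1, A, B = fit_sasha(TS, S)
        assert T1 == pytest.approx(1000.0, rel=1e-6)
        assert A == pytest.approx(1.0, rel=1e-6)
        assert B == pytest.approx(1.0, rel=1e-6)

    def test_sasha_infinite_ts_pins_amplitude(self):
        TS = np.array([103.0, 600.0, math.inf])
        S = np.array([0.2, 0.6, 1.7])
        _, A, _ = fit_sasha(TS, S)
        assert A == pytest.approx(1.7, rel=0.01)

    def test_sasha_two_point_degenerate(self):
        with pytest.raises(ValueError):
            fit_sasha([103.0, 600.0], [0.2, 0.6])

    def test_t2prep_round_trip(self):
        T2p = np.array([0.0, 25.0, 50.0, math.inf])
        S = 1.0 * np.exp(-T2p / 45.0) + 0.1
        S[np.isinf(T2p)] = 0.1
        T2, A, B = fit_t2prep(T2p, S)
        assert T2 == pytest.approx(45.0, rel=1e-6)
        assert A == pytest.approx(1.0, rel=1e-6)
        assert B == pytest.approx(0.1, rel=1e-6)

    def test_t2prep_two_parameter_fallback_biases_up(self):
        T2p = np.array([0.0, 25.0, 50.0, math.inf])
        S = 1.0 * np.exp(-T2p / 45.0) + 0.1
        S[np.isinf(T2p)] = 0.1
        T2_3p, _, _ = fit_t2prep(T2p, S)
        with pytest.warns(UserWarning):
            T2_2p, _, _ = fit_t2prep(T2p[:3], S[:3])
        assert T2_2p > T2_3p  # dropping the offset weighting inflates T2

    def test_t2star_multiecho_round_trip(self):
        TE = np.linspace(1.6, 16.3, 8)
        S = 1.0 * np.exp(-TE / 25.0)
        T2star, A = fit_t2star_multiecho(TE, S)
        assert T2star == pytest.approx(25.0, rel=1e-9)
        assert A == pytest.approx(1.0, rel=1e-9)

    def test_t2star_loglinear_matches_nonlinear_noise_free(self):
        from saturn.fitting import _loglinear_decay

        TE = np.linspace(1.6, 16.3, 8)
        S = 0.7 * np.exp(-TE / 33.0)
        A_log, tau_log = _loglinear_decay(TE, S)
        T2star, A = fit_t2star_multiecho(TE, S)
        assert T2star == pytest.approx(tau_log, rel=1e-6)
        assert A == pytest.approx(A_log, rel=1e-6)

    def test_t2star_single_echo_rejected(self):
        with pytest.raises(ValueError):
            fit_t2star_multiecho([2.0], [1.0])

    def test_t2star_truncation_restores_accuracy(self):
        TE = np.linspace(1.6, 16.3, 8)
        S = 1.0 * np.exp(-TE / 5.0)
        floored = np.maximum(S, 0.07)  # emulate a noise floor on the last echoes
        biased, _ = fit_t2star_multiecho(TE, floored)
        truncated, _ = fit_t2star_multiecho(TE, floored, noise_sd=0.04, truncation_k=2)
        assert abs(truncated - 5.0) < abs(biased - 5.0)


class TestComputeSD:
    def test_constant_model_closed_form(self):
        # S = A at 4 samples with sigma = 1: SD(A) = sigma / sqrt(N) = 0.5
        J = np.ones((4, 1))
        fit = FitResult(
            params=FitParams(1, 0, 1000, 50, 25),
            residuals=np.zeros(4), covariance=None, converged=True,
            n_truncated_echoes=0, rss=0.0, jacobian=J, noise_sd=1.0,
        )
        cov = 1.0 * np.linalg.inv(J.T @ J)
        assert math.sqrt(cov[0, 0]) == pytest.approx(0.5)

    def test_noise_free_fit_has_negligible_sd(self, baseline_protocol):
        truth = FitParams(A=1.0, B=0.05, T1=1500, T2=40, T2star=30)
        fit = fit_saturn(series_from_model(baseline_protocol, truth))
        sds = compute_sd(fit)
        assert sds["T1"] < 1e-4 and sds["T2"] < 1e-5 and sds["T2star"] < 1e-5

    def test_external_noise_sd_scales_linearly(self, clean_series):
        fit = fit_saturn(clean_series)
        sd1 = compute_sd(fit, noise_sd=0.01)
        sd2 = compute_sd(fit, noise_sd=0.02)
        assert sd2["T2star"] == pytest.approx(2 * sd1["T2star"], rel=1e-9)

    def test_unconverged_fit_rejected(self):
        fit = FitResult(
            params=FitParams(1, 0, 1000, 50, 25),
            residuals=np.zeros(4), covariance=None, converged=False,
            n_truncated_echoes=0, rss=0.0, jacobian=None,
        )
        with pytest.raises(ValueError):
            compute_sd(fit)


class TestFitMaps:
    def _stack(self, protocol, tissues, labels):
        from saturn import simulate_acquisition

        coords = protocol.sample_coordinates()
        stack = np.zeros(labels.shape + (len(coords),))
        for lab, tissue in tissues.items():
            series = simulate_acquisition(protocol, tissue)
            stack[labels == lab] = series.magnitude
        return stack, coords

    def test_two_compartment_round_trip(self, baseline_protocol):
        labels = np.zeros((6, 6), int)
        labels[:3] = 1
        labels[3:] = 2
        tissues = {
            1: TissueParams(T1=1400, T2=45, T2star=30),
            2: TissueParams(T1=1700, T2=60, T2star=20),
        }
        stack, coords = self._stack(baseline_protocol, tissues, labels)
        maps = fit_maps(stack, coords[:, 1], coords[:, 2], coords[:, 3])
        for lab, tissue in tissues.items():
            sel = labels == lab
            assert np.nanmax(np.abs(maps.T1[sel] / tissue.T1 - 1)) < 0.02
            assert np.nanmax(np.abs(maps.T2[sel] / tissue.T2 - 1)) < 0.02
            assert np.nanmax(np.abs(maps.T2star[sel] / tissue.T2star - 1)) < 0.02

    def test_uniform_phantom_gives_constant_maps(self, baseline_protocol):
        labels = np.ones((3, 3), int)
        stack, coords = self._stack(
            baseline_protocol, {1: TissueParams(T1=1500, T2=50, T2star=25)}, labels
        )
        maps = fit_maps(stack, coords[:, 1], coords[:, 2], coords[:, 3])
        assert np.ptp(maps.T1) == pytest.approx(0.0, abs=1e-9)

    def test_empty_mask_is_not_an_error(self, baseline_protocol):
        coords = baseline_protocol.sample_coordinates()
        stack = np.zeros((4, 4, len(coords)))
        maps = fit_maps(
            stack, coords[:, 1], coords[:, 2], coords[:, 3],
            mask=np.zeros((4, 4), bool),
        )
        assert not maps.mask.any()
        assert np.isnan(maps.T1).all()

    def test_failed_voxels_flagged_not_fatal(self, baseline_protocol):
        labels = np.zeros((2, 2), int)
        labels[0, 0] = 1
        stack, coords = self._stack(
            baseline_protocol, {1: TissueParams(T1=1500, T2=50, T2star=25)}, labels
        )
        maps = fit_maps(stack, coords[:, 1], coords[:, 2], coords[:, 3])
        assert maps.mask[0, 0]
        assert maps.mask.sum() == 1  # all-zero voxels skipped, no exception
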