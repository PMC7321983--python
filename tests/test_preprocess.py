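"""Interpolation, smoothing, epoching and baseline normalization."""

import numpy as np
import pytest

from fusmap.cortex import make_cortex
from fusmap.doppler import DopplerSeries
from fusmap.events import (
    EventLog,
    TimingConfig,
    eccentricity_stimuli,
    make_event_log,
)
from fusmap.hemodynamics import HemodynamicModel
from fusmap.preprocess import (
    PreprocParams,
    epoch_and_normalize,
    interpolate_temporal,
    preprocess,
    response_mean,
    smooth3d,
    smoothing_kernel,
)
from fusmap.simulate import simulate_cbv_series


def _series(images, dt=1.0):
    return DopplerSeries(images=np.asarray(images, float), dt=dt)


def _flat_series(level=100.0, shape=(3, 4), n=40):
    return _series(np.full(shape + (n,), level))


def _one_trial_log(t_onset=20.0, stim=None):
    import pandas as pd

    stim = stim or eccentricity_stimuli()
    table = pd.DataFrame(
        {
            "trial_id": [0],
            "t_onset": [t_onset],
            "condition_id": [0],
            "stimulus_kind": ["eccentricity"],
            "stim_duration": [0.5],
            "correct": [True],
        }
    )
    return EventLog(table, stim)


class TestInterpolation:
    def test_constant_series_unchanged(self):
        out = interpolate_temporal(_flat_series(), 10)
        assert out.dt == pytest.approx(0.1)
        assert np.allclose(out.images, 100.0)

    def test_knot_values_preserved(self, rng):
        series = _series(rng.uniform(50, 150, (2, 3, 12)))
        out = interpolate_temporal(series, 10)
        assert np.allclose(out.images[:, :, ::10], series.images)

    def test_cubic_polynomial_reproduced(self):
        """Cubic splines are exact on cubics away from the boundary."""
        t = np.arange(20.0)
        poly = 500.0 + 3.0 * t - 0.5 * t**2 + 0.02 * t**3
        series = _series(poly[None, None, :])
        out = interpolate_temporal(series, 10)
        t_fine = out.times
        expected = 500.0 + 3.0 * t_fine - 0.5 * t_fine**2 + 0.02 * t_fine**3
        interior = (t_fine >= 2) & (t_fine <= 17)
        assert np.allclose(out.images[0, 0, interior], expected[interior],
                           rtol=1e-9, atol=1e-6)

    def test_too_short_series_refused(self):
        with pytest.raises(ValueError, match="at least 4"):
            interpolate_temporal(_flat_series(n=3), 10)


class TestSmoothing:
    def test_unit_dc_gain(self):
        out = smooth3d(_flat_series(level=42.0))
        assert np.allclose(out.images, 42.0, rtol=1e-12)

    def test_impulse_response_is_normalized_kernel(self):
        images = np.zeros((7, 7, 7))
        images[3, 3, 3] = 1.0
        out = smooth3d(_series(images))
        k = smoothing_kernel((3, 3, 3), 0.65)
        assert k.sum() == pytest.approx(1.0)
        assert np.allclose(out.images[2:5, 2:5, 2:5], k)
        assert out.images.sum() == pytest.approx(1.0)

    def test_noise_variance_reduction_matches_kernel_norm(self, rng):
        """White noise variance shrinks by sum(w_i^2) (analytic oracle)."""
        k = smoothing_kernel((3, 3, 3), 0.65)
        expected = np.sum(k**2)
        noise = rng.standard_normal((50, 50, 44)) + 10.0
        out = smooth3d(_series(noise))
        interior = out.images[2:-2, 2:-2, 2:-2]
        assert interior.var() / noise[2:-2, 2:-2, 2:-2].var() == pytest.approx(
            expected, rel=0.05
        )


class TestEpochingAndNormalization:
    def test_flat_series_gives_zero_tensor(self):
        tensor = epoch_and_normalize(
            _flat_series(n=40), _one_trial_log(20.0)
        )
        assert np.allclose(tensor.data, 0.0)

    def test_step_to_120pct_baseline(self):
        images = np.full((2, 2, 40), 100.0)
        images[:, :, 20:] = 120.0
        tensor = epoch_and_normalize(_series(images), _one_trial_log(20.0))
        post = tensor.rel_time >= 0
        assert np.allclose(tensor.data[:, :, post, 0], 20.0, atol=1e-4)
        pre = tensor.rel_time < 0
        assert np.allclose(tensor.data[:, :, pre, 0], 0.0, atol=1e-4)

    def test_baseline_window_mean_is_zero(self, ecc_setup):
        _, _, tensor = ecc_setup
        base = (tensor.rel_time < 0) & (tensor.rel_time >= -5.0)
        means = tensor.data[:, :, base, :].mean(axis=2)
        assert np.max(np.abs(means)) < 1e-4  # float32 tensor

    def test_trial_near_session_start_dropped(self):
        # a 2-s onset cannot host the 5-s baseline: the trial drops with a
        # warning, and with no trial left epoching fails loudly
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(ValueError, match="no trial"):
                epoch_and_normalize(_flat_series(n=40), _one_trial_log(2.0))

    def test_only_correct_trials_epoched(self):
        import pandas as pd

        stim = eccentricity_stimuli()
        table = pd.DataFrame(
            {
                "trial_id": [0, 1],
                "t_onset": [15.0, 28.0],
                "condition_id": [0, 0],
                "stimulus_kind": ["eccentricity"] * 2,
                "stim_duration": [0.5] * 2,
                "correct": [True, False],
            }
        )
        tensor = epoch_and_normalize(_flat_series(n=45), EventLog(table, stim))
        assert tensor.n_trials == 1
        assert tensor.trial_id[0] == 0

    def test_generator_amplitude_recovered(self):
        """Noiseless 16% trial: tensor peaks at 16 +- 1% at 2.5 +- 0.2 s
        (oracle: closed-form kernel evaluation)."""
        from scipy.ndimage import binary_erosion

        cortex = make_cortex(shape=(12, 24), thickness_mm=1.0,
                             od_column_width=520.0)
        stim = eccentricity_stimuli(n_conditions=1, ecc_range=(7.0, 10.0))
        log = make_event_log(
            stim, 3, timing=TimingConfig(t_start=19.5, extra_gap_s=6.0), seed=0
        )
        h = HemodynamicModel(response_amplitude=16.0, tuning_width_ecc=1.5)
        series = simulate_cbv_series(cortex, log, h, noise_sd=0.0, seed=0)
        tensor = preprocess(series, log, protocol="fig1")
        # an interior pixel (smoothing must not mix in off-ribbon zeros)
        interior = binary_erosion(cortex.mask)
        pref = np.where(interior, cortex.ecc_pref, np.inf)
        iz, ix = np.unravel_index(np.argmin(np.abs(pref - 8.5)), cortex.shape)
        trace = tensor.data[iz, ix, :, 0]
        t_peak = tensor.rel_time[np.argmax(trace)]
        assert t_peak == pytest.approx(2.5, abs=0.2)
        assert trace.max() == pytest.approx(16.0, abs=1.0)


class TestResponseMean:
    def test_constant_window(self):
        images = np.full((2, 2, 40), 100.0)
        images[:, :, 22:] = 110.0  # +10% from t=22 on (onset 20)
        tensor = epoch_and_normalize(_series(images), _one_trial_log(20.0))
        resp = response_mean(tensor, (2.0, 3.0))
        assert np.allclose(resp, 10.0, atol=1e-6)

    def test_linear_ramp_gives_midpoint(self):
        n = 40
        images = np.tile(np.ones(n) * 100.0, (2, 2, 1))
        t = np.arange(n, dtype=float)
        ramp = np.clip(10.0 * (t - 22.0), 0.0, 10.0)  # 0 -> 10% over [22, 23]
        images = images * (1.0 + ramp / 100.0)
        tensor = epoch_and_normalize(_series(images), _one_trial_log(20.0))
        resp = response_mean(tensor, (2.0, 3.0))
        assert np.allclose(resp, 5.0, atol=0.5)

    def test_matches_rectangle_rule_on_raw_samples(self, ecc_setup):
        """Window mean after 10x interpolation stays within interpolation
        error of the rectangle rule on the raw 1-Hz samples."""
        cortex, stim, tensor = ecc_setup
        resp = response_mean(tensor, (2.0, 3.0))
        raw_sel = np.isin(tensor.rel_time.round(6), [2.0, 3.0])
        raw_mean = tensor.data[:, :, raw_sel, :].mean(axis=2)
        # the interpolated window mean deviates from the coarse 2-point
        # rectangle rule by less than 0.5% CBV on smooth responses
        active = np.abs(resp) > 1.0
        assert np.median(np.abs((resp - raw_mean)[active])) < 0.5

    def test_window_outside_epoch_rejected(self):
        tensor = epoch_and_normalize(_flat_series(n=40), _one_trial_log(20.0))
        with pytest.raises(ValueError, match="window"):
            response_mean(tensor, (9.0, 12.0))


def test_operation_order_regression(ecc_setup):
    """Permuting smooth/epoch changes outputs by < 1% CBV on smooth data
    (away from the epoch's temporal edges, where the kernel support differs)."""
    from scipy.ndimage import convolve

    from fusmap.preprocess import smoothing_kernel

    cortex, stim, _ = ecc_setup
    log = make_event_log(stim, 2, timing=TimingConfig(extra_gap_s=4.0), seed=5)
    series = simulate_cbv_series(cortex, log, HemodynamicModel(),
                                 noise_sd=0.0, seed=5)
    params = PreprocParams()
    canonical = epoch_and_normalize(
        smooth3d(interpolate_temporal(series, 10), params), log, params
    )
    # permuted: epoch first, then smooth each trial volume
    unsmoothed = epoch_and_normalize(interpolate_temporal(series, 10), log, params)
    k = smoothing_kernel(params.smooth_shape, params.smooth_sd)
    permuted = np.stack(
        [
            convolve(unsmoothed.data[:, :, :, i].astype(float), k, mode="nearest")
            for i in range(unsmoothed.n_trials)
        ],
        axis=3,
    )
    interior = slice(2, -2)
    diff = np.abs(canonical.data[:, :, interior, :] - permuted[:, :, interior, :])
    assert diff.max() < 1.0  # < 1% CBV anywhere in the epoch interior
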