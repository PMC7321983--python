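"""Ocular-dominance maps, layer profiles, bandwidths and spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusmap.odmap import (
    LayerProfile,
    find_extrema,
    layer_profile,
    layer_selectivity_table,
    layer_spectrum,
    mean_bandwidth,
    od_band_frequencies,
    od_from_trials,
    od_map,
    segment_layers,
    shuffle_control,
    spectral_index,
    standardize_map,
)
from fusmap.pipeline import ribbon_boundary_paths
from fusmap.preprocess import response_mean


def _profile(values, pitch=100.0, fit=None):
    values = np.asarray(values, float)
    return LayerProfile(
        distance_um=pitch * (np.arange(len(values)) + 0.5),
        values=values,
        fit=values - values.mean() if fit is None else fit,
        pitch_um=pitch,
        layer="IV",
        n_raw=len(values),
    )


@pytest.fixture(scope="module")
def od_analysis(od_cortex, od_tensor):
    """OD map + shuffle null + segmentation from the shared session."""
    resp = response_mean(od_tensor, "od")
    contra = np.moveaxis(resp[:, :, od_tensor.condition_id == 0], 2, 0)
    ipsi = np.moveaxis(resp[:, :, od_tensor.condition_id == 1], 2, 0)
    od = od_from_trials(contra, ipsi, region=od_cortex.mask)
    null = shuffle_control(contra, ipsi, region=od_cortex.mask)
    top, bottom = ribbon_boundary_paths(od_cortex)
    seg = segment_layers(top, bottom, od_cortex.shape, od_cortex.pixel_pitch)
    return od, null, seg


class TestStandardize:
    def test_already_standard_unchanged(self, rng):
        x = rng.standard_normal((6, 8))
        x = (x - x.mean()) / x.std()
        assert np.allclose(standardize_map(x), x, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(5.0, 3.0, (6, 8))
        assert np.allclose(standardize_map(3.0 * x + 7.0), standardize_map(x))

    def test_hand_computed_3x3(self):
        x = np.arange(9, dtype=float).reshape(3, 3)
        z = standardize_map(x)
        expected = (x - 4.0) / x.std()
        assert np.allclose(z, expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            standardize_map(np.ones((3, 3)))


class TestOdMap:
    def test_equal_eyes_give_zero(self, rng):
        z = rng.standard_normal((5, 5))
        assert np.allclose(od_map(z, z).od_index, 0.0)

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal((2, 5, 5))
        assert np.allclose(od_map(a, b).od_index, -od_map(b, a).od_index)

    def test_recovers_column_phase_in_layer_iv(self, od_cortex, od_analysis):
        """Map sign agrees with the generating od_phase on >90% of
        layer-IV pixels at pixel SNR ~5."""
        od, _, seg = od_analysis
        sel = seg.layer_mask("IV") & od_cortex.mask
        agree = np.sign(od.od_index[sel]) == od_cortex.od_phase[sel]
        assert agree.mean() > 0.90


class TestShuffleControl:
    def test_columns_cancel_in_noiseless_scene(self, rng):
        """Eye-antisymmetric columnar signal vanishes in the even/odd map
        while the true contra-ipsi map keeps it."""
        texture = rng.normal(10.0, 2.0, (12, 20))
        phase = np.where(np.arange(20) % 4 < 2, 1.0, -1.0)[None, :]
        contra = np.stack([texture + 3.0 * phase] * 4)
        ipsi = np.stack([texture - 3.0 * phase] * 4)
        true = od_from_trials(contra, ipsi)
        null = shuffle_control(contra, ipsi)
        assert np.allclose(null.od_index, 0.0, atol=1e-9)
        assert np.nanstd(true.od_index) > 0.5
        assert null.shuffled and not true.shuffled

    def test_shuffled_spectral_index_below_true(self, od_analysis):
        od, null, seg = od_analysis
        si_true = spectral_index(layer_spectrum(layer_profile(od, seg, "IV")))
        si_null = spectral_index(layer_spectrum(layer_profile(null, seg, "IV")))
        assert si_null < si_true

    def test_requires_two_blocks_per_eye(self, rng):
        one = rng.standard_normal((1, 4, 4))
        two = rng.standard_normal((2, 4, 4))
        with pytest.raises(ValueError, match="two blocks"):
            shuffle_control(one, two)


class TestSegmentLayers:
    def test_parallel_paths_linear_depth(self):
        top = np.array([[1.0, 0.0], [1.0, 7.0]])
        bottom = np.array([[5.0, 0.0], [5.0, 7.0]])
        seg = segment_layers(top, bottom, (60, 60), pixel_pitch=(0.1, 0.11))
        # rows between 1 and 5 mm depth: depth fraction rises linearly
        rows = np.arange(60) * 0.1 + 0.05
        inside = (rows >= 1.0) & (rows <= 5.0)
        expected = (rows[inside] - 1.0) / 4.0
        observed = seg.depth[inside, 30]
        assert np.allclose(observed, expected, atol=0.01)

    def test_mid_depth_is_layer_iv(self):
        top = np.array([[1.0, 0.0], [1.0, 7.0]])
        bottom = np.array([[5.0, 0.0], [5.0, 7.0]])
        seg = segment_layers(top, bottom, (60, 60))
        mid_row = int((1.0 + 0.5 * 4.0) / 0.1)  # depth fraction 0.5
        from fusmap.cortex import layer_code

        assert seg.layer_index[mid_row, 30] == layer_code("IV")

    def test_curved_paths_match_dense_oracle(self):
        """Depth from KD-tree projection matches brute-force nearest-point
        distances on densely sampled curved boundaries."""
        x = np.linspace(0.0, 7.0, 40)
        top = np.column_stack([1.5 + 0.5 * np.sin(x), x])
        bottom = np.column_stack([4.5 + 0.5 * np.sin(x), x])
        seg = segment_layers(top, bottom, (60, 64))
        # oracle at a handful of pixels
        xf = np.linspace(0.0, 7.0, 4000)
        topf = np.column_stack([1.5 + 0.5 * np.sin(xf), xf])
        botf = np.column_stack([4.5 + 0.5 * np.sin(xf), xf])
        rng = np.random.default_rng(0)
        pts = np.argwhere(seg.mask)[rng.choice(seg.mask.sum(), 20, replace=False)]
        for iz, ix in pts:
            p = np.array([(iz + 0.5) * 0.1, (ix + 0.5) * 0.11])
            dt = np.min(np.linalg.norm(topf - p, axis=1))
            db = np.min(np.linalg.norm(botf - p, axis=1))
            assert seg.depth[iz, ix] == pytest.approx(dt / (dt + db), abs=0.02)

    def test_crossing_paths_rejected(self):
        top = np.array([[1.0, 0.0], [5.0, 7.0]])
        bottom = np.array([[5.0, 0.0], [1.0, 7.0]])
        with pytest.raises(ValueError, match="cross"):
            segment_layers(top, bottom, (60, 60))


class TestLayerProfile:
    def test_constant_od_gives_flat_centered_profile(self, od_cortex, od_analysis):
        _, _, seg = od_analysis
        from fusmap.odmap import ODMap

        od = ODMap(od_index=np.where(od_cortex.mask, 1.7, np.nan))
        prof = layer_profile(od, seg, "IV")
        assert np.allclose(prof.values, 1.7, atol=1e-9)
        assert np.allclose(prof.fit, 0.0, atol=1e-6)

    def test_sinusoid_survives_resampling(self, od_cortex, od_analysis):
        """1,000-um period at 100-um pitch: < 2% amplitude loss."""
        _, _, seg = od_analysis
        from fusmap.odmap import ODMap

        phase = 2 * np.pi * seg.arc_length / 1000.0
        od = ODMap(od_index=np.where(od_cortex.mask, np.sin(phase), np.nan))
        prof = layer_profile(od, seg, "IV", pitch_um=100.0)
        spec = layer_spectrum(prof)
        # amplitude from the profile itself
        amp = (prof.values.max() - prof.values.min()) / 2.0
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_origin_at_first_in_roi_column(self, od_cortex, od_analysis):
        od, _, seg = od_analysis
        roi = np.zeros(od_cortex.shape, bool)
        roi[:, 40:90] = True
        prof = layer_profile(od, seg, "IV", roi=roi)
        assert prof.distance_um[0] == pytest.approx(prof.pitch_um / 2.0)

    def test_too_few_samples_rejected(self, od_analysis):
        od, _, seg = od_analysis
        roi = np.zeros(od.od_index.shape, bool)
        roi[:, :3] = True
        with pytest.raises(ValueError):
            layer_profile(od, seg, "IV", roi=roi)


class TestExtremaAndBandwidth:
    def test_full_sinusoid_extrema_found(self):
        x = np.arange(0, 6000, 100.0)
        y = np.sin(2 * np.pi * x / 1000.0)
        prof = _profile(y, fit=y - y.mean())
        maxima, minima = find_extrema(prof)
        assert len(maxima) == 6
        assert len(minima) in (5, 6)

    def test_small_amplitude_fails_min_abs(self):
        x = np.arange(0, 6000, 100.0)
        y = 0.2 * np.sin(2 * np.pi * x / 1000.0)
        maxima, minima = find_extrema(_profile(y, fit=y))
        assert len(maxima) == 0 and len(minima) == 0

    def test_matches_brute_force_prominence_scan(self, rng):
        """Oracle: exhaustive prominence computation on every local max."""
        y = rng.normal(0, 1.0, 80)
        prof = _profile(y, fit=y)
        maxima, _ = find_extrema(prof, min_prominence=0.75, min_abs=0.25)
        brute = []
        for i in range(1, 79):
            if y[i] > y[i - 1] and y[i] > y[i + 1] and y[i] > 0.25:
                # prominence: climb down both sides to the higher key saddle
                left = y[:i]
                right = y[i + 1 :]
                higher_l = np.nonzero(left >= y[i])[0]
                lo_l = left[higher_l[-1] :].min() if len(higher_l) else left.min()
                higher_r = np.nonzero(right >= y[i])[0]
                lo_r = right[: higher_r[0] + 1].min() if len(higher_r) else right.min()
                if y[i] - max(lo_l, lo_r) >= 0.75:
                    brute.append(i)
        assert list(maxima) == brute

    def test_sinusoid_bandwidth_is_half_period(self):
        x = np.arange(0, 8000, 100.0)
        y = np.sin(2 * np.pi * x / 1000.0)
        prof = _profile(y, fit=y)
        bw, sem = mean_bandwidth(prof)
        assert bw == pytest.approx(500.0, abs=10.0)
        assert sem < 10.0

    def test_two_extrema_give_single_half_distance(self):
        x = np.arange(0, 1600, 100.0)
        y = np.sin(2 * np.pi * x / 1000.0)
        prof = _profile(y, fit=y)
        maxima = np.array([2, 12])
        bw, sem = mean_bandwidth(prof, maxima=maxima, minima=np.array([]))
        assert bw == pytest.approx(500.0)
        assert sem == 0.0

    def test_insufficient_extrema_rejected(self):
        prof = _profile(np.zeros(20))
        with pytest.raises(ValueError, match="bandwidth"):
            mean_bandwidth(prof, maxima=np.array([3]), minima=np.array([7]))


class TestSpectrum:
    def test_band_endpoints(self):
        lo, hi = od_band_frequencies((350.0, 700.0))
        assert lo == pytest.approx(7.1429e-4, rel=1e-4)
        assert hi == pytest.approx(1.4286e-3, rel=1e-4)

    def test_cosine_peak_at_expected_frequency(self):
        x = np.arange(0, 11000, 100.0)
        y = np.cos(2 * np.pi * x / 1100.0)
        spec = layer_spectrum(_profile(y))
        peak = spec.frequency[np.argmax(spec.magnitude)]
        df = spec.frequency[1] - spec.frequency[0]
        assert abs(peak - 1.0 / 1100.0) <= df

    def test_constant_profile_energy_at_dc(self):
        spec = layer_spectrum(_profile(np.full(64, 2.0)))
        assert np.argmax(spec.magnitude) <= 1  # smeared by the 3-pt average
        assert spectral_index(spec) == pytest.approx(0.0, abs=0.05)

    def test_matches_naive_dft_oracle(self, rng):
        y = rng.normal(0, 1, 50)
        mag = np.abs(np.fft.rfft(y))
        naive = np.array(
            [
                abs(sum(y[n] * np.exp(-2j * np.pi * k * n / 50) for n in range(50)))
                for k in range(26)
            ]
        )
        assert np.allclose(mag, naive, atol=1e-8)

    def test_in_band_cosine_has_high_index(self):
        # 16 whole periods in the window keep spectral leakage negligible
        x = np.arange(0, 17600, 100.0)
        y = np.cos(2 * np.pi * x / 1100.0)
        spec = layer_spectrum(_profile(y))
        assert spectral_index(spec) > 0.8

    def test_white_noise_index_matches_flat_spectrum(self, rng):
        """Flat magnitude spectrum: index ~ band width / Nyquist ~ 0.143."""
        vals = [
            spectral_index(layer_spectrum(_profile(rng.normal(0, 1, 128))))
            for _ in range(150)
        ]
        lo, hi = od_band_frequencies()
        expected = (hi - lo) / 5.0e-3  # Nyquist at 100-um pitch
        assert np.mean(vals) == pytest.approx(expected, abs=0.03)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 100.0))
    def test_index_in_unit_interval_and_scale_invariant(self, seed, scale):
        y = np.random.default_rng(seed).normal(0, 1, 64)
        si = spectral_index(layer_spectrum(_profile(y)))
        si_scaled = spectral_index(layer_spectrum(_profile(scale * y)))
        assert 0.0 <= si <= 1.0
        assert si_scaled == pytest.approx(si, rel=1e-9)

    def test_band_beyond_nyquist_rejected(self):
        prof = _profile(np.sin(np.arange(30)), pitch=1000.0)  # Nyquist 5e-4
        with pytest.raises(ValueError, match="Nyquist"):
            spectral_index(layer_spectrum(prof))


class TestLayerSelectivity:
    def test_layer_iv_restricted_modulation_peaks_in_iv(self, hemo):
        """Gain {IV: 1, others: 0}: layer IV spectral index strictly highest."""
        from fusmap.cortex import make_cortex
        from fusmap.events import TimingConfig, make_event_log, od_stimuli
        from fusmap.preprocess import preprocess
        from fusmap.simulate import simulate_cbv_series

        cortex = make_cortex(
            shape=(30, 128), thickness_mm=1.5, od_column_width=520.0,
            od_layer_gain={"IV": 1.0},
        )
        events = make_event_log(
            od_stimuli(), 8, timing=TimingConfig(extra_gap_s=4.0), seed=41
        )
        series = simulate_cbv_series(cortex, events, hemo, noise_sd=2.0, seed=42)
        tensor = preprocess(series, events, protocol="od")
        resp = response_mean(tensor, "od")
        contra = np.moveaxis(resp[:, :, tensor.condition_id == 0], 2, 0)
        ipsi = np.moveaxis(resp[:, :, tensor.condition_id == 1], 2, 0)
        od = od_from_trials(contra, ipsi, region=cortex.mask)
        top, bottom = ribbon_boundary_paths(cortex)
        seg = segment_layers(top, bottom, cortex.shape, cortex.pixel_pitch)
        table = layer_selectivity_table(od, seg, {"full": cortex.mask})
        si = table["full"]
        assert si.idxmax() == "IV"
        assert (si["IV"] > si.drop("IV") + 1e-6).all()

    def test_empty_layer_flagged(self, od_analysis):
        od, _, seg = od_analysis
        roi = np.zeros(od.od_index.shape, bool)
        roi[:, 60:62] = True  # too narrow for any profile
        with pytest.warns(UserWarning):
            table = layer_selectivity_table(od, seg, {"narrow": roi})
        assert table["narrow"].isna().all()
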