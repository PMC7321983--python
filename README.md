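# fusmap

Functional-ultrasound (fUS) visual-cortex mapping: a tested Python
pipeline from ultrafast compound frame blocks, through SVD clutter
filtering and 1-Hz power-Doppler cerebral-blood-volume (CBV) series, to
activation maps, retinotopic preference maps and layer-resolved
ocular-dominance (OD) band quantification.

fUS imaging measures hemodynamics at mesoscale (~100 µm, 1 Hz) through
the whole cortical depth, which makes it possible to map retinotopy and
columnar organization in deep cortical folds that optical methods cannot
reach. Public raw recordings of this kind are not available at desk
scale, so the package ships a synthetic scene generator that emulates
the statistical structure the analysis assumes — a 98 × 128-pixel
imaging plane (0.11 × 0.1 mm pitch), a layered cortical ribbon,
hemodynamic responses peaking ~2.5 s after a 0.5-s stimulus, Gaussian
retinotopic tuning, OD columns of configurable width with laminar
gain, low-rank tissue clutter plus moving blood scatterers — while
retaining ground truth, so every analysis stage is validated by
parameter recovery.

## The analysis in brief

**Doppler formation.** Each 1-s slot holds a block of 200 complex
compounded frames (15 tilted plane waves at a 7,500-Hz PRF → 500
compound frames/s, 0.4 s of data). The block's space × time (Casorati)
matrix is SVD-filtered by truncating its `n_cut` leading singular
components (tissue clutter is low-rank and dominant); the power-Doppler
pixel value is the mean squared magnitude of the filtered samples,
proportional to the number of moving blood scatterers — hence to CBV.

**CBV preprocessing.** The 1-Hz series is cubic-spline upsampled to
0.1 s, smoothed with a normalized 3 × 3 × 3 Gaussian-weighted kernel
(σ = 0.65 voxels), epoched around each correct-trial onset, and
expressed as ΔCBV(t) = 100 · (S(t) − S̄₀)/S̄₀ with S̄₀ the 5-s pre-onset
baseline mean. Responses are window means (2–3 s post-onset for
single-condition maps, 2.5–3 s for retinotopy, 2.5–3.5 s for OD).

**Activation reliability.** Maps are binarized at +10% ΔCBV and
compared with a 20-trial reference map; the proportion of identically
classified pixels versus the number of averaged trials (1–20, 100
random combinations each) is fitted with a Naka–Rushton saturation
p(n) = b + r·nᵉ/(nᵉ + n₅₀ᵉ).

**Retinotopy.** Per pixel, the response vector across stimulus
conditions (9 eccentricity bands of 1.5 DVA, or 12 polar-angle wedges
of 15°) is fitted with a Gaussian over the condition value; pixels with
R² > 0.02 carry the fitted centre as their preference. Raw maps are
cleaned by a 3 × 3 median filter, nearest-valid hole filling and a
1 × 3 lateral mean.

**Ocular dominance.** The OD index is the difference of z-scored
contralateral- and ipsilateral-eye maps. The cortex between two
boundary paths is segmented into layers I, II/III, IV, V, VI by depth
fraction; the OD index along a layer is resampled at 100 µm, spline
fitted, and quantified by (a) the mean half-distance between
consecutive extrema (prominence ≥ 0.75, |value| > 0.25) — the column
bandwidth — and (b) the spectral index, the fraction of the FFT
magnitude spectrum inside the band corresponding to 350–700-µm-wide
columns, i.e. 1/(2·700) to 1/(2·350) µm⁻¹. An even/odd trial shuffle
provides the null map.

## Worked example

Simulate an OD session (520-µm columns, 8 trials per eye, pixel SNR ≈ 5)
and recover the column width and laminar spectral index:

```python
import numpy as np
from fusmap import (make_cortex, make_event_log, od_stimuli, TimingConfig,
                    HemodynamicModel, simulate_cbv_series, preprocess,
                    response_mean)
from fusmap.odmap import (od_from_trials, segment_layers, layer_profile,
                          find_extrema, mean_bandwidth, layer_spectrum,
                          spectral_index)
from fusmap.pipeline import ribbon_boundary_paths

cortex = make_cortex(shape=(30, 128), thickness_mm=1.5, od_column_width=520.0)
events = make_event_log(od_stimuli(), 8, timing=TimingConfig(extra_gap_s=4.0),
                        seed=0)
series = simulate_cbv_series(cortex, events, HemodynamicModel(),
                             noise_sd=3.0, seed=1)
tensor = preprocess(series, events, protocol="od")

resp = response_mean(tensor, "od")
contra = np.moveaxis(resp[:, :, tensor.condition_id == 0], 2, 0)
ipsi = np.moveaxis(resp[:, :, tensor.condition_id == 1], 2, 0)
od = od_from_trials(contra, ipsi, region=cortex.mask)

top, bottom = ribbon_boundary_paths(cortex)
seg = segment_layers(top, bottom, cortex.shape, cortex.pixel_pitch)
profile = layer_profile(od, seg, layer="IV")
bw, sem = mean_bandwidth(profile, *find_extrema(profile))
si = spectral_index(layer_spectrum(profile))
print(f"layer-IV OD bandwidth: {bw:.1f} +- {sem:.1f} um (ground truth 520 um)")
print(f"layer-IV spectral index: {100*si:.1f}% of magnitude in the "
      f"350-700 um column band")
```

Output:

```
layer-IV OD bandwidth: 510.9 +- 18.0 um (ground truth 520 um)
layer-IV spectral index: 48.7% of magnitude in the 350-700 um column band
```

The estimated bandwidth recovers the generated 520-µm columns within a
few percent, and roughly half of the layer-IV spatial-frequency
magnitude falls in the classical OD band — the signature the analysis
is designed to detect.

End-to-end runs are also available from the shell:

```sh
fusmap run --protocol od --seed 1 --out od_run     # report.json + artifacts
fusmap synth --protocol eccentricity --out scene   # scene + events + series
```

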