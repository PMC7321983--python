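"""Ocular-dominance maps, laminar profiles, bandwidths and spectra.

The OD index map is the pixelwise difference of the standardized
(z-scored) contralateral- and ipsilateral-eye activation maps.  Its
laminar structure is quantified by:

* segmenting the cortical ribbon into layers from manually supplied
  top/bottom boundary paths (depth fraction indexed with a Haessler-style
  fraction table);
* collecting the OD index along a layer's arc-length coordinate,
  resampling it on a uniform pitch, centring it and fitting a smoothing
  spline; local extrema of the fit with prominence >= 0.75 and absolute
  value > 0.25 OD-index units mark band centres, and the mean bandwidth
  is the averaged half-distance between consecutive same-sign extrema;
* an FFT magnitude spectrum of the profile (3-sample moving average,
  max-normalized) whose "spectral index" is the fraction of total
  magnitude falling in the spatial-frequency band corresponding to
  350-700 um wide columns, i.e. 1/(2*700) to 1/(2*350) um^-1.

An even/odd block shuffle control sends half of each eye's trials to
each side of the subtraction, cancelling any true eye preference and
providing a null map for the spectral comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .cortex import HAESSLER_FRACTIONS, LAYERS, layer_code

__all__ = [
    "OD_BAND_UM",
    "od_band_frequencies",
    "ODMap",
    "LayerSegmentation",
    "LayerProfile",
    "SpectrumResult",
    "standardize_map",
    "od_map",
    "od_from_trials",
    "shuffle_control",
    "segment_layers",
    "layer_profile",
    "find_extrema",
    "mean_bandwidth",
    "layer_spectrum",
    "spectral_index",
    "layer_selectivity_table",
]

#: Classical OD column-width band (um) used for the spectral index.
OD_BAND_UM = (350.0, 700.0)


def od_band_frequencies(
    width_band_um: tuple[float, float] = OD_BAND_UM,
) -> tuple[float, float]:
    """Spatial-frequency band (um^-1) for a column-width band.

    A column of width w tiles the cortex with period 2w, hence frequency
    1/(2w); the 350-700 um width band maps to
    (1/(2*700), 1/(2*350)) = (7.1429e-4, 1.4286e-3) um^-1.
    """
    lo_w, hi_w = width_band_um
    return 1.0 / (2.0 * hi_w), 1.0 / (2.0 * lo_w)


@dataclass
class ODMap:
    """Standardized contra minus ipsi map (OD index per pixel)."""

    od_index: np.ndarray  # [nz, nx]; NaN outside crop
    crop: np.ndarray | None = None  # bool mask
    shuffled: bool = False  # True for the even/odd control


def standardize_map(values: np.ndarray, region: np.ndarray | None = None) -> np.ndarray:
    """Z-score a map over a region (zero mean, unit SD on the region).

    Values outside the region are set to NaN.  Affine-invariant:
    ``a * x + b`` standardizes to the same map as ``x`` for a > 0.
    """
    values = np.asarray(values, dtype=float)
    if region is None:
        region = np.isfinite(values)
    region = np.asarray(region, bool)
    sel = values[region]
    if sel.size < 2:
        raise ValueError("region must contain more than one pixel")
    sd = sel.std()
    if sd == 0:
        raise ValueError("zero variance over the region")
    out = np.full(values.shape, np.nan)
    out[region] = (values[region] - sel.mean()) / sd
    return out


def od_map(
    contra_z: np.ndarray, ipsi_z: np.ndarray, crop: np.ndarray | None = None
) -> ODMap:
    """Difference of standardized eye maps, optionally cropped."""
    contra_z = np.asarray(contra_z, float)
    ipsi_z = np.asarray(ipsi_z, float)
    if contra_z.shape != ipsi_z.shape:
        raise ValueError("eye maps must share geometry")
    diff = contra_z - ipsi_z
    if crop is not None:
        diff = np.where(crop, diff, np.nan)
    return ODMap(od_index=diff, crop=crop)


def od_from_trials(
    contra_trials: np.ndarray,
    ipsi_trials: np.ndarray,
    region: np.ndarray | None = None,
) -> ODMap:
    """OD map from per-trial response maps [n_trials, nz, nx] per eye."""
    contra = np.asarray(contra_trials, float).mean(axis=0)
    ipsi = np.asarray(ipsi_trials, float).mean(axis=0)
    return od_map(
        standardize_map(contra, region), standardize_map(ipsi, region), crop=region
    )


def shuffle_control(
    contra_trials: np.ndarray,
    ipsi_trials: np.ndarray,
    region: np.ndarray | None = None,
) -> ODMap:
    """Even/odd block shuffle null through the same standardize/subtract path.

    Even-indexed blocks of both eyes are averaged into the first map and
    odd-indexed blocks into the second, so any consistent eye preference
    cancels while acquisition noise propagates unchanged.
    """
    contra_trials = np.asarray(contra_trials, float)
    ipsi_trials = np.asarray(ipsi_trials, float)
    if len(contra_trials) < 2 or len(ipsi_trials) < 2:
        raise ValueError("need at least two blocks per eye")
    even = np.concatenate([contra_trials[0::2], ipsi_trials[0::2]]).mean(axis=0)
    odd = np.concatenate([contra_trials[1::2], ipsi_trials[1::2]]).mean(axis=0)
    out = od_map(
        standardize_map(even, region), standardize_map(odd, region), crop=region
    )
    out.shuffled = True
    return out


@dataclass
class LayerSegmentation:
    """Depth fraction, laminar label and arc coordinate between two paths."""

    depth: np.ndarray  # [nz, nx] in [0, 1], NaN outside the ribbon
    layer_index: np.ndarray  # int8, -1 outside
    arc_length: np.ndarray  # um along the top path, NaN outside
    mask: np.ndarray  # bool, between the paths
    fractions: dict = field(default_factory=lambda: dict(HAESSLER_FRACTIONS))

    def layer_mask(self, layer: str) -> np.ndarray:
        return self.layer_index == layer_code(layer)


def _dense_path(path_mm: np.ndarray, step_mm: float = 0.01):
    path_mm = np.asarray(path_mm, dtype=float)
    seg = np.diff(path_mm, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n = max(int(np.ceil(cum[-1] / step_mm)) + 1, 2)
    s = np.linspace(0.0, cum[-1], n)
    pts = np.column_stack(
        [np.interp(s, cum, path_mm[:, 0]), np.interp(s, cum, path_mm[:, 1])]
    )
    tan = np.gradient(pts, s, axis=0)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return pts, s, tan


def segment_layers(
    top_path_mm: np.ndarray,
    bottom_path_mm: np.ndarray,
    shape: tuple[int, int],
    pixel_pitch: tuple[float, float] = (0.1, 0.11),
    fractions: dict | None = None,
) -> LayerSegmentation:
    """Segment the ribbon between two boundary paths into layers.

    Depth is the relative distance between the nearest points on the top
    (pial) and bottom (white-matter) paths; the laminar label follows the
    fraction table.  Paths are (z, x) polylines in mm, ordered in the
    same lateral direction, and must not cross.
    """
    fractions = fractions or HAESSLER_FRACTIONS
    bounds = np.concatenate([[lo for lo, _ in fractions.values()], [1.0]])
    if not (
        np.isclose(bounds[0], 0.0)
        and np.isclose(bounds[-1], 1.0)
        and np.all(np.diff(sorted(bounds)) >= 0)
    ):
        raise ValueError("layer fractions must partition [0, 1]")
    top_pts, top_s, top_tan = _dense_path(top_path_mm)
    bot_pts, _, bot_tan = _dense_path(bottom_path_mm)
    top_tree = cKDTree(top_pts)
    bot_tree = cKDTree(bot_pts)

    # crossing check: every top sample must lie on the pial side of the
    # bottom path and vice versa
    db, jb = bot_tree.query(top_pts)
    side = (top_pts - bot_pts[jb])[:, 0] * bot_tan[jb][:, 1] - (
        top_pts - bot_pts[jb]
    )[:, 1] * bot_tan[jb][:, 0]
    if np.any(side > 1e-9):
        raise ValueError("boundary paths cross")

    nz, nx = shape
    zc = (np.arange(nz) + 0.5) * pixel_pitch[0]
    xc = (np.arange(nx) + 0.5) * pixel_pitch[1]
    ZC, XC = np.meshgrid(zc, xc, indexing="ij")
    pix = np.column_stack([ZC.ravel(), XC.ravel()])

    d_top, i_top = top_tree.query(pix)
    d_bot, i_bot = bot_tree.query(pix)
    # signed side: positive below the path (towards white matter)
    dt = pix - top_pts[i_top]
    tt = top_tan[i_top]
    side_top = dt[:, 0] * tt[:, 1] - dt[:, 1] * tt[:, 0]
    dbp = pix - bot_pts[i_bot]
    tb = bot_tan[i_bot]
    side_bot = dbp[:, 0] * tb[:, 1] - dbp[:, 1] * tb[:, 0]
    inside = (side_top >= 0) & (side_bot <= 0)

    depth = np.full(nz * nx, np.nan)
    denom = d_top + d_bot
    ok = inside & (denom > 0)
    depth[ok] = d_top[ok] / denom[ok]
    arc = np.full(nz * nx, np.nan)
    arc[ok] = top_s[i_top[ok]] * 1000.0

    layer_index = np.full(nz * nx, -1, dtype=np.int8)
    for name, (lo, hi) in fractions.items():
        sel = ok & (depth >= lo) & (depth < hi if hi < 1.0 else depth <= hi)
        layer_index[sel] = layer_code(name)

    return LayerSegmentation(
        depth=depth.reshape(nz, nx),
        layer_index=layer_index.reshape(nz, nx),
        arc_length=arc.reshape(nz, nx),
        mask=ok.reshape(nz, nx),
        fractions=dict(fractions),
    )


@dataclass
class LayerProfile:
    """OD index along one layer's arc coordinate, uniformly resampled.

    ``distance_um`` starts at the first in-ROI column (left edge);
    ``values`` is the raw binned OD index (uncentred, used for the
    spectrum); ``fit`` is the centred smoothing-spline fit used for
    extrema detection.
    """

    distance_um: np.ndarray
    values: np.ndarray
    fit: np.ndarray
    pitch_um: float
    layer: str
    n_raw: int

    def __len__(self) -> int:
        return len(self.distance_um)


def layer_profile(
    od: ODMap,
    seg: LayerSegmentation,
    layer: str = "IV",
    roi: np.ndarray | None = None,
    pitch_um: float = 100.0,
    lam: float | None = None,
) -> LayerProfile:
    """Collect, resample and spline-fit the OD index along a layer.

    OD values of the layer's pixels (within the optional ROI and the
    map's crop) are averaged into uniform ``pitch_um`` bins of their
    arc-length coordinate; empty interior bins are filled by linear
    interpolation.  The profile is centred and fitted with a smoothing
    spline (generalized cross-validation chooses the penalty when
    ``lam`` is None).
    """
    sel = seg.layer_mask(layer)
    if roi is not None:
        sel = sel & np.asarray(roi, bool)
    sel = sel & np.isfinite(od.od_index)
    if not np.any(sel):
        raise ValueError(f"layer {layer} empty in the ROI")
    x = seg.arc_length[sel]
    y = od.od_index[sel]
    if x.size < 10:
        raise ValueError("fewer than 10 samples along the layer")
    x = x - x.min()  # origin at the first in-ROI column

    n_bins = int(np.floor(x.max() / pitch_um)) + 1
    idx = np.minimum((x / pitch_um).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    grid = pitch_um * (np.arange(n_bins) + 0.5)
    with np.errstate(invalid="ignore"):
        binned = sums / counts
    filled = np.flatnonzero(counts > 0)
    values = np.interp(grid, grid[filled], binned[filled])
    if len(values) < 10:
        raise ValueError("fewer than 10 resampled points along the layer")

    centered = values - values.mean()
    spline = make_smoothing_spline(grid, centered, lam=lam)
    fit = np.asarray(spline(grid))
    return LayerProfile(
        distance_um=grid,
        values=values,
        fit=fit,
        pitch_um=float(pitch_um),
        layer=layer,
        n_raw=int(x.size),
    )


def find_extrema(
    profile: LayerProfile | np.ndarray,
    min_prominence: float = 0.75,
    min_abs: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of qualified maxima and minima of the spline-fitted profile.

    Maxima require prominence >= ``min_prominence`` and value >
    ``min_abs``; minima are symmetric (value < -``min_abs``).
    """
    y = profile.fit if isinstance(profile, LayerProfile) else np.asarray(profile)
    maxima, _ = find_peaks(y, prominence=min_prominence)
    maxima = maxima[y[maxima] > min_abs]
    minima, _ = find_peaks(-y, prominence=min_prominence)
    minima = minima[y[minima] < -min_abs]
    return maxima, minima


def mean_bandwidth(
    profile: LayerProfile,
    maxima: np.ndarray | None = None,
    minima: np.ndarray | None = None,
    min_prominence: float = 0.75,
    min_abs: float = 0.25,
) -> tuple[float, float]:
    """Mean column bandwidth (um) +- SEM from profile extrema.

    Half-distances between consecutive maxima and consecutive minima are
    pooled; with a single half-distance the SEM is reported as 0.
    """
    if maxima is None or minima is None:
        maxima, minima = find_extrema(profile, min_prominence, min_abs)
    x = profile.distance_um
    halves = []
    for ext in (maxima, minima):
        if len(ext) >= 2:
            halves.extend(np.diff(x[ext]) / 2.0)
    if not halves:
        raise ValueError("need two maxima or two minima to estimate bandwidth")
    halves = np.asarray(halves)
    sem = float(halves.std(ddof=1) / np.sqrt(len(halves))) if len(halves) > 1 else 0.0
    return float(halves.mean()), sem


@dataclass
class SpectrumResult:
    """One-sided spatial magnitude spectrum of a layer profile."""

    frequency: np.ndarray  # um^-1
    magnitude: np.ndarray  # moving-average(3), max-normalized
    band: tuple[float, float]  # um^-1
    layer: str | None = None


def layer_spectrum(
    profile: LayerProfile,
    width_band_um: tuple[float, float] = OD_BAND_UM,
) -> SpectrumResult:
    """FFT magnitude spectrum of the raw (uncentred) profile.

    One-sided; smoothed with a 3-sample moving average and normalized by
    its maximum.  DC is retained so a constant profile concentrates all
    magnitude at zero frequency.
    """
    y = profile.values
    freq = np.fft.rfftfreq(len(y), d=profile.pitch_um)
    mag = np.abs(np.fft.rfft(y))
    if len(mag) >= 3:
        kernel = np.ones(3) / 3.0
        mag = np.convolve(mag, kernel, mode="same")
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return SpectrumResult(
        frequency=freq,
        magnitude=mag,
        band=od_band_frequencies(width_band_um),
        layer=profile.layer,
    )


def spectral_index(spectrum: SpectrumResult) -> float:
    """Fraction of total spectral magnitude inside the column band.

    In [0, 1]; invariant to overall profile scaling.  The total includes
    the zero-frequency bin.
    """
    lo, hi = spectrum.band
    nyquist = spectrum.frequency.max()
    if hi > nyquist + 1e-12:
        raise ValueError("band extends beyond the Nyquist frequency")
    total = spectrum.magnitude.sum()
    if total == 0:
        return 0.0
    sel = (spectrum.frequency >= lo) & (spectrum.frequency <= hi)
    return float(spectrum.magnitude[sel].sum() / total)


def layer_selectivity_table(
    od: ODMap,
    seg: LayerSegmentation,
    rois: dict[str, np.ndarray],
    layers: tuple[str, ...] = LAYERS,
    pitch_um: float = 100.0,
    width_band_um: tuple[float, float] = OD_BAND_UM,
    lam: float | None = None,
) -> pd.DataFrame:
    """Spectral index per layer (rows) per ROI (columns).

    Layers empty in an ROI produce NaN cells with a warning.
    """
    out = pd.DataFrame(index=list(layers), columns=list(rois), dtype=float)
    for roi_name, roi in rois.items():
        for layer in layers:
            try:
                prof = layer_profile(od, seg, layer, roi, pitch_um=pitch_um, lam=lam)
            except ValueError as exc:
                warnings.warn(
                    f"layer {layer} / ROI {roi_name}: {exc}", stacklevel=2
                )
                continue
            out.loc[layer, roi_name] = spectral_index(
                layer_spectrum(prof, width_band_um)
            )
    return out
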