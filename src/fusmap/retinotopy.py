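"""Retinotopic preference maps from per-condition activation maps.

For each pixel, the vector of windowed ΔCBV responses across stimulus
conditions is fitted with a Gaussian (plus offset) over the condition
value (DVA for eccentricity, degrees for polar angle, both on a linear
non-wrapping domain).  Pixels with a coefficient of determination above
a small threshold (R^2 > 0.02 against the flat-mean model) are deemed
retinotopically modulated; the fitted Gaussian centre is the pixel's
preference and its SD the tuning bandwidth.  Raw maps are then cleaned
with a 3x3 median filter, nearest-valid hole filling inside the
analysis mask, and a 1x3 lateral mean filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .activation import ActivationMap

__all__ = [
    "TuningFit",
    "PreferenceMap",
    "condition_stack",
    "fit_pixel_tuning",
    "preference_map",
    "postprocess_map",
    "repeatability",
]

R2_THRESHOLD = 0.02


@dataclass
class TuningFit:
    amplitude: float  # % ΔCBV
    center: float  # condition units (DVA or degrees)
    width: float  # Gaussian SD, same units
    offset: float
    r_squared: float

    @property
    def fwhm(self) -> float:
        """Full width at half maximum of the fitted tuning curve."""
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.width


@dataclass
class PreferenceMap:
    """Per-pixel tuning-fit products: centre, width, R^2 and validity."""

    center: np.ndarray  # NaN where invalid
    width: np.ndarray
    r_squared: np.ndarray
    valid: np.ndarray  # bool
    condition_values: np.ndarray
    mask: np.ndarray | None = None  # analysis region (cortex crop)
    postprocessed: bool = False

    @property
    def value_range(self) -> tuple[float, float]:
        return float(self.condition_values.min()), float(self.condition_values.max())


def condition_stack(
    maps: list[ActivationMap | np.ndarray],
    condition_values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-condition activation maps ordered by condition value.

    Returns ``(stack [n_cond, nz, nx], sorted condition values)``.
    """
    if len(maps) < 4:
        raise ValueError("need at least 4 conditions")
    arrays = [
        m.values if isinstance(m, ActivationMap) else np.asarray(m) for m in maps
    ]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"mismatched map shapes: {sorted(shapes)}")
    condition_values = np.asarray(condition_values, dtype=float)
    if len(condition_values) != len(arrays):
        raise ValueError("one condition value per map required")
    order = np.argsort(condition_values)
    return np.stack([arrays[i] for i in order]), condition_values[order]


def _gauss(v, amplitude, center, width, offset):
    return offset + amplitude * np.exp(-0.5 * ((v - center) / width) ** 2)


def _coarse_grid(condition_values: np.ndarray):
    # width floor of half the condition spacing: anything narrower is not
    # identifiable from the sampled tuning curve and invites spike fits
    vmin, vmax = condition_values.min(), condition_values.max()
    step = np.min(np.diff(np.unique(condition_values)))
    centers = np.linspace(vmin, vmax, 4 * len(condition_values) + 1)
    widths = np.geomspace(step / 2.0, (vmax - vmin), 8)
    return centers, widths, step


def _coarse_fit_many(Y: np.ndarray, v: np.ndarray):
    """Vectorized coarse grid fit for many pixels.

    ``Y`` is [n_cond, n_pix]; returns per-pixel arrays
    (sse, amplitude, center, width, offset) for the best grid node.
    """
    centers, widths, _ = _coarse_grid(v)
    n = len(v)
    n_pix = Y.shape[1]
    ys = Y.sum(axis=0)
    best_sse = np.full(n_pix, np.inf)
    best = [np.zeros(n_pix) for _ in range(4)]  # a, c, w, o
    yy = np.einsum("cp,cp->p", Y, Y)
    for c in centers:
        for w in widths:
            g = np.exp(-0.5 * ((v - c) / w) ** 2)
            gg, gs = float(g @ g), float(g.sum())
            det = gg * n - gs * gs
            if det < 1e-12:
                continue
            gy = g @ Y
            a = (gy * n - gs * ys) / det
            o = (gg * ys - gs * gy) / det
            # responses are positive CBV bumps: clamp to a >= 0 (the
            # offset-only solution when the unconstrained amplitude dips)
            neg = a < 0
            a = np.where(neg, 0.0, a)
            o = np.where(neg, ys / n, o)
            # SSE = y.y - 2(a g.y + o y.sum) + a^2 g.g + 2 a o g.sum + n o^2
            sse = (
                yy
                - 2.0 * (a * gy + o * ys)
                + a * a * gg
                + 2.0 * a * o * gs
                + n * o * o
            )
            better = sse < best_sse
            best_sse = np.where(better, sse, best_sse)
            best[0] = np.where(better, a, best[0])
            best[1] = np.where(better, c, best[1])
            best[2] = np.where(better, w, best[2])
            best[3] = np.where(better, o, best[3])
    return np.maximum(best_sse, 0.0), best[0], best[1], best[2], best[3]


def _refine_one(y, v, seed, step):
    """Bounded local refinement of one pixel from a coarse seed."""
    vmin, vmax = v.min(), v.max()

    def resid(theta):
        return _gauss(v, *theta) - y

    sol = least_squares(
        resid,
        list(seed),
        bounds=(
            [0.0, vmin, step / 2.0, -np.inf],
            [np.inf, vmax, 10.0 * (vmax - vmin), np.inf],
        ),
        method="trf",
    )
    return sol.x, float(2.0 * sol.cost)


def fit_pixel_tuning(
    responses: np.ndarray,
    condition_values: np.ndarray,
    refine: bool = True,
) -> TuningFit:
    """Least-squares Gaussian + offset fit of one pixel's tuning curve.

    A coarse, deterministic grid over (centre, width) with closed-form
    amplitude/offset solves seeds a bounded local refinement.  R^2 is
    computed against the flat-mean model; an all-equal response vector
    yields R^2 = 0.
    """
    y = np.asarray(responses, dtype=float)
    v = np.asarray(condition_values, dtype=float)
    if y.size < 4 or not np.all(np.isfinite(y)):
        raise ValueError("need >= 4 finite responses")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return TuningFit(0.0, float(v[np.argmax(y)]), 1.0, float(y.mean()), 0.0)

    _, _, step = _coarse_grid(v)
    sse_arr, a_, c_, w_, o_ = _coarse_fit_many(y[:, None], v)
    sse, a, c, w, o = sse_arr[0], a_[0], c_[0], w_[0], o_[0]
    if refine:
        theta, rss = _refine_one(y, v, (a, c, w, o), step)
        if rss <= sse:
            a, c, w, o = theta
            sse = rss
    r2 = 1.0 - sse / sst
    return TuningFit(float(a), float(c), float(abs(w)), float(o), float(r2))


def preference_map(
    stack: np.ndarray,
    condition_values: np.ndarray,
    r2_threshold: float = R2_THRESHOLD,
    mask: np.ndarray | None = None,
    refine: bool = True,
) -> PreferenceMap:
    """Fit every (masked) pixel's tuning curve and threshold on R^2.

    Pixels with fitted amplitude <= 0 (inverted tuning) are rejected along
    with sub-threshold R^2; valid pixels carry the fitted Gaussian centre
    clamped to the stimulated range.
    """
    n_cond, nz, nx = stack.shape
    v = np.asarray(condition_values, dtype=float)
    if mask is None:
        mask = np.ones((nz, nx), dtype=bool)
    center = np.full((nz, nx), np.nan)
    width = np.full((nz, nx), np.nan)
    r2 = np.full((nz, nx), np.nan)
    vmin, vmax = v.min(), v.max()
    _, _, step = _coarse_grid(v)

    iz, ix = np.nonzero(mask)
    Y = stack[:, iz, ix]  # [n_cond, n_masked]
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    sse, a, c, w, o = _coarse_fit_many(Y, v)
    for k in range(len(iz)):
        if sst[k] == 0.0:
            r2[iz[k], ix[k]] = 0.0
            continue
        ak, ck, wk, ok, ssek = a[k], c[k], w[k], o[k], sse[k]
        if refine:
            theta, rss = _refine_one(Y[:, k], v, (ak, ck, wk, ok), step)
            if rss <= ssek:
                ak, ck, wk, ok = theta
                ssek = rss
        r2k = 1.0 - ssek / sst[k]
        r2[iz[k], ix[k]] = r2k
        if r2k > r2_threshold and ak > 0:
            center[iz[k], ix[k]] = np.clip(ck, vmin, vmax)
            width[iz[k], ix[k]] = abs(wk)
    valid = np.isfinite(center)
    return PreferenceMap(
        center=center,
        width=width,
        r_squared=r2,
        valid=valid,
        condition_values=v,
        mask=mask,
    )


def _nanmedian3(values: np.ndarray) -> np.ndarray:
    """3x3 median over finite neighbours (NaN-aware)."""
    out = np.full_like(values, np.nan)
    nz, nx = values.shape
    for i in range(nz):
        for j in range(nx):
            win = values[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
            finite = win[np.isfinite(win)]
            if finite.size:
                out[i, j] = np.median(finite)
    return out


def postprocess_map(pm: PreferenceMap) -> PreferenceMap:
    """Clean a raw preference map: median filter, hole fill, lateral mean.

    1. 3x3 median over valid pixels (NaN-aware, result kept on valid
       pixels only);
    2. nearest-valid interpolation refills invalid pixels inside the
       analysis mask;
    3. a 1x3 lateral mean (each pixel averaged with its two lateral
       neighbours) smooths the filled map.

    Pixels outside the analysis mask stay untouched (NaN); centres never
    leave the stimulated range.
    """
    mask = pm.mask if pm.mask is not None else np.ones(pm.center.shape, bool)
    center = np.where(pm.valid, pm.center, np.nan)

    med = _nanmedian3(center)
    center = np.where(pm.valid, med, np.nan)

    if np.any(np.isfinite(center)):
        invalid = ~np.isfinite(center)
        _, (iz, ix) = ndimage.distance_transform_edt(invalid, return_indices=True)
        filled = center[iz, ix]
        center = np.where(mask, filled, np.nan)

    padded = np.pad(center, ((0, 0), (1, 1)), mode="edge")
    stackd = np.stack([padded[:, :-2], padded[:, 1:-1], padded[:, 2:]])
    counts = np.sum(np.isfinite(stackd), axis=0)
    center = np.where(
        counts > 0, np.nansum(stackd, axis=0) / np.maximum(counts, 1), np.nan
    )
    center = np.where(mask, center, np.nan)

    vmin, vmax = pm.value_range
    center = np.clip(center, vmin, vmax)
    return replace(
        pm,
        center=center,
        valid=np.isfinite(center),
        postprocessed=True,
    )


def repeatability(
    map_a: PreferenceMap, map_b: PreferenceMap, tol: float = 2.0
) -> float:
    """Percent of jointly valid pixels with |Δ preference| <= ``tol``.

    The session-to-session repeatability statistic (tolerance 2 DVA for
    eccentricity maps).
    """
    if map_a.center.shape != map_b.center.shape:
        raise ValueError("maps must share geometry")
    joint = map_a.valid & map_b.valid
    if not np.any(joint):
        raise ValueError("no jointly valid pixels")
    same = np.abs(map_a.center[joint] - map_b.center[joint]) <= tol
    return float(100.0 * same.mean())
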