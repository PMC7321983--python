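"""Synthetic cortical scene model.

The imaging plane is a ``[nz x nx]`` pixel grid (depth x lateral) with
anisotropic pixel pitch (0.1 mm in depth, 0.11 mm laterally by default,
i.e. a ~10 x 14 mm field at the default 98 x 128 shape).  The cortex is
modelled as a ribbon of constant thickness around a mid-layer polyline;
each in-ribbon pixel carries

* a depth fraction (0 at the pial surface, 1 at the white-matter border),
* a laminar label obtained by indexing the depth fraction with Haessler's
  fraction scheme (layers I, II/III, IV, V, VI),
* an arc-length coordinate (micrometres along the mid-layer path),
* retinotopic preferences (eccentricity in DVA, polar angle in degrees),
* an ocular-dominance phase in {-1, +1} alternating as a square wave of
  half-period ``od_column_width`` along the arc-length coordinate, with a
  per-layer modulation depth (``od_layer_gain``).

All fields are ground truth for downstream recovery tests: the simulator
consumes them and the analysis should get them back.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LAYERS",
    "HAESSLER_FRACTIONS",
    "CortexModel",
    "make_cortex",
    "straight_path",
    "folded_path",
    "layer_code",
]

#: Laminar labels in pial-to-white order.  Code -1 marks off-ribbon pixels.
LAYERS = ("I", "II/III", "IV", "V", "VI")

#: Default depth-fraction boundaries assigning pixels to layers
#: (Haessler-style fractional scheme; configurable, not anatomy-exact).
HAESSLER_FRACTIONS = {
    "I": (0.0, 0.08),
    "II/III": (0.08, 0.35),
    "IV": (0.35, 0.60),
    "V": (0.60, 0.80),
    "VI": (0.80, 1.0),
}

_PATH_STEP_MM = 0.01  # densification step for the mid-layer polyline


def layer_code(name: str) -> int:
    """Integer code of a laminar label (index into :data:`LAYERS`)."""
    return LAYERS.index(name)


@dataclass
class CortexModel:
    """Ground-truth cortical ribbon on the imaging grid.

    Off-ribbon pixels hold NaN in the real-valued images, code -1 in
    ``layer_index`` and 0 in ``od_phase``.
    """

    mask: np.ndarray  # bool [nz, nx]
    pixel_pitch: tuple[float, float]  # (depth, lateral) mm
    depth_fraction: np.ndarray  # float [nz, nx], in [0, 1] on mask
    layer_index: np.ndarray  # int8 [nz, nx], index into LAYERS, -1 off mask
    arc_length: np.ndarray  # float [nz, nx], um along mid-layer path
    ecc_pref: np.ndarray  # float [nz, nx], DVA
    ang_pref: np.ndarray  # float [nz, nx], degrees
    od_phase: np.ndarray  # int8 [nz, nx], +-1 on mask, 0 off
    od_column_width: float  # um, half-period of the od_phase square wave
    od_layer_gain: dict[str, float] = field(default_factory=dict)
    path_mm: np.ndarray | None = None  # mid-layer polyline, (z, x) mm
    thickness_mm: float = 2.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def field_of_view_mm(self) -> tuple[float, float]:
        """(depth, lateral) extent of the imaging plane in mm."""
        nz, nx = self.mask.shape
        return nz * self.pixel_pitch[0], nx * self.pixel_pitch[1]

    def layer_mask(self, layer: str) -> np.ndarray:
        return self.layer_index == layer_code(layer)

    def od_gain_map(self) -> np.ndarray:
        """Per-pixel OD modulation depth from the per-layer gain table."""
        g = np.zeros(self.shape)
        for name, gain in self.od_layer_gain.items():
            g[self.layer_mask(name)] = gain
        return g

    def replace(self, **kwargs) -> "CortexModel":
        return dataclasses.replace(self, **kwargs)


def straight_path(
    depth_mm: float = 3.0, x_span_mm: tuple[float, float] = (0.0, 14.08)
) -> np.ndarray:
    """Horizontal mid-layer polyline at a fixed depth, as (z, x) mm."""
    return np.array([[depth_mm, x_span_mm[0]], [depth_mm, x_span_mm[1]]])


def folded_path(
    depth_mm: float = 2.5,
    fold_depth_mm: float = 4.0,
    x_span_mm: tuple[float, float] = (0.0, 14.08),
    fold_center_mm: float = 9.0,
    fold_width_mm: float = 5.0,
    n: int = 200,
) -> np.ndarray:
    """Mid-layer polyline with a smooth sulcus-like dip (calcarine-flavoured).

    The path runs left to right at ``depth_mm`` and dips by ``fold_depth_mm``
    over a Gaussian bump of width ``fold_width_mm`` centred laterally at
    ``fold_center_mm``.
    """
    x = np.linspace(x_span_mm[0], x_span_mm[1], n)
    z = depth_mm + fold_depth_mm * np.exp(
        -0.5 * ((x - fold_center_mm) / (fold_width_mm / 4.0)) ** 2
    )
    return np.column_stack([z, x])


def _densify(path_mm: np.ndarray, step_mm: float = _PATH_STEP_MM):
    """Resample a polyline at ~``step_mm`` spacing.

    Returns (points [n, 2], cumulative arc length [n] mm, unit tangents [n, 2]).
    """
    path_mm = np.asarray(path_mm, dtype=float)
    if path_mm.ndim != 2 or path_mm.shape[0] < 2 or path_mm.shape[1] != 2:
        raise ValueError("path must be an (n >= 2) x 2 array of (z, x) mm")
    seg = np.diff(path_mm, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        raise ValueError("path contains repeated vertices")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n_dense = max(int(np.ceil(total / step_mm)) + 1, 2)
    s = np.linspace(0.0, total, n_dense)
    z = np.interp(s, cum, path_mm[:, 0])
    x = np.interp(s, cum, path_mm[:, 1])
    pts = np.column_stack([z, x])
    tan = np.gradient(pts, s, axis=0)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return pts, s, tan


def make_cortex(
    shape: tuple[int, int] = (98, 128),
    pixel_pitch: tuple[float, float] = (0.1, 0.11),
    path_mm: np.ndarray | None = None,
    thickness_mm: float = 2.0,
    od_column_width: float = 520.0,
    od_layer_gain: dict[str, float] | None = None,
    ecc_range: tuple[float, float] = (1.5, 15.0),
    ang_range: tuple[float, float] = (0.0, 180.0),
    layer_fractions: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
) -> CortexModel:
    """Build a ground-truth cortical ribbon scene.

    Parameters
    ----------
    shape, pixel_pitch
        Imaging grid (depth x lateral) and pitch in mm per pixel.
    path_mm
        Mid-layer polyline as (z, x) mm vertices; defaults to a straight
        horizontal ribbon through the middle of the field.
    thickness_mm
        Cortical thickness; the ribbon spans +-thickness/2 around the path.
    od_column_width
        Width of one ocular-dominance band in micrometres = half-period of
        the alternating phase along arc length.  Must exceed twice the depth
        pixel pitch, otherwise the columns are unresolvable on the grid.
    od_layer_gain
        Laminar modulation depth of the OD columns, mapping layer name to a
        gain in [0, 1].  Defaults emulate a layer-IV dominated pattern with
        weaker expression in II/III and V.
    ecc_range, ang_range
        Stimulated ranges; preferences vary linearly along arc length
        (eccentricity) and across depth (polar angle is also arc-indexed so
        both protocols see a smooth gradient).
    seed
        Unused by the deterministic geometry; accepted for interface
        symmetry with the stochastic generators.
    """
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    if od_column_width <= 2.0 * pixel_pitch[0] * 1000.0:
        raise ValueError(
            "unresolvable columns: od_column_width must exceed twice the "
            "depth pixel pitch"
        )
    nz, nx = shape
    if path_mm is None:
        path_mm = straight_path(
            depth_mm=nz * pixel_pitch[0] / 2.0,
            x_span_mm=(0.0, nx * pixel_pitch[1]),
        )
    if od_layer_gain is None:
        od_layer_gain = {"I": 0.1, "II/III": 0.6, "IV": 1.0, "V": 0.6, "VI": 0.1}
    fractions = layer_fractions or HAESSLER_FRACTIONS

    pts, s_mm, tan = _densify(np.asarray(path_mm, dtype=float))

    # pixel centres in mm, (z, x)
    zc = (np.arange(nz) + 0.5) * pixel_pitch[0]
    xc = (np.arange(nx) + 0.5) * pixel_pitch[1]
    ZC, XC = np.meshgrid(zc, xc, indexing="ij")
    pix = np.column_stack([ZC.ravel(), XC.ravel()])

    tree = cKDTree(pts)
    _, idx = tree.query(pix)
    d = pix - pts[idx]
    t = tan[idx]
    # signed normal offset: positive below the path (towards white matter)
    # for a left-to-right path; normal = rotate tangent by +90 deg in (z, x)
    signed = d[:, 0] * t[:, 1] - d[:, 1] * t[:, 0]
    half = thickness_mm / 2.0
    mask = (np.abs(signed) <= half).reshape(nz, nx)

    depth_fraction = np.full((nz, nx), np.nan)
    depth_fraction.ravel()[mask.ravel()] = (
        (signed + half) / thickness_mm
    )[mask.ravel()]
    depth_fraction = np.clip(depth_fraction, 0.0, 1.0)

    arc_um = np.full((nz, nx), np.nan)
    arc_um.ravel()[mask.ravel()] = s_mm[idx][mask.ravel()] * 1000.0

    layer_index = np.full((nz, nx), -1, dtype=np.int8)
    for name, (lo, hi) in fractions.items():
        sel = mask & (depth_fraction >= lo) & (
            depth_fraction < hi if hi < 1.0 else depth_fraction <= hi
        )
        layer_index[sel] = layer_code(name)

    od_phase = np.zeros((nz, nx), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        band = np.floor(arc_um / od_column_width)
    od_phase[mask] = np.where(band[mask] % 2 == 0, 1, -1)

    total_um = s_mm[-1] * 1000.0
    ecc_pref = np.full((nz, nx), np.nan)
    ecc_pref[mask] = ecc_range[0] + (ecc_range[1] - ecc_range[0]) * (
        arc_um[mask] / total_um
    )
    ang_pref = np.full((nz, nx), np.nan)
    ang_pref[mask] = ang_range[0] + (ang_range[1] - ang_range[0]) * (
        arc_um[mask] / total_um
    )

    return CortexModel(
        mask=mask,
        pixel_pitch=pixel_pitch,
        depth_fraction=depth_fraction,
        layer_index=layer_index,
        arc_length=arc_um,
        ecc_pref=ecc_pref,
        ang_pref=ang_pref,
        od_phase=od_phase,
        od_column_width=float(od_column_width),
        od_layer_gain=dict(od_layer_gain),
        path_mm=np.asarray(path_mm, dtype=float),
        thickness_mm=float(thickness_mm),
    )
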