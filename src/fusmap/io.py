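"""Container I/O: HDF5 array stores, CSV tables, TIFF map export.

HDF5 layout convention: named datasets per field plus a single JSON
metadata attribute (``meta``) on the root group.  Event logs are plain
CSV (see :mod:`fusmap.events`); 2-D maps export to multi-page TIFF.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import tifffile

from .cortex import CortexModel
from .doppler import Acquisition, DopplerSeries, FrameBlock
from .preprocess import TrialTensor

__all__ = [
    "save_series",
    "load_series",
    "save_blocks",
    "load_blocks",
    "save_cortex",
    "load_cortex",
    "save_tensor",
    "load_tensor",
    "save_maps_tiff",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_meta(group, meta: dict) -> None:
    group.attrs["meta"] = json.dumps(meta, default=str)


def _read_meta(group) -> dict:
    raw = group.attrs.get("meta", "{}")
    return json.loads(raw)


def _save_cortex_group(g, cortex: CortexModel) -> None:
    g.create_dataset("mask", data=cortex.mask)
    g.create_dataset("depth_fraction", data=cortex.depth_fraction)
    g.create_dataset("layer_index", data=cortex.layer_index)
    g.create_dataset("arc_length", data=cortex.arc_length)
    g.create_dataset("ecc_pref", data=cortex.ecc_pref)
    g.create_dataset("ang_pref", data=cortex.ang_pref)
    g.create_dataset("od_phase", data=cortex.od_phase)
    if cortex.path_mm is not None:
        g.create_dataset("path_mm", data=cortex.path_mm)
    _write_meta(
        g,
        {
            "pixel_pitch": list(cortex.pixel_pitch),
            "od_column_width": cortex.od_column_width,
            "od_layer_gain": cortex.od_layer_gain,
            "thickness_mm": cortex.thickness_mm,
        },
    )


def _load_cortex_group(g) -> CortexModel:
    meta = _read_meta(g)
    return CortexModel(
        mask=g["mask"][...].astype(bool),
        pixel_pitch=tuple(meta["pixel_pitch"]),
        depth_fraction=g["depth_fraction"][...],
        layer_index=g["layer_index"][...].astype(np.int8),
        arc_length=g["arc_length"][...],
        ecc_pref=g["ecc_pref"][...],
        ang_pref=g["ang_pref"][...],
        od_phase=g["od_phase"][...].astype(np.int8),
        od_column_width=float(meta["od_column_width"]),
        od_layer_gain=dict(meta["od_layer_gain"]),
        path_mm=g["path_mm"][...] if "path_mm" in g else None,
        thickness_mm=float(meta.get("thickness_mm", 2.0)),
    )


def save_cortex(path, cortex: CortexModel) -> None:
    with h5py.File(path, "w") as f:
        _save_cortex_group(f, cortex)


def load_cortex(path) -> CortexModel:
    with h5py.File(path, "r") as f:
        return _load_cortex_group(f)


def save_series(path, series: DopplerSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=series.images, compression="gzip")
        _write_meta(
            f,
            {
                "pixel_pitch": list(series.pixel_pitch),
                "t0": series.t0,
                "dt": series.dt,
                **series.meta,
            },
        )
        if series.truth is not None:
            _save_cortex_group(f.create_group("truth"), series.truth)


def load_series(path) -> DopplerSeries:
    with h5py.File(path, "r") as f:
        meta = _read_meta(f)
        truth = _load_cortex_group(f["truth"]) if "truth" in f else None
        return DopplerSeries(
            images=f["images"][...],
            pixel_pitch=tuple(meta.pop("pixel_pitch")),
            t0=float(meta.pop("t0")),
            dt=float(meta.pop("dt")),
            meta=meta,
            truth=truth,
        )


def save_blocks(path, blocks: list[FrameBlock]) -> None:
    acq = blocks[0].acquisition
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "frames",
            data=np.stack([b.frames for b in blocks]),
            compression="gzip",
        )
        f.create_dataset("t0", data=np.array([b.t0 for b in blocks]))
        _write_meta(
            f,
            {
                "prf": acq.prf,
                "angle_min": acq.angle_min,
                "angle_max": acq.angle_max,
                "angle_step": acq.angle_step,
                "n_frames_per_block": acq.n_frames_per_block,
            },
        )


def load_blocks(path) -> list[FrameBlock]:
    with h5py.File(path, "r") as f:
        meta = _read_meta(f)
        acq = Acquisition(
            prf=meta["prf"],
            angle_min=meta["angle_min"],
            angle_max=meta["angle_max"],
            angle_step=meta["angle_step"],
            n_frames_per_block=int(meta["n_frames_per_block"]),
        )
        frames = f["frames"][...]
        t0 = f["t0"][...]
        return [
            FrameBlock(frames=frames[i], acquisition=acq, t0=float(t0[i]))
            for i in range(frames.shape[0])
        ]


def save_tensor(path, tensor: TrialTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=tensor.data, compression="gzip")
        f.create_dataset("rel_time", data=tensor.rel_time)
        f.create_dataset("condition_id", data=tensor.condition_id)
        f.create_dataset("trial_id", data=tensor.trial_id)
        f.create_dataset(
            "stimulus_kind", data=np.asarray(tensor.stimulus_kind, dtype=_STR)
        )
        _write_meta(f, {"protocol": tensor.protocol})
        if tensor.truth is not None:
            _save_cortex_group(f.create_group("truth"), tensor.truth)


def load_tensor(path) -> TrialTensor:
    with h5py.File(path, "r") as f:
        meta = _read_meta(f)
        truth = _load_cortex_group(f["truth"]) if "truth" in f else None
        kinds = np.array(
            [s.decode() if isinstance(s, bytes) else s for s in f["stimulus_kind"][...]]
        )
        return TrialTensor(
            data=f["data"][...],
            rel_time=f["rel_time"][...],
            condition_id=f["condition_id"][...],
            trial_id=f["trial_id"][...],
            stimulus_kind=kinds,
            protocol=meta.get("protocol"),
            truth=truth,
        )


def save_maps_tiff(path, maps: list[np.ndarray]) -> None:
    """Write 2-D maps as a multi-page float32 TIFF."""
    pages = np.stack([np.asarray(m, dtype=np.float32) for m in maps])
    tifffile.imwrite(path, pages, photometric="minisblack")
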