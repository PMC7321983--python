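"""Forward simulators: 1-Hz CBV series and raw ultrafast frame blocks.

Two entry points at different levels of the acquisition chain:

``simulate_cbv_series``
    Generates the 1-Hz power-Doppler series directly.  Each pixel's time
    course is ``baseline * (1 + sum of tuned trial responses / 100) +
    noise``; the tuned response of a trial is the hemodynamic kernel
    scaled by a Gaussian tuning weight (retinotopic protocols) or by the
    ocular-dominance phase/eye match and laminar gain (OD protocol).

``simulate_frame_blocks``
    Generates complex ultrafast blocks as the sum of a strong rank<=3
    tissue component (slow sinusoidal temporal signatures) and moving
    blood scatterers whose frame-to-frame phase advance encodes axial
    velocity, so SVD clutter filtering is meaningful and Doppler power
    is proportional to scatterer density.
"""

from __future__ import annotations

import numpy as np

from .cortex import CortexModel
from .doppler import Acquisition, DopplerSeries, FrameBlock
from .events import EventLog
from .hemodynamics import HemodynamicModel

__all__ = ["condition_weight_maps", "simulate_cbv_series", "simulate_frame_blocks"]

SPEED_OF_SOUND_M_S = 1540.0
CENTER_FREQUENCY_HZ = 15e6  # probe centre frequency


def condition_weight_maps(
    cortex: CortexModel,
    events: EventLog,
    hemo: HemodynamicModel,
    amplitude_range: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[int, np.ndarray]:
    """Peak ΔCBV (%) per pixel for every condition present in the log.

    Retinotopic conditions use Gaussian tuning around the pixel
    preference; OD conditions use ``A * (1 + gain * phase * eye) / 2`` so
    a matched eye drives the full amplitude and an unmatched eye drives
    ``A * (1 - gain) / 2``.  Blank trials have zero weight.

    If ``amplitude_range`` is given (e.g. ``(10, 40)`` percent), per-pixel
    peak amplitudes are drawn uniformly from it instead of the constant
    ``hemo.response_amplitude``.
    """
    stimuli = events.stimuli
    if stimuli is None:
        raise ValueError("event log carries no StimulusSet")
    if amplitude_range is not None:
        if rng is None:
            raise ValueError("amplitude_range requires an rng")
        amp = np.where(
            cortex.mask,
            rng.uniform(*amplitude_range, size=cortex.shape),
            0.0,
        )
    else:
        amp = np.where(cortex.mask, hemo.response_amplitude, 0.0)

    maps: dict[int, np.ndarray] = {}
    gain = cortex.od_gain_map()
    for cid in np.unique(events.condition_id):
        if cid < 0:  # blank
            maps[int(cid)] = np.zeros(cortex.shape)
            continue
        value = stimuli.condition_values[cid]
        kind = stimuli.condition_kinds[cid]
        if kind in ("eccentricity", "angular"):
            pref = cortex.ecc_pref if kind == "eccentricity" else cortex.ang_pref
            w = hemo.tuning_weight(value, np.nan_to_num(pref), kind)
        elif kind in ("od_contra", "od_ipsi"):
            eye = 1.0 if kind == "od_contra" else -1.0
            w = (1.0 + gain * cortex.od_phase * eye) / 2.0
        else:
            raise ValueError(f"unknown stimulus kind {kind!r}")
        maps[int(cid)] = amp * np.where(cortex.mask, w, 0.0)
    return maps


def simulate_cbv_series(
    cortex: CortexModel,
    events: EventLog,
    hemo: HemodynamicModel | None = None,
    noise_sd: float = 0.0,
    baseline: float = 1000.0,
    amplitude_range: tuple[float, float] | None = None,
    duration_s: float | None = None,
    tail_s: float = 15.0,
    seed: int | None = None,
) -> DopplerSeries:
    """Simulate the 1-Hz Doppler/CBV series for a session.

    Parameters
    ----------
    noise_sd
        Additive i.i.d. Gaussian noise SD, in percent of baseline (the
        single-trial pixel SNR is ``response_amplitude / noise_sd``).
    baseline
        Mean Doppler power per pixel (arbitrary units); preprocessing
        normalizes it away.
    duration_s
        Session length; defaults to the last onset plus ``tail_s`` so
        every trial has a full response window.

    The generating cortex model is retained on the returned series
    (``series.truth``) for downstream recovery tests.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    hemo = hemo or HemodynamicModel()
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = events.session_end(tail_s)
    n_frames = int(np.ceil(duration_s))
    if events.t_onset[-1] + 10.0 > n_frames:
        raise ValueError("session too short for all events plus a 10-s tail")

    weights = condition_weight_maps(
        cortex, events, hemo, amplitude_range=amplitude_range, rng=rng
    )
    t = np.arange(n_frames, dtype=float)
    frac = np.zeros(cortex.shape + (n_frames,), dtype=float)
    for onset, cid in zip(events.t_onset, events.condition_id):
        w = weights[int(cid)]
        if not np.any(w):
            continue
        k = hemo.kernel(t - onset)
        nz = np.flatnonzero(k > 1e-12)
        if nz.size == 0:
            continue
        frac[:, :, nz] += w[:, :, None] * k[nz][None, None, :]

    images = baseline * (1.0 + frac / 100.0)
    if noise_sd > 0:
        images = images + rng.normal(
            0.0, noise_sd / 100.0 * baseline, size=images.shape
        )
        images = np.maximum(images, 0.0)
    return DopplerSeries(
        images=images,
        pixel_pitch=cortex.pixel_pitch,
        t0=0.0,
        dt=1.0,
        meta={
            "seed": seed,
            "noise_sd": noise_sd,
            "baseline": baseline,
            "generator": "simulate_cbv_series",
        },
        truth=cortex,
    )


def _blood_signals(
    flow_density: float,
    n_pix: int,
    n_frames: int,
    frame_rate: float,
    velocities: tuple[float, float],
    rng: np.random.Generator,
    flow_weight: np.ndarray | None = None,
) -> np.ndarray:
    """Sum of moving-scatterer signals per voxel, [n_pix, n_frames] complex."""
    lam = flow_density * (
        flow_weight if flow_weight is not None else np.ones(n_pix)
    )
    counts = rng.poisson(lam)
    total = int(counts.sum())
    out = np.zeros((n_pix, n_frames), dtype=complex)
    if total == 0:
        return out
    vox = np.repeat(np.arange(n_pix), counts)
    phases = rng.uniform(0.0, 2.0 * np.pi, total)
    speed = rng.uniform(velocities[0], velocities[1], total)
    sign = rng.choice([-1.0, 1.0], total)
    # axial Doppler shift of a scatterer moving at v: f_D = 2 v f0 / c
    f_d = sign * 2.0 * (speed * 1e-3) * CENTER_FREQUENCY_HZ / SPEED_OF_SOUND_M_S
    t = np.arange(n_frames) / frame_rate
    sig = np.exp(1j * (phases[:, None] + 2.0 * np.pi * f_d[:, None] * t[None, :]))
    np.add.at(out, vox, sig)
    return out


def simulate_frame_blocks(
    shape: tuple[int, int],
    n_blocks: int,
    flow_density: float = 2.0,
    tissue_amp: float = 30.0,
    velocities: tuple[float, float] = (1.0, 10.0),
    flow_weight: np.ndarray | None = None,
    tissue_rank: int = 3,
    acquisition: Acquisition | None = None,
    seed: int | None = None,
    include_tissue: bool = True,
) -> list[FrameBlock]:
    """Simulate ultrafast blocks of tissue clutter plus blood scatterers.

    Parameters
    ----------
    flow_density
        Expected number of moving scatterers per voxel (Poisson); expected
        blood power per voxel is proportional to it.
    tissue_amp
        RMS amplitude of each tissue component relative to the RMS of a
        unit-density blood signal.
    velocities
        Axial speed range in mm/s, within (0, 30].
    flow_weight
        Optional [nz, nx] relative vascular density map scaling the local
        scatterer rate (e.g. a cortex mask).
    include_tissue
        Set False to generate the blood-only twin of a block sequence
        (same seed -> identical scatterers), used as the oracle for
        clutter-filter recovery tests.
    """
    if flow_density < 0:
        raise ValueError("flow_density must be nonnegative")
    if not (0.0 < velocities[0] <= velocities[1] <= 30.0):
        raise ValueError("velocities must lie within (0, 30] mm/s")
    acq = acquisition or Acquisition()
    rng = np.random.default_rng(seed)
    nz, nx = shape
    n_pix = nz * nx
    nt = acq.n_frames_per_block
    fr = acq.frame_rate
    fw = None if flow_weight is None else np.asarray(flow_weight, float).ravel()

    # fixed tissue spatial patterns for the whole session (smooth fields)
    n_r = min(tissue_rank, 3)
    u = rng.standard_normal((n_pix, n_r)) + 1j * rng.standard_normal((n_pix, n_r))
    u /= np.linalg.norm(u, axis=0, keepdims=True)
    tissue_freqs = np.array([0.4, 1.1, 2.3])[:n_r]  # Hz, breathing/cardiac-like
    tissue_phase = rng.uniform(0, 2 * np.pi, n_r)
    # scale so each tissue component's RMS is tissue_amp x blood RMS;
    # a unit-density blood voxel has E|s|^2 = flow_density
    blood_rms = np.sqrt(max(flow_density, 1.0))
    t = np.arange(nt) / fr

    blocks = []
    for b in range(n_blocks):
        blood = _blood_signals(
            flow_density, n_pix, nt, fr, velocities, rng, flow_weight=fw
        )
        frames = blood
        if include_tissue and tissue_amp > 0:
            v = np.exp(
                1j
                * (
                    2 * np.pi * tissue_freqs[:, None] * (t[None, :] + b)
                    + tissue_phase[:, None]
                )
            )
            tissue = (u * (tissue_amp * blood_rms * np.sqrt(n_pix))) @ v
            frames = frames + tissue
        blocks.append(
            FrameBlock(frames=frames.reshape(nz, nx, nt), acquisition=acq, t0=float(b))
        )
    return blocks
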