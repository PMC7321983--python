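"""Activation maps and trial-count reliability analysis.

An activation map is the per-pixel mean ΔCBV over a post-onset window,
averaged across a set of trials.  Map reliability versus trial count is
quantified by binarizing maps at a +10% ΔCBV threshold and scoring the
proportion of pixels classified identically to a 20-trial reference map
(true positives + true negatives over all pixels), for 1..20 averaged
trials, 100 random trial combinations each.  The resulting curve is
summarized with a Naka-Rushton saturation fit

    p(n) = baseline + r_max * n^e / (n^e + n50^e).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .preprocess import TrialTensor, response_mean

__all__ = [
    "ActivationMap",
    "ReliabilityCurve",
    "NakaRushtonFit",
    "activation_map",
    "binarize",
    "classification_analysis",
    "fit_naka_rushton",
    "naka_rushton",
    "snr_db",
]

DEFAULT_THRESHOLD = 10.0  # % ΔCBV


@dataclass
class ActivationMap:
    """Trial-averaged ΔCBV image (percent) with provenance."""

    values: np.ndarray  # [nz, nx] % ΔCBV
    n_trials: int
    window: tuple[float, float]
    condition_id: int | None = None


def activation_map(
    tensor: TrialTensor,
    trial_subset: np.ndarray | None = None,
    window: tuple[float, float] | str = "fig1",
) -> ActivationMap:
    """Average the windowed response over a subset of trials."""
    resp = response_mean(tensor, window)
    if trial_subset is None:
        trial_subset = np.arange(tensor.n_trials)
    trial_subset = np.asarray(trial_subset)
    if trial_subset.size == 0:
        raise ValueError("empty trial subset")
    if isinstance(window, str):
        from .preprocess import RESPONSE_WINDOWS

        window = RESPONSE_WINDOWS[window]
    cids = np.unique(tensor.condition_id[trial_subset])
    return ActivationMap(
        values=resp[:, :, trial_subset].mean(axis=2),
        n_trials=int(trial_subset.size),
        window=tuple(window),
        condition_id=int(cids[0]) if cids.size == 1 else None,
    )


def binarize(
    amap: ActivationMap | np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Pixels at or above the ΔCBV threshold (+10% by default)."""
    values = amap.values if isinstance(amap, ActivationMap) else np.asarray(amap)
    return values >= threshold


@dataclass
class NakaRushtonFit:
    r_max: float
    n_50: float
    exponent: float
    baseline: float
    rss: float
    converged: bool = True

    def __call__(self, n: np.ndarray) -> np.ndarray:
        return naka_rushton(n, self.baseline, self.r_max, self.n_50, self.exponent)


@dataclass
class ReliabilityCurve:
    """Proportion of correctly classified pixels vs number of averaged trials."""

    n_averaged: np.ndarray  # 1..20
    proportion_correct: np.ndarray  # grand mean over sessions
    sd: np.ndarray
    per_session: np.ndarray  # [n_sessions, len(n_averaged)]
    fit: NakaRushtonFit | None = field(default=None)


def naka_rushton(n, baseline, r_max, n_50, exponent):
    n = np.asarray(n, dtype=float)
    ne = n**exponent
    return baseline + r_max * ne / (ne + n_50**exponent)


def _session_curve(
    responses: np.ndarray,  # [n_pix, 40]
    rng: np.random.Generator,
    n_reference: int,
    n_combinations: int,
    n_range: np.ndarray,
    threshold: float,
) -> np.ndarray:
    n_trials = responses.shape[1]
    ref_idx = rng.choice(n_trials, size=n_reference, replace=False)
    pool = np.setdiff1d(np.arange(n_trials), ref_idx)
    ref_map = binarize(responses[:, ref_idx].mean(axis=1), threshold)
    out = np.empty(len(n_range))
    for j, n in enumerate(n_range):
        props = np.empty(n_combinations)
        for c in range(n_combinations):
            combo = rng.choice(pool, size=n, replace=False)
            test_map = binarize(responses[:, combo].mean(axis=1), threshold)
            props[c] = np.mean(test_map == ref_map)
        out[j] = props.mean()
    return out


def classification_analysis(
    tensor: TrialTensor,
    condition_id: int | None = None,
    window: tuple[float, float] | str = "fig1",
    threshold: float = DEFAULT_THRESHOLD,
    n_reference: int = 20,
    n_combinations: int = 100,
    n_max: int = 20,
    session_size: int = 40,
    mask: np.ndarray | None = None,
    seed: int | None = None,
) -> ReliabilityCurve:
    """Correct-classification curve against a 20-trial reference map.

    Trials of one condition are split into notional 40-trial sessions
    (a leftover of fewer than 40 trials is dropped with a warning).  Per
    session, 20 random trials form the binarized reference; for each
    n in 1..20, 100 random n-trial combinations drawn from the remaining
    trials (never from the reference set, without replacement within a
    combination) are averaged, binarized at the same threshold and scored
    as the fraction of pixels classified identically to the reference.
    Curves are averaged combinations -> session -> grand mean.
    """
    if condition_id is not None:
        tensor = tensor.for_condition(condition_id)
    resp = response_mean(tensor, window)  # [nz, nx, n_trials]
    if mask is not None:
        resp = resp[mask]  # [n_masked, n_trials]
    else:
        resp = resp.reshape(-1, resp.shape[2])
    n_trials = resp.shape[1]
    if n_trials < session_size:
        raise ValueError(
            f"need at least {session_size} trials of the condition "
            f"(reference {n_reference} + averaging pool), got {n_trials}"
        )
    n_sessions = n_trials // session_size
    if n_trials % session_size:
        warnings.warn(
            f"dropping {n_trials % session_size} leftover trials "
            f"after splitting into {n_sessions} notional sessions",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_range = np.arange(1, n_max + 1)
    per_session = np.stack(
        [
            _session_curve(
                resp[:, s * session_size : (s + 1) * session_size],
                rng,
                n_reference,
                n_combinations,
                n_range,
                threshold,
            )
            for s in range(n_sessions)
        ]
    )
    return ReliabilityCurve(
        n_averaged=n_range,
        proportion_correct=per_session.mean(axis=0),
        sd=per_session.std(axis=0),
        per_session=per_session,
    )


def fit_naka_rushton(
    curve: ReliabilityCurve | tuple[np.ndarray, np.ndarray],
) -> NakaRushtonFit:
    """Deterministic multi-start least-squares Naka-Rushton fit.

    Starts from a fixed grid over (n50, exponent); baseline and r_max
    start from the curve's endpoints.  Bounds keep proportions
    physical (baseline, r_max in [0, 1]; n50 > 0).
    """
    if isinstance(curve, ReliabilityCurve):
        n, p = curve.n_averaged, curve.proportion_correct
    else:
        n, p = curve
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(np.unique(n)) < 4:
        raise ValueError("need at least 4 distinct trial counts to fit")

    def resid(theta):
        baseline, r_max, n_50, exponent = theta
        return naka_rushton(n, baseline, r_max, n_50, exponent) - p

    lo = [0.0, 0.0, 1e-3, 0.1]
    hi = [1.0, 1.5, 1e3, 10.0]
    p0b = float(np.clip(p.min(), 0.0, 1.0))
    p0r = float(np.clip(p.max() - p.min(), 1e-6, 1.5))
    best = None
    for n50_0 in (1.0, 2.0, 4.0, 8.0, 16.0):
        for e0 in (0.5, 1.0, 2.0, 4.0):
            theta0 = [p0b, p0r, n50_0, e0]
            try:
                sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        raise RuntimeError("Naka-Rushton fit failed from every start")
    rss, sol = best
    baseline, r_max, n_50, exponent = sol.x
    return NakaRushtonFit(
        r_max=float(r_max),
        n_50=float(n_50),
        exponent=float(exponent),
        baseline=float(baseline),
        rss=rss,
        converged=bool(sol.success),
    )


def snr_db(
    amap: ActivationMap | np.ndarray,
    active_roi: np.ndarray,
    quiet_roi: np.ndarray,
) -> float:
    """Map SNR: ``10 log10(mean active-ROI response / SD of quiet ROI)``.

    ROIs are boolean masks and must be disjoint.
    """
    values = amap.values if isinstance(amap, ActivationMap) else np.asarray(amap)
    active_roi = np.asarray(active_roi, bool)
    quiet_roi = np.asarray(quiet_roi, bool)
    if np.any(active_roi & quiet_roi):
        raise ValueError("ROIs must be disjoint")
    sd = values[quiet_roi].std()
    if sd == 0:
        raise ValueError("quiet ROI has zero variance")
    return float(10.0 * np.log10(values[active_roi].mean() / sd))
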