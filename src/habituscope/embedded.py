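"""Movement inference for head-embedded fish and habituation scoring.

Head-embedded larvae cannot be video-tracked during two-photon imaging, but
their attempted movements distort the acquired frames.  The per-frame
registration correlation (each frame's phase-correlation peak against the
motion-correction reference) therefore dips transiently whenever the fish
moves.  "Motion power" converts that trace into a movement proxy: the
standard deviation over a trailing three-frame window, smoothed with a
Savitzky-Golay filter (window 15 frames, order 2), then z-scored over the
whole recording.  A flash counts as responded-to when motion power exceeds
3 (z) within 10 s of its onset, and the per-flash response flags give the
percent-habituation score

    %Habituation = 100 * (P_early - P_late) / (P_early + P_late)

with P_early / P_late the response probabilities over the first / second
half of the 60 flashes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "MotionPower",
    "HabituationScore",
    "motion_power",
    "detect_embedded_responses",
    "habituation_index",
    "epoch_sum_images",
    "zdrift_qc",
]


@dataclass(frozen=True)
class MotionPower:
    """Z-scored motion-power series plus the parameters that produced it."""

    power: np.ndarray
    rolling_window: int = 3
    smooth_window: int = 15
    smooth_order: int = 2


@dataclass(frozen=True)
class HabituationScore:
    p_early: float
    p_late: float
    percent: float  # NaN when both probabilities are zero


def motion_power(corr_trace: np.ndarray, rolling_window: int = 3,
                 smooth_window: int = 15,
                 smooth_order: int = 2) -> MotionPower:
    """Rolling std -> Savitzky-Golay smoothing -> z-score.

    The rolling window is trailing; the leading edge is padded by repeating
    the first sample.  A constant input yields identically zero power (the
    z-score guards against zero variance).
    """
    x = np.asarray(corr_trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("corr_trace must be 1-D")
    if len(x) < smooth_window:
        raise ValueError(f"trace length {len(x)} < smoothing window "
                         f"{smooth_window}")
    padded = np.concatenate([np.full(rolling_window - 1, x[0]), x])
    win = np.lib.stride_tricks.sliding_window_view(padded, rolling_window)
    rstd = win.std(axis=1)
    sm = savgol_filter(rstd, smooth_window, smooth_order)
    sd = sm.std()
    power = (sm - sm.mean()) / sd if sd > 0 else np.zeros_like(sm)
    return MotionPower(power=power, rolling_window=rolling_window,
                       smooth_window=smooth_window, smooth_order=smooth_order)


def detect_embedded_responses(power: MotionPower | np.ndarray,
                              flash_onsets: np.ndarray, rate: float,
                              z_thresh: float = 3.0,
                              window: float = 10.0) -> np.ndarray:
    """Per-flash response flags: motion power strictly above ``z_thresh``
    within ``window`` seconds after onset (half-open window ``(t, t+w]``)."""
    p = power.power if isinstance(power, MotionPower) else np.asarray(power)
    n = len(p)
    flags = np.zeros(len(flash_onsets), dtype=bool)
    for i, onset in enumerate(np.asarray(flash_onsets, dtype=float)):
        lo = int(np.floor(onset * rate)) + 1
        hi = int(np.floor((onset + window) * rate)) + 1
        lo, hi = max(lo, 0), min(hi, n)
        if lo < hi:
            flags[i] = p[lo:hi].max() > z_thresh
    return flags


def habituation_index(flags: np.ndarray,
                      split: int | None = None) -> HabituationScore:
    """Percent habituation from per-flash response flags.

    ``split`` is the number of flashes in the early half (default: half the
    series, 30 for the standard 60-flash block).  Returns NaN percent with a
    warning when the fish never responded in either half.
    """
    f = np.asarray(flags, dtype=float)
    if split is None:
        split = len(f) // 2
    if not 0 < split < len(f):
        raise ValueError("split must fall inside the flag series")
    p_early = float(f[:split].mean())
    p_late = float(f[split:].mean())
    if p_early + p_late == 0:
        warnings.warn("no responses in either half; percent habituation is "
                      "undefined", stacklevel=2)
        pct = float("nan")
    else:
        pct = 100.0 * (p_early - p_late) / (p_early + p_late)
    return HabituationScore(p_early=p_early, p_late=p_late, percent=pct)


def epoch_sum_images(frames: np.ndarray, n_epochs: int = 5) -> np.ndarray:
    """Sum a (time, y, x) functional recording into ``n_epochs`` equal epochs."""
    frames = np.asarray(frames)
    t = frames.shape[0]
    if t < n_epochs:
        raise ValueError("fewer frames than epochs")
    per = t // n_epochs
    return np.array([frames[i * per:(i + 1) * per].sum(axis=0)
                     for i in range(n_epochs)])


def zdrift_qc(epoch_images: np.ndarray, anatomy_stack: np.ndarray,
              z_step_um: float = 1.0, max_drift_um: float = 3.0):
    """Estimate axial drift of the imaging plane across epochs.

    Each epoch-sum image is matched against every slice of the anatomy
    reference (acquired at ``z_step_um`` axial steps) by Pearson correlation;
    drift is the displacement of the best-matching slice relative to the
    first epoch.  Fish fail QC when the maximum absolute drift exceeds
    ``max_drift_um`` (strictly greater; a drift of exactly the limit passes).

    Returns
    -------
    (max_drift_um_observed, passed, per_epoch_best_z_um)
    """
    epochs = np.asarray(epoch_images, dtype=float)
    stack = np.asarray(anatomy_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("reference stack too thin to bracket z shifts")
    if epochs.shape[1:] != stack.shape[1:]:
        raise ValueError("epoch images and reference slices differ in shape")
    flat = stack.reshape(stack.shape[0], -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    norms[norms == 0] = 1.0
    best = np.empty(epochs.shape[0])
    for i, img in enumerate(epochs):
        v = img.ravel() - img.mean()
        nv = np.linalg.norm(v)
        corr = flat @ v / (norms * (nv if nv > 0 else 1.0))
        best[i] = np.argmax(corr)
    if best[0] in (0, stack.shape[0] - 1):
        warnings.warn("best match at reference-stack edge; drift may be "
                      "underestimated", stacklevel=2)
    z_um = best * z_step_um
    drift = float(np.abs(z_um - z_um[0]).max())
    return drift, drift <= max_drift_um, z_um
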