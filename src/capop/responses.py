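"""Event-locked responses, tuning curves, and HSV topographic maps.

Responses are grouped by the value of the experimental variable (stimulus
angle, tone frequency, ...). The per-ROI tuning curve is the trial-averaged
response as a function of that variable; its peak location v_peak, width
(FWHM) and peak amplitude map to hue, saturation and value of an HSV color
code painted over the imaged plane, with optional clip/offset rescaling to
keep skewed response distributions readable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from capop.core_model import EventTimeline, ROIMap
from capop.transients import TransientRaster

HUE_SPAN = 0.75  # top quarter of the hue wheel unused so extremes stay distinct


@dataclass
class TrialTensor:
    """Peri-event ΔF/F0 responses, shape (ROI, value, trial, frame).

    Missing trials (windows crossing the recording edge) are NaN.
    ``significant_trial`` marks trials with at least one significant
    transient frame in the post-event window.
    """

    responses: np.ndarray
    grid: np.ndarray
    window: tuple
    frame_rate: float
    significant_trial: np.ndarray
    has_significance: bool = True

    @property
    def n_pre(self) -> int:
        return int(round(self.window[0] * self.frame_rate))


@dataclass
class TuningCurveSet:
    """Per-ROI tuning statistics over the variable grid.

    ``width`` is the full width at half maximum of the mean curve above its
    minimum, linearly interpolated between grid points and clamped to the
    grid span; flat curves get the full span and are flagged unresponsive.
    """

    grid: np.ndarray
    mean: np.ndarray       # (N, V)
    sem: np.ndarray        # (N, V)
    v_peak: np.ndarray     # (N,)
    width: np.ndarray      # (N,)
    peak_amp: np.ndarray   # (N,)
    unresponsive: np.ndarray  # (N,) bool


@dataclass
class HSVMapParams:
    """Clip/offset rescaling of the saturation and value channels.

    Raw channel c is mapped to clamp((c − offset)/(clip − offset), 0, 1);
    offset=0, clip=1 is the identity. ``transparency`` ties the alpha
    channel to value so weak responses fade out.
    """

    sat_offset: float = 0.0
    sat_clip: float = 1.0
    val_offset: float = 0.0
    val_clip: float = 1.0
    transparency: bool = False

    def __post_init__(self) -> None:
        if not (self.sat_offset < self.sat_clip and self.val_offset < self.val_clip):
            raise ValueError("offset must be < clip for each channel")


def event_locked(dff: np.ndarray, events: EventTimeline, frame_rate: float,
                 window: tuple = (2.0, 5.0),
                 raster: TransientRaster | None = None) -> TrialTensor:
    """Cut peri-event single-trial responses grouped by variable value.

    ``window = (pre, post)`` seconds; the peri-event axis covers
    ``[-pre, post)`` around each event. Trials whose window crosses the
    recording edge are dropped with a warning.
    """
    dff = np.atleast_2d(dff)
    n_rois, T = dff.shape
    pre, post = window
    n_pre = int(round(pre * frame_rate))
    n_post = int(round(post * frame_rate))
    n_len = n_pre + n_post
    grid = events.grid
    trials_per_value = [np.flatnonzero(events.values == v) for v in grid]
    max_trials = max(len(t) for t in trials_per_value)
    resp = np.full((n_rois, len(grid), max_trials, n_len), np.nan)
    sig = np.zeros((n_rois, len(grid), max_trials), dtype=bool)
    dropped = 0
    for vi, ev_idx in enumerate(trials_per_value):
        for j, e in enumerate(ev_idx):
            f_ev = int(np.floor(events.times[e] * frame_rate + 1e-9))
            lo, hi = f_ev - n_pre, f_ev + n_post
            if lo < 0 or hi > T:
                dropped += 1
                continue
            resp[:, vi, j, :] = dff[:, lo:hi]
            if raster is not None:
                sig[:, vi, j] = raster.significant[:, f_ev:hi].any(axis=1)
    if dropped:
        warnings.warn(f"{dropped} trial(s) dropped: window crosses recording edge")
    return TrialTensor(responses=resp, grid=grid, window=window,
                       frame_rate=frame_rate, significant_trial=sig,
                       has_significance=raster is not None)


def _fwhm(grid: np.ndarray, y: np.ndarray) -> float:
    """FWHM of a sampled curve above its minimum, linear interpolation."""
    span = grid[-1] - grid[0]
    lo, hi = y.min(), y.max()
    if hi <= lo:
        return float(span)
    half = lo + 0.5 * (hi - lo)
    k = int(np.argmax(y))
    # walk left from the peak to the half-crossing
    left = grid[0]
    for i in range(k, 0, -1):
        if y[i - 1] < half <= y[i]:
            f = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = grid[i - 1] + f * (grid[i] - grid[i - 1])
            break
    right = grid[-1]
    for i in range(k, len(y) - 1):
        if y[i + 1] < half <= y[i]:
            f = (y[i] - half) / (y[i] - y[i + 1])
            right = grid[i] + f * (grid[i + 1] - grid[i])
            break
    return float(min(max(right - left, 0.0), span))


def tuning_curves(trials: TrialTensor, statistic: str = "mean",
                  min_sig_frac: float = 0.5) -> TuningCurveSet:
    """Trial-averaged tuning curves with peak location, amplitude and FWHM.

    The per-trial response scalar is the mean (or peak, with
    ``statistic="peak"``) ΔF/F0 over the post-event window. ``v_peak`` ties
    break to the lowest grid value.

    When the trial tensor carries single-trial significance, a cell is a
    responder only if some stimulus value drives significant transients in
    at least ``min_sig_frac`` of its trials. Non-responders are flagged
    unresponsive and assigned the full grid span as width (zero
    selectivity): an isolated spontaneous transient that happens to land in
    one trial window must not masquerade as sharp tuning.
    """
    post = trials.responses[..., trials.n_pre:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if statistic == "mean":
            per_trial = np.nanmean(post, axis=3)
        elif statistic == "peak":
            per_trial = np.nanmax(post, axis=3)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        mean = np.nanmean(per_trial, axis=2)
        n_tr = np.sum(np.isfinite(per_trial), axis=2)
        sd = np.nanstd(per_trial, axis=2, ddof=1)
    sem = np.where(n_tr > 1, sd / np.sqrt(np.maximum(n_tr, 1)), np.nan)
    n_rois = mean.shape[0]
    grid = trials.grid
    v_peak = np.empty(n_rois)
    width = np.empty(n_rois)
    peak_amp = np.empty(n_rois)
    unresponsive = np.zeros(n_rois, dtype=bool)
    if trials.has_significance:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            valid = np.isfinite(per_trial)
            sig_frac = np.where(valid, trials.significant_trial, False).sum(axis=2) \
                / np.maximum(valid.sum(axis=2), 1)
        responder = sig_frac.max(axis=1) >= min_sig_frac
    else:
        responder = np.ones(n_rois, dtype=bool)
    span = grid[-1] - grid[0]
    for i in range(n_rois):
        y = mean[i]
        k = int(np.argmax(y))  # first maximum = lowest grid value on ties
        v_peak[i] = grid[k]
        peak_amp[i] = y[k]
        if not responder[i]:
            unresponsive[i] = True
            width[i] = span
            continue
        width[i] = _fwhm(grid, y)
        if np.ptp(y) == 0:
            unresponsive[i] = True
    return TuningCurveSet(grid=grid, mean=mean, sem=sem, v_peak=v_peak,
                          width=width, peak_amp=peak_amp,
                          unresponsive=unresponsive)


def hsv_map(tuning: TuningCurveSet, p: HSVMapParams | None = None) -> np.ndarray:
    """Per-ROI (hue, sat, val, alpha) in [0, 1]⁴ from the tuning statistics.

    hue encodes v_peak over [0, 0.75] of the hue wheel; saturation encodes
    selectivity (1 − width/span); value encodes peak amplitude relative to
    the strongest ROI. Saturation and value pass through the clip/offset
    rescaling of ``p``.
    """
    p = p or HSVMapParams()
    grid = tuning.grid
    if len(grid) < 2:
        raise ValueError("variable grid must hold at least 2 values for a hue map")
    span = grid[-1] - grid[0]
    hue = (tuning.v_peak - grid[0]) / span * HUE_SPAN
    sat_raw = 1.0 - tuning.width / span
    amax = np.nanmax(tuning.peak_amp)
    val_raw = np.clip(tuning.peak_amp, 0, None) / amax if amax > 0 \
        else np.zeros_like(tuning.peak_amp)
    sat = np.clip((sat_raw - p.sat_offset) / (p.sat_clip - p.sat_offset), 0, 1)
    val = np.clip((val_raw - p.val_offset) / (p.val_clip - p.val_offset), 0, 1)
    alpha = val if p.transparency else np.ones_like(val)
    return np.column_stack([hue, sat, val, alpha])


def render_map(rois: ROIMap, hsv: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Composite HSV-colored ROIs over a grayscale background image."""
    hsv = np.asarray(hsv, dtype=float)
    if hsv.shape[0] != len(rois):
        raise ValueError("one HSV row required per ROI")
    bg = np.asarray(background, dtype=float)
    rng = np.ptp(bg)
    gray = (bg - bg.min()) / rng if rng > 0 else np.zeros_like(bg)
    out = np.repeat(gray[:, :, None], 3, axis=2)
    rgb = hsv_to_rgb(hsv[:, :3])
    for i, px in enumerate(rois.rois):
        a = hsv[i, 3]
        out[px[:, 0], px[:, 1], :] = (
            a * rgb[i] + (1 - a) * out[px[:, 0], px[:, 1], :])
    return out
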