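"""Trace extraction, neuropil decontamination, baseline F0, and ΔF/F0.

The measured somatic signal is modeled as
``F_measured = F_soma + α·F_neuropil``: fluorescence from the neuropil
(out-of-focus axons and dendrites) adds to the soma with contamination
factor α. The neuropil signal local to each ROI is taken from a perisomatic
disk mask of 20 μm radius that excludes the pixels of all detected ROIs.
ΔF/F0 uses either a windowed baseline (e.g. pre-stimulus) or a slow
running-percentile baseline F_smooth that tracks drift while ignoring the
faster calcium transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from capop.core_model import (EventTimeline, MovieStack, ROIMap,
                              frames_in_window, register_session_type)


@register_session_type
@dataclass
class FluoTraces:
    """Per-ROI fluorescence time series, shape (N, T), arbitrary units."""

    F: np.ndarray
    source: str = "raw"  # raw | neuropil | corrected

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))

    @property
    def n_rois(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]


@register_session_type
@dataclass
class DFFTraces:
    """Relative fluorescence change (F − F0)/F0 with its baseline."""

    dff: np.ndarray
    F0: np.ndarray
    f0_method: str = "smooth"  # window | smooth

    def __post_init__(self) -> None:
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        self.F0 = np.asarray(self.F0, dtype=float)

    @property
    def n_rois(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


def extract_traces(movie: MovieStack, rois: ROIMap) -> FluoTraces:
    """Mean intensity over each ROI's pixels per frame; artifact frames NaN."""
    n_rois = len(rois)
    T = movie.n_frames
    F = np.empty((n_rois, T))
    data = movie.data
    for i, px in enumerate(rois.rois):
        if (px[:, 0].max() >= data.shape[1]) or (px[:, 1].max() >= data.shape[2]):
            raise ValueError(f"ROI {i} has pixels outside the frame")
        sub = data[:, px[:, 0], px[:, 1]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
            F[i] = np.nanmean(sub, axis=1)
        if np.isnan(F[i]).all():
            warnings.warn(f"ROI {i} is fully outside the valid region; trace masked")
    if movie.bad_frames:
        F[:, sorted(movie.bad_frames)] = np.nan
    return FluoTraces(F=F, source="raw")


def perisomatic_masks(rois: ROIMap, shape: tuple, radius: float = 20.0,
                      pixel_size: float = 1.0) -> list:
    """Perisomatic neuropil mask per ROI.

    Each mask is a disk of ``radius`` μm centered on the ROI centroid with
    the pixels of *all* detected ROIs removed; masks of different ROIs may
    overlap each other. An empty mask (very dense fields) yields a warning
    and an empty pixel array — the neuropil trace is then undefined.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    r_px = radius / pixel_size
    rows, cols = shape
    any_roi = np.zeros(shape, dtype=bool)
    for px in rois.rois:
        any_roi[px[:, 0], px[:, 1]] = True
    out = []
    cents = rois.centroids
    for i in range(len(rois)):
        cy, cx = cents[i, 0], cents[i, 1]
        r0 = max(int(np.floor(cy - r_px)), 0)
        r1 = min(int(np.ceil(cy + r_px)) + 1, rows)
        c0 = max(int(np.floor(cx - r_px)), 0)
        c1 = min(int(np.ceil(cx + r_px)) + 1, cols)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= r_px ** 2
        keep = disk & ~any_roi[r0:r1, c0:c1]
        px = np.column_stack([rr[keep], cc[keep]]).astype(np.intp)
        if len(px) == 0:
            warnings.warn(f"ROI {i}: empty perisomatic mask; neuropil undefined")
        out.append(px)
    return out


def extract_neuropil_traces(movie: MovieStack, masks: list) -> FluoTraces:
    """Mean intensity over each perisomatic mask per frame."""
    T = movie.n_frames
    F = np.full((len(masks), T), np.nan)
    for i, px in enumerate(masks):
        if len(px) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            F[i] = np.nanmean(movie.data[:, px[:, 0], px[:, 1]], axis=1)
    if movie.bad_frames:
        F[:, sorted(movie.bad_frames)] = np.nan
    return FluoTraces(F=F, source="neuropil")


def neuropil_correct(soma: FluoTraces, npil: FluoTraces,
                     alpha: float = 0.9) -> FluoTraces:
    """Subtract the scaled local neuropil signal: F_soma = F_meas − α·F_npil."""
    if soma.F.shape != npil.F.shape:
        raise ValueError("soma and neuropil trace shapes differ")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    return FluoTraces(F=soma.F - alpha * npil.F, source="corrected")


@dataclass
class SanityReport:
    """Per-ROI data-quality flags raised by :func:`sanity_check`."""

    nonfinite: list = field(default_factory=list)
    negative: list = field(default_factory=list)
    saturated: list = field(default_factory=list)
    zero_variance: list = field(default_factory=list)

    def is_clean(self) -> bool:
        return not (self.nonfinite or self.negative or self.saturated
                    or self.zero_variance)


def sanity_check(traces: FluoTraces, sensor_max: float | None = None,
                 negative_frac: float = 0.01,
                 saturated_frac: float = 0.01) -> SanityReport:
    """Screen traces for common acquisition/processing problems.

    Flags, per ROI: unexpected non-finite samples; negative corrected
    fluorescence in more than ``negative_frac`` of frames (neuropil
    over-subtraction); samples pinned at ``sensor_max`` (default: the global
    data maximum if it is hit repeatedly) in ≥ ``saturated_frac`` of frames;
    zero-variance (dead) traces. Report only — nothing is modified.
    """
    rep = SanityReport()
    F = traces.F
    if sensor_max is None:
        sensor_max = np.nanmax(F) if np.isfinite(F).any() else np.inf
    for i in range(F.shape[0]):
        x = F[i]
        finite = np.isfinite(x)
        n = finite.sum()
        if n == 0:
            rep.nonfinite.append(i)
            continue
        if (~finite).any():
            rep.nonfinite.append(i)
        xv = x[finite]
        if (xv < 0).mean() > negative_frac:
            rep.negative.append(i)
        if (xv >= sensor_max).mean() >= saturated_frac and np.ptp(xv) > 0:
            rep.saturated.append(i)
        if np.ptp(xv) == 0:
            rep.zero_variance.append(i)
    return rep


def estimate_f0_window(traces: FluoTraces, frame_rate: float,
                       window: tuple = (0.0, np.inf),
                       events: EventTimeline | None = None) -> np.ndarray:
    """Baseline F0 as the mean fluorescence in a time window.

    Without events: one scalar per ROI, the mean over the global window
    ``[t0, t1)``. With events: ``window`` is relative to each event time
    (typically negative pre-event offsets, e.g. ``(-2.0, 0.0)``) and the
    result has shape (N, n_events). All-artifact windows yield NaN.
    """
    F = traces.F
    T = F.shape[1]
    if events is None:
        idx = frames_in_window(window[0], min(window[1], T / frame_rate),
                               frame_rate, T)
        if len(idx) == 0:
            raise ValueError("F0 window covers no frames")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(F[:, idx], axis=1)
    out = np.full((F.shape[0], len(events)), np.nan)
    for j, t_ev in enumerate(events.times):
        idx = frames_in_window(t_ev + window[0], t_ev + window[1], frame_rate, T)
        if len(idx) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[:, j] = np.nanmean(F[:, idx], axis=1)
    if np.isnan(out).any():
        warnings.warn("some per-event F0 windows contained no valid frames")
    return out


def estimate_f_smooth(traces: FluoTraces, frame_rate: float,
                      window: float = 30.0, percentile: float = 8.0,
                      tau_decay: float | None = None) -> np.ndarray:
    """Slow baseline F_smooth: running percentile + same-width moving average.

    A centered sliding window of ``window`` seconds takes the given low
    percentile (default 8th) of F — robust to the sparse positive calcium
    transients riding on the baseline — and the result is smoothed by a
    moving average of the same width. Because the p-th percentile of the
    baseline noise sits Φ⁻¹(p)·σ_F below its center, that offset is added
    back using a robust noise-scale estimate (median |ΔF|/√2), so ΔF/F0
    computed against F_smooth is centered on transient-free stretches. The
    window must be long relative to the indicator decay (validated as
    window ≥ 10·τ when τ is given). Output is strictly positive, floored at
    a small fraction of the trace scale, shape (N, T).
    """
    from scipy.stats import norm as _norm
    if tau_decay is not None and window < 10 * tau_decay:
        warnings.warn("F_smooth window < 10·tau_decay: baseline may absorb transients")
    F = traces.F
    width = max(int(round(window * frame_rate)), 1)
    out = np.empty_like(F)
    for i in range(F.shape[0]):
        x = F[i]
        finite = np.isfinite(x)
        xf = x.copy()
        if not finite.all():
            if not finite.any():
                out[i] = np.nan
                continue
            xf[~finite] = np.interp(np.flatnonzero(~finite),
                                    np.flatnonzero(finite), x[finite])
        base = ndimage.percentile_filter(xf, percentile, size=width,
                                         mode="nearest")
        base = ndimage.uniform_filter1d(base, size=width, mode="nearest")
        if len(xf) > 1:
            sigma_f = 1.4826 * np.median(np.abs(np.diff(xf))) / np.sqrt(2.0)
            base = base - _norm.ppf(percentile / 100.0) * sigma_f
        floor = 1e-6 * max(np.nanmax(np.abs(xf)), 1e-12)
        out[i] = np.maximum(base, floor)
    return out


def compute_dff(traces: FluoTraces, F0: np.ndarray,
                f0_method: str = "smooth") -> DFFTraces:
    """ΔF/F0 = (F − F0)/F0, with scalar-per-ROI or per-frame F0."""
    F = traces.F
    F0 = np.asarray(F0, dtype=float)
    if F0.ndim == 1:
        F0b = F0[:, None]
    else:
        F0b = F0
    if np.any(F0b[np.isfinite(F0b)] <= 0):
        raise ValueError("F0 must be positive everywhere; run sanity_check "
                         "and revisit neuropil correction")
    dff = (F - F0b) / F0b
    return DFFTraces(dff=dff, F0=F0, f0_method=f0_method)
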