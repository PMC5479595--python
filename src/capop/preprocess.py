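"""Rigid within-plane registration and motion-artifact flagging.

Registration is rigid translation only: each frame is aligned to a template
by upsampled cross-correlation (sub-pixel precision), the raw displacement
series is smoothed with a moving average to suppress frame-to-frame
estimation jitter, and frames are resampled by the negated displacement.
Frames whose aligned similarity to the template is low, or whose raw
displacement jumps abruptly, are flagged as motion artifacts for exclusion
from all downstream trace statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from capop.core_model import CapopError, MovieStack


class DegenerateTemplateError(CapopError):
    """The registration template has no spatial structure (zero variance)."""


@dataclass
class DisplacementSeries:
    """Per-frame rigid displacement of the movie relative to a template.

    ``dy``/``dx`` are the smoothed displacements actually used for
    registration; ``raw_dy``/``raw_dx`` keep the unsmoothed estimates, on
    which displacement jumps are measured. ``quality`` is the Pearson
    correlation of each aligned frame with the template, in [−1, 1].
    """

    dy: np.ndarray
    dx: np.ndarray
    raw_dy: np.ndarray
    raw_dx: np.ndarray
    template: np.ndarray
    quality: np.ndarray

    def __len__(self) -> int:
        return len(self.dy)


def select_template_frames(movie: MovieStack, n: int = 100) -> np.ndarray:
    """Indices of the ``n`` frames most correlated with the movie mean.

    A robust template source: frames dominated by transients or motion
    correlate poorly with the time-average and are excluded.
    """
    mean = movie.data.mean(axis=0).ravel()
    mean = mean - mean.mean()
    denom = np.linalg.norm(mean)
    corrs = np.empty(movie.n_frames)
    for t in range(movie.n_frames):
        f = movie.data[t].ravel().astype(float)
        f = f - f.mean()
        nf = np.linalg.norm(f)
        corrs[t] = (f @ mean) / (nf * denom) if nf > 0 and denom > 0 else 0.0
    return np.argsort(corrs)[::-1][: min(n, movie.n_frames)]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 2:
        return 0.0
    a, b = a[mask], b[mask]
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def estimate_displacements(movie: MovieStack, template_frames=None,
                           smooth_window: float = 1.0,
                           upsample_factor: int = 20) -> DisplacementSeries:
    """Estimate per-frame rigid (dy, dx) against a template.

    ``template_frames`` defaults to :func:`select_template_frames`. The raw
    sub-pixel estimates are smoothed by a centered moving average of width
    ``smooth_window`` seconds (0 disables smoothing).
    """
    if template_frames is None:
        template_frames = select_template_frames(movie)
    template_frames = np.asarray(list(template_frames), dtype=np.intp)
    if template_frames.size == 0:
        raise ValueError("template_frames must be non-empty")
    template = movie.data[template_frames].mean(axis=0).astype(float)
    if np.ptp(template) == 0:
        raise DegenerateTemplateError("template has zero variance")

    T = movie.n_frames
    raw = np.empty((T, 2))
    for t in range(T):
        shift, _, _ = phase_cross_correlation(
            template, movie.data[t].astype(float),
            upsample_factor=upsample_factor, normalization=None)
        raw[t] = -shift  # displacement of the frame relative to the template

    width = max(int(round(smooth_window * movie.frame_rate)), 1)
    if width > 1:
        smooth = ndimage.uniform_filter1d(raw, size=width, axis=0, mode="nearest")
    else:
        smooth = raw.copy()

    quality = np.empty(T)
    for t in range(T):
        aligned = ndimage.shift(movie.data[t].astype(float), -smooth[t],
                                order=1, mode="constant", cval=np.nan)
        quality[t] = _pearson(aligned.ravel(), template.ravel())
    return DisplacementSeries(dy=smooth[:, 0], dx=smooth[:, 1],
                              raw_dy=raw[:, 0], raw_dx=raw[:, 1],
                              template=template, quality=quality)


def apply_registration(movie: MovieStack, disp: DisplacementSeries) -> MovieStack:
    """Translate each frame by (−dy, −dx) with sub-pixel interpolation.

    Pixels shifted in from outside the field are marked invalid (NaN).
    """
    if len(disp) != movie.n_frames:
        raise ValueError("displacement series length must equal frame count")
    out = np.empty_like(movie.data, dtype=float)
    for t in range(movie.n_frames):
        d = (disp.dy[t], disp.dx[t])
        if d == (0.0, 0.0):
            out[t] = movie.data[t]
        else:
            out[t] = ndimage.shift(movie.data[t].astype(float), (-d[0], -d[1]),
                                   order=1, mode="constant", cval=np.nan)
    if np.isnan(out).all(axis=(1, 2)).any():
        warnings.warn("some registered frames are entirely out of field")
    return MovieStack(data=out, frame_rate=movie.frame_rate,
                      pixel_size=movie.pixel_size, plane_id=movie.plane_id,
                      bad_frames=set(movie.bad_frames))


def detect_artifact_frames(disp: DisplacementSeries,
                           quality_thr: float | None = None,
                           disp_thr: float = 5.0) -> set:
    """Flag frames with low template similarity or abrupt displacement jumps.

    ``quality_thr`` defaults to median(quality) − 3·MAD(quality). A frame is
    flagged when ``quality < quality_thr`` or when the raw displacement jump
    into it exceeds ``disp_thr`` pixels. The result is meant to be stored in
    ``MovieStack.bad_frames``.
    """
    quality = disp.quality
    if quality_thr is None:
        med = np.median(quality)
        mad = np.median(np.abs(quality - med))
        quality_thr = med - 3.0 * mad
    flagged = set(np.flatnonzero(quality < quality_thr).tolist())
    jump = np.hypot(np.diff(disp.raw_dy), np.diff(disp.raw_dx))
    flagged |= set((np.flatnonzero(jump > disp_thr) + 1).tolist())
    return flagged
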