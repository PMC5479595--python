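"""Ground-truth synthetic data: cells, spiking activity, and rendered movies.

The generator emulates the features of real population calcium imaging that
the pipeline must cope with: ring-shaped (cytosol-labeled) and disk-shaped
(nucleus-labeled) cells on a shared neuropil background, spike-driven
exponential-decay calcium transients with indicator kinetics τ, additive
Gaussian baseline noise, slow baseline drift, rigid frame jitter, planted
overlapping correlated-ROI assemblies, and stimulus-locked Gaussian tuning.

Every operation is a pure function of its parameters and a seed, so all
outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from capop.core_model import EventTimeline, MovieStack, ROIMap


@dataclass
class CellSet:
    """Planted cells: geometry ground truth for segmentation tests.

    ``masks`` holds the labeled pixels of each cell — the full disk for
    nucleus-labeled (``disk``) cells, the cytosolic annulus for
    nucleus-excluded (``ring``) cells. ``full_masks`` always holds the whole
    cell disk (annulus plus nucleus interior).
    """

    masks: list
    full_masks: list
    centers: np.ndarray  # (n, 2) float, (row, col)
    mode: str
    radius_px: float
    field_shape: tuple

    def to_roimap(self) -> ROIMap:
        return ROIMap(rois=[m.copy() for m in self.masks])


@dataclass
class GroundTruth:
    """Planted activity: spikes, noiseless ΔF/F0 and observed noisy traces."""

    spike_counts: np.ndarray      # (cells, frames) int
    true_dff: np.ndarray          # (cells, frames) noiseless ΔF/F0
    observed: np.ndarray          # (cells, frames) with drift and noise
    frame_rate: float
    tau_decay: float
    amplitude: np.ndarray         # per-cell ΔF/F0 per spike
    noise_sigma: float
    memberships: list = field(default_factory=list)
    assembly_event_frames: list = field(default_factory=list)
    preferred_values: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.spike_counts.shape[0]

    @property
    def n_frames(self) -> int:
        return self.spike_counts.shape[1]

    def spike_times(self, cell: int) -> np.ndarray:
        """Spike times of one cell in seconds (frame onset times)."""
        frames = np.repeat(np.arange(self.n_frames),
                           self.spike_counts[cell])
        return frames / self.frame_rate


@dataclass
class RenderResult:
    """A rendered movie plus the rendering ground truth."""

    movie: MovieStack
    jitter: np.ndarray            # (frames, 2) planted (dy, dx) in pixels
    neuropil_trace: np.ndarray    # (frames,) shared neuropil time course
    baseline: float
    cell_gain: float


def make_cells(n_cells: int, mode: str, field_shape: tuple, pixel_size: float,
               radius: float = 5.0, min_gap: float = 3.0, seed: int = 0,
               margin: float = 2.0, max_attempts: int = 20000) -> CellSet:
    """Plant non-overlapping cells by dart throwing.

    Parameters are physical: ``radius`` and ``min_gap`` in μm, converted to
    pixels with ``pixel_size``. ``mode`` is ``"disk"`` (uniformly filled,
    nucleus-labeled) or ``"ring"`` (bright cytosolic annulus around a darker
    nucleus). Raises ``RuntimeError`` with the achieved count if the field
    cannot hold ``n_cells`` at the requested spacing.
    """
    if mode not in ("disk", "ring"):
        raise ValueError(f"mode must be 'disk' or 'ring', got {mode!r}")
    rng = np.random.default_rng(seed)
    r_px = radius / pixel_size
    gap_px = min_gap / pixel_size
    min_dist = 2 * r_px + gap_px
    rows, cols = field_shape
    lo = r_px + margin / pixel_size
    centers: list = []
    attempts = 0
    while len(centers) < n_cells and attempts < max_attempts:
        attempts += 1
        c = np.array([rng.uniform(lo, rows - lo), rng.uniform(lo, cols - lo)])
        if all(np.hypot(*(c - p)) >= min_dist for p in centers):
            centers.append(c)
    if len(centers) < n_cells:
        raise RuntimeError(
            f"cell packing failed: placed {len(centers)}/{n_cells} cells "
            f"in {attempts} attempts")
    centers_arr = np.array(centers) if centers else np.empty((0, 2))

    rr, cc = np.mgrid[0:rows, 0:cols]
    masks, full_masks = [], []
    inner = 0.55 * r_px  # nucleus radius for ring cells
    for c in centers_arr:
        d = np.hypot(rr - c[0], cc - c[1])
        disk = d <= r_px
        full = np.argwhere(disk)
        if mode == "disk":
            lab = full
        else:
            lab = np.argwhere(disk & (d > inner))
        masks.append(lab)
        full_masks.append(full)
    return CellSet(masks=masks, full_masks=full_masks, centers=centers_arr,
                   mode=mode, radius_px=r_px, field_shape=tuple(field_shape))


def _decay_kernel(tau_decay: float, frame_rate: float) -> np.ndarray:
    """Single-exponential calcium kernel with instantaneous rise, unit peak."""
    n = max(int(np.ceil(10 * tau_decay * frame_rate)), 1)
    t = np.arange(n) / frame_rate
    return np.exp(-t / tau_decay)


def make_activity(n_cells: int, duration: float, frame_rate: float,
                  tau_decay: float = 0.25,
                  amplitude: float | np.ndarray = 0.2,
                  noise_sigma: float = 0.05,
                  memberships: Sequence[np.ndarray] | None = None,
                  assembly_event_rate: float = 0.5,
                  within_prob: float = 0.3,
                  background_rate: float = 0.1,
                  drift: float = 0.0,
                  events: EventTimeline | None = None,
                  preferred_values: np.ndarray | None = None,
                  tuning_sigma: float = 15.0,
                  stim_spikes_peak: float = 2.0,
                  seed: int = 0) -> GroundTruth:
    """Simulate spiking and calcium traces for a population.

    Spiking is the superposition of three processes:

    * independent background Poisson spiking at ``background_rate`` Hz;
    * assembly events — each planted assembly emits events as a Poisson
      process at ``assembly_event_rate`` Hz, and every event recruits each
      member independently with probability ``within_prob`` (members may
      belong to several assemblies; shared cells follow all of them);
    * stimulus-locked responses — at each event of ``events``, cell *i*
      fires Poisson(``stim_spikes_peak``·exp(−(v−pref_i)²/2σ_v²)) spikes.

    The noiseless ΔF/F0 is the spike train convolved with a unit-peak
    exponential kernel exp(−t/τ) scaled by ``amplitude`` per spike; the
    observed trace adds a multiplicative linear drift and i.i.d. Gaussian
    noise of scale ``noise_sigma``.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * frame_rate))
    amp = np.broadcast_to(np.asarray(amplitude, dtype=float), (n_cells,)).copy()
    memberships = [np.asarray(m, dtype=np.intp) for m in (memberships or [])]

    spikes = rng.poisson(background_rate / frame_rate,
                         size=(n_cells, n_frames)).astype(np.int64)

    assembly_event_frames = []
    for members in memberships:
        n_ev = rng.poisson(assembly_event_rate * duration)
        ev_frames = np.sort(rng.integers(0, n_frames, size=n_ev))
        assembly_event_frames.append(ev_frames)
        for f in ev_frames:
            recruited = members[rng.random(len(members)) < within_prob]
            spikes[recruited, f] += 1

    if events is not None and preferred_values is not None:
        preferred_values = np.asarray(preferred_values, dtype=float)
        ev_frames = np.clip((events.times * frame_rate).astype(int), 0, n_frames - 1)
        for f, v in zip(ev_frames, events.values):
            lam = stim_spikes_peak * np.exp(
                -((v - preferred_values) ** 2) / (2 * tuning_sigma ** 2))
            spikes[:, f] += rng.poisson(lam)

    kernel = _decay_kernel(tau_decay, frame_rate)
    true_dff = np.empty((n_cells, n_frames))
    for i in range(n_cells):
        conv = np.convolve(spikes[i].astype(float), kernel)[:n_frames]
        true_dff[i] = amp[i] * conv

    t = np.arange(n_frames) / frame_rate
    observed = true_dff * (1.0 + drift * t) + rng.normal(
        0.0, noise_sigma, size=true_dff.shape)
    return GroundTruth(spike_counts=spikes, true_dff=true_dff, observed=observed,
                       frame_rate=frame_rate, tau_decay=tau_decay, amplitude=amp,
                       noise_sigma=noise_sigma, memberships=memberships,
                       assembly_event_frames=assembly_event_frames,
                       preferred_values=preferred_values)


def render_movie(cells: CellSet, dff: np.ndarray, frame_rate: float,
                 pixel_size: float, baseline: float = 20.0,
                 cell_gain: float = 100.0, neuropil_gain: float = 0.0,
                 alpha_true: float = 0.9, jitter_sd: float = 0.0,
                 pixel_noise: float = 1.0, seed: int = 0,
                 neuropil_texture: float = 0.15) -> RenderResult:
    """Render a fluorescence movie from planted cells and ΔF/F0 traces.

    Each frame is ``baseline + neuropil + Σ cells·(1 + dff)``, rigidly
    shifted by an integer jitter drawn per frame, plus Gaussian pixel noise.
    The neuropil term is a near-uniform field (static multiplicative texture
    of amplitude ``neuropil_texture``) driven by a shared time course — the
    low-pass-filtered population-mean ΔF/F0 — and attenuated by
    ``alpha_true`` inside cell somata, reproducing the contamination model
    F_measured = F_soma + α·F_neuropil.
    """
    rng = np.random.default_rng(seed)
    n_cells, n_frames = dff.shape
    rows, cols = cells.field_shape

    cell_img = np.zeros((rows, cols))
    cell_of_pixel = [np.zeros((rows, cols), dtype=bool) for _ in range(n_cells)]
    inside_any = np.zeros((rows, cols), dtype=bool)
    for i, m in enumerate(cells.masks):
        cell_of_pixel[i][m[:, 0], m[:, 1]] = True
        cell_img[m[:, 0], m[:, 1]] = cell_gain
    for m in cells.full_masks:
        inside_any[m[:, 0], m[:, 1]] = True

    # shared neuropil: slow population-mean time course on a textured field
    pop = dff.mean(axis=0)
    w = max(int(round(frame_rate)), 1)
    npil_trace = ndimage.uniform_filter1d(pop, size=w, mode="nearest")
    texture = 1.0 + neuropil_texture * ndimage.gaussian_filter(
        rng.standard_normal((rows, cols)), sigma=8)
    npil_field = neuropil_gain * texture
    npil_field = np.where(inside_any, alpha_true * npil_field, npil_field)

    jitter = np.round(rng.normal(0.0, jitter_sd, size=(n_frames, 2))).astype(int)
    data = np.empty((n_frames, rows, cols), dtype=np.float32)
    for t in range(n_frames):
        frame = baseline + npil_field * (1.0 + npil_trace[t])
        for i in range(n_cells):
            frame = frame + cell_of_pixel[i] * (cell_gain * (1.0 + dff[i, t]))
        if jitter_sd > 0:
            frame = np.roll(frame, shift=tuple(jitter[t]), axis=(0, 1))
        frame = frame + rng.normal(0.0, pixel_noise, size=frame.shape)
        data[t] = frame
    movie = MovieStack(data=data, frame_rate=frame_rate, pixel_size=pixel_size)
    return RenderResult(movie=movie, jitter=jitter, neuropil_trace=npil_trace,
                        baseline=baseline, cell_gain=cell_gain)


def mean_image(cells: CellSet, contrast: float = 1.0, background: float = 0.1,
               illumination_gradient: float = 0.0, noise: float = 0.01,
               nucleus_dim: float = 0.25, seed: int = 0) -> np.ndarray:
    """Render a static (time-averaged) image of planted cells.

    For ``ring`` cells the nucleus interior is rendered at ``nucleus_dim``
    of the annulus brightness. ``illumination_gradient`` g scales intensity
    linearly from 1 at the left edge to 1+g at the right edge (uneven
    illumination). Used for segmentation tests.
    """
    rng = np.random.default_rng(seed)
    rows, cols = cells.field_shape
    img = np.full((rows, cols), background)
    for m in cells.masks:
        img[m[:, 0], m[:, 1]] = background + contrast
    if cells.mode == "ring":
        for full, lab in zip(cells.full_masks, cells.masks):
            ring = set(map(tuple, lab))
            interior = np.array([p for p in full if tuple(p) not in ring])
            if len(interior):
                img[interior[:, 0], interior[:, 1]] = (
                    background + nucleus_dim * contrast)
    if illumination_gradient:
        grad = 1.0 + illumination_gradient * np.linspace(0, 1, cols)
        img = img * grad[None, :]
    img = img + rng.normal(0.0, noise, size=img.shape)
    return img
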