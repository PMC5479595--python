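"""Closed-loop validation experiments on synthetic ground truth.

Each function builds a dataset with the :mod:`capop.synthgen` generator,
runs the corresponding pipeline stage, and measures recovery of the planted
truth. These experiments back the package's quality claims: the same
functions drive the acceptance script and the acceptance test suite.

All experiments are deterministic given their ``seed``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist
from scipy.stats import ks_2samp, spearmanr

from capop import assemblies as asm
from capop import responses as resp
from capop import segment as seg
from capop import signals as sig
from capop import surrogates as sur
from capop import synthgen
from capop import transients as tra
from capop.core_model import EventTimeline
from capop.signals import DFFTraces


def _jaccard(a, b) -> float:
    a, b = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# 1. Marčenko–Pastur null calibration
# ---------------------------------------------------------------------------

def mp_null_calibration(n_rois: int = 200, n_frames: int = 2000,
                        n_rep: int = 100, group_size: int = 20,
                        seed: int = 0) -> dict:
    """Eigenvalue threshold calibration on i.i.d. noise and one planted group.

    Measures (a) the mean fraction of correlation-matrix eigenvalues above
    λ_max across ``n_rep`` pure-noise replicates — the false-discovery rate
    of the component-retention rule — and (b) the number of components
    retained when ``group_size`` of the ROIs are perfectly correlated.
    """
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_rep):
        Z = asm.build_activity(rng.normal(size=(n_rois, n_frames)))
        fracs.append(asm.pca_mp(Z).n_retained / n_rois)

    X = rng.normal(size=(n_rois, n_frames))
    X[:group_size] = rng.normal(size=n_frames)  # one perfectly correlated group
    pca = asm.pca_mp(asm.build_activity(X))
    top = np.argsort(np.abs(pca.loadings[:, 0]))[::-1][:group_size] \
        if pca.n_retained >= 1 else np.empty(0, dtype=int)
    return {
        "noise_frac_above_lambda_max": float(np.mean(fracs)),
        "planted_group_n_retained": int(pca.n_retained),
        "planted_group_loading_recovery": float(
            len(set(top) & set(range(group_size))) / group_size),
    }


# ---------------------------------------------------------------------------
# 2. End-to-end assembly recovery
# ---------------------------------------------------------------------------

def assembly_recovery(n_rois: int = 500, n_assemblies: int = 8,
                      duration: float = 600.0, frame_rate: float = 10.0,
                      n_shared: int = 5, seed: int = 0) -> dict:
    """PCA-promax recovery of planted overlapping assemblies.

    Plants ``n_assemblies`` assemblies of 20–40 ROIs (the first two sharing
    ``n_shared`` ROIs; each assembly event recruits members with probability
    0.3, background spiking at 0.02/frame), detects significant transients,
    and runs the full automatic chain on the transient raster (PCA → promax
    → auto zMax → merge → shuffle significance). Reports the worst
    per-assembly Jaccard overlap, whether every shared ROI was assigned to
    both parent assemblies, and that the k-means baseline partition cannot
    represent the overlap (its member sets are disjoint by construction).
    """
    rng = np.random.default_rng(seed)
    sizes = rng.integers(20, 41, size=n_assemblies)
    members, start = [], 0
    for s in sizes:
        members.append(np.arange(start, start + s))
        start += s
    members[1] = np.concatenate([members[0][:n_shared], members[1][n_shared:]])

    gt = synthgen.make_activity(
        n_cells=n_rois, duration=duration, frame_rate=frame_rate,
        memberships=members, assembly_event_rate=0.5, within_prob=0.3,
        background_rate=0.02 * frame_rate, seed=seed + 1)
    dff = DFFTraces(dff=gt.observed, F0=np.ones(n_rois))
    noise = tra.estimate_sigma(dff, "gauss_fit")
    raster = tra.detect_static(dff, noise, k=3.0)
    Z = asm.build_activity(raster)
    detected = asm.detect_assemblies(Z, n_shuffle=1000, seed=seed + 2)

    jaccards = [max((_jaccard(m, d) for d in detected.members), default=0.0)
                for m in members]
    shared = members[0][:n_shared]
    n_in_both = sum(1 for s in shared
                    if sum(1 for d in detected.members if s in d) >= 2)

    km = asm.cluster_baseline(Z, method="kmeans", k=n_assemblies, seed=seed + 3)
    km_all = np.concatenate(km.members)
    km_disjoint = len(km_all) == len(np.unique(km_all))
    return {
        "n_detected": len(detected),
        "min_jaccard": float(min(jaccards)),
        "jaccards": [float(j) for j in jaccards],
        "shared_rois_in_both": bool(n_in_both == n_shared),
        "n_shared_in_both": int(n_in_both),
        "n_shared": int(n_shared),
        "kmeans_partition_disjoint": bool(km_disjoint),
    }


# ---------------------------------------------------------------------------
# 3. Transient inference
# ---------------------------------------------------------------------------

def transient_benchmark(frame_rate: float = 60.0, tau_decay: float = 0.25,
                        noise_sigma: float = 0.05, snr: float = 4.0,
                        confidence: float = 0.95, seed: int = 0) -> dict:
    """Sensitivity and false positives of transient inference.

    Planted transients have ``snr``·σ peaks (GCaMP6f-like kinetics). Reports
    the fraction of planted spikes followed by significant fluorescence
    within 40 ms (dynamic method), the significant-frame fraction on pure
    noise for the dynamic method, and the static k = 3 exceedance rate on
    10⁵ noise frames (nominal Gaussian value Φ̄(3) ≈ 1.35e−3).
    """
    gt = synthgen.make_activity(
        n_cells=20, duration=100.0, frame_rate=frame_rate, tau_decay=tau_decay,
        amplitude=snr * noise_sigma, noise_sigma=noise_sigma,
        background_rate=0.08, seed=seed + 1)
    dff = DFFTraces(dff=gt.observed, F0=np.ones(gt.n_cells))
    noise = tra.estimate_sigma(dff, "gauss_fit")
    raster = tra.detect_dynamic(dff, noise, tau_decay, frame_rate, confidence)
    hits = tot = 0
    for i in range(gt.n_cells):
        st = gt.spike_times(i)
        sa = tra.associate_spikes(raster, st, frame_rate, window=0.04, roi=i)
        hits += int(sa.associated.sum())
        tot += len(st)

    gt0 = synthgen.make_activity(n_cells=10, duration=150.0,
                                 frame_rate=frame_rate, background_rate=0.0,
                                 noise_sigma=noise_sigma, seed=seed + 2)
    dff0 = DFFTraces(dff=gt0.observed, F0=np.ones(10))
    noise0 = tra.estimate_sigma(dff0, "gauss_fit")
    dyn0 = tra.detect_dynamic(dff0, noise0, tau_decay, frame_rate, confidence)

    rng = np.random.default_rng(seed + 3)
    x = rng.normal(0, noise_sigma, size=(1, 100000))
    dffs = DFFTraces(dff=x, F0=np.ones(1))
    ns = tra.estimate_sigma(dffs, "gauss_fit")
    static = tra.detect_static(dffs, ns, k=3.0)
    return {
        "dynamic_sensitivity": float(hits / tot),
        "n_planted_spikes": int(tot),
        "dynamic_noise_frame_frac": float(dyn0.significant.mean()),
        "static_k3_noise_frame_frac": float(static.significant.mean()),
        "static_k3_nominal": float(stats.norm.sf(3.0)),
    }


# ---------------------------------------------------------------------------
# 4. Neuropil decontamination
# ---------------------------------------------------------------------------

def neuropil_benchmark(n_cells: int = 20, duration: float = 100.0,
                       frame_rate: float = 5.0, alpha: float = 0.9,
                       seed: int = 0) -> dict:
    """Recovery of somatic signals under shared-background contamination.

    Renders a movie whose neuropil background drives every soma with
    contamination factor α, extracts ROI and perisomatic traces, corrects
    with the same α, and reports the worst per-ROI correlation with the
    ground-truth somatic signal plus the error of the mean off-diagonal
    pairwise correlation relative to ground truth.
    """
    cells = synthgen.make_cells(n_cells, "disk", (128, 128), pixel_size=1.0,
                                radius=4.0, seed=seed + 1)
    gt = synthgen.make_activity(n_cells, duration=duration,
                                frame_rate=frame_rate, background_rate=0.15,
                                noise_sigma=0.03, seed=seed + 2)
    res = synthgen.render_movie(cells, gt.observed, frame_rate=frame_rate,
                                pixel_size=1.0, neuropil_gain=400.0,
                                alpha_true=alpha, seed=seed + 3)
    rois = cells.to_roimap()
    soma = sig.extract_traces(res.movie, rois)
    masks = sig.perisomatic_masks(rois, res.movie.frame_shape, radius=20.0,
                                  pixel_size=1.0)
    npil = sig.extract_neuropil_traces(res.movie, masks)
    corrected = sig.neuropil_correct(soma, npil, alpha=alpha)

    def offdiag(M):
        return float(M[np.triu_indices(len(M), 1)].mean())

    r = [float(np.corrcoef(corrected.F[i], gt.observed[i])[0, 1])
         for i in range(n_cells)]
    c_raw = offdiag(np.corrcoef(soma.F))
    c_cor = offdiag(np.corrcoef(corrected.F))
    c_true = offdiag(np.corrcoef(gt.observed))
    return {
        "min_trace_correlation": float(min(r)),
        "raw_offdiag_corr": c_raw,
        "corrected_offdiag_corr": c_cor,
        "true_offdiag_corr": c_true,
        "offdiag_corr_error": float(abs(c_cor - c_true)),
    }


# ---------------------------------------------------------------------------
# 5. Segmentation
# ---------------------------------------------------------------------------

def segmentation_benchmark(n_cells: int = 50, seed: int = 0) -> dict:
    """Detection rate of planted disk and ring cells at IoU ≥ 0.5."""

    def iou(a, b):
        A = set(map(tuple, a))
        B = set(map(tuple, b))
        return len(A & B) / len(A | B)

    def rate(cells, rois):
        return float(np.mean([any(iou(m, r) >= 0.5 for r in rois.rois)
                              for m in cells.masks]))

    disks = synthgen.make_cells(n_cells, "disk", (256, 256), pixel_size=1.0,
                                radius=4.0, min_gap=3.0, seed=seed + 1)
    img_d = synthgen.mean_image(disks, noise=0.01, seed=seed + 1)
    p_d = seg.SegmentationParams(mode="labeled_nuclei", roi_size_opt="smaller",
                                 thr_soma=0.1, thr_neuropil=0.45, area_min=10)
    norm_d = seg.normalize_contrast(img_d, p_d.local_contrast)
    rois_d = seg.filter_rois(seg.detect_rois(norm_d, p_d), norm_d, p_d)

    rings = synthgen.make_cells(n_cells, "ring", (256, 256), pixel_size=1.0,
                                radius=5.0, min_gap=3.0, seed=seed + 2)
    img_r = synthgen.mean_image(rings, nucleus_dim=0.0, noise=0.01, seed=seed + 2)
    p_r = seg.SegmentationParams(mode="unlabeled_nuclei", roi_size_opt="bigger",
                                 thr_soma=0.15, thr_neuropil=0.3, area_min=10)
    norm_r = seg.normalize_contrast(img_r, p_r.local_contrast)
    rois_r = seg.detect_rois(norm_r, p_r, pixel_size=1.0)
    return {
        "disk_detection_rate": rate(disks, rois_d),
        "ring_detection_rate": rate(rings, rois_r),
        "n_disk_rois": len(rois_d),
        "n_ring_rois": len(rois_r),
    }


# ---------------------------------------------------------------------------
# 6. Tuning-map recovery
# ---------------------------------------------------------------------------

def tuning_benchmark(n_tuned: int = 30, n_flat: int = 10,
                     frame_rate: float = 5.0, seed: int = 0) -> dict:
    """Topographic tuning recovery and flat-cell saturation.

    Tuned cells carry a linear gradient of preferred stimulus values; flat
    cells are silent non-responders. Tuning is computed from significant
    transients only (masked ΔF/F0), so non-responders have exactly flat
    curves. Reports the Spearman correlation between planted and recovered
    preferred values and the maximum HSV saturation over flat cells.
    """
    n = n_tuned + n_flat
    pref = np.linspace(-45.0, 45.0, n_tuned)
    values = np.tile(np.arange(-45.0, 50.0, 15.0), 6)  # 7 values x 6 trials
    times = 10.0 + 12.0 * np.arange(len(values))
    ev = EventTimeline(times=times, values=values)
    tau = 0.5  # GCaMP6s-like kinetics: well sampled at 5 Hz
    gt_t = synthgen.make_activity(
        n_tuned, duration=times.max() + 12, frame_rate=frame_rate,
        tau_decay=tau, background_rate=0.02, noise_sigma=0.05, events=ev,
        preferred_values=pref, tuning_sigma=15.0, stim_spikes_peak=3.0,
        seed=seed + 1)
    gt_f = synthgen.make_activity(
        n_flat, duration=times.max() + 12, frame_rate=frame_rate,
        tau_decay=tau, background_rate=0.0, noise_sigma=0.05, seed=seed + 2)
    dff = DFFTraces(dff=np.vstack([gt_t.observed, gt_f.observed]),
                    F0=np.ones(n))
    noise = tra.estimate_sigma(dff, "gauss_fit")
    raster = tra.detect_dynamic(dff, noise, tau, frame_rate, confidence=0.95)
    trials = resp.event_locked(raster.masked_dff, ev, frame_rate,
                               window=(2.0, 4.0), raster=raster)
    tuning = resp.tuning_curves(trials)
    hsv = resp.hsv_map(tuning)
    rho = spearmanr(pref, tuning.v_peak[:n_tuned]).statistic
    return {
        "spearman_rho": float(rho),
        "flat_cell_max_saturation": float(hsv[n_tuned:, 1].max()),
        "n_flat_unresponsive": int(tuning.unresponsive[n_tuned:].sum()),
    }


# ---------------------------------------------------------------------------
# 7. Surrogate null models
# ---------------------------------------------------------------------------

def surrogate_benchmark(n_rois: int = 100, n_rep: int = 200,
                        seed: int = 0) -> dict:
    """TSA distance preservation and RSA discrimination.

    Checks that every emitted topographical surrogate satisfies the
    pairwise-distance KS ≤ 0.1 bound, that the RSA null rejects a planted
    correlated assembly on pooled pairwise correlations, and that it does
    NOT reject an assembly whose member activity levels match the
    population (no spurious differences).
    """
    cells = synthgen.make_cells(n_rois, "disk", (320, 320), pixel_size=1.0,
                                radius=4.0, min_gap=4.0, seed=seed + 1)
    rois = cells.to_roimap()
    cents = rois.centroids[:, :2]
    order = np.argsort(cents[:, 0] + cents[:, 1])
    compact = np.sort(order[:20])  # spatially compact assembly

    rng = np.random.default_rng(seed + 2)
    X = rng.normal(size=(n_rois, 1500))
    ev = rng.random(1500) < 0.08
    X[compact[:, None], np.flatnonzero(ev)[None, :]] += 2.5
    Z = asm.build_activity(X)
    a = asm.AssemblySet(members=[compact])

    tsa = sur.topographic_surrogates(a, rois, n_rep=min(n_rep, 100),
                                     tol=0.1, seed=seed + 3)
    ks_vals = [ks_2samp(pdist(cents[compact]), pdist(cents[rep[0]])).statistic
               for rep in tsa.replicates]
    tsa_ok_frac = float(np.mean(np.asarray(ks_vals) <= 0.1))

    rsa = sur.random_surrogates(a, n_rois=n_rois, n_rep=n_rep, seed=seed + 4)
    corr_cmp = sur.pool_compare(a, rsa, "pairwise_correlation", Z=Z)

    matched_vals = rng.normal(1.0, 0.2, size=n_rois)  # activity matched
    act_cmp = sur.pool_compare(a, rsa, "mean_activity", roi_values=matched_vals)
    return {
        "tsa_ks_pass_frac": tsa_ok_frac,
        "tsa_ks_max": float(max(ks_vals)),
        "rsa_correlation_p": float(corr_cmp.p_value),
        "rsa_matched_activity_p": float(act_cmp.p_value),
    }


# ---------------------------------------------------------------------------
# 8. Determinism and monotonicity
# ---------------------------------------------------------------------------

def determinism_benchmark(seed: int = 0) -> dict:
    """Repeat every stochastic stage with a fixed seed and compare outputs.

    Also sweeps the zMax, static-k and dynamic-confidence thresholds on a
    small instance and asserts the significant/member sets shrink
    monotonically as the thresholds tighten.
    """
    gt1 = synthgen.make_activity(8, duration=60, frame_rate=10.0,
                                 memberships=[np.arange(4)], seed=seed + 1)
    gt2 = synthgen.make_activity(8, duration=60, frame_rate=10.0,
                                 memberships=[np.arange(4)], seed=seed + 1)
    synth_ok = (np.array_equal(gt1.observed, gt2.observed)
                and np.array_equal(gt1.spike_counts, gt2.spike_counts))

    cells = synthgen.make_cells(6, "disk", (64, 64), pixel_size=1.0,
                                radius=4.0, seed=seed + 2)
    m1 = synthgen.render_movie(cells, gt1.observed[:6], 10.0, 1.0,
                               jitter_sd=1.0, seed=seed + 3)
    m2 = synthgen.render_movie(cells, gt1.observed[:6], 10.0, 1.0,
                               jitter_sd=1.0, seed=seed + 3)
    render_ok = np.array_equal(m1.movie.data, m2.movie.data)

    rng = np.random.default_rng(seed + 4)
    X = rng.normal(size=(60, 800))
    X[:15, rng.random(800) < 0.06] += 3.0
    Z = asm.build_activity(X)
    d1 = asm.detect_assemblies(Z, n_shuffle=200, seed=seed + 5)
    d2 = asm.detect_assemblies(Z, n_shuffle=200, seed=seed + 5)
    asm_ok = (len(d1) == len(d2) and
              all(np.array_equal(a, b) for a, b in zip(d1.members, d2.members)))

    k1 = asm.cluster_baseline(Z, "kmeans", k=3, seed=seed + 6)
    k2 = asm.cluster_baseline(Z, "kmeans", k=3, seed=seed + 6)
    km_ok = all(np.array_equal(a, b) for a, b in zip(k1.members, k2.members))

    a = asm.AssemblySet(members=[np.arange(15)])
    cells2 = synthgen.make_cells(100, "disk", (320, 320), pixel_size=1.0,
                                 radius=4.0, min_gap=4.0, seed=seed + 7)
    rois = cells2.to_roimap()
    s1 = sur.random_surrogates(a, 100, n_rep=20, seed=seed + 8)
    s2 = sur.random_surrogates(a, 100, n_rep=20, seed=seed + 8)
    a2 = asm.AssemblySet(members=[np.arange(8)])
    t1 = sur.topographic_surrogates(a2, rois, n_rep=5, seed=seed + 9)
    t2 = sur.topographic_surrogates(a2, rois, n_rep=5, seed=seed + 9)
    sur_ok = (all(np.array_equal(x[0], y[0])
                  for x, y in zip(s1.replicates, s2.replicates))
              and all(np.array_equal(x[0], y[0])
                      for x, y in zip(t1.replicates, t2.replicates)))

    # monotonicity sweeps
    pca = asm.pca_mp(Z)
    rot, unit = asm.promax_rotate(pca)
    prev = None
    zmax_mono = True
    for z in (0.5, 1.0, 1.5, 2.0, 3.0, np.inf):
        cur = set()
        for m in asm.build_assemblies(rot, unit, z).members:
            cur |= set(m.tolist())
        if prev is not None and not cur <= prev:
            zmax_mono = False
        prev = cur

    gt = synthgen.make_activity(5, duration=50, frame_rate=20.0,
                                amplitude=0.2, noise_sigma=0.05,
                                background_rate=0.2, seed=seed + 10)
    dff = DFFTraces(dff=gt.observed, F0=np.ones(5))
    noise = tra.estimate_sigma(dff)
    k_mono = True
    prev = None
    for k in (1.5, 2.0, 3.0, 4.0, 6.0):
        cur = tra.detect_static(dff, noise, k=k).significant
        if prev is not None and not np.all(cur <= prev):
            k_mono = False
        prev = cur
    conf_mono = True
    prev = None
    for conf in (0.8, 0.9, 0.95, 0.99):
        cur = tra.detect_dynamic(dff, noise, 0.25, 20.0, conf).significant
        if prev is not None and not np.all(cur <= prev):
            conf_mono = False
        prev = cur
    return {
        "synthgen_deterministic": bool(synth_ok),
        "render_deterministic": bool(render_ok),
        "assemblies_deterministic": bool(asm_ok),
        "kmeans_deterministic": bool(km_ok),
        "surrogates_deterministic": bool(sur_ok),
        "zmax_monotone": bool(zmax_mono),
        "static_k_monotone": bool(k_mono),
        "confidence_monotone": bool(conf_mono),
    }
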