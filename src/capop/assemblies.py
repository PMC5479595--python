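"""Non-exclusive neuronal-assembly detection by PCA-promax.

The z-scored ROI×frame activity matrix is reduced by PCA, keeping only
components whose correlation-matrix eigenvalues exceed the Marčenko–Pastur
upper bound for random data,

    λ_max = (1 + √(N/T))² + N^(−2/3),

(N ROIs, T frames; the second term is a finite-size correction). Because a
neuron may take part in several assemblies, the retained subspace is then
rotated obliquely (varimax followed by promax), which concentrates each
ROI's loading on few, possibly correlated, rotated components. An ROI joins
an assembly when its z-scored loading on that rotated component exceeds a
threshold zMax, chosen automatically at the first minimum of the density of
per-ROI maximal loadings. Near-duplicate assemblies (unit component dot
product > 0.6) are merged, and only assemblies that are significantly
correlated and synchronous versus membership-shuffled nulls are kept.

Exclusive k-means and hierarchical clusterings are provided as baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from capop.core_model import register_session_type
from capop.signals import DFFTraces
from capop.transients import TransientRaster


@register_session_type
@dataclass
class ActivityMatrix:
    """Z-scored ROI activity, one row per ROI (mean 0, SD 1 over used frames)."""

    Z: np.ndarray
    source: str = "dff"  # dff | significant
    kept_rois: np.ndarray = None
    dropped_rois: np.ndarray = None

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.kept_rois is None:
            self.kept_rois = np.arange(self.Z.shape[0], dtype=np.intp)
        if self.dropped_rois is None:
            self.dropped_rois = np.empty(0, dtype=np.intp)

    @property
    def n_rois(self) -> int:
        return self.Z.shape[0]

    @property
    def n_frames(self) -> int:
        return self.Z.shape[1]


@register_session_type
@dataclass
class PCASpace:
    """Eigen-decomposition of the ROI correlation matrix with the MP bound."""

    eigenvalues: np.ndarray     # all N, descending
    loadings: np.ndarray        # ROI × retained, eigvec·√λ
    components: np.ndarray      # ROI × retained, unit eigenvectors
    lambda_max: float
    n_retained: int


@register_session_type
@dataclass
class AssemblySet:
    """Detected assemblies: member index sets (overlap allowed) + dynamics."""

    members: list
    components: np.ndarray = None        # ROI × assembly, unit norm
    rotated_loadings: np.ndarray = None  # ROI × assembly
    zmax: float = np.nan
    activity: np.ndarray = None          # assembly × frame
    p_corr: np.ndarray = None
    p_sync: np.ndarray = None
    method: str = "pca_promax"

    def __post_init__(self) -> None:
        self.members = [np.asarray(m, dtype=np.intp) for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


def marchenko_pastur_lambda_max(n_rois: int, n_frames: int,
                                finite_size_correction: bool = True) -> float:
    """Upper eigenvalue bound for the correlation matrix of random activity."""
    lam = (1.0 + np.sqrt(n_rois / n_frames)) ** 2
    if finite_size_correction:
        lam += n_rois ** (-2.0 / 3.0)
    return float(lam)


def build_activity(data, source: str = "dff") -> ActivityMatrix:
    """Z-score per-ROI activity; frames with any non-finite sample are dropped.

    ``data`` may be :class:`DFFTraces` (``source="dff"``),
    :class:`TransientRaster` (``source="significant"``, uses ``masked_dff``)
    or a plain (N, T) array. Zero-variance ROIs are dropped with a report.
    """
    if isinstance(data, DFFTraces):
        X = data.dff
    elif isinstance(data, TransientRaster):
        X = data.masked_dff
        source = "significant"
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("at least 2 ROIs required")
    good_frames = np.isfinite(X).all(axis=0)
    X = X[:, good_frames]
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all ROIs have zero variance")
    dropped = np.flatnonzero(~keep)
    if len(dropped):
        warnings.warn(f"dropping {len(dropped)} zero-variance ROI(s)")
    Xk = X[keep]
    Z = (Xk - Xk.mean(axis=1, keepdims=True)) / Xk.std(axis=1, keepdims=True)
    if Z.shape[1] < Z.shape[0]:
        warnings.warn("T < N: Marčenko–Pastur regime assumption is weak")
    return ActivityMatrix(Z=Z, source=source,
                          kept_rois=np.flatnonzero(keep).astype(np.intp),
                          dropped_rois=dropped.astype(np.intp))


def pca_mp(Z: ActivityMatrix) -> PCASpace:
    """PCA of the ROI correlation matrix; keep eigenvalues above λ_max."""
    X = Z.Z
    N, T = X.shape
    if N < 2 or T < 2:
        raise ValueError("need at least 2 ROIs and 2 frames")
    C = (X @ X.T) / T  # rows are z-scored, so this is the correlation matrix
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    lam_max = marchenko_pastur_lambda_max(N, T)
    n_ret = int(np.sum(evals > lam_max))
    comp = evecs[:, :n_ret]
    loadings = comp * np.sqrt(np.clip(evals[:n_ret], 0, None))
    return PCASpace(eigenvalues=evals, loadings=loadings, components=comp,
                    lambda_max=lam_max, n_retained=n_ret)


def _varimax(A: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation matrix for loadings A (SVD algorithm)."""
    p, k = A.shape
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        L = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (L ** 3 - L @ np.diag(np.sum(L ** 2, axis=0)) / p))
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    return R


def promax_rotate(pca: PCASpace, kappa: float = 4.0) -> tuple:
    """Oblique promax rotation of the retained loadings.

    Varimax (Kaiser-normalized) followed by an oblique least-squares fit to
    the power-``kappa`` target. Component signs are flipped so each rotated
    component's largest-magnitude loading is positive. Returns
    ``(rotated_loadings, unit_components)``, both ROI × n_retained.
    """
    if pca.n_retained < 1:
        raise ValueError("no informative components: all eigenvalues below λ_max")
    L = pca.loadings
    if pca.n_retained == 1:
        rot = L.copy()
        if np.abs(rot).max() > 0 and rot[np.argmax(np.abs(rot[:, 0])), 0] < 0:
            rot = -rot
        unit = rot / np.linalg.norm(rot, axis=0, keepdims=True)
        return rot, unit
    h = np.sqrt(np.sum(L ** 2, axis=1, keepdims=True))
    h[h == 0] = 1.0
    A = L / h  # Kaiser normalization
    R = _varimax(A)
    V = (A @ R) * h  # un-normalized varimax pattern
    # promax target and oblique least-squares transform
    P = np.sign(V) * np.abs(V) ** kappa
    U, *_ = np.linalg.lstsq(V, P, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    rot = V @ U
    # sign convention: dominant loading positive
    for j in range(rot.shape[1]):
        if rot[np.argmax(np.abs(rot[:, j])), j] < 0:
            rot[:, j] = -rot[:, j]
    norms = np.linalg.norm(rot, axis=0)
    norms[norms == 0] = 1.0
    unit = rot / norms
    return rot, unit


def zscore_loadings(rotated: np.ndarray) -> np.ndarray:
    """Robustly z-score loadings per component across ROIs.

    Centered on the median and scaled by 1.4826·MAD (Gaussian-consistent),
    so the standardization reflects the non-member bulk: the member
    loadings are exactly the outliers being looked for, and letting them
    inflate a mean/SD z-score compresses the very separation the zMax
    threshold needs. Makes loadings comparable across components.
    """
    med = np.median(rotated, axis=0, keepdims=True)
    mad = np.median(np.abs(rotated - med), axis=0, keepdims=True)
    scale = 1.4826 * mad
    fallback = rotated.std(axis=0, keepdims=True)
    scale = np.where(scale > 0, scale, np.where(fallback > 0, fallback, 1.0))
    return (rotated - med) / scale


def select_zmax(rotated: np.ndarray, smooth: float = 1.0,
                manual: float | None = None, grid_points: int = 512) -> float:
    """Threshold on z-scored maximal loadings: first density minimum above the mode.

    The per-ROI maximum z-scored loading over components is kernel-density
    estimated; zMax is the first local minimum above the global mode — the
    point where the non-member bulk's density dies away, before the member
    cloud. The bandwidth is Silverman's rule on a robust (MAD-based) scale
    estimate, times ``smooth``: the loading distribution is strongly
    bimodal by construction, and a bandwidth derived from the full-sample
    SD over-smooths the valley. Sitting at the lower edge of the valley
    keeps ROIs that belong to several assemblies — whose per-assembly
    loadings are diluted by their larger total variance — inside their
    assemblies; occasional borderline non-members are cheap by comparison
    and are screened later by the shuffle significance test.
    ``manual`` overrides the estimate.
    """
    if manual is not None:
        return float(manual)
    zl = zscore_loadings(rotated)
    m = zl.max(axis=1)
    sd = m.std()
    robust_sd = 1.4826 * np.median(np.abs(m - np.median(m)))
    if robust_sd == 0 or sd == 0:
        raise ValueError("degenerate loading distribution — choose zmax manually")
    kde = stats.gaussian_kde(m)
    bw0 = 1.06 * robust_sd * len(m) ** (-0.2) * smooth
    lo, hi = m.min(), m.max()
    pad = 0.05 * (hi - lo)
    xs = np.linspace(lo - pad, hi + pad, grid_points)
    # a valley can be smoothed away when the member cloud inflates the scale
    # estimate; retry with a progressively narrower kernel before giving up
    for shrink in (1.0, 0.5, 0.25, 0.125):
        kde.set_bandwidth(bw0 * shrink / sd)
        d = kde(xs)
        mode = int(np.argmax(d))
        for i in range(mode + 1, grid_points - 1):
            if d[i] < d[i - 1] and d[i] <= d[i + 1]:
                # a genuine valley, not a sampling wiggle: clearly below the
                # bulk mode and followed by a prominent second cloud
                second_cloud = np.max(d[i + 1:])
                if (d[i] <= 0.5 * d[mode] and second_cloud >= 2.0 * d[i]
                        and second_cloud >= 0.05 * d[mode]):
                    return float(xs[i])
    raise ValueError("no local minimum found above the mode; the loading "
                     "distribution looks unimodal — choose zmax manually")


def build_assemblies(rotated: np.ndarray, unit_components: np.ndarray,
                     zmax: float) -> AssemblySet:
    """Membership: ROIs whose z-scored loading exceeds zmax; empty sets dropped.

    Because each ROI's z-scored activity has unit total variance, an ROI
    that takes part in m assemblies splits that variance among them and its
    per-assembly loadings shrink by ≈ √m. A plain ``loading > zmax`` rule
    therefore systematically drops exactly the multi-assembly ROIs the
    oblique rotation exists to find. The membership test compensates: for
    each ROI, count candidate assemblies m_c = #{loadings > zmax/√2}; when
    m_c ≥ 2 the ROI joins every component whose loading exceeds zmax/√m_c.
    Single-assembly ROIs (m_c ≤ 1) are judged against plain zmax.
    """
    if np.isnan(zmax):
        raise ValueError("zmax must not be NaN")
    zl = zscore_loadings(rotated)
    n_rois, n_comp = zl.shape
    accept = np.zeros((n_rois, n_comp), dtype=bool)
    for i in range(n_rois):
        m_c = int(np.sum(zl[i] > zmax / np.sqrt(2.0)))
        thr = zmax / np.sqrt(m_c) if m_c >= 2 else zmax
        accept[i] = zl[i] > thr
    members, keep_cols = [], []
    for j in range(n_comp):
        m = np.flatnonzero(accept[:, j])
        if len(m):
            members.append(m)
            keep_cols.append(j)
    if not members:
        warnings.warn("no assembly has any member at this zmax")
        return AssemblySet(members=[], components=unit_components[:, :0],
                           rotated_loadings=rotated[:, :0], zmax=float(zmax))
    return AssemblySet(members=members,
                       components=unit_components[:, keep_cols],
                       rotated_loadings=rotated[:, keep_cols],
                       zmax=float(zmax))


def merge_similar(assemblies: AssemblySet, dot_thr: float = 0.6) -> AssemblySet:
    """Merge assemblies whose unit components have dot product > ``dot_thr``.

    Iterative: the pair with the largest dot product (ties → lower index
    pair) is merged — member union, renormalized mean component — and the
    scan restarts until no pair exceeds the threshold.
    """
    members = [m.copy() for m in assemblies.members]
    comps = [assemblies.components[:, j].copy() for j in range(len(members))]
    while len(members) > 1:
        best, best_dot = None, dot_thr
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                dot = float(abs(comps[a] @ comps[b]))
                if dot > best_dot:
                    best, best_dot = (a, b), dot
        if best is None:
            break
        a, b = best
        members[a] = np.unique(np.concatenate([members[a], members[b]]))
        merged = comps[a] + comps[b]
        comps[a] = merged / np.linalg.norm(merged)
        del members[b], comps[b]
    comp_arr = np.column_stack(comps) if comps else assemblies.components[:, :0]
    return AssemblySet(members=members, components=comp_arr,
                       rotated_loadings=assemblies.rotated_loadings,
                       zmax=assemblies.zmax, method=assemblies.method)


def test_significance(assemblies: AssemblySet, Z: ActivityMatrix,
                      n_shuffle: int = 1000, alpha: float = 0.05,
                      coactive_z: float = 2.0, seed: int = 0) -> AssemblySet:
    """Keep assemblies more correlated AND more synchronous than shuffled ones.

    For each assembly of size m the observed statistics are (1) the mean
    pairwise correlation among members and (2) the peak per-frame count of
    co-active members (z > ``coactive_z``). Nulls come from ``n_shuffle``
    random m-ROI sets (activity untouched, membership randomized);
    p = (1 + #{null ≥ observed})/(1 + n_shuffle). Single-member assemblies
    are dropped with a report.
    """
    if n_shuffle < 100:
        raise ValueError("n_shuffle must be at least 100")
    rng = np.random.default_rng(seed)
    X = Z.Z
    N, T = X.shape
    C = (X @ X.T) / T
    B = X > coactive_z

    def stats_for(idx: np.ndarray) -> tuple:
        sub = C[np.ix_(idx, idx)]
        m = len(idx)
        mean_corr = (sub.sum() - m) / (m * (m - 1))
        peak_sync = int(B[idx].sum(axis=0).max())
        return mean_corr, peak_sync

    kept, p_corr_list, p_sync_list, kept_cols = [], [], [], []
    for j, mem in enumerate(assemblies.members):
        if len(mem) < 2:
            warnings.warn(f"assembly {j} has a single member; dropped")
            continue
        obs_c, obs_s = stats_for(mem)
        null_c = np.empty(n_shuffle)
        null_s = np.empty(n_shuffle)
        for r in range(n_shuffle):
            idx = rng.choice(N, size=len(mem), replace=False)
            null_c[r], null_s[r] = stats_for(idx)
        p_c = (1 + np.sum(null_c >= obs_c)) / (1 + n_shuffle)
        p_s = (1 + np.sum(null_s >= obs_s)) / (1 + n_shuffle)
        if p_c < alpha and p_s < alpha:
            kept.append(mem)
            p_corr_list.append(p_c)
            p_sync_list.append(p_s)
            kept_cols.append(j)
    comps = assemblies.components[:, kept_cols] if assemblies.components is not None \
        and assemblies.components.shape[1] == len(assemblies.members) else None
    out = AssemblySet(members=kept, components=comps,
                      rotated_loadings=assemblies.rotated_loadings,
                      zmax=assemblies.zmax, method=assemblies.method,
                      p_corr=np.array(p_corr_list), p_sync=np.array(p_sync_list))
    out.activity = assembly_activity(out, Z) if kept else None
    return out


def cluster_baseline(Z: ActivityMatrix, method: str = "kmeans", k: int = 2,
                     reduce: bool = True, seed: int = 0) -> AssemblySet:
    """Exclusive baseline clustering of ROIs (k-means or hierarchical).

    Features are the rows of Z, optionally projected onto the MP-retained
    principal components first (``reduce=True``; large T makes raw-trace
    clustering slow or non-convergent). Hierarchical clustering uses
    correlation distance with average linkage. The returned member sets
    form a disjoint partition, unlike PCA-promax.
    """
    if not 2 <= k <= Z.n_rois:
        raise ValueError("k must lie in [2, N]")
    if reduce:
        pca = pca_mp(Z)
        feats = pca.loadings if pca.n_retained >= 1 else Z.Z
    else:
        feats = Z.Z
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
        labels = km.fit_predict(feats)
    elif method == "hierarchical":
        X = Z.Z
        C = (X @ X.T) / X.shape[1]
        dist = 1.0 - C[np.triu_indices(Z.n_rois, k=1)]
        link = linkage(np.clip(dist, 0, None), method="average")
        labels = fcluster(link, t=k, criterion="maxclust") - 1
    else:
        raise ValueError(f"unknown method {method!r}")
    members = [np.flatnonzero(labels == c) for c in range(labels.max() + 1)]
    members = [m for m in members if len(m)]
    out = AssemblySet(members=members, method=method)
    out.activity = assembly_activity(out, Z)
    return out


def assembly_activity(assemblies: AssemblySet, Z: ActivityMatrix) -> np.ndarray:
    """Activation time course per assembly: mean member z-scored activity."""
    return np.vstack([Z.Z[m].mean(axis=0) for m in assemblies.members]) \
        if len(assemblies) else np.empty((0, Z.n_frames))


def detect_assemblies(Z: ActivityMatrix, kappa: float = 4.0,
                      zmax: float | None = None, smooth: float = 1.0,
                      dot_thr: float = 0.6, n_shuffle: int = 1000,
                      alpha: float = 0.05, seed: int = 0) -> AssemblySet:
    """Full PCA-promax chain: PCA → promax → zMax → merge → significance."""
    pca = pca_mp(Z)
    rot, unit = promax_rotate(pca, kappa=kappa)
    z = select_zmax(rot, smooth=smooth, manual=zmax)
    asm = build_assemblies(rot, unit, z)
    asm = merge_similar(asm, dot_thr=dot_thr)
    asm = test_significance(asm, Z, n_shuffle=n_shuffle, alpha=alpha, seed=seed)
    return asm
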