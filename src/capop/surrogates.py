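"""Surrogate control assemblies and pooled-feature comparison.

Two null models preserve every ROI's own activity trace and only randomize
which ROIs are grouped together:

* RSA (random surrogate assembly) — each original assembly is replaced by
  an equally sized uniform random ROI set, destroying all structure;
* TSA (topographical surrogate assembly) — the original members' centroid
  cloud is rigidly transformed (rotation, optional reflection, translation)
  and snapped to unused ROI centroids, preserving the distribution of
  pairwise physical distances; replicates are accepted only if the
  two-sample KS distance between original and surrogate pairwise-distance
  distributions stays within tolerance.

Pooled per-ROI or per-pair features of the original assemblies are compared
against the surrogate pool with shared-bin histograms and a KS test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist, pdist

from capop.assemblies import ActivityMatrix, AssemblySet
from capop.core_model import ROIMap


@dataclass
class SurrogateSet:
    """Replicated surrogate assemblies mirroring an original AssemblySet.

    ``replicates[r][a]`` is the member index array of surrogate ``a`` in
    replicate ``r``; every surrogate has the size of its original.
    """

    kind: str  # RSA | TSA
    replicates: list
    seed: int

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def random_surrogates(assemblies: AssemblySet, n_rois: int, n_rep: int = 1000,
                      seed: int = 0) -> SurrogateSet:
    """RSA: uniform same-size random ROI sets, sampled without replacement."""
    sizes = [len(m) for m in assemblies.members]
    if any(s > n_rois for s in sizes):
        raise ValueError("assembly size exceeds ROI count")
    rng = np.random.default_rng(seed)
    reps = [[np.sort(rng.choice(n_rois, size=s, replace=False)) for s in sizes]
            for _ in range(n_rep)]
    return SurrogateSet(kind="RSA", replicates=reps, seed=seed)


def topographic_surrogates(assemblies: AssemblySet, rois: ROIMap,
                           pixel_size: float = 1.0, n_rep: int = 1000,
                           tol: float = 0.1, seed: int = 0,
                           max_attempts: int = 500) -> SurrogateSet:
    """TSA: rigid-transform + nearest-unused-centroid snap, KS-gated.

    Each replicate rotates (and possibly reflects) the original member
    centroids about their center of mass, translates them to a random
    location within the centroid bounding box, and maps each transformed
    point to the nearest ROI centroid not yet used in that surrogate. The
    replicate is accepted only if KS(original pair distances, surrogate
    pair distances) ≤ ``tol``; after ``max_attempts`` failures an error
    reports the attempt budget.
    """
    rng = np.random.default_rng(seed)
    cents = rois.centroids[:, :2] * pixel_size
    n_rois = len(rois)
    lo = cents.min(axis=0)
    hi = cents.max(axis=0)
    orig_pd = [pdist(cents[m]) for m in assemblies.members]
    reps = []
    for _ in range(n_rep):
        rep = []
        for a, m in enumerate(assemblies.members):
            pts = cents[m]
            center = pts.mean(axis=0)
            ok = False
            for _att in range(max_attempts):
                theta = rng.uniform(0, 2 * np.pi)
                c, s = np.cos(theta), np.sin(theta)
                R = np.array([[c, -s], [s, c]])
                if rng.random() < 0.5:
                    R = R @ np.diag([1.0, -1.0])  # reflection
                rotated = (pts - center) @ R.T
                # translate so the whole transformed cloud stays inside the
                # centroid bounding box; otherwise snapping pulls border
                # points inward and distorts the distance distribution
                t_lo = lo - rotated.min(axis=0)
                t_hi = hi - rotated.max(axis=0)
                target = np.where(t_hi > t_lo, rng.uniform(t_lo, np.maximum(t_hi, t_lo)),
                                  0.5 * (t_lo + t_hi))
                moved = rotated + target
                idx = _snap_to_unused(moved, cents)
                if len(m) > 1:
                    ks = stats.ks_2samp(orig_pd[a], pdist(cents[idx])).statistic
                else:
                    ks = 0.0
                if ks <= tol:
                    rep.append(np.sort(idx))
                    ok = True
                    break
            if not ok:
                raise RuntimeError(
                    f"TSA: no acceptable placement for assembly {a} of size "
                    f"{len(m)} after {max_attempts} attempts (field too "
                    f"small or tolerance too tight)")
        reps.append(rep)
    return SurrogateSet(kind="TSA", replicates=reps, seed=seed)


def _snap_to_unused(points: np.ndarray, cents: np.ndarray) -> np.ndarray:
    """Greedy nearest-centroid assignment without reuse."""
    d = cdist(points, cents)
    used = np.zeros(len(cents), dtype=bool)
    out = np.empty(len(points), dtype=np.intp)
    # assign in order of best available match to keep the shape tight
    order = np.argsort(d.min(axis=1))
    for i in order:
        row = np.where(used, np.inf, d[i])
        j = int(np.argmin(row))
        out[i] = j
        used[j] = True
    return out


@dataclass
class PoolComparison:
    """Pooled original vs surrogate feature distributions and KS test."""

    feature: str
    orig_values: np.ndarray
    surr_values: np.ndarray
    bins: np.ndarray
    hist_orig: np.ndarray   # normalized frequency (density)
    hist_surr: np.ndarray
    ks_stat: float
    p_value: float


def pool_compare(assemblies: AssemblySet, surrogates: SurrogateSet,
                 feature: str = "pairwise_correlation", *,
                 roi_values: np.ndarray | None = None,
                 Z: ActivityMatrix | None = None,
                 rois: ROIMap | None = None,
                 pixel_size: float = 1.0) -> PoolComparison:
    """Pool a feature over original and surrogate assemblies and compare.

    Built-in features: ``mean_activity`` (per-ROI values supplied via
    ``roi_values``), ``pairwise_correlation`` (member-pair correlations from
    ``Z``) and ``pairwise_distance`` (member-pair physical distances from
    ``rois`` centroids, μm). ``roi_values`` may also carry any user-defined
    per-ROI quantity. Returns shared-bin normalized histograms and the
    two-sample KS p-value.
    """
    if feature in ("mean_activity", "per_roi"):
        if roi_values is None:
            raise ValueError(f"feature {feature!r} requires roi_values")
        roi_values = np.asarray(roi_values, dtype=float)

        def values_of(members: np.ndarray) -> np.ndarray:
            if members.max(initial=-1) >= len(roi_values):
                raise ValueError("feature length mismatch: roi_values shorter "
                                 "than ROI index range")
            return roi_values[members]
    elif feature == "pairwise_correlation":
        if Z is None:
            raise ValueError("feature 'pairwise_correlation' requires Z")
        C = (Z.Z @ Z.Z.T) / Z.n_frames

        def values_of(members: np.ndarray) -> np.ndarray:
            if len(members) < 2:
                return np.empty(0)
            return C[np.ix_(members, members)][np.triu_indices(len(members), k=1)]
    elif feature == "pairwise_distance":
        if rois is None:
            raise ValueError("feature 'pairwise_distance' requires rois")
        cents = rois.centroids[:, :2] * pixel_size

        def values_of(members: np.ndarray) -> np.ndarray:
            if len(members) < 2:
                return np.empty(0)
            return pdist(cents[members])
    else:
        raise ValueError(f"unknown feature {feature!r}")

    orig = np.concatenate([values_of(m) for m in assemblies.members]) \
        if len(assemblies) else np.empty(0)
    surr = np.concatenate([values_of(m) for rep in surrogates.replicates
                           for m in rep]) \
        if surrogates.replicates else np.empty(0)
    pooled = np.concatenate([orig, surr])
    bins = np.histogram_bin_edges(pooled, bins="fd") if len(pooled) else np.array([0, 1])
    h_orig, _ = np.histogram(orig, bins=bins, density=True)
    h_surr, _ = np.histogram(surr, bins=bins, density=True)
    if len(orig) and len(surr):
        res = stats.ks_2samp(orig, surr)
        ks, p = float(res.statistic), float(res.pvalue)
    else:
        ks, p = np.nan, np.nan
    return PoolComparison(feature=feature, orig_values=orig, surr_values=surr,
                          bins=bins, hist_orig=h_orig, hist_surr=h_surr,
                          ks_stat=ks, p_value=p)
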