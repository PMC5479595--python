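import numpy as np
import pytest

from capop import assemblies as asm
from capop import synthgen


def _planted_activity(seed=1, n=200, T=1500, groups=((0, 20), (20, 40)),
                      overlap=0):
    """Noise matrix with planted co-activation groups; returns (Z, members)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(n, T))
    members = []
    for g0, g1 in groups:
        m = np.arange(g0, g1)
        members.append(m)
        events = rng.random(T) < 0.06
        X[m[:, None], np.flatnonzero(events)[None, :]] += 3.0
    return asm.build_activity(X), members


class TestBuildActivity:
    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        Z = asm.build_activity(rng.uniform(1, 5, size=(6, 300)))
        assert np.all(np.abs(Z.Z.mean(axis=1)) < 1e-10)
        assert np.all(np.abs(Z.Z.std(axis=1) - 1) < 1e-10)

    def test_zero_variance_rows_dropped(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 100))
        X[2] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            Z = asm.build_activity(X)
        assert Z.n_rois == 3
        assert np.array_equal(Z.dropped_rois, [2])

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            asm.build_activity(np.ones((3, 50)))

    def test_multiplane_concatenation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(3, 100))
        b = rng.normal(size=(2, 100))
        Z = asm.build_activity(np.vstack([a, b]))
        assert Z.n_rois == 5


class TestPcaMP:
    def test_lambda_max_formula_at_n_equals_t(self):
        # N = T: (1 + 1)^2 + N^(-2/3)
        for n in (50, 200):
            assert np.isclose(asm.marchenko_pastur_lambda_max(n, n),
                              4.0 + n ** (-2.0 / 3.0))

    def test_eigenvalue_sum_equals_trace(self):
        Z, _ = _planted_activity()
        pca = asm.pca_mp(Z)
        assert abs(pca.eigenvalues.sum() - Z.n_rois) < 1e-6 * Z.n_rois

    def test_pure_noise_rarely_exceeds_bound(self):
        rng = np.random.default_rng(3)
        fracs = [asm.pca_mp(asm.build_activity(
            rng.normal(size=(100, 1000)))).n_retained / 100
            for _ in range(20)]
        assert np.mean(fracs) < 0.01

    def test_planted_perfect_group_single_component(self):
        rng = np.random.default_rng(4)
        n, T = 200, 2000
        X = rng.normal(size=(n, T))
        shared = rng.normal(size=T)
        X[:20] = shared  # 20 perfectly correlated ROIs
        pca = asm.pca_mp(asm.build_activity(X))
        assert pca.n_retained == 1
        top20 = np.argsort(np.abs(pca.loadings[:, 0]))[::-1][:20]
        assert set(top20) == set(range(20))


class TestPromax:
    def test_single_component_identity_up_to_sign(self):
        Z, _ = _planted_activity(groups=((0, 30),))
        pca = asm.pca_mp(Z)
        assert pca.n_retained == 1
        rot, unit = asm.promax_rotate(pca)
        assert np.allclose(np.abs(rot), np.abs(pca.loadings), atol=1e-9)
        assert np.isclose(np.linalg.norm(unit[:, 0]), 1.0)

    def test_two_orthogonal_assemblies_separated(self):
        Z, members = _planted_activity(seed=5)
        pca = asm.pca_mp(Z)
        rot, _ = asm.promax_rotate(pca)
        assert rot.shape[1] >= 2
        for m in members:
            j = np.argmax([np.abs(rot[m, c]).mean() for c in range(rot.shape[1])])
            within = np.abs(rot[m, j]).mean()
            others = np.setdiff1d(np.arange(Z.n_rois), np.concatenate(members))
            cross = np.abs(rot[others, j]).mean()
            assert cross < 0.1 * within

    def test_oblique_structure_nonorthogonal_components(self):
        rng = np.random.default_rng(6)
        n, T = 150, 1500
        X = rng.normal(size=(n, T))
        m1 = np.arange(0, 25)
        m2 = np.arange(20, 45)  # shares 5 ROIs with m1
        for m in (m1, m2):
            ev = rng.random(T) < 0.06
            X[m[:, None], np.flatnonzero(ev)[None, :]] += 3.0
        pca = asm.pca_mp(asm.build_activity(X))
        rot, unit = asm.promax_rotate(pca)
        dots = np.abs(unit.T @ unit - np.eye(unit.shape[1]))
        assert dots.max() > 1e-3  # genuinely oblique
        z = asm.select_zmax(rot)
        sets = asm.build_assemblies(rot, unit, z)
        rec = [set(m) for m in sets.members]
        assert any(len(set(m1) & r) / len(set(m1) | r) >= 0.9 for r in rec)
        assert any(len(set(m2) & r) / len(set(m2) | r) >= 0.9 for r in rec)

    def test_matches_reference_promax_loadings(self):
        # independent cross-check against statsmodels' promax on the same
        # varimax-normalized input
        from statsmodels.multivariate.factor_rotation import promax as sm_promax
        Z, members = _planted_activity(seed=7)
        pca = asm.pca_mp(Z)
        rot, _ = asm.promax_rotate(pca, kappa=4.0)
        ref, _ = sm_promax(pca.loadings, k=4)
        # columns may be permuted/sign-flipped; compare absolute correlation
        k = rot.shape[1]
        M = np.abs(np.corrcoef(rot.T, ref.T)[:k, k:])
        best = M.max(axis=1)
        assert np.all(best > 0.99)

    def test_no_retained_components_raises(self):
        rng = np.random.default_rng(8)
        Z = asm.build_activity(rng.normal(size=(80, 900)))
        pca = asm.pca_mp(Z)
        if pca.n_retained == 0:
            with pytest.raises(ValueError, match="no informative"):
                asm.promax_rotate(pca)


class TestSelectZmax:
    def test_bimodal_maxima_threshold_in_valley(self):
        rng = np.random.default_rng(9)
        load = rng.normal(0, 1, size=(500, 3))
        load[:60] += 5.0  # members
        z = asm.select_zmax(load)
        zl = asm.zscore_loadings(load)
        m = zl.max(axis=1)
        # threshold separates the two modes
        assert np.median(m[:60]) > z > np.median(m[60:])

    def test_manual_override(self):
        rng = np.random.default_rng(10)
        assert asm.select_zmax(rng.normal(size=(50, 2)), manual=2.0) == 2.0

    def test_unimodal_raises(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError, match="manual"):
            asm.select_zmax(rng.normal(size=(2000, 1)), smooth=3.0)


class TestBuildMergeSignificance:
    def test_zmax_extremes(self):
        rng = np.random.default_rng(12)
        rot = rng.normal(size=(40, 3))
        unit = rot / np.linalg.norm(rot, axis=0)
        assert len(asm.build_assemblies(rot, unit, np.inf)) == 0
        full = asm.build_assemblies(rot, unit, -np.inf)
        assert all(len(m) == 40 for m in full.members)

    def test_zmax_monotonicity(self):
        rng = np.random.default_rng(13)
        rot = rng.normal(size=(100, 4))
        rot[:15, 0] += 4
        rot[15:30, 1] += 4
        unit = rot / np.linalg.norm(rot, axis=0)
        prev = None
        for z in (0.5, 1.0, 1.5, 2.0, 3.0):
            sets = {j: set(m) for j, m in
                    enumerate(asm.build_assemblies(rot, unit, z).members)}
            cur = set().union(*sets.values()) if sets else set()
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_merge_duplicates_and_keep_orthogonal(self):
        v1 = np.zeros(20)
        v1[:5] = 1.0
        v2 = np.zeros(20)
        v2[10:15] = 1.0
        unit = np.column_stack([v1 / np.linalg.norm(v1)] * 2 +
                               [v2 / np.linalg.norm(v2)])
        a = asm.AssemblySet(members=[np.arange(5), np.arange(5), np.arange(10, 15)],
                            components=unit, rotated_loadings=unit)
        merged = asm.merge_similar(a, dot_thr=0.6)
        assert len(merged) == 2

    def test_significance_keeps_planted_rejects_random(self):
        Z, members = _planted_activity(seed=14)
        rng = np.random.default_rng(15)
        random_set = rng.choice(Z.n_rois, size=20, replace=False)
        a = asm.AssemblySet(members=[members[0], random_set])
        out = asm.test_significance(a, Z, n_shuffle=500, seed=16)
        assert len(out) == 1
        assert set(out.members[0]) == set(members[0])
        assert out.p_corr[0] <= 0.01

    def test_random_membership_rejected_at_alpha_rate(self):
        rng = np.random.default_rng(17)
        Z = asm.build_activity(rng.normal(size=(60, 800)))
        rejections = 0
        n_rep = 40
        for r in range(n_rep):
            a = asm.AssemblySet(members=[rng.choice(60, size=10, replace=False)])
            out = asm.test_significance(a, Z, n_shuffle=200, seed=100 + r)
            rejections += len(out)  # kept == falsely "significant"
        # both tests must pass at alpha=0.05 -> keep rate <= ~alpha
        assert rejections / n_rep <= 0.10


class TestClusterBaseline:
    def test_two_separated_clusters_recovered(self):
        Z, members = _planted_activity(seed=18, n=60,
                                       groups=((0, 20), (20, 40)))
        out = asm.cluster_baseline(Z, method="kmeans", k=3, seed=0)
        # exclusive partition
        allm = np.concatenate(out.members)
        assert len(allm) == len(set(allm.tolist())) == Z.n_rois
        for m in members:
            best = max(len(set(m) & set(c)) / len(set(m) | set(c))
                       for c in out.members)
            assert best >= 0.95

    def test_hierarchical_partition(self):
        Z, members = _planted_activity(seed=19, n=60, groups=((0, 20), (20, 40)))
        out = asm.cluster_baseline(Z, method="hierarchical", k=3)
        allm = np.concatenate(out.members)
        assert len(allm) == len(set(allm.tolist())) == Z.n_rois

    def test_kmeans_deterministic_under_seed(self):
        Z, _ = _planted_activity(seed=20, n=50, groups=((0, 15),))
        a = asm.cluster_baseline(Z, "kmeans", k=4, seed=7)
        b = asm.cluster_baseline(Z, "kmeans", k=4, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a.members, b.members))


class TestAssemblyActivity:
    def test_single_member_and_population(self):
        rng = np.random.default_rng(21)
        Z = asm.build_activity(rng.normal(size=(5, 200)))
        a = asm.AssemblySet(members=[np.array([2]), np.arange(5)])
        act = asm.assembly_activity(a, Z)
        assert np.array_equal(act[0], Z.Z[2])
        assert np.allclose(act[1], Z.Z.mean(axis=0))

    def test_planted_activation_frames_hit(self):
        members = [np.arange(0, 25)]
        gt = synthgen.make_activity(80, duration=300, frame_rate=10.0,
                                    memberships=members, within_prob=0.9,
                                    assembly_event_rate=0.2,
                                    background_rate=0.02, seed=22)
        Z = asm.build_activity(gt.observed)
        a = asm.AssemblySet(members=members)
        act = asm.assembly_activity(a, Z)
        ev = gt.assembly_event_frames[0]
        thr = np.percentile(act[0], 95)
        hits = np.mean([act[0, f:f + 3].max() > thr for f in ev if f < 2990])
        assert hits >= 0.9
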