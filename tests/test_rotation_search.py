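import numpy as np
import pytest

from ssevec import (
    MatchParams,
    Rotation,
    SseType,
    UndefinedStatisticsError,
    ValidationError,
    apply_rotation,
    collect_minima,
    element_similarity,
    group_directions,
    initial_rotations,
    minimize_match_score,
    pair_mean_similarity,
    rotation_statistics,
    similarity_matrix,
    total_match_score,
    z_score,
)
from ssevec.reduction import ReducedRepresentation
from ssevec.rotation_search import _candidate_quats
from ssevec.synthetic import HingeSpec, hinge_pair, random_representation


def _rep(vectors, types, lengths=None, rep_id="r"):
    vectors = np.asarray(vectors, float)
    vectors = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    if lengths is None:
        lengths = np.full(len(vectors), 10)
    return ReducedRepresentation(rep_id, vectors, list(types), np.asarray(lengths))


@pytest.fixture
def orthogonal_helices():
    return _rep(np.eye(3), [SseType.HELIX] * 3)


class TestRotation:
    def test_identity_and_apply(self, rep8):
        assert apply_rotation(rep8, Rotation.identity()) == rep8

    def test_half_turn_about_z(self):
        r = Rotation.from_axis_angle([0, 0, 1], np.pi)
        assert np.allclose(r.apply(np.array([1.0, 0, 0])), [-1, 0, 0], atol=1e-12)

    def test_double_cover(self, rep8):
        q = Rotation.from_axis_angle([1, 1, 0], 0.7)
        neg = Rotation(-q.q)
        assert np.allclose(apply_rotation(rep8, q).vectors, apply_rotation(rep8, neg).vectors)
        assert q.angle_to(neg) == 0.0

    def test_angles_preserved(self, rep8, rng):
        R = Rotation.random(rng)
        before = rep8.vectors @ rep8.vectors.T
        after_rep = apply_rotation(rep8, R)
        after = after_rep.vectors @ after_rep.vectors.T
        assert np.allclose(before, after, atol=1e-9)


class TestElementSimilarity:
    def test_zero_angle(self):
        v = np.array([0.0, 0, 1])
        assert element_similarity(v, v, SseType.HELIX, SseType.HELIX, 0.1) == 1.0

    def test_type_mismatch(self):
        v = np.array([0.0, 0, 1])
        assert element_similarity(v, v, SseType.HELIX, SseType.STRAND, 0.1) == 0.0

    def test_angle_equal_delta(self):
        delta = 0.25
        v = np.array([0.0, 0, 1])
        w = np.array([np.sin(delta), 0, np.cos(delta)])
        got = element_similarity(v, w, SseType.STRAND, SseType.STRAND, delta)
        assert got == pytest.approx(np.exp(-1), abs=1e-12)

    def test_non_unit_rejected(self):
        with pytest.raises(ValidationError):
            element_similarity(
                np.array([2.0, 0, 0]), np.array([1.0, 0, 0]),
                SseType.HELIX, SseType.HELIX, 0.1,
            )


class TestSimilarityMatrix:
    def test_self_identity_diagonal(self, rep8, params_exact):
        d = similarity_matrix(rep8, rep8, Rotation.identity(), params_exact)
        assert np.allclose(np.diag(d.values), 1.0)
        assert (d.values >= 0).all() and (d.values <= 1).all()

    def test_type_disjoint_zero(self):
        x = _rep(np.eye(3), [SseType.HELIX] * 3)
        y = _rep(np.eye(3), [SseType.STRAND] * 3)
        p = MatchParams(delta=0.3, mc_samples=1000)
        assert similarity_matrix(x, y, Rotation.identity(), p).values.sum() == 0.0
        assert total_match_score(x, y, Rotation.identity(), p) == 0.0

    def test_length_penalty_at_tolerance(self):
        x = _rep([[0, 0, 1]], [SseType.HELIX], [15])
        y = _rep([[0, 0, 1]], [SseType.HELIX], [10])
        p = MatchParams(delta=0.3, len_tol=5.0, mc_samples=1000)
        d = similarity_matrix(x, y, Rotation.identity(), p)
        assert d.values[0, 0] == pytest.approx(np.exp(-1), abs=1e-12)
        assert d.length_weighted

    def test_orthogonal_self_score(self, orthogonal_helices, params_exact):
        F = total_match_score(
            orthogonal_helices, orthogonal_helices, Rotation.identity(), params_exact
        )
        assert F == pytest.approx(-3.0, abs=1e-50)


class TestRotationStatistics:
    def test_per_pair_mean_quadrature(self):
        # independent Riemann-sum oracle of (1/2) Int exp(-t^2/d^2) sin t dt
        t = np.linspace(0, np.pi, 200001)
        for delta in (0.1, 0.3, 0.5):
            oracle = 0.5 * np.trapezoid(np.exp(-(t**2) / delta**2) * np.sin(t), t)
            assert pair_mean_similarity(delta) == pytest.approx(oracle, rel=1e-6)
        assert pair_mean_similarity(0.3) == pytest.approx(0.0222, abs=5e-4)

    def test_mc_mean_matches_quadrature(self, rep8):
        p = MatchParams(delta=0.3, mc_samples=20000, seed=2)
        stats = rotation_statistics(rep8, rep8, p)
        assert abs(stats.mc_mean_F - stats.mean_F) < 3 * stats.mc_sem_F

    def test_wide_delta_limit(self, orthogonal_helices):
        p = MatchParams(delta=200.0, mc_samples=1000, seed=0)
        stats = rotation_statistics(orthogonal_helices, orthogonal_helices, p)
        assert stats.mean_F == pytest.approx(-9.0, rel=1e-3)
        assert stats.std_F < 0.01

    def test_no_same_type_pair(self):
        x = _rep(np.eye(3), [SseType.HELIX] * 3)
        y = _rep(np.eye(3), [SseType.STRAND] * 3)
        with pytest.raises(UndefinedStatisticsError):
            rotation_statistics(x, y, MatchParams(delta=0.3, mc_samples=1000))

    def test_z_score_centering_and_scaling(self, rep8, params_fuzzy):
        stats = rotation_statistics(rep8, rep8, params_fuzzy)
        assert z_score(stats.mean_F, stats) == 0.0
        assert z_score(stats.mean_F - stats.std_F, stats) == pytest.approx(-1.0)

    def test_self_match_is_significant(self, params_fuzzy):
        x = random_representation(8, seed=21)
        F = total_match_score(x, x, Rotation.identity(), params_fuzzy)
        stats = rotation_statistics(x, x, params_fuzzy)
        assert z_score(F, stats) <= -3.0


class TestInitialRotations:
    def test_all_helix_candidate_count(self):
        x = _rep(np.eye(3), [SseType.HELIX] * 3)
        p = MatchParams(delta=0.3, m=2, mc_samples=1000)
        # C(3,2) ordered pairs on each side -> 9 combinations before dedup
        assert len(_candidate_quats(x, x, p)) == 9

    def test_type_disjoint_empty(self):
        x = _rep(np.eye(3), [SseType.HELIX] * 3)
        y = _rep(np.eye(3), [SseType.STRAND] * 3)
        assert initial_rotations(x, y, MatchParams(delta=0.3, mc_samples=1000)) == []

    def test_self_guesses_contain_identity(self, rep8, params_exact):
        rots = initial_rotations(rep8, rep8, params_exact)
        best = min(r.angle_to(Rotation.identity()) for r in rots)
        assert best < 1e-6


class TestMinimize:
    def test_stationary_start(self, rep8, params_exact):
        stats = rotation_statistics(rep8, rep8, params_exact)
        m = minimize_match_score(rep8, rep8, Rotation.identity(), params_exact, stats)
        F0 = total_match_score(rep8, rep8, Rotation.identity(), params_exact)
        assert m.F <= F0 + 1e-9
        assert m.rotation.angle_to(Rotation.identity()) < 1e-3

    def test_planted_rotation_recovery(self, rep8, params_exact, rng):
        R_true = Rotation.random(rng)
        y = apply_rotation(rep8, R_true)
        stats = rotation_statistics(rep8, y, params_exact)
        # start near, not at, the optimum
        R0 = Rotation.from_axis_angle([0, 0, 1], np.deg2rad(8)).compose(R_true)
        m = minimize_match_score(rep8, y, R0, params_exact, stats)
        F_self = total_match_score(rep8, rep8, Rotation.identity(), params_exact)
        assert abs(m.F - F_self) < 1e-6
        assert np.rad2deg(m.rotation.angle_to(R_true)) < 1.0

    def test_max_iter_zero_is_noop(self, rep8, params_exact, rng):
        R0 = Rotation.random(rng)
        p = MatchParams(delta=0.1, mc_samples=1000, seed=7, max_iter=0)
        stats = rotation_statistics(rep8, rep8, p)
        m = minimize_match_score(rep8, rep8, R0, p, stats)
        assert m.F == pytest.approx(total_match_score(rep8, rep8, R0, p), abs=1e-12)
        assert m.rotation.angle_to(R0) < 1e-12


class TestGradient:
    def test_analytic_matches_central_difference(self, rep8, rng):
        from ssevec.rotation_search import _PairProblem, _quat_from_rotvec, _quat_multiply

        y = random_representation(7, seed=17)
        prob = _PairProblem(rep8, y, MatchParams(delta=0.3, mc_samples=1000))
        for _ in range(5):
            q = Rotation.random(rng).q
            _, g = prob.F_and_grad(q[None, :])
            h = 1e-6
            num = np.empty(3)
            for k in range(3):
                e = np.zeros(3)
                e[k] = h
                fp = prob.F(_quat_multiply(_quat_from_rotvec(e), q)[None, :])[0]
                fm = prob.F(_quat_multiply(_quat_from_rotvec(-e), q)[None, :])[0]
                num[k] = (fp - fm) / (2 * h)
            assert np.allclose(g[0], num, atol=1e-5)


class TestGroupDirections:
    def test_full_merge(self):
        x = _rep([[0, 0, 1]] * 4, [SseType.HELIX] * 4)
        grouped, groups = group_directions(x, np.deg2rad(10))
        assert grouped.count == 1
        assert sorted(groups[0]) == [0, 1, 2, 3]

    def test_no_merge(self, rep8):
        grouped, groups = group_directions(rep8, np.deg2rad(0.01))
        assert grouped.count == rep8.count
        assert all(len(g) == 1 for g in groups)

    def test_two_clusters(self, rng):
        base1, base2 = np.array([0.0, 0, 1]), np.array([1.0, 0, 0])
        vecs = []
        for base in (base1, base2):
            for k in range(3):
                tilt = Rotation.from_axis_angle([0, 1, 0], np.deg2rad(5) * (k - 1))
                vecs.append(tilt.apply(base))
        x = _rep(vecs, [SseType.HELIX] * 6)
        grouped, groups = group_directions(x, np.deg2rad(15))
        assert grouped.count == 2
        assert sorted(len(g) for g in groups) == [3, 3]


class TestCollectMinima:
    def test_self_match_first_minimum_identity(self, rep8, params_exact):
        minima = collect_minima(rep8, rep8, params_exact)
        assert minima
        assert np.rad2deg(minima[0].rotation.angle_to(Rotation.identity())) < 1.0
        zs = [m.z for m in minima]
        assert zs == sorted(zs)

    def test_type_disjoint_empty(self):
        x = _rep(np.eye(3), [SseType.HELIX] * 3)
        y = _rep(np.eye(3), [SseType.STRAND] * 3)
        assert collect_minima(x, y, MatchParams(delta=0.3, mc_samples=1000)) == []

    def test_hinge_pair_two_minima(self, params_fuzzy):
        a, b = hinge_pair(HingeSpec(n_sse=12, split_index=6, hinge_angle=70.0, seed=4))
        minima = collect_minima(a, b, params_fuzzy)
        assert len(minima) >= 2

    def test_grouped_search_matches_ungrouped(self, rng):
        # two well-separated clusters of nearly parallel helices
        vecs = []
        for base in (np.array([0.0, 0, 1]), np.array([1.0, 0, 0])):
            for k in range(3):
                tilt = Rotation.from_axis_angle([0, 1, 0], np.deg2rad(4) * (k - 1))
                vecs.append(tilt.apply(base))
        x = _rep(vecs, [SseType.HELIX] * 6, rep_id="x")
        q = Rotation.random(rng)
        y = apply_rotation(x, q)
        plain = MatchParams(delta=0.3, mc_samples=1000, seed=7)
        grouped = MatchParams(delta=0.3, mc_samples=1000, seed=7, group_eps=np.deg2rad(12))
        m_plain = collect_minima(x, y, plain)
        m_grouped = collect_minima(x, y, grouped)
        assert m_plain and m_grouped
        assert abs(m_plain[0].z - m_grouped[0].z) < 0.5
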