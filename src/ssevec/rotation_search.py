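"""Rotation-space matching of two reduced representations.

The match between two typed unit-vector sets ``X`` and ``Y`` is scored by

    F(R; X, Y) = - sum_ij  1{type_i = type_j} * exp(-theta_ij(R)^2 / delta^2),

where ``theta_ij(R)`` is the angle between the rotated query vector
``R v_i`` and the target vector ``w_j`` and ``delta`` (radians) sets how
steeply credit falls off with angular mismatch.  ``F`` is minimized over the
rotation group, parametrized by unit quaternions: candidate rotations are
enumerated from pairs of same-type, same-order vectors, then refined by
steepest descent in the quaternion tangent space.

Whether a minimum is deeper than chance is judged by a rotational z-score:
F's deviation from its mean over uniformly random rotations, in units of the
standard deviation over rotations.  The mean is semi-analytic (a 1-D
quadrature per same-type pair); the standard deviation is estimated by
seeded Monte Carlo.
"""

from __future__ import annotations

import dataclasses
import functools
from typing import Sequence

import numpy as np
from scipy import integrate
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation as ScipyRotation

from .errors import UndefinedStatisticsError, ValidationError
from .reduction import ReducedRepresentation, SseType

_UNIT_TOL = 1e-9
_ARMIJO_C = 1e-4
_MAX_BACKTRACKS = 40
_MAX_STEP_ANGLE = 0.5  # radians; caps a single descent step
_MC_CHUNK = 20000


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first convention, q and -q identified)


def _quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValidationError("zero-norm quaternion")
    return q / norm

def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Batch quaternion (..., 4, scalar first) to rotation matrix (..., 3, 3)."""
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m

def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b for scalar-first batches."""
    aw, ax, ay, az = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    bw, bx, by, bz = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )

def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Rotation vectors (..., 3) to scalar-first quaternions."""
    v = np.asarray(v, dtype=float)
    angle = np.linalg.norm(v, axis=-1, keepdims=True)
    half = 0.5 * angle
    # sinc-based form is stable near zero angle
    factor = np.where(angle > 1e-12, np.sin(half) / np.where(angle > 1e-12, angle, 1.0), 0.5)
    return np.concatenate([np.cos(half), factor * v], axis=-1)


@dataclasses.dataclass(frozen=True)
class Rotation:
    """A proper rotation stored as a unit quaternion (scalar first).

    ``q`` and ``-q`` denote the same rotation; every operation here is
    invariant under that sign flip.
    """

    q: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", _quat_normalize(np.asarray(self.q, float)))
        if self.q.shape != (4,):
            raise ValidationError("quaternion must have 4 components")

    @classmethod
    def identity(cls) -> "Rotation":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "Rotation":
        return cls(ScipyRotation.from_matrix(m).as_quat(scalar_first=True))

    @classmethod
    def from_axis_angle(cls, axis: Sequence[float], angle_rad: float) -> "Rotation":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        return cls(_quat_from_rotvec(axis * angle_rad))

    @classmethod
    def random(cls, rng: np.random.Generator) -> "Rotation":
        """Haar-uniform random rotation from a normalized 4-D Gaussian."""
        return cls(rng.normal(size=4))

    def as_matrix(self) -> np.ndarray:
        return _quat_to_matrix(self.q)

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.as_matrix().T

    def compose(self, other: "Rotation") -> "Rotation":
        """self o other: apply ``other`` first, then ``self``."""
        return Rotation(_quat_multiply(self.q, other.q))

    def inverse(self) -> "Rotation":
        return Rotation(self.q * np.array([1.0, -1.0, -1.0, -1.0]))

    def angle_to(self, other: "Rotation") -> float:
        """Angle (radians) of the relative rotation, in [0, pi]."""
        dot = min(1.0, abs(float(self.q @ other.q)))
        return 2.0 * np.arccos(dot)


@dataclasses.dataclass
class MatchParams:
    """All tunable parameters of the rotational match.

    Angles ``delta`` and ``group_eps`` are radians; the rotation-distance
    thresholds are degrees.  ``len_tol`` (residues) switches on the
    length-mismatch down-weighting of the similarity matrix when set.
    """

    delta: float = 0.5
    len_tol: float | None = None
    m: int = 3
    group_eps: float | None = None
    gap_open: float = -1.0
    mc_samples: int = 2000
    seed: int = 0
    z_cut: float = -2.0
    align_mode: str = "semiglobal"
    collinearity_deg: float = 5.0
    seed_dedup_deg: float = 1.0
    minima_dedup_deg: float = 5.0
    min_separation_deg: float = 15.0
    top_seeds: int | None = 32
    top_minima: int = 10
    max_iter: int = 500
    grad_tol: float = 1e-8
    f_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValidationError("delta must be positive")
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if self.mc_samples < 1000:
            raise ValidationError("mc_samples must be >= 1000")
        if self.len_tol is not None and self.len_tol <= 0:
            raise ValidationError("len_tol must be positive when set")
        if self.group_eps is not None and self.group_eps <= 0:
            raise ValidationError("group_eps must be positive when set")
        if self.align_mode not in ("global", "semiglobal", "local"):
            raise ValidationError(f"unknown align_mode {self.align_mode!r}")


@dataclasses.dataclass
class SimilarityMatrix:
    """Pairwise similarities D_ij(R) for one (X, Y, R) triple."""

    values: np.ndarray  # (N_x, N_y) in [0, 1]
    rotation: Rotation
    length_weighted: bool = False


@dataclasses.dataclass
class RotationStats:
    """Moments of F over Haar-uniform rotations for one (X, Y) pair."""

    mean_F: float
    std_F: float
    mc_mean_F: float
    mc_sem_F: float
    n_samples: int
    n_pairs: int


@dataclasses.dataclass
class LocalMinimum:
    rotation: Rotation
    F: float
    z: float


# ---------------------------------------------------------------------------
# similarity and match score


def apply_rotation(X: ReducedRepresentation, R: Rotation) -> ReducedRepresentation:
    """Rotate every vector of a representation; types/lengths/order unchanged."""
    return ReducedRepresentation(
        id=X.id,
        vectors=R.apply(X.vectors),
        types=list(X.types),
        lengths=X.lengths.copy(),
        meta=None if X.meta is None else [dict(m) for m in X.meta],
    )


def element_similarity(
    v: np.ndarray,
    w: np.ndarray,
    type_v: SseType,
    type_w: SseType,
    delta: float,
) -> float:
    """Gaussian angular similarity of two typed unit vectors.

    Zero for mismatched types, else exp(-theta^2/delta^2) with theta the
    angle between the vectors (N->C sense; antiparallel is *not* identified
    with parallel).
    """
    v = np.asarray(v, float)
    w = np.asarray(w, float)
    if abs(np.linalg.norm(v) - 1) > _UNIT_TOL or abs(np.linalg.norm(w) - 1) > _UNIT_TOL:
        raise ValidationError("element_similarity requires unit vectors")
    if delta <= 0:
        raise ValidationError("delta must be positive")
    if SseType(type_v) is not SseType(type_w):
        return 0.0
    theta = np.arccos(np.clip(v @ w, -1.0, 1.0))
    return float(np.exp(-(theta**2) / delta**2))


def pair_weights(
    X: ReducedRepresentation, Y: ReducedRepresentation, params: MatchParams
) -> np.ndarray:
    """Rotation-independent weight of each (i, j) pair.

    1 for same-type pairs (0 otherwise), multiplied by the length-mismatch
    factor exp(-(dL/len_tol)^2) when ``params.len_tol`` is set.
    """
    same = X.type_codes()[:, None] == Y.type_codes()[None, :]
    w = same.astype(float)
    if params.len_tol is not None:
        dL = np.abs(X.lengths[:, None] - Y.lengths[None, :]).astype(float)
        w = w * np.exp(-((dL / params.len_tol) ** 2))
    return w


def similarity_matrix(
    X: ReducedRepresentation,
    Y: ReducedRepresentation,
    R: Rotation,
    params: MatchParams,
) -> SimilarityMatrix:
    """Evaluate D_ij(R) for all pairs, optionally length-weighted."""
    if X.count == 0 or Y.count == 0:
        raise ValidationError("similarity_matrix requires nonempty representations")
    w = pair_weights(X, Y, params)
    cos = np.clip(R.apply(X.vectors) @ Y.vectors.T, -1.0, 1.0)
    theta = np.arccos(cos)
    values = w * np.exp(-(theta**2) / params.delta**2)
    return SimilarityMatrix(
        values=values, rotation=R, length_weighted=params.len_tol is not None
    )


def total_match_score(
    X: ReducedRepresentation,
    Y: ReducedRepresentation,
    R: Rotation,
    params: MatchParams,
) -> float:
    """F(R; X, Y) = -sum of the similarity matrix; in [-N_x*N_y, 0]."""
    if X.count == 0 or Y.count == 0:
        return 0.0
    return -float(similarity_matrix(X, Y, R, params).values.sum())


# ---------------------------------------------------------------------------
# batched evaluation of F and its tangent-space gradient


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product over the last axis without np.cross overhead."""
    c = np.empty_like(a)
    c[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    c[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    c[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return c


class _PairProblem:
    """Precomputed arrays for repeated F evaluations on one (X, Y) pair."""

    def __init__(
        self, X: ReducedRepresentation, Y: ReducedRepresentation, params: MatchParams
    ):
        self.Xv = X.vectors
        self.XvT = np.ascontiguousarray(X.vectors.T)
        self.Yv = Y.vectors
        self.delta = params.delta
        self.W = pair_weights(X, Y, params)
        self.ix, self.iy = np.nonzero(self.W)
        self.w_sel = self.W[self.ix, self.iy]
        self._neg_inv_d2 = -1.0 / params.delta**2

    @property
    def n_pairs(self) -> int:
        return len(self.ix)

    def F(self, qs: np.ndarray) -> np.ndarray:
        """F for a batch of quaternions (S, 4) -> (S,)."""
        if self.n_pairs == 0:
            return np.zeros(len(qs))
        u = _quat_to_matrix(qs) @ self.XvT  # (S, 3, N)
        cos = self.Yv @ u  # (S, M, N)
        c = cos[:, self.iy, self.ix]
        np.clip(c, -1.0, 1.0, out=c)
        theta = np.arccos(c)
        return -(self.w_sel * np.exp(theta * theta * self._neg_inv_d2)).sum(axis=1)

    def F_and_grad(self, qs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """F and its gradient wrt a left rotation-vector perturbation.

        The gradient is analytic: with u_i = R v_i and theta_ij the angle to
        w_j, dF/de = -sum_ij W_ij exp(-theta^2/d^2) (2 theta / (d^2 sin theta))
        (u_i x w_j).
        """
        S = len(qs)
        if self.n_pairs == 0:
            return np.zeros(S), np.zeros((S, 3))
        u = _quat_to_matrix(qs) @ self.XvT  # (S, 3, N)
        cos = self.Yv @ u  # (S, M, N)
        c = cos[:, self.iy, self.ix]
        np.clip(c, -1.0, 1.0, out=c)
        theta = np.arccos(c)
        gauss = self.w_sel * np.exp(theta * theta * self._neg_inv_d2)
        F = -gauss.sum(axis=1)
        sin = np.maximum(np.sqrt(1.0 - c * c), 1e-9)
        coef = gauss * (-2.0 * self._neg_inv_d2) * theta / sin
        coef_full = np.zeros((S,) + self.W.shape)
        coef_full[:, self.ix, self.iy] = coef
        # sum_j coef_ij w_j, then u_i x (.) — cross is linear in its 2nd arg
        A = coef_full @ self.Yv  # (S, N, 3)
        grad = -_cross3(u.transpose(0, 2, 1), A).sum(axis=1)
        return F, grad


def _steepest_descent(
    prob: _PairProblem,
    q0s: np.ndarray,
    max_iter: int,
    grad_tol: float,
    f_tol: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched steepest descent on F over unit quaternions.

    Monotone non-increasing in F for every seed; a seed stops when its
    tangent-gradient norm drops below ``grad_tol``, its accepted step
    improves F by less than ``f_tol``, its backtracking line search stalls,
    or ``max_iter`` is reached.  Returns (quaternions, F).
    """
    q = _quat_normalize(np.array(q0s, dtype=float))
    F = prob.F(q)
    if max_iter == 0 or prob.n_pairs == 0:
        return q, F
    S = len(q)
    step = np.full(S, 0.1)
    active = np.ones(S, dtype=bool)
    for _ in range(max_iter):
        idx = np.nonzero(active)[0]
        if len(idx) == 0:
            break
        _, g = prob.F_and_grad(q[idx])
        gnorm = np.sqrt((g * g).sum(axis=1))
        converged = gnorm < grad_tol
        active[idx[converged]] = False
        live = ~converged
        idx = idx[live]
        if len(idx) == 0:
            continue
        g = g[live]
        gnorm = gnorm[live]
        # cap the trial step so a single move never exceeds _MAX_STEP_ANGLE
        t = np.minimum(step[idx] * 2.0, _MAX_STEP_ANGLE / gnorm)
        f_cur = F[idx]
        need = np.ones(len(idx), dtype=bool)
        for _bt in range(_MAX_BACKTRACKS):
            sub = np.nonzero(need)[0]
            if len(sub) == 0:
                break
            dq = _quat_from_rotvec(-t[sub, None] * g[sub])
            q_trial = _quat_multiply(dq, q[idx[sub]])
            q_trial /= np.sqrt((q_trial * q_trial).sum(axis=1))[:, None]
            f_trial = prob.F(q_trial)
            ok = f_trial <= f_cur[sub] - _ARMIJO_C * t[sub] * gnorm[sub] ** 2
            acc = sub[ok]
            if len(acc):
                improvement = f_cur[acc] - f_trial[ok]
                q[idx[acc]] = q_trial[ok]
                F[idx[acc]] = f_trial[ok]
                step[idx[acc]] = t[acc]
                # freeze seeds whose accepted step no longer moves F
                active[idx[acc[improvement < f_tol]]] = False
                need[acc] = False
            t[sub[~ok]] *= 0.5
        # seeds whose line search never succeeded have stalled: freeze them
        active[idx[need]] = False
    return q, F


# ---------------------------------------------------------------------------
# rotational statistics and z-score


@functools.lru_cache(maxsize=64)
def pair_mean_similarity(delta: float) -> float:
    """Mean of exp(-theta^2/delta^2) over Haar-uniform rotations.

    For a uniform rotation the angle between a rotated and a fixed unit
    vector has density sin(theta)/2 on [0, pi], so the per-pair mean is
    (1/2) Int_0^pi exp(-theta^2/delta^2) sin(theta) dtheta, evaluated by
    adaptive quadrature.
    """
    val, _ = integrate.quad(
        lambda t: np.exp(-(t**2) / delta**2) * np.sin(t), 0.0, np.pi
    )
    return 0.5 * val


def rotation_statistics(
    X: ReducedRepresentation, Y: ReducedRepresentation, params: MatchParams
) -> RotationStats:
    """Moments of F(R; X, Y) over uniformly random rotations.

    The mean is semi-analytic: each same-type pair contributes its
    (rotation-independent) weight times the quadrature mean of the angular
    Gaussian.  The standard deviation is estimated over ``mc_samples``
    seeded Haar-uniform rotations.
    """
    prob = _PairProblem(X, Y, params)
    if prob.n_pairs == 0:
        raise UndefinedStatisticsError(
            "no same-type SSE pair between the two representations"
        )
    mean_F = -float(prob.w_sel.sum()) * pair_mean_similarity(params.delta)
    rng = np.random.default_rng(params.seed)
    samples = np.empty(params.mc_samples)
    done = 0
    while done < params.mc_samples:
        n = min(_MC_CHUNK, params.mc_samples - done)
        qs = _quat_normalize(rng.normal(size=(n, 4)))
        samples[done : done + n] = prob.F(qs)
        done += n
    std = float(samples.std(ddof=1))
    return RotationStats(
        mean_F=mean_F,
        std_F=std,
        mc_mean_F=float(samples.mean()),
        mc_sem_F=std / np.sqrt(params.mc_samples),
        n_samples=params.mc_samples,
        n_pairs=prob.n_pairs,
    )


def z_score(F: float, stats: RotationStats) -> float:
    """Distance of F from the rotational mean, in standard deviations."""
    if stats.std_F <= 0:
        raise UndefinedStatisticsError("zero standard deviation over rotations")
    return (F - stats.mean_F) / stats.std_F


# ---------------------------------------------------------------------------
# initial guesses


def _ordered_pairs(X: ReducedRepresentation, m: int, collinearity_deg: float):
    """Index pairs (i, j), i < j <= i + m, skipping near-(anti)collinear pairs."""
    thresh = np.deg2rad(collinearity_deg)
    out = []
    for i in range(X.count):
        for j in range(i + 1, min(i + m, X.count - 1) + 1):
            theta = np.arccos(np.clip(X.vectors[i] @ X.vectors[j], -1.0, 1.0))
            if min(theta, np.pi - theta) < thresh:
                continue
            out.append((i, j))
    return out


def _pair_frames(vectors: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Orthonormal frame (columns e1, e2, e3) for each vector pair."""
    if not pairs:
        return np.empty((0, 3, 3))
    a = vectors[[p[0] for p in pairs]]
    b = vectors[[p[1] for p in pairs]]
    e1 = a
    u = b - (np.sum(a * b, axis=1, keepdims=True)) * a
    e2 = u / np.linalg.norm(u, axis=1, keepdims=True)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=2)


def _candidate_quats(
    X: ReducedRepresentation, Y: ReducedRepresentation, params: MatchParams
) -> np.ndarray:
    """All plane-matching seed rotations (S, 4), unfiltered for duplicates.

    For each ordered pair (i, j) in X and type-matching ordered pair (k, l)
    in Y, the seed maps v_i onto w_k and span(v_i, v_j) onto span(w_k, w_l).
    """
    px = _ordered_pairs(X, params.m, params.collinearity_deg)
    py = _ordered_pairs(Y, params.m, params.collinearity_deg)
    if not px or not py:
        return np.empty((0, 4))
    tx = X.type_codes()
    ty = Y.type_codes()
    sig_x = np.array([[tx[i], tx[j]] for i, j in px])
    sig_y = np.array([[ty[k], ty[l]] for k, l in py])
    Ex = _pair_frames(X.vectors, px)
    Ey = _pair_frames(Y.vectors, py)
    mats = []
    for s in ((0, 0), (0, 1), (1, 0), (1, 1)):
        mx = (sig_x[:, 0] == s[0]) & (sig_x[:, 1] == s[1])
        my = (sig_y[:, 0] == s[0]) & (sig_y[:, 1] == s[1])
        if not mx.any() or not my.any():
            continue
        # R = F E^T for every combination of frames
        R = np.einsum("qab,pcb->pqac", Ey[my], Ex[mx]).reshape(-1, 3, 3)
        mats.append(R)
    if not mats:
        return np.empty((0, 4))
    allmats = np.concatenate(mats, axis=0)
    return ScipyRotation.from_matrix(allmats).as_quat(scalar_first=True)


def _greedy_distinct(
    qs: np.ndarray,
    order: np.ndarray,
    min_sep_deg: float,
    limit: int | None = None,
) -> list[int]:
    """Greedily pick indices (in ``order``) pairwise separated by >= min_sep."""
    max_dot = np.cos(np.deg2rad(min_sep_deg) / 2.0)
    chosen: list[int] = []
    chosen_q: list[np.ndarray] = []
    for idx in order:
        q = qs[idx]
        if chosen_q and np.max(np.abs(np.asarray(chosen_q) @ q)) > max_dot:
            continue
        chosen.append(int(idx))
        chosen_q.append(q)
        if limit is not None and len(chosen) >= limit:
            break
    return chosen


def initial_rotations(
    X: ReducedRepresentation, Y: ReducedRepresentation, params: MatchParams
) -> list[Rotation]:
    """Deduplicated seed rotations from same-type, same-order vector pairs."""
    qs = _candidate_quats(X, Y, params)
    if len(qs) == 0:
        return []
    keep = _greedy_distinct(qs, np.arange(len(qs)), params.seed_dedup_deg)
    return [Rotation(qs[i]) for i in keep]


# ---------------------------------------------------------------------------
# minimization and minima collection


def minimize_match_score(
    X: ReducedRepresentation,
    Y: ReducedRepresentation,
    R0: Rotation,
    params: MatchParams,
    stats: RotationStats | None = None,
) -> LocalMinimum:
    """Steepest-descent refinement of one seed rotation.

    F is monotone non-increasing across iterations; ``params.max_iter = 0``
    returns the seed's own F and z.
    """
    prob = _PairProblem(X, Y, params)
    q, F = _steepest_descent(
        prob,
        R0.q[None, :],
        max_iter=params.max_iter,
        grad_tol=params.grad_tol,
        f_tol=params.f_tol,
    )
    if not np.isfinite(F[0]):
        raise ArithmeticError("non-finite match score during descent")
    if stats is None:
        stats = rotation_statistics(X, Y, params)
    return LocalMinimum(rotation=Rotation(q[0]), F=float(F[0]), z=z_score(F[0], stats))


def group_directions(
    X: ReducedRepresentation, group_eps: float
) -> tuple[ReducedRepresentation, list[list[int]]]:
    """Merge nearly parallel same-type vectors (single linkage).

    Returns the compact representation (one normalized mean direction per
    group, ordered by each group's first original index) and the unfold map:
    ``groups[g]`` lists the original indices merged into compact vector g.
    """
    if group_eps <= 0:
        raise ValidationError("group_eps must be positive")
    codes = X.type_codes()
    groups: list[list[int]] = []
    for t in np.unique(codes):
        idx = np.nonzero(codes == t)[0]
        if len(idx) == 1:
            groups.append([int(idx[0])])
            continue
        v = X.vectors[idx]
        theta = np.arccos(np.clip(v @ v.T, -1.0, 1.0))
        np.fill_diagonal(theta, 0.0)
        labels = fcluster(
            linkage(squareform(theta, checks=False), method="single"),
            t=group_eps,
            criterion="distance",
        )
        for lab in np.unique(labels):
            groups.append([int(i) for i in idx[labels == lab]])
    groups.sort(key=lambda g: min(g))
    vectors, types, lengths = [], [], []
    for g in groups:
        mean = X.vectors[g].sum(axis=0)
        vectors.append(mean / np.linalg.norm(mean))
        types.append(X.types[g[0]])
        lengths.append(int(round(float(X.lengths[g].mean()))))
    grouped = ReducedRepresentation(
        id=f"{X.id}|grouped",
        vectors=np.asarray(vectors),
        types=types,
        lengths=np.asarray(lengths),
    )
    return grouped, groups


def collect_minima(
    X: ReducedRepresentation,
    Y: ReducedRepresentation,
    params: MatchParams,
    stats: RotationStats | None = None,
) -> list[LocalMinimum]:
    """Enumerate seeds, descend, deduplicate, and keep significant minima.

    Seeds come from :func:`initial_rotations` (on direction-grouped
    representations when ``params.group_eps`` is set) and are pruned to the
    ``params.top_seeds`` most promising distinct starting points by their
    seed-stage F.  Minima within ``params.minima_dedup_deg`` are merged
    keeping the deeper F; minima with z above ``params.z_cut`` are
    discarded.  The result is sorted by ascending z (deepest first).
    """
    prob = _PairProblem(X, Y, params)
    if prob.n_pairs == 0:
        return []
    if params.group_eps is not None:
        gx, _ = group_directions(X, params.group_eps)
        gy, _ = group_directions(Y, params.group_eps)
        qs = _candidate_quats(gx, gy, params)
    else:
        qs = _candidate_quats(X, Y, params)
    if len(qs) == 0:
        return []
    F0 = prob.F(qs)
    order = np.argsort(F0, kind="stable")
    keep = _greedy_distinct(qs, order, params.seed_dedup_deg, limit=params.top_seeds)
    q_opt, F_opt = _steepest_descent(
        prob,
        qs[keep],
        max_iter=params.max_iter,
        grad_tol=params.grad_tol,
        f_tol=params.f_tol,
    )
    # merge basins: nearby minima collapse to the deepest one
    order = np.argsort(F_opt, kind="stable")
    distinct = _greedy_distinct(q_opt, order, params.minima_dedup_deg)
    if stats is None:
        stats = rotation_statistics(X, Y, params)
    minima = [
        LocalMinimum(
            rotation=Rotation(q_opt[i]),
            F=float(F_opt[i]),
            z=z_score(float(F_opt[i]), stats),
        )
        for i in distinct
    ]
    minima = [m for m in minima if m.z <= params.z_cut]
    minima.sort(key=lambda m: m.z)
    return minima
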