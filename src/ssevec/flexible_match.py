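"""Conformationally flexible matching via two complementary rotation minima.

A flexible match models a hinge-type conformational change: each structural
domain keeps its internal organization, so each domain is matched by its own
rotation.  Operationally, two significant and well-separated local minima of
F are combined by taking the entrywise maximum of their similarity matrices,
D^max_ij = max(D_ij(R1), D_ij(R2)), aligning on D^max, and scoring the
result with a heuristic that rewards both deep minima and broad coverage.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np

from .errors import ValidationError
from .reduction import ReducedRepresentation
from .rotation_search import (
    MatchParams,
    Rotation,
    SimilarityMatrix,
    collect_minima,
    similarity_matrix,
)
from .sse_alignment import SseAlignment, align_sses


@dataclasses.dataclass
class FlexibleMatch:
    """Two complementary rotations and their combined alignment.

    ``separation`` is the angular distance between the two rotations in
    degrees; both z-scores pass the significance threshold and the
    separation passes the distinctness threshold by construction.
    """

    r1: Rotation
    r2: Rotation
    z1: float
    z2: float
    combined_alignment: SseAlignment
    score: float
    separation: float
    domain1: list[int]
    domain2: list[int]


def combined_similarity(D1: SimilarityMatrix, D2: SimilarityMatrix) -> SimilarityMatrix:
    """Entrywise maximum of two similarity matrices of identical shape."""
    if D1.values.shape != D2.values.shape:
        raise ValidationError(
            f"shape mismatch: {D1.values.shape} vs {D2.values.shape}"
        )
    return SimilarityMatrix(
        values=np.maximum(D1.values, D2.values),
        rotation=D1.rotation,
        length_weighted=D1.length_weighted or D2.length_weighted,
    )


def rotation_separation(r1: Rotation, r2: Rotation) -> float:
    """Angle (degrees) of the relative rotation r1^-1 o r2, in [0, 180]."""
    return float(np.rad2deg(r1.angle_to(r2)))


def flexible_score(z1: float, z2: float, T_max: float) -> float:
    """Heuristic ranking score for a flexible hit: ((|z1|+|z2|)/2) * T(D^max)."""
    if T_max < 0:
        raise ValidationError("T_max must be non-negative")
    return 0.5 * (abs(z1) + abs(z2)) * T_max


def _attribution(D1: np.ndarray, D2: np.ndarray, pairs) -> tuple[list[int], list[int]]:
    """Split aligned query SSEs by which rotation explains them better.

    A pair is exclusive to a rotation when its D entry under that rotation
    strictly exceeds the entry under the other one.
    """
    dom1, dom2 = [], []
    for i, j in pairs:
        if D1[i, j] > D2[i, j]:
            dom1.append(i)
        elif D2[i, j] > D1[i, j]:
            dom2.append(i)
    return dom1, dom2


def flexible_search(
    X: ReducedRepresentation,
    Y: ReducedRepresentation,
    params: MatchParams,
    minima=None,
) -> FlexibleMatch | None:
    """Search for a two-rotation (hinge) match between two representations.

    Takes the ``params.top_minima`` most significant minima (precomputed
    ``minima`` may be supplied to avoid repeating :func:`collect_minima`),
    and for every pair separated by at least ``params.min_separation_deg``
    builds D^max, aligns it, and checks complementarity: each rotation must
    contribute at least one exclusively matched pair.  The best-scoring pair
    is returned only if its combined T strictly exceeds the best
    single-rotation T; otherwise the relation is rigid (or absent) and the
    result is ``None``.

    The pair search generalizes to n > 2 complementary rotations in the
    obvious way; only n = 2 is implemented.
    """
    if minima is None:
        minima = collect_minima(X, Y, params)
    if len(minima) < 2:
        return None
    minima = minima[: params.top_minima]
    mats = [similarity_matrix(X, Y, m.rotation, params) for m in minima]
    alns = [align_sses(d, params.gap_open, params.align_mode) for d in mats]
    best_rigid_T = max(a.total_score for a in alns)

    best: FlexibleMatch | None = None
    for a, b in combinations(range(len(minima)), 2):
        sep = rotation_separation(minima[a].rotation, minima[b].rotation)
        if sep < params.min_separation_deg:
            continue
        dmax = combined_similarity(mats[a], mats[b])
        aln = align_sses(dmax, params.gap_open, params.align_mode)
        if aln.total_score <= best_rigid_T:
            continue
        dom1, dom2 = _attribution(mats[a].values, mats[b].values, aln.pairs)
        if not dom1 or not dom2:
            continue  # one rotation explains everything: not a flexible match
        score = flexible_score(minima[a].z, minima[b].z, aln.total_score)
        if best is None or score > best.score:
            best = FlexibleMatch(
                r1=minima[a].rotation,
                r2=minima[b].rotation,
                z1=minima[a].z,
                z2=minima[b].z,
                combined_alignment=aln,
                score=score,
                separation=sep,
                domain1=dom1,
                domain2=dom2,
            )
    return best
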