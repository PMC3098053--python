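"""Order-preserving SSE correspondence by dynamic programming.

Given the similarity matrix D evaluated at an optimal rotation, the SSE
correspondence is the strictly order-preserving partial map M: i -> M(i)
(increasing in both indices) that maximizes the sum of matched D entries
minus gap penalties.  The reported total aligned score T(D) is the pure sum
of D over matched pairs; unmatched SSEs are ignored by T.

The gap model charges a constant penalty per gap opening (default -1) and
nothing per extension, so the recurrences are Gotoh-style with three states:
ending in a match, in a gap in Y (X element unmatched), or in a gap in X.
Three modes are provided: global (Needleman-Wunsch), semiglobal (free end
gaps in both sequences; the default for substructure search) and local
(Smith-Waterman).  With all D >= 0 and this gap model, semiglobal and local
optima coincide; both are kept for interface completeness.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np

from .errors import ValidationError

_NEG = -1e30
_TIE_TOL = 1e-9

MODES = ("global", "semiglobal", "local")


@dataclasses.dataclass
class SseAlignment:
    """An order-preserving SSE map with its total aligned score T(D).

    ``pairs`` are 0-based (i, j) indices, strictly increasing in both
    coordinates.  ``total_score`` is the sum of D over the matched pairs
    (gap penalties excluded); ``objective`` is the DP objective including
    the ``gap_count`` charged gap openings.
    """

    pairs: list[tuple[int, int]]
    total_score: float
    gap_count: int
    mode: str
    objective: float

    def __post_init__(self) -> None:
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if not (i1 < i2 and j1 < j2):
                raise ValidationError(
                    f"alignment violates order preservation: ({i1},{j1}) then ({i2},{j2})"
                )

    def __len__(self) -> int:
        return len(self.pairs)


def length_mismatch_factor(delta_L: float, len_tol: float) -> float:
    """Down-weighting of a pair by SSE length mismatch: exp(-(dL/tol)^2)."""
    if delta_L < 0:
        raise ValidationError("delta_L must be non-negative")
    if len_tol <= 0:
        raise ValidationError("len_tol must be positive")
    return float(np.exp(-((delta_L / len_tol) ** 2)))


def _as_matrix(D) -> np.ndarray:
    values = getattr(D, "values", D)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("similarity matrix must be 2-D")
    if not np.isfinite(values).all():
        raise ValidationError("similarity matrix must be finite")
    return values


def _fill(D: np.ndarray, g: float, free_ends: bool):
    """Row-vectorized Gotoh fill; returns (M, Ix, Iy) of shape (n+1, m+1)."""
    n, m = D.shape
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in Y: X element unmatched
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in X: Y element unmatched
    M[0, 0] = 0.0
    if not free_ends:
        # leading gap run in Y only (row 0): one opening
        enter = np.maximum(M[0] + g, Ix[0] + g)
        Iy[0, 1:] = np.maximum.accumulate(enter[:-1])
    for i in range(1, n + 1):
        Ix[i] = np.maximum.reduce([M[i - 1] + g, Ix[i - 1], Iy[i - 1] + g])
        prev = np.maximum.reduce([M[i - 1, :-1], Ix[i - 1, :-1], Iy[i - 1, :-1]])
        if free_ends:
            prev = np.maximum(prev, 0.0)
        M[i, 1:] = D[i - 1] + prev
        M[i, 0] = _NEG
        enter = np.maximum(M[i] + g, Ix[i] + g)
        Iy[i, 1:] = np.maximum.accumulate(enter[:-1])
    return M, Ix, Iy


def _traceback(D, g, M, Ix, Iy, start_state, i, j, free_ends):
    """Reconstruct pairs and count charged gap openings; deterministic ties.

    Tie-break priority at equal scores: match, then (for free ends) the free
    start, then gap-in-Y, then gap-in-X.
    """
    pairs: list[tuple[int, int]] = []
    gap_count = 0
    state = start_state
    while True:
        if state == "M":
            if i == 0 and j == 0:
                break
            pairs.append((i - 1, j - 1))
            target = M[i, j] - D[i - 1, j - 1]
            cand = [("M", M[i - 1, j - 1])]
            if free_ends:
                cand.append(("start", 0.0))
            cand += [("Ix", Ix[i - 1, j - 1]), ("Iy", Iy[i - 1, j - 1])]
            i, j = i - 1, j - 1
        elif state == "Ix":
            target = Ix[i, j]
            cand = [
                ("M", M[i - 1, j] + g),
                ("Ix", Ix[i - 1, j]),
                ("Iy", Iy[i - 1, j] + g),
            ]
            i = i - 1
        else:  # Iy
            target = Iy[i, j]
            cand = [
                ("M", M[i, j - 1] + g),
                ("Ix", Ix[i, j - 1] + g),
                ("Iy", Iy[i, j - 1]),
            ]
            j = j - 1
        for name, val in cand:
            if val >= target - _TIE_TOL:
                if name == "start":
                    pairs.reverse()
                    return pairs, gap_count
                # a gap run is charged where it was entered from another state
                if state in ("Ix", "Iy") and name != state:
                    gap_count += 1
                state = name
                break
        else:  # pragma: no cover - defensive
            raise RuntimeError("traceback lost the DP path")
    pairs.reverse()
    return pairs, gap_count


def align_sses(D, gap_open: float = -1.0, mode: str = "semiglobal") -> SseAlignment:
    """Optimal order-preserving SSE alignment of a similarity matrix.

    ``D`` may be a :class:`~ssevec.rotation_search.SimilarityMatrix` or a
    plain array.  ``gap_open`` is the (negative) score added once per gap
    opening; extensions are free.  ``total_score`` is recomputed as the pure
    sum of matched D entries.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown alignment mode {mode!r}")
    values = _as_matrix(D)
    n, m = values.shape
    if n == 0 or m == 0:
        return SseAlignment([], 0.0, 0, mode, 0.0)
    g = float(gap_open)
    free_ends = mode in ("semiglobal", "local")
    M, Ix, Iy = _fill(values, g, free_ends)
    if free_ends:
        best = float(M.max())
        if best <= 0.0:
            return SseAlignment([], 0.0, 0, mode, 0.0)
        i, j = np.unravel_index(int(np.argmax(M)), M.shape)
        pairs, gaps = _traceback(values, g, M, Ix, Iy, "M", int(i), int(j), True)
        objective = best
    else:
        states = [("M", M[n, m]), ("Ix", Ix[n, m]), ("Iy", Iy[n, m])]
        start_state, objective = max(states, key=lambda s: s[1])
        # tie priority: match over gap-in-Y over gap-in-X
        for name, val in states:
            if val >= objective - _TIE_TOL:
                start_state, objective = name, val
                break
        pairs, gaps = _traceback(values, g, M, Ix, Iy, start_state, n, m, False)
        objective = float(objective)
    total = float(values[tuple(zip(*pairs))].sum()) if pairs else 0.0
    return SseAlignment(pairs, total, gaps, mode, objective)


def brute_force_best_map(D) -> tuple[list[tuple[int, int]], float]:
    """Exhaustive maximum over all strictly order-preserving partial maps.

    A test oracle only: refuses matrices larger than 8x8.  Returns the
    lexicographically first maximizing map and its score (sum of matched D).
    """
    values = _as_matrix(D)
    n, m = values.shape
    if n > 8 or m > 8:
        raise ValidationError("brute_force_best_map is limited to 8x8 matrices")
    best_pairs: list[tuple[int, int]] = []
    best_score = 0.0
    for k in range(1, min(n, m) + 1):
        for rows in combinations(range(n), k):
            for cols in combinations(range(m), k):
                score = float(values[rows, cols].sum())
                if score > best_score + 1e-15:
                    best_score = score
                    best_pairs = list(zip(rows, cols))
    return best_pairs, best_score
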