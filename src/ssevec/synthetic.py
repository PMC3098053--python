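"""Synthetic fixtures: random representations, hinge conformer pairs,
decoy databases, and ideal-geometry PDB files.

Every generator is deterministic given its seed.  The representations drawn
here have uniformly random SSE directions — they emulate the combinatorial
diversity of a structure database, not realistic fold topologies or packing
(translations are outside the representation by design).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ValidationError
from .reduction import ReducedRepresentation, SseType
from .rotation_search import Rotation

#: conventional residue-length ranges for synthetic SSEs (inclusive)
HELIX_LENGTHS = (6, 20)
STRAND_LENGTHS = (3, 10)

#: ideal helix geometry: 1.5 A rise and 100 deg twist per residue, 2.3 A radius
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3
#: ideal extended strand: 3.5 A per residue along the axis
STRAND_STEP = 3.5


@dataclasses.dataclass
class HingeSpec:
    """Parameters of a planted two-domain hinge-motion conformer pair."""

    n_sse: int = 12
    split_index: int = 6
    hinge_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    hinge_angle: float = 70.0  # degrees
    noise_sigma: float = 0.0  # degrees
    seed: int = 0
    helix_fraction: float = 0.65

    def __post_init__(self) -> None:
        if not 1 <= self.split_index < self.n_sse:
            raise ValidationError("split_index must satisfy 1 <= split < n_sse")
        if not 0.0 <= self.hinge_angle <= 180.0:
            raise ValidationError("hinge_angle must be in [0, 180] degrees")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def random_representation(
    n: int,
    helix_fraction: float = 0.65,
    seed: int = 0,
    rep_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> ReducedRepresentation:
    """A representation with n directions uniform on the sphere.

    Types are helix with probability ``helix_fraction``; lengths are uniform
    over the conventional per-type ranges.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0.0 <= helix_fraction <= 1.0:
        raise ValidationError("helix_fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    vectors = _unit(rng.normal(size=(n, 3)))
    types = [
        SseType.HELIX if u < helix_fraction else SseType.STRAND
        for u in rng.random(n)
    ]
    lengths = np.array(
        [
            rng.integers(*HELIX_LENGTHS, endpoint=True)
            if t is SseType.HELIX
            else rng.integers(*STRAND_LENGTHS, endpoint=True)
            for t in types
        ]
    )
    return ReducedRepresentation(
        id=rep_id if rep_id is not None else f"synthetic_{seed}_{n}",
        vectors=vectors,
        types=types,
        lengths=lengths,
    )


def perturb(
    X: ReducedRepresentation,
    noise_sigma: float,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> ReducedRepresentation:
    """Tilt each vector independently by |Normal(0, sigma)| degrees.

    The tilt axis is a uniformly random direction perpendicular to the
    vector; types, lengths and order are unchanged.
    """
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    if noise_sigma == 0:
        return ReducedRepresentation(
            id=X.id, vectors=X.vectors.copy(), types=list(X.types),
            lengths=X.lengths.copy(),
        )
    out = np.empty_like(X.vectors)
    for i, v in enumerate(X.vectors):
        angle = abs(rng.normal(0.0, np.deg2rad(noise_sigma)))
        raw = rng.normal(size=3)
        perp = raw - (raw @ v) * v
        while np.linalg.norm(perp) < 1e-12:  # pragma: no cover - measure zero
            raw = rng.normal(size=3)
            perp = raw - (raw @ v) * v
        axis = perp / np.linalg.norm(perp)
        out[i] = Rotation.from_axis_angle(axis, angle).apply(v)
    return ReducedRepresentation(
        id=X.id, vectors=_unit(out), types=list(X.types), lengths=X.lengths.copy()
    )


def hinge_pair(
    spec: HingeSpec,
) -> tuple[ReducedRepresentation, ReducedRepresentation]:
    """Two conformers related by a hinge motion between two rigid blocks.

    Conformer A is random; conformer B equals A with the vectors at indices
    >= ``split_index`` rotated about the hinge axis by the hinge angle, then
    angular noise applied to every vector of B.
    """
    rng = np.random.default_rng(spec.seed)
    a = random_representation(
        spec.n_sse,
        helix_fraction=spec.helix_fraction,
        rep_id=f"hinge_{spec.seed}_A",
        rng=rng,
    )
    hinge = Rotation.from_axis_angle(
        np.asarray(spec.hinge_axis, float), np.deg2rad(spec.hinge_angle)
    )
    vectors = a.vectors.copy()
    vectors[spec.split_index :] = hinge.apply(vectors[spec.split_index :])
    b = ReducedRepresentation(
        id=f"hinge_{spec.seed}_B",
        vectors=vectors,
        types=list(a.types),
        lengths=a.lengths.copy(),
    )
    if spec.noise_sigma > 0:
        b = perturb(b, spec.noise_sigma, rng=rng)
    return a, b


def decoy_database(
    n_entries: int,
    size_range: tuple[int, int] = (4, 20),
    seed: int = 0,
    helix_fraction: float = 0.65,
) -> list[ReducedRepresentation]:
    """Independent random representations with unique ids, >= 4 SSEs each."""
    if n_entries < 1:
        raise ValidationError("n_entries must be >= 1")
    lo, hi = size_range
    if lo < 4:
        raise ValidationError("database entries need at least 4 SSEs")
    rng = np.random.default_rng(seed)
    db = []
    for k in range(n_entries):
        n = int(rng.integers(lo, hi, endpoint=True))
        db.append(
            random_representation(
                n, helix_fraction=helix_fraction, rep_id=f"decoy_{seed}_{k:04d}",
                rng=rng,
            )
        )
    return db


# ---------------------------------------------------------------------------
# ideal-geometry PDB fixtures


def _put(line: list[str], s: str, col: int) -> None:
    for k, ch in enumerate(s):
        line[col - 1 + k] = ch


def _helix_record(ser: int, chain: str, start: int, end: int, length: int) -> str:
    line = list(" " * 80)
    _put(line, "HELIX", 1)
    _put(line, f"{ser:>3d}", 8)
    _put(line, f"{ser:>3d}", 12)
    _put(line, "ALA", 16)
    _put(line, chain, 20)
    _put(line, f"{start:>4d}", 22)
    _put(line, "ALA", 28)
    _put(line, chain, 32)
    _put(line, f"{end:>4d}", 34)
    _put(line, " 1", 39)
    _put(line, f"{length:>5d}", 72)
    return "".join(line).rstrip()


def _sheet_record(ser: int, chain: str, start: int, end: int) -> str:
    line = list(" " * 80)
    _put(line, "SHEET", 1)
    _put(line, f"{ser:>3d}", 8)
    _put(line, f"{ser:>3d}", 12)
    _put(line, f"{1:>2d}", 15)
    _put(line, "ALA", 18)
    _put(line, chain, 22)
    _put(line, f"{start:>4d}", 23)
    _put(line, "ALA", 29)
    _put(line, chain, 33)
    _put(line, f"{end:>4d}", 34)
    _put(line, f"{0:>2d}", 39)
    return "".join(line).rstrip()


def _atom_record(serial: int, resseq: int, xyz: np.ndarray, chain: str = "A") -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:>5d}  CA  ALA {chain}{resseq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
    )


def _axis_frame(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix whose third column is the given (unit) axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return np.stack([e1, e2, axis], axis=1)


def ideal_sse_coords(
    kind: SseType, n_res: int, axis=(0.0, 0.0, 1.0), origin=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """C-alpha coordinates of one ideal helix or extended strand."""
    if n_res < 3:
        raise ValidationError("n_res must be >= 3")
    kind = SseType(kind)
    frame = _axis_frame(np.asarray(axis, float))
    k = np.arange(n_res)
    if kind is SseType.HELIX:
        phi = np.deg2rad(HELIX_TWIST_DEG) * k
        local = np.stack(
            [HELIX_RADIUS * np.cos(phi), HELIX_RADIUS * np.sin(phi), HELIX_RISE * k],
            axis=1,
        )
    else:
        local = np.stack([np.zeros(n_res), np.zeros(n_res), STRAND_STEP * k], axis=1)
    return local @ frame.T + np.asarray(origin, float)


def ideal_sse_pdb(
    kind: SseType,
    n_res: int,
    axis=(0.0, 0.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    chain: str = "A",
    first_residue: int = 1,
) -> str:
    """PDB text for one ideal SSE with its HELIX/SHEET record."""
    kind = SseType(kind)
    coords = ideal_sse_coords(kind, n_res, axis=axis, origin=origin)
    start = first_residue
    end = first_residue + n_res - 1
    if kind is SseType.HELIX:
        header = [_helix_record(1, chain, start, end, n_res)]
    else:
        header = [_sheet_record(1, chain, start, end)]
    lines = header + [
        _atom_record(i + 1, start + i, coords[i], chain) for i in range(n_res)
    ]
    return "\n".join(lines + ["END", ""])


def multi_sse_pdb(segments: list[tuple[SseType, int, np.ndarray, np.ndarray]],
                  chain: str = "A") -> str:
    """PDB text for several SSEs on one chain, with a gap residue between each.

    ``segments`` is a list of (kind, n_res, axis, origin) tuples in sequence
    order; residue numbering is contiguous within an SSE with one skipped
    number between consecutive SSEs.
    """
    records, atoms = [], []
    serial, resseq, n_helix, n_sheet = 1, 1, 0, 0
    for kind, n_res, axis, origin in segments:
        kind = SseType(kind)
        coords = ideal_sse_coords(kind, n_res, axis=axis, origin=origin)
        start, end = resseq, resseq + n_res - 1
        if kind is SseType.HELIX:
            n_helix += 1
            records.append(_helix_record(n_helix, chain, start, end, n_res))
        else:
            n_sheet += 1
            records.append(_sheet_record(n_sheet, chain, start, end))
        for i in range(n_res):
            atoms.append(_atom_record(serial, resseq, coords[i], chain))
            serial += 1
            resseq += 1
        resseq += 1  # leave a numbering gap between SSEs
    return "\n".join(records + atoms + ["END", ""])
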