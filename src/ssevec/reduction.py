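"""Reduction of protein chains to ordered, typed SSE unit vectors.

A protein chain is reduced to one direction vector per secondary-structure
element (SSE): an ordered list of 3-D unit vectors, each tagged as helix or
strand and carrying the element's residue length.  The order is the order of
the SSEs on the peptide sequence.  Translational placement of the elements is
deliberately discarded — two structures are compared purely by SSE direction,
type and sequential order.

SSE boundaries are taken from HELIX/SHEET records in the input file (or from
an external assignment); no geometric secondary-structure assignment is
attempted here.  Each element's direction is the first principal axis of its
C-alpha point cloud, oriented N->C.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    ChainNotFoundError,
    DegenerateGeometryError,
    EmptyRepresentationError,
    FormatError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: default minimum residue counts below which an annotated SSE is discarded
MIN_HELIX_RESIDUES = 4
MIN_STRAND_RESIDUES = 3

UNIT_NORM_TOL = 1e-9


class SseType(str, enum.Enum):
    """The two element types carried by the representation."""

    HELIX = "helix"
    STRAND = "strand"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclasses.dataclass
class SseAnnotation:
    """One HELIX/SHEET record (author residue numbering, inclusive)."""

    chain_id: str
    start_residue: int
    end_residue: int
    sse_type: SseType


@dataclasses.dataclass
class ChainTrace:
    """Ordered C-alpha trace of one chain, plus its SSE annotations."""

    structure_id: str
    chain_id: str
    residue_ids: list[int]
    coords: np.ndarray  # (n, 3) Angstrom
    annotations: list[SseAnnotation] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residue_ids)


@dataclasses.dataclass
class SseSegment:
    """A single secondary-structure element before reduction to a vector."""

    chain_id: str
    start_residue: int
    end_residue: int
    sse_type: SseType
    ca_coords: np.ndarray  # (n, 3), ordered N->C

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.start_residue > self.end_residue:
            raise ValidationError(
                f"segment start {self.start_residue} > end {self.end_residue}"
            )
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValidationError("ca_coords must be an (n, 3) array")
        if len(self.ca_coords) < 2:
            raise ValidationError("segment needs at least 2 C-alpha points")


@dataclasses.dataclass
class ReducedRepresentation:
    """Ordered typed unit-vector representation of one chain.

    ``vectors[i]`` is the N->C direction of the i-th SSE on the sequence,
    ``types[i]`` its helix/strand indicator and ``lengths[i]`` its residue
    count.  ``meta`` optionally retains per-SSE provenance (chain and author
    residue range) so files round-trip losslessly.
    """

    id: str
    vectors: np.ndarray  # (N, 3) unit vectors
    types: list[SseType]
    lengths: np.ndarray  # (N,) int
    meta: list[dict] | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.types = [SseType(t) for t in self.types]
        n = len(self.vectors)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValidationError("vectors must be an (N, 3) array")
        if len(self.types) != n or len(self.lengths) != n:
            raise ValidationError(
                f"mismatched list lengths: {n} vectors, {len(self.types)} types, "
                f"{len(self.lengths)} lengths"
            )
        if self.meta is not None and len(self.meta) != n:
            raise ValidationError("meta length does not match vector count")
        if n:
            norms = np.linalg.norm(self.vectors, axis=1)
            bad = np.abs(norms - 1.0) > UNIT_NORM_TOL
            if bad.any():
                raise ValidationError(
                    f"vector {int(np.argmax(bad))} is not unit norm "
                    f"(|v| = {norms[np.argmax(bad)]:.12g})"
                )

    @property
    def count(self) -> int:
        return len(self.vectors)

    def __len__(self) -> int:
        return len(self.vectors)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReducedRepresentation):
            return NotImplemented
        return (
            self.id == other.id
            and np.array_equal(self.vectors, other.vectors)
            and self.types == other.types
            and np.array_equal(self.lengths, other.lengths)
            and self.meta == other.meta
        )

    def type_codes(self) -> np.ndarray:
        """Types as an int array (0 = helix, 1 = strand) for vectorized masks."""
        return np.array([0 if t is SseType.HELIX else 1 for t in self.types])


# ---------------------------------------------------------------------------
# structure reading


def _extract_annotations(st: gemmi.Structure) -> list[SseAnnotation]:
    ann: list[SseAnnotation] = []
    for h in st.helices:
        ann.append(
            SseAnnotation(
                chain_id=h.start.chain_name,
                start_residue=h.start.res_id.seqid.num,
                end_residue=h.end.res_id.seqid.num,
                sse_type=SseType.HELIX,
            )
        )
    for sheet in st.sheets:
        for s in sheet.strands:
            ann.append(
                SseAnnotation(
                    chain_id=s.start.chain_name,
                    start_residue=s.start.res_id.seqid.num,
                    end_residue=s.end.res_id.seqid.num,
                    sse_type=SseType.STRAND,
                )
            )
    return ann


def load_ca_trace(path: str | Path, chain: str | None = None) -> list[ChainTrace]:
    """Read a PDB/mmCIF file into ordered per-chain C-alpha traces.

    Residues lacking a C-alpha atom are skipped with a logged warning.
    HELIX/SHEET records found in the file are attached to the trace of the
    chain they annotate.

    Raises :class:`ParseError` for unreadable files and
    :class:`ChainNotFoundError` if ``chain`` is requested but absent.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, SystemError) as exc:
        raise ParseError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no models found in {path}")
    annotations = _extract_annotations(st)
    structure_id = st.name.strip() or path.stem

    model = st[0]
    traces: list[ChainTrace] = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        residue_ids: list[int] = []
        coords: list[list[float]] = []
        for res in ch:
            ca = res.find_atom("CA", "*")
            if ca is None:
                logger.warning(
                    "%s chain %s residue %d has no C-alpha; skipped",
                    structure_id,
                    ch.name,
                    res.seqid.num,
                )
                continue
            residue_ids.append(res.seqid.num)
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        if not residue_ids:
            continue
        traces.append(
            ChainTrace(
                structure_id=structure_id,
                chain_id=ch.name,
                residue_ids=residue_ids,
                coords=np.asarray(coords, dtype=float),
                annotations=[a for a in annotations if a.chain_id == ch.name],
            )
        )
    if chain is not None and not traces:
        raise ChainNotFoundError(f"chain {chain!r} not found in {path}")
    if not traces:
        raise ParseError(f"no C-alpha atoms found in {path}")
    return traces


# ---------------------------------------------------------------------------
# SSE assignment and axis fitting


def assign_sses(
    trace: ChainTrace,
    annotations: Sequence[SseAnnotation] | None = None,
    min_helix: int = MIN_HELIX_RESIDUES,
    min_strand: int = MIN_STRAND_RESIDUES,
) -> list[SseSegment]:
    """Turn HELIX/SHEET annotations into ordered, length-filtered segments.

    ``annotations`` defaults to the records carried on the trace.  Segments
    shorter than the per-type minima (counted as C-alpha residues actually
    present in the trace) are discarded; overlapping records raise a
    :class:`ValidationError`.
    """
    if len(trace) == 0:
        raise ValidationError("empty trace")
    if annotations is None:
        annotations = trace.annotations
    chain_ann = sorted(
        (a for a in annotations if a.chain_id == trace.chain_id),
        key=lambda a: (a.start_residue, a.end_residue),
    )
    for prev, cur in zip(chain_ann, chain_ann[1:]):
        if cur.start_residue <= prev.end_residue:
            raise ValidationError(
                f"overlapping SSE records {prev.start_residue}-{prev.end_residue} "
                f"and {cur.start_residue}-{cur.end_residue} on chain {trace.chain_id}"
            )

    resid = np.asarray(trace.residue_ids)
    segments: list[SseSegment] = []
    for a in chain_ann:
        sel = (resid >= a.start_residue) & (resid <= a.end_residue)
        n_res = int(sel.sum())
        minimum = min_helix if a.sse_type is SseType.HELIX else min_strand
        if n_res < minimum:
            logger.info(
                "dropping %s %d-%d on chain %s (%d residues < minimum %d)",
                a.sse_type.value,
                a.start_residue,
                a.end_residue,
                trace.chain_id,
                n_res,
                minimum,
            )
            continue
        segments.append(
            SseSegment(
                chain_id=trace.chain_id,
                start_residue=a.start_residue,
                end_residue=a.end_residue,
                sse_type=a.sse_type,
                ca_coords=trace.coords[sel],
            )
        )
    return segments


def segment_axis(segment: SseSegment) -> tuple[np.ndarray, int]:
    """Principal axis of a segment's C-alpha cloud, oriented N->C.

    Returns ``(unit_vector, residue_count)``.  The axis is the first
    principal component of the centred coordinates; its sign is chosen so
    that the dot product with (last - first C-alpha) is non-negative.
    """
    pts = segment.ca_coords
    centered = pts - pts.mean(axis=0)
    # principal axis via SVD of the centred cloud
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-8:
        raise DegenerateGeometryError(
            "all C-alpha points coincide; no axis is defined"
        )
    axis = vt[0]
    span = pts[-1] - pts[0]
    if axis @ span < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), len(pts)


def reduce_structure(
    trace: ChainTrace, segments: Sequence[SseSegment]
) -> ReducedRepresentation:
    """Reduce an annotated chain to its typed unit-vector representation."""
    if not segments:
        raise EmptyRepresentationError(
            f"{trace.structure_id} chain {trace.chain_id}: no SSEs survive reduction"
        )
    vectors, types, lengths, meta = [], [], [], []
    for seg in sorted(segments, key=lambda s: s.start_residue):
        axis, n_res = segment_axis(seg)
        vectors.append(axis)
        types.append(seg.sse_type)
        lengths.append(n_res)
        meta.append(
            {
                "chain": seg.chain_id,
                "start": seg.start_residue,
                "end": seg.end_residue,
            }
        )
    return ReducedRepresentation(
        id=f"{trace.structure_id}_{trace.chain_id}",
        vectors=np.asarray(vectors),
        types=types,
        lengths=np.asarray(lengths),
        meta=meta,
    )


def reduce_file(
    path: str | Path,
    chain: str | None = None,
    annotations: Sequence[SseAnnotation] | None = None,
    min_helix: int = MIN_HELIX_RESIDUES,
    min_strand: int = MIN_STRAND_RESIDUES,
) -> list[ReducedRepresentation]:
    """Convenience: load a structure file and reduce every requested chain."""
    reps = []
    for trace in load_ca_trace(path, chain=chain):
        segs = assign_sses(
            trace, annotations=annotations, min_helix=min_helix, min_strand=min_strand
        )
        if not segs:
            logger.info(
                "%s chain %s: no SSEs after filtering; skipped",
                trace.structure_id,
                trace.chain_id,
            )
            continue
        reps.append(reduce_structure(trace, segs))
    if not reps:
        raise EmptyRepresentationError(f"no chain of {path} yields any SSE")
    return reps


# ---------------------------------------------------------------------------
# representation file format (one JSON record per line)


def _rep_to_record(rep: ReducedRepresentation) -> dict:
    sses = []
    for i in range(rep.count):
        entry = {
            "type": rep.types[i].value,
            "vector": [float(x) for x in rep.vectors[i]],
            "length": int(rep.lengths[i]),
        }
        if rep.meta is not None:
            entry.update(rep.meta[i])
        sses.append(entry)
    return {"id": rep.id, "sses": sses}


def _record_to_rep(record: dict, lineno: int | None = None) -> ReducedRepresentation:
    where = f" (line {lineno})" if lineno is not None else ""
    if not isinstance(record, dict) or "id" not in record:
        raise FormatError(f"record missing field 'id'{where}")
    if "sses" not in record or not isinstance(record["sses"], list):
        raise FormatError(f"record {record.get('id')!r} missing field 'sses'{where}")
    vectors, types, lengths, meta = [], [], [], []
    has_meta = False
    for k, sse in enumerate(record["sses"]):
        for field in ("type", "vector", "length"):
            if field not in sse:
                raise FormatError(
                    f"record {record['id']!r} SSE {k} missing field {field!r}{where}"
                )
        try:
            types.append(SseType(sse["type"]))
        except ValueError as exc:
            raise FormatError(
                f"record {record['id']!r} SSE {k}: bad field 'type' {sse['type']!r}"
            ) from exc
        vec = np.asarray(sse["vector"], dtype=float)
        if vec.shape != (3,):
            raise FormatError(
                f"record {record['id']!r} SSE {k}: field 'vector' is not 3-D"
            )
        if abs(np.linalg.norm(vec) - 1.0) > UNIT_NORM_TOL:
            raise FormatError(
                f"record {record['id']!r} SSE {k}: field 'vector' is not unit norm"
            )
        vectors.append(vec)
        lengths.append(int(sse["length"]))
        m = {key: sse[key] for key in ("chain", "start", "end") if key in sse}
        meta.append(m)
        has_meta = has_meta or bool(m)
    try:
        return ReducedRepresentation(
            id=record["id"],
            vectors=np.asarray(vectors).reshape(len(vectors), 3),
            types=types,
            lengths=np.asarray(lengths, dtype=int),
            meta=meta if has_meta else None,
        )
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_representations(
    reps: Iterable[ReducedRepresentation], path: str | Path
) -> None:
    """Write representations as line-delimited JSON (one record per line)."""
    with open(path, "w") as fh:
        for rep in reps:
            fh.write(json.dumps(_rep_to_record(rep)) + "\n")


def write_representation(rep: ReducedRepresentation, path: str | Path) -> None:
    write_representations([rep], path)


def read_representations(path: str | Path) -> list[ReducedRepresentation]:
    """Read a line-delimited JSON representation file."""
    reps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"line {lineno} is not valid JSON: {exc}") from exc
            reps.append(_record_to_rep(record, lineno=lineno))
    return reps


def read_representation(path: str | Path) -> ReducedRepresentation:
    """Read a single-record representation file."""
    reps = read_representations(path)
    if len(reps) != 1:
        raise FormatError(f"expected exactly one record in {path}, found {len(reps)}")
    return reps[0]
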