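import json

import numpy as np
import pytest

from ssevec import (
    ChainNotFoundError,
    DegenerateGeometryError,
    EmptyRepresentationError,
    FormatError,
    ParseError,
    ReducedRepresentation,
    SseAnnotation,
    SseSegment,
    SseType,
    ValidationError,
    assign_sses,
    load_ca_trace,
    read_representations,
    reduce_structure,
    segment_axis,
    write_representations,
)
from ssevec.reduction import ChainTrace, reduce_file
from ssevec.rotation_search import Rotation
from ssevec.synthetic import (
    ideal_sse_coords,
    ideal_sse_pdb,
    multi_sse_pdb,
    random_representation,
)


def _trace(coords, start=1, chain="A", annotations=()):
    coords = np.asarray(coords, float)
    return ChainTrace(
        structure_id="test",
        chain_id=chain,
        residue_ids=list(range(start, start + len(coords))),
        coords=coords,
        annotations=list(annotations),
    )


class TestLoadCaTrace:
    def test_ideal_helix_fixture(self, tmp_path):
        p = tmp_path / "helix.pdb"
        p.write_text(ideal_sse_pdb(SseType.HELIX, 12))
        traces = load_ca_trace(p)
        assert len(traces) == 1
        assert len(traces[0]) == 12
        assert traces[0].residue_ids == list(range(1, 13))
        assert len(traces[0].annotations) == 1
        assert traces[0].annotations[0].sse_type is SseType.HELIX

    def test_chain_selection(self, tmp_path):
        a = ideal_sse_pdb(SseType.HELIX, 8, chain="A").splitlines()
        b = ideal_sse_pdb(SseType.HELIX, 8, chain="B").splitlines()
        # records first, then atoms, as in a real header-then-coordinates file
        text = "\n".join([a[0], b[0]] + a[1:-1] + b[1:-1] + ["END", ""])
        p = tmp_path / "two_chains.pdb"
        p.write_text(text)
        traces = load_ca_trace(p, chain="B")
        assert [t.chain_id for t in traces] == ["B"]
        assert len(load_ca_trace(p)) == 2

    def test_missing_chain(self, tmp_path):
        p = tmp_path / "helix.pdb"
        p.write_text(ideal_sse_pdb(SseType.HELIX, 8))
        with pytest.raises(ChainNotFoundError):
            load_ca_trace(p, chain="Z")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ParseError):
            load_ca_trace(p)


class TestAssignSses:
    def test_helix_record_pass_through(self, tmp_path):
        p = tmp_path / "helix.pdb"
        p.write_text(ideal_sse_pdb(SseType.HELIX, 12))
        (trace,) = load_ca_trace(p)
        segs = assign_sses(trace)
        assert len(segs) == 1
        assert segs[0].sse_type is SseType.HELIX
        assert len(segs[0].ca_coords) == 12

    def test_short_helix_dropped(self):
        trace = _trace(np.outer(np.arange(10), [1.0, 0, 0]))
        ann = [
            SseAnnotation("A", 1, 2, SseType.HELIX),  # 2 residues < minimum 4
            SseAnnotation("A", 4, 9, SseType.HELIX),
        ]
        segs = assign_sses(trace, ann)
        assert [(s.start_residue, s.end_residue) for s in segs] == [(4, 9)]

    def test_strand_order_preserved(self):
        trace = _trace(np.outer(np.arange(12), [1.0, 0, 0]))
        ann = [
            SseAnnotation("A", 7, 11, SseType.STRAND),
            SseAnnotation("A", 1, 5, SseType.STRAND),
        ]
        segs = assign_sses(trace, ann)
        assert [s.start_residue for s in segs] == [1, 7]
        assert all(s.sse_type is SseType.STRAND for s in segs)

    def test_overlap_rejected(self):
        trace = _trace(np.outer(np.arange(12), [1.0, 0, 0]))
        ann = [
            SseAnnotation("A", 1, 6, SseType.HELIX),
            SseAnnotation("A", 5, 10, SseType.HELIX),
        ]
        with pytest.raises(ValidationError):
            assign_sses(trace, ann)


class TestSegmentAxis:
    def test_collinear_points(self):
        pts = np.outer(np.arange(5), [1.0, 0, 0])
        seg = SseSegment("A", 1, 5, SseType.STRAND, pts)
        axis, length = segment_axis(seg)
        assert np.allclose(axis, [1, 0, 0])
        assert length == 5

    def test_orientation_follows_trace_direction(self):
        pts = np.outer(np.arange(5), [1.0, 0, 0])
        seg_fwd = SseSegment("A", 1, 5, SseType.STRAND, pts)
        seg_rev = SseSegment("A", 1, 5, SseType.STRAND, pts[::-1])
        assert np.allclose(segment_axis(seg_fwd)[0], [1, 0, 0])
        assert np.allclose(segment_axis(seg_rev)[0], [-1, 0, 0])

    def test_ideal_helix_axis(self):
        pts = ideal_sse_coords(SseType.HELIX, 12)
        seg = SseSegment("A", 1, 12, SseType.HELIX, pts)
        axis, _ = segment_axis(seg)
        angle = np.rad2deg(np.arccos(np.clip(axis @ [0, 0, 1], -1, 1)))
        assert angle < 3.0

    def test_coincident_points(self):
        seg = SseSegment("A", 1, 3, SseType.HELIX, np.zeros((3, 3)))
        with pytest.raises(DegenerateGeometryError):
            segment_axis(seg)


class TestReduceStructure:
    def test_order_and_types(self, tmp_path):
        segments = [
            (SseType.HELIX, 10, (0, 0, 1), (0, 0, 0)),
            (SseType.HELIX, 8, (1, 0, 0), (20, 0, 0)),
            (SseType.STRAND, 5, (0, 1, 0), (40, 0, 0)),
        ]
        p = tmp_path / "three.pdb"
        p.write_text(multi_sse_pdb(segments))
        (rep,) = reduce_file(p)
        assert rep.count == 3
        assert rep.types == [SseType.HELIX, SseType.HELIX, SseType.STRAND]
        assert rep.lengths.tolist() == [10, 8, 5]

    def test_single_helix_vector(self, tmp_path):
        p = tmp_path / "helix.pdb"
        p.write_text(ideal_sse_pdb(SseType.HELIX, 12))
        (rep,) = reduce_file(p)
        angle = np.rad2deg(np.arccos(np.clip(rep.vectors[0] @ [0, 0, 1], -1, 1)))
        assert angle < 3.0

    def test_no_segments_error(self):
        trace = _trace(np.outer(np.arange(5), [1.0, 0, 0]))
        with pytest.raises(EmptyRepresentationError):
            reduce_structure(trace, [])

    def test_reduction_commutes_with_rotation(self):
        segments = [
            (SseType.HELIX, 12, (0, 0, 1), (0.0, 0.0, 0.0)),
            (SseType.STRAND, 6, (1, 1, 0), (25.0, 0.0, 0.0)),
            (SseType.HELIX, 9, (0, 1, 1), (0.0, 25.0, 0.0)),
        ]
        ann = []
        coords = []
        resid = 1
        for kind, n, axis, origin in segments:
            ann.append(SseAnnotation("A", resid, resid + n - 1, SseType(kind)))
            coords.append(ideal_sse_coords(kind, n, axis=axis, origin=origin))
            resid += n + 1
        all_coords = np.concatenate(coords)
        ids = []
        resid = 1
        for kind, n, _, _ in segments:
            ids.extend(range(resid, resid + n))
            resid += n + 1
        trace = ChainTrace("t", "A", ids, all_coords, ann)
        rep = reduce_structure(trace, assign_sses(trace))
        Q = Rotation.from_axis_angle([1, 2, 3], 1.1)
        rotated = ChainTrace("t", "A", ids, all_coords @ Q.as_matrix().T, ann)
        rep_rot = reduce_structure(rotated, assign_sses(rotated))
        assert np.allclose(rep_rot.vectors, Q.apply(rep.vectors), atol=1e-6)


class TestRepresentationIO:
    def test_round_trip_random(self, tmp_path):
        reps = [random_representation(n, seed=n) for n in (1, 4, 9)]
        reps[0].meta = [{"chain": "A", "start": 1, "end": 9}]
        path = tmp_path / "reps.jsonl"
        write_representations(reps, path)
        back = read_representations(path)
        assert back == reps

    def test_non_unit_vector_rejected(self, tmp_path):
        record = {
            "id": "bad",
            "sses": [{"type": "helix", "vector": [1.0, 1.0, 0.0], "length": 8}],
        }
        path = tmp_path / "bad.jsonl"
        path.write_text(json.dumps(record) + "\n")
        with pytest.raises(FormatError, match="vector"):
            read_representations(path)

    def test_missing_field_named(self, tmp_path):
        record = {"id": "bad", "sses": [{"type": "helix", "length": 8}]}
        path = tmp_path / "bad.jsonl"
        path.write_text(json.dumps(record) + "\n")
        with pytest.raises(FormatError, match="vector"):
            read_representations(path)

    def test_mismatched_construction_rejected(self):
        with pytest.raises(ValidationError):
            ReducedRepresentation(
                id="x",
                vectors=np.array([[1.0, 0, 0], [0, 1.0, 0]]),
                types=[SseType.HELIX],
                lengths=np.array([5, 5]),
            )
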