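"""Database building and ranked rigid/flexible scans; the CLI entry point.

A database is a line-delimited JSON file of reduced representations, one
record per chain with at least four SSEs.  A scan compares one query
representation against every entry: rigid hits are ranked by the total
aligned score T(D) at the best rotation minimum, flexible hits by the
two-rotation heuristic score.  The rotational z-score of the best minimum
is reported alongside T so geometric-only and alignment-constrained
rankings can both be inspected.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import click
import numpy as np

from . import reduction
from .errors import EmptyDatabaseError, SsevecError, ValidationError
from .flexible_match import FlexibleMatch, flexible_search
from .reduction import ReducedRepresentation, SseAnnotation, SseType
from .rotation_search import MatchParams, Rotation, collect_minima, similarity_matrix
from .sse_alignment import SseAlignment, align_sses

logger = logging.getLogger(__name__)

MIN_SSE_COUNT = 4  # structures with fewer SSEs carry too little signal


@dataclasses.dataclass
class SearchHit:
    """One ranked entry of a scan report."""

    target_id: str
    mode: str  # "rigid" or "flexible"
    T: float
    z: float
    alignment: SseAlignment
    flex_score: float | None = None
    flexible: FlexibleMatch | None = None
    n_sse: int = 0
    rank: int = 0


_REP_SUFFIXES = {".jsonl", ".json", ".ndjson"}


def build_database(
    paths: Sequence[str | Path],
    min_sse: int = MIN_SSE_COUNT,
    min_helix: int = reduction.MIN_HELIX_RESIDUES,
    min_strand: int = reduction.MIN_STRAND_RESIDUES,
) -> list[ReducedRepresentation]:
    """Collect representations from structure and/or representation files.

    Entries with fewer than ``min_sse`` SSEs are skipped with a logged
    reason; duplicate ids raise an error naming the id.  Record order
    follows the input order deterministically.
    """
    entries: list[ReducedRepresentation] = []
    seen: set[str] = set()
    for path in paths:
        path = Path(path)
        if path.suffix.lower() in _REP_SUFFIXES:
            reps = reduction.read_representations(path)
        else:
            reps = reduction.reduce_file(path, min_helix=min_helix, min_strand=min_strand)
        for rep in reps:
            if rep.count < min_sse:
                logger.info(
                    "skipping %s: %d SSEs < minimum %d", rep.id, rep.count, min_sse
                )
                continue
            if rep.id in seen:
                raise ValidationError(f"duplicate representation id {rep.id!r}")
            seen.add(rep.id)
            entries.append(rep)
    if not entries:
        raise EmptyDatabaseError("no valid entries for the database")
    return entries


def scan(
    query: ReducedRepresentation,
    db: Iterable[ReducedRepresentation],
    params: MatchParams,
    mode: str = "rigid",
    top: int | None = None,
) -> list[SearchHit]:
    """Rank every database entry against the query.

    Rigid hits are sorted by descending T (ties broken by target id);
    in flexible mode, entries with a two-rotation match are ranked first by
    descending flexible score.  Entries with no significant rotation
    minimum get T = 0 and z = 0.
    """
    if mode not in ("rigid", "flexible"):
        raise ValidationError(f"unknown scan mode {mode!r}")
    if query.count < MIN_SSE_COUNT:
        raise ValidationError(
            f"query {query.id!r} has {query.count} SSEs; need >= {MIN_SSE_COUNT}"
        )
    hits: list[SearchHit] = []
    for target in db:
        t0 = time.perf_counter()
        minima = collect_minima(query, target, params)
        best_T = 0.0
        best_aln = SseAlignment([], 0.0, 0, params.align_mode, 0.0)
        for minimum in minima:
            d = similarity_matrix(query, target, minimum.rotation, params)
            aln = align_sses(d, params.gap_open, params.align_mode)
            if aln.total_score > best_T:
                best_T, best_aln = aln.total_score, aln
        hit = SearchHit(
            target_id=target.id,
            mode="rigid",
            T=best_T,
            z=minima[0].z if minima else 0.0,
            alignment=best_aln,
            n_sse=target.count,
        )
        if mode == "flexible" and len(minima) >= 2:
            fm = flexible_search(query, target, params, minima=minima)
            if fm is not None:
                hit.mode = "flexible"
                hit.flexible = fm
                hit.flex_score = fm.score
                hit.alignment = fm.combined_alignment
                hit.T = fm.combined_alignment.total_score
        hits.append(hit)
        logger.debug(
            "scanned %s vs %s in %.1f ms (%d minima)",
            query.id,
            target.id,
            1e3 * (time.perf_counter() - t0),
            len(minima),
        )
    if mode == "flexible":
        hits.sort(
            key=lambda h: (
                0 if h.flex_score is not None else 1,
                -(h.flex_score or 0.0),
                -h.T,
                h.target_id,
            )
        )
    else:
        hits.sort(key=lambda h: (-h.T, h.target_id))
    if top is not None:
        hits = hits[:top]
    for rank, hit in enumerate(hits, start=1):
        hit.rank = rank
    return hits


# ---------------------------------------------------------------------------
# report rendering


def _render_alignment(aln: SseAlignment, query, target) -> str:
    if not aln.pairs:
        return "-"
    return ";".join(
        f"{i}:{query.types[i].value[0]}↔{j}:{target.types[j].value[0]}"
        for i, j in aln.pairs
    )


def _render_rotation(r: Rotation) -> str:
    q = r.q
    angle = 2.0 * np.arccos(min(1.0, abs(float(q[0]))))
    axis = q[1:4] if q[0] >= 0 else -q[1:4]
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
    return (
        f"q=({q[0]:.6f},{q[1]:.6f},{q[2]:.6f},{q[3]:.6f})"
        f"|axis=({axis[0]:.4f},{axis[1]:.4f},{axis[2]:.4f})"
        f"|angle={np.rad2deg(angle):.2f}"
    )


def write_report(
    hits: Sequence[SearchHit],
    query: ReducedRepresentation,
    db: Sequence[ReducedRepresentation],
    params: MatchParams,
    mode: str,
    out: TextIO,
) -> None:
    """Tab-separated scan report with a parameter header block."""
    by_id = {rep.id: rep for rep in db}
    out.write(f"# query\t{query.id}\n")
    out.write(f"# query_n_sse\t{query.count}\n")
    out.write(f"# mode\t{mode}\n")
    for field in dataclasses.fields(params):
        out.write(f"# {field.name}\t{getattr(params, field.name)}\n")
    cols = [
        "rank", "target_id", "mode", "n_sse", "T", "z", "flex_score",
        "separation_deg", "z1", "z2", "r1", "r2", "domain1", "domain2",
        "alignment",
    ]
    out.write("\t".join(cols) + "\n")
    for h in hits:
        target = by_id[h.target_id]
        if h.flexible is not None:
            fm = h.flexible
            flex_cols = [
                f"{fm.score:.6f}", f"{fm.separation:.2f}",
                f"{fm.z1:.4f}", f"{fm.z2:.4f}",
                _render_rotation(fm.r1), _render_rotation(fm.r2),
                ",".join(map(str, fm.domain1)) or "-",
                ",".join(map(str, fm.domain2)) or "-",
            ]
        else:
            flex_cols = ["-"] * 8
        out.write(
            "\t".join(
                [
                    str(h.rank), h.target_id, h.mode, str(h.n_sse),
                    f"{h.T:.6f}", f"{h.z:.4f}", *flex_cols,
                    _render_alignment(h.alignment, query, target),
                ]
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# CLI


def read_sse_file(path: str | Path) -> list[SseAnnotation]:
    """External SSE assignments: TSV lines 'chain<TAB>start<TAB>end<TAB>type'."""
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValidationError(
                    f"{path} line {lineno}: expected 'chain start end type'"
                )
            chain, start, end, sse_type = parts
            annotations.append(
                SseAnnotation(chain, int(start), int(end), SseType(sse_type))
            )
    return annotations


@click.group()
@click.option("-v", "--verbose", count=True, help="-v for info, -vv for debug timing.")
def cli(verbose: int) -> None:
    """Reduced SSE-vector comparison of protein structures."""
    level = logging.WARNING - 10 * min(verbose, 2)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command("reduce")
@click.argument("structure", type=click.Path(exists=True))
@click.option("--chain", default=None, help="Restrict to one chain.")
@click.option("--sse-file", type=click.Path(exists=True), default=None,
              help="External SSE assignment (chain/start/end/type TSV).")
@click.option("--min-helix", default=reduction.MIN_HELIX_RESIDUES, show_default=True)
@click.option("--min-strand", default=reduction.MIN_STRAND_RESIDUES, show_default=True)
@click.option("-o", "--output", type=click.Path(), required=True)
def cli_reduce(structure, chain, sse_file, min_helix, min_strand, output):
    """Reduce a PDB/mmCIF structure to typed SSE unit vectors."""
    annotations = read_sse_file(sse_file) if sse_file else None
    try:
        reps = reduction.reduce_file(
            structure, chain=chain, annotations=annotations,
            min_helix=min_helix, min_strand=min_strand,
        )
    except SsevecError as exc:
        raise click.ClickException(str(exc)) from exc
    reduction.write_representations(reps, output)
    click.echo(f"wrote {len(reps)} representation(s) to {output}", err=True)


@cli.command("build")
@click.argument("inputs", nargs=-1, required=True, type=click.Path(exists=True))
@click.option("--min-sse", default=MIN_SSE_COUNT, show_default=True)
@click.option("-o", "--output", type=click.Path(), required=True)
def cli_build(inputs, min_sse, output):
    """Build a representation database from structures or records."""
    try:
        db = build_database(inputs, min_sse=min_sse)
    except SsevecError as exc:
        raise click.ClickException(str(exc)) from exc
    reduction.write_representations(db, output)
    click.echo(f"wrote {len(db)} entries to {output}", err=True)


@cli.command("scan")
@click.argument("query", type=click.Path(exists=True))
@click.argument("database", type=click.Path(exists=True))
@click.option("--delta", default=0.5, show_default=True, help="Gaussian width (rad).")
@click.option("--len-tol", default=None, type=float,
              help="Length-mismatch tolerance (residues); off when omitted.")
@click.option("--gap-open", default=-1.0, show_default=True)
@click.option("--mode", default="rigid", type=click.Choice(["rigid", "flexible"]),
              show_default=True)
@click.option("--align", default="semiglobal",
              type=click.Choice(["global", "semiglobal", "local"]), show_default=True)
@click.option("--m", "m_trunc", default=3, show_default=True,
              help="Seed-pair index truncation.")
@click.option("--group-eps", default=None, type=float,
              help="Direction-grouping angle (rad); off when omitted.")
@click.option("--z-cut", default=-2.0, show_default=True)
@click.option("--mc-samples", default=2000, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--top", default=None, type=int, help="Report only the top hits.")
@click.option("-o", "--output", type=click.File("w"), default="-")
def cli_scan(query, database, delta, len_tol, gap_open, mode, align, m_trunc,
             group_eps, z_cut, mc_samples, seed, top, output):
    """Scan a query representation against a database."""
    params = MatchParams(
        delta=delta, len_tol=len_tol, gap_open=gap_open, align_mode=align,
        m=m_trunc, group_eps=group_eps, z_cut=z_cut, mc_samples=mc_samples,
        seed=seed,
    )
    try:
        q = reduction.read_representation(query)
        db = reduction.read_representations(database)
        t0 = time.perf_counter()
        hits = scan(q, db, params, mode=mode, top=top)
        logger.info("scanned %d targets in %.2f s", len(db), time.perf_counter() - t0)
    except SsevecError as exc:
        raise click.ClickException(str(exc)) from exc
    write_report(hits, q, db, params, mode, output)


if __name__ == "__main__":  # pragma: no cover
    cli()
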