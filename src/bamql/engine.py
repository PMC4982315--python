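"""The driver: stream reads, apply compiled queries, route to outputs.

Reads come from a BAM or SAM source (``-`` or ``/dev/stdin`` work), each
in-scope record is evaluated exactly once against the compiled query, and
accepted records are written — unmodified — to a BAM target, with the
input header plus an appended ``@PG`` line recording the query.  Counts of
accepted and rejected reads are returned for every run.

Index use: when the input has a BAI/CSI index and the query's plan
restricts matches to a reference subset (with no unmapped component), the
engine iterates just those references through the index.  Otherwise it
scans sequentially, still skipping evaluation of records the plan rules
out.  Both traversals produce identical outputs by construction.
"""

from __future__ import annotations

import logging
import secrets
from dataclasses import dataclass
from typing import Iterator, List, Optional, Tuple, Union

import pysam

from . import __version__, ast
from .chrom_names import ChromAliasTable, default_alias_table
from .index_planner import ALL_READS, RegionPlan, infer_plan
from .parser import parse_query
from .read_model import FilterStats, MalformedRecord, view_from_record
from .semantics import EvalContext, compile_query

__all__ = ["ChainStage", "ChainSpec", "run_query", "run_chain",
           "collect_accepted", "record_key"]

logger = logging.getLogger("bamql")

QueryLike = Union[str, ast.QueryNode]


def _as_node(query: QueryLike) -> ast.QueryNode:
    return parse_query(query) if isinstance(query, str) else query


def record_key(rec: pysam.AlignedSegment) -> Tuple[str, int, int, int]:
    """Stable identity of one record within a file."""
    return (rec.query_name or "", rec.flag, rec.reference_id,
            rec.reference_start)


@dataclass(frozen=True)
class ChainStage:
    query: ast.QueryNode
    output: Optional[str]  # None: count matches but write nowhere


@dataclass
class ChainSpec:
    """Ordered filter stages; each record goes to the first stage it satisfies."""

    stages: List[ChainStage]
    leftover: Optional[str] = None  # target for reads matching no stage

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("a chain needs at least one stage")
        targets = [s.output for s in self.stages if s.output is not None]
        if self.leftover is not None:
            targets.append(self.leftover)
        if len(targets) != len(set(targets)):
            raise ValueError("chain output targets must be pairwise distinct")


def _open_input(path: str) -> pysam.AlignmentFile:
    if path == "-":
        path = "/dev/stdin"
    return pysam.AlignmentFile(path, require_index=False)


def _pg_header(af: pysam.AlignmentFile, query_text: str) -> dict:
    header = af.header.to_dict()
    pg = header.setdefault("PG", [])
    used = {entry.get("ID") for entry in pg}
    pg_id = "bamql"
    n = 1
    while pg_id in used:
        n += 1
        pg_id = f"bamql.{n}"
    entry = {"ID": pg_id, "PN": "bamql", "VN": __version__, "CL": query_text}
    if pg:
        last = pg[-1].get("ID")
        if last:
            entry["PP"] = last
    pg.append(entry)
    return header


def _open_output(path: str, af: pysam.AlignmentFile,
                 query_text: str) -> pysam.AlignmentFile:
    if path == "-":
        path = "/dev/stdout"
    return pysam.AlignmentFile(path, "wb",
                               header=_pg_header(af, query_text))


def _resolve_seed(seed: Optional[int]) -> int:
    if seed is None:
        seed = secrets.randbelow(2 ** 31)
        logger.info("no seed given; using entropy seed %d", seed)
    return seed


def _has_index(af: pysam.AlignmentFile) -> bool:
    try:
        return af.has_index()
    except (AttributeError, ValueError):
        return False


def _index_total(af: pysam.AlignmentFile) -> int:
    """Total records in the file, from the index alone."""
    per_ref = sum(s.total for s in af.get_index_statistics())
    return per_ref + af.nocoordinate


def _scan(af: pysam.AlignmentFile, plan: RegionPlan, use_index: bool,
          need_out_of_scope: bool) -> Iterator[Tuple[pysam.AlignedSegment, bool]]:
    """Yield (record, in_scope) pairs in input order.

    The indexed fast path visits only the plan's references and therefore
    never yields out-of-scope records; callers that need them (to write a
    rejects file or a chain leftover) set ``need_out_of_scope``, forcing
    the sequential path.  Restricting to the plan's references preserves
    input order because the input is coordinate sorted.
    """
    indexed_ok = (use_index and not plan.all_reads
                  and not plan.include_unplaced
                  and not need_out_of_scope and _has_index(af))
    if indexed_ok:
        for name in af.references:  # header order == file order when sorted
            if name in plan.references:
                for rec in af.fetch(contig=name):
                    yield rec, True
        return
    for rec in af.fetch(until_eof=True):
        if use_index and not plan.all_reads:
            name = (af.get_reference_name(rec.reference_id)
                    if rec.reference_id >= 0 else None)
            yield rec, plan.covers(name, bool(rec.flag & 0x4))
        else:
            yield rec, True


def run_query(input_path: str,
              query: QueryLike,
              accept_out: Optional[str] = None,
              reject_out: Optional[str] = None,
              seed: Optional[int] = None,
              use_index: bool = True,
              skip_malformed: bool = False,
              alias_table: Optional[ChromAliasTable] = None,
              ) -> FilterStats:
    """Filter one BAM/SAM source through one query.

    Every in-scope record is evaluated exactly once; accepted records are
    written to ``accept_out`` (if given) in input order, rejected ones to
    ``reject_out`` (if given).  Records the region plan rules out are
    counted as rejected without evaluation.  Returns the accepted/rejected
    totals; their sum is the number of records in the file.
    """
    node = _as_node(query)
    seed = _resolve_seed(seed)
    table = alias_table or default_alias_table()
    query_text = ast.render(node)
    stats = FilterStats(label=query_text)

    with _open_input(input_path) as af:
        header_names = list(af.references)
        ctx = EvalContext(seed=seed, alias_table=table,
                          header_names=header_names)
        predicate = compile_query(node, ctx)
        plan = infer_plan(node, header_names, table) if use_index else ALL_READS

        out = rej = None
        try:
            if accept_out is not None:
                out = _open_output(accept_out, af, query_text)
            if reject_out is not None:
                rej = _open_output(reject_out, af, query_text)
            indexed_fast = (use_index and not plan.all_reads
                            and not plan.include_unplaced
                            and reject_out is None and _has_index(af))
            for rec, in_scope in _scan(af, plan, use_index,
                                       need_out_of_scope=rej is not None):
                if in_scope and _accepts(predicate, rec, skip_malformed):
                    stats.accepted += 1
                    if out is not None:
                        out.write(rec)
                else:
                    stats.rejected += 1
                    if rej is not None:
                        rej.write(rec)
            if indexed_fast:
                # records the index skipped entirely count as rejected
                stats.rejected += _index_total(af) - stats.total
        finally:
            if out is not None:
                out.close()
            if rej is not None:
                rej.close()
    return stats


def _accepts(predicate, rec: pysam.AlignedSegment,
             skip_malformed: bool) -> bool:
    try:
        view = view_from_record(rec)
    except MalformedRecord as exc:
        if skip_malformed:
            logger.warning("skipping malformed record: %s", exc)
            return False
        raise
    return predicate(view)


def run_chain(input_path: str,
              chain: ChainSpec,
              seed: Optional[int] = None,
              use_index: bool = True,
              skip_malformed: bool = False,
              independent: bool = False,
              alias_table: Optional[ChromAliasTable] = None,
              ) -> List[FilterStats]:
    """Route reads through an ordered chain of filters.

    Default (exclusive) routing writes each record to the FIRST stage it
    satisfies and withholds it from later stages, so stage outputs are
    pairwise disjoint and their union is the accept set of the OR of all
    stage queries.  With ``independent=True`` every stage sees every
    record, as if the stages ran as separate filters.

    Returns one :class:`FilterStats` per stage: ``accepted`` counts the
    records the stage claimed, ``rejected`` the records offered to it but
    not claimed (so, under exclusive routing, the last stage's ``rejected``
    is the number of reads matching no stage).  Reads matching no stage go
    to ``chain.leftover`` when set, else are dropped.
    """
    seed = _resolve_seed(seed)
    table = alias_table or default_alias_table()
    nodes = [s.query for s in chain.stages]
    texts = [ast.render(n) for n in nodes]
    per_stage = [FilterStats(label=t) for t in texts]

    with _open_input(input_path) as af:
        header_names = list(af.references)
        ctx = EvalContext(seed=seed, alias_table=table,
                          header_names=header_names)
        predicates = [compile_query(n, ctx) for n in nodes]
        if use_index:
            plan = RegionPlan(False)
            for n in nodes:
                plan = plan.union(infer_plan(n, header_names, table))
        else:
            plan = ALL_READS

        outs: List[Optional[pysam.AlignmentFile]] = []
        left = None
        try:
            for stage, text in zip(chain.stages, texts):
                outs.append(None if stage.output is None
                            else _open_output(stage.output, af, text))
            if chain.leftover is not None:
                left = _open_output(chain.leftover, af,
                                    "leftover: " + " | ".join(texts))
            need_all = left is not None
            indexed_fast = (use_index and not plan.all_reads
                            and not plan.include_unplaced
                            and not need_all and _has_index(af))
            evaluated = 0
            for rec, in_scope in _scan(af, plan, use_index, need_all):
                evaluated += 1
                claimed = False
                view = None
                if in_scope:
                    try:
                        view = view_from_record(rec)
                    except MalformedRecord as exc:
                        if not skip_malformed:
                            raise
                        logger.warning("skipping malformed record: %s", exc)
                for i, predicate in enumerate(predicates):
                    if claimed and not independent:
                        continue
                    if view is not None and predicate(view):
                        per_stage[i].accepted += 1
                        if outs[i] is not None:
                            outs[i].write(rec)
                        claimed = True
                    else:
                        per_stage[i].rejected += 1
                if not claimed and left is not None:
                    left.write(rec)
            if indexed_fast:
                skipped = _index_total(af) - evaluated
                for st in per_stage:
                    st.rejected += skipped
        finally:
            for o in outs:
                if o is not None:
                    o.close()
            if left is not None:
                left.close()
    return per_stage


def collect_accepted(input_path: str,
                     query: QueryLike,
                     seed: Optional[int] = None,
                     use_index: bool = True,
                     alias_table: Optional[ChromAliasTable] = None,
                     ) -> Tuple[FilterStats, List[Tuple[str, int, int, int]]]:
    """Like :func:`run_query` with no outputs, returning accepted record keys.

    Convenience for equivalence testing and ad hoc counting.
    """
    node = _as_node(query)
    seed = _resolve_seed(seed)
    table = alias_table or default_alias_table()
    stats = FilterStats(label=ast.render(node))
    keys: List[Tuple[str, int, int, int]] = []

    with _open_input(input_path) as af:
        header_names = list(af.references)
        ctx = EvalContext(seed=seed, alias_table=table,
                          header_names=header_names)
        predicate = compile_query(node, ctx)
        plan = infer_plan(node, header_names, table) if use_index else ALL_READS
        indexed_fast = (use_index and not plan.all_reads
                        and not plan.include_unplaced and _has_index(af))
        for rec, in_scope in _scan(af, plan, use_index, False):
            if in_scope and predicate(view_from_record(rec)):
                stats.accepted += 1
                keys.append(record_key(rec))
            else:
                stats.rejected += 1
        if indexed_fast:
            stats.rejected += _index_total(af) - stats.total
    return stats, keys
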