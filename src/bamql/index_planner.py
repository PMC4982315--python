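"""Static over-approximation of where a query's matches can live.

Given a query AST and the reference names of the open file, infer a
:class:`RegionPlan`: either "scan everything" or a restriction to a subset
of references (plus, possibly, records stored without coordinates).  The
plan lets the engine drive BAI/CSI region iteration instead of a full
scan, with the hard guarantee — exercised by the identity tests — that a
planned traversal accepts exactly the same reads as a sequential one.

The analysis is deliberately conservative: only ``chr()`` restricts to
references and only ``unmapped?`` restricts to coordinate-less records;
everything else (including ``mate_chr``, whose matches can sit on any
chromosome) widens to all reads, and negation discards any restriction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Optional

from . import ast
from .chrom_names import ChromAliasTable, candidate_references, \
    default_alias_table

__all__ = ["RegionPlan", "ALL_READS", "infer_plan"]


@dataclass(frozen=True)
class RegionPlan:
    """Where matching reads can be located.

    ``all_reads`` makes the other fields irrelevant.  Otherwise matches
    are confined to ``references`` plus — when ``include_unplaced`` — any
    record flagged unmapped (wherever stored) and any record without a
    coordinate.
    """

    all_reads: bool
    references: FrozenSet[str] = frozenset()
    include_unplaced: bool = False

    def union(self, other: "RegionPlan") -> "RegionPlan":
        if self.all_reads or other.all_reads:
            return ALL_READS
        return RegionPlan(False, self.references | other.references,
                          self.include_unplaced or other.include_unplaced)

    def intersect(self, other: "RegionPlan") -> "RegionPlan":
        if self.all_reads:
            return other
        if other.all_reads:
            return self
        return RegionPlan(False, self.references & other.references,
                          self.include_unplaced and other.include_unplaced)

    def covers(self, ref_name: Optional[str], is_unmapped: bool) -> bool:
        """Scope membership of one record (by placement and unmapped bit)."""
        if self.all_reads:
            return True
        if self.include_unplaced and (is_unmapped or ref_name is None):
            return True
        return ref_name is not None and ref_name in self.references


ALL_READS = RegionPlan(all_reads=True)


def infer_plan(node: ast.QueryNode, header_names: List[str],
               table: ChromAliasTable | None = None) -> RegionPlan:
    """Infer a sound region plan for ``node`` over the given header.

    Soundness: every read satisfying the query is covered by the plan.
    ``AllReads`` is always a valid answer; restrictions only ever come
    from ``chr()`` (reference subset) and ``unmapped?`` (coordinate-less
    records), combined through the connectives — intersection for ``&``,
    union for ``|``/``^``, and the two-branch union for conditionals.
    """
    table = table or default_alias_table()

    def go(n: ast.QueryNode) -> RegionPlan:
        if isinstance(n, ast.Chr):
            return RegionPlan(
                False,
                frozenset(candidate_references(n.glob, header_names, table)),
                include_unplaced=False)
        if isinstance(n, ast.FlagPred) and n.kind == "unmapped":
            return RegionPlan(False, frozenset(), include_unplaced=True)
        if isinstance(n, ast.And):
            return go(n.left).intersect(go(n.right))
        if isinstance(n, (ast.Or, ast.Xor)):
            return go(n.left).union(go(n.right))
        if isinstance(n, ast.Conditional):
            return go(ast.And(n.cond, n.then_expr)).union(
                go(ast.And(ast.Not(n.cond), n.else_expr)))
        return ALL_READS

    return go(node)
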