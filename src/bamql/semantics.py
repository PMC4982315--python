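"""Meaning of every query predicate, plus AST-to-closure compilation.

:func:`eval_node` is the direct recursive interpreter; :func:`compile_query`
builds a nest of Python closures so that node dispatch happens once per
query instead of once per read.  The two are interchangeable and tested
against each other.

``random(p)``
    Each Random node draws one uniform per read.  The draw is *keyed*, not
    streamed: u is derived by hashing (run seed, read identity, the node's
    static left-to-right ordinal in the tree) with BLAKE2b.  Under a fixed
    seed the outcome for a given read is therefore a pure function of the
    read — independent of traversal order, of whether an index skipped
    other reads, and of short-circuiting — which is what makes indexed and
    sequential runs, and independent re-evaluations, agree bit-for-bit.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Dict, List, Optional

from . import ast
from .chrom_names import ChromAliasTable, chr_glob_match, default_alias_table
from .read_model import ReadView

__all__ = [
    "EvalContext", "IUPAC_MASKS", "EvalError", "error_probability",
    "iupac_compatible", "base_at_reference", "eval_node", "compile_query",
    "keyed_uniform",
]

#: IUPAC letter -> set of concrete bases it denotes.
IUPAC_MASKS: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class EvalError(ValueError):
    """Evaluation failure, annotated with the read name where known."""


@dataclass
class EvalContext:
    """Per-run evaluation state shared by all predicates.

    ``seed`` drives every ``random(p)`` draw; ``None`` means draws use
    seed 0 (the engine substitutes a logged entropy seed before it gets
    here, so ``None`` only arises in direct library use).
    """

    seed: Optional[int] = None
    alias_table: ChromAliasTable = field(default_factory=default_alias_table)
    header_names: List[str] = field(default_factory=list)


def error_probability(mapq: int) -> Optional[float]:
    """Mapping error probability 10^(-mapq/10), or None when unavailable.

    MAPQ 255 is the SAM sentinel for "mapping quality not available"; no
    probability can be derived from it.
    """
    if not 0 <= mapq <= 255:
        raise EvalError(f"MAPQ out of range: {mapq}")
    if mapq == 255:
        return None
    return 10.0 ** (-mapq / 10.0)


def iupac_compatible(read_base: str, query_code: str) -> bool:
    """True iff the two IUPAC codes share at least one concrete base."""
    try:
        a = IUPAC_MASKS[read_base.upper()]
        b = IUPAC_MASKS[query_code.upper()]
    except KeyError as exc:
        raise EvalError(f"not an IUPAC nucleotide letter: {exc.args[0]!r}")
    return bool(a & b)


def base_at_reference(read: ReadView, position: int) -> Optional[str]:
    """Query base aligned opposite 1-based reference ``position``.

    Walks the CIGAR from ``read.start``: M/=/X advance both cursors, I/S
    advance the query, D/N advance the reference, H/P neither.  Returns
    ``None`` when the read does not cover the position or the position
    falls in a deletion or intron skip.
    """
    if read.start is None or read.seq is None:
        return None
    ref = read.start
    q = 0
    for op, ln in read.cigar:
        if op in "M=X":
            if ref <= position < ref + ln:
                return read.seq[q + position - ref]
            ref += ln
            q += ln
        elif op in "IS":
            q += ln
        elif op in "DN":
            if ref <= position < ref + ln:
                return None
            ref += ln
        elif op in "HP":
            pass
        else:
            raise EvalError(f"{read.qname}: unknown CIGAR op {op!r}")
        if ref > position:
            return None
    return None


def keyed_uniform(seed: int, read: ReadView, ordinal: int) -> float:
    """Deterministic uniform in [0,1) for (seed, read, Random-node ordinal)."""
    h = hashlib.blake2b(
        f"{read.qname}\x00{read.flag}\x00{read.ref_name or ''}"
        f"\x00{read.start or 0}\x00{ordinal}".encode(),
        digest_size=8,
        key=seed.to_bytes(8, "little", signed=False),
    )
    return int.from_bytes(h.digest(), "little") / 2.0 ** 64


@lru_cache(maxsize=4096)
def _random_count(node: ast.QueryNode) -> int:
    """Number of Random nodes in the subtree (for static ordinal layout)."""
    return sum(1 for n in ast.walk(node) if isinstance(n, ast.Random))


def _glob_pattern(glob: str) -> re.Pattern:
    out = []
    for ch in glob:
        out.append(".*" if ch == "*" else "." if ch == "?" else re.escape(ch))
    return re.compile("^(?:" + "".join(out) + ")$")


def eval_node(node: ast.QueryNode, read: ReadView, ctx: EvalContext,
              _ordinal: int = 0) -> bool:
    """Evaluate ``node`` on one read.

    ``_ordinal`` is the static index of the first Random node inside this
    subtree; callers never pass it.
    """
    if isinstance(node, ast.TrueLit):
        return True
    if isinstance(node, ast.FalseLit):
        return False
    if isinstance(node, ast.Not):
        return not eval_node(node.operand, read, ctx, _ordinal)
    if isinstance(node, ast.And):
        return (eval_node(node.left, read, ctx, _ordinal)
                and eval_node(node.right, read, ctx,
                              _ordinal + _random_count(node.left)))
    if isinstance(node, ast.Or):
        return (eval_node(node.left, read, ctx, _ordinal)
                or eval_node(node.right, read, ctx,
                             _ordinal + _random_count(node.left)))
    if isinstance(node, ast.Xor):
        return (eval_node(node.left, read, ctx, _ordinal)
                != eval_node(node.right, read, ctx,
                             _ordinal + _random_count(node.left)))
    if isinstance(node, ast.Conditional):
        o_then = _ordinal + _random_count(node.cond)
        o_else = o_then + _random_count(node.then_expr)
        if eval_node(node.cond, read, ctx, _ordinal):
            return eval_node(node.then_expr, read, ctx, o_then)
        return eval_node(node.else_expr, read, ctx, o_else)
    if isinstance(node, ast.FlagPred):
        return bool(read.flag & node.bit)
    if isinstance(node, ast.RawFlag):
        return (read.flag & node.mask) == node.mask
    if isinstance(node, ast.Chr):
        return (not read.is_unmapped and read.ref_name is not None
                and chr_glob_match(node.glob, read.ref_name, ctx.alias_table))
    if isinstance(node, ast.MateChr):
        return (not read.is_mate_unmapped
                and read.mate_ref_name is not None
                and chr_glob_match(node.glob, read.mate_ref_name,
                                   ctx.alias_table))
    if isinstance(node, ast.SplitPair):
        return (not read.is_unmapped
                and not read.is_mate_unmapped
                and read.ref_name is not None
                and read.mate_ref_name is not None
                and read.ref_name != read.mate_ref_name)
    if isinstance(node, ast.MappingQuality):
        p = error_probability(read.mapq)
        return p is not None and p < node.max_error_prob
    if isinstance(node, ast.After):
        return read.end is not None and read.end >= node.position
    if isinstance(node, ast.Before):
        return read.start is not None and read.start <= node.position
    if isinstance(node, ast.PositionRange):
        return (read.start is not None and read.end is not None
                and read.start <= node.end and read.end >= node.start)
    if isinstance(node, ast.Nt):
        base = base_at_reference(read, node.position)
        return base is not None and iupac_compatible(base, node.code)
    if isinstance(node, ast.NtExact):
        base = base_at_reference(read, node.position)
        return base is not None and base.upper() == node.code.upper()
    if isinstance(node, ast.ReadGroup):
        return (read.read_group is not None
                and _glob_pattern(node.glob).match(read.read_group) is not None)
    if isinstance(node, ast.HeaderRegex):
        return re.search(node.pattern, read.qname) is not None
    if isinstance(node, ast.Random):
        seed = ctx.seed if ctx.seed is not None else 0
        return keyed_uniform(seed, read, _ordinal) < node.p
    raise TypeError(f"not a QueryNode: {node!r}")


Predicate = Callable[[ReadView], bool]


def compile_query(node: ast.QueryNode, ctx: EvalContext) -> Predicate:
    """Compile an AST into a per-read predicate closure.

    The returned function agrees with :func:`eval_node` on every read;
    tree dispatch, glob/regex compilation and Random-ordinal layout are
    all resolved once here instead of per read.
    """
    return _compile(node, ctx, 0)


def _compile(node: ast.QueryNode, ctx: EvalContext, ordinal: int) -> Predicate:
    if isinstance(node, ast.TrueLit):
        return lambda read: True
    if isinstance(node, ast.FalseLit):
        return lambda read: False
    if isinstance(node, ast.Not):
        f = _compile(node.operand, ctx, ordinal)
        return lambda read: not f(read)
    if isinstance(node, (ast.And, ast.Or, ast.Xor)):
        left = _compile(node.left, ctx, ordinal)
        right = _compile(node.right, ctx, ordinal + _random_count(node.left))
        if isinstance(node, ast.And):
            return lambda read: left(read) and right(read)
        if isinstance(node, ast.Or):
            return lambda read: left(read) or right(read)
        return lambda read: left(read) != right(read)
    if isinstance(node, ast.Conditional):
        cond = _compile(node.cond, ctx, ordinal)
        o_then = ordinal + _random_count(node.cond)
        then_f = _compile(node.then_expr, ctx, o_then)
        else_f = _compile(node.else_expr, ctx,
                          o_then + _random_count(node.then_expr))
        return lambda read: then_f(read) if cond(read) else else_f(read)
    if isinstance(node, ast.FlagPred):
        bit = node.bit
        return lambda read: bool(read.flag & bit)
    if isinstance(node, ast.RawFlag):
        mask = node.mask
        return lambda read: (read.flag & mask) == mask
    if isinstance(node, ast.Chr):
        matching = frozenset(
            n for n in ctx.header_names
            if chr_glob_match(node.glob, n, ctx.alias_table))
        header_set = frozenset(ctx.header_names)
        glob, table = node.glob, ctx.alias_table
        return lambda read: (not read.is_unmapped
                             and read.ref_name is not None
                             and (read.ref_name in matching
                                  or (read.ref_name not in header_set
                                      and chr_glob_match(glob, read.ref_name,
                                                         table))))
    if isinstance(node, ast.MateChr):
        glob, table = node.glob, ctx.alias_table
        return lambda read: (not read.is_mate_unmapped
                             and read.mate_ref_name is not None
                             and chr_glob_match(glob, read.mate_ref_name,
                                                table))
    if isinstance(node, ast.SplitPair):
        return lambda read: (not read.is_unmapped
                             and not read.is_mate_unmapped
                             and read.ref_name is not None
                             and read.mate_ref_name is not None
                             and read.ref_name != read.mate_ref_name)
    if isinstance(node, ast.MappingQuality):
        threshold = node.max_error_prob
        def mq(read: ReadView) -> bool:
            p = error_probability(read.mapq)
            return p is not None and p < threshold
        return mq
    if isinstance(node, ast.After):
        pos = node.position
        return lambda read: read.end is not None and read.end >= pos
    if isinstance(node, ast.Before):
        pos = node.position
        return lambda read: read.start is not None and read.start <= pos
    if isinstance(node, ast.PositionRange):
        start, end = node.start, node.end
        return lambda read: (read.start is not None and read.end is not None
                             and read.start <= end and read.end >= start)
    if isinstance(node, ast.Nt):
        pos, mask = node.position, IUPAC_MASKS[node.code.upper()]
        def nt(read: ReadView) -> bool:
            base = base_at_reference(read, pos)
            if base is None:
                return False
            read_mask = IUPAC_MASKS.get(base.upper())
            if read_mask is None:
                raise EvalError(
                    f"{read.qname}: not an IUPAC nucleotide letter: {base!r}")
            return bool(read_mask & mask)
        return nt
    if isinstance(node, ast.NtExact):
        pos, code = node.position, node.code.upper()
        def nt_exact(read: ReadView) -> bool:
            base = base_at_reference(read, pos)
            return base is not None and base.upper() == code
        return nt_exact
    if isinstance(node, ast.ReadGroup):
        pattern = _glob_pattern(node.glob)
        return lambda read: (read.read_group is not None
                             and pattern.match(read.read_group) is not None)
    if isinstance(node, ast.HeaderRegex):
        rx = re.compile(node.pattern)
        return lambda read: rx.search(read.qname) is not None
    if isinstance(node, ast.Random):
        seed = ctx.seed if ctx.seed is not None else 0
        p, o = node.p, ordinal
        return lambda read: keyed_uniform(seed, read, o) < p
    raise TypeError(f"not a QueryNode: {node!r}")
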