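"""Query abstract syntax tree.

A query is a finite tree of logical connectives over predicate leaves.
Nodes are immutable dataclasses, so structural equality and hashing come
for free; the parser builds these trees and :func:`render` serializes them
back to concrete syntax.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

__all__ = [
    "QueryNode", "Not", "And", "Or", "Xor", "Conditional", "TrueLit",
    "FalseLit", "FlagPred", "RawFlag", "Chr", "MateChr", "SplitPair",
    "MappingQuality", "After", "Before", "PositionRange", "Nt", "NtExact",
    "ReadGroup", "HeaderRegex", "Random", "FLAG_BITS", "IUPAC_LETTERS",
    "render", "walk",
]

#: SAM FLAG bit for each named flag predicate.
FLAG_BITS = {
    "paired": 0x1,
    "proper_pair": 0x2,
    "unmapped": 0x4,
    "mate_unmapped": 0x8,
    "mapped_to_reverse": 0x10,
    "mate_mapped_to_reverse": 0x20,
    "read1": 0x40,
    "read2": 0x80,
    "secondary": 0x100,
    "failed_qc": 0x200,
    "duplicate": 0x400,
    "supplementary": 0x800,
}

#: The IUPAC nucleotide alphabet accepted by nt()/nt_exact().
IUPAC_LETTERS = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class TrueLit:
    """``true`` — always satisfied."""


@dataclass(frozen=True)
class FalseLit:
    """``false`` — never satisfied."""


@dataclass(frozen=True)
class Not:
    operand: "QueryNode"


@dataclass(frozen=True)
class And:
    left: "QueryNode"
    right: "QueryNode"


@dataclass(frozen=True)
class Or:
    left: "QueryNode"
    right: "QueryNode"


@dataclass(frozen=True)
class Xor:
    left: "QueryNode"
    right: "QueryNode"


@dataclass(frozen=True)
class Conditional:
    """``cond then then_expr else else_expr``."""

    cond: "QueryNode"
    then_expr: "QueryNode"
    else_expr: "QueryNode"


@dataclass(frozen=True)
class FlagPred:
    """A named SAM FLAG bit test such as ``paired?`` or ``duplicate?``."""

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in FLAG_BITS:
            raise ValueError(f"unknown flag predicate: {self.kind!r}")

    @property
    def bit(self) -> int:
        return FLAG_BITS[self.kind]


@dataclass(frozen=True)
class RawFlag:
    """``raw_flag(int)`` — all bits of ``mask`` are set in the read's FLAG."""

    mask: int

    def __post_init__(self) -> None:
        if not 0 <= self.mask < 1 << 16:
            raise ValueError(f"raw_flag mask must fit in 16 bits: {self.mask}")


@dataclass(frozen=True)
class Chr:
    """``chr(glob)`` — the read is mapped to a matching chromosome."""

    glob: str


@dataclass(frozen=True)
class MateChr:
    """``mate_chr(glob)`` — the mate is mapped to a matching chromosome."""

    glob: str


@dataclass(frozen=True)
class SplitPair:
    """``split_pair?`` — read and mate mapped, to different references."""


@dataclass(frozen=True)
class MappingQuality:
    """``mapping_quality(p)`` — mapping error probability strictly below p."""

    max_error_prob: float

    def __post_init__(self) -> None:
        if not 0.0 < self.max_error_prob <= 1.0:
            raise ValueError(
                f"mapping_quality probability must be in (0,1]: "
                f"{self.max_error_prob}")


@dataclass(frozen=True)
class After:
    """``after(pos)`` — alignment covers pos or any higher position."""

    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based and must be >= 1")


@dataclass(frozen=True)
class Before:
    """``before(pos)`` — alignment covers pos or any lower position."""

    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based and must be >= 1")


@dataclass(frozen=True)
class PositionRange:
    """``position(start, end)`` — alignment overlaps [start, end]."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if self.start > self.end:
            raise ValueError(
                f"position range start must not exceed end: "
                f"{self.start} > {self.end}")


def _check_iupac(code: str) -> None:
    if code.upper() not in IUPAC_LETTERS:
        raise ValueError(f"not an IUPAC nucleotide letter: {code!r}")


@dataclass(frozen=True)
class Nt:
    """``nt(pos, n)`` — base at reference pos is IUPAC-compatible with n."""

    position: int
    code: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        _check_iupac(self.code)


@dataclass(frozen=True)
class NtExact:
    """``nt_exact(pos, n)`` — base at reference pos equals n letter-for-letter."""

    position: int
    code: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        _check_iupac(self.code)


@dataclass(frozen=True)
class ReadGroup:
    """``read_group(glob)`` — the read's RG tag matches the glob."""

    glob: str


@dataclass(frozen=True)
class HeaderRegex:
    """``header ~ /regex/`` — unanchored regex search over the read name."""

    pattern: str


@dataclass(frozen=True)
class Random:
    """``random(p)`` — satisfied with probability p, deterministic under seed."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"random probability must be in [0,1]: {self.p}")


QueryNode = Union[
    TrueLit, FalseLit, Not, And, Or, Xor, Conditional, FlagPred, RawFlag,
    Chr, MateChr, SplitPair, MappingQuality, After, Before, PositionRange,
    Nt, NtExact, ReadGroup, HeaderRegex, Random,
]


def _num(x: float) -> str:
    # repr round-trips floats exactly; integers print without the trailing .0
    return repr(x)


def render(node: QueryNode) -> str:
    """Serialize ``node`` to concrete query syntax.

    Every binary connective and conditional is wrapped in explicit
    parentheses, so the output parses back to a structurally identical tree
    regardless of operator precedence.  Equal trees render to equal strings.
    """
    if isinstance(node, TrueLit):
        return "true"
    if isinstance(node, FalseLit):
        return "false"
    if isinstance(node, Not):
        return f"!({render(node.operand)})"
    if isinstance(node, And):
        return f"({render(node.left)} & {render(node.right)})"
    if isinstance(node, Or):
        return f"({render(node.left)} | {render(node.right)})"
    if isinstance(node, Xor):
        return f"({render(node.left)} ^ {render(node.right)})"
    if isinstance(node, Conditional):
        return (f"({render(node.cond)} then {render(node.then_expr)}"
                f" else {render(node.else_expr)})")
    if isinstance(node, FlagPred):
        return f"{node.kind}?"
    if isinstance(node, RawFlag):
        return f"raw_flag({node.mask})"
    if isinstance(node, Chr):
        return f"chr({node.glob})"
    if isinstance(node, MateChr):
        return f"mate_chr({node.glob})"
    if isinstance(node, SplitPair):
        return "split_pair?"
    if isinstance(node, MappingQuality):
        return f"mapping_quality({_num(node.max_error_prob)})"
    if isinstance(node, After):
        return f"after({node.position})"
    if isinstance(node, Before):
        return f"before({node.position})"
    if isinstance(node, PositionRange):
        return f"position({node.start}, {node.end})"
    if isinstance(node, Nt):
        return f"nt({node.position}, {node.code})"
    if isinstance(node, NtExact):
        return f"nt_exact({node.position}, {node.code})"
    if isinstance(node, ReadGroup):
        return f"read_group({node.glob})"
    if isinstance(node, HeaderRegex):
        return f"header ~ /{node.pattern}/"
    if isinstance(node, Random):
        return f"random({_num(node.p)})"
    raise TypeError(f"not a QueryNode: {node!r}")


def walk(node: QueryNode):
    """Yield ``node`` and all descendants in left-to-right preorder."""
    yield node
    if isinstance(node, Not):
        yield from walk(node.operand)
    elif isinstance(node, (And, Or, Xor)):
        yield from walk(node.left)
        yield from walk(node.right)
    elif isinstance(node, Conditional):
        yield from walk(node.cond)
        yield from walk(node.then_expr)
        yield from walk(node.else_expr)
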