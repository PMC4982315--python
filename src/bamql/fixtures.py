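"""Deterministic synthetic-BAM generation and a naive reference filter.

Every other module is tested against files produced here, so no external
data is ever needed.  :func:`generate_bam` writes a coordinate-sorted,
indexed BAM realizing a :class:`SyntheticSpec` — mixed chromosome-name
spellings, paired and unpaired reads, unmapped reads with and without a
placement coordinate, cross-chromosome mates, a MAPQ distribution that
includes the 255 sentinel, CIGARs exercising I/D/N/S/H ops, read groups,
and occasional IUPAC ambiguity bases — together with a per-read
:class:`TruthTable` of every attribute the generator chose.

:func:`oracle_filter` is a deliberately naive, unoptimized evaluator of
query semantics written directly against pysam record attributes (using
``get_aligned_pairs`` for the sequence predicates rather than this
package's own CIGAR walk).  It shares no evaluation code with the engine
and serves as the ground truth in every equivalence test.

The generator emulates the *shape* of real short-read data (flags,
coordinates, CIGAR structure) but not realistic error models, base
qualities, insert-size distributions or actual mate records; see the
methods note for what that does and does not validate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import random
import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

import pysam

from . import ast

__all__ = ["SyntheticSpec", "TruthRow", "TruthTable", "generate_bam",
           "oracle_filter", "random_query", "DEFAULT_CONTIGS",
           "MIXED_SPELLING_CONTIGS"]

#: Default contig set: mixed spellings of human-style names.
DEFAULT_CONTIGS: Tuple[Tuple[str, int], ...] = (
    ("chr1", 20000), ("2", 20000), ("chr3", 20000),
    ("chrY", 20000), ("24", 20000), ("MT", 20000),
)

#: Alias for the contig spelling mix used in the desk-scale tests.
MIXED_SPELLING_CONTIGS = DEFAULT_CONTIGS

_READ_GROUPS = ("lane1", "lane2", "batchA")

# CIGAR templates as (ops, total query length); rendered per read
_CIGAR_TEMPLATES = (
    "50M",
    "10M2I38M",
    "20M5D30M",
    "10M100N40M",
    "5S40M5S",
    "25M1D24M",
    "3H44M3H",
    "48M2S",
)

_BASES = "ACGT"
_AMBIG = "RYN"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic file.

    Fractions are probabilities per generated read; ``unmapped_placed_frac``
    is the fraction *of unmapped reads* that carry their mate's coordinate
    (and so sit inside a contig region of the sorted file).
    """

    contigs: Tuple[Tuple[str, int], ...] = DEFAULT_CONTIGS
    n_reads: int = 1000
    paired_frac: float = 0.6
    unmapped_frac: float = 0.1
    unmapped_placed_frac: float = 0.5
    cross_chrom_mate_frac: float = 0.1
    ambiguity_base_rate: float = 0.02
    read_groups: Tuple[str, ...] = _READ_GROUPS
    missing_rg_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("paired_frac", "unmapped_frac", "unmapped_placed_frac",
                     "cross_chrom_mate_frac", "ambiguity_base_rate",
                     "missing_rg_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]: {v}")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if not self.contigs and self.n_reads:
            raise ValueError("cannot place reads without contigs")
        max_span = 200  # longest CIGAR template reference span
        for name, length in self.contigs:
            if length <= max_span:
                raise ValueError(
                    f"contig {name!r} shorter than the maximum read span")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one generated record."""

    qname: str
    flag: int
    contig: Optional[str]        # raw spelling, None if unplaced
    pos: Optional[int]           # 1-based leftmost, None if unplaced
    end: Optional[int]           # 1-based rightmost (mapped reads only)
    mapq: int
    cigar: Optional[str]
    seq: str
    read_group: Optional[str]
    mate_contig: Optional[str]
    mate_pos: Optional[int]


TruthTable = List[TruthRow]


def _parse_cigar(text: str) -> List[Tuple[str, int]]:
    return [(m.group(2), int(m.group(1)))
            for m in re.finditer(r"(\d+)([MIDNSHP=X])", text)]


def _query_len(ops: List[Tuple[str, int]]) -> int:
    return sum(ln for op, ln in ops if op in "MIS=X")


def _ref_len(ops: List[Tuple[str, int]]) -> int:
    return sum(ln for op, ln in ops if op in "MDN=X")


def generate_bam(spec: SyntheticSpec, path: str,
                 truth_path: Optional[str] = None,
                 ) -> TruthTable:
    """Write a coordinate-sorted, indexed BAM realizing ``spec``.

    Identical spec (including seed) produces a byte-identical file.  The
    returned truth table has one row per record, in file order, agreeing
    exactly with the emitted records; with ``truth_path`` it is also
    written as TSV.
    """
    rng = random.Random(spec.seed)
    names = [n for n, _ in spec.contigs]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in spec.contigs],
        "RG": [{"ID": rg, "SM": "synthetic"} for rg in spec.read_groups],
    }

    drafts = []  # (sort key, record fields dict)
    for i in range(spec.n_reads):
        qname = f"read{i:06d}"
        flag = 0
        paired = rng.random() < spec.paired_frac
        if paired:
            flag |= 0x1
            flag |= 0x40 if rng.random() < 0.5 else 0x80
        unmapped = rng.random() < spec.unmapped_frac

        tid = rng.randrange(len(names))
        pos0 = rng.randrange(0, spec.contigs[tid][1] - 300)
        cigar_text: Optional[str] = rng.choice(_CIGAR_TEMPLATES)
        ops = _parse_cigar(cigar_text)
        seq_len = _query_len(ops)
        seq = "".join(
            rng.choice(_AMBIG) if rng.random() < spec.ambiguity_base_rate
            else rng.choice(_BASES)
            for _ in range(seq_len))
        mapq = rng.choice((0, 1, 10, 20, 30, 37, 60, 255))

        mate_tid = -1
        mate_pos0 = -1
        if paired:
            mate_unmapped = rng.random() < spec.unmapped_frac
            if mate_unmapped:
                flag |= 0x8
                if not unmapped:
                    mate_tid, mate_pos0 = tid, pos0  # placed with the pair
            else:
                if rng.random() < spec.cross_chrom_mate_frac:
                    mate_tid = rng.randrange(len(names))
                else:
                    mate_tid = tid
                mate_pos0 = rng.randrange(0, spec.contigs[mate_tid][1] - 300)
                if rng.random() < 0.5:
                    flag |= 0x20

        if unmapped:
            flag |= 0x4
            cigar_text = None
            mapq = 0
            placed = (paired and mate_tid >= 0
                      and rng.random() < spec.unmapped_placed_frac)
            if placed:
                tid, pos0 = mate_tid, mate_pos0
            else:
                tid, pos0 = -1, -1
        else:
            if rng.random() < 0.5:
                flag |= 0x10
            if paired and not (flag & 0x8) and mate_tid == tid:
                if rng.random() < 0.8:
                    flag |= 0x2  # proper pair
            r = rng.random()
            if r < 0.05:
                flag |= 0x100
            elif r < 0.08:
                flag |= 0x800
            if rng.random() < 0.05:
                flag |= 0x400
            if rng.random() < 0.03:
                flag |= 0x200

        rg = (None if rng.random() < spec.missing_rg_frac
              else rng.choice(spec.read_groups))

        drafts.append({
            "qname": qname, "flag": flag, "tid": tid, "pos0": pos0,
            "mapq": mapq, "cigar": cigar_text, "seq": seq, "rg": rg,
            "mate_tid": mate_tid, "mate_pos0": mate_pos0,
        })

    # coordinate sort: placed records by (tid, pos), unplaced at the end
    drafts.sort(key=lambda d: ((0, d["tid"], d["pos0"])
                               if d["tid"] >= 0 else (1, 0, 0)))

    truth: TruthTable = []
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for d in drafts:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = d["qname"]
            rec.flag = d["flag"]
            rec.reference_id = d["tid"]
            rec.reference_start = d["pos0"]
            rec.mapping_quality = d["mapq"]
            if d["cigar"]:
                rec.cigarstring = d["cigar"]
            rec.query_sequence = d["seq"]
            rec.next_reference_id = d["mate_tid"]
            rec.next_reference_start = d["mate_pos0"]
            if d["rg"] is not None:
                rec.set_tag("RG", d["rg"], "Z")
            out.write(rec)

            mapped = not d["flag"] & 0x4
            end = None
            if mapped:
                end = d["pos0"] + _ref_len(_parse_cigar(d["cigar"]))
            truth.append(TruthRow(
                qname=d["qname"], flag=d["flag"],
                contig=names[d["tid"]] if d["tid"] >= 0 else None,
                pos=d["pos0"] + 1 if d["tid"] >= 0 else None,
                end=end, mapq=d["mapq"], cigar=d["cigar"], seq=d["seq"],
                read_group=d["rg"],
                mate_contig=names[d["mate_tid"]] if d["mate_tid"] >= 0 else None,
                mate_pos=d["mate_pos0"] + 1 if d["mate_tid"] >= 0 else None,
            ))

    pysam.index(path)
    if truth_path:
        _write_truth(truth, truth_path)
    return truth


def _write_truth(truth: TruthTable, path: str) -> None:
    cols = [f.name for f in dataclasses.fields(TruthRow)]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in truth:
            fh.write("\t".join(
                "." if v is None else str(v)
                for v in dataclasses.astuple(row)) + "\n")


# ---------------------------------------------------------------------------
# Naive reference filter
# ---------------------------------------------------------------------------

_ALIASES = {"23": "X", "24": "Y", "MT": "M", "25": "M"}


def _naive_canonical(name: str) -> str:
    s = name.upper()
    if s.startswith("CHR"):
        s = s[3:]
    return _ALIASES.get(s, s)


def _naive_chr_match(glob: str, name: str) -> bool:
    canonical = _naive_canonical(name)
    spellings = {canonical}
    for alias, canon in _ALIASES.items():
        if canon == canonical:
            spellings.add(alias)
    rx_parts = []
    for g in {glob.upper(), _naive_canonical_glob(glob)}:
        rx_parts.append("".join(
            ".*" if ch == "*" else "." if ch == "?" else re.escape(ch)
            for ch in g))
    rx = re.compile("^(?:" + "|".join(rx_parts) + ")$")
    return any(rx.match(s) for s in spellings)


def _naive_canonical_glob(glob: str) -> str:
    g = glob.upper()
    return g[3:] if g.startswith("CHR") else g


_NAIVE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
    "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _naive_base_at(rec: pysam.AlignedSegment, position: int) -> Optional[str]:
    # independent route: pysam's aligned-pairs machinery, not a CIGAR walk
    if rec.is_unmapped or rec.query_sequence is None:
        return None
    for qpos, rpos in rec.get_aligned_pairs():
        if rpos == position - 1:
            return rec.query_sequence[qpos] if qpos is not None else None
    return None


def _naive_uniform(seed: int, rec: pysam.AlignedSegment, ordinal: int) -> float:
    # mirror of the documented keyed-draw contract: the key is the read's
    # (name, flag, reference name, 1-based alignment start, node ordinal),
    # where unmapped reads contribute no alignment start
    ref = rec.reference_name if rec.reference_id >= 0 else ""
    mapped = not rec.is_unmapped and rec.reference_id >= 0
    start = rec.reference_start + 1 if mapped else 0
    h = hashlib.blake2b(
        f"{rec.query_name}\x00{rec.flag}\x00{ref or ''}"
        f"\x00{start}\x00{ordinal}".encode(),
        digest_size=8, key=seed.to_bytes(8, "little"))
    return int.from_bytes(h.digest(), "little") / 2.0 ** 64


def _naive_eval(node: ast.QueryNode, rec: pysam.AlignedSegment,
                seed: int, ordinal: int) -> bool:
    """Plain recursive evaluation; both operands always evaluated."""
    randoms = lambda n: sum(
        1 for x in ast.walk(n) if isinstance(x, ast.Random))
    if isinstance(node, ast.TrueLit):
        return True
    if isinstance(node, ast.FalseLit):
        return False
    if isinstance(node, ast.Not):
        return not _naive_eval(node.operand, rec, seed, ordinal)
    if isinstance(node, (ast.And, ast.Or, ast.Xor)):
        a = _naive_eval(node.left, rec, seed, ordinal)
        b = _naive_eval(node.right, rec, seed, ordinal + randoms(node.left))
        if isinstance(node, ast.And):
            return a and b
        if isinstance(node, ast.Or):
            return a or b
        return a != b
    if isinstance(node, ast.Conditional):
        c = _naive_eval(node.cond, rec, seed, ordinal)
        o_then = ordinal + randoms(node.cond)
        t = _naive_eval(node.then_expr, rec, seed, o_then)
        e = _naive_eval(node.else_expr, rec, seed,
                        o_then + randoms(node.then_expr))
        return (c and t) or (not c and e)
    if isinstance(node, ast.FlagPred):
        return bool(rec.flag & ast.FLAG_BITS[node.kind])
    if isinstance(node, ast.RawFlag):
        return (rec.flag & node.mask) == node.mask
    if isinstance(node, ast.Chr):
        return (not rec.is_unmapped and rec.reference_id >= 0
                and _naive_chr_match(node.glob, rec.reference_name))
    if isinstance(node, ast.MateChr):
        return (not bool(rec.flag & 0x8) and rec.next_reference_id >= 0
                and _naive_chr_match(node.glob, rec.next_reference_name))
    if isinstance(node, ast.SplitPair):
        return (not rec.is_unmapped and not bool(rec.flag & 0x8)
                and rec.reference_id >= 0 and rec.next_reference_id >= 0
                and rec.reference_id != rec.next_reference_id)
    if isinstance(node, ast.MappingQuality):
        if rec.mapping_quality == 255:
            return False
        return 10.0 ** (-rec.mapping_quality / 10.0) < node.max_error_prob
    if isinstance(node, ast.After):
        return (not rec.is_unmapped and rec.reference_id >= 0
                and rec.reference_end >= node.position)
    if isinstance(node, ast.Before):
        return (not rec.is_unmapped and rec.reference_id >= 0
                and rec.reference_start + 1 <= node.position)
    if isinstance(node, ast.PositionRange):
        return (not rec.is_unmapped and rec.reference_id >= 0
                and rec.reference_start + 1 <= node.end
                and rec.reference_end >= node.start)
    if isinstance(node, ast.Nt):
        base = _naive_base_at(rec, node.position)
        return (base is not None
                and set(_NAIVE_IUPAC[base.upper()])
                & set(_NAIVE_IUPAC[node.code.upper()]) != set())
    if isinstance(node, ast.NtExact):
        base = _naive_base_at(rec, node.position)
        return base is not None and base.upper() == node.code.upper()
    if isinstance(node, ast.ReadGroup):
        if not rec.has_tag("RG"):
            return False
        rx = "".join(".*" if ch == "*" else "." if ch == "?" else re.escape(ch)
                     for ch in node.glob)
        return re.match("^(?:" + rx + ")$", str(rec.get_tag("RG"))) is not None
    if isinstance(node, ast.HeaderRegex):
        return re.search(node.pattern, rec.query_name or "") is not None
    if isinstance(node, ast.Random):
        return _naive_uniform(seed, rec, ordinal) < node.p
    raise TypeError(f"not a QueryNode: {node!r}")


def oracle_filter(records: Sequence[pysam.AlignedSegment],
                  node: ast.QueryNode,
                  seed: int = 0) -> Set[Tuple[str, int, int, int]]:
    """Accept set of ``node`` over ``records``, by naive evaluation.

    No compilation, no index, no short-circuiting.  Returns the set of
    (qname, flag, reference_id, reference_start) record keys accepted.
    """
    accepted = set()
    for rec in records:
        if _naive_eval(node, rec, seed, 0):
            accepted.add((rec.query_name or "", rec.flag,
                          rec.reference_id, rec.reference_start))
    return accepted


# ---------------------------------------------------------------------------
# Random query generation
# ---------------------------------------------------------------------------

def random_query(rng: random.Random,
                 contigs: Sequence[Tuple[str, int]] = DEFAULT_CONTIGS,
                 read_groups: Sequence[str] = _READ_GROUPS,
                 max_depth: int = 5,
                 allow_random: bool = True,
                 restricted_bias: float = 0.0) -> ast.QueryNode:
    """Sample a query AST covering every predicate variant.

    Arguments are drawn from the fixture's contigs, positions and read
    groups so a sampled query has a realistic chance of matching reads.
    With probability ``restricted_bias`` the sampled tree is conjoined
    with a ``chr()`` predicate (or disjoined with ``unmapped?``), so that
    a tunable share of the corpus exercises index-restricted plans.
    """
    max_len = max(ln for _, ln in contigs)

    def leaf() -> ast.QueryNode:
        choices = [
            lambda: ast.TrueLit(),
            lambda: ast.FalseLit(),
            lambda: ast.FlagPred(rng.choice(list(ast.FLAG_BITS))),
            lambda: ast.RawFlag(rng.choice((0x1, 0x4, 0x40, 0x4 | 0x8,
                                            0x1 | 0x2, 77))),
            lambda: ast.Chr(rng.choice(
                [n for n, _ in contigs] + ["*", "1*", "chr?", "Y", "24", "M"])),
            lambda: ast.MateChr(rng.choice(
                [n for n, _ in contigs] + ["*", "2", "MT"])),
            lambda: ast.SplitPair(),
            lambda: ast.MappingQuality(
                rng.choice((0.001, 0.01, 0.05, 0.5, 1.0))),
            lambda: ast.After(rng.randrange(1, max_len)),
            lambda: ast.Before(rng.randrange(1, max_len)),
            lambda: _position_range(),
            lambda: ast.Nt(rng.randrange(1, max_len),
                           rng.choice("ACGTRYN")),
            lambda: ast.NtExact(rng.randrange(1, max_len),
                                rng.choice("ACGTN")),
            lambda: ast.ReadGroup(rng.choice(list(read_groups) + ["*", "lane*"])),
            lambda: ast.HeaderRegex(rng.choice(
                ("^read", "read00", "7$", "read.*1", "42"))),
        ]
        if allow_random:
            choices.append(lambda: ast.Random(
                rng.choice((0.0, 0.1, 0.25, 0.5, 0.9, 1.0))))
        return rng.choice(choices)()

    def _position_range() -> ast.QueryNode:
        a = rng.randrange(1, max_len)
        b = rng.randrange(1, max_len)
        return ast.PositionRange(min(a, b), max(a, b))

    def go(depth: int) -> ast.QueryNode:
        if depth >= max_depth or rng.random() < 0.4:
            return leaf()
        kind = rng.randrange(5)
        if kind == 0:
            return ast.Not(go(depth + 1))
        if kind == 1:
            return ast.And(go(depth + 1), go(depth + 1))
        if kind == 2:
            return ast.Or(go(depth + 1), go(depth + 1))
        if kind == 3:
            return ast.Xor(go(depth + 1), go(depth + 1))
        return ast.Conditional(go(depth + 1), go(depth + 1), go(depth + 1))

    tree = go(0)
    if rng.random() < restricted_bias:
        anchor = ast.Chr(rng.choice(
            [n for n, _ in contigs] + ["1*", "Y", "24", "M", "chr?"]))
        if rng.random() < 0.25:
            tree = ast.Or(ast.And(anchor, tree), ast.FlagPred("unmapped"))
        else:
            tree = ast.And(anchor, tree)
    return tree
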