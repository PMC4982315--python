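"""Chromosome-name normalization and glob matching.

Reference sequence names for the same chromosome vary across pipelines:
the human Y chromosome may be spelled ``Y``, ``chrY``, ``24`` or ``chr24``,
and the mitochondrial genome ``M``, ``MT``, ``25`` or any ``chr``-prefixed
variant, in any case.  Queries should not care.  This module maps raw
header names onto canonical tokens and matches chromosome globs against
the whole alias class, so ``chr(Y)`` selects reads on a contig named
``24`` and vice versa.

The built-in alias table covers the human convention (X=23, Y=24,
M=MT=25).  Autosome aliasing beyond the ``chr`` prefix is not performed;
the X row is included by symmetry with Y.  Other species' conventions can
be supplied as a two-column override file via :func:`load_alias_table`.
"""

from __future__ import annotations

import re
from functools import lru_cache
from typing import Dict, Iterable, List, Set

__all__ = [
    "ChromAliasTable", "default_alias_table", "load_alias_table",
    "normalize_name", "chr_glob_match", "candidate_references",
]


class ChromAliasTable:
    """Mapping from canonical chromosome token to its alias spellings.

    Alias sets are pairwise disjoint and each canonical token is a member
    of its own alias set.  All lookups are over upper-cased, ``chr``-prefix
    stripped spellings.
    """

    def __init__(self, aliases: Dict[str, Set[str]]):
        table: Dict[str, Set[str]] = {}
        reverse: Dict[str, str] = {}
        for canonical, spellings in aliases.items():
            canonical = canonical.upper()
            spellings = {s.upper() for s in spellings} | {canonical}
            for s in spellings:
                if reverse.get(s, canonical) != canonical:
                    raise ValueError(
                        f"alias {s!r} claimed by both {reverse[s]!r} "
                        f"and {canonical!r}")
                reverse[s] = canonical
            table[canonical] = spellings
        self._table = table
        self._reverse = reverse

    def canonical(self, stripped: str) -> str:
        """Canonical token for an upper-cased, prefix-stripped spelling."""
        return self._reverse.get(stripped, stripped)

    def alias_class(self, canonical: str) -> Set[str]:
        """All spellings of ``canonical`` (just itself if not in the table)."""
        return self._table.get(canonical, {canonical})

    def items(self):
        return self._table.items()


def default_alias_table() -> ChromAliasTable:
    """Human naming: autosomes 1..22, X=23, Y=24, M=MT=25."""
    aliases: Dict[str, Set[str]] = {str(i): set() for i in range(1, 23)}
    aliases["X"] = {"23"}
    aliases["Y"] = {"24"}
    aliases["M"] = {"MT", "25"}
    return ChromAliasTable(aliases)


def load_alias_table(lines: Iterable[str]) -> ChromAliasTable:
    """Build a table from two-column text: ``canonical<whitespace>alias``.

    Blank lines and ``#`` comments are ignored.  A canonical token with no
    aliases may be declared by listing it alone on a line.
    """
    aliases: Dict[str, Set[str]] = {}
    for raw in lines:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        canonical = parts[0].upper()
        aliases.setdefault(canonical, set()).update(p.upper() for p in parts[1:])
    return ChromAliasTable(aliases)


_CHR_PREFIX = re.compile(r"^chr", re.IGNORECASE)


def _strip(raw: str) -> str:
    # iterate so normalization is a fixpoint even for degenerate
    # double-prefixed names like "chrchr1"
    s = raw.upper()
    while True:
        stripped = _CHR_PREFIX.sub("", s, count=1)
        if stripped == s:
            return s
        s = stripped


def normalize_name(raw: str, table: ChromAliasTable | None = None) -> str:
    """Canonicalize a reference name.

    Leading ``chr`` prefixes are stripped case-insensitively, the
    remainder upper-cased, then mapped through the alias table; unknown
    names pass through (stripped and upper-cased).  Idempotent.
    """
    table = table or _DEFAULT
    return table.canonical(_strip(raw))


def _translate(glob: str) -> str:
    # whole-name anchored; * and ? only, anything else literal
    out = []
    for ch in glob:
        if ch == "*":
            out.append(".*")
        elif ch == "?":
            out.append(".")
        else:
            out.append(re.escape(ch))
    return "^(?:" + "".join(out) + ")$"


@lru_cache(maxsize=4096)
def _compiled(glob_upper: str) -> re.Pattern:
    return re.compile(_translate(glob_upper))


def chr_glob_match(glob: str, raw: str,
                   table: ChromAliasTable | None = None) -> bool:
    """True iff ``glob`` matches the chromosome that ``raw`` names.

    The glob (``*`` any run, ``?`` one character; anchored; case
    insensitive) is tested against every spelling in the alias class of
    ``raw``'s canonical token, so the outcome depends only on which
    chromosome ``raw`` denotes, never on its spelling.  A glob written
    with a literal ``chr`` prefix is also tried with the prefix removed.
    """
    table = table or _DEFAULT
    canonical = normalize_name(raw, table)
    candidates = table.alias_class(canonical)
    patterns = [_compiled(glob.upper())]
    stripped_glob = _strip(glob)
    if stripped_glob != glob.upper():
        patterns.append(_compiled(stripped_glob))
    return any(p.match(c) for p in patterns for c in candidates)


def candidate_references(glob: str, header_names: List[str],
                         table: ChromAliasTable | None = None) -> List[str]:
    """Header names whose chromosome the glob matches, in header order."""
    table = table or _DEFAULT
    return [n for n in header_names if chr_glob_match(glob, n, table)]


_DEFAULT = default_alias_table()
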