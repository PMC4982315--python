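"""Predicate meaning: flags, mapping, position, sequence, random, connectives."""

import itertools
import math
import random

import pytest

from bamql import ast, parse_query
from bamql.read_model import ReadView
from bamql.semantics import (EvalContext, IUPAC_MASKS, base_at_reference,
                             compile_query, error_probability, eval_node,
                             iupac_compatible, keyed_uniform)
from bamql.fixtures import random_query


def make_read(flag=0, qname="r", ref="chr1", mate_ref=None, start=100,
              cigar=(("M", 10),), seq="ACGTACGTAC", mapq=30, rg=None):
    unmapped = bool(flag & 0x4)
    end = None
    if not unmapped and start is not None:
        end = start + sum(ln for op, ln in cigar if op in "MDN=X") - 1
    return ReadView(flag=flag, qname=qname,
                    ref_name=ref if ref else None,
                    mate_ref_name=mate_ref,
                    start=None if unmapped else start,
                    end=None if unmapped else end,
                    mapq=mapq, cigar=cigar if not unmapped else (),
                    seq=seq, read_group=rg)


CTX = EvalContext(seed=7, header_names=["chr1", "chr2"])


class TestErrorProbability:
    def test_mapq_zero_is_certain_error(self):
        assert error_probability(0) == 1.0

    def test_mapq_twenty(self):
        assert error_probability(20) == pytest.approx(1e-2)

    def test_sentinel_unavailable(self):
        assert error_probability(255) is None

    def test_monotone_decreasing(self):
        probs = [error_probability(q) for q in range(0, 255, 10)]
        assert probs == sorted(probs, reverse=True)


class TestIupac:
    def test_n_matches_any_base(self):
        for base in "ACGT":
            assert iupac_compatible(base, "N")

    def test_disjoint_singletons(self):
        assert not iupac_compatible("A", "C")

    def test_brute_force_against_expansion_table(self):
        # oracle: two codes are compatible iff their expansions intersect
        for a, b in itertools.product(IUPAC_MASKS, repeat=2):
            expected = bool(IUPAC_MASKS[a] & IUPAC_MASKS[b])
            assert iupac_compatible(a, b) is expected
            assert iupac_compatible(a.lower(), b) is expected

    def test_unknown_letter_raises(self):
        with pytest.raises(ValueError):
            iupac_compatible("Z", "A")


class TestBaseAtReference:
    READ = make_read(start=100, cigar=(("M", 5), ("D", 1), ("M", 5)),
                     seq="ACGTACGTAC")

    def test_worked_example(self):
        # ref 100-104 <-> query 0-4, 105 deleted, 106-110 <-> query 5-9
        assert base_at_reference(self.READ, 102) == "G"
        assert base_at_reference(self.READ, 105) is None
        assert base_at_reference(self.READ, 106) == "C"

    def test_outside_alignment(self):
        assert base_at_reference(self.READ, 99) is None
        assert base_at_reference(self.READ, 111) is None

    def test_independent_cursor_walk_agrees(self):
        """Cross-check against a from-scratch reference/query cursor table."""
        read = make_read(start=50,
                         cigar=(("S", 2), ("M", 3), ("I", 2), ("M", 2),
                                ("N", 4), ("M", 3)),
                         seq="ACGTACGTACGT")
        # build the mapping by explicit enumeration
        mapping = {}
        ref, q = 50, 0
        for op, ln in read.cigar:
            for _ in range(ln):
                if op in "M=X":
                    mapping[ref] = read.seq[q]
                    ref += 1
                    q += 1
                elif op in "IS":
                    q += 1
                elif op in "DN":
                    mapping[ref] = None
                    ref += 1
        for pos in range(45, 70):
            assert base_at_reference(read, pos) == mapping.get(pos), pos

    def test_insertion_shifts_query_cursor(self):
        read = make_read(start=10, cigar=(("M", 2), ("I", 3), ("M", 2)),
                         seq="AACCCGG")
        assert base_at_reference(read, 11) == "A"
        assert base_at_reference(read, 12) == "G"  # insertion skipped


class TestPredicates:
    def test_flag_predicates_match_their_bits(self):
        for kind, bit in ast.FLAG_BITS.items():
            read = make_read(flag=bit)
            assert eval_node(ast.FlagPred(kind), read, CTX)
            other = make_read(flag=0xFFF & ~bit)
            assert not eval_node(ast.FlagPred(kind), other, CTX)

    def test_raw_flag_bitwise(self):
        read = make_read(flag=77)
        assert eval_node(ast.RawFlag(4), read, CTX)       # 77 & 4 == 4
        assert eval_node(ast.RawFlag(77), read, CTX)
        assert not eval_node(ast.RawFlag(2), read, CTX)   # 77 & 2 == 0

    def test_literals(self):
        read = make_read()
        assert eval_node(ast.TrueLit(), read, CTX)
        assert not eval_node(ast.FalseLit(), read, CTX)

    def test_chr_fails_on_unmapped(self):
        read = make_read(flag=0x4, ref="chr1")  # placed-unmapped
        assert not eval_node(ast.Chr("*"), read, CTX)

    def test_split_pair(self):
        read = make_read(flag=0x1, ref="chr1", mate_ref="chr2")
        assert eval_node(ast.SplitPair(), read, CTX)
        same = make_read(flag=0x1, ref="chr1", mate_ref="chr1")
        assert not eval_node(ast.SplitPair(), same, CTX)
        mate_unmapped = make_read(flag=0x1 | 0x8, ref="chr1", mate_ref="chr1")
        assert not eval_node(ast.SplitPair(), mate_unmapped, CTX)

    def test_mapping_quality_strictness(self):
        read = make_read(mapq=20)  # error prob exactly 0.01
        assert not eval_node(ast.MappingQuality(0.01), read, CTX)
        assert eval_node(ast.MappingQuality(0.011), read, CTX)
        sentinel = make_read(mapq=255)
        assert not eval_node(ast.MappingQuality(1.0), sentinel, CTX)

    def test_position_predicates(self):
        read = make_read(start=100, cigar=(("M", 10),))  # spans 100..109
        assert eval_node(ast.After(109), read, CTX)
        assert eval_node(ast.After(50), read, CTX)
        assert not eval_node(ast.After(110), read, CTX)
        assert eval_node(ast.Before(100), read, CTX)
        assert not eval_node(ast.Before(99), read, CTX)
        assert eval_node(ast.PositionRange(105, 200), read, CTX)
        assert not eval_node(ast.PositionRange(110, 200), read, CTX)
        unmapped = make_read(flag=0x4)
        for node in (ast.After(1), ast.Before(10 ** 6),
                     ast.PositionRange(1, 10 ** 6)):
            assert not eval_node(node, unmapped, CTX)

    def test_nt_vs_nt_exact(self):
        read = make_read(start=100, seq="ARGTACGTAC")  # R = A or G at 101
        assert eval_node(ast.Nt(101, "A"), read, CTX)
        assert eval_node(ast.Nt(101, "G"), read, CTX)
        assert not eval_node(ast.Nt(101, "C"), read, CTX)
        assert not eval_node(ast.NtExact(101, "A"), read, CTX)
        assert eval_node(ast.NtExact(101, "R"), read, CTX)

    def test_nt_n_accepts_exactly_covered_positions(self):
        read = make_read(start=100, cigar=(("M", 5), ("D", 1), ("M", 5)),
                         seq="ACGTACGTAC")
        for pos in range(95, 115):
            covered = base_at_reference(read, pos) is not None
            assert eval_node(ast.Nt(pos, "N"), read, CTX) is covered

    def test_read_group_glob_case_sensitive(self):
        read = make_read(rg="lane1")
        assert eval_node(ast.ReadGroup("lane*"), read, CTX)
        assert not eval_node(ast.ReadGroup("LANE*"), read, CTX)
        assert not eval_node(ast.ReadGroup("lane1"), make_read(), CTX)

    def test_header_regex_unanchored_search(self):
        read = make_read(qname="SRR123.456")
        assert eval_node(ast.HeaderRegex("123"), read, CTX)
        assert eval_node(ast.HeaderRegex("^SRR"), read, CTX)
        assert not eval_node(ast.HeaderRegex("^123"), read, CTX)


class TestRandom:
    def test_extremes(self):
        reads = [make_read(qname=f"r{i}") for i in range(200)]
        zero = ast.Random(0.0)
        one = ast.Random(1.0)
        assert not any(eval_node(zero, r, CTX) for r in reads)
        assert all(eval_node(one, r, CTX) for r in reads)

    def test_reproducible_under_seed(self):
        reads = [make_read(qname=f"r{i}") for i in range(500)]
        node = ast.Random(0.3)
        ctx_a = EvalContext(seed=42)
        ctx_b = EvalContext(seed=42)
        ctx_c = EvalContext(seed=43)
        a = [eval_node(node, r, ctx_a) for r in reads]
        b = [eval_node(node, r, ctx_b) for r in reads]
        c = [eval_node(node, r, ctx_c) for r in reads]
        assert a == b
        assert a != c

    def test_accept_fraction_within_binomial_bounds(self):
        n, p = 20000, 0.25
        reads = (make_read(qname=f"r{i}") for i in range(n))
        node = ast.Random(p)
        ctx = EvalContext(seed=5)
        k = sum(eval_node(node, r, ctx) for r in reads)
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(k - n * p) < 3.3 * sigma  # 99.9% interval

    def test_distinct_nodes_draw_independently(self):
        read = make_read()
        # two Random nodes in one tree use distinct ordinals
        assert keyed_uniform(1, read, 0) != keyed_uniform(1, read, 1)


class TestConnectives:
    def _reads(self, n=2000, seed=0):
        rng = random.Random(seed)
        out = []
        for i in range(n):
            flag = rng.randrange(1 << 12)
            out.append(make_read(flag=flag, qname=f"r{i}",
                                 ref="chr1" if not flag & 0x4 else None,
                                 mate_ref=rng.choice(["chr1", "chr2", None]),
                                 start=rng.randrange(1, 1000),
                                 mapq=rng.choice((0, 20, 60, 255))))
        return out

    def _random_free_pair(self, seed):
        rng = random.Random(seed)
        return (random_query(rng, max_depth=3, allow_random=False),
                random_query(rng, max_depth=3, allow_random=False))

    @pytest.mark.parametrize("seed", range(15))
    def test_de_morgan(self, seed):
        a, b = self._random_free_pair(seed)
        for read in self._reads(300, seed):
            lhs = eval_node(ast.Not(ast.And(a, b)), read, CTX)
            rhs = eval_node(ast.Or(ast.Not(a), ast.Not(b)), read, CTX)
            assert lhs == rhs
            lhs = eval_node(ast.Not(ast.Or(a, b)), read, CTX)
            rhs = eval_node(ast.And(ast.Not(a), ast.Not(b)), read, CTX)
            assert lhs == rhs

    @pytest.mark.parametrize("seed", range(15))
    def test_xor_decomposition(self, seed):
        a, b = self._random_free_pair(seed + 100)
        for read in self._reads(300, seed):
            lhs = eval_node(ast.Xor(a, b), read, CTX)
            rhs = eval_node(ast.And(ast.Or(a, b),
                                    ast.Not(ast.And(a, b))), read, CTX)
            assert lhs == rhs

    @pytest.mark.parametrize("seed", range(15))
    def test_conditional_decomposition(self, seed):
        rng = random.Random(seed + 200)
        c = random_query(rng, max_depth=2, allow_random=False)
        t = random_query(rng, max_depth=2, allow_random=False)
        e = random_query(rng, max_depth=2, allow_random=False)
        for read in self._reads(300, seed):
            lhs = eval_node(ast.Conditional(c, t, e), read, CTX)
            rhs = eval_node(ast.Or(ast.And(c, t),
                                   ast.And(ast.Not(c), e)), read, CTX)
            assert lhs == rhs

    def test_mapping_quality_monotonicity(self):
        reads = self._reads(1000, 3)
        accept = {p: {r.qname for r in reads
                      if eval_node(ast.MappingQuality(p), r, CTX)}
                  for p in (0.001, 0.01, 0.5, 1.0)}
        assert accept[0.001] <= accept[0.01] <= accept[0.5] <= accept[1.0]


class TestCompile:
    @pytest.mark.parametrize("seed", range(25))
    def test_compiled_closure_agrees_with_interpreter(self, seed):
        rng = random.Random(seed)
        node = random_query(rng, max_depth=5)
        ctx = EvalContext(seed=seed, header_names=["chr1", "chr2"])
        f = compile_query(node, ctx)
        reads = TestConnectives()._reads(400, seed)
        for read in reads:
            assert f(read) == eval_node(node, read, ctx), ast.render(node)

    def test_compile_true_is_constant(self):
        f = compile_query(ast.TrueLit(), CTX)
        assert f(make_read()) and f(make_read(flag=0x4))

    def test_recompilation_is_deterministic_with_random(self):
        node = parse_query("random(0.5) & paired?")
        reads = [make_read(flag=0x1, qname=f"r{i}") for i in range(500)]
        for _ in range(2):
            runs = []
            for _ in range(2):
                f = compile_query(node, EvalContext(seed=9))
                runs.append([f(r) for r in reads])
            assert runs[0] == runs[1]
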