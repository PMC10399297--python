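import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canalnet.boolfunc import (
    HMDecomposition,
    TruthTable,
    canalizing_certificates,
    canalizing_depth,
    hm_decompose,
    hm_recompose,
    is_nested_canalizing,
    restrict,
)
from canalnet.encoding import decode_assignment, encode_assignment

from _util import all_truth_tables, oracle_depth, random_table, table_from_int

AND2 = TruthTable.from_callable(2, lambda a, b: a & b)
XOR2 = TruthTable.from_callable(2, lambda a, b: a ^ b)


class TestTruthTable:
    def test_evaluate_known_gates(self):
        assert AND2.evaluate((1, 1)) == 1
        assert AND2.evaluate((0, 1)) == 0
        assert XOR2.evaluate((1, 0)) == 1
        assert XOR2.evaluate((1, 1)) == 0

    def test_all_zero_assignment_reads_first_entry(self, rng):
        for n in (1, 2, 4):
            f = random_table(rng, n)
            assert f.evaluate((0,) * n) == int(f.bits[0])

    def test_length_validation(self):
        with pytest.raises(ValueError):
            TruthTable(2, [0, 1, 0])
        with pytest.raises(ValueError):
            AND2.evaluate((1,))

    @given(st.integers(0, 5), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_json_round_trip(self, n, data):
        bits = data.draw(st.lists(st.integers(0, 1), min_size=1 << n, max_size=1 << n))
        f = TruthTable(n, bits)
        assert TruthTable.from_json_dict(f.to_json_dict()) == f

    @given(st.integers(1, 8), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_assignment_encoding_round_trips(self, n, data):
        assignment = tuple(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        assert decode_assignment(encode_assignment(assignment), n) == assignment


class TestRestriction:
    def test_and_is_canalizing_at_zero(self):
        assert restrict(AND2, 1, 0) == TruthTable.constant(1, 0)
        assert restrict(AND2, 2, 0) == TruthTable.constant(1, 0)

    def test_xor_restrictions_stay_nonconstant(self):
        # fixing x1 in x1+x2 leaves x2 or its negation, never a constant
        assert restrict(XOR2, 1, 0) == TruthTable(1, [0, 1])
        assert restrict(XOR2, 1, 1) == TruthTable(1, [1, 0])

    def test_out_of_range_variable(self):
        with pytest.raises(ValueError):
            restrict(AND2, 3, 0)

    def test_restrictions_commute(self, rng):
        for _ in range(25):
            f = random_table(rng, 4)
            a = restrict(restrict(f, 3, 1), 1, 0)
            # after removing x1 first, old x3 becomes local variable 2
            b = restrict(restrict(f, 1, 0), 2, 1)
            assert a == b


class TestCertificates:
    def test_and_certificates(self):
        certs = {(c.variable, c.canalizing_input, c.canalized_output)
                 for c in canalizing_certificates(AND2)}
        assert certs == {(1, 0, 0), (2, 0, 0)}

    def test_xor_has_none(self):
        assert canalizing_certificates(XOR2) == []

    def test_constants_have_none(self):
        assert canalizing_certificates(TruthTable.constant(2, 0)) == []
        assert canalizing_certificates(TruthTable.constant(3, 1)) == []

    def test_certificate_means_constant_restriction(self, rng):
        for _ in range(50):
            f = random_table(rng, 3)
            for c in canalizing_certificates(f):
                g = restrict(f, c.variable, c.canalizing_input)
                assert g == TruthTable.constant(2, c.canalized_output)


class TestCanalizingDepth:
    @pytest.mark.parametrize(
        "builder, expected",
        [
            (lambda: TruthTable.from_callable(3, lambda a, b, c: (a ^ b) & c), 1),
            (lambda: TruthTable.from_callable(3, lambda a, b, c: a & b & c), 3),
            (lambda: TruthTable.from_callable(3, lambda a, b, c: a ^ b ^ c), 0),
        ],
        ids=["xor-times-x3", "triple-and", "triple-xor"],
    )
    def test_reference_depths(self, builder, expected):
        assert canalizing_depth(builder()) == expected

    def test_matches_definition_oracle_exhaustively(self):
        for n in (1, 2):
            for f in all_truth_tables(n):
                assert canalizing_depth(f) == oracle_depth(f)

    def test_peeling_order_independence(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 5))
            f = random_table(rng, n)
            reference = canalizing_depth(f)
            for _ in range(20):
                assert canalizing_depth(f, rng=rng) == reference

    def test_every_function_is_classified(self):
        # depth classes partition the whole function space
        for n in (1, 2, 3):
            counts = {}
            for f in all_truth_tables(n):
                k = canalizing_depth(f)
                assert 0 <= k <= n
                counts[k] = counts.get(k, 0) + 1
            assert sum(counts.values()) == 1 << (1 << n)

    def test_negating_output_preserves_depth(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 6))
            f = random_table(rng, n)
            assert canalizing_depth(f) == canalizing_depth(f.negate())

    def test_nested_iff_depth_equals_n(self):
        for f in all_truth_tables(3):
            nested = is_nested_canalizing(f)
            assert nested == (not f.is_constant() and canalizing_depth(f) == 3)
            if not f.is_zero():
                d = hm_decompose(f)
                # maximal depth <=> empty-variable constant-1 core
                assert (d.depth == 3) == (d.core_vars == () and d.core_is_one())


class TestLayeredDecomposition:
    def test_two_layer_worked_example(self):
        # f = x1(x2+1)(x3x4 + x3 + x4): layers {x1:0, x2:1} then {x3:1, x4:1},
        # b = 0, depth 4, constant-1 core on the empty set
        f = TruthTable.from_callable(
            4, lambda a, b, c, d: a & (b ^ 1) & ((c & d) ^ c ^ d)
        )
        d = hm_decompose(f)
        assert d.layers == (((1, 0), (2, 1)), ((3, 1), (4, 1)))
        assert d.b == 0 and d.depth == 4 and d.r == 2
        assert d.core_vars == () and d.core_is_one()
        assert hm_recompose(d) == f

    def test_two_layer_example_with_nontrivial_core(self):
        # g = x5(x4(x3+1)(x1+x2) + 1) + 1 has layers {x5:0} then {x4:0, x3:1}
        # around the noncanalizing core x1 + x2
        g = TruthTable.from_callable(
            5, lambda a, b, c, d, e: (e & d & (c ^ 1) & (a ^ b)) ^ e ^ 1
        )
        dec = hm_decompose(g)
        assert dec.layers == (((5, 0),), ((3, 1), (4, 0)))
        assert dec.b == 1 and dec.depth == 3 and dec.r == 2
        assert dec.core_vars == (1, 2)
        assert dec.core == TruthTable.from_callable(2, lambda a, b: a ^ b)
        assert hm_recompose(dec) == g

    def test_single_layer_when_outer_variable_reaches_the_core(self):
        # 1 + x5(x1+x2)(x3+1)x4: here x5, x4 and x3 all canalize the full
        # function simultaneously, so there is a single layer of size 3
        g = TruthTable.from_callable(
            5, lambda a, b, c, d, e: 1 ^ (e & (a ^ b) & (c ^ 1) & d)
        )
        dec = hm_decompose(g)
        assert dec.layers == (((3, 1), (4, 0), (5, 0)),)
        assert dec.b == 1 and dec.core_vars == (1, 2)
        assert hm_recompose(dec) == g

    def test_single_variable_identity(self):
        d = hm_decompose(TruthTable(1, [0, 1]))
        assert d.layers == (((1, 0),),)
        assert d.b == 0 and d.core_is_one() and d.core_vars == ()

    def test_single_literal_negated(self):
        d = hm_decompose(TruthTable(1, [1, 0]))
        assert d.layers == (((1, 1),),)
        assert d.b == 0  # forced by the exceptional case

    def test_noncanalizing_input_is_its_own_core(self):
        d = hm_decompose(XOR2)
        assert d.r == 0 and d.b == 0 and d.core == XOR2
        assert hm_recompose(d) == XOR2

    def test_zero_function_is_rejected(self):
        with pytest.raises(ValueError):
            hm_decompose(TruthTable.constant(3, 0))

    def test_round_trip_exhaustive_small(self):
        for n in (1, 2, 3):
            for m in range(1, 1 << (1 << n)):
                f = table_from_int(n, m)
                d = hm_decompose(f)
                assert hm_recompose(d) == f
                assert d.depth == canalizing_depth(f)

    def test_round_trip_random_six_variables(self, rng):
        for _ in range(1000):
            f = random_table(rng, 6)
            if f.is_zero():
                continue
            assert hm_recompose(hm_decompose(f)) == f

    def test_invalid_decomposition_is_rejected(self):
        good = hm_decompose(AND2)
        bad = HMDecomposition(
            n_vars=2,
            b=good.b,
            layers=(((1, 0), (1, 0)),),  # repeated variable
            core=good.core,
            core_vars=good.core_vars,
        )
        with pytest.raises(ValueError):
            hm_recompose(bad)
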