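"""Unit tests for permutation primitives, the cost model, and the metrics."""

import pytest
from hypothesis import given, settings, strategies as st

from revsym import (
    Inversion,
    Permutation,
    Strip,
    delta,
    delta_nb,
    delta_smp,
    identity,
    identity_slice,
    inversion_cost,
    nb_count,
    smp_count,
    strips,
)
from revsym.heuristics import delta_nb_fast

from conftest import all_permutations

SIGNED_EXAMPLE = Permutation((-5, 3, 4, -2, 1), signed=True)


def random_perms(max_n=7, signed=None):
    """Hypothesis strategy for permutations of size 1..max_n."""
    def build(draw):
        n = draw(st.integers(1, max_n))
        mags = draw(st.permutations(list(range(1, n + 1))))
        is_signed = draw(st.booleans()) if signed is None else signed
        if is_signed:
            signs = draw(st.lists(st.sampled_from([-1, 1]), min_size=n, max_size=n))
            mags = [s * m for s, m in zip(signs, mags)]
        return Permutation(tuple(mags), is_signed)
    return st.composite(build)()


class TestAccessors:
    @pytest.mark.parametrize(
        "element,pos,sign,slc",
        [(5, 1, -1, 1), (3, 2, 1, 2), (4, 3, 1, 3), (2, 4, -1, 2), (1, 5, 1, 1)],
    )
    def test_position_sign_slice(self, element, pos, sign, slc):
        assert SIGNED_EXAMPLE.position(element) == pos
        assert SIGNED_EXAMPLE.sign_of(element) == sign
        assert SIGNED_EXAMPLE.slice_of(element) == slc

    def test_slice_is_sign_independent(self):
        unsigned = SIGNED_EXAMPLE.dropped_signs()
        for e in range(1, 6):
            assert unsigned.slice_of(e) == SIGNED_EXAMPLE.slice_of(e)
            assert unsigned.position(e) == SIGNED_EXAMPLE.position(e)

    def test_identity_fixed_points(self):
        ident = identity(10, signed=True)
        for e in (1, 3, 9):
            assert ident.position(e) == e
            assert ident.sign_of(e) == 1
        assert identity(5).slice_of(3) == 3
        assert identity(10).slice_of(9) == 2

    def test_unsigned_position_example(self):
        assert Permutation((5, 3, 4, 2, 1)).position(1) == 5

    def test_out_of_range_element(self):
        with pytest.raises(ValueError):
            SIGNED_EXAMPLE.position(6)
        with pytest.raises(ValueError):
            SIGNED_EXAMPLE.sign_of(0)

    def test_invalid_permutations_rejected(self):
        with pytest.raises(ValueError):
            Permutation((1, 1, 2))
        with pytest.raises(ValueError):
            Permutation((1, -2, 3), signed=False)
        with pytest.raises(ValueError):
            Permutation(())


class TestCostModel:
    @pytest.mark.parametrize(
        "n,i,j,expected",
        [(10, 2, 9, 1), (10, 2, 5, 4), (10, 3, 3, 1), (9, 1, 5, 5)],
    )
    def test_cost_examples(self, n, i, j, expected):
        assert inversion_cost(n, Inversion(i, j)) == expected

    def test_perfectly_symmetric_inversions_cost_one(self):
        for n in range(2, 21):
            for i in range(1, n // 2 + 1):
                assert inversion_cost(n, Inversion(i, n - i + 1)) == 1

    def test_mirror_symmetry_and_bounds(self):
        for n in range(1, 51):
            for i in range(1, n + 1):
                for j in range(i, n + 1):
                    c = inversion_cost(n, Inversion(i, j))
                    assert c == inversion_cost(n, Inversion(n - j + 1, n - i + 1))
                    assert 1 <= c <= (n + 1) // 2

    def test_invalid_endpoints(self):
        with pytest.raises(ValueError):
            inversion_cost(5, Inversion(3, 2))
        with pytest.raises(ValueError):
            inversion_cost(5, Inversion(0, 2))


class TestApplyComposeInvert:
    def test_signed_apply(self):
        assert SIGNED_EXAMPLE.apply(Inversion(2, 4)).elements == (-5, 2, -4, -3, 1)

    def test_unsigned_apply(self):
        assert Permutation((5, 3, 4, 2, 1)).apply(Inversion(1, 5)).elements == (1, 2, 4, 3, 5)

    def test_unsigned_unitary_rejected(self):
        with pytest.raises(ValueError):
            Permutation((2, 1)).apply(Inversion(1, 1))

    @settings(derandomize=True, max_examples=200)
    @given(random_perms(), st.data())
    def test_apply_is_involution(self, perm, data):
        lo = 1 if perm.signed else 2
        if perm.n < lo:
            return
        i = data.draw(st.integers(1, perm.n if perm.signed else perm.n - 1))
        j = data.draw(st.integers(i if perm.signed else i + 1, perm.n))
        inv = Inversion(i, j)
        assert perm.apply(inv).apply(inv) == perm

    @settings(derandomize=True, max_examples=200)
    @given(random_perms())
    def test_compose_inverse_is_identity(self, perm):
        assert perm.compose(perm.inverse()).is_identity()
        assert perm.inverse().compose(perm).is_identity()
        assert perm.compose(identity(perm.n, perm.signed)) == perm

    def test_invert_example(self):
        assert Permutation((2, 3, 1)).inverse().elements == (3, 1, 2)


class TestBreakpointsAndStrips:
    def test_identity_has_no_breakpoints(self):
        assert nb_count(identity(6)) == 0
        assert nb_count(identity(6, signed=True)) == 0

    def test_small_examples(self):
        assert nb_count(Permutation((2, 1))) == 2
        assert nb_count(Permutation((2, 1), signed=True)) == 3

    @pytest.mark.parametrize("signed", [False, True])
    def test_zero_breakpoints_iff_identity(self, signed):
        for n in range(1, 7 if signed else 7):
            for perm in all_permutations(n, signed):
                assert (nb_count(perm) == 0) == perm.is_identity()

    def test_strips_examples(self):
        assert strips(Permutation((3, 4, 5, 1, 2))) == [
            Strip(1, 3, "increasing"),
            Strip(4, 5, "increasing"),
        ]
        assert strips(Permutation((5, 4, 1, 2, 3))) == [
            Strip(1, 2, "decreasing"),
            Strip(3, 5, "increasing"),
        ]
        assert strips(identity(4)) == [Strip(1, 4, "increasing")]

    def test_singleton_strips_are_decreasing(self):
        # (0,1) is an adjacency with the sentinel but (1,3) breaks: [1] is a
        # singleton strip, and singletons count as decreasing
        assert strips(Permutation((1, 3, 2)))[0] == Strip(1, 1, "decreasing")

    def test_strips_partition_positions(self):
        for perm in all_permutations(5, False):
            st_ = strips(perm)
            covered = [k for s in st_ for k in range(s.start, s.end + 1)]
            assert covered == list(range(1, 6))


class TestSliceMisplacedPairs:
    def test_identity_is_zero(self):
        assert smp_count(identity(8)) == 0
        assert smp_count(identity(8, signed=True)) == 0

    def test_brute_force_example(self):
        # of the three element pairs of (3 1 2) only {1, 2} has inverted slice order
        assert smp_count(Permutation((3, 1, 2))) == 1

    def test_sign_blind(self):
        assert smp_count(SIGNED_EXAMPLE) == smp_count(SIGNED_EXAMPLE.dropped_signs())


class TestDeltas:
    def test_delta_nb_sorting_step(self):
        assert delta("NB", Permutation((2, 1)), Inversion(1, 2)) == -2

    def test_delta_smp_symmetric_is_zero(self):
        perm = Permutation((4, 1, 3, 2, 6, 5))
        for i in (1, 2, 3):
            assert delta("SMP", perm, Inversion(i, 6 - i + 1)) == 0

    @pytest.mark.parametrize("signed", [False, True])
    def test_fast_delta_nb_matches_recount(self, signed):
        for n in range(1, 6):
            for perm in all_permutations(n, signed):
                for inv in perm.inversions():
                    assert delta_nb_fast(perm, inv) == delta_nb(perm, inv)

    def test_delta_nb_bounded(self):
        for n in range(2, 7):
            for perm in all_permutations(n, False):
                for inv in perm.inversions():
                    assert -2 <= delta_nb(perm, inv) <= 2

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            delta("XYZ", identity(3), Inversion(1, 2))

    @settings(derandomize=True, max_examples=100)
    @given(random_perms(max_n=9, signed=False), st.data())
    def test_fast_smp_after_matches_recount(self, perm, data):
        from revsym.heuristics import _smp_after

        if perm.n < 2:
            return
        i = data.draw(st.integers(1, perm.n - 1))
        j = data.draw(st.integers(i + 1, perm.n))
        inv = Inversion(i, j)
        assert _smp_after(perm.elements, inv) == smp_count(perm.apply(inv))


class TestIdentitySlice:
    def test_range(self):
        for n in range(1, 20):
            values = {identity_slice(n, k) for k in range(1, n + 1)}
            assert values == set(range(1, (n + 1) // 2 + 1))
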