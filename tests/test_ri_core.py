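"""Tests for the RI4 index family and barrier cascades."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribarriers.ri_core import (
    BARRIER_ORDER,
    BarrierCascade,
    BarrierStrength,
    CooccurrenceCounts,
    FloweringSeries,
    MatingCounts,
    RI4EInputs,
    UndefinedInputError,
    barrier_for,
    cascade_total,
    read_barrier_table,
    ri_4e,
    ri_4e_from_barriers,
    ri_cooccurrence,
    ri_mating,
    ri_temporal,
    ri_to_mating_ratio,
    write_barrier_table,
)

_METHOD_FOR = {
    "ecogeography": "RI4C",
    "phenology": "RI4S2",
    "pollinator_assemblage": "RI4C",
    "pollen_adhesion": "RI4A",
    "pollen_germination": "RI4A",
    "seed_development": "RI4A",
}


def make_cascade(values, names=None, **kw) -> BarrierCascade:
    names = names or BARRIER_ORDER[: len(values)]
    barriers = tuple(
        # negative (disassortative) test values need a signed method
        barrier_for(n, "focal", v, _METHOD_FOR[n] if v >= 0 else "RI4S2")
        for n, v in zip(names, values)
    )
    return BarrierCascade(barriers, **kw)


def ri_temporal_oracle(A, B, A_total, B_total) -> float:
    """Exact-rational direct summation of the RI4S2 per-period terms."""
    sH = Fraction(0)
    sC = Fraction(0)
    for a, b in zip(A, B):
        a, b = Fraction(a), Fraction(b)
        if a + b == 0:
            continue
        sH += (a / A_total) * (b / (a + b)) * Fraction(B_total, A_total + B_total)
        sC += (a / A_total) * (a / (a + b)) * Fraction(A_total, A_total + B_total)
    return float(1 - Fraction(2) * sH / (sH + sC))


class TestCooccurrence:
    @pytest.mark.parametrize(
        "s, u, expected",
        [
            (504, 2485, 0.8314),  # white-sand habitat overlap
            (504, 424, 0.4569),  # brown-sand habitat overlap
            (0, 7, 1.0),
            (7, 0, 0.0),
        ],
    )
    def test_examples(self, s, u, expected):
        assert ri_cooccurrence(CooccurrenceCounts(s, u)) == pytest.approx(expected, abs=5e-5)

    def test_degenerate_counts_rejected(self):
        with pytest.raises(UndefinedInputError):
            CooccurrenceCounts(0, 0)
        with pytest.raises(ValueError):
            CooccurrenceCounts(-1, 2)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_bounded(self, s, u):
        if s + u <= 0:
            return
        assert 0.0 <= ri_cooccurrence(CooccurrenceCounts(s, u)) <= 1.0


class TestMating:
    @pytest.mark.parametrize(
        "h, c, expected",
        [
            (0.164, 0.39, 0.4079),  # seed-set rates
            (0.44, 0.46, 0.0222),  # germination proportions
            (0.0, 5.0, 1.0),
            (3.0, 3.0, 0.0),
        ],
    )
    def test_examples(self, h, c, expected):
        assert ri_mating(MatingCounts(h, c)) == pytest.approx(expected, abs=5e-5)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_bounded_and_antisymmetric(self, h, c):
        if h + c <= 0:
            return
        ri = ri_mating(MatingCounts(h, c))
        assert -1.0 <= ri <= 1.0
        assert ri == pytest.approx(-ri_mating(MatingCounts(c, h)), abs=1e-12)


class TestTemporal:
    def test_identical_phenology_is_random_mating(self):
        s = FloweringSeries(("m1", "m2"), (3, 5), (3, 5), 10, 10)
        assert ri_temporal(s) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_phenology_is_complete_isolation(self):
        s = FloweringSeries(("m1", "m2", "m3"), (3, 2, 0), (0, 0, 4), 5, 6)
        assert ri_temporal(s) == pytest.approx(1.0, abs=1e-12)

    def test_small_series_matches_exact_oracle(self):
        s = FloweringSeries(("m1", "m2", "m3"), (3, 2, 0), (1, 4, 2), 5, 8)
        expected = ri_temporal_oracle((3, 2, 0), (1, 4, 2), 5, 8)
        assert expected == pytest.approx(-1 / 15, abs=1e-12)
        assert ri_temporal(s) == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle_on_random_series(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            n = rng.integers(1, 8)
            at = int(rng.integers(1, 20))
            bt = int(rng.integers(1, 20))
            A = rng.integers(0, at + 1, size=n)
            B = rng.integers(0, bt + 1, size=n)
            if not ((A > 0).any()):
                continue
            s = FloweringSeries(tuple(map(str, range(n))), tuple(A), tuple(B), at, bt)
            try:
                got = ri_temporal(s)
            except UndefinedInputError:
                continue
            want = ri_temporal_oracle(tuple(A), tuple(B), at, bt)
            assert got == pytest.approx(want, abs=1e-12)
            assert -1.0 <= got <= 1.0

    def test_invariant_to_uniform_rescaling(self):
        base = ri_temporal(FloweringSeries(("a", "b"), (2, 1), (1, 3), 4, 5))
        scaled = ri_temporal(FloweringSeries(("a", "b"), (6, 3), (3, 9), 12, 15))
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_empty_periods_contribute_nothing(self):
        with_gap = FloweringSeries(("a", "b", "c"), (2, 0, 1), (1, 0, 3), 4, 5)
        without = FloweringSeries(("a", "c"), (2, 1), (1, 3), 4, 5)
        assert ri_temporal(with_gap) == pytest.approx(ri_temporal(without), abs=1e-12)

    def test_no_focal_flowering_is_undefined(self):
        with pytest.raises(UndefinedInputError):
            ri_temporal(FloweringSeries(("a",), (0,), (3,), 4, 5))


class TestMatingRatio:
    @pytest.mark.parametrize("ri, expected", [(0.0, 1.0), (1.0, 0.0), (0.82, 0.0989)])
    def test_examples(self, ri, expected):
        assert ri_to_mating_ratio(ri) == pytest.approx(expected, abs=5e-5)

    @given(st.floats(-0.999, 1.0))
    def test_round_trip(self, ri):
        r = ri_to_mating_ratio(ri)
        assert ri_mating(MatingCounts(H=r, C=1.0)) == pytest.approx(ri, abs=1e-9)

    def test_complete_disassortative_is_infinite(self):
        with pytest.raises(UndefinedInputError):
            ri_to_mating_ratio(-1.0)


class TestCascade:
    def test_brown_sand_total(self):
        result = cascade_total(make_cascade((0.45, 0.69, 0.82, 0.18, 0.02, 0.40)))
        assert result.total == pytest.approx(0.9852, abs=5e-5)
        assert round(result.total, 2) == 0.99

    def test_white_sand_total_with_disassortative_barrier(self):
        result = cascade_total(make_cascade((0.83, -0.23, 0.82)))
        assert result.total == pytest.approx(0.9624, abs=5e-5)
        assert round(result.total, 2) == 0.96

    def test_single_barrier(self):
        result = cascade_total(make_cascade((0.3,)))
        assert result.total == pytest.approx(0.3)
        assert result.absolute_contribution == pytest.approx((0.3,))
        assert result.relative_contribution == pytest.approx((1.0,))

    def test_contributions_sum_to_total(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = rng.integers(1, 7)
            values = rng.uniform(-0.9, 1.0, size=k)
            result = cascade_total(make_cascade(tuple(values)))
            assert sum(result.absolute_contribution) == pytest.approx(result.total, abs=1e-9)
            if result.total != 0:
                assert sum(result.relative_contribution) == pytest.approx(1.0, abs=1e-9)
            assert result.total <= 1.0 + 1e-12

    def test_zero_barrier_is_neutral(self):
        with_zero = cascade_total(make_cascade((0.45, 0.0, 0.82), BARRIER_ORDER[:3]))
        without = cascade_total(
            make_cascade((0.45, 0.82), ("ecogeography", "pollinator_assemblage"))
        )
        assert with_zero.total == pytest.approx(without.total, abs=1e-12)

    def test_complete_barrier_forces_total_one(self):
        result = cascade_total(make_cascade((0.2, 1.0, 0.5), BARRIER_ORDER[:3]))
        assert result.total == pytest.approx(1.0, abs=1e-12)

    def test_unavailable_barriers_skipped(self):
        barriers = (
            barrier_for("ecogeography", "f", 0.5, "RI4C"),
            barrier_for("phenology", "f", math.nan, "RI4S2", available=False),
            barrier_for("pollinator_assemblage", "f", 0.5, "RI4C"),
        )
        result = cascade_total(BarrierCascade(barriers))
        assert result.barrier_names == ("ecogeography", "pollinator_assemblage")
        assert result.total == pytest.approx(0.75)

    def test_sympatry_drops_ecogeography(self):
        cascade = make_cascade((0.45, 0.69), include_ecogeography=False)
        result = cascade_total(cascade)
        assert result.barrier_names == ("phenology",)
        assert result.total == pytest.approx(0.69)

    def test_out_of_order_barriers_rejected(self):
        barriers = (
            barrier_for("phenology", "f", 0.5, "RI4S2"),
            barrier_for("ecogeography", "f", 0.5, "RI4C"),
        )
        with pytest.raises(ValueError, match="order"):
            BarrierCascade(barriers)


class TestRI4E:
    def test_no_discrimination_is_zero(self):
        inputs = RI4EInputs(0.6, 0.4, p_H_given_S=0.5, p_H_given_U=0.2, p_C_given_S=0.5, p_C_given_U=0.2)
        assert ri_4e(inputs) == pytest.approx(0.0, abs=1e-12)

    def test_no_heterospecific_flow_is_one(self):
        inputs = RI4EInputs(0.6, 0.4, 0.0, 0.0, 0.5, 0.5)
        assert ri_4e(inputs) == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_example(self):
        # literal evaluation of the formula on the brown-sand barrier values
        ratio = 1.0
        for v in (0.69, 0.82, 0.18, 0.02, 0.40):
            ratio *= (1 - v) / (1 + v)
        h = 0.55 * 0.5 * ratio
        c = 0.55 * 0.5 + 0.45 * 0.5
        expected = 1 - 2 * h / (h + c)
        assert expected == pytest.approx(0.9943, abs=5e-5)
        inputs = RI4EInputs(0.55, 0.45, 0.5 * ratio, 0.0, 0.5, 0.5)
        assert ri_4e(inputs) == pytest.approx(expected, abs=1e-12)

    def test_from_barriers_matches_hand_evaluation(self):
        cascade = make_cascade((0.45, 0.69, 0.82, 0.18, 0.02, 0.40))
        assert ri_4e_from_barriers(cascade) == pytest.approx(0.9943, abs=5e-5)

    def test_trivial_limits(self):
        assert ri_4e_from_barriers(make_cascade((0.0, 0.0), BARRIER_ORDER[:2])) == pytest.approx(0.0)
        # no shared habitat isolates completely regardless of later barriers
        assert ri_4e_from_barriers(make_cascade((1.0, 0.3), BARRIER_ORDER[:2])) == pytest.approx(1.0)

    @pytest.mark.parametrize("ri1, ri2", [(0.3, 0.5), (0.9, -0.4), (0.0, 0.7)])
    def test_sympatric_reduction_to_pooled_mating(self, ri1, ri2):
        # without unshared habitat the co-occurrence form collapses to RI4A on
        # the compounded sympatric success probabilities
        cascade = make_cascade((ri1, ri2), ("phenology", "pollinator_assemblage"),
                               include_ecogeography=False)
        g = cascade.baseline_gene_flow
        pooled_h = g * ri_to_mating_ratio(ri1) * ri_to_mating_ratio(ri2)
        expected = ri_mating(MatingCounts(H=pooled_h, C=g))
        assert ri_4e_from_barriers(cascade) == pytest.approx(expected, abs=1e-12)

    def test_missing_ecogeography_rejected(self):
        cascade = make_cascade((0.3,), ("phenology",))
        with pytest.raises(ValueError, match="ecogeographic"):
            ri_4e_from_barriers(cascade)


class TestBarrierTableIO:
    def test_round_trip(self, tmp_path):
        barriers = [
            barrier_for("ecogeography", "white_sand", 0.83, "RI4C"),
            barrier_for("phenology", "white_sand", -0.23, "RI4S2"),
            barrier_for("pollen_adhesion", "white_sand", math.nan, "RI4A", available=False),
        ]
        path = tmp_path / "barriers.csv"
        write_barrier_table(barriers, path)
        back = read_barrier_table(path)
        assert [b.barrier_name for b in back] == [b.barrier_name for b in barriers]
        for orig, rt in zip(barriers, back):
            assert rt.available == orig.available
            if orig.available:
                assert rt.value == pytest.approx(orig.value)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            BarrierStrength("ecogeography", "prepollination", "f", 1.5, "RI4C")
        with pytest.raises(ValueError):
            BarrierStrength("phenology", "prepollination", "f", -0.5, "RI4C")
        # negative values fine for the mating/temporal forms
        barrier_for("phenology", "f", -0.5, "RI4S2")
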