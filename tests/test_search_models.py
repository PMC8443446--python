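"""Closed-form search models: worked examples, identities, and guards."""

import json
import math

import pytest
from hypothesis import given, settings, strategies as st

from recadim.search_models import (
    DiffusionCoefficients,
    NucleoidGeometry,
    ProbingBudget,
    capture_rate_2d,
    capture_rate_3d,
    max_probe_time,
    model_speed_ratio,
    parallel_speedup,
    predict_all,
    predictions_from_json,
    predictions_to_json,
    probing_tests_per_segment,
    repair_success_fraction,
    search_time_2d,
    search_time_3d,
)

GEOM = NucleoidGeometry(half_length=1.0, nucleoid_radius=0.2, reaction_radius=0.001)
DIFF = DiffusionCoefficients(D_R=0.0007, D_L=0.00007)


def geometries():
    radii = st.floats(0.05, 1.0)
    return st.builds(
        lambda L, R, frac: NucleoidGeometry(L, R, R * frac),
        st.floats(0.1, 10.0), radii, st.floats(1e-4, 0.5),
    )


def diffusions():
    return st.builds(
        lambda d, fold: DiffusionCoefficients(d * fold, d),
        st.floats(1e-6, 1e-2), st.floats(1.0, 100.0),
    )


class TestCaptureRate2d:
    def test_worked_example(self):
        # 2π(2L)D/ln(R/r) at L=1, R/r=200, D=7e-4
        expected = 4 * math.pi * 0.0007 / math.log(200.0)
        assert capture_rate_2d(GEOM, DIFF) == pytest.approx(expected, rel=1e-12)
        assert capture_rate_2d(GEOM, DIFF) == pytest.approx(1.66e-3, rel=0.01)

    def test_linear_in_diffusivity(self):
        double = DiffusionCoefficients(D_R=2 * DIFF.D_R, D_L=DIFF.D_L)
        assert capture_rate_2d(GEOM, double) == pytest.approx(
            2 * capture_rate_2d(GEOM, DIFF))

    def test_diverges_as_reaction_radius_approaches_nucleoid_radius(self):
        tight = NucleoidGeometry(1.0, 0.2, 0.2 * (1 - 1e-9))
        assert capture_rate_2d(tight, DIFF) > 1e6 * capture_rate_2d(GEOM, DIFF)

    def test_rejects_reaction_radius_at_or_above_R(self):
        with pytest.raises(ValueError):
            NucleoidGeometry(1.0, 0.2, 0.2)


class TestSearchTime2d:
    def test_formula_convention(self):
        expected = 0.2**2 * math.log(200.0) / (2 * 0.0007)
        assert search_time_2d(GEOM, DIFF) == pytest.approx(expected)
        assert expected == pytest.approx(151, rel=0.01)

    def test_printed_convention_rounds_to_300_s(self):
        t = search_time_2d(GEOM, DIFF, convention="printed")
        assert t == pytest.approx(0.2**2 * math.log(200.0) / 0.0007)
        # one significant figure: the headline 5-minute association time
        assert round(t, -2) == 300.0

    def test_independent_of_length(self):
        long_cell = NucleoidGeometry(7.3, 0.2, 0.001)
        assert search_time_2d(long_cell, DIFF) == pytest.approx(
            search_time_2d(GEOM, DIFF))

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            search_time_2d(GEOM, DIFF, convention="half")


class TestNaive3d:
    def test_rate_worked_example(self):
        assert capture_rate_3d(GEOM, DIFF) == pytest.approx(
            4 * math.pi * 0.001 * 7e-5)
        assert capture_rate_3d(GEOM, DIFF) == pytest.approx(8.80e-7, rel=0.01)

    def test_rate_linear_in_reaction_radius(self):
        bigger = NucleoidGeometry(1.0, 0.2, 0.002)
        assert capture_rate_3d(bigger, DIFF) == pytest.approx(
            2 * capture_rate_3d(GEOM, DIFF))

    def test_time_worked_example_and_linearity_in_length(self):
        assert search_time_3d(GEOM, DIFF) == pytest.approx(
            1.0 * 0.2**2 / (2 * 0.001 * 7e-5))
        assert search_time_3d(GEOM, DIFF) == pytest.approx(2.86e5, rel=0.01)
        doubled = NucleoidGeometry(2.0, 0.2, 0.001)
        assert search_time_3d(doubled, DIFF) == pytest.approx(
            2 * search_time_3d(GEOM, DIFF))


class TestModelSpeedRatio:
    def test_printed_parameters_give_1750(self):
        geom = NucleoidGeometry(1.0, 0.3, 0.001)
        ratio = model_speed_ratio(geom, DIFF)
        assert ratio == pytest.approx(1753, abs=1)
        assert round(ratio, -1) == 1750

    def test_constructed_identity_ratio_one(self):
        geom = NucleoidGeometry(0.001 * math.log(200.0), 0.2, 0.001)
        diff = DiffusionCoefficients(D_R=1e-3, D_L=1e-3)
        assert model_speed_ratio(geom, diff) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(geometries(), diffusions())
    def test_equals_3d_over_2d_time(self, geom, diff):
        ratio = search_time_3d(geom, diff) / search_time_2d(geom, diff)
        assert model_speed_ratio(geom, diff) == pytest.approx(ratio, rel=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(geometries(), diffusions(), st.floats(1.5, 20.0))
    def test_scales_linearly_with_length(self, geom, diff, fold):
        scaled = NucleoidGeometry(geom.half_length * fold, geom.nucleoid_radius,
                                  geom.reaction_radius)
        assert model_speed_ratio(scaled, diff) == pytest.approx(
            fold * model_speed_ratio(geom, diff), rel=1e-9)


class TestParallelSpeedup:
    @pytest.mark.parametrize("filament, segment, expected", [
        (1750, 10, 175), (2000, 2000, 1), (2000, 1, 2000)])
    def test_worked_examples(self, filament, segment, expected):
        assert parallel_speedup(filament, segment) == pytest.approx(expected)

    def test_segment_larger_than_filament_rejected(self):
        with pytest.raises(ValueError):
            parallel_speedup(100, 200)


class TestProbingBudget:
    def test_segment_count_and_probe_bound(self):
        budget = ProbingBudget()
        assert probing_tests_per_segment(budget) == pytest.approx(4800)
        assert max_probe_time(budget) == pytest.approx(0.0625)
        assert max_probe_time(budget) * 1000 == pytest.approx(63, abs=1)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(1.0, 1e5))
    def test_count_invariant_under_probe_segment_length(self, n_bp):
        budget = ProbingBudget(probe_segment_bp=n_bp)
        assert probing_tests_per_segment(budget) == pytest.approx(4800)

    def test_equal_genome_and_filament(self):
        budget = ProbingBudget(genome_dsDNA_bp=2000, filament_ssDNA_bp=2000)
        assert probing_tests_per_segment(budget) == 1
        assert max_probe_time(budget) == budget.available_time

    def test_doubling_available_time_doubles_bound(self):
        b1, b2 = ProbingBudget(), ProbingBudget(available_time=600)
        assert max_probe_time(b2) == pytest.approx(2 * max_probe_time(b1))

    def test_invalid_budgets_rejected(self):
        with pytest.raises(ValueError):
            ProbingBudget(filament_ssDNA_bp=0)
        with pytest.raises(ValueError):
            ProbingBudget(genome_dsDNA_bp=1000, filament_ssDNA_bp=2000)


class TestAlgebraicIdentities:
    @settings(deadline=None, derandomize=True)
    @given(geometries(), diffusions())
    def test_2d_time_is_volume_over_rate(self, geom, diff):
        assert search_time_2d(geom, diff) == pytest.approx(
            geom.volume() / capture_rate_2d(geom, diff), rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(geometries(), diffusions())
    def test_3d_time_is_volume_over_rate(self, geom, diff):
        assert search_time_3d(geom, diff) == pytest.approx(
            geom.volume() / capture_rate_3d(geom, diff), rel=1e-12)


class TestRepairSuccess:
    def test_printed_counts(self):
        assert repair_success_fraction(447, 468) == pytest.approx(100 * 447 / 468)
        assert round(repair_success_fraction(447, 468), 1) == 95.5

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            repair_success_fraction(10, 5)


class TestPredictAll:
    def test_table_consistent_with_individual_operations(self):
        rows = {r.model_name: r for r in predict_all()}
        assert rows["reduced_2d"].search_time == pytest.approx(
            search_time_2d(GEOM, DIFF))
        assert rows["naive_3d"].search_time == pytest.approx(
            search_time_3d(GEOM, DIFF))
        summary = rows["summary"].parameters
        assert summary["probing_tests_per_segment"] == pytest.approx(4800)
        assert summary["max_probe_time_s"] == pytest.approx(0.0625)
        assert summary["speed_ratio_2d_over_3d"] == pytest.approx(1753, abs=1)

    def test_json_round_trip(self):
        rows = predict_all()
        back = predictions_from_json(predictions_to_json(rows))
        assert [r.to_dict() for r in back] == [r.to_dict() for r in rows]
        json.loads(predictions_to_json(rows))  # valid JSON
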