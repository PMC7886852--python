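"""Surplus ratios, state classification and vector aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corecc import (
    CarryingState,
    ConfigError,
    StructuralError,
    ValidationError,
    aggregate,
    aggregate_overall,
    assess_tree,
    classify_state,
    compute_surplus_ratio,
)
from corecc.assessment import IndicatorPair, SurplusResult

from conftest import build_corecc_tree, oracle_assess, random_tree

ratios = st.floats(min_value=-5.0, max_value=1.0, allow_nan=False)


class TestSurplusRatio:
    @pytest.mark.parametrize(
        "pressure, support, expected",
        [
            (5.0, 5.0, 0.0),  # full-load boundary
            (0.0, 5.0, 1.0),  # zero pressure: maximal surplus
            (6.0, 3.0, -1.0),  # pressure double the support
            (0.62, 1.0, 0.38),
        ],
    )
    def test_values(self, pressure, support, expected):
        assert compute_surplus_ratio(pressure, support) == pytest.approx(expected)

    def test_sign_convention(self):
        """d > 0 iff p < s; d < 0 iff p > s; always d <= 1."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            p, s = rng.uniform(0, 4), rng.uniform(0.1, 4)
            d = compute_surplus_ratio(p, s)
            assert d <= 1.0
            assert (d > 0) == (p < s)
            assert (d < 0) == (p > s)

    def test_nonpositive_support_names_indicator(self):
        with pytest.raises(ValidationError, match="water"):
            compute_surplus_ratio(1.0, 0.0, indicator="water")
        with pytest.raises(ValidationError):
            IndicatorPair(id="x", name="x", pressure=1.0, support=-2.0)

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValidationError):
            compute_surplus_ratio(-0.1, 1.0)


class TestClassifyState:
    @pytest.mark.parametrize(
        "d, width, expected",
        [
            (-0.04, 0.10, CarryingState.OVER_LOADED),
            (0.05, 0.10, CarryingState.WARNING),
            (0.38, 0.10, CarryingState.SURPLUS),
            (0.0, 0.10, CarryingState.FULL_LOADED),
            (0.10, 0.10, CarryingState.SURPLUS),  # boundary: d >= width
            (0.05, 0.0, CarryingState.SURPLUS),  # width 0: warning unreachable
            (1e-9, 0.0, CarryingState.SURPLUS),
        ],
    )
    def test_classification(self, d, width, expected):
        assert classify_state(d, width) is expected

    @pytest.mark.parametrize("width", [-0.1, 1.0, 1.5])
    def test_bad_width(self, width):
        with pytest.raises(ConfigError):
            classify_state(0.5, width)

    def test_degree_is_abs_ratio_times_100(self):
        r = SurplusResult.from_ratio(-1.45)
        assert r.degree == pytest.approx(145.0)
        assert r.state is CarryingState.OVER_LOADED


class TestAggregate:
    @pytest.mark.parametrize(
        "children, expected",
        [
            ([0.87], 0.87),  # singleton identity
            ([0.38, 0.44], 0.409),  # resource-supply dimension, 41%
            ([0.04, 0.08, -0.60], -0.201),  # socio-economic, 20% overload
        ],
    )
    def test_known_values(self, children, expected):
        assert aggregate(children) == pytest.approx(expected, abs=5e-4)

    def test_overall_known_value(self):
        # dimension ratios recomputed at full precision, then pooled
        dims = [
            aggregate([0.38, 0.44]),
            aggregate([0.87]),
            aggregate([aggregate([-0.04]), aggregate([-1.45, 0.14, -0.67, 0.14])]),
            aggregate([0.04, 0.08, -0.60]),
        ]
        assert aggregate_overall(dims) == pytest.approx(0.048, abs=3e-3)
        assert aggregate_overall([0.0, 0.0, 0.0, 0.0]) == 0.0

    def test_empty_is_structural_error(self):
        with pytest.raises(StructuralError):
            aggregate([])

    def test_child_above_one_rejected(self):
        with pytest.raises(ValidationError):
            aggregate([0.2, 1.2])

    @given(st.lists(ratios, min_size=1, max_size=10), ratios)
    @settings(derandomize=True, max_examples=200)
    def test_invariants(self, children, c):
        """Permutation invariance, equal-value identity, child bound."""
        D = aggregate(children)
        assert D <= max(children) + 1e-12
        assert aggregate(list(reversed(children))) == pytest.approx(D, abs=1e-12)
        assert aggregate([c] * 5) == pytest.approx(c, abs=1e-9)

    @given(
        st.lists(ratios, min_size=2, max_size=8),
        st.integers(min_value=0, max_value=7),
        st.floats(min_value=1e-6, max_value=0.5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_each_child(self, children, idx, bump):
        """Raising one child's ratio strictly raises the aggregate."""
        idx = idx % len(children)
        bumped = list(children)
        bumped[idx] = min(1.0, bumped[idx] + bump)
        if bumped[idx] > children[idx]:
            assert aggregate(bumped) > aggregate(children)


class TestAssessTree:
    def test_zsi_dimension_and_overall(self, zsi_tree):
        """The case-study tree reproduces the published hierarchy."""
        report = assess_tree(zsi_tree)
        dims = report.dimension_results()
        assert dims["resources_supply"].d == pytest.approx(0.41, abs=0.005)
        assert dims["environmental_assimilation"].d == pytest.approx(0.87)
        assert dims["ecosystem_services"].d == pytest.approx(-0.35, abs=0.005)
        assert dims["socio_economic"].d == pytest.approx(-0.20, abs=0.005)
        assert report.overall.d == pytest.approx(0.047, abs=0.002)
        assert report.overall.state is CarryingState.WARNING  # within 10% buffer
        assert assess_tree(zsi_tree, warning_width=0.0).overall.state is CarryingState.SURPLUS

    def test_trivial_tree_full_loaded(self):
        tree = build_corecc_tree([{"mode": "flat", "factors": [[(2.0, 2.0)]]}])
        report = assess_tree(tree)
        assert report.overall.d == 0.0
        assert report.overall.state is CarryingState.FULL_LOADED
        for node in report.nodes:
            assert node.result.d == 0.0

    def test_matches_independent_oracle_on_random_trees(self, rng):
        """assess_tree equals a naive plain-python re-evaluation."""
        for _ in range(50):
            dims = random_tree(rng)
            want_dims, want_overall = oracle_assess(dims)
            report = assess_tree(build_corecc_tree(dims))
            got_dims = [
                n.result.d for n in report.nodes if n.level == "dimension"
            ]
            np.testing.assert_allclose(got_dims, want_dims, rtol=1e-12)
            assert report.overall.d == pytest.approx(want_overall, rel=1e-12)

    def test_factor_rows_only_for_nested(self):
        nested = build_corecc_tree(
            [{"mode": "nested", "factors": [[(1.0, 2.0)], [(1.0, 4.0), (2.0, 4.0)]]}]
        )
        flat = build_corecc_tree(
            [{"mode": "flat", "factors": [[(1.0, 2.0)], [(1.0, 4.0), (2.0, 4.0)]]}]
        )
        assert any(n.level == "factor" for n in assess_tree(nested).nodes)
        assert not any(n.level == "factor" for n in assess_tree(flat).nodes)
        # flat pools the three indicators in one step
        want = 1 - math.sqrt(((1 - 0.5) ** 2 + (1 - 0.75) ** 2 + (1 - 0.5) ** 2) / 3)
        got = assess_tree(flat).dimension_results()["d0"].d
        assert got == pytest.approx(want, rel=1e-12)

    def test_error_paths_name_the_node(self):
        from corecc import AssessmentTree, Dimension, Factor

        empty = AssessmentTree(
            dimensions=[Dimension(id="d", name="d", factors=[Factor(id="f", name="f")])]
        )
        with pytest.raises(StructuralError, match="'d'/'f'"):
            assess_tree(empty)
        with pytest.raises(StructuralError):
            assess_tree(AssessmentTree(dimensions=[]))
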