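"""Unit and property tests for the aggregation-operator zoo."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggfuse import operators as ops

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


# ---------------------------------------------------------------------------
# Frozen example values (boundary cases and hand-derived arithmetic)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, y, a, b, expected",
    [
        (1.0, 1.0, 0.3, 0.7, 1.0),
        (0.0, 0.0, 0.3, 0.7, 0.0),
        (0.8, 0.2, 0.01, 0.99, 0.206),
        (0.2, 0.8, 0.01, 0.99, 0.794),
    ],
)
def test_generalized_choquet_form_values(x, y, a, b, expected):
    assert ops.generalized_choquet_form(x, y, a, b) == pytest.approx(expected)


def test_generalized_choquet_form_rejects_bad_params():
    with pytest.raises(ops.OperatorError):
        ops.generalized_choquet_form(0.5, 0.5, a=1.2, b=0.5)


def test_weighted_ratio_aggregation_values():
    # single argument with unit weight is the identity
    for x in (0.0, 0.3, 1.0):
        assert ops.weighted_ratio_aggregation([x], [1.0]) == pytest.approx(x)
    assert ops.weighted_ratio_aggregation([1, 1], [1, 1]) == pytest.approx(1.0)
    # (2.25 - 0.25) / (2.25 + 0.25)
    assert ops.weighted_ratio_aggregation([0.5, 0.5], [1, 1]) == pytest.approx(0.8)
    with pytest.raises(ops.OperatorError):
        ops.weighted_ratio_aggregation([0.5, 0.5], [1.0])


@pytest.mark.parametrize(
    "x, y, r, expected",
    [
        (0.3, 0.3, 2.0, 0.3),  # tie branch
        (0.2, 0.6, 2.0, 0.4),  # r=2 reduces to the arithmetic mean
        (1.0, 0.0, 2.0, 0.5),
    ],
)
def test_stolarsky_mean_values(x, y, r, expected):
    assert ops.stolarsky_mean(x, y, r) == pytest.approx(expected)


def test_stolarsky_mean_rejects_degenerate_exponents():
    for r in (0.0, 1.0):
        with pytest.raises(ops.OperatorError):
            ops.stolarsky_mean(0.2, 0.4, r)


def test_lukasiewicz_mean_blend_values():
    assert ops.lukasiewicz_mean_blend(0, 0) == pytest.approx(0.0)
    assert ops.lukasiewicz_mean_blend(1, 1) == pytest.approx(1.0)
    assert ops.lukasiewicz_mean_blend(0.8, 0.9) == pytest.approx(0.775)
    # not idempotent below the diagonal of the Lukasiewicz t-norm
    assert ops.lukasiewicz_mean_blend(0.5, 0.5) == pytest.approx(0.25)


def test_sp_symmetric_sum_values():
    assert ops.sp_symmetric_sum(0, 0) == pytest.approx(0.0)
    assert ops.sp_symmetric_sum(1, 1) == pytest.approx(1.0)
    assert ops.sp_symmetric_sum(0.2, 0.8) == pytest.approx(0.5)
    assert ops.sp_symmetric_sum(0.5, 0.5) == pytest.approx(0.5)


def test_log_generator_aggregation_values():
    for y in (0.0, 0.4, 1.0):
        assert ops.log_generator_aggregation(0.0, y) == pytest.approx(0.0)
        assert ops.log_generator_aggregation(1.0, y) == pytest.approx(y)
    # 2^(log2(1.5)^2) - 1, evaluated independently to 30 digits
    assert ops.log_generator_aggregation(0.5, 0.5) == pytest.approx(
        0.26767166548691503, abs=1e-12
    )


def test_log_product_literal_breaks_upper_boundary():
    # the literal printed form evaluates to 2 at (1, 1): kept for comparison
    assert ops.log_product_literal(1.0, 1.0) == pytest.approx(2.0)


def test_censored_midpoint_values():
    assert ops.censored_midpoint(0.3, 0.4) == pytest.approx(0.35)
    assert ops.censored_midpoint(0.6, 0.8) == pytest.approx(0.65)  # 0.6 -> 0.5
    assert ops.censored_midpoint(1.0, 1.0) == pytest.approx(1.0)
    # interval is half-open: 0.7 itself is not censored
    assert ops.censored_midpoint(0.7, 0.7) == pytest.approx(0.7)
    assert ops.censored_midpoint(0.5, 0.5) == pytest.approx(0.5)


def test_bertino_form_values():
    for x in (0.0, 0.4, 1.0):
        assert ops.bertino_form(x, x) == pytest.approx(x * x)
    assert ops.bertino_form(0.5, 1.0) == pytest.approx(0.25)
    # the printed form is asymmetric: swapping arguments changes the value
    assert ops.bertino_form(1.0, 0.5) == pytest.approx(0.5)


def test_max_symmetric_sum_values():
    assert ops.max_symmetric_sum(0.5, 0.5) == pytest.approx(0.5)
    assert ops.max_symmetric_sum(1.0, 0.0) == pytest.approx(0.5)
    assert ops.max_symmetric_sum(0.9, 0.6) == pytest.approx(0.9 / 1.3)


def test_exp_generator_tnorm_values():
    for alpha in (0.5, 1.0, 3.3):
        assert ops.exp_generator_tnorm(1.0, 1.0, alpha) == pytest.approx(1.0)
        assert ops.exp_generator_tnorm(0.7, 0.0, alpha) == pytest.approx(0.0)
    # independent high-precision evaluation at the reported operating point
    expected = float(
        np.log(np.exp(0.8**-3.3) * 2 - np.e) ** (-1 / 3.3)
    )
    got = ops.exp_generator_tnorm(0.8, 0.8, 3.3)
    assert got == pytest.approx(expected, abs=1e-12)
    assert got == pytest.approx(0.749, abs=1e-3)
    with pytest.raises(ops.OperatorError):
        ops.exp_generator_tnorm(0.5, 0.5, alpha=-1.0)


def test_owa_special_weight_profiles(rng):
    values = rng.random(6)
    n = len(values)
    assert ops.owa(values, np.full(n, 1 / n)) == pytest.approx(values.mean())
    assert ops.owa(values, np.eye(n)[0]) == pytest.approx(values.max())
    assert ops.owa(values, np.eye(n)[-1]) == pytest.approx(values.min())
    with pytest.raises(ops.OperatorError):
        ops.owa(values, np.full(n, 0.5))


# ---------------------------------------------------------------------------
# Bivariate reduction
# ---------------------------------------------------------------------------


def test_reduce_bivariate_single_value_and_fold_shape():
    spec = ops.get_operator("sp_symmetric_sum")
    assert ops.reduce_bivariate(spec, [0.42]) == pytest.approx(0.42)
    # mean-op fold is ((a+b)/2 + c)/2, not the 3-way mean
    mean2 = lambda x, y: (x + y) / 2
    assert ops.reduce_bivariate(mean2, [0.2, 0.4, 0.8]) == pytest.approx(
        ((0.2 + 0.4) / 2 + 0.8) / 2
    )
    # composition of the symmetric-sum examples: sp(sp(0.2,0.8), 0.5) = 0.5
    assert ops.reduce_bivariate(spec, [0.2, 0.8, 0.5]) == pytest.approx(0.5)
    with pytest.raises(ops.OperatorError):
        ops.reduce_bivariate(spec, [])


def test_reduce_bivariate_descending_order_sorts_first():
    first = lambda x, y: x  # projection exposes the fold order
    assert ops.reduce_bivariate(first, [0.2, 0.9, 0.5]) == pytest.approx(0.2)
    assert ops.reduce_bivariate(
        first, [0.2, 0.9, 0.5], order="descending"
    ) == pytest.approx(0.9)


def test_reduce_bivariate_idempotent_operator(rng):
    # max_symmetric_sum is idempotent everywhere (f(v, v) = v); the SP
    # symmetric sum is only fixed at 0 / 0.5 / 1, so it is not listed here
    spec = ops.get_operator("max_symmetric_sum")
    for v in rng.random(20):
        for k in (2, 3, 5, 8):
            assert ops.reduce_bivariate(spec, [v] * k) == pytest.approx(v)
    sp = ops.get_operator("sp_symmetric_sum")
    for v in (0.0, 0.5, 1.0):
        assert ops.reduce_bivariate(sp, [v] * 4) == pytest.approx(v)


def test_reduce_bivariate_censored_midpoint_idempotent_outside_censor_band(rng):
    spec = ops.get_operator("censored_midpoint")
    values = np.concatenate([rng.uniform(0, 0.5, 10), rng.uniform(0.7, 1, 10)])
    for v in values:
        assert ops.reduce_bivariate(spec, [v] * 4) == pytest.approx(v)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------


@settings(max_examples=200, derandomize=True)
@given(x=unit, y=unit)
def test_stolarsky_r2_equals_arithmetic_mean(x, y):
    assert ops.stolarsky_mean(x, y, 2.0) == pytest.approx((x + y) / 2, abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(x=unit)
def test_sp_symmetric_sum_self_dual(x):
    assert ops.sp_symmetric_sum(x, 1.0 - x) == pytest.approx(0.5, abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(y=unit)
def test_neutral_element_one(y):
    assert ops.log_generator_aggregation(1.0, y) == pytest.approx(y, abs=1e-9)
    for alpha in (1.0, 3.3):
        assert ops.exp_generator_tnorm(1.0, y, alpha) == pytest.approx(y, abs=1e-9)


_RANGE_EXEMPT = {"log_product_literal", "bertino_form"}  # documented violations


@pytest.mark.parametrize("name", sorted(set(ops.list_operators()) - _RANGE_EXEMPT))
def test_all_registered_operators_map_into_unit_interval(name, rng):
    entry = ops.OPERATOR_REGISTRY[name]
    params = {"a": 0.3, "b": 0.8, "r": 2.0, "alpha": 3.3}
    spec = ops.get_operator(
        name, **{k: params[k] for k in entry.param_names}
    )
    n = 2 if entry.arity == "bivariate" else 5
    pts = rng.random((10_000, n))
    w = np.full(n, 1.0 / n) if entry.requires_weights else None
    out = np.asarray(ops.evaluate_operator(spec, pts, weights=w))
    assert np.all(out >= -1e-9) and np.all(out <= 1 + 1e-9)


# ---------------------------------------------------------------------------
# Axiom checker
# ---------------------------------------------------------------------------


def test_axiom_checker_arithmetic_mean_passes():
    rep = ops.check_aggregation_axioms(ops.get_operator("arithmetic_mean"),
                                       n_samples=500, seed=0, n_args=4)
    assert rep.passed and rep.boundary_ok and not rep.monotonicity_violations


def test_axiom_checker_sp_symmetric_sum_passes():
    rep = ops.check_aggregation_axioms(ops.get_operator("sp_symmetric_sum"),
                                       n_samples=2000, seed=1)
    assert rep.passed and rep.boundary_ok and not rep.monotonicity_violations


def test_axiom_checker_bertino_flags_monotonicity_without_failing():
    rep = ops.check_aggregation_axioms(ops.get_operator("bertino_form"),
                                       n_samples=5000, seed=2)
    assert rep.boundary_ok
    assert rep.monotonicity_violations  # e.g. decreasing in x for y < x < 0.5
    assert rep.passed  # violations are documented exceptions


def test_axiom_checker_literal_log_form_flags_boundary():
    rep = ops.check_aggregation_axioms(ops.get_operator("log_product_literal"),
                                       n_samples=500, seed=3)
    assert not rep.boundary_ok
    assert "boundary" in rep.failed_axioms
    assert rep.passed  # documented exception


def _grid_monotone_violation_exists(func, step=0.01):
    """Exhaustive grid oracle: any coordinate-wise monotonicity violation."""
    g = np.arange(0.0, 1.0 + step / 2, step)
    X, Y = np.meshgrid(g, g, indexing="ij")
    F = np.asarray(func(X, Y))
    dx = np.diff(F, axis=0)
    dy = np.diff(F, axis=1)
    return bool((dx < -1e-9).any() or (dy < -1e-9).any())


@pytest.mark.parametrize(
    "name",
    ["generalized_choquet_form", "sp_symmetric_sum", "max_symmetric_sum",
     "lukasiewicz_mean_blend", "censored_midpoint", "bertino_form",
     "log_generator_aggregation", "product_tnorm"],
)
def test_axiom_checker_agrees_with_grid_oracle(name):
    entry = ops.OPERATOR_REGISTRY[name]
    params = {"a": 0.3, "b": 0.8}
    spec = ops.get_operator(name, **{k: params[k] for k in entry.param_names})
    func = ops._bound_func(spec)
    oracle_violates = _grid_monotone_violation_exists(func)
    rep = ops.check_aggregation_axioms(spec, n_samples=20_000, seed=4)
    assert bool(rep.monotonicity_violations) == oracle_violates
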