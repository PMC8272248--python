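"""Tests for Sugeno λ-measures and the fuzzy integrals."""

import itertools

import numpy as np
import pytest

from aggfuse import measures as ms
from aggfuse.operators import get_operator


# ---------------------------------------------------------------------------
# λ solver
# ---------------------------------------------------------------------------


def test_lambda_additive_case_returns_zero():
    assert ms.sugeno_lambda_solve([0.5, 0.3, 0.2]) == 0.0


@pytest.mark.parametrize(
    "densities, expected",
    [
        # nonzero roots of the normalization polynomial, solved independently
        # with numpy.roots on prod(1+λg) - (1+λ)
        ((0.5, 0.5, 0.5), -0.7639320225002102),
        ((0.2, 0.2, 0.2), 2.8077640640441515),
    ],
)
def test_lambda_matches_polynomial_solver(densities, expected):
    # independent oracle: the polynomial root inside (-1, inf) \ {0}
    coeffs = np.poly1d([1.0])
    for g in densities:
        coeffs = coeffs * np.poly1d([g, 1.0])
    poly = coeffs - np.poly1d([1.0, 1.0])
    roots = [
        float(r.real)
        for r in poly.roots
        if abs(r.imag) < 1e-12 and r.real > -1 and abs(r.real) > 1e-9
    ]
    assert len(roots) == 1
    lam = ms.sugeno_lambda_solve(densities)
    assert lam == pytest.approx(roots[0], abs=1e-10)
    assert lam == pytest.approx(expected, abs=1e-4)


def test_lambda_sign_follows_density_sum(rng):
    for _ in range(50):
        g = rng.uniform(0.05, 0.6, size=rng.integers(2, 7))
        lam = ms.sugeno_lambda_solve(g)
        residual = np.prod(1 + lam * g) - (1 + lam)
        assert abs(residual) < 1e-12
        if abs(g.sum() - 1) > 1e-9:
            assert (lam < 0) == (g.sum() > 1)


def test_lambda_degenerate_inputs_raise():
    with pytest.raises(ms.DegenerateMeasureError):
        ms.sugeno_lambda_solve([0.0, 0.0, 0.0])
    with pytest.raises(ms.DegenerateMeasureError):
        ms.sugeno_lambda_solve([1.0, 0.3, 0.2])
    with pytest.raises(ms.DegenerateMeasureError):
        ms.sugeno_lambda_solve([0.4, 0.0, 0.0])


# ---------------------------------------------------------------------------
# Measure of nested sets and subsets
# ---------------------------------------------------------------------------


def test_nested_measure_additive_is_partial_sum():
    m = ms.FuzzyMeasure.from_densities([0.5, 0.3, 0.2])
    profile = ms.SortedProfile.from_values([0.9, 0.5, 0.2])
    assert ms.measure_of_nested_set(m, profile, 1) == pytest.approx(0.5)
    assert ms.measure_of_nested_set(m, profile, 2) == pytest.approx(0.8)
    assert ms.measure_of_nested_set(m, profile, 3) == pytest.approx(1.0)


def test_nested_measure_lambda_recurrence_value():
    m = ms.FuzzyMeasure.from_densities([0.5, 0.5, 0.5])
    profile = ms.SortedProfile.from_values([0.9, 0.5, 0.2])
    expected = 0.5 + 0.5 + m.lam * 0.5 * 0.5  # one recurrence step
    assert ms.measure_of_nested_set(m, profile, 2) == pytest.approx(expected)
    assert expected == pytest.approx(0.8090, abs=1e-4)
    assert ms.measure_of_nested_set(m, profile, 3) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("n", [2, 4, 6, 8])
def test_recurrence_matches_closed_form_exhaustively(n, rng):
    g = rng.uniform(0.05, 0.5, n)
    m = ms.FuzzyMeasure.from_densities(g)
    # oracle: closed form (prod(1+λ g_i) - 1)/λ over every subset, compared
    # against the recurrence evaluated along a profile ordering that subset
    for k in range(1, n + 1):
        for subset in itertools.combinations(range(n), k):
            values = np.zeros(n)
            values[list(subset)] = np.linspace(0.9, 0.5, k)
            profile = ms.SortedProfile.from_values(values)
            rec = ms.measure_of_nested_set(m, profile, k)
            assert rec == pytest.approx(m.g(subset), abs=1e-9)


def test_full_set_measure_is_one(rng):
    for _ in range(20):
        g = rng.uniform(0.05, 0.6, 5)
        m = ms.FuzzyMeasure.from_densities(g)
        profile = ms.SortedProfile.from_values(rng.random(5))
        assert ms.measure_of_nested_set(m, profile, 5) == pytest.approx(1.0, abs=1e-9)
        assert m.g(range(5)) == 1.0


def test_measure_monotone_under_inclusion(rng):
    g = rng.uniform(0.05, 0.5, 6)
    m = ms.FuzzyMeasure.from_densities(g)
    subsets = list(
        itertools.chain.from_iterable(
            itertools.combinations(range(6), k) for k in range(7)
        )
    )
    for a in subsets:
        for b in subsets:
            if set(a) <= set(b):
                assert m.g(a) <= m.g(b) + 1e-9


# ---------------------------------------------------------------------------
# Choquet and Sugeno integrals
# ---------------------------------------------------------------------------


def _choquet_oracle(values, measure):
    """Independent formulation: Σ h_(i) (g(A_i) − g(A_{i−1}))."""
    order = np.argsort(-np.asarray(values), kind="stable")
    total, prev = 0.0, 0.0
    for i in range(len(values)):
        gA = measure.g(order[: i + 1])
        total += values[order[i]] * (gA - prev)
        prev = gA
    return total


def test_choquet_additive_equals_weighted_mean():
    m = ms.FuzzyMeasure.from_densities([0.5, 0.3, 0.2])
    assert ms.choquet_integral([0.9, 0.5, 0.2], m) == pytest.approx(0.64)


def test_sugeno_additive_example():
    m = ms.FuzzyMeasure.from_densities([0.5, 0.3, 0.2])
    assert ms.sugeno_integral([0.9, 0.5, 0.2], m) == pytest.approx(0.5)


def test_choquet_matches_subset_enumeration_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(2, 7))
        g = rng.uniform(0.05, 0.6, n)
        m = ms.FuzzyMeasure.from_densities(g)
        values = rng.random(n)
        assert ms.choquet_integral(values, m) == pytest.approx(
            _choquet_oracle(values, m), abs=1e-12
        )


def test_choquet_additive_reduction_random(rng):
    # for λ=0 the integral is exactly the dot product with the densities
    for _ in range(1000):
        n = int(rng.integers(2, 8))
        g = rng.dirichlet(np.ones(n))
        m = ms.FuzzyMeasure(tuple(g), 0.0)
        values = rng.random(n)
        assert ms.choquet_integral(values, m) == pytest.approx(
            float(values @ g), abs=1e-12
        )


def test_integral_idempotency_on_constant_input(rng):
    for _ in range(1000):
        n = int(rng.integers(2, 7))
        m = ms.FuzzyMeasure.from_densities(rng.uniform(0.05, 0.6, n))
        c = float(rng.random())
        assert ms.choquet_integral([c] * n, m) == pytest.approx(c, abs=1e-9)
        assert ms.sugeno_integral([c] * n, m) == pytest.approx(c, abs=1e-9)


def test_integral_monotone_and_internal(rng):
    for _ in range(200):
        n = int(rng.integers(2, 6))
        m = ms.FuzzyMeasure.from_densities(rng.uniform(0.05, 0.6, n))
        v = rng.random(n)
        ch, su = ms.choquet_integral(v, m), ms.sugeno_integral(v, m)
        assert v.min() - 1e-12 <= ch <= v.max() + 1e-12
        i = int(rng.integers(n))
        v2 = v.copy()
        v2[i] = v[i] + rng.random() * (1 - v[i])
        assert ms.choquet_integral(v2, m) >= ch - 1e-12
        assert ms.sugeno_integral(v2, m) >= su - 1e-12


def test_integral_dimension_mismatch():
    m = ms.FuzzyMeasure.from_densities([0.4, 0.4])
    with pytest.raises(ValueError):
        ms.choquet_integral([0.1, 0.2, 0.3], m)


# ---------------------------------------------------------------------------
# Generalized (pre-aggregation) integrals
# ---------------------------------------------------------------------------


def _nested_g(measure, values):
    order = np.argsort(-np.asarray(values), kind="stable")
    return order, np.array(
        [measure.g(order[: i + 1]) for i in range(len(values))]
    )


def test_cmmin_boundary_values():
    m = ms.FuzzyMeasure.from_densities([0.3, 0.3, 0.3])
    product = get_operator("product_tnorm")
    assert ms.generalized_integral_cmmin([1, 1, 1], m, product) == pytest.approx(1.0)
    assert ms.generalized_integral_cmmin([0, 0, 0], m, product) == pytest.approx(0.0)


def test_cmmin_matches_direct_summation_oracle():
    m = ms.FuzzyMeasure.from_densities([0.5, 0.3, 0.2])
    values = [0.9, 0.5, 0.2]
    order, gA = _nested_g(m, values)
    h = np.array(values)[order]
    h = np.append(h, 0.0)
    expected = sum(
        (min(h[i], gA[i]) - min(h[i + 1], gA[i])) * gA[i] for i in range(3)
    )
    got = ms.generalized_integral_cmmin(values, m, get_operator("product_tnorm"))
    assert got == pytest.approx(expected, abs=1e-12)


def test_cminm_boundary_and_projection_oracle():
    m = ms.FuzzyMeasure.from_densities([1 / 3, 1 / 3, 1 / 3])
    assert ms.generalized_integral_cminm([1, 1, 1], m, np.minimum) == pytest.approx(1.0)
    assert ms.generalized_integral_cminm([0, 0, 0], m, np.minimum) == pytest.approx(0.0)
    # with M(x, y) = x each term telescopes to min(h_i, g(A_i)) increments
    values = [0.9, 0.5, 0.2]
    order, gA = _nested_g(m, values)
    h = np.append(np.array(values)[order], 0.0)
    expected = sum(
        min(h[i], gA[i]) - min(h[i + 1], gA[i]) for i in range(3)
    )
    got = ms.generalized_integral_cminm(values, m, lambda x, y: x)
    assert got == pytest.approx(expected, abs=1e-12)


def test_generalized_integrals_stay_in_unit_interval(rng):
    tnorms = [get_operator("product_tnorm"), get_operator("lukasiewicz_tnorm"),
              get_operator("exp_generator_tnorm", alpha=3.3), np.minimum]
    for _ in range(100):
        n = int(rng.integers(2, 6))
        m = ms.FuzzyMeasure.from_densities(rng.uniform(0.05, 0.6, n))
        v = rng.random(n)
        for t in tnorms:
            for f in (ms.generalized_integral_cmmin, ms.generalized_integral_cminm):
                out = f(v, m, t)
                assert 0.0 <= out <= 1.0
    # boundaries are attained
    m = ms.FuzzyMeasure.from_densities([0.4, 0.4, 0.4])
    assert ms.generalized_integral_cmmin([1, 1, 1], m, np.minimum) == 1.0
    assert ms.generalized_integral_cminm([0, 0, 0], m, np.minimum) == 0.0


def test_sorted_profile_structure():
    p = ms.SortedProfile.from_values([0.2, 0.9, 0.5])
    assert p.values == (0.9, 0.5, 0.2, 0.0)
    assert p.permutation == (1, 2, 0)
    assert p.cumulative_set(2) == (1, 2)
    # stable on ties: original index order preserved
    p2 = ms.SortedProfile.from_values([0.5, 0.5, 0.1])
    assert p2.permutation == (0, 1, 2)
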