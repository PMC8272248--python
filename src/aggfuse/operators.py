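"""Aggregation operators for classifier fusion.

An aggregation function maps ``[0, 1]^n`` to ``[0, 1]``, preserves the
bounds (all-zeros to 0, all-ones to 1) and is monotone in every coordinate.
This module registers the bivariate and n-ary operators used for fusing
per-classifier class probabilities: weighted means, symmetric sums, OWA,
t-norms, Stolarsky means and several generalized-Choquet-style forms, plus
an axiom checker and a left-fold reducer that lifts bivariate operators to
n arguments.

All operator formulas are written with :mod:`numpy` ufuncs so that scalar
and array arguments broadcast alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "OperatorSpec",
    "AxiomReport",
    "OPERATOR_REGISTRY",
    "get_operator",
    "list_operators",
    "evaluate_operator",
    "reduce_bivariate",
    "check_aggregation_axioms",
    "generalized_choquet_form",
    "weighted_ratio_aggregation",
    "stolarsky_mean",
    "lukasiewicz_mean_blend",
    "sp_symmetric_sum",
    "log_generator_aggregation",
    "log_product_literal",
    "censored_midpoint",
    "bertino_form",
    "max_symmetric_sum",
    "exp_generator_tnorm",
    "owa",
]

_BOUNDARY_TOL = 1e-9


class OperatorError(ValueError):
    """Invalid operator parameter or malformed aggregation input."""


# ---------------------------------------------------------------------------
# Operator specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OperatorSpec:
    """A named aggregation operator with fixed parameter values.

    Parameters
    ----------
    name
        Registry key of the evaluation rule.
    arity
        ``"bivariate"`` or ``"nary"``.  Bivariate operators are lifted to
        ``n`` arguments by :func:`reduce_bivariate`.
    params
        Free parameters of the formula (``a``, ``b``, ``r``, ``alpha`` as
        applicable).
    requires_weights
        True when the formula takes one weight per classifier (weighted
        means, OWA, the weighted ratio form).
    requires_measure
        True for fuzzy-integral operators that aggregate against a fuzzy
        measure rather than a weight vector.
    known_axiom_exceptions
        Axioms (``"boundary"``, ``"monotonicity"``) this operator is
        documented to violate; the axiom checker treats only these
        violations as expected.
    """

    name: str
    arity: str = "bivariate"
    params: Mapping[str, float] = field(default_factory=dict)
    requires_weights: bool = False
    requires_measure: bool = False
    known_axiom_exceptions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.arity not in ("bivariate", "nary"):
            raise OperatorError(f"unknown arity {self.arity!r}")
        object.__setattr__(self, "params", dict(self.params))

    @property
    def label(self) -> str:
        """Name with parameter values, e.g. ``stolarsky_mean[r=2]``."""
        if not self.params:
            return self.name
        inner = ",".join(
            f"{k}={v:g}" if isinstance(v, (int, float)) else f"{k}={v}"
            for k, v in sorted(self.params.items())
        )
        return f"{self.name}[{inner}]"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "arity": self.arity,
            "params": dict(self.params),
            "requires_weights": self.requires_weights,
            "requires_measure": self.requires_measure,
        }


def _check_unit(*xs, names: str = "argument") -> None:
    for x in xs:
        arr = np.asarray(x, dtype=float)
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise OperatorError(f"{names} outside [0, 1]: {x!r}")


# ---------------------------------------------------------------------------
# The top-ten fused-operator formulas
# ---------------------------------------------------------------------------


def generalized_choquet_form(x, y, a: float, b: float):
    """Two-branch convex blend, the best-performing fusion rule.

    ``a*x + (1-a)*y`` when ``x >= y``, else ``(1-b)*x + b*y``.  Each branch
    is a weighted mean, so the output stays in ``[0, 1]`` for any
    ``a, b in [0, 1]``.
    """
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise OperatorError(f"parameters a={a}, b={b} must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.where(x >= y, a * x + (1.0 - a) * y, (1.0 - b) * x + b * y)


def weighted_ratio_aggregation(values, weights):
    """Ratio of products form ``(P+ - P-)/(P+ + P-)``.

    ``P+ = prod(1 + w_i x_i)`` and ``P- = prod(1 - w_i x_i)``.  Weights are
    per-classifier accuracies used raw (no normalization); the single
    argument case reduces to the identity for ``w = 1``.

    ``values`` may be 1-D (one observation) or 2-D with classifiers on the
    last axis.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape[-1] != w.shape[-1]:
        raise OperatorError(
            f"dimension mismatch: {v.shape[-1]} values vs {w.shape[-1]} weights"
        )
    plus = np.prod(1.0 + w * v, axis=-1)
    minus = np.prod(1.0 - w * v, axis=-1)
    return (plus - minus) / (plus + minus)


def stolarsky_mean(x, y, r: float):
    """Stolarsky mean ``((x^r - y^r) / (r (x - y)))^(1/(r-1))``; ``x`` at ties.

    ``r = 2`` reduces to the arithmetic mean; ``r = 0`` and ``r = 1`` are
    outside the parameterization used here.
    """
    if r == 0 or r == 1:
        raise OperatorError("stolarsky_mean requires r not in {0, 1}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    tie = np.isclose(x, y, rtol=0.0, atol=1e-15)
    xs = np.where(tie, 0.25, x)  # dummy values keep the formula finite at ties
    ys = np.where(tie, 0.75, y)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        core = (xs**r - ys**r) / (r * (xs - ys))
        out = core ** (1.0 / (r - 1.0))
    out = np.where(tie, x, out)
    if r < 0:
        # continuous limit: the mean vanishes when either argument is 0
        out = np.where(np.minimum(x, y) <= 0.0, 0.0, out)
    return out


def lukasiewicz_mean_blend(x, y):
    """Half-sum of the Lukasiewicz t-norm and the arithmetic mean.

    ``0.5 * (max(x + y - 1, 0) + (x + y) / 2)``.  Associative in the
    source construction; not idempotent (``f(0.5, 0.5) = 0.25``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 0.5 * (np.maximum(x + y - 1.0, 0.0) + (x + y) / 2.0)


def sp_symmetric_sum(x, y):
    """SP-based symmetric sum ``(x + y - xy) / (1 + x + y - 2xy)``.

    Self-dual: ``f(x, 1-x) = 0.5``; denominator is >= 1 on the unit square.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (x + y - x * y) / (1.0 + x + y - 2.0 * x * y)


def log_generator_aggregation(x, y):
    """Multiplicative-generator form ``2^(log2(1+x) * log2(1+y)) - 1``.

    The generator ``t -> log2(1+t)`` maps ``[0, 1]`` onto itself, so the
    product of generator images pulled back through the inverse generator
    is an aggregation function with neutral element 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.exp2(np.log2(1.0 + x) * np.log2(1.0 + y)) - 1.0


def log_product_literal(x, y):
    """Literal log-product form ``2 ln(1+x) ln(1+y) / ln(2)^2``.

    Kept for comparison with :func:`log_generator_aggregation`; evaluates
    to 2 at ``(1, 1)`` and therefore violates the upper boundary axiom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 2.0 * np.log1p(x) * np.log1p(y) / (np.log(2.0) ** 2)


def censored_midpoint(x, y):
    """Arithmetic mean after censoring arguments in ``[0.5, 0.7)`` to 0.5.

    The substitution applies to each argument independently; the censoring
    interval is half-open (0.5 included, 0.7 excluded).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = np.where((x >= 0.5) & (x < 0.7), 0.5, x)
    yc = np.where((y >= 0.5) & (y < 0.7), 0.5, y)
    return (xc + yc) / 2.0


def bertino_form(x, y):
    """Bertino-copula-derived form, implemented exactly as printed.

    ``min(x, y)^2`` when ``x <= y``, else ``max(x, y)^2 - |x - y|``.  The
    printed form is asymmetric, fails coordinate-wise monotonicity on part
    of the unit square (e.g. decreasing in ``x`` for ``y < x < 0.5``) and
    can go negative there (e.g. ``f(0.5, 0.05) = -0.2``); both are
    recorded as documented axiom exceptions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.where(
        x <= y,
        np.minimum(x, y) ** 2,
        np.maximum(x, y) ** 2 - np.abs(x - y),
    )


def max_symmetric_sum(x, y):
    """Max-based symmetric sum ``max(x, y) / (1 + |x - y|)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.maximum(x, y) / (1.0 + np.abs(x - y))


def exp_generator_tnorm(x, y, alpha: float):
    """Exponential-generator t-norm ``(ln(e^(x^-a) + e^(y^-a) - e))^(-1/a)``.

    Continuous Archimedean t-norm with additive generator
    ``t -> e^(t^-alpha) - e``; neutral element 1, annihilator 0 (taken as
    the limit for zero arguments).  Requires ``alpha > 0``.
    """
    if alpha <= 0:
        raise OperatorError(f"alpha must be positive, got {alpha}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zero = (x <= 0.0) | (y <= 0.0)
    xs = np.where(zero, 1.0, x)
    ys = np.where(zero, 1.0, y)
    with np.errstate(over="ignore", invalid="ignore"):
        a, b = xs**-alpha, ys**-alpha
        # log-sum-exp form of ln(e^a + e^b - e): stable for small arguments,
        # whose generator values overflow the naive expression
        m = np.maximum(a, b)
        inner = np.exp(a - m) + np.exp(b - m) - np.exp(1.0 - m)
        out = (m + np.log(inner)) ** (-1.0 / alpha)
    # below ~1e-93 even the generator value overflows; there the dominant
    # term makes the t-norm coincide with min to double precision
    out = np.where(np.isinf(m), np.minimum(xs, ys), out)
    return np.where(zero, 0.0, out)


def owa(values, owa_weights):
    """Ordered weighted average: weights applied to descending-sorted inputs.

    ``owa_weights`` must sum to 1.  Uniform weights give the arithmetic
    mean; ``(1, 0, ..., 0)`` gives the maximum and ``(0, ..., 0, 1)`` the
    minimum.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(owa_weights, dtype=float)
    if abs(float(w.sum()) - 1.0) > 1e-9:
        raise OperatorError(f"OWA weights must sum to 1, got {w.sum()!r}")
    if v.shape[-1] != w.shape[-1]:
        raise OperatorError(
            f"dimension mismatch: {v.shape[-1]} values vs {w.shape[-1]} weights"
        )
    return np.sort(v, axis=-1)[..., ::-1] @ w


# ---------------------------------------------------------------------------
# Standard operator families (means, t-norms, medians)
# ---------------------------------------------------------------------------


def _arithmetic_mean(values):
    return np.mean(np.asarray(values, dtype=float), axis=-1)


def _quadratic_mean(values):
    return np.sqrt(np.mean(np.asarray(values, dtype=float) ** 2, axis=-1))


def _geometric_mean(values):
    v = np.asarray(values, dtype=float)
    return np.exp(np.mean(np.log(np.maximum(v, 1e-300)), axis=-1)) * (
        np.min(v, axis=-1) > 0
    )


def _median(values):
    return np.median(np.asarray(values, dtype=float), axis=-1)


def _weighted_median(values, weights):
    """Weight-wise 0.5-quantile of the values (weights normalized to sum 1)."""
    v = np.atleast_2d(np.asarray(values, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise OperatorError("weighted median needs positive total weight")
    w = w / w.sum()
    order = np.argsort(v, axis=-1)
    vs = np.take_along_axis(v, order, axis=-1)
    ws = np.broadcast_to(w, v.shape)
    ws = np.take_along_axis(ws, order, axis=-1)
    cum = np.cumsum(ws, axis=-1)
    idx = np.argmax(cum >= 0.5 - 1e-12, axis=-1)
    out = np.take_along_axis(vs, idx[:, None], axis=-1)[:, 0]
    return out if np.asarray(values).ndim > 1 else float(out[0])


def _weighted_mean(values, weights):
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise OperatorError("weighted mean needs positive total weight")
    return (v @ w) / w.sum()


def _minimum(values):
    return np.min(np.asarray(values, dtype=float), axis=-1)


def _maximum(values):
    return np.max(np.asarray(values, dtype=float), axis=-1)


def _product_tnorm(x, y):
    return np.asarray(x, dtype=float) * np.asarray(y, dtype=float)


def _lukasiewicz_tnorm(x, y):
    return np.maximum(np.asarray(x, dtype=float) + np.asarray(y, dtype=float) - 1.0, 0.0)


def _einstein_tnorm(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return x * y / (2.0 - (x + y - x * y))


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _RegistryEntry:
    func: Callable
    arity: str
    param_names: tuple[str, ...] = ()
    requires_weights: bool = False
    known_axiom_exceptions: tuple[str, ...] = ()


OPERATOR_REGISTRY: dict[str, _RegistryEntry] = {
    "generalized_choquet_form": _RegistryEntry(
        generalized_choquet_form, "bivariate", ("a", "b")
    ),
    "weighted_ratio_aggregation": _RegistryEntry(
        weighted_ratio_aggregation, "nary", (), requires_weights=True
    ),
    "stolarsky_mean": _RegistryEntry(stolarsky_mean, "bivariate", ("r",)),
    "lukasiewicz_mean_blend": _RegistryEntry(lukasiewicz_mean_blend, "bivariate"),
    "sp_symmetric_sum": _RegistryEntry(sp_symmetric_sum, "bivariate"),
    "log_generator_aggregation": _RegistryEntry(log_generator_aggregation, "bivariate"),
    "log_product_literal": _RegistryEntry(
        log_product_literal,
        "bivariate",
        known_axiom_exceptions=("boundary", "range"),
    ),
    "censored_midpoint": _RegistryEntry(censored_midpoint, "bivariate"),
    "bertino_form": _RegistryEntry(
        bertino_form,
        "bivariate",
        known_axiom_exceptions=("monotonicity", "range"),
    ),
    "max_symmetric_sum": _RegistryEntry(max_symmetric_sum, "bivariate"),
    "exp_generator_tnorm": _RegistryEntry(exp_generator_tnorm, "bivariate", ("alpha",)),
    "owa": _RegistryEntry(owa, "nary", requires_weights=True),
    "arithmetic_mean": _RegistryEntry(_arithmetic_mean, "nary"),
    "quadratic_mean": _RegistryEntry(_quadratic_mean, "nary"),
    "geometric_mean": _RegistryEntry(_geometric_mean, "nary"),
    "median": _RegistryEntry(_median, "nary"),
    "weighted_median": _RegistryEntry(
        _weighted_median, "nary", requires_weights=True
    ),
    "weighted_mean": _RegistryEntry(_weighted_mean, "nary", requires_weights=True),
    "minimum": _RegistryEntry(_minimum, "nary"),
    "maximum": _RegistryEntry(_maximum, "nary"),
    "product_tnorm": _RegistryEntry(_product_tnorm, "bivariate"),
    "lukasiewicz_tnorm": _RegistryEntry(_lukasiewicz_tnorm, "bivariate"),
    "einstein_tnorm": _RegistryEntry(_einstein_tnorm, "bivariate"),
}


def get_operator(name: str, **params: float) -> OperatorSpec:
    """Build an :class:`OperatorSpec` for a registered operator."""
    try:
        entry = OPERATOR_REGISTRY[name]
    except KeyError:
        raise OperatorError(f"unknown operator {name!r}") from None
    missing = set(entry.param_names) - set(params)
    if missing:
        raise OperatorError(f"{name} requires parameters {sorted(missing)}")
    allowed = set(entry.param_names)
    if entry.arity == "bivariate":
        allowed.add("fold_order")  # per-operator override of the fold order
    extra = set(params) - allowed
    if extra:
        raise OperatorError(f"{name} does not take parameters {sorted(extra)}")
    return OperatorSpec(
        name=name,
        arity=entry.arity,
        params=params,
        requires_weights=entry.requires_weights,
        known_axiom_exceptions=entry.known_axiom_exceptions,
    )


def list_operators() -> list[str]:
    return sorted(OPERATOR_REGISTRY)


def _bound_func(spec: OperatorSpec) -> Callable:
    """Bind an OperatorSpec's parameters into a plain callable."""
    entry = OPERATOR_REGISTRY[spec.name]
    params = {k: v for k, v in spec.params.items() if k != "fold_order"}
    if not params:
        return entry.func
    return lambda *args: entry.func(*args, **params)


def reduce_bivariate(op: OperatorSpec | Callable, values, order: str = "registry"):
    """Lift a bivariate operator to n arguments by a left fold.

    ``r_1 = v_1; r_k = op(r_{k-1}, v_k)``.  ``order="registry"`` folds in
    the given (classifier-registry) order; ``order="descending"`` sorts each
    observation's values non-increasingly first.

    ``values`` may be 1-D or 2-D with the classifier axis last.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[-1] == 0:
        raise OperatorError("cannot reduce an empty list of values")
    if order == "descending":
        v = np.sort(v, axis=-1)[..., ::-1]
    elif order != "registry":
        raise OperatorError(f"unknown fold order {order!r}")
    func = _bound_func(op) if isinstance(op, OperatorSpec) else op
    acc = v[..., 0]
    for k in range(1, v.shape[-1]):
        acc = func(acc, v[..., k])
    return acc


def evaluate_operator(
    spec: OperatorSpec,
    values,
    weights: Sequence[float] | None = None,
    fold_order: str = "registry",
):
    """Evaluate a registered operator on a vector (or batch) of inputs.

    Bivariate operators are lifted with :func:`reduce_bivariate`; n-ary
    operators are applied directly.  Weight-taking operators require
    ``weights``.
    """
    entry = OPERATOR_REGISTRY[spec.name]
    if entry.requires_weights:
        if weights is None:
            raise OperatorError(f"{spec.name} requires weights")
        params = {k: v for k, v in spec.params.items() if k != "fold_order"}
        return entry.func(values, weights, **params)
    if spec.arity == "bivariate":
        # an operator-level fold_order parameter overrides the call-level one
        order = spec.params.get("fold_order", fold_order)
        return reduce_bivariate(spec, values, order=order)
    return _bound_func(spec)(values)


# ---------------------------------------------------------------------------
# Axiom checking
# ---------------------------------------------------------------------------


@dataclass
class AxiomReport:
    """Result of checking the aggregation axioms on one operator."""

    operator: str
    boundary_ok: bool
    boundary_values: tuple[float, float]
    monotonicity_violations: list[tuple]
    range_ok: bool
    passed: bool
    failed_axioms: tuple[str, ...]
    n_samples: int

    def summary(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        parts = [f"{self.operator}: {status}"]
        parts.append(f"boundary={'ok' if self.boundary_ok else 'violated'}")
        parts.append(f"monotonicity_violations={len(self.monotonicity_violations)}")
        parts.append(f"range={'ok' if self.range_ok else 'violated'}")
        if self.failed_axioms:
            parts.append(f"failed={','.join(self.failed_axioms)}")
        return " ".join(parts)


def check_aggregation_axioms(
    op: OperatorSpec,
    n_samples: int = 2000,
    seed: int = 0,
    n_args: int = 2,
    weights: Sequence[float] | None = None,
) -> AxiomReport:
    """Check boundary conditions, monotonicity and range on random samples.

    Boundary: ``p(0,...,0) = 0`` and ``p(1,...,1) = 1`` within 1e-9.
    Monotonicity: non-strict, on ``n_samples`` random pairs ``x <= y``.
    Operators whose ``known_axiom_exceptions`` cover every failed axiom
    still pass.
    """
    entry = OPERATOR_REGISTRY[op.name]
    if entry.requires_weights and weights is None:
        weights = np.full(n_args, 1.0 / n_args) if op.name == "owa" else np.ones(n_args)

    def apply(pts: np.ndarray) -> np.ndarray:
        return np.asarray(evaluate_operator(op, pts, weights=weights), dtype=float)

    rng = np.random.default_rng(seed)
    lo = float(apply(np.zeros((1, n_args)))[0])
    hi = float(apply(np.ones((1, n_args)))[0])
    boundary_ok = abs(lo) <= _BOUNDARY_TOL and abs(hi - 1.0) <= _BOUNDARY_TOL

    x = rng.random((n_samples, n_args))
    y = x + rng.random((n_samples, n_args)) * (1.0 - x)  # y >= x coordinate-wise
    fx, fy = apply(x), apply(y)
    bad = fx > fy + _BOUNDARY_TOL
    violations = [
        (tuple(x[i]), tuple(y[i]), float(fx[i]), float(fy[i]))
        for i in np.flatnonzero(bad)[:50]
    ]

    allv = np.concatenate([fx, fy])
    range_ok = bool(np.all(allv >= -_BOUNDARY_TOL) and np.all(allv <= 1 + _BOUNDARY_TOL))

    failed = []
    if not boundary_ok:
        failed.append("boundary")
    if violations:
        failed.append("monotonicity")
    if not range_ok:
        failed.append("range")
    allowed = set(op.known_axiom_exceptions) | set(entry.known_axiom_exceptions)
    passed = all(f in allowed for f in failed)
    return AxiomReport(
        operator=op.label,
        boundary_ok=boundary_ok,
        boundary_values=(lo, hi),
        monotonicity_violations=violations,
        range_ok=range_ok,
        passed=passed,
        failed_axioms=tuple(failed),
        n_samples=n_samples,
    )
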