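"""Sugeno λ-fuzzy measures and fuzzy integrals.

A fuzzy measure on the set of classifiers is a set function ``g`` with
``g(∅) = 0``, ``g(X) = 1`` and monotonicity under inclusion.  The Sugeno
λ-measure builds one from per-classifier densities ``g_i`` (here: their
cross-validated accuracies) via

    g(A ∪ B) = g(A) + g(B) + λ g(A) g(B)        (A, B disjoint)

where λ > −1 is pinned down by normalization: ``1 + λ = Π (1 + λ g_i)``.
On top of the measure this module provides the Choquet integral, the
Sugeno integral and two generalized (pre-aggregation) integral forms in
which a t-norm ``M`` replaces parts of the Choquet summand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .operators import OperatorSpec, OPERATOR_REGISTRY, _bound_func

__all__ = [
    "FuzzyMeasure",
    "SortedProfile",
    "DegenerateMeasureError",
    "sugeno_lambda_solve",
    "measure_of_nested_set",
    "choquet_integral",
    "sugeno_integral",
    "generalized_integral_cmmin",
    "generalized_integral_cminm",
]

_TOL = 1e-9


class DegenerateMeasureError(ValueError):
    """Densities admit no valid Sugeno λ-measure."""


def _lambda_residual(lam: float, densities: np.ndarray) -> float:
    return float(np.prod(1.0 + lam * densities) - (1.0 + lam))


def sugeno_lambda_solve(densities: Sequence[float]) -> float:
    """Solve ``1 + λ = Π (1 + λ g_i)`` for the unique λ in (−1, ∞).

    λ = 0 when the densities already sum to 1 (additive measure); λ < 0
    when they oversum (sub-additive correction) and λ > 0 when they
    undersum.  Root-finding is bracketed bisection/Brent to a residual
    below 1e-12.
    """
    g = np.asarray(densities, dtype=float)
    if g.ndim != 1 or g.size < 1:
        raise ValueError("densities must be a 1-D sequence")
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError("densities must lie in [0, 1]")
    nonzero = g[g > 0]
    if nonzero.size == 0:
        raise DegenerateMeasureError("all densities are zero")
    total = float(g.sum())
    if abs(total - 1.0) <= _TOL:
        return 0.0
    if nonzero.size == 1:
        # single nonzero density: normalization forces g_i = 1, no finite λ
        raise DegenerateMeasureError(
            "need at least two nonzero densities for a non-additive measure"
        )
    if np.any(g >= 1.0) and total > 1.0:
        # a certain classifier alongside other mass pushes λ to the -1 boundary
        raise DegenerateMeasureError(
            "density 1 alongside other nonzero densities is degenerate"
        )
    if total > 1.0:
        hi = -1e-12
        lo = None
        for delta in (1e-12, 1e-13, 1e-14, 1e-15):
            cand = -1.0 + delta
            if _lambda_residual(cand, g) > 0:
                lo = cand
                break
        if lo is None:  # root indistinguishable from -1 at double precision
            raise DegenerateMeasureError("no resolvable root in (-1, 0)")
    else:
        lo, hi = 1e-12, 2.0
        while _lambda_residual(hi, g) <= 0:
            hi *= 2.0
            if hi > 1e12:
                raise DegenerateMeasureError("failed to bracket λ > 0")
    lam = float(brentq(_lambda_residual, lo, hi, args=(g,), xtol=1e-15, rtol=1e-15))
    # polish with Newton steps so the residual is comfortably < 1e-12
    for _ in range(3):
        r = _lambda_residual(lam, g)
        if abs(r) < 1e-14:
            break
        dr = float(
            np.sum(g / (1.0 + lam * g)) * np.prod(1.0 + lam * g) - 1.0
        )
        if dr == 0:
            break
        lam -= r / dr
    return lam


@dataclass(frozen=True)
class FuzzyMeasure:
    """Sugeno λ-measure over a finite set of classifiers.

    Attributes
    ----------
    densities
        Singleton measures ``g_i``, one per classifier, each in [0, 1].
    lam
        The normalizing λ (> −1); 0 for an additive measure.
    element_labels
        Classifier identifiers, in the same order as ``densities``.
    """

    densities: tuple[float, ...]
    lam: float
    element_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        g = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "densities", tuple(float(x) for x in g))
        if not self.element_labels:
            object.__setattr__(
                self, "element_labels", tuple(f"c{i}" for i in range(g.size))
            )
        if len(self.element_labels) != g.size:
            raise ValueError("element_labels must match densities in length")
        if self.lam <= -1.0:
            raise ValueError("λ must exceed -1")
        if abs(_lambda_residual(self.lam, g)) > 1e-6:
            raise ValueError("λ does not normalize these densities")

    @classmethod
    def from_densities(
        cls, densities: Sequence[float], element_labels: Iterable[str] = ()
    ) -> "FuzzyMeasure":
        """Build a measure by solving for λ from the densities."""
        lam = sugeno_lambda_solve(densities)
        return cls(tuple(float(d) for d in densities), lam, tuple(element_labels))

    @property
    def n(self) -> int:
        return len(self.densities)

    def g(self, subset: Iterable[int]) -> float:
        """Measure of a classifier subset, by the closed form.

        ``g(A) = (Π_{i∈A} (1 + λ g_i) − 1) / λ``, reducing to ``Σ g_i``
        for λ = 0.
        """
        idx = sorted(set(subset))
        if not idx:
            return 0.0
        if any(i < 0 or i >= self.n for i in idx):
            raise IndexError("subset index out of range")
        gi = np.asarray(self.densities, dtype=float)[idx]
        if self.lam == 0.0:
            val = float(gi.sum())
        else:
            val = float((np.prod(1.0 + self.lam * gi) - 1.0) / self.lam)
        if len(idx) == self.n:
            return 1.0
        return min(max(val, 0.0), 1.0)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.element_labels),
            "densities": list(self.densities),
            "lambda": self.lam,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyMeasure":
        return cls(tuple(d["densities"]), float(d["lambda"]), tuple(d["labels"]))


@dataclass(frozen=True)
class SortedProfile:
    """Non-increasing rearrangement of the integrand values.

    ``values`` holds ``h(x_(1)) ≥ … ≥ h(x_(n))`` with a trailing
    ``h(x_(n+1)) = 0``; ``permutation`` maps sorted position to original
    index, so ``cumulative_sets[i]`` (the top-(i+1) set ``A_{i+1}``) is
    ``permutation[:i+1]``.
    """

    values: tuple[float, ...]
    permutation: tuple[int, ...]

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SortedProfile":
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        order = np.argsort(-v, kind="stable")  # ties keep original index order
        return cls(
            tuple(float(x) for x in v[order]) + (0.0,),
            tuple(int(i) for i in order),
        )

    @property
    def n(self) -> int:
        return len(self.permutation)

    def cumulative_set(self, i: int) -> tuple[int, ...]:
        """Original indices of the top-``i`` set ``A_i`` (1-based ``i``)."""
        if not 1 <= i <= self.n:
            raise IndexError(f"i must be in [1, {self.n}]")
        return self.permutation[:i]


def measure_of_nested_set(measure: FuzzyMeasure, profile: SortedProfile, i: int) -> float:
    """``g(A_i)`` for the nested top-``i`` set, via the λ recurrence.

    ``g(A_1) = g_(1)``; ``g(A_{i+1}) = g(A_i) + g_(i+1) + λ g_(i+1) g(A_i)``.
    The full set returns 1 (normalization).
    """
    if not 1 <= i <= profile.n:
        raise IndexError(f"i must be in [1, {profile.n}]")
    dens = np.asarray(measure.densities, dtype=float)[list(profile.permutation)]
    acc = float(dens[0])
    for k in range(1, i):
        acc = acc + dens[k] + measure.lam * dens[k] * acc
    return acc


def _nested_measures(measure: FuzzyMeasure, profile: SortedProfile) -> np.ndarray:
    dens = np.asarray(measure.densities, dtype=float)[list(profile.permutation)]
    out = np.empty(profile.n)
    acc = 0.0
    for k in range(profile.n):
        acc = acc + dens[k] + measure.lam * dens[k] * acc if k else float(dens[0])
        out[k] = acc
    return out


def _validated(values: Sequence[float], measure: FuzzyMeasure) -> SortedProfile:
    v = np.asarray(values, dtype=float)
    if v.size != measure.n:
        raise ValueError(
            f"dimension mismatch: {v.size} values vs measure over {measure.n}"
        )
    return SortedProfile.from_values(v)


def choquet_integral(values: Sequence[float], measure: FuzzyMeasure) -> float:
    """Discrete Choquet integral ``Σ_i (h_(i) − h_(i+1)) g(A_i)``.

    Idempotent, monotone and internal: the result lies between the min and
    the max of ``values``.  Reduces to the weighted arithmetic mean for an
    additive measure.
    """
    profile = _validated(values, measure)
    h = np.asarray(profile.values)
    gA = _nested_measures(measure, profile)
    return float(np.sum((h[:-1] - h[1:]) * gA))


def sugeno_integral(values: Sequence[float], measure: FuzzyMeasure) -> float:
    """Discrete Sugeno integral ``max_i min(h_(i), g(A_i))``."""
    profile = _validated(values, measure)
    h = np.asarray(profile.values)[:-1]
    gA = _nested_measures(measure, profile)
    return float(np.max(np.minimum(h, gA)))


def _as_binary(m: OperatorSpec | Callable) -> Callable:
    if isinstance(m, OperatorSpec):
        if m.name == "minimum":  # the minimum t-norm, registered n-ary
            return np.minimum
        if m.arity != "bivariate":
            raise ValueError(f"{m.name} is not bivariate; the integral needs a t-norm")
        return _bound_func(m)
    return m


def generalized_integral_cmmin(
    values: Sequence[float], measure: FuzzyMeasure, m: OperatorSpec | Callable
) -> float:
    """Pre-aggregation integral ``Σ_i M(Δ_i, g(A_i))`` (CC-integral style).

    ``Δ_i = min(h_(i), g(A_i)) − min(h_(i+1), g(A_i))`` is the capped
    Sugeno-type increment and ``M`` any t-norm.  The sum is clamped to
    [0, 1]; with ``M = min`` and an additive measure this is close to, but
    not generally equal to, the Choquet integral.
    """
    func = _as_binary(m)
    profile = _validated(values, measure)
    h = np.asarray(profile.values)
    gA = _nested_measures(measure, profile)
    delta = np.minimum(h[:-1], gA) - np.minimum(h[1:], gA)
    total = float(np.sum(func(delta, gA)))
    return min(max(total, 0.0), 1.0)


def generalized_integral_cminm(
    values: Sequence[float], measure: FuzzyMeasure, m: OperatorSpec | Callable
) -> float:
    """Pre-aggregation integral with ``M`` applied inside the cap.

    ``Σ_i [min(M(h_(i), g(A_i)), g(A_i)) − min(M(h_(i+1), g(A_i)), g(A_i))]``,
    clamped to [0, 1].
    """
    func = _as_binary(m)
    profile = _validated(values, measure)
    h = np.asarray(profile.values)
    gA = _nested_measures(measure, profile)
    hi = np.minimum(func(h[:-1], gA), gA)
    lo = np.minimum(func(h[1:], gA), gA)
    total = float(np.sum(hi - lo))
    return min(max(total, 0.0), 1.0)


def enumerate_measure(measure: FuzzyMeasure) -> dict[frozenset, float]:
    """All subset measures via the closed form (oracle/diagnostic helper)."""
    out: dict[frozenset, float] = {frozenset(): 0.0}
    for k in range(1, measure.n + 1):
        for subset in combinations(range(measure.n), k):
            out[frozenset(subset)] = measure.g(subset)
    return out
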