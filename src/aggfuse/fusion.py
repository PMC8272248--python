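"""Classifier fusion: combining per-classifier class probabilities.

Each base classifier emits, for every observation, a probability vector
over the three workload classes.  Fusion aggregates, class by class, the
probabilities assigned by all classifiers with a chosen aggregation
operator (n-ary directly, bivariate via a left fold, fuzzy integrals
against a Sugeno λ-measure whose densities are the classifiers'
cross-validated accuracies), then predicts the argmax class.

The module also expands the operator registry into parameter grids and
ranks every expanded variant by validation accuracy.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import operators as ops
from .measures import (
    DegenerateMeasureError,
    FuzzyMeasure,
    choquet_integral,
    generalized_integral_cmmin,
    generalized_integral_cminm,
    sugeno_integral,
)

log = logging.getLogger(__name__)

__all__ = [
    "ProbabilityCube",
    "FusionResult",
    "EvaluationReport",
    "integral_spec",
    "INTEGRAL_OPERATORS",
    "measure_from_accuracies",
    "derive_densities_cv",
    "fuse",
    "expand_param_grids",
    "default_param_grids",
    "compact_param_grids",
    "dominance_param_grids",
    "grid_search_operators",
]

CLASS_LABELS = ("low", "medium", "high")

#: integral-type fusion rules evaluated against a fuzzy measure
INTEGRAL_OPERATORS = (
    "choquet_integral",
    "sugeno_integral",
    "generalized_cmmin",
    "generalized_cminm",
)

#: upper clip for accuracy-derived densities: keeps the λ-measure
#: normalization solvable in double precision for up to ~10 classifiers
_DENSITY_CAP = 0.98


# ---------------------------------------------------------------------------
# Probability cube
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbabilityCube:
    """(observations × classifiers × classes) class-membership probabilities.

    Every (observation, classifier) row must sum to 1 within 1e-6.
    """

    values: np.ndarray
    classifier_labels: tuple[str, ...]
    class_labels: tuple[str, ...] = CLASS_LABELS
    observation_ids: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 3:
            raise ValueError("cube must be 3-D (obs × classifiers × classes)")
        if v.shape[1] != len(self.classifier_labels):
            raise ValueError("classifier_labels does not match cube shape")
        if v.shape[2] != len(self.class_labels):
            raise ValueError("class_labels does not match cube shape")
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        sums = v.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(f"rows must sum to 1 (worst deviation {worst:g})")
        if not self.observation_ids:
            object.__setattr__(self, "observation_ids", tuple(range(v.shape[0])))

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    @property
    def n_classifiers(self) -> int:
        return self.values.shape[1]

    def to_long_frame(self) -> pd.DataFrame:
        """Long CSV layout: observation_id, classifier, class, probability."""
        n_o, n_c, n_k = self.values.shape
        return pd.DataFrame(
            {
                "observation_id": np.repeat(list(self.observation_ids), n_c * n_k),
                "classifier": list(
                    np.tile(np.repeat(self.classifier_labels, n_k), n_o)
                ),
                "class": list(np.tile(self.class_labels, n_o * n_c)),
                "probability": self.values.ravel(),
            }
        )

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "ProbabilityCube":
        required = {"observation_id", "classifier", "class", "probability"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        obs = list(dict.fromkeys(frame["observation_id"]))
        clf = tuple(sorted(frame["classifier"].unique()))
        klass = tuple(
            k for k in CLASS_LABELS if k in set(frame["class"])
        ) or tuple(sorted(frame["class"].unique()))
        pivot = frame.set_index(["observation_id", "classifier", "class"])[
            "probability"
        ]
        values = np.empty((len(obs), len(clf), len(klass)))
        for i, o in enumerate(obs):
            for j, c in enumerate(clf):
                for k, cl in enumerate(klass):
                    values[i, j, k] = pivot[(o, c, cl)]
        return cls(values, clf, klass, tuple(obs))

    def to_json(self) -> str:
        return json.dumps(
            {
                "classifier_labels": list(self.classifier_labels),
                "class_labels": list(self.class_labels),
                "observation_ids": list(self.observation_ids),
                "values": self.values.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ProbabilityCube":
        d = json.loads(text)
        return cls(
            np.asarray(d["values"], dtype=float),
            tuple(d["classifier_labels"]),
            tuple(d["class_labels"]),
            tuple(d["observation_ids"]),
        )


@dataclass(frozen=True)
class FusionResult:
    """Fused class scores and argmax labels for one operator."""

    fused_scores: np.ndarray  # (n_observations, n_classes)
    labels: np.ndarray  # int class indices
    operator: ops.OperatorSpec
    measure_or_weights: object = None
    class_labels: tuple[str, ...] = CLASS_LABELS

    @property
    def label_names(self) -> list[str]:
        return [self.class_labels[i] for i in self.labels]


# ---------------------------------------------------------------------------
# Integral operator specs and measures
# ---------------------------------------------------------------------------


def integral_spec(name: str, tnorm: str | None = None, **tnorm_params) -> ops.OperatorSpec:
    """Spec for a fuzzy-integral fusion rule.

    ``tnorm`` (a registered bivariate operator name, with its parameters)
    is required for the two generalized pre-aggregation forms and ignored
    for the plain Choquet and Sugeno integrals.
    """
    if name not in INTEGRAL_OPERATORS:
        raise ops.OperatorError(f"unknown integral operator {name!r}")
    params: dict = {}
    if name in ("generalized_cmmin", "generalized_cminm"):
        if tnorm is None:
            raise ops.OperatorError(f"{name} requires a t-norm choice")
        if tnorm not in ops.OPERATOR_REGISTRY:
            raise ops.OperatorError(f"unknown t-norm {tnorm!r}")
        params["tnorm"] = tnorm
        params.update(tnorm_params)
    return ops.OperatorSpec(
        name=name, arity="nary", params=params, requires_measure=True
    )


def measure_from_accuracies(
    accuracies: Sequence[float], labels: Sequence[str] = ()
) -> FuzzyMeasure:
    """Sugeno λ-measure with cross-validated accuracies as densities.

    Accuracies are used unnormalized (λ absorbs the deviation of their sum
    from 1) but clipped into ``[1e-3, 0.98]`` so the normalization root
    stays resolvable in floating point.
    """
    g = np.clip(np.asarray(accuracies, dtype=float), 1e-3, _DENSITY_CAP)
    return FuzzyMeasure.from_densities(g, tuple(labels))


def derive_densities_cv(
    train_table: pd.DataFrame,
    classifier_names: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-classifier fuzzy-measure densities from grouped cross-validation.

    Runs ``n_folds``-fold cross-validation on the training table with folds
    grouped by participant (subject-independent) and returns each
    classifier's mean fold accuracy, in the order of ``classifier_names``.
    """
    from .pipeline import feature_matrix, make_classifier  # deferred import

    participants = np.asarray(sorted(train_table["participant_id"].unique()))
    if len(participants) < n_folds:
        raise ValueError(
            f"{len(participants)} participants cannot form {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(participants))
    fold_of = {p: i % n_folds for i, p in enumerate(participants[order])}
    folds = train_table["participant_id"].map(fold_of).to_numpy()

    import warnings

    from sklearn.exceptions import ConvergenceWarning

    X, y, _ = feature_matrix(train_table, feature_columns)
    densities = np.zeros(len(classifier_names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for ci, name in enumerate(classifier_names):
            accs = []
            for f in range(n_folds):
                tr, te = folds != f, folds == f
                clf = make_classifier(name, seed=seed + 7919 * f)
                clf.fit(X[tr], y[tr])
                accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
            densities[ci] = float(np.mean(accs))
    return densities


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------


def _integral_value(
    op: ops.OperatorSpec, values: np.ndarray, measure: FuzzyMeasure
) -> float:
    if op.name == "choquet_integral":
        return choquet_integral(values, measure)
    if op.name == "sugeno_integral":
        return sugeno_integral(values, measure)
    params = dict(op.params)
    tnorm = ops.get_operator(
        params.pop("tnorm"), **{k: v for k, v in params.items()}
    )
    if op.name == "generalized_cmmin":
        return generalized_integral_cmmin(values, measure, tnorm)
    return generalized_integral_cminm(values, measure, tnorm)


def fuse(
    cube: ProbabilityCube,
    op: ops.OperatorSpec,
    weights_or_measure=None,
    fold_order: str = "registry",
) -> FusionResult:
    """Fuse a probability cube into class scores and labels.

    For each observation and class the classifier probabilities are
    aggregated with ``op``; the predicted label is the argmax over classes,
    ties broken by the lowest class index.  Fused scores are not
    renormalized across classes.
    """
    n_o, _, n_k = cube.values.shape
    scores = np.empty((n_o, n_k))
    if op.requires_measure:
        measure = weights_or_measure
        if not isinstance(measure, FuzzyMeasure):
            raise ValueError(f"{op.name} requires a FuzzyMeasure")
        for i in range(n_o):
            for j in range(n_k):
                scores[i, j] = _integral_value(op, cube.values[i, :, j], measure)
    elif op.requires_weights:
        if weights_or_measure is None:
            raise ValueError(f"{op.name} requires weights")
        w = np.asarray(weights_or_measure, dtype=float)
        for j in range(n_k):
            scores[:, j] = ops.evaluate_operator(op, cube.values[:, :, j], weights=w)
    else:
        for j in range(n_k):
            scores[:, j] = ops.evaluate_operator(
                op, cube.values[:, :, j], fold_order=fold_order
            )
    labels = np.argmax(scores, axis=1)  # first max wins: lowest class index
    return FusionResult(scores, labels, op, weights_or_measure, cube.class_labels)


# ---------------------------------------------------------------------------
# Parameter grids and grid search
# ---------------------------------------------------------------------------


def _owa_weight_family(n: int) -> dict[str, np.ndarray]:
    """A few standard OWA weight profiles for ``n`` inputs."""
    fams = {
        "uniform": np.full(n, 1.0 / n),
        "max": np.eye(n)[0],
        "min": np.eye(n)[-1],
    }
    if n >= 3:
        olympic = np.full(n, 1.0 / (n - 2))
        olympic[0] = olympic[-1] = 0.0
        fams["olympic"] = olympic
    for q in (0.25, 0.75):
        # linear quantifier-style weights tilted toward the top (q<0.5) or
        # bottom (q>0.5) order statistics
        raw = np.linspace(1 - q, q, n)
        fams[f"linear_{q:g}"] = raw / raw.sum()
    return fams


def default_param_grids() -> dict[str, list[dict]]:
    """The full sweep: parameter grids expanding to >2000 operator variants.

    The two-branch generalized-Choquet family is swept on a fine 51×51
    grid of its (a, b) parameters — this is the >1000-member
    pre-aggregation family — alongside Stolarsky exponents, generator
    t-norm shapes, OWA weight profiles, the parameterless operators and
    the four fuzzy-integral rules with several t-norm choices.
    """
    ab = np.round(np.linspace(0.0, 1.0, 51), 4)
    grids: dict[str, list[dict]] = {
        "generalized_choquet_form": [
            {"a": float(a), "b": float(b)} for a, b in itertools.product(ab, ab)
        ],
        "stolarsky_mean": [{"r": float(r)} for r in (-2.0, -1.0, 0.5, 2.0, 3.0)],
        "exp_generator_tnorm": [
            {"alpha": float(a)} for a in np.round(np.arange(0.5, 5.01, 0.1), 2)
        ],
    }
    for name in (
        "lukasiewicz_mean_blend",
        "sp_symmetric_sum",
        "log_generator_aggregation",
        "censored_midpoint",
        "bertino_form",
        "max_symmetric_sum",
        "arithmetic_mean",
        "quadratic_mean",
        "geometric_mean",
        "median",
        "weighted_median",
        "weighted_mean",
        "weighted_ratio_aggregation",
        "minimum",
        "maximum",
        "product_tnorm",
        "lukasiewicz_tnorm",
        "einstein_tnorm",
        "owa",
    ):
        grids[name] = [{}]
    grids["choquet_integral"] = [{}]
    grids["sugeno_integral"] = [{}]
    tnorms = [
        {"tnorm": "minimum"},
        {"tnorm": "product_tnorm"},
        {"tnorm": "lukasiewicz_tnorm"},
        {"tnorm": "einstein_tnorm"},
    ] + [{"tnorm": "exp_generator_tnorm", "alpha": float(a)} for a in (1.0, 2.0, 3.3, 5.0)]
    grids["generalized_cmmin"] = list(tnorms)
    grids["generalized_cminm"] = list(tnorms)
    return grids


def compact_param_grids() -> dict[str, list[dict]]:
    """A representative sub-grid for repeated-protocol experiments.

    Keeps the ten headline operators at (and around) their reported
    operating points, the OWA/weighted families, the standard means and
    the four integral rules — small enough to evaluate inside a repeated
    subject-independent protocol.
    """
    grids = default_param_grids()
    ab = (0.01, 0.25, 0.5, 0.75, 0.99)
    grids["generalized_choquet_form"] = [
        {"a": float(a), "b": float(b)} for a, b in itertools.product(ab, ab)
    ]
    grids["stolarsky_mean"] = [{"r": float(r)} for r in (-1.0, 2.0, 3.0)]
    grids["exp_generator_tnorm"] = [{"alpha": float(a)} for a in (1.0, 3.3)]
    tnorms = [
        {"tnorm": "minimum"},
        {"tnorm": "product_tnorm"},
        {"tnorm": "exp_generator_tnorm", "alpha": 3.3},
    ]
    grids["generalized_cmmin"] = list(tnorms)
    grids["generalized_cminm"] = list(tnorms)
    return grids


def dominance_param_grids() -> dict[str, list[dict]]:
    """Grid for fusion-vs-individual dominance experiments (~600 variants).

    Densifies the two-branch generalized-Choquet family (including
    descending-fold variants) and adds descending-fold versions of the
    other bivariate headline operators on top of the compact grid, while
    staying cheap enough for repeated-protocol use.
    """
    grids = compact_param_grids()
    ab21 = np.round(np.linspace(0.0, 1.0, 21), 3)
    ab11 = np.round(np.linspace(0.0, 1.0, 11), 2)
    grids["generalized_choquet_form"] = [
        {"a": float(a), "b": float(b)} for a, b in itertools.product(ab21, ab21)
    ] + [
        {"a": float(a), "b": float(b), "fold_order": "descending"}
        for a, b in itertools.product(ab11, ab11)
    ]
    grids["stolarsky_mean"] = [
        {"r": float(r), **extra}
        for r in (-1.0, 2.0, 3.0)
        for extra in ({}, {"fold_order": "descending"})
    ]
    for name in (
        "lukasiewicz_mean_blend",
        "sp_symmetric_sum",
        "log_generator_aggregation",
        "censored_midpoint",
        "bertino_form",
        "max_symmetric_sum",
    ):
        grids[name] = [{}, {"fold_order": "descending"}]
    grids["exp_generator_tnorm"] = [
        {"alpha": float(a)} for a in (0.5, 1.0, 2.0, 3.3, 5.0)
    ]
    return grids


def expand_param_grids(
    param_grids: Mapping[str, list[dict]] | None = None,
) -> list[ops.OperatorSpec]:
    """Expand grids into concrete :class:`OperatorSpec` variants.

    ``owa`` is expanded lazily at fusion time into its weight-profile
    family; here it contributes one spec per profile name via the
    ``profile`` parameter.
    """
    grids = default_param_grids() if param_grids is None else dict(param_grids)
    specs: list[ops.OperatorSpec] = []
    for name in sorted(grids):
        for params in grids[name]:
            if name in INTEGRAL_OPERATORS:
                p = dict(params)
                specs.append(integral_spec(name, **p))
            elif name == "owa":
                for profile in sorted(_owa_weight_family(3)):  # n resolved later
                    specs.append(
                        ops.OperatorSpec(
                            name="owa",
                            arity="nary",
                            params={"profile": profile},
                            requires_weights=True,
                        )
                    )
            else:
                specs.append(ops.get_operator(name, **params))
    return specs


@dataclass
class EvaluationReport:
    """Ranked per-operator (and per-classifier) accuracies.

    ``entries`` has one row per evaluated entry with columns ``name``,
    ``kind`` (``operator`` or ``classifier``), ``mean_accuracy``,
    ``sd_accuracy`` and ``n_repetitions``; ``per_repetition`` maps entry
    name to the accuracy trace.  The ranking is sorted by mean accuracy
    descending with alphabetical tie-break.
    """

    entries: pd.DataFrame
    per_repetition: dict[str, list[float]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def ranking(self) -> pd.DataFrame:
        return self.entries.sort_values(
            ["mean_accuracy", "name"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)

    def best(self, kind: str = "operator") -> pd.Series:
        sub = self.ranking[self.ranking["kind"] == kind]
        if sub.empty:
            raise ValueError(f"no entries of kind {kind!r}")
        return sub.iloc[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "entries": self.entries.to_dict(orient="records"),
                "per_repetition": self.per_repetition,
                "metadata": self.metadata,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(
            pd.DataFrame(d["entries"]),
            {k: list(v) for k, v in d["per_repetition"].items()},
            d["metadata"],
        )


def _resolve_weights(
    spec: ops.OperatorSpec, weights: np.ndarray, n_classifiers: int
):
    """Weight vector appropriate for a weight-taking operator.

    Raw accuracies for the ratio form and weighted mean/median; sorted,
    sum-1-normalized weights for OWA profiles.
    """
    if spec.name == "owa":
        profile = spec.params.get("profile")
        if profile is not None:
            return _owa_weight_family(n_classifiers)[profile]
        w = np.sort(weights)[::-1]
        return w / w.sum()
    return weights


def apply_operator_to_cube(
    spec: ops.OperatorSpec,
    cube: ProbabilityCube,
    measure: FuzzyMeasure | None,
    weights: np.ndarray | None,
    fold_order: str = "registry",
) -> FusionResult:
    """Dispatch one grid variant on a cube with the right auxiliary data."""
    if spec.requires_measure:
        return fuse(cube, spec, measure)
    if spec.requires_weights:
        if weights is None:
            raise ValueError(f"{spec.label} requires weights")
        w = _resolve_weights(spec, np.asarray(weights, dtype=float), cube.n_classifiers)
        if spec.name == "owa":
            scores, labels = _fuse_owa(cube, w)
            return FusionResult(scores, labels, spec, w, cube.class_labels)
        return fuse(cube, spec, w)
    return fuse(cube, spec, fold_order=fold_order)


def _fuse_owa(cube: ProbabilityCube, w: np.ndarray):
    n_o, _, n_k = cube.values.shape
    scores = np.empty((n_o, n_k))
    for j in range(n_k):
        scores[:, j] = ops.owa(cube.values[:, :, j], w)
    return scores, np.argmax(scores, axis=1)


def grid_search_operators(
    cube_train: ProbabilityCube | None,
    y_train: np.ndarray | None,
    cube_val: ProbabilityCube,
    y_val: np.ndarray,
    param_grids: Mapping[str, list[dict]] | None = None,
    measure: FuzzyMeasure | None = None,
    weights: np.ndarray | None = None,
    fold_order: str = "registry",
) -> EvaluationReport:
    """Rank every expanded operator variant by validation accuracy.

    When ``weights``/``measure`` are not supplied they are derived from
    the training cube: each classifier's accuracy on the training
    observations becomes its weight and its λ-measure density.
    """
    y_val = np.asarray(y_val)
    if weights is None:
        if cube_train is None or y_train is None:
            raise ValueError("supply weights/measure or a training cube")
        y_train = np.asarray(y_train)
        preds = np.argmax(cube_train.values, axis=2)
        weights = (preds == y_train[:, None]).mean(axis=0)
    if measure is None:
        measure = measure_from_accuracies(weights, cube_val.classifier_labels)

    specs = expand_param_grids(param_grids)
    records = []
    per_rep: dict[str, list[float]] = {}
    for spec in specs:
        try:
            result = apply_operator_to_cube(
                spec, cube_val, measure, weights, fold_order
            )
            acc = float(np.mean(result.labels == y_val))
        except DegenerateMeasureError:
            acc = float("nan")
        records.append(
            {
                "name": spec.label,
                "kind": "operator",
                "mean_accuracy": acc,
                "sd_accuracy": 0.0,
                "n_repetitions": 1,
            }
        )
        per_rep[spec.label] = [acc]
    entries = pd.DataFrame(records)
    log.info("grid search evaluated %d operator variants", len(specs))
    return EvaluationReport(
        entries,
        per_rep,
        metadata={
            "n_variants": len(specs),
            "n_validation_observations": cube_val.n_observations,
            "fold_order": fold_order,
        },
    )
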