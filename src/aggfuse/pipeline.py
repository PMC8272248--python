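"""Subject-independent evaluation protocol for workload classification.

The protocol mirrors a three-class (low/medium/high cognitive workload)
classification study on a per-participant feature table: z-score
normalization fitted on training data, ANOVA-based feature selection with
normality/homogeneity screens and Tukey HSD post-hoc tests, a roster of
eight standard classifiers, and repeated train/test splits grouped by
participant (six held-out participants, i.e. 18 balanced test
observations per repetition).  Each repetition also derives fuzzy-measure
densities from grouped cross-validation and scores every fusion operator
in a grid alongside the individual classifiers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .fusion import (
    EvaluationReport,
    ProbabilityCube,
    apply_operator_to_cube,
    compact_param_grids,
    derive_densities_cv,
    dominance_param_grids,
    expand_param_grids,
    measure_from_accuracies,
)
from .synthetic import CLASS_LABELS

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ROSTER",
    "SelectionReport",
    "make_classifier",
    "feature_columns",
    "feature_matrix",
    "Normalizer",
    "normalize_features",
    "anova_feature_selection",
    "subject_independent_split",
    "train_base_classifiers",
    "ClassifierEnsemble",
    "quick_accuracy",
    "evaluate_protocol",
]

_META_COLUMNS = ("participant_id", "label")

#: the eight base models, in fixed (alphabetical) registry order — this is
#: also the left-fold order for bivariate fusion operators
DEFAULT_ROSTER = (
    "cubic_svm",
    "decision_tree",
    "knn",
    "linear_svm",
    "logistic_regression",
    "mlp",
    "quadratic_svm",
    "random_forest",
)


def make_classifier(name: str, seed: int = 0):
    """Instantiate a base classifier by roster name.

    Margin-based SVMs are wrapped in sigmoid (Platt) calibration fitted on
    internal training folds so they emit class probabilities.
    """

    def _svm(kernel: str, degree: int = 3) -> CalibratedClassifierCV:
        base = SVC(kernel=kernel, degree=degree, coef0=1.0 if kernel == "poly" else 0.0,
                   random_state=seed)
        return CalibratedClassifierCV(base, method="sigmoid", cv=5, ensemble=False)

    if name == "linear_svm":
        return _svm("linear")
    if name == "quadratic_svm":
        return _svm("poly", 2)
    if name == "cubic_svm":
        return _svm("poly", 3)
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=60, random_state=seed)
    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=300,
                             random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLUMNS]


def feature_matrix(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X, y, feature names) with labels encoded as 0/1/2 = low/medium/high."""
    cols = list(columns) if columns is not None else feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = table["label"].map({c: i for i, c in enumerate(CLASS_LABELS)}).to_numpy()
    if np.any(pd.isna(y)):
        raise ValueError(f"labels must be one of {CLASS_LABELS}")
    return X, y, cols


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass
class Normalizer:
    """Z-score normalizer with statistics estimated on the training subset.

    Zero-variance features are dropped (with a warning) rather than
    divided by zero; ``inverse_transform`` recovers original values from
    z-scores via ``x = μ + σ z``.
    """

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str] = field(default_factory=list)

    @classmethod
    def fit(cls, table: pd.DataFrame, columns: Sequence[str] | None = None
            ) -> "Normalizer":
        cols = list(columns) if columns is not None else feature_columns(table)
        if table.empty:
            raise ValueError("cannot fit a normalizer on an empty table")
        X = table[cols].to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        # relative threshold: a constant feature's std is float noise, not 0
        keep = sd > 1e-12 * np.maximum(1.0, np.abs(mu))
        dropped = [c for c, k in zip(cols, keep) if not k]
        if dropped:
            log.warning("dropping zero-variance features: %s", dropped)
        return cls(
            [c for c, k in zip(cols, keep) if k], mu[keep], sd[keep], dropped
        )

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table[[c for c in _META_COLUMNS if c in table.columns]].copy()
        Z = (table[self.columns].to_numpy(dtype=float) - self.means) / self.sds
        out[self.columns] = Z
        return out

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table[[c for c in _META_COLUMNS if c in table.columns]].copy()
        X = table[self.columns].to_numpy(dtype=float) * self.sds + self.means
        out[self.columns] = X
        return out


def normalize_features(
    table: pd.DataFrame,
    stats_from: pd.DataFrame | None = None,
    columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, Normalizer]:
    """Z-score ``table`` using statistics from ``stats_from`` (training data).

    Returns the transformed table and the fitted normalizer.  When
    ``stats_from`` is omitted the statistics come from ``table`` itself.
    """
    norm = Normalizer.fit(stats_from if stats_from is not None else table, columns)
    return norm.transform(table), norm


# ---------------------------------------------------------------------------
# Statistical feature selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionReport:
    """Per-feature screening, ANOVA and post-hoc results.

    ``table`` columns: ``ks_p`` (normality of within-class z-scores),
    ``levene_p`` (variance homogeneity), ``screen_failed``, ``anova_p``
    and Tukey HSD p-values per class pair (NaN when ANOVA is not
    significant); ``selected`` flags ANOVA p < alpha on features passing
    the screens (or all features, when screen failures are included).
    """

    table: pd.DataFrame
    alpha: float
    screen_alpha: float
    include_screen_failures: bool

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    @property
    def screened_out(self) -> list[str]:
        return list(self.table.index[self.table["screen_failed"]])


def anova_feature_selection(
    table: pd.DataFrame,
    alpha: float = 0.05,
    screen_alpha: float = 0.05,
    include_screen_failures: bool = False,
    columns: Sequence[str] | None = None,
) -> SelectionReport:
    """One-way ANOVA feature selection with screens and Tukey post-hoc.

    Per feature: a Kolmogorov–Smirnov normality check on within-class
    standardized residuals and Levene's homogeneity-of-variance test act
    as screens; features failing either (p < ``screen_alpha``) are by
    default excluded from selection.  One-way ANOVA across the three
    workload classes selects features with p < ``alpha``; Tukey's HSD
    identifies which class pairs differ for the significant features.
    """
    cols = list(columns) if columns is not None else feature_columns(table)
    labels = table["label"].to_numpy()
    groups_by_class = {c: table.loc[labels == c, cols] for c in CLASS_LABELS}
    sizes = [len(g) for g in groups_by_class.values()]
    if sum(s >= 2 for s in sizes) < 2:
        raise ValueError("need at least 2 classes with >= 2 observations")

    pairs = [(0, 1), (0, 2), (1, 2)]
    pair_names = [f"tukey_p_{CLASS_LABELS[a]}_{CLASS_LABELS[b]}" for a, b in pairs]
    rows = []
    for feat in cols:
        gs = [groups_by_class[c][feat].to_numpy(dtype=float) for c in CLASS_LABELS]
        resid = np.concatenate([(g - g.mean()) / (g.std(ddof=1) or 1.0) for g in gs])
        ks_p = float(stats.kstest(resid, "norm").pvalue)
        levene_p = float(stats.levene(*gs).pvalue)
        anova_p = float(stats.f_oneway(*gs).pvalue)
        screen_failed = (ks_p < screen_alpha) or (levene_p < screen_alpha)
        row = {
            "ks_p": ks_p,
            "levene_p": levene_p,
            "screen_failed": screen_failed,
            "anova_p": anova_p,
        }
        significant = anova_p < alpha
        if significant:
            tuk = stats.tukey_hsd(*gs)
            row[pair_names[0]] = float(tuk.pvalue[0, 1])
            row[pair_names[1]] = float(tuk.pvalue[0, 2])
            row[pair_names[2]] = float(tuk.pvalue[1, 2])
        else:
            row.update({p: float("nan") for p in pair_names})
        row["selected"] = bool(
            significant and (include_screen_failures or not screen_failed)
        )
        rows.append(row)
    report = pd.DataFrame(rows, index=pd.Index(cols, name="feature"))
    return SelectionReport(report, alpha, screen_alpha, include_screen_failures)


# ---------------------------------------------------------------------------
# Splitting and base classifiers
# ---------------------------------------------------------------------------


def subject_independent_split(
    table: pd.DataFrame, n_test_participants: int = 6, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out all rows of ``n_test_participants`` random participants."""
    participants = np.asarray(sorted(table["participant_id"].unique()))
    if len(participants) <= n_test_participants:
        raise ValueError(
            f"{len(participants)} participants cannot spare "
            f"{n_test_participants} for testing"
        )
    rng = np.random.default_rng(seed)
    test_ids = set(rng.choice(participants, n_test_participants, replace=False))
    mask = table["participant_id"].isin(test_ids).to_numpy()
    return table.loc[~mask].reset_index(drop=True), table.loc[mask].reset_index(
        drop=True
    )


@dataclass
class ClassifierEnsemble:
    """Fitted base classifiers sharing one feature space."""

    models: dict[str, object]
    feature_names: list[str]

    @property
    def roster(self) -> tuple[str, ...]:
        return tuple(self.models)

    def predict_cube(self, table: pd.DataFrame) -> ProbabilityCube:
        """Per-classifier class probabilities for every row of ``table``."""
        X = table[self.feature_names].to_numpy(dtype=float)
        cube = np.stack(
            [self.models[name].predict_proba(X) for name in self.roster], axis=1
        )
        cube = np.clip(cube, 0.0, 1.0)
        cube /= cube.sum(axis=2, keepdims=True)
        return ProbabilityCube(cube, self.roster)

    def accuracies(self, table: pd.DataFrame) -> dict[str, float]:
        X, y, _ = feature_matrix(table, self.feature_names)
        return {
            name: float(np.mean(m.predict(X) == y))
            for name, m in self.models.items()
        }


def train_base_classifiers(
    train: pd.DataFrame,
    roster: Sequence[str] = DEFAULT_ROSTER,
    seed: int = 0,
    columns: Sequence[str] | None = None,
) -> ClassifierEnsemble:
    """Fit the roster on the training table (sorted to registry order)."""
    X, y, cols = feature_matrix(train, columns)
    models: dict[str, object] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for name in sorted(roster):
            clf = make_classifier(name, seed=seed)
            clf.fit(X, y)
            models[name] = clf
    return ClassifierEnsemble(models, cols)


def quick_accuracy(
    table: pd.DataFrame,
    roster: Sequence[str] = DEFAULT_ROSTER,
    n_repetitions: int = 3,
    n_test_participants: int = 6,
    seed: int = 0,
) -> dict[str, float]:
    """Mean test accuracy per model over a few subject-independent splits."""
    rng = np.random.default_rng(seed)
    accs: dict[str, list[float]] = {name: [] for name in sorted(roster)}
    for _ in range(n_repetitions):
        s = int(rng.integers(2**31))
        train, test = subject_independent_split(table, n_test_participants, s)
        norm = Normalizer.fit(train)
        ens = train_base_classifiers(norm.transform(train), roster, seed=s)
        for name, a in ens.accuracies(norm.transform(test)).items():
            accs[name].append(a)
    return {name: float(np.mean(v)) for name, v in accs.items()}


# ---------------------------------------------------------------------------
# The repeated protocol
# ---------------------------------------------------------------------------


def evaluate_protocol(
    table: pd.DataFrame,
    roster: Sequence[str] = DEFAULT_ROSTER,
    param_grids: Mapping[str, list[dict]] | None = None,
    n_repetitions: int = 200,
    seed: int = 0,
    n_test_participants: int = 6,
    n_folds: int = 5,
    selection_mode: str | None = None,
    alpha: float = 0.05,
    fold_order: str = "registry",
) -> EvaluationReport:
    """Repeated subject-independent evaluation of classifiers and fusion.

    Each repetition (seeded sequentially from the master ``seed``):
    resample the held-out participants, z-score on training statistics,
    optionally select features (``selection_mode`` None, ``"global"`` —
    once on the full table before the loop — or ``"per-repetition"`` on
    training data only), train the roster, derive fuzzy-measure densities
    by participant-grouped cross-validation, fuse the test-set probability
    cube with every operator variant in the grid, and score accuracy.

    Returns an :class:`EvaluationReport` covering both individual
    classifiers and fusion operators.
    """
    if selection_mode not in (None, "none", "global", "per-repetition"):
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    grids = compact_param_grids() if param_grids is None else param_grids
    specs = expand_param_grids(grids)
    roster = tuple(sorted(roster))

    global_cols: list[str] | None = None
    if selection_mode == "global":
        sel = anova_feature_selection(table, alpha=alpha)
        global_cols = sel.selected
        log.info("global selection kept %d features", len(global_cols))

    rng = np.random.default_rng(seed)  # repetition seeds: sequential draws
    acc_traces: dict[str, list[float]] = {f"clf:{n}": [] for n in roster}
    for spec in specs:
        acc_traces[spec.label] = []

    for rep in range(n_repetitions):
        rep_seed = int(rng.integers(2**31))
        train, test = subject_independent_split(table, n_test_participants, rep_seed)
        cols = feature_columns(table)
        if selection_mode == "per-repetition":
            cols = anova_feature_selection(train, alpha=alpha).selected or cols
        elif selection_mode == "global":
            cols = global_cols or cols
        norm = Normalizer.fit(train, cols)
        train_n, test_n = norm.transform(train), norm.transform(test)

        ens = train_base_classifiers(train_n, roster, seed=rep_seed,
                                     columns=norm.columns)
        densities = derive_densities_cv(
            train_n, roster, n_folds=n_folds, seed=rep_seed,
            feature_columns=norm.columns,
        )
        measure = measure_from_accuracies(densities, roster)

        cube = ens.predict_cube(test_n)
        _, y_test, _ = feature_matrix(test_n, norm.columns)
        for name, a in ens.accuracies(test_n).items():
            acc_traces[f"clf:{name}"].append(a)
        for spec in specs:
            res = apply_operator_to_cube(spec, cube, measure, densities, fold_order)
            acc_traces[spec.label].append(float(np.mean(res.labels == y_test)))

    records = [
        {
            "name": name,
            "kind": "classifier" if name.startswith("clf:") else "operator",
            "mean_accuracy": float(np.mean(trace)),
            "sd_accuracy": float(np.std(trace, ddof=1)) if len(trace) > 1 else 0.0,
            "n_repetitions": len(trace),
        }
        for name, trace in acc_traces.items()
    ]
    return EvaluationReport(
        pd.DataFrame(records),
        {k: list(v) for k, v in acc_traces.items()},
        metadata={
            "n_repetitions": n_repetitions,
            "n_test_participants": n_test_participants,
            "n_folds": n_folds,
            "selection_mode": selection_mode or "none",
            "seed": seed,
            "n_variants": len(specs),
            "roster": list(roster),
        },
    )


def fusion_dominance_experiment(
    n_runs: int = 50,
    n_repetitions: int = 12,
    master_seed: int = 7,
    param_grids: Mapping[str, list[dict]] | None = None,
    n_folds: int = 2,
    generator_config=None,
) -> pd.DataFrame:
    """Best-fused vs best-individual accuracy over independently seeded runs.

    Each run regenerates the synthetic study under a fresh seed, executes
    ``n_repetitions`` subject-independent repetitions, grid-searches the
    fusion operators, and records the best operator's and the best
    individual classifier's mean accuracy.  Returns one row per run with
    the accuracy difference in percentage points — the study-level claim
    is that fusion never loses materially and usually wins strictly.
    """
    from .synthetic import GeneratorConfig, generate

    grids = dominance_param_grids() if param_grids is None else param_grids
    base_cfg = generator_config if generator_config is not None else GeneratorConfig()
    rng = np.random.default_rng(master_seed)
    rows = []
    for run in range(n_runs):
        gen_seed = int(rng.integers(2**31))
        protocol_seed = int(rng.integers(2**31))
        table = generate(base_cfg, seed=gen_seed)
        report = evaluate_protocol(
            table,
            param_grids=grids,
            n_repetitions=n_repetitions,
            seed=protocol_seed,
            n_folds=n_folds,
        )
        r = report.ranking
        best_op = r[r.kind == "operator"].iloc[0]
        best_clf = r[r.kind == "classifier"].iloc[0]
        rows.append(
            {
                "run": run,
                "best_operator": best_op["name"],
                "best_operator_accuracy": best_op["mean_accuracy"],
                "best_classifier": best_clf["name"],
                "best_classifier_accuracy": best_clf["mean_accuracy"],
                "difference_pp": 100.0
                * (best_op["mean_accuracy"] - best_clf["mean_accuracy"]),
            }
        )
        log.info(
            "run %d: %s %.4f vs %s %.4f",
            run, best_op["name"], best_op["mean_accuracy"],
            best_clf["name"], best_clf["mean_accuracy"],
        )
    return pd.DataFrame(rows)
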