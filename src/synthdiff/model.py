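"""Budgeted ensemble classifier for synthesis difficulty.

The modeling layer follows the Model/Results convention: a
:class:`SynthesisDifficultyModel` is built from a feature matrix and
labels; its :meth:`~SynthesisDifficultyModel.fit` runs a seeded,
iteration-capped search over a portfolio of scikit-learn base learners,
combines the fitted candidates by greedy forward ensemble selection on an
internal validation fold, and returns a
:class:`SynthesisDifficultyResults` holding the deployable
:class:`ModelBundle`, held-out diagnostics, permutation importance and
partial dependence.

The search is an automated-model-search *contract*: deterministic given a
seed and an iteration cap, with wall-clock budgets available for
production use where reproducibility of the exact ensemble is not needed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .features import Normalizer, extract_matrix
from .manifest import MANIFEST_VERSION, get_manifest
from .metrics import ConfusionCounts, MetricsReport, confusion, f1
from .seqio import EASY, HARD, LabeledDataset, SequenceRecord

BUNDLE_FORMAT_VERSION = 1

#: Decision threshold on the HARD probability; a tie (exactly 0.5) is
#: called HARD — the positive, actionable class.
HARD_THRESHOLD = 0.5


def encode_labels(labels: Sequence[str]) -> np.ndarray:
    """EASY/HARD -> 0/1 (HARD positive)."""
    return np.array([1 if l == HARD else 0 for l in labels], dtype=int)


def decode_labels(y: np.ndarray) -> list[str]:
    return [HARD if v else EASY for v in y]


@dataclass(frozen=True)
class SplitSpec:
    """3:1 train/test split specification (seeded, stratification optional)."""

    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


def split_dataset(
    items, spec: SplitSpec = SplitSpec(), labels: Sequence[str] | None = None
):
    """Deterministic train/test partition of ids (or of range(n)).

    `items` is an integer n, a list of ids, or a LabeledDataset. Test size
    is floor(n * test_fraction). When labels are available the split warns
    if either partition misses a class.
    """
    if isinstance(items, LabeledDataset):
        ids = items.ids
        labels = items.label_vector()
    elif isinstance(items, int):
        ids = list(range(items))
    else:
        ids = list(items)
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 items to split")
    n_test = int(np.floor(n * spec.test_fraction))
    if n_test == 0 or n_test == n:
        raise ValueError("test_fraction yields an empty partition")
    train, test = train_test_split(
        ids, test_size=n_test, random_state=spec.seed, shuffle=True
    )
    if labels is not None:
        lab = dict(zip(ids, labels))
        for part, name in ((train, "train"), (test, "test")):
            if len({lab[i] for i in part}) < 2:
                warnings.warn(
                    f"{name} partition contains a single class; "
                    "consider a different seed",
                    stacklevel=2,
                )
    return train, test


# ---------------------------------------------------------------------------
# base-learner portfolio


class SigmoidSVC:
    """Linear SVM with a logistic squash of the decision margin so the
    ensemble can average probabilities across heterogeneous learners."""

    def __init__(self, C: float = 1.0, random_state: int = 0):
        self.C = C
        self.random_state = random_state
        self._svc = LinearSVC(C=C, random_state=random_state)

    def fit(self, X, y):
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        return self

    def predict_proba(self, X):
        d = self._svc.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-d))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _portfolio():
    """(family, constructor(rng) -> estimator) pairs. Eight families:
    bagged/boosted trees, naive Bayes, a single tree, nearest neighbors,
    a linear SVM and linear discriminant analysis."""

    def rf(rng):
        return RandomForestClassifier(
            n_estimators=int(rng.choice([50, 100, 200])),
            max_features=rng.choice(["sqrt", "log2"]),
            random_state=int(rng.integers(2**31)),
        )

    def et(rng):
        return ExtraTreesClassifier(
            n_estimators=int(rng.choice([50, 100, 200])),
            max_features=rng.choice(["sqrt", "log2"]),
            random_state=int(rng.integers(2**31)),
        )

    def ada(rng):
        return AdaBoostClassifier(
            n_estimators=int(rng.choice([50, 100, 200])),
            learning_rate=float(rng.choice([0.5, 1.0])),
            random_state=int(rng.integers(2**31)),
        )

    def nb(rng):
        if rng.random() < 0.5:
            return GaussianNB()
        return BernoulliNB(alpha=float(rng.choice([0.1, 1.0])), binarize=0.5)

    def dt(rng):
        depth = rng.choice([3, 5, 10, 0])
        return DecisionTreeClassifier(
            max_depth=None if depth == 0 else int(depth),
            random_state=int(rng.integers(2**31)),
        )

    def knn(rng):
        return KNeighborsClassifier(n_neighbors=int(rng.choice([1, 5, 11, 21])))

    def svc(rng):
        return SigmoidSVC(
            C=float(rng.choice([0.1, 1.0, 10.0])),
            random_state=int(rng.integers(2**31)),
        )

    def lda(rng):
        return LinearDiscriminantAnalysis()

    return [
        ("random_forest", rf),
        ("extra_trees", et),
        ("adaboost", ada),
        ("naive_bayes", nb),
        ("decision_tree", dt),
        ("knn", knn),
        ("linear_svc", svc),
        ("lda", lda),
    ]


@dataclass
class ModelBundle:
    """The deployable predictor: fitted weighted ensemble + the frozen
    preprocessing (normalizer, selection mask) and metadata."""

    ensemble: list[tuple[str, object, float]]
    normalizer: Normalizer
    feature_names: list[str]  # selected features, manifest order
    manifest_version: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.array([x[2] for x in self.ensemble], dtype=float)
        if len(w) == 0 or (w <= 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("ensemble weights must be positive and sum to 1")

    def hard_probability(self, X: np.ndarray) -> np.ndarray:
        """Weight-averaged probability of the HARD class."""
        p = np.zeros(len(X))
        for _, est, w in self.ensemble:
            p += w * est.predict_proba(X)[:, 1]
        return p

    def predict_from_selected(self, X: np.ndarray) -> np.ndarray:
        return (self.hard_probability(X) >= HARD_THRESHOLD).astype(int)


@dataclass
class PredictionRow:
    id: str
    label: str | None
    hard_probability: float | None
    features: dict[str, float] | None
    error: str | None = None


def train_model(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    budget_iterations: int = 16,
    budget_seconds: float | None = None,
    ensemble_size: int = 10,
    validation_fraction: float = 0.25,
    normalizer: Normalizer | None = None,
    metadata: dict | None = None,
) -> ModelBundle:
    """Budgeted portfolio search + greedy forward ensemble selection.

    `matrix` must already be normalized and reduced to the selected
    features. Candidates are sampled from the portfolio round-robin with
    seeded hyperparameters, fitted on an inner training part, and scored
    (F1, HARD positive) on an internal validation fold; greedy forward
    selection with replacement then picks the ensemble, whose weights are
    the selection counts. Deterministic given `seed` and
    `budget_iterations`; `budget_seconds`, if set, additionally stops the
    search by wall clock.
    """
    if budget_iterations < 1:
        raise ValueError("budget must allow at least one candidate fit")
    y = encode_labels(list(labels))
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    Xtr, Xval, ytr, yval = train_test_split(
        X, y, test_size=validation_fraction,
        random_state=int(rng.integers(2**31)), stratify=y,
    )
    if len(np.unique(ytr)) < 2:
        raise ValueError("inner training fold lost a class; need more data")

    portfolio = _portfolio()
    candidates: list[tuple[str, object, np.ndarray]] = []
    t0 = time.monotonic()
    for it in range(budget_iterations):
        if budget_seconds is not None and it > 0 and time.monotonic() - t0 > budget_seconds:
            break
        family, ctor = portfolio[it % len(portfolio)]
        est = ctor(rng)
        try:
            est.fit(Xtr, ytr)
            proba = est.predict_proba(Xval)[:, 1]
        except Exception as exc:  # a family can fail on degenerate folds
            warnings.warn(f"candidate {family} failed: {exc}", stacklevel=2)
            continue
        candidates.append((family, est, proba))
    if not candidates:
        raise RuntimeError("no candidate model could be fitted within the budget")

    # Greedy forward selection with replacement on validation F1.
    def val_f1(p: np.ndarray) -> float:
        pred = (p >= HARD_THRESHOLD).astype(int)
        c = confusion(decode_labels(yval), decode_labels(pred))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return f1(c)

    chosen: list[int] = []
    current = np.zeros(len(yval))
    best_score = -1.0
    for _ in range(ensemble_size):
        step_best, step_idx = -1.0, -1
        for idx, (_, _, proba) in enumerate(candidates):
            trial = (current * len(chosen) + proba) / (len(chosen) + 1)
            s = val_f1(trial)
            if s > step_best + 1e-12:
                step_best, step_idx = s, idx
        if not chosen:
            chosen.append(step_idx)
            current = candidates[step_idx][2].copy()
            best_score = step_best
        elif step_best >= best_score - 1e-12:
            current = (current * len(chosen) + candidates[step_idx][2]) / (len(chosen) + 1)
            chosen.append(step_idx)
            best_score = max(best_score, step_best)
        else:
            break

    counts: dict[int, int] = {}
    for idx in chosen:
        counts[idx] = counts.get(idx, 0) + 1
    total = sum(counts.values())
    ensemble = [
        (candidates[idx][0], candidates[idx][1], c / total)
        for idx, c in sorted(counts.items())
    ]
    meta = {
        "seed": seed,
        "budget_iterations": budget_iterations,
        "budget_seconds": budget_seconds,
        "n_candidates": len(candidates),
        "validation_f1": best_score,
        "n_train": int(len(y)),
    }
    if metadata:
        meta.update(metadata)
    return ModelBundle(
        ensemble=ensemble,
        normalizer=normalizer,
        feature_names=list(matrix.columns),
        manifest_version=MANIFEST_VERSION,
        metadata=meta,
    )


def evaluate_bundle(
    bundle: ModelBundle, matrix: pd.DataFrame, labels: Sequence[str]
) -> MetricsReport:
    """Score a fitted bundle on an already-normalized, masked matrix."""
    X = matrix[bundle.feature_names].to_numpy(dtype=float)
    pred = decode_labels(bundle.predict_from_selected(X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MetricsReport.from_counts(confusion(list(labels), pred))


@dataclass
class RepeatReport:
    """Per-metric mean/std/min/max over repeated train/evaluate cycles."""

    runs: list[MetricsReport]

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.runs])

    def stats(self) -> pd.DataFrame:
        rows = {}
        for m in ("F1", "MCC", "CK"):
            v = self._values(m)
            rows[m] = {
                "mean": v.mean(),
                "std": v.std(ddof=0),
                "min": v.min(),
                "max": v.max(),
            }
        return pd.DataFrame(rows).T


def repeat_evaluate(
    train_matrix: pd.DataFrame,
    train_labels: Sequence[str],
    test_matrix: pd.DataFrame,
    test_labels: Sequence[str],
    n_repeats: int = 10,
    seed: int = 0,
    budget_iterations: int = 16,
) -> RepeatReport:
    """Repeat the budgeted model search `n_repeats` times on a fixed split
    (the search seed varies; the split does not) and collect the held-out
    metrics of each run."""
    if n_repeats < 2:
        raise ValueError("n_repeats must be at least 2")
    runs = []
    for r in range(n_repeats):
        bundle = train_model(
            train_matrix, train_labels,
            seed=seed + 1000 * r,
            budget_iterations=budget_iterations,
        )
        runs.append(evaluate_bundle(bundle, test_matrix, test_labels))
    return RepeatReport(runs=runs)


def predict_records(
    bundle: ModelBundle, records: Sequence[SequenceRecord]
) -> list[PredictionRow]:
    """Extraction -> normalization -> mask -> ensemble vote, per record.

    A record that fails extraction yields an error row; the rest are
    scored normally. Output order equals input order.
    """
    if bundle.manifest_version != MANIFEST_VERSION:
        raise ValueError(
            f"bundle manifest version {bundle.manifest_version!r} does not "
            f"match this package ({MANIFEST_VERSION!r})"
        )
    rows: list[PredictionRow] = []
    for rec in records:
        try:
            full = extract_matrix([rec])
            norm = bundle.normalizer.apply(full) if bundle.normalizer else full
            sel = norm[bundle.feature_names]
            p = float(bundle.hard_probability(sel.to_numpy(dtype=float))[0])
            rows.append(
                PredictionRow(
                    id=rec.id,
                    label=HARD if p >= HARD_THRESHOLD else EASY,
                    hard_probability=p,
                    features={k: float(v) for k, v in sel.iloc[0].items()},
                )
            )
        except Exception as exc:
            rows.append(PredictionRow(rec.id, None, None, None, error=str(exc)))
    return rows


def permutation_importance(
    bundle: ModelBundle,
    matrix: pd.DataFrame,
    labels: Sequence[str],
    n_shuffles: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean F1 decrease per selected feature under column permutation.

    Returns a DataFrame indexed by feature with columns mean_decrease,
    std_decrease and rank (1 = most important).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    base = evaluate_bundle(bundle, matrix, labels).F1
    rng = np.random.default_rng(seed)
    X = matrix[bundle.feature_names].to_numpy(dtype=float)
    y = list(labels)
    out = {}
    for j, name in enumerate(bundle.feature_names):
        drops = []
        for _ in range(n_shuffles):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            pred = decode_labels(bundle.predict_from_selected(Xp))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                score = f1(confusion(y, pred))
            drops.append(base - score)
        drops = np.array(drops)
        out[name] = {"mean_decrease": drops.mean(), "std_decrease": drops.std(ddof=0)}
    df = pd.DataFrame(out).T
    df["rank"] = (
        df["mean_decrease"].rank(ascending=False, method="first").astype(int)
    )
    return df.sort_values("rank")


def partial_dependence(
    bundle: ModelBundle,
    matrix: pd.DataFrame,
    feature: str,
    grid_points: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard partial dependence of the HARD probability on one selected
    feature: the column is overwritten with each grid value (spanning the
    observed range) and the predicted probabilities are averaged."""
    if feature not in bundle.feature_names:
        raise KeyError(f"{feature!r} is not among the selected features")
    X = matrix[bundle.feature_names].to_numpy(dtype=float)
    j = bundle.feature_names.index(feature)
    col = X[:, j]
    grid = np.linspace(col.min(), col.max(), grid_points)
    means = np.empty(grid_points)
    for g, v in enumerate(grid):
        Xp = X.copy()
        Xp[:, j] = v
        means[g] = bundle.hard_probability(Xp).mean()
    return grid, means


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": BUNDLE_FORMAT_VERSION,
            "manifest_version": bundle.manifest_version,
            "bundle": bundle,
        },
        path,
    )


def load_bundle(path: str | Path) -> ModelBundle:
    try:
        payload = joblib.load(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: corrupt or unreadable bundle file: {exc}") from exc
    if not isinstance(payload, dict) or "bundle" not in payload:
        raise ValueError(f"{path}: not a model bundle file")
    if payload.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"{path}: bundle format version {payload.get('format_version')!r} "
            f"!= supported {BUNDLE_FORMAT_VERSION}"
        )
    if payload.get("manifest_version") != MANIFEST_VERSION:
        raise ValueError(
            f"{path}: bundle manifest version {payload.get('manifest_version')!r} "
            f"!= package manifest {MANIFEST_VERSION!r}"
        )
    return payload["bundle"]


# ---------------------------------------------------------------------------
# Model / Results


class SynthesisDifficultyModel:
    """Synthesis-difficulty classifier specification bound to data.

    Parameters
    ----------
    matrix
        Raw (unnormalized) feature matrix, one row per sequence.
    labels
        EASY/HARD label per row, aligned with the matrix index.
    feature_names
        Optional subset of features to train on (a selection mask); default
        all columns.
    split
        Train/test :class:`SplitSpec`; normalization is fit on the training
        rows only and frozen into the resulting bundle.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        labels: Sequence[str],
        feature_names: Sequence[str] | None = None,
        split: SplitSpec = SplitSpec(),
    ):
        if len(matrix) != len(labels):
            raise ValueError("matrix rows and labels must align")
        self.matrix = matrix
        self.labels = list(labels)
        self.feature_names = (
            list(feature_names) if feature_names is not None else list(matrix.columns)
        )
        missing = [f for f in self.feature_names if f not in matrix.columns]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        self.split = split
        lab = dict(zip(matrix.index, self.labels))
        self.train_ids, self.test_ids = split_dataset(
            list(matrix.index), split, labels=self.labels
        )
        self._ytrain = [lab[i] for i in self.train_ids]
        self._ytest = [lab[i] for i in self.test_ids]

    @classmethod
    def from_dataset(
        cls,
        dataset: LabeledDataset,
        feature_names: Sequence[str] | None = None,
        split: SplitSpec = SplitSpec(),
    ) -> "SynthesisDifficultyModel":
        matrix = extract_matrix(dataset.records)
        return cls(matrix, dataset.label_vector(), feature_names, split)

    def _prepared(self):
        train_raw = self.matrix.loc[self.train_ids]
        test_raw = self.matrix.loc[self.test_ids]
        normalizer = Normalizer.fit(train_raw)
        train = normalizer.apply(train_raw)[self.feature_names]
        test = normalizer.apply(test_raw)[self.feature_names]
        return normalizer, train, test

    def fit(
        self,
        seed: int = 0,
        budget_iterations: int = 16,
        budget_seconds: float | None = None,
        n_repeats: int | None = None,
    ) -> "SynthesisDifficultyResults":
        """Run the budgeted search and return Results.

        With ``n_repeats`` set, additionally runs the repeat-evaluation
        protocol (same split, varying search seed) and attaches the
        mean/std/min/max table.
        """
        normalizer, train, test = self._prepared()
        bundle = train_model(
            train,
            self._ytrain,
            seed=seed,
            budget_iterations=budget_iterations,
            budget_seconds=budget_seconds,
            normalizer=normalizer,
        )
        report = None
        if n_repeats is not None:
            report = repeat_evaluate(
                train, self._ytrain, test, self._ytest,
                n_repeats=n_repeats, seed=seed,
                budget_iterations=budget_iterations,
            )
        return SynthesisDifficultyResults(self, bundle, repeat_report=report)


class SynthesisDifficultyResults:
    """Fitted ensemble plus held-out diagnostics."""

    def __init__(
        self,
        model: SynthesisDifficultyModel,
        bundle: ModelBundle,
        repeat_report: RepeatReport | None = None,
    ):
        self.model = model
        self.bundle = bundle
        self.repeat_report = repeat_report
        _, self._train, self._test = model._prepared()
        self.test_metrics = evaluate_bundle(bundle, self._test, model._ytest)
        self.train_metrics = evaluate_bundle(bundle, self._train, model._ytrain)

    def predict(self, records: Sequence[SequenceRecord]) -> list[PredictionRow]:
        return predict_records(self.bundle, records)

    def permutation_importance(self, n_shuffles: int = 10, seed: int = 0) -> pd.DataFrame:
        return permutation_importance(
            self.bundle, self._test, self.model._ytest,
            n_shuffles=n_shuffles, seed=seed,
        )

    def partial_dependence(self, feature: str, grid_points: int = 20):
        return partial_dependence(self.bundle, self._test, feature, grid_points)

    def save(self, path: str | Path) -> None:
        save_bundle(self.bundle, path)

    def summary(self) -> str:
        m = self.test_metrics
        lines = [
            "Synthesis difficulty ensemble",
            "=" * 46,
            f"training sequences:   {len(self.model.train_ids)}",
            f"held-out sequences:   {len(self.model.test_ids)}",
            f"selected features:    {len(self.bundle.feature_names)}",
            f"search seed / budget: {self.bundle.metadata.get('seed')} / "
            f"{self.bundle.metadata.get('budget_iterations')} iterations",
            "",
            "ensemble composition (family: weight)",
        ]
        for fam, _, w in self.bundle.ensemble:
            lines.append(f"  {fam:<16s} {w:.3f}")
        lines += [
            "",
            f"held-out F1  = {m.F1:.3f}",
            f"held-out MCC = {m.MCC:.3f}",
            f"held-out CK  = {m.CK:.3f}",
        ]
        if self.repeat_report is not None:
            lines.append("")
            lines.append("repeat protocol (held-out, over repeated searches):")
            lines.append(self.repeat_report.stats().to_string(float_format="%.3f"))
        return "\n".join(lines)
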