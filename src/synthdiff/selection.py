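"""Feature reduction: variance filter, label-correlation filter, and a
genetic-algorithm wrapper, plus the 74-configuration experiment grid.

Filters compose cheapest-first (variance -> correlation -> GA), each stage
operating on the survivors of the previous one. Masks carry provenance so
a written mask file records how it was produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

from .metrics import confusion, f1
from .model import decode_labels, encode_labels, repeat_evaluate

CORRELATION_CUTOFFS = (0.1, 0.15, 0.2, 0.3)
VARIANCE_CUTOFFS = (0.01, 0.02, 0.03, 0.04)
GA_ROUNDS = (10_000, 100_000)


class EmptySelectionError(ValueError):
    """A reduction stage removed every feature."""


@dataclass
class SelectionMask:
    """Boolean keep-mask over a feature matrix's columns with provenance."""

    feature_names: list[str]
    keep: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if len(self.keep) != len(self.feature_names):
            raise ValueError("mask length must match feature names")
        if not self.keep.any():
            raise EmptySelectionError("selection mask keeps no features")

    @property
    def n_selected(self) -> int:
        return int(self.keep.sum())

    def selected(self) -> list[str]:
        return [n for n, k in zip(self.feature_names, self.keep) if k]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self.provenance:
                fh.write(f"# {p}\n")
            for n in self.selected():
                fh.write(n + "\n")

    @classmethod
    def read(cls, path: str | Path, feature_names: Sequence[str]) -> "SelectionMask":
        prov, names = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    prov.append(line[1:].strip())
                elif line.strip():
                    names.append(line.strip())
        unknown = [n for n in names if n not in set(feature_names)]
        if unknown:
            raise ValueError(f"{path}: unknown features {unknown[:5]}")
        keep = np.array([n in set(names) for n in feature_names])
        return cls(list(feature_names), keep, prov)


def variance_filter(matrix: pd.DataFrame, cutoff: float) -> SelectionMask:
    """Keep features whose sample variance (over the normalized matrix)
    is at least `cutoff`."""
    if cutoff < 0:
        raise ValueError("variance cutoff must be non-negative")
    var = matrix.var(axis=0, ddof=0).to_numpy()
    return SelectionMask(
        list(matrix.columns), var >= cutoff, [f"variance cutoff={cutoff}"]
    )


def correlation_filter(
    matrix: pd.DataFrame, labels: Sequence[str], cutoff: float
) -> SelectionMask:
    """Keep features with |point-biserial correlation with the label|
    >= cutoff (HARD encoded 1). Constant features (undefined correlation)
    are dropped."""
    y = encode_labels(list(labels))
    if len(np.unique(y)) < 2:
        raise ValueError("correlation filter needs both classes in the labels")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    keep = np.abs(np.where(np.isfinite(r), r, 0.0)) >= cutoff
    return SelectionMask(
        list(matrix.columns), keep, [f"correlation cutoff={cutoff}"]
    )


@dataclass
class GAConfig:
    """Genetic-algorithm wrapper parameters.

    rounds counts fitness evaluations (not generations). The fitness of a
    mask is the mean stratified 3-fold cross-validated F1 of the reference
    learner on the masked features minus a parsimony penalty per kept
    feature. The default learner is Gaussian naive Bayes — fast enough for
    tens of thousands of evaluations; any scikit-learn classifier factory
    can be injected.
    """

    rounds: int = 10_000
    population: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float | None = None  # default 1/n_features
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0
    parsimony_penalty: float = 1e-4
    cv_folds: int = 3
    learner_factory: Callable[[], object] = GaussianNB

    def __post_init__(self) -> None:
        if self.rounds < self.population:
            raise ValueError("rounds must be at least the population size")
        for p in (self.crossover_prob,) + (
            (self.mutation_prob,) if self.mutation_prob is not None else ()
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def _cv_f1(X: np.ndarray, y: np.ndarray, cfg: GAConfig, seed: int) -> float:
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        est = cfg.learner_factory()
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores.append(f1(confusion(decode_labels(y[te]), decode_labels(pred))))
    return float(np.mean(scores))


def ga_select(
    matrix: pd.DataFrame, labels: Sequence[str], config: GAConfig = GAConfig()
) -> SelectionMask:
    """Evolve binary feature masks by tournament selection, one-point
    crossover and per-bit mutation, with elitism; returns the best-ever
    mask. Fully reproducible given the config seed."""
    y = encode_labels(list(labels))
    if len(y) < 20:
        raise ValueError("GA selection needs at least 20 rows")
    if len(np.unique(y)) < 2:
        raise ValueError("GA selection needs both classes")
    X = matrix.to_numpy(dtype=float)
    n_feat = X.shape[1]
    rng = np.random.default_rng(config.seed)
    mut = config.mutation_prob if config.mutation_prob is not None else 1.0 / n_feat
    cv_seed = int(rng.integers(2**31))

    cache: dict[bytes, float] = {}
    evals = 0

    def fitness(mask: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        key = mask.tobytes()
        if key in cache:
            return cache[key]
        if not mask.any():
            score = -1.0
        else:
            score = _cv_f1(X[:, mask], y, config, cv_seed)
            score -= config.parsimony_penalty * mask.sum()
        cache[key] = score
        return score

    pop = rng.random((config.population, n_feat)) < 0.5
    # guard against an all-zero chromosome in the initial population
    for row in pop:
        if not row.any():
            row[rng.integers(n_feat)] = True
    fits = np.array([fitness(ind) for ind in pop])
    best_idx = int(fits.argmax())
    best_mask, best_fit = pop[best_idx].copy(), float(fits[best_idx])

    while evals < config.rounds:
        order = np.argsort(-fits)
        new = [pop[i].copy() for i in order[: config.elitism]]
        while len(new) < config.population:
            def pick() -> np.ndarray:
                idx = rng.integers(len(pop), size=config.tournament_size)
                return pop[idx[np.argmax(fits[idx])]]

            a, b = pick().copy(), pick().copy()
            if rng.random() < config.crossover_prob:
                cut = int(rng.integers(1, n_feat))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for child in (a, b):
                flip = rng.random(n_feat) < mut
                child[flip] = ~child[flip]
                if len(new) < config.population:
                    new.append(child)
        pop = np.array(new)
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = int(fits.argmax())
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()

    return SelectionMask(
        list(matrix.columns),
        best_mask,
        [f"ga rounds={config.rounds} seed={config.seed} fitness={best_fit:.4f}"],
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the reduction experiment grid; at least one component."""

    correlation_cutoff: float | None = None
    variance_cutoff: float | None = None
    ga_rounds: int | None = None

    def __post_init__(self) -> None:
        if (
            self.correlation_cutoff is None
            and self.variance_cutoff is None
            and self.ga_rounds is None
        ):
            raise ValueError("an experiment config needs at least one method")

    def describe(self) -> str:
        parts = []
        if self.variance_cutoff is not None:
            parts.append(f"var={self.variance_cutoff}")
        if self.correlation_cutoff is not None:
            parts.append(f"corr={self.correlation_cutoff}")
        if self.ga_rounds is not None:
            parts.append(f"ga={self.ga_rounds}")
        return "+".join(parts)


def build_experiment_grid() -> list[ExperimentConfig]:
    """The 74 reduction experiments: 10 single-method (4 correlation +
    4 variance + 2 GA), 32 two-method (4x4 corr x var + 4x2 corr x GA +
    4x2 var x GA), 32 three-method (4x4x2). Deterministic order."""
    grid: list[ExperimentConfig] = []
    for c in CORRELATION_CUTOFFS:
        grid.append(ExperimentConfig(correlation_cutoff=c))
    for v in VARIANCE_CUTOFFS:
        grid.append(ExperimentConfig(variance_cutoff=v))
    for g in GA_ROUNDS:
        grid.append(ExperimentConfig(ga_rounds=g))
    for c in CORRELATION_CUTOFFS:
        for v in VARIANCE_CUTOFFS:
            grid.append(ExperimentConfig(correlation_cutoff=c, variance_cutoff=v))
    for c in CORRELATION_CUTOFFS:
        for g in GA_ROUNDS:
            grid.append(ExperimentConfig(correlation_cutoff=c, ga_rounds=g))
    for v in VARIANCE_CUTOFFS:
        for g in GA_ROUNDS:
            grid.append(ExperimentConfig(variance_cutoff=v, ga_rounds=g))
    for c in CORRELATION_CUTOFFS:
        for v in VARIANCE_CUTOFFS:
            for g in GA_ROUNDS:
                grid.append(
                    ExperimentConfig(
                        correlation_cutoff=c, variance_cutoff=v, ga_rounds=g
                    )
                )
    assert len(grid) == 74
    return grid


def apply_config(
    config: ExperimentConfig,
    matrix: pd.DataFrame,
    labels: Sequence[str],
    ga_config: GAConfig | None = None,
    ga_rounds_cap: int | None = None,
) -> SelectionMask:
    """Compose the configured stages in fixed order variance ->
    correlation -> GA; each stage sees only the previous stage's
    survivors. An empty survivor set raises, naming the stage.
    `ga_rounds_cap` bounds the GA budget for smoke-scale runs."""
    names = list(matrix.columns)
    keep = np.ones(len(names), dtype=bool)
    prov: list[str] = []
    current = matrix

    def stage(mask_fn, stage_name):
        nonlocal keep, current, prov
        try:
            m = mask_fn(current)
        except EmptySelectionError as exc:
            raise EmptySelectionError(f"stage {stage_name!r}: {exc}") from exc
        sub = np.zeros(len(names), dtype=bool)
        sel = set(m.selected())
        for i, n in enumerate(names):
            if keep[i] and n in sel:
                sub[i] = True
        keep = sub
        prov += m.provenance
        current = matrix.loc[:, [n for n, k in zip(names, keep) if k]]

    if config.variance_cutoff is not None:
        stage(lambda mdf: variance_filter(mdf, config.variance_cutoff), "variance")
    if config.correlation_cutoff is not None:
        stage(
            lambda mdf: correlation_filter(mdf, labels, config.correlation_cutoff),
            "correlation",
        )
    if config.ga_rounds is not None:
        cfg = ga_config or GAConfig()
        rounds = config.ga_rounds
        if ga_rounds_cap is not None:
            rounds = min(rounds, ga_rounds_cap)
        cfg = GAConfig(
            rounds=max(rounds, cfg.population),
            population=cfg.population,
            crossover_prob=cfg.crossover_prob,
            mutation_prob=cfg.mutation_prob,
            tournament_size=cfg.tournament_size,
            elitism=cfg.elitism,
            seed=cfg.seed,
            parsimony_penalty=cfg.parsimony_penalty,
            cv_folds=cfg.cv_folds,
            learner_factory=cfg.learner_factory,
        )
        stage(lambda mdf: ga_select(mdf, labels, cfg), "ga")
    return SelectionMask(names, keep, prov)


def run_experiments(
    grid: Sequence[ExperimentConfig],
    train_matrix: pd.DataFrame,
    train_labels: Sequence[str],
    test_matrix: pd.DataFrame,
    test_labels: Sequence[str],
    n_repeats: int = 10,
    seed: int = 0,
    budget_iterations: int = 16,
    ga_config: GAConfig | None = None,
    ga_rounds_cap: int | None = None,
) -> pd.DataFrame:
    """Run every config: select on the training matrix, then repeat the
    budgeted train/evaluate cycle and average F1/MCC/CK. Matrices must be
    normalized (fit on train). Returns one row per config, sortable by
    f1_mean."""
    if not len(grid):
        raise ValueError("experiment grid is empty")
    rows = []
    for i, cfg in enumerate(grid):
        try:
            mask = apply_config(
                cfg, train_matrix, train_labels,
                ga_config=ga_config, ga_rounds_cap=ga_rounds_cap,
            )
            sel = mask.selected()
            report = repeat_evaluate(
                train_matrix[sel], train_labels,
                test_matrix[sel], test_labels,
                n_repeats=n_repeats, seed=seed,
                budget_iterations=budget_iterations,
            )
            stats = report.stats()
            rows.append(
                {
                    "config": cfg.describe(),
                    "correlation_cutoff": cfg.correlation_cutoff,
                    "variance_cutoff": cfg.variance_cutoff,
                    "ga_rounds": cfg.ga_rounds,
                    "n_selected": mask.n_selected,
                    "f1_mean": stats.loc["F1", "mean"],
                    "f1_std": stats.loc["F1", "std"],
                    "mcc_mean": stats.loc["MCC", "mean"],
                    "mcc_std": stats.loc["MCC", "std"],
                    "ck_mean": stats.loc["CK", "mean"],
                    "ck_std": stats.loc["CK", "std"],
                }
            )
        except Exception as exc:
            raise RuntimeError(f"experiment {cfg.describe()!r} failed: {exc}") from exc
    return pd.DataFrame(rows)


def best_config(results: pd.DataFrame) -> pd.Series:
    """Ties resolved by higher f1_mean, then fewer features, then grid order."""
    df = results.reset_index(drop=True)
    order = df.sort_values(
        by=["f1_mean", "n_selected"], ascending=[False, True], kind="stable"
    )
    return order.iloc[0]
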