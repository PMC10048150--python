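"""Variance / correlation filters, GA wrapper selection, and the
74-configuration experiment grid."""

import numpy as np
import pandas as pd
import pytest

import synthdiff as sd
from synthdiff.selection import (
    EmptySelectionError,
    ExperimentConfig,
    GAConfig,
    SelectionMask,
    apply_config,
    best_config,
    build_experiment_grid,
    correlation_filter,
    ga_select,
    variance_filter,
)
from synthdiff.simulate import informative_noise_matrix


@pytest.fixture(scope="module")
def planted():
    X, labels, informative = informative_noise_matrix(n_rows=120, seed=5)
    return X, labels, informative


class TestVarianceFilter:
    def test_constant_column_dropped_alternating_kept(self):
        m = pd.DataFrame({"const": [0.5] * 8, "alt": [0.0, 1.0] * 4})
        mask = variance_filter(m, 0.01)
        assert mask.selected() == ["alt"]  # alternating has variance 0.25

    def test_toy_matrix_matches_direct_variance(self):
        m = pd.DataFrame(
            {"a": [0.0, 0.0, 1.0, 1.0], "b": [0.4, 0.5, 0.6, 0.5], "c": [0.0, 0.1, 0.0, 0.1]}
        )
        var = m.var(axis=0, ddof=0)
        mask = variance_filter(m, 0.02)
        assert set(mask.selected()) == set(var.index[var >= 0.02])

    def test_negative_cutoff_errors(self):
        with pytest.raises(ValueError):
            variance_filter(pd.DataFrame({"a": [0.0, 1.0]}), -0.1)

    def test_monotone_in_cutoff(self, planted):
        X, _, _ = planted
        small = set(variance_filter(X, 0.01).selected())
        large = set(variance_filter(X, 0.04).selected())
        assert large <= small


class TestCorrelationFilter:
    def test_label_copy_is_kept_constant_is_dropped(self):
        y = ["HARD", "EASY", "HARD", "EASY", "HARD", "EASY"]
        m = pd.DataFrame(
            {"copy": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0], "const": [0.3] * 6}
        )
        mask = correlation_filter(m, y, 0.5)
        assert mask.selected() == ["copy"]

    def test_toy_matrix_matches_hand_computed_correlations(self):
        y = ["HARD", "HARD", "HARD", "EASY", "EASY", "EASY"]
        m = pd.DataFrame(
            {
                "strong": [0.9, 0.8, 0.85, 0.1, 0.2, 0.15],
                "weak": [0.5, 0.6, 0.4, 0.45, 0.55, 0.5],
            }
        )
        yv = np.array([1, 1, 1, 0, 0, 0])
        r = {c: np.corrcoef(m[c], yv)[0, 1] for c in m}
        for cutoff in (0.1, 0.3):
            got = set(correlation_filter(m, y, cutoff).selected())
            assert got == {c for c in m if abs(r[c]) >= cutoff}

    def test_single_class_labels_error(self):
        m = pd.DataFrame({"a": [0.0, 1.0]})
        with pytest.raises(ValueError, match="both classes"):
            correlation_filter(m, ["HARD", "HARD"], 0.1)

    def test_monotone_in_cutoff(self, planted):
        X, y, _ = planted
        small = set(correlation_filter(X, y, 0.1).selected())
        large = set(correlation_filter(X, y, 0.3).selected())
        assert large <= small


class TestGA:
    def test_rounds_below_population_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(rounds=10, population=50)

    def test_same_seed_gives_identical_mask(self, planted):
        X, y, _ = planted
        cfg = GAConfig(rounds=300, population=30, seed=4)
        m1 = ga_select(X, y, cfg)
        m2 = ga_select(X, y, cfg)
        assert np.array_equal(m1.keep, m2.keep)

    def test_small_budget_still_prefers_informative_features(self, planted):
        X, y, informative = planted
        mask = ga_select(X, y, GAConfig(rounds=1200, population=30, seed=0))
        got = set(mask.selected())
        assert sum(1 for f in informative if f in got) >= 3

    def test_needs_enough_rows_and_both_classes(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)))
        X.columns = [f"f{i}" for i in range(4)]
        with pytest.raises(ValueError, match="20 rows"):
            ga_select(X, ["HARD", "EASY"] * 5, GAConfig(rounds=60, population=10))


class TestGrid:
    def test_grid_is_74_decomposed_10_32_32(self):
        grid = build_experiment_grid()
        assert len(grid) == 74

        def n_methods(c):
            return sum(
                x is not None
                for x in (c.correlation_cutoff, c.variance_cutoff, c.ga_rounds)
            )

        by = {1: 0, 2: 0, 3: 0}
        for c in grid:
            by[n_methods(c)] += 1
        assert by == {1: 10, 2: 32, 3: 32}

    def test_grid_is_deterministic_and_unique(self):
        g1, g2 = build_experiment_grid(), build_experiment_grid()
        assert g1 == g2
        assert len(set(g1)) == 74

    def test_config_requires_at_least_one_method(self):
        with pytest.raises(ValueError):
            ExperimentConfig()


class TestApplyConfig:
    def test_single_variance_config_equals_filter(self, planted):
        X, y, _ = planted
        cfg = ExperimentConfig(variance_cutoff=0.01)
        assert apply_config(cfg, X, y).selected() == variance_filter(X, 0.01).selected()

    def test_impossible_cutoff_names_the_stage(self, planted):
        X, y, _ = planted
        with pytest.raises(EmptySelectionError, match="variance"):
            apply_config(ExperimentConfig(variance_cutoff=1e9), X, y)

    def test_stages_compose_as_subsets(self, planted):
        X, y, _ = planted
        ga_cfg = GAConfig(rounds=300, population=30, seed=1)
        triple = apply_config(
            ExperimentConfig(correlation_cutoff=0.1, variance_cutoff=0.01, ga_rounds=300),
            X, y, ga_config=ga_cfg,
        )
        pair = apply_config(
            ExperimentConfig(correlation_cutoff=0.1, variance_cutoff=0.01), X, y
        )
        assert set(triple.selected()) <= set(pair.selected())
        assert triple.n_selected <= pair.n_selected

    def test_mask_round_trip(self, planted, tmp_path):
        X, y, _ = planted
        mask = apply_config(ExperimentConfig(correlation_cutoff=0.1), X, y)
        p = tmp_path / "mask.txt"
        mask.write(p)
        back = SelectionMask.read(p, list(X.columns))
        assert back.selected() == mask.selected()


class TestRunExperiments:
    def test_results_schema_and_determinism(self, planted):
        X, y, _ = planted
        Xtr, Xte = X.iloc[:90], X.iloc[90:]
        ytr, yte = y[:90], y[90:]
        grid = [
            ExperimentConfig(correlation_cutoff=0.2),
            ExperimentConfig(variance_cutoff=0.01),
        ]
        kw = dict(n_repeats=2, seed=0, budget_iterations=4)
        r1 = sd.run_experiments(grid, Xtr, ytr, Xte, yte, **kw)
        r2 = sd.run_experiments(grid, Xtr, ytr, Xte, yte, **kw)
        assert list(r1.columns[:5]) == [
            "config", "correlation_cutoff", "variance_cutoff", "ga_rounds", "n_selected",
        ]
        pd.testing.assert_frame_equal(r1, r2)
        assert len(r1) == 2
        assert (r1["f1_mean"] >= 0.9).all()  # separable planted signal

    def test_best_config_prefers_fewer_features_on_ties(self):
        df = pd.DataFrame(
            {
                "config": ["a", "b"],
                "n_selected": [30, 10],
                "f1_mean": [0.9, 0.9],
            }
        )
        assert best_config(df)["config"] == "b"

    def test_empty_grid_rejected(self, planted):
        X, y, _ = planted
        with pytest.raises(ValueError):
            sd.run_experiments([], X, y, X, y)
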