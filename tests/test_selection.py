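"""Lande–Arnold selection gradients and metric pre-selection."""

import numpy as np
import pandas as pd
import pytest

from evocamo import selection


def stratum_frame(traits: dict, fitness, rep=0, speed="fast", gen=0):
    n = len(fitness)
    return pd.DataFrame(
        {"replicate_id": rep, "speed_class": speed, "generation": gen,
         "fitness": fitness, **traits}
    )


class TestStandardize:
    def test_relative_fitness_averages_one(self):
        rng = np.random.default_rng(0)
        df = stratum_frame({"t": rng.normal(size=50)}, rng.uniform(1, 4, 50))
        _, w, _, _ = selection.standardize_and_relativize(df, ["t"])
        assert w.mean() == pytest.approx(1.0, abs=1e-12)

    def test_z_scores_match_direct_formula(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(0, 60, 40)
        df = stratum_frame({"t": col}, rng.uniform(1, 4, 40))
        z, _, kept, _ = selection.standardize_and_relativize(df, ["t"])
        expected = (col - col.mean()) / col.std()
        assert np.allclose(z["t"].to_numpy(), expected, atol=1e-9)
        assert kept == ["t"]

    def test_zero_variance_trait_dropped_with_flag(self):
        rng = np.random.default_rng(2)
        df = stratum_frame({"t": np.ones(30), "u": rng.normal(size=30)},
                           rng.uniform(1, 4, 30))
        _, _, kept, flags = selection.standardize_and_relativize(df, ["t", "u"])
        assert kept == ["u"]
        assert any("zero-variance" in f and "'t'" in f for f in flags)

    def test_constant_fitness_flagged(self):
        rng = np.random.default_rng(3)
        df = stratum_frame({"t": rng.normal(size=30)}, np.full(30, 2.0))
        z, w, kept, flags = selection.standardize_and_relativize(df, ["t"])
        assert any("fitness" in f for f in flags)
        beta = selection.selection_gradients(z[kept], w)
        assert np.allclose(beta, 0.0)

    def test_too_small_stratum_rejected(self):
        df = stratum_frame({"t": [1.0, 2.0]}, [1.0, 2.0])
        with pytest.raises(ValueError, match="bugs"):
            selection.standardize_and_relativize(df, ["t"])


class TestSelectionGradients:
    def test_noiseless_single_trait(self):
        z = np.linspace(-2, 2, 30)
        df = stratum_frame({"t": z}, 1 + 0.3 * (z - z.mean()) / z.std())
        grad = selection.stratum_gradient(df, ["t"])
        assert grad.beta[0] == pytest.approx(0.3, abs=1e-9)

    def test_planted_two_trait_recovery(self):
        # beta = (0.2, -0.1) at n = 128 recovered within +/-0.03 on average
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            z1, z2 = rng.normal(size=128), rng.normal(size=128)
            w = 1 + 0.2 * z1 - 0.1 * z2 + rng.normal(0, 0.05, 128)
            df = stratum_frame({"a": z1, "b": z2}, 2.0 * w)
            grad = selection.stratum_gradient(df, ["a", "b"])
            errs.append(grad.beta - np.array([0.2, -0.1]))
        mean_err = np.abs(np.mean(errs, axis=0))
        assert np.all(mean_err <= 0.03)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            Z = rng.normal(size=(60, 3))
            w = 1 + Z @ [0.2, -0.1, 0.05] + rng.normal(0, 0.1, 60)
            z = pd.DataFrame(Z, columns=list("abc"))
            beta = selection.selection_gradients(z, pd.Series(w))
            # independent brute force: solve the normal equations directly
            X = np.hstack([np.ones((60, 1)), Z])
            oracle = np.linalg.solve(X.T @ X, X.T @ w)[1:]
            assert np.allclose(beta, oracle, atol=1e-8)

    def test_collinear_trait_dropped(self):
        rng = np.random.default_rng(8)
        z1 = rng.normal(size=50)
        df = stratum_frame({"a": z1, "b": 2 * z1 + 1}, rng.uniform(1, 3, 50))
        grad = selection.stratum_gradient(df, ["a", "b"])
        assert grad.traits == ["a"]
        assert "b" in grad.dropped_traits


class TestInformativeMetrics:
    def test_planted_signal_selected_first(self):
        rng = np.random.default_rng(0)
        n = 400
        sd_lum = rng.uniform(0, 60, n)
        df = pd.DataFrame(
            {"sd_lum": sd_lum,
             "gabor_vertical_s4": rng.normal(size=n),
             "edge_right_s4": rng.normal(size=n),
             "fitness": np.exp(1.0 - 0.01 * sd_lum + rng.normal(0, 0.05, n))}
        )
        chosen = selection.select_informative_metrics(df, k=2)
        assert chosen[0] == "sd_lum"

    def test_k_zero_returns_empty(self):
        df = pd.DataFrame({"sd_lum": [1.0, 2.0], "fitness": [1.0, 2.0]})
        assert selection.select_informative_metrics(df, k=0) == []

    def test_k_too_large_rejected(self):
        df = pd.DataFrame({"sd_lum": [1.0, 2.0], "fitness": [1.0, 2.0]})
        with pytest.raises(ValueError, match="candidate"):
            selection.select_informative_metrics(df, k=5)


class TestTrajectory:
    def make_table(self, n_reps=3, n_gens=4, n_bugs=20, slope=0.2, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for rep in range(n_reps):
            for gen in range(n_gens):
                z = rng.normal(size=n_bugs)
                w = 1 + slope * z + rng.normal(0, 0.05, n_bugs)
                frames.append(stratum_frame({"sd_lum": 30 + 10 * z}, 2 * w,
                                            rep=rep, gen=gen))
        return pd.concat(frames, ignore_index=True)

    def test_replicate_averaging_shape(self):
        table = self.make_table()
        per_stratum, averaged = selection.gradient_trajectory(table, ["sd_lum"])
        assert len(averaged) == 4  # one row per (speed, generation, trait)
        assert set(averaged.columns) == {"speed_class", "generation", "trait", "beta"}

    def test_recovers_planted_gradient_sign(self):
        _, averaged = selection.gradient_trajectory(self.make_table(slope=-0.25),
                                                    ["sd_lum"])
        assert (averaged["beta"] < 0).all()


class TestGenerationTrend:
    def test_pure_noise_not_significant(self):
        rng = np.random.default_rng(0)
        slope, p = selection.generation_trend(rng.normal(0, 1, 40))
        assert p > 0.01

    def test_strong_drift_detected(self):
        rng = np.random.default_rng(1)
        y = np.cumsum(0.5 + rng.normal(0, 0.1, 40))
        slope, p = selection.generation_trend(y)
        assert slope == pytest.approx(0.5, abs=0.1)
        assert p < 1e-6

    def test_constant_series_inert(self):
        slope, p = selection.generation_trend(np.full(10, 3.0))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0
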