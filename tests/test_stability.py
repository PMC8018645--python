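"""Joint regression, ecovalence and AMMI: trivial identities, brute-force
double-centring oracles, and algebraic cross-links (sum of ecovalences =
interaction SS = sum of squared singular values)."""

import numpy as np
import pandas as pd
import pytest

from metaplast.stability import (
    ammi,
    best_environments,
    ecovalence,
    environmental_index,
    fw_regression,
)


def mat(arr, v="V", e="E"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{v}{i}" for i in range(arr.shape[0])],
        columns=[f"{e}{j}" for j in range(arr.shape[1])],
    )


def additive(n_v=4, n_e=5, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, 1, n_v)
    h = rng.normal(0, 2, n_e)
    return mat(10.0 + np.add.outer(g, h)), g, h


class TestEnvironmentalIndex:
    def test_additive_matrix_index_is_gbar_plus_h(self):
        m, g, h = additive()
        idx = environmental_index(m)
        np.testing.assert_allclose(idx.to_numpy(), 10.0 + g.mean() + h, rtol=1e-12)

    def test_constant_matrix_gives_constant_index(self):
        idx = environmental_index(mat(np.full((3, 4), 7.0)))
        np.testing.assert_allclose(idx.to_numpy(), 7.0)

    def test_missing_cell_error_names_cell(self):
        m = mat(np.ones((3, 3)))
        m.iloc[1, 2] = np.nan
        with pytest.raises(ValueError, match=r"V1.*E2"):
            environmental_index(m)


class TestFwRegression:
    def test_identity_response_gives_unit_slopes(self):
        m, _, _ = additive()
        fit = fw_regression(m)
        np.testing.assert_allclose(fit.slopes.to_numpy(), 1.0, atol=1e-10)

    def test_constant_variety_has_zero_slope(self):
        rng = np.random.default_rng(1)
        rows = [np.full(5, 3.0), rng.normal(0, 2, 5), rng.normal(0, 2, 5)]
        fit = fw_regression(mat(np.array(rows)))
        assert fit.slopes.iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_slopes_average_to_one(self, random_means):
        fit = fw_regression(random_means)
        assert fit.slopes.mean() == pytest.approx(1.0, rel=1e-9)

    def test_matches_polyfit_oracle(self, random_means):
        fit = fw_regression(random_means)
        i = random_means.mean(axis=0).to_numpy()
        for v in random_means.index:
            b, a = np.polyfit(i, random_means.loc[v].to_numpy(), 1)
            assert fit.table.loc[v, "slope"] == pytest.approx(b, rel=1e-9)
            assert fit.table.loc[v, "intercept"] == pytest.approx(a, rel=1e-9)

    def test_generator_slopes_recovered_within_two_se(self):
        from metaplast.core import block_means
        from metaplast.simulate import CompoundSpec, SimSpec, simulate_panel

        slopes = [0.5, 1.0, 1.5]
        spec = SimSpec(
            n_varieties=3, n_locations=10, n_years=2, n_blocks=2,
            compounds=[CompoundSpec("c1", mu=20, sigma_g=0.5, sigma_e=2.0,
                                    sigma_resid=0.3)],
            fw_slopes={"c1": slopes}, seed=31,
        )
        table, _ = simulate_panel(spec)
        fit = fw_regression(block_means(table)["c1"])
        for v, beta in zip(fit.table.index, slopes):
            err = abs(fit.table.loc[v, "slope"] - beta)
            assert err <= 2.0 * fit.table.loc[v, "slope_se"]

    def test_degenerate_index_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fw_regression(mat(np.ones((3, 4))))


class TestEcovalence:
    def test_purely_additive_matrix_has_zero_ecovalence(self):
        m, _, _ = additive()
        res = ecovalence(m)
        np.testing.assert_allclose(res.table["ecovalence"].to_numpy(), 0.0, atol=1e-18)

    def test_single_cell_perturbation_matches_brute_force(self):
        m, _, _ = additive(n_v=4, n_e=5, seed=3)
        delta = 2.0
        m2 = m.copy()
        m2.iloc[1, 2] += delta
        y = m2.to_numpy()
        z = y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + y.mean()
        res = ecovalence(m2)
        np.testing.assert_allclose(res.table["ecovalence"].to_numpy(), (z**2).sum(1), rtol=1e-10)
        # touched variety carries the dominant ((1-1/V)(1-1/E) delta)^2 term
        v, e = 4, 5
        lead = ((1 - 1 / v) * (1 - 1 / e) * delta) ** 2
        assert res.table["ecovalence"].iloc[1] == pytest.approx(lead + (z[1] ** 2).sum() - z[1, 2] ** 2)

    def test_sum_equals_two_way_interaction_ss(self, random_means):
        res = ecovalence(random_means)
        y = random_means.to_numpy()
        z = y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + y.mean()
        assert res.interaction_ss == pytest.approx((z**2).sum(), rel=1e-12)
        assert res.table["share"].sum() == pytest.approx(1.0)

    def test_shift_invariance(self, random_means):
        base = ecovalence(random_means).table["ecovalence"]
        shifted = ecovalence(random_means + 100.0).table["ecovalence"]
        per_env = ecovalence(
            random_means + np.arange(random_means.shape[1])
        ).table["ecovalence"]
        np.testing.assert_allclose(base, shifted, atol=1e-9)
        np.testing.assert_allclose(base, per_env, atol=1e-9)

    def test_incomplete_matrix_rejected(self):
        m = mat(np.ones((3, 3)))
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            ecovalence(m)


class TestAmmi:
    def test_rank_one_interaction_recovered(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=5)
        w = rng.normal(size=6)
        u -= u.mean()
        w -= w.mean()
        m = mat(10.0 + np.outer(u, w))
        model = ammi(m, k=1)
        lam = model.singular_values
        assert np.all(lam[1:] < 1e-9 * lam[0])
        got = model.variety_scores["IPC1"].to_numpy()
        want = u / np.linalg.norm(u)
        assert min(np.abs(got - want).max(), np.abs(got + want).max()) < 1e-9

    def test_lambda_squares_equal_ecovalence_sum(self, random_means):
        model = ammi(random_means, k=2)
        eco = ecovalence(random_means)
        assert model.interaction_ss == pytest.approx(eco.interaction_ss, rel=1e-12)

    def test_full_rank_reconstruction(self, random_means):
        k_full = min(random_means.shape) - 1
        model = ammi(random_means, k=k_full)
        np.testing.assert_allclose(
            model.fitted(k_full).to_numpy(), random_means.to_numpy(), atol=1e-9
        )

    def test_main_effects_sum_to_zero_and_scores_orthonormal(self, random_means):
        model = ammi(random_means, k=2)
        assert model.genotype_effects.sum() == pytest.approx(0.0, abs=1e-10)
        assert model.environment_effects.sum() == pytest.approx(0.0, abs=1e-10)
        u = model.variety_scores.to_numpy()
        np.testing.assert_allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-10)

    def test_sign_convention_deterministic(self, random_means):
        m1 = ammi(random_means, k=2)
        m2 = ammi(random_means.copy(), k=2)
        pd.testing.assert_frame_equal(m1.environment_scores, m2.environment_scores)
        for k in range(m1.environment_scores.shape[1]):
            col = m1.environment_scores.iloc[:, k]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_k_too_large_rejected(self, random_means):
        with pytest.raises(ValueError):
            ammi(random_means, k=min(random_means.shape))

    def test_ipc1_recovery_under_noise(self):
        """Across 200 simulated compounds with rank-1 interaction at SNR 4,
        fitted IPC1 variety scores correlate strongly with the planted ones."""
        rng = np.random.default_rng(7)
        n_v, n_e = 5, 12
        good = 0
        for _ in range(200):
            u = rng.normal(size=n_v)
            w = rng.normal(size=n_e)
            u -= u.mean()
            w -= w.mean()
            inter = np.outer(u, w)
            inter *= 1.0 / np.sqrt((inter**2).mean())  # RMS 1 interaction
            noise = rng.normal(0, 0.25, size=(n_v, n_e))  # SNR 4
            model = ammi(mat(10.0 + inter + noise), k=1)
            got = model.variety_scores["IPC1"].to_numpy()
            rho = abs(np.corrcoef(got, u)[0, 1])
            good += rho > 0.9
        assert good / 200 > 0.95


class TestBestEnvironments:
    def test_additive_model_ranks_identically_for_all_varieties(self):
        m, _, _ = additive()
        model = ammi(m, k=1)
        orders = [tuple(best_environments(model, v).index) for v in m.index]
        assert len(set(orders)) == 1

    def test_planted_interaction_favours_target_environment(self):
        m, _, _ = additive(n_v=4, n_e=5, seed=9)
        m.iloc[2, 3] += 50.0
        model = ammi(m, k=1)
        assert best_environments(model, "V2").index[0] == "E3"

    def test_full_rank_ranking_equals_raw_cell_means(self, random_means):
        k_full = min(random_means.shape) - 1
        model = ammi(random_means, k=k_full)
        v = random_means.index[0]
        expected = list(random_means.loc[v].sort_values(ascending=False).index)
        assert list(best_environments(model, v).index) == expected

    def test_unknown_variety_rejected(self, random_means):
        model = ammi(random_means, k=1)
        with pytest.raises(KeyError):
            best_environments(model, "nope")
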