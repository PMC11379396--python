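"""Minres extraction, quartimin rotation, factor-count votes and fit stats."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from crossfa import (
    EfaConfig,
    choose_n_factors,
    correlation_model,
    empirical_bic,
    fit_minres,
    item_exclusion_loop,
    kmo_msa,
    model_fit_stats,
    parallel_analysis,
    rotate_oblimin,
    vss_complexity1,
)
from crossfa.data_model import MeanRatingsMatrix
from crossfa.efa import CorrelationModel, fit_factor_model, model_df, residual_correlations


def _mrm(values: np.ndarray, items=None) -> MeanRatingsMatrix:
    items = items or [f"i{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, columns=items,
                      index=[f"s{i}" for i in range(values.shape[0])])
    return MeanRatingsMatrix(values=df, n_raters_per_cell=df.notna().astype(int))


def _model_R(lam: np.ndarray, phi: np.ndarray | None = None) -> np.ndarray:
    phi = phi if phi is not None else np.eye(lam.shape[1])
    R = lam @ phi @ lam.T
    np.fill_diagonal(R, 1.0)
    return R


def _sample_from_R(R: np.ndarray, n: int, rng) -> np.ndarray:
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
    return rng.standard_normal((n, len(R))) @ chol.T


def _simple_lam(p: int, k: int, loading: float = 0.7) -> np.ndarray:
    lam = np.zeros((p, k))
    lam[np.arange(p), np.arange(p) % k] = loading
    return lam


class TestCorrelationModel:
    def test_identical_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 1))
        m = _mrm(np.column_stack([x, x, -x]) + 0, ["a", "b", "c"])
        # add tiny noise to avoid the constant-column guard being confused
        cm = correlation_model(m)
        assert cm.R[0, 1] == pytest.approx(1.0)
        assert cm.R[0, 2] == pytest.approx(-1.0)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 3))
        cm = correlation_model(_mrm(x))
        for a in range(3):
            for b in range(3):
                xa, xb = x[:, a], x[:, b]
                num = np.sum((xa - xa.mean()) * (xb - xb.mean()))
                den = np.sqrt(np.sum((xa - xa.mean()) ** 2) * np.sum((xb - xb.mean()) ** 2))
                assert cm.R[a, b] == pytest.approx(num / den, abs=1e-12)

    def test_constant_column_rejected(self):
        x = np.column_stack([np.arange(4.0), np.full(4, 2.0)])
        with pytest.raises(ValueError, match="i1"):
            correlation_model(_mrm(x))


class TestKmoMsa:
    def test_two_items_give_half(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        msa, overall, _ = kmo_msa(CorrelationModel(("a", "b"), R, 50))
        assert msa["a"] == pytest.approx(0.5)
        assert msa["b"] == pytest.approx(0.5)

    def test_identity_degenerate(self):
        msa, overall, _ = kmo_msa(CorrelationModel(("a", "b", "c"), np.eye(3), 50))
        assert msa.isna().all()

    def test_matches_pairwise_partial_oracle(self):
        """Anti-image partials recomputed per pair by explicit conditioning."""
        rng = np.random.default_rng(2)
        lam = _simple_lam(6, 2, 0.7)
        R = _model_R(lam)
        cm = CorrelationModel(tuple(f"i{j}" for j in range(6)), R, 100)
        msa, _, _ = kmo_msa(cm)
        p = 6
        for j in range(p):
            r2 = q2 = 0.0
            for k in range(p):
                if k == j:
                    continue
                others = [m for m in range(p) if m not in (j, k)]
                Roo = R[np.ix_(others, others)]
                rj = R[j, others]
                rk = R[k, others]
                sol_j = np.linalg.solve(Roo, rj)
                sol_k = np.linalg.solve(Roo, rk)
                num = R[j, k] - rj @ sol_k
                den = np.sqrt((1 - rj @ sol_j) * (1 - rk @ sol_k))
                q2 += (num / den) ** 2
                r2 += R[j, k] ** 2
            assert msa.iloc[j] == pytest.approx(r2 / (r2 + q2), abs=1e-10)


class TestMinres:
    def test_compound_symmetry_closed_form(self):
        R = np.full((3, 3), 0.49)
        np.fill_diagonal(R, 1.0)
        L, psi, obj, _ = fit_minres(CorrelationModel(("a", "b", "c"), R, 100), 1)
        np.testing.assert_allclose(L.ravel(), [0.7, 0.7, 0.7], atol=1e-6)

    def test_identity_gives_zero_loadings(self):
        L, psi, obj, _ = fit_minres(CorrelationModel(tuple("abcd"), np.eye(4), 100), 1)
        assert np.abs(L).max() < 1e-6
        assert obj == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_matches_brute_force_oracle(self, seed):
        """Derivative-free multistart optimizer over uniquenesses reaches the
        same off-diagonal objective to 1e-6 on 8-item, 2-factor instances."""
        rng = np.random.default_rng(seed)
        lam = _simple_lam(8, 2, 0.65) + rng.normal(0, 0.1, size=(8, 2))
        R = np.corrcoef(_sample_from_R(_model_R(lam), 300, rng), rowvar=False)
        cm = CorrelationModel(tuple(f"i{j}" for j in range(8)), R, 300)
        _, _, obj, _ = fit_minres(cm, 2)

        def oracle_obj(psi):
            psi = np.clip(psi, 1e-3, 1.0)
            vals, vecs = np.linalg.eigh(R - np.diag(psi))
            idx = np.argsort(vals)[::-1][:2]
            L = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))
            E = R - L @ L.T
            np.fill_diagonal(E, 0)
            return np.sum(E**2)

        best = np.inf
        for trial in range(12):
            x0 = rng.uniform(0.05, 0.95, size=8)
            res = optimize.minimize(oracle_obj, x0, method="Nelder-Mead",
                                    options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12})
            best = min(best, res.fun)
        assert obj <= best + 1e-6
        assert abs(obj - best) < 1e-6

    def test_heywood_case_clamped_and_flagged(self):
        # implied loading on item 1 exceeds 1 (0.9*0.9/0.3 > 1): classic Heywood
        R = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.3], [0.9, 0.3, 1.0]])
        L, psi, _, heywood = fit_minres(CorrelationModel(("a", "b", "c"), R, 100), 1)
        assert heywood[0]
        assert psi[0] == pytest.approx(1e-3, abs=1e-9)

    def test_column_order_and_sign_convention(self):
        rng = np.random.default_rng(4)
        lam = np.zeros((9, 2))
        lam[:6, 0], lam[6:, 1] = 0.8, 0.7
        R = np.corrcoef(_sample_from_R(_model_R(lam), 500, rng), rowvar=False)
        L, *_ = fit_minres(CorrelationModel(tuple(f"i{j}" for j in range(9)), R, 500), 2)
        ss = (L**2).sum(axis=0)
        assert ss[0] >= ss[1]
        assert (L.sum(axis=0) >= 0).all()


class TestOblimin:
    def test_perfect_cluster_is_fixed_point(self):
        lam = np.zeros((10, 2))
        lam[:5, 0], lam[5:, 1] = 0.8, 0.7
        L, phi, _ = rotate_oblimin(lam)
        np.testing.assert_allclose(np.abs(L), np.abs(lam), atol=1e-3)
        np.testing.assert_allclose(phi, np.eye(2), atol=1e-3)

    @pytest.mark.parametrize("seed", range(3))
    def test_recovers_premixed_simple_structure(self, seed):
        rng = np.random.default_rng(seed)
        lam = _simple_lam(12, 3, 0.75)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        L, phi, _ = rotate_oblimin(lam @ Q)
        # each recovered column congruent >= 0.99 with some original column
        for j in range(3):
            c = [
                abs(L[:, j] @ lam[:, m])
                / (np.linalg.norm(L[:, j]) * np.linalg.norm(lam[:, m]))
                for m in range(3)
            ]
            assert max(c) >= 0.99

    def test_criterion_descends(self):
        rng = np.random.default_rng(9)
        lam = rng.normal(size=(15, 3))
        _, _, trace = rotate_oblimin(lam)
        assert trace[-1] <= trace[0] + 1e-12
        assert all(b <= a + 1e-10 for a, b in zip(trace, trace[1:]))

    def test_single_factor_passthrough(self):
        lam = np.array([[0.6], [0.7]])
        L, phi, _ = rotate_oblimin(lam)
        np.testing.assert_allclose(L, lam)
        np.testing.assert_allclose(phi, [[1.0]])


class TestFactorCountVotes:
    def test_parallel_analysis_null_and_recovery(self):
        null_ok = recover_ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noise = _mrm(rng.standard_normal((100, 10)))
            if parallel_analysis(noise, seed=seed + 1) <= 1:
                null_ok += 1
            lam = _simple_lam(15, 3, 0.7)
            data = _sample_from_R(_model_R(lam), 150, rng)
            if parallel_analysis(_mrm(data), seed=seed + 1) == 3:
                recover_ok += 1
        assert null_ok >= 47      # >= 95% of 50
        assert recover_ok >= 45   # >= 90% of 50

    def test_parallel_analysis_depends_on_R_only(self):
        rng = np.random.default_rng(0)
        data = _sample_from_R(_model_R(_simple_lam(10, 2)), 200, rng)
        cm = correlation_model(_mrm(data))
        k1 = parallel_analysis(cm, seed=5)
        k2 = parallel_analysis(cm, seed=5)
        assert k1 == k2

    def test_vss_exact_one_factor(self):
        R = _model_R(_simple_lam(8, 1, 0.7))
        cm = CorrelationModel(tuple(f"i{j}" for j in range(8)), R, 200)
        stats, k = vss_complexity1(cm, 3)
        assert k == 1
        assert all(0 <= v <= 1 for v in stats.values())

    def test_vss_recovers_two_oblique_factors(self):
        phi = np.array([[1.0, 0.3], [0.3, 1.0]])
        ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            lam = _simple_lam(12, 2, 0.75)
            data = _sample_from_R(_model_R(lam, phi), 150, rng)
            cm = correlation_model(_mrm(data))
            _, k = vss_complexity1(cm, 4)
            ok += k == 2
        assert ok >= 45

    def test_ebic_zero_residual_at_true_k(self):
        lam = _simple_lam(12, 2, 0.7)
        R = _model_R(lam)
        cm = CorrelationModel(tuple(f"i{j}" for j in range(12)), R, 150)
        stats, k = empirical_bic(cm, 4)
        assert k <= 2
        L0, *_ = fit_minres(cm, 2)
        E = residual_correlations(R, L0)
        assert np.abs(E).max() < 1e-4

    def test_ebic_recovery_and_monotone_chisq(self):
        ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            lam = _simple_lam(15, 3, 0.75)
            data = _sample_from_R(_model_R(lam), 150, rng)
            cm = correlation_model(_mrm(data))
            _, k = empirical_bic(cm, 5)
            ok += k == 3
        assert ok >= 40   # >= 80% of 50
        # nested models: residual chi-square non-increasing in k
        rng = np.random.default_rng(123)
        data = _sample_from_R(_model_R(_simple_lam(12, 3, 0.7)), 200, rng)
        cm = correlation_model(_mrm(data))
        echisq = []
        for k in range(1, 5):
            L0, *_ = fit_minres(cm, k)
            E = residual_correlations(cm.R, L0)
            echisq.append(np.sum(E[np.triu_indices(12, 1)] ** 2))
        assert all(b <= a + 1e-8 for a, b in zip(echisq, echisq[1:]))

    @pytest.mark.parametrize(
        "votes,expected", [((5, 5, 5), 5), ((4, 5, 7), 5), ((4, 4, 6), 4)]
    )
    def test_median_vote(self, votes, expected):
        assert choose_n_factors(*votes).k_chosen == expected


class TestFitStats:
    def test_perfect_fit_zero_rmsr(self):
        lam = _simple_lam(9, 2, 0.7)
        R = _model_R(lam)
        cm = CorrelationModel(tuple(f"i{j}" for j in range(9)), R, 100)
        L, phi, psi, _, _ = fit_factor_model(cm, 2)
        stats = model_fit_stats(cm, L, phi, psi)
        assert stats["rmsr"] == pytest.approx(0.0, abs=1e-5)

    def test_alpha_limit_for_perfectly_correlated_items(self):
        p = 5
        R = np.ones((p, p))
        cm = CorrelationModel(tuple(f"i{j}" for j in range(p)), R, 100)
        stats = model_fit_stats(cm, np.ones((p, 1)), np.eye(1), np.zeros(p))
        assert stats["alpha"] == pytest.approx(1.0)

    def test_omega_total_matches_generating_model(self):
        """Fitted omega within 0.02 of 1 - sum(u2)/sum(R) from the truth."""
        devs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lam = _simple_lam(12, 2, 0.75)
            R_pop = _model_R(lam)
            omega_pop = 1 - (1 - np.diag(lam @ lam.T)).sum() / R_pop.sum()
            data = _sample_from_R(R_pop, 400, rng)
            cm = correlation_model(_mrm(data))
            L, phi, psi, _, _ = fit_factor_model(cm, 2)
            stats = model_fit_stats(cm, L, phi, psi)
            devs.append(stats["omega_total"] - omega_pop)
        assert abs(np.mean(devs)) < 0.02

    def test_rotation_preserves_fit(self):
        rng = np.random.default_rng(3)
        lam = _simple_lam(12, 3, 0.7)
        data = _sample_from_R(_model_R(lam), 250, rng)
        cm = correlation_model(_mrm(data))
        L0, psi, obj, _ = fit_minres(cm, 3)
        L, phi, _ = rotate_oblimin(L0)
        E_un = residual_correlations(cm.R, L0)
        E_rot = residual_correlations(cm.R, L, phi)
        np.testing.assert_allclose(np.sum(E_un**2), np.sum(E_rot**2), atol=1e-8)
        h2_un = (L0**2).sum(axis=1)
        h2_rot = np.diag(L @ phi @ L.T)
        np.testing.assert_allclose(h2_un, h2_rot, atol=1e-8)

    def test_reconstruction_equals_objective(self):
        rng = np.random.default_rng(8)
        data = _sample_from_R(_model_R(_simple_lam(10, 2, 0.7)), 200, rng)
        cm = correlation_model(_mrm(data))
        L, phi, psi, obj, _ = fit_factor_model(cm, 2)
        E = residual_correlations(cm.R, L, phi)
        assert np.sum(E**2) == pytest.approx(obj, abs=1e-8)


class TestExclusionLoop:
    def test_clean_input_is_fixed_point(self):
        rng = np.random.default_rng(0)
        lam = _simple_lam(12, 2, 0.8)
        data = _sample_from_R(_model_R(lam), 300, rng)
        sol, log, vote = item_exclusion_loop(
            _mrm(data), EfaConfig(k_max=4), seed=0
        )
        assert log.entries == []
        assert len(sol.items) == 12

    def test_noise_items_excluded_across_seeds(self):
        ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            lam = _simple_lam(20, 2, 0.8)
            data = _sample_from_R(_model_R(lam), 200, rng)
            noise = rng.standard_normal((200, 2))
            values = np.hstack([data, noise])
            items = [f"i{j}" for j in range(20)] + ["junk0", "junk1"]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol, log, _ = item_exclusion_loop(
                    _mrm(values, items), EfaConfig(k_max=4), seed=seed
                )
            if {"junk0", "junk1"} <= set(log.items):
                ok += 1
        assert ok >= 45

    def test_under_identified_raises(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((50, 5))
        with pytest.raises(Exception):
            item_exclusion_loop(_mrm(data), EfaConfig(freeze_k=4), seed=0)

    def test_exclusion_stage_vocabulary(self):
        from crossfa.data_model import ExclusionStage

        assert ExclusionStage.LOW_ICC.value == "Low ICC"
        assert ExclusionStage.LOW_MSA.value == "Low MSA"
        assert ExclusionStage.LOW_COMMUNALITY.value == "Low Communality"
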