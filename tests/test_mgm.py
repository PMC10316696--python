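"""Mixed graphical model: pseudo-likelihood, proximal fit, edge extraction."""

import numpy as np
import pandas as pd
import pytest

from knockdag.dataset import Dataset, VariableMeta, standardize
from knockdag.mgm import (
    MgmFit,
    MgmModel,
    MgmPenalties,
    _MgmData,
    extract_linear_edges,
    fit_mgm,
    neg_pseudolikelihood,
)


def _chain_gaussian(rng, n=2000):
    """5 standardized variables; precision couples (a,b) and (c,d) only."""
    prec = np.eye(5)
    prec[0, 1] = prec[1, 0] = -0.4
    prec[2, 3] = prec[3, 2] = -0.4
    sigma = np.linalg.inv(prec)
    x = rng.standard_normal((n, 5)) @ np.linalg.cholesky(sigma).T
    d = Dataset.from_dataframe(pd.DataFrame(x, columns=list("abcde")))
    return standardize(d, which="all")[0]


class TestObjective:
    def test_null_model_equals_sum_of_intercept_losses(self, rng):
        std = _chain_gaussian(rng, 400)
        data = _MgmData(std)
        fit = MgmFit.zeros(data)
        # oracle: per-node Gaussian loss at the intercept-only fit, averaged over samples
        expected = sum(0.5 * np.mean(std.column(c) ** 2) for c in std.names)
        assert neg_pseudolikelihood(std, fit) == pytest.approx(expected, rel=1e-12)

    def test_continuous_objective_equals_per_node_ols_losses(self, rng):
        std = _chain_gaussian(rng, 300)
        data = _MgmData(std)
        fit = MgmFit.zeros(data)
        b = rng.normal(0, 0.2, (5, 5))
        fit.beta = (b + b.T) / 2
        np.fill_diagonal(fit.beta, 0.0)
        fit.alpha_pot = rng.normal(0, 0.1, 5)
        # independent recomputation: one least-squares loss per node, shared beta
        x = std.values
        expected = 0.0
        for s in range(5):
            mean_s = fit.alpha_pot[s] + x @ fit.beta[:, s]
            expected += 0.5 * np.mean((x[:, s] - mean_s) ** 2)
        assert neg_pseudolikelihood(std, fit) == pytest.approx(expected, rel=1e-10)

    def test_non_finite_parameters_rejected(self, rng):
        std = _chain_gaussian(rng, 100)
        fit = MgmFit.zeros(_MgmData(std))
        fit.beta[0, 1] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            neg_pseudolikelihood(std, fit)


class TestFit:
    def test_huge_penalty_zeroes_every_block(self, rng):
        std = _chain_gaussian(rng, 300)
        fit = fit_mgm(std, MgmPenalties(50.0, 50.0, 50.0))
        assert np.all(fit.beta == 0.0)
        assert len(extract_linear_edges(fit)) == 0

    def test_recovers_known_sparse_precision(self, rng):
        std = _chain_gaussian(rng, 2000)
        fit = fit_mgm(std, MgmPenalties(0.3, 0.3, 0.3))
        edges = extract_linear_edges(fit)
        found = {tuple(sorted((r.var_a, r.var_b))) for _, r in edges.iterrows()}
        assert found == {("a", "b"), ("c", "d")}

    def test_objective_trace_non_increasing(self, rng):
        std = _chain_gaussian(rng, 500)
        fit = fit_mgm(std, MgmPenalties(0.3, 0.3, 0.3))
        tr = fit.objective_trace
        assert len(tr) >= 2
        assert all(tr[i + 1] <= tr[i] + 1e-12 for i in range(len(tr) - 1))

    def test_stationarity_of_selected_coefficients(self, rng):
        # perturbing a surviving beta entry away from the optimum cannot
        # decrease the penalized objective
        std = _chain_gaussian(rng, 1500)
        pen = MgmPenalties(0.3, 0.3, 0.3)
        fit = fit_mgm(std, pen, max_iter=5000, tol=1e-13)
        i, j = 0, 1
        assert fit.beta[i, j] != 0.0
        base = neg_pseudolikelihood(std, fit) + 0.3 * abs(fit.beta[i, j])
        for h in (1e-4, -1e-4):
            pert = fit.copy_params()
            pert.beta[i, j] += h
            pert.beta[j, i] += h
            val = neg_pseudolikelihood(std, pert) + 0.3 * abs(pert.beta[i, j])
            assert val >= base - 1e-8

    def test_row_permutation_invariance(self, rng):
        std = _chain_gaussian(rng, 800)
        perm = rng.permutation(std.n_samples)
        shuffled = Dataset(std.values[perm], list(std.meta), [std.sample_ids[k] for k in perm])
        f1 = fit_mgm(std, MgmPenalties())
        f2 = fit_mgm(shuffled, MgmPenalties())
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)

    def test_column_permutation_permutes_fit(self, rng):
        std = _chain_gaussian(rng, 800)
        order = [2, 0, 4, 1, 3]
        permuted = Dataset(std.values[:, order], [std.meta[k] for k in order], list(std.sample_ids))
        f1 = fit_mgm(std, MgmPenalties())
        f2 = fit_mgm(permuted, MgmPenalties())
        p = np.asarray(order)
        np.testing.assert_allclose(f2.beta, f1.beta[np.ix_(p, p)], atol=1e-8)

    def test_false_edge_rate_on_independent_noise(self, rng):
        n_edges = 0
        n_pairs = 0
        for seed in range(5):
            g = np.random.default_rng(1000 + seed)
            d = Dataset.from_dataframe(pd.DataFrame(g.standard_normal((1000, 10))))
            std, _ = standardize(d, which="all")
            n_edges += len(extract_linear_edges(fit_mgm(std, MgmPenalties(0.3, 0.3, 0.3))))
            n_pairs += 45
        assert n_edges / n_pairs < 0.05

    def test_too_few_samples_rejected(self, rng):
        d = Dataset.from_dataframe(pd.DataFrame(rng.standard_normal((8, 3))))
        with pytest.raises(ValueError):
            fit_mgm(d)


class TestMixedBlocks:
    def test_ordinal_driven_by_continuous_recovered(self, rng):
        x = rng.standard_normal((2000, 3))
        codes = (x[:, 0] > 0.5).astype(float) + (x[:, 0] > -0.5).astype(float)
        meta = [VariableMeta(c, "continuous") for c in "abc"] + [VariableMeta("g", "ordinal", (0, 1, 2))]
        d = Dataset(np.column_stack([x, codes]), meta)
        res = MgmModel(d).fit()
        found = {tuple(sorted((r.var_a, r.var_b))) for _, r in res.edges.iterrows()}
        assert ("a", "g") in found
        assert ("b", "g") not in found and ("c", "g") not in found

    def test_edge_effect_sizes_are_block_norms(self):
        fit = MgmFit(
            cont_names=["u", "v"], disc_names=["g"], levels=[3],
            beta=np.array([[0.0, -0.4], [-0.4, 0.0]]),
            alpha_pot=np.zeros(2),
            nu=[np.array([[0.3, 0.0, -0.4], [0.0, 0.0, 0.0]])],
            phi={},
            disc_pot=[np.zeros(3)],
        )
        edges = extract_linear_edges(fit)
        eff = {tuple(sorted((r.var_a, r.var_b))): r.effect_size for _, r in edges.iterrows()}
        assert eff[("u", "v")] == pytest.approx(0.4)  # |beta|
        assert eff[("g", "u")] == pytest.approx(0.5)  # ||nu row||_2
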