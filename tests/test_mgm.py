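"""Nodewise EBIC-LASSO estimation: formula oracles, recovery, invariants."""

import numpy as np
import pytest

from psychnet.exceptions import SpecError
from psychnet.mgm import (
    EstimationConfig,
    MixedGraphicalModel,
    ebic,
    estimate_network,
    estimate_with_covariates,
    fit_node,
)
from psychnet.simulate import GeneratorConfig, generate_cohort

from conftest import make_continuous_dataset

FAST = EstimationConfig(n_lambda=40)


class TestEbicFormula:
    def test_direct_arithmetic(self):
        # 200 + 3 log 100 + 2*0.25*3 log 10
        assert ebic(-100.0, 3, 100, 10, 0.25) == pytest.approx(217.2694, abs=1e-4)

    def test_gamma_zero_reduces_to_bic(self):
        assert ebic(-100.0, 3, 100, 10, 0.0) == pytest.approx(213.8155, abs=1e-4)

    @pytest.mark.parametrize("gamma", [0.0, 0.25, 0.5])
    def test_k_zero_ignores_gamma(self, gamma):
        assert ebic(-42.0, 0, 500, 12, gamma) == 84.0

    def test_negative_k_fatal(self):
        with pytest.raises(SpecError):
            ebic(-1.0, -1, 10, 3, 0.25)

    def test_config_bounds(self):
        with pytest.raises(SpecError):
            EstimationConfig(gamma=0.7)
        with pytest.raises(SpecError):
            EstimationConfig(rule="XOR")


class TestFitNode:
    def test_near_duplicate_predictor_recovered(self, rng):
        n = 500
        x = rng.standard_normal(n)
        noise = rng.standard_normal((n, 5))
        y = x + 0.01 * rng.standard_normal(n)
        data = make_continuous_dataset(
            np.column_stack([y, x, noise]),
            names=["y", "x"] + [f"z{i}" for i in range(5)],
        )
        fit = fit_node("y", data, FAST)
        assert fit.aggregates["x"] == pytest.approx(1.0, abs=0.02)
        for i in range(5):
            assert fit.aggregates[f"z{i}"] == 0.0
        assert fit.signs["x"] == 1

    def test_independent_columns_select_nothing(self):
        empties = 0
        for seed in range(5):
            data, _ = generate_cohort(GeneratorConfig(n=1000, seed=seed, preset="independent"))
            fits = [fit_node(v, data, FAST) for v in data.names]
            if all(f.k == 0 for f in fits):
                empties += 1
        assert empties >= 4

    def test_null_model_ebic_at_lambda_max(self, rng):
        """At the top of the path (k = 0) the EBIC equals -2x the null
        Gaussian log-likelihood of the standardized target."""
        data = make_continuous_dataset(rng.standard_normal((200, 4)))
        fit = fit_node("V1", data, FAST)
        n = 200
        rss0 = n - 1  # standardized target, mean-zero model
        ll0 = -0.5 * n * (np.log(2 * np.pi * rss0 / n) + 1)
        assert fit.k_path[0] == 0
        assert fit.ebic_path[0] == pytest.approx(-2 * ll0, rel=1e-10)

    def test_monotone_sparsity_at_selection(self, rng):
        data = make_continuous_dataset(rng.standard_normal((150, 5)))
        for v in data.names:
            fit = fit_node(v, data, FAST)
            assert fit.k <= fit.k_path[-1] or fit.k == 0


class TestEstimateNetwork:
    def test_chain_recovery(self):
        hits = 0
        for seed in range(1, 6):
            data, _ = generate_cohort(GeneratorConfig(n=2000, seed=seed, preset="chain"))
            net = estimate_network(data, FAST)
            if {(a, b) for a, b, _, _ in net.edge_list()} == {("V1", "V2"), ("V2", "V3")}:
                hits += 1
        assert hits >= 4

    def test_independent_preset_empty(self):
        empties = 0
        for seed in range(5):
            data, _ = generate_cohort(GeneratorConfig(n=1000, seed=seed, preset="independent"))
            if estimate_network(data, FAST).n_edges() == 0:
                empties += 1
        assert empties >= 4

    def test_symmetry_and_and_rule_audit(self, mixed_dataset):
        est = MixedGraphicalModel(n_lambda=40).fit(mixed_dataset)
        w = est.weights_
        assert np.array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        for i, a in enumerate(est.nodes_):
            for j, b in enumerate(est.nodes_):
                if i < j and w[i, j] != 0:
                    assert est.nodewise_[a].aggregates[b] > 0
                    assert est.nodewise_[b].aggregates[a] > 0

    def test_categorical_edges_unsigned_nonnegative(self, mixed_dataset):
        net = estimate_network(mixed_dataset, FAST)
        gi = net.nodes.index("g")
        for i in range(net.p):
            if net.weights[gi, i] != 0:
                assert not net.sign_defined[gi, i]
                assert net.weights[gi, i] > 0

    def test_gaussian_oracle_equivalence(self, rng):
        """Small all-continuous network: selected edges match the generating
        precision matrix and magnitudes track the true partial correlations."""
        names = ["a", "b", "c", "d"]
        partials = {("a", "b"): 0.35, ("b", "c"): 0.3, ("c", "d"): 0.4, ("a", "d"): 0.25}
        from psychnet.simulate import Marginal

        cfg = GeneratorConfig(
            n=5000, seed=42, preset="chain", names=names,
            communities=["X", "X", "Y", "Y"], roles=["factor"] * 4,
            marginals={v: Marginal("normal") for v in names}, partials=partials,
        )
        data, truth = generate_cohort(cfg)
        net = estimate_network(data, FAST)
        got = {(a, b) for a, b, _, _ in net.edge_list()}
        assert got == {tuple(sorted(k)) for k in partials}
        est = np.array([dict(net.edge_list() and {(a, b): w for a, b, w, _ in net.edge_list()})[
            tuple(sorted(k))] for k in partials])
        true = np.array(list(partials.values()))
        assert np.corrcoef(est, true)[0, 1] >= 0.95

    def test_gamma_increase_never_adds_edges(self):
        data, _ = generate_cohort(GeneratorConfig(n=800, seed=9, preset="chain"))
        loose = estimate_network(data, EstimationConfig(gamma=0.0, n_lambda=40))
        strict = estimate_network(data, EstimationConfig(gamma=0.5, n_lambda=40))
        e0 = {(a, b) for a, b, _, _ in loose.edge_list()}
        e5 = {(a, b) for a, b, _, _ in strict.edge_list()}
        assert e5 <= e0

    def test_preconditions(self, rng):
        small = make_continuous_dataset(rng.standard_normal((5, 3)))
        with pytest.raises(SpecError):
            estimate_network(small, FAST)
        two_cols = make_continuous_dataset(rng.standard_normal((50, 2)))
        with pytest.raises(SpecError):
            estimate_network(two_cols, FAST)


class TestCovariates:
    def test_unknown_covariate_fatal(self, mixed_dataset):
        with pytest.raises(SpecError):
            estimate_with_covariates(mixed_dataset, ["nope"], FAST)

    def test_metadata_records_covariates(self, mixed_dataset):
        net = estimate_with_covariates(mixed_dataset, ["g"], FAST)
        assert net.meta["covariates"] == ["g"]

    def test_independent_noise_covariate_preserves_subgraph(self, rng):
        stable = 0
        for seed in range(5):
            data, _ = generate_cohort(GeneratorConfig(n=2000, seed=seed, preset="chain"))
            base = estimate_network(data, FAST)
            noise_rng = np.random.default_rng(1000 + seed)
            aug = data.values.copy()
            aug["cov"] = noise_rng.standard_normal(data.n)
            from psychnet.data import CohortDataset, VariableSpec

            specs = data.specs + [VariableSpec("cov", community="COVARIATE", role="covariate")]
            aug_data = CohortDataset(aug, specs)
            net = estimate_with_covariates(aug_data, ["cov"], FAST)
            sub = {(a, b) for a, b, _, _ in net.edge_list() if "cov" not in (a, b)}
            if sub == {(a, b) for a, b, _, _ in base.edge_list()}:
                stable += 1
        assert stable >= 4

    def test_common_cause_induces_no_spurious_symptom_edge(self, rng):
        """x and y independent given the covariate c: with c in the model the
        x-y edge must stay absent (partialling, collider-free)."""
        hits = 0
        for seed in range(5):
            g = np.random.default_rng(seed)
            n = 2000
            c = g.standard_normal(n)
            x = 0.6 * c + g.standard_normal(n)
            y = 0.6 * c + g.standard_normal(n)
            data = make_continuous_dataset(np.column_stack([x, y, c]), names=["x", "y", "c"])
            net = estimate_with_covariates(data, ["c"], FAST)
            xi, yi = net.nodes.index("x"), net.nodes.index("y")
            if net.weights[xi, yi] == 0:
                hits += 1
        assert hits >= 4
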