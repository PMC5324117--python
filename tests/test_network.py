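"""Weighted co-expression network: TOM against the triple-loop oracle,
module recovery, eigengenes against direct SVD, trait ranking, hubs and
guilt-by-association."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lncmap.network import (
    UNASSIGNED,
    adjacency_matrix,
    adjacency_tom,
    build_network,
    detect_modules,
    guilt_by_association,
    identify_hubs,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    tom_from_adjacency,
)
from lncmap.simulate import ModuleSpec, simulate_coexpression


def tom_brute(adj: np.ndarray) -> np.ndarray:
    """Direct triple-loop topological overlap (oracle)."""
    n = adj.shape[0]
    k = adj.sum(axis=0) - 1.0
    tom = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum(adj[i, u] * adj[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = tom[j, i] = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return tom


def _expr(X):
    return pd.DataFrame(
        X, index=[f"g{i}" for i in range(X.shape[0])],
        columns=[f"s{j}" for j in range(X.shape[1])],
    )


class TestAdjacencyTom:
    def test_identical_pair_network(self):
        x = np.arange(10.0)
        net = adjacency_tom(_expr(np.vstack([x, 2 * x + 1])), beta=6)
        assert net.adjacency == pytest.approx(np.ones((2, 2)))
        assert net.tom == pytest.approx(np.ones((2, 2)))

    def test_uncorrelated_pair_without_neighbors_has_tiny_tom(self):
        rng = np.random.default_rng(25)
        X = rng.normal(size=(2, 500))
        net = adjacency_tom(_expr(X), beta=6)
        assert net.tom[0, 1] < 1e-3

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(26)
        X = rng.normal(size=(50, 20))
        adj = adjacency_matrix(_expr(X), beta=6)
        assert np.abs(tom_from_adjacency(adj) - tom_brute(adj)).max() < 1e-10

    def test_bounds_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(27)
        X = rng.normal(size=(40, 15))
        net = adjacency_tom(_expr(X), beta=4)
        for m in (net.adjacency, net.tom):
            assert np.allclose(m, m.T)
            assert np.all((m >= 0) & (m <= 1 + 1e-12))
            assert np.allclose(np.diag(m), 1.0)

    def test_constant_row_rejected(self):
        X = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            adjacency_tom(_expr(X), beta=6)


class TestSoftThreshold:
    def test_block_adjacency_invariant_to_beta_within_blocks(self):
        expr, labels, _ = simulate_coexpression(
            (ModuleSpec(10, 1.0, False), ModuleSpec(10, 1.0, False)), n_samples=20, seed=28
        )
        for beta in (1, 6, 12):
            adj = adjacency_matrix(expr, beta=beta)
            block = adj[:10, :10]
            assert block == pytest.approx(np.ones((10, 10)), abs=1e-9)

    def test_fallback_to_power_six(self):
        rng = np.random.default_rng(29)
        X = rng.normal(size=(40, 10))  # pure noise never fits scale-free well
        beta, table = pick_soft_threshold(_expr(X), candidate_powers=(1, 2), fit_min=0.999)
        assert beta == 6
        assert set(table["power"]) == {1, 2}

    def test_reproducible_selection_on_structured_data(self):
        picks = set()
        for seed in (1, 2, 3):
            expr, _, _ = simulate_coexpression(n_samples=30, n_background=60, seed=seed)
            beta, _ = pick_soft_threshold(expr)
            picks.add(beta)
        assert len(picks) == 1


class TestModules:
    def test_three_planted_blocks_recovered_exactly(self):
        expr, labels, _ = simulate_coexpression(seed=30)
        net = adjacency_tom(expr, beta=6)
        detected, _ = detect_modules(net.tom, net.gene_ids, min_module_size=30)
        assert adjusted_rand_score(labels.tolist(), detected.tolist()) == 1.0
        assert set(detected) == {"M1", "M2", "M3"}

    def test_pure_noise_is_mostly_unassigned(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(120, 30))
        net = adjacency_tom(_expr(X), beta=6)
        detected, _ = detect_modules(net.tom, net.gene_ids, min_module_size=30)
        assert (detected == UNASSIGNED).mean() > 0.5

    def test_duplicating_genes_preserves_partition(self):
        expr, labels, _ = simulate_coexpression(
            (ModuleSpec(20, 0.9, False), ModuleSpec(20, 0.9, False)), n_samples=25, seed=32
        )
        doubled = pd.concat([expr, expr.set_index(expr.index + "_copy")])
        net = adjacency_tom(doubled, beta=6)
        detected, _ = detect_modules(net.tom, net.gene_ids, min_module_size=10)
        for g in expr.index:
            assert detected[g] == detected[g + "_copy"]


class TestEigengenes:
    def test_identical_rows_all_have_unit_kme(self):
        rng = np.random.default_rng(33)
        x = rng.normal(size=12)
        X = np.vstack([2 * x + 1, -3 * x, x])
        labels = pd.Series(["M1"] * 3, index=[f"g{i}" for i in range(3)])
        eg, kme, var = module_eigengenes(_expr(X).iloc[:3], labels)
        assert np.allclose(kme.abs(), 1.0)
        assert var["M1"] == pytest.approx(1.0)

    def test_sign_convention_positive_against_average_profile(self):
        expr, labels, _ = simulate_coexpression(seed=34)
        eg, kme, _ = module_eigengenes(expr, labels)
        for module, eig in eg.iterrows():
            members = labels.index[labels == module]
            X = expr.loc[members].to_numpy()
            Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
            assert np.dot(Xs.mean(0), eig.to_numpy()) > 0
        assert np.allclose(np.linalg.norm(eg.to_numpy(), axis=1), 1.0)

    def test_variance_explained_matches_direct_svd(self):
        expr, labels, _ = simulate_coexpression(seed=35)
        _, _, var = module_eigengenes(expr, labels)
        for module in var:
            members = labels.index[labels == module]
            X = expr.loc[members].to_numpy()
            Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
            s = np.linalg.svd(Xs, compute_uv=False)
            assert var[module] == pytest.approx(s[0] ** 2 / (s**2).sum(), abs=1e-10)

    def test_member_order_invariance_up_to_sign_convention(self):
        expr, labels, _ = simulate_coexpression(seed=36)
        eg1, _, _ = module_eigengenes(expr, labels)
        perm = np.random.default_rng(0).permutation(len(expr))
        eg2, _, _ = module_eigengenes(expr.iloc[perm], labels.iloc[perm])
        assert np.allclose(eg1.to_numpy(), eg2.loc[eg1.index].to_numpy(), atol=1e-9)


class TestTraitAndHubs:
    def test_eigengene_equal_to_trait(self):
        trait = np.array([1.0, 0, 0, 1, 0, 1, 0, 0])
        eg = pd.DataFrame([trait], index=["M1"], columns=[f"s{i}" for i in range(8)])
        out = module_trait_correlation(eg, trait)
        assert out.loc["M1", "r"] == pytest.approx(1.0)
        assert out.loc["M1", "p"] < 1e-10

    def test_orthogonal_eigengene(self):
        trait = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        eig = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        eg = pd.DataFrame([eig], index=["M1"], columns=[f"s{i}" for i in range(8)])
        assert module_trait_correlation(eg, trait).loc["M1", "r"] == pytest.approx(0.0)

    def test_constant_trait_rejected(self):
        eg = pd.DataFrame([[1.0, 2, 3]], index=["M1"], columns=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            module_trait_correlation(eg, [1.0, 1.0, 1.0])

    def test_trait_linked_module_ranks_first_across_seeds(self):
        """The planted trait-linked module tops |eigengene-trait r| in
        >= 95% of seeds."""
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            expr, labels, trait = simulate_coexpression(seed=seed)
            net = build_network(expr, beta=6, min_module_size=30, trait_vector=trait)
            members = labels.index[labels == "planted1"]  # the trait-linked block
            detected = net.module_labels.loc[members].mode().iloc[0]
            if net.module_trait.index[0] == detected:
                wins += 1
        assert wins >= 95

    def test_hub_threshold(self):
        labels = pd.Series(["M1", "M1", UNASSIGNED], index=list("abc"))
        kme = pd.Series([0.95, 0.5, 0.99], index=list("abc"))
        hubs = identify_hubs(kme, labels)
        assert hubs.tolist() == [True, False, False]


class TestGuiltByAssociation:
    def _setup(self, seed=37):
        expr, labels, trait = simulate_coexpression(n_samples=30, n_background=50, seed=seed)
        # rename one module gene as the query lncRNA, rest are "coding genes"
        lnc = labels.index[labels == "planted1"][0]
        pcg = [g for g in expr.index if g != lnc]
        go_map = {g: {"GO:HALLMARK"} for g in labels.index[labels == "planted1"] if g != lnc}
        for g in pcg:
            go_map.setdefault(g, set()).add("GO:GENERIC")
        return expr, lnc, pcg, go_map

    def test_planted_module_term_is_enriched(self):
        expr, lnc, pcg, go_map = self._setup()
        out = guilt_by_association(lnc, expr, pcg, go_map, min_genes=30)
        assert out.assessed
        hallmark = [r for r in out.enriched_terms if r.term_id == "GO:HALLMARK"]
        assert hallmark and hallmark[0].q < 0.05

    def test_too_few_correlated_genes_not_assessed(self):
        expr, lnc, pcg, go_map = self._setup()
        out = guilt_by_association(lnc, expr, pcg, go_map, min_genes=200)
        assert not out.assessed

    def test_uncorrelated_lncrna_not_assessed(self):
        rng = np.random.default_rng(38)
        expr, lnc, pcg, go_map = self._setup()
        expr.loc[lnc] = rng.normal(size=expr.shape[1])
        out = guilt_by_association(lnc, expr, pcg, go_map, min_genes=30)
        assert not out.assessed

    def test_missing_lncrna_errors(self):
        expr, _, pcg, go_map = self._setup()
        with pytest.raises(KeyError):
            guilt_by_association("nope", expr, pcg, go_map)
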