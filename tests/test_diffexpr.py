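"""Two-library MA-plot test, BH adjustment, DE calling and neighbor-gene
correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_tx
from lncmap.diffexpr import bh_adjust, call_de, de_pair, mars_test, neighbor_correlation
from lncmap.expression import ExpressionMatrix
from lncmap.io import CountMatrix
from lncmap.simulate import simulate_two_library_counts

LN2 = np.log(2.0)


class TestMars:
    def test_equal_counts_equal_libraries(self):
        M, A, z, p = mars_test(100, 100, 1e7, 1e7)
        assert M == 0.0 and z == 0.0 and p == 1.0

    def test_log_ratio(self):
        M, _, _, _ = mars_test(100, 50, 1e7, 1e7)
        assert M == 1.0

    def test_antisymmetry_under_library_swap(self):
        rng = np.random.default_rng(17)
        c1 = rng.integers(1, 1000, size=200)
        c2 = rng.integers(1, 1000, size=200)
        M1, _, z1, p1 = mars_test(c1, c2, 8e6, 1.3e7)
        M2, _, z2, p2 = mars_test(c2, c1, 1.3e7, 8e6)
        assert np.allclose(M1, -M2)
        assert np.allclose(z1, -z2)
        assert np.allclose(p1, p2)

    def test_invalid_library_size(self):
        with pytest.raises(ValueError):
            mars_test(1, 1, 0, 1e6)

    def test_conditional_moments_match_monte_carlo(self):
        """The normal-approximation moments of M | A under the binomial
        sampling model agree with direct simulation at fixed A strata."""
        rng = np.random.default_rng(18)
        n1, n2 = 8_000_000, 12_000_000
        geo = np.sqrt(n1 * n2)
        for lam in (200.0, 1000.0):
            p_common = lam / geo
            c1 = rng.binomial(n1, p_common, size=300_000)
            c2 = rng.binomial(n2, p_common, size=300_000)
            M = np.log2(np.maximum(c1, 1)) - np.log2(np.maximum(c2, 1))
            A = 0.5 * (np.log2(np.maximum(c1, 1)) + np.log2(np.maximum(c2, 1)))
            a0 = float(np.median(A))
            sel = np.abs(A - a0) < 0.02
            assert sel.sum() > 5000
            p_hat = 2.0 ** a0 / geo
            pred_mean = np.log2(n1 / n2)
            pred_var = 4 * (1 - p_hat) * geo / (LN2**2 * (n1 + n2) * 2.0 ** a0)
            assert M[sel].mean() == pytest.approx(pred_mean, abs=0.02)
            assert M[sel].var() == pytest.approx(pred_var, rel=0.15)

    def test_null_type_one_error_calibrated(self):
        c1, c2, _ = simulate_two_library_counts(10_000, seed=19)
        _, _, _, p = mars_test(c1, c2, 1e7, 1e7)
        for alpha in (0.01, 0.05):
            assert (p < alpha).mean() == pytest.approx(alpha, abs=0.01)


class TestBH:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_q_at_least_p_ordering_and_monotone(self, ps):
        q = bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallDe:
    def _counts(self):
        rng = np.random.default_rng(20)
        base = rng.integers(200, 2000, size=300)
        c = {
            "d0": base.copy(),
            "d30": base.copy(),
            "d240": base.copy(),
        }
        # plant 30 four-fold changes at day 0
        c["d0"][:30] = c["d0"][:30] * 4
        noise = {k: rng.poisson(v) for k, v in c.items()}
        df = pd.DataFrame(noise, index=[f"t{i}" for i in range(300)])
        return CountMatrix(df, pd.Series([10**7] * 3, index=df.columns))

    def test_conjunctive_fc_and_q_rule(self):
        cm = self._counts()
        res = de_pair(cm, "d0", "d30")
        planted = {f"t{i}" for i in range(30)}
        sig = res.significant_ids
        assert planted <= sig
        tab = res.table
        # every significant call satisfies both thresholds
        assert (tab.loc[sorted(sig), "q"] < 0.05).all()
        assert (tab.loc[sorted(sig), "log2FC"].abs() >= 1.0).all()
        # strong q alone is not enough: |log2FC| < 1 rows are never called
        small_fc = tab[tab["log2FC"].abs() < 1.0]
        assert not small_fc["significant"].any()

    def test_pairwise_summary_and_venn(self):
        cm = self._counts()
        out = call_de(cm, ("d0", "d30", "d240"))
        sig_01 = set(out["significant_per_pair"][("d0", "d30")])
        sig_02 = set(out["significant_per_pair"][("d0", "d240")])
        planted = {f"t{i}" for i in range(30)}
        assert planted <= sig_01 and planted <= sig_02
        assert set(out["union"]) == sig_01 | sig_02 | set(
            out["significant_per_pair"][("d30", "d240")]
        )
        venn_total = sum(len(v) for v in out["venn"].values())
        assert venn_total == len(out["union"])

    def test_planted_fdr_and_recall(self):
        c1, c2, de = simulate_two_library_counts(
            10_000, planted_fraction=0.1, planted_log2fc=2.0, seed=21
        )
        df = pd.DataFrame({"a": c1, "b": c2}, index=[f"t{i}" for i in range(10_000)])
        cm = CountMatrix(df, pd.Series([10**7, 10**7], index=["a", "b"]))
        res = de_pair(cm, "a", "b")
        called = res.table["significant"].to_numpy()
        recall = (called & de).sum() / de.sum()
        fdr = (called & ~de).sum() / max(called.sum(), 1)
        assert recall >= 0.95
        assert fdr <= 0.05 + 2 * np.sqrt(0.05 / max(called.sum(), 1)) + 0.01


class TestNeighborCorrelation:
    def _setup(self, r_target, n_pairs=200, n_samples=30, seed=22):
        rng = np.random.default_rng(seed)
        lncs, genes, rows, ids = [], [], [], []
        for i in range(n_pairs):
            chrom = f"c{i}"
            genes.append(
                make_tx(f"g{i}.t1", [(0, 1000), (1500, 3000)], chrom=chrom,
                        gene_id=f"g{i}", biotype="protein_coding")
            )
            lncs.append(make_tx(f"l{i}", [(9000, 9400), (9600, 10000)], chrom=chrom))
            x = rng.normal(0, 1, n_samples)
            y = r_target * x + np.sqrt(1 - r_target**2) * rng.normal(0, 1, n_samples)
            rows += [2.0 ** (3 + x) - 1, 2.0 ** (3 + y) - 1]
            ids += [f"l{i}", f"g{i}.t1"]
        rpkm = pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(n_samples)])
        verdicts = {f"l{i}": "intergenic" for i in range(n_pairs)}
        return lncs, genes, rpkm, verdicts

    def test_identical_profiles_give_r_one(self):
        lncs, genes, rpkm, verdicts = self._setup(1.0, n_pairs=5)
        out = neighbor_correlation(lncs, genes, rpkm, verdicts)
        assert all(p.pearson_r == pytest.approx(1.0) for p in out["pairs"])
        assert all(p.relation == "nearest_intergenic" for p in out["pairs"])
        assert all(p.distance > 0 for p in out["pairs"])

    def test_planted_r_recovered(self):
        lncs, genes, rpkm, verdicts = self._setup(0.4)
        out = neighbor_correlation(lncs, genes, rpkm, verdicts)
        assert out["nearest_intergenic"]["n"] == 200
        assert out["nearest_intergenic"]["mean_r"] == pytest.approx(0.4, abs=0.05)

    def test_orthogonal_profiles_near_zero(self):
        lncs, genes, rpkm, verdicts = self._setup(0.0)
        out = neighbor_correlation(lncs, genes, rpkm, verdicts)
        assert abs(out["nearest_intergenic"]["mean_r"]) < 0.05

    def test_lncrna_without_chromosome_gene_is_skipped(self):
        lncs, genes, rpkm, verdicts = self._setup(0.5, n_pairs=3)
        lonely = make_tx("solo", [(100, 300), (400, 700)], chrom="empty_chr")
        verdicts["solo"] = "intergenic"
        rng = np.random.default_rng(0)
        rpkm.loc["solo"] = rng.lognormal(2, 1, rpkm.shape[1])
        out = neighbor_correlation(lncs + [lonely], genes, rpkm, verdicts)
        assert out["n_skipped"] == 1
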