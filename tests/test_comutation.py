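"""Fisher comutation, fixed-margin sampling, exclusivity test, and filters."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from krasnet.comutation import (
    BinaryMutationMatrix,
    build_network,
    ComutationInteraction,
    exclusivity_statistic,
    expression_filter,
    fisher_enrichment_p,
    fit_hypermutant_cutoff,
    increased_comutation,
    rc_exclusivity_test,
    reduced_comutation,
    sample_fixed_margin,
)
from krasnet.synthetic_data import InteractionSpec, generate_mutation_matrix


def exact_hypergeom_tail(both, n_carriers, n_gene, n_total):
    """Brute-force upper tail of the hypergeometric pmf via binomial coefficients."""
    num = 0
    den = comb(n_total, n_carriers)
    for k in range(both, min(n_carriers, n_gene) + 1):
        if n_total - n_gene >= n_carriers - k >= 0:
            num += comb(n_gene, k) * comb(n_total - n_gene, n_carriers - k)
    return num / den


def enumerate_fixed_margin(rows_m, cols_m):
    n, m = len(rows_m), len(cols_m)
    out = []
    for bits in itertools.product([0, 1], repeat=n * m):
        M = np.array(bits).reshape(n, m)
        if (M.sum(1) == rows_m).all() and (M.sum(0) == cols_m).all():
            out.append(M)
    return out


class TestFisher:
    def test_example_table_matches_exact_tail(self):
        # 5 of 10 carriers mutated, 10 of 90 non-carriers
        p = fisher_enrichment_p(both=5, n_carriers=10, n_gene=15, n_total=100)
        assert p == pytest.approx(exact_hypergeom_tail(5, 10, 15, 100), rel=1e-10)

    def test_oracle_exhaustive_small_tables(self):
        """One-sided p equals the exact combinatorial tail for all small tables."""
        for n_total in (5, 11, 23):
            for n_gene in range(n_total + 1):
                for n_car in range(n_total + 1):
                    for both in range(max(0, n_gene + n_car - n_total),
                                      min(n_gene, n_car) + 1):
                        p = fisher_enrichment_p(both, n_car, n_gene, n_total)
                        assert p == pytest.approx(
                            exact_hypergeom_tail(both, n_car, n_gene, n_total), abs=1e-12
                        )

    def test_rare_gene_excluded(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(0, index=[f"s{i}" for i in range(200)], columns=["RARE", "COMMON"])
        M.iloc[:1, 0] = 1  # 0.5% < 1%
        M.iloc[:50, 1] = 1
        alleles = pd.Series(["G12D"] * 30 + ["WT"] * 170, index=M.index)
        out = increased_comutation(BinaryMutationMatrix(M, alleles), "G12D", p_threshold=1.1)
        assert "RARE" not in {i.gene for i in out}

    def test_low_event_low_frequency_gene_excluded(self):
        M = pd.DataFrame(0, index=[f"s{i}" for i in range(100)], columns=["G1"])
        alleles = pd.Series(["G12D"] * 50 + ["WT"] * 50, index=M.index)
        M.iloc[[0, 1], 0] = 1  # 2 comutation events, 4% of carriers
        M.iloc[95:97, 0] = 1   # keep overall frequency above 1%
        out = increased_comutation(BinaryMutationMatrix(M, alleles), "G12D", p_threshold=1.1)
        assert out == []

    def test_no_carriers_skipped(self):
        M = pd.DataFrame([[1], [0]], index=["a", "b"], columns=["G1"])
        alleles = pd.Series(["WT", "WT"], index=M.index)
        assert increased_comutation(BinaryMutationMatrix(M, alleles), "G12D") == []


class TestFixedMarginSampler:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_margins_always_preserved(self, seed):
        rng = np.random.default_rng(seed)
        M = pd.DataFrame((rng.random((8, 6)) < 0.4).astype(int))
        out = sample_fixed_margin(M, n_trades=200, seed=seed)
        assert (out.sum(0).values == M.sum(0).values).all()
        assert (out.sum(1).values == M.sum(1).values).all()

    def test_zero_trades_identity(self):
        M = pd.DataFrame([[1, 0], [0, 1]])
        out = sample_fixed_margin(M, n_trades=0, seed=0)
        assert (out.values == M.values).all()

    def test_two_fillin_margins_sampled_evenly(self):
        """Margins admitting exactly two matrices are visited ~50/50."""
        base = np.array([[0, 0, 0], [1, 0, 1], [0, 1, 1]])
        mats = enumerate_fixed_margin(base.sum(1), base.sum(0))
        assert len(mats) == 2
        M = pd.DataFrame(base)
        counts = [0, 0]
        for d in range(10_000):
            out = sample_fixed_margin(M, n_trades=30, seed=d).values
            counts[next(i for i, m in enumerate(mats) if (m == out).all())] += 1
        frac = counts[0] / sum(counts)
        assert 0.45 <= frac <= 0.55


class TestExclusivityTest:
    def test_statistic_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = (rng.random(50) < 0.3).astype(int), (rng.random(50) < 0.4).astype(int)
        assert exclusivity_statistic(a, b) == exclusivity_statistic(b, a)

    def test_one_mutation_per_sample_p_one(self):
        """Every fixed-margin arrangement of one-hot rows is fully exclusive."""
        M = pd.DataFrame(np.eye(6, 3, dtype=int)[[0, 1, 2, 0, 1, 2]], columns=list("abc"))
        p, obs = rc_exclusivity_test(M, "a", "b", n_perm=300, seed=0, burn_in=100, thin=10)
        assert p == 1.0

    @pytest.mark.parametrize("seed", [0, 3])
    def test_permutation_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        base = (rng.random((4, 4)) < 0.55).astype(int)
        mats = enumerate_fixed_margin(base.sum(1), base.sum(0))
        obs = exclusivity_statistic(base[:, 0], base[:, 1])
        p_exact = np.mean([exclusivity_statistic(m[:, 0], m[:, 1]) >= obs for m in mats])
        df = pd.DataFrame(base, columns=list("abcd"))
        p_perm, _ = rc_exclusivity_test(df, "a", "b", n_perm=3000, seed=seed,
                                        burn_in=300, thin=25)
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-12) / 3000)
        assert abs(p_perm - p_exact) <= 3 * se + 2 / 3001

    def test_conservative_p_is_super_uniform(self):
        """Default tie handling keeps P(p <= alpha) at or below ~alpha."""
        rng = np.random.default_rng(2)
        n, G = 120, 6
        base = pd.DataFrame((rng.random((n, G)) < 0.3).astype(int),
                            columns=[f"g{i}" for i in range(G)])
        pvals = []
        for rep in range(200):
            obs = sample_fixed_margin(base, n_trades=1200, seed=rep)
            p, _ = rc_exclusivity_test(obs, "g0", "g1", n_perm=99, seed=rep,
                                       burn_in=800, thin=40)
            pvals.append(p)
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25):
            assert (pvals <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 200)

    def test_low_exclusive_count_gene_filtered(self):
        M = pd.DataFrame(0, index=[f"s{i}" for i in range(100)], columns=["G1"])
        alleles = pd.Series(["G12D"] * 5 + ["WT"] * 95, index=M.index)
        M.iloc[95:99, 0] = 1  # 4 gene events + 5 carriers = 9 exclusive events
        out = reduced_comutation(
            BinaryMutationMatrix(M, alleles), "G12D", n_perm=50, min_gene_freq=0.0
        )
        assert out == []

    def test_planted_exclusivity_detected(self):
        hits = 0
        for r in range(8):
            spec = InteractionSpec(n_samples=1000, planted=(("G12D", "G029", -3.0),))
            m, al, assay, _ = generate_mutation_matrix(spec, seed=r)
            out = reduced_comutation(
                BinaryMutationMatrix(m, al, assay), "G12D",
                n_perm=400, seed=r, thin=150,
            )
            hits += "G029" in {i.gene for i in out}
        assert hits / 8 >= 0.8

    def test_planted_cooccurrence_detected(self):
        hits = 0
        for r in range(10):
            spec = InteractionSpec(n_samples=1000, planted=(("G12D", "G010", 2.0),))
            m, al, assay, _ = generate_mutation_matrix(spec, seed=100 + r)
            out = increased_comutation(BinaryMutationMatrix(m, al, assay), "G12D")
            hits += "G010" in {i.gene for i in out}
        assert hits / 10 >= 0.8


class TestHypermutantCutoff:
    def test_planted_components_recovered(self):
        rng = np.random.default_rng(0)
        n = 1000
        is_hyper = rng.random(n) < 0.17
        logb = np.where(is_hyper, rng.normal(3.0, 0.2, n), rng.normal(2.0, 0.2, n))
        burdens = pd.Series(np.round(10 ** logb), index=[f"s{i}" for i in range(n)])
        cut = fit_hypermutant_cutoff(burdens, seed=1)
        assert not cut.fallback_used
        recovered = pd.Index(burdens.index[is_hyper]).isin(cut.flagged).mean()
        assert recovered >= 0.99
        assert abs(cut.top_fraction - 0.17) <= 0.03

    def test_equal_burdens_trigger_fallback(self):
        burdens = pd.Series(100.0, index=[f"s{i}" for i in range(50)])
        cut = fit_hypermutant_cutoff(burdens, seed=0)
        assert cut.fallback_used

    def test_unimodal_burdens_trigger_fallback(self):
        rng = np.random.default_rng(5)
        burdens = pd.Series(np.exp(rng.normal(5, 0.5, 500)), index=[f"s{i}" for i in range(500)])
        cut = fit_hypermutant_cutoff(burdens, seed=0, fallback_top_fraction=0.17)
        assert cut.fallback_used
        assert cut.top_fraction == pytest.approx(0.17, abs=0.01)

    def test_exclusion_reduces_gene_counts(self):
        m, al, assay, tr = generate_mutation_matrix(InteractionSpec(n_samples=200), seed=1)
        bmm = BinaryMutationMatrix(m, al, assay)
        cut = fit_hypermutant_cutoff(tr["burdens"], seed=0)
        sub = bmm.subset(bmm.matrix.index.difference(cut.flagged))
        assert (sub.matrix.sum(0) <= bmm.matrix.sum(0)).all()


class TestExpressionFilter:
    def test_median_at_threshold_passes(self):
        src = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["KRAS"])
        assert expression_filter("KRAS", [src]) is True

    def test_low_everywhere_fails(self):
        src1 = pd.DataFrame({"s1": [0.5]}, index=["KRAS"])
        src2 = pd.DataFrame({"s1": [0.2]}, index=["KRAS"])
        assert expression_filter("KRAS", [src1, src2]) is False

    def test_absent_gene_not_expressed(self):
        src = pd.DataFrame({"s1": [5.0]}, index=["TP53"])
        assert expression_filter("KRAS", [src]) is False


class TestNetwork:
    def _interactions(self, ps, direction="increased"):
        return [
            ComutationInteraction("G12D", f"GENE{i}", direction, 5, 0.2, p)
            for i, p in enumerate(ps)
        ]

    def test_above_threshold_never_enters(self):
        net = build_network(self._interactions([0.02, 0.005]))
        assert list(net["gene"]) == ["GENE1"]

    def test_no_curated_sets_identity(self):
        ps = [0.001, 0.009, 0.05]
        net = build_network(self._interactions(ps))
        assert len(net) == 2
        assert net["p_adj_set"].isna().all()

    def test_curated_subset_bh_matches_oracle(self):
        from statsmodels.stats.multitest import multipletests

        ps = list(np.linspace(0.001, 0.0099, 10))
        inter = self._interactions(ps)
        curated = {"kras_pathway": [f"GENE{i}" for i in range(10)]}
        net = build_network(inter, curated, fdr_threshold=0.25)
        p_adj = multipletests(np.array(ps), method="fdr_bh")[1]
        keep = {f"GENE{i}" for i, q in enumerate(p_adj) if q < 0.25}
        assert set(net["gene"]) == keep
        got = net.set_index("gene")["p_adj_set"]
        for i, q in enumerate(p_adj):
            if f"GENE{i}" in got.index:
                assert got[f"GENE{i}"] == pytest.approx(q)
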