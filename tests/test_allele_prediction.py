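"""Candidate alleles, per-sample probabilities, bootstrap CIs, and tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from krasnet.allele_prediction import test_observed_vs_predicted as observed_vs_predicted_test
from krasnet.allele_prediction import (
    allele_probability_table,
    candidate_alleles,
    compare_probability_groups,
    incidence_weighted_hotspot_distribution,
    per_sample_allele_probability,
    predicted_frequency,
)
from krasnet.codon_spectrum import CHANNEL_LABELS, build_kras_allele_map


@pytest.fixture(scope="module")
def amap():
    return build_kras_allele_map()


def _spectrum(counts_by_label):
    s = pd.Series(0.0, index=list(CHANNEL_LABELS))
    for lab, n in counts_by_label.items():
        s[lab] = n
    return s


class TestCandidates:
    def test_threshold_filters_rare_alleles(self):
        counts = {"G12D": 50, "G12V": 40, "G12S": 2}
        assert candidate_alleles(counts, 0.03) == {"G12D", "G12V"}

    def test_zero_threshold_keeps_all(self):
        counts = {"G12D": 1, "Q61H": 1}
        assert candidate_alleles(counts, 0.0) == {"G12D", "Q61H"}

    def test_pan_cancer_union(self):
        per_cancer = {"A": {"G12D": 5, "G12V": 95}, "B": {"G12V": 100}}
        cands = candidate_alleles(per_cancer, 0.03, pan_cancer=True)
        assert "G12D" in cands  # frequent nowhere near B, but candidate via A

    def test_no_candidate_raises(self):
        with pytest.raises(ValueError):
            candidate_alleles({"G12D": 1}, threshold=1.1)


class TestPerSampleProbability:
    def test_all_mass_on_one_allele(self, amap):
        ch = amap["G12D"][0].channel.label
        p = per_sample_allele_probability(_spectrum({ch: 10}), amap, {"G12D", "G12V"})
        assert p["G12D"] == 1.0 and p["G12V"] == 0.0

    def test_multi_channel_allele_sums_channels(self, amap):
        """Q61H's score equals the brute-force sum of both causative channels."""
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 20, 96).astype(float)
        s = pd.Series(counts, index=list(CHANNEL_LABELS))
        cands = ["G12D", "Q61H"]
        p = per_sample_allele_probability(s, amap, cands)
        freqs = counts / counts.sum()
        brute = {
            a: sum(freqs[ac.channel.index] for ac in amap[a]) for a in cands
        }
        tot = sum(brute.values())
        assert p["Q61H"] == pytest.approx(brute["Q61H"] / tot)
        assert len(amap["Q61H"]) == 2

    def test_uniform_spectrum_proportional_to_channel_count(self, amap):
        s = pd.Series(1.0, index=list(CHANNEL_LABELS))
        p = per_sample_allele_probability(s, amap, {"G12D", "Q61H"})
        # Q61H has two causative channels, G12D one
        assert p["Q61H"] == pytest.approx(2 / 3)

    def test_burden_invariance(self, amap):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 10, 96).astype(float)
        s = pd.Series(counts, index=list(CHANNEL_LABELS))
        cands = {"G12D", "G12V", "Q61H"}
        p1 = per_sample_allele_probability(s, amap, cands)
        p2 = per_sample_allele_probability(s * 17, amap, cands)
        assert np.allclose(p1.values, p2.values, equal_nan=True)

    def test_zero_scores_flagged_undefined(self, amap):
        s = _spectrum({})
        assert per_sample_allele_probability(s, amap, {"G12D"}).isna().all()


class TestPredictedFrequency:
    def test_constant_probabilities_zero_width_ci(self):
        pt = pd.DataFrame([[0.5, 0.3, 0.2]] * 10, columns=list("abc"))
        res = predicted_frequency(pt, n_boot=200, seed=0)
        assert np.allclose(res["predicted"].values, [0.5, 0.3, 0.2])
        assert np.allclose(res["ci_lo"].values, res["ci_hi"].values)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            predicted_frequency(pd.DataFrame([[1.0]], columns=["a"]), n_boot=200)

    def test_bootstrap_coverage(self):
        """Percentile CI covers the true mean in >= 93% of 200 replicates."""
        alpha = np.array([2.0, 1.0, 1.0])
        true = alpha / alpha.sum()
        cover = 0
        for r in range(200):
            X = np.random.default_rng(r).dirichlet(alpha, size=500)
            res = predicted_frequency(pd.DataFrame(X, columns=list("abc")), n_boot=2000, seed=r)
            cover += res.loc["a", "ci_lo"] <= true[0] <= res.loc["a", "ci_hi"]
        assert cover / 200 >= 0.93


class TestObservedVsPredicted:
    def test_exact_agreement_gives_zero_statistic(self):
        pred = pd.Series({"G12D": 0.5, "G12V": 0.5})
        out = observed_vs_predicted_test({"G12D": 50, "G12V": 50}, pred)
        assert np.allclose(out["chi2"].values, 0.0)
        assert np.allclose(out["p"].values, 1.0)

    def test_null_multinomial_rarely_rejects(self):
        rng_master = np.random.default_rng(0)
        pred = pd.Series({"a": 0.5, "b": 0.3, "c": 0.2})
        rej = []
        for r in range(100):
            counts = np.random.default_rng(r).multinomial(1000, pred.values)
            out = observed_vs_predicted_test(dict(zip(pred.index, counts)), pred)
            rej.append((out["p_adj"] < 0.05).mean())
        assert np.mean(rej) <= 0.10

    def test_planted_threefold_deviation_detected(self):
        pred = pd.Series({"a": 0.1, "b": 0.45, "c": 0.45})
        shifted = np.array([0.3, 0.35, 0.35])
        hits = 0
        for r in range(50):
            counts = np.random.default_rng(r).multinomial(1000, shifted)
            out = observed_vs_predicted_test(dict(zip(pred.index, counts)), pred)
            hits += out.loc["a", "p_adj"] < 0.05
        assert hits / 50 >= 0.95


class TestProbabilityGroups:
    def test_identical_groups_p_one(self):
        probs = pd.Series(np.tile([0.1, 0.2, 0.3], 3), index=[f"s{i}" for i in range(9)])
        labels = pd.Series(["has"] * 3 + ["other"] * 3 + ["WT"] * 3, index=probs.index)
        out = compare_probability_groups(probs, labels)
        assert (out["p_adj"] == 1.0).all()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0.6, 0.1, 100), rng.normal(0.4, 0.1, 100),
                               rng.normal(0.4, 0.1, 100)])
        probs = pd.Series(vals, index=[f"s{i}" for i in range(300)])
        labels = pd.Series(["has"] * 100 + ["other"] * 100 + ["WT"] * 100, index=probs.index)
        out = compare_probability_groups(probs, labels)
        assert (out["p_adj"] < 0.05).all()

    def test_tiny_groups_match_exhaustive_enumeration(self):
        x = [0.15, 0.8, 0.42]
        y = [0.3, 0.55, 0.7]
        probs = pd.Series(x + y + y, index=[f"s{i}" for i in range(9)])
        labels = pd.Series(["has"] * 3 + ["other"] * 3 + ["WT"] * 3, index=probs.index)
        out = compare_probability_groups(probs, labels)
        pooled = np.array(x + y)
        ranks = pd.Series(pooled).rank().values
        obs = ranks[:3].sum()
        stats = [sum(ranks[list(i)]) for i in itertools.combinations(range(6), 3)]
        mu = np.mean(stats)
        exact = np.mean([abs(s - mu) >= abs(obs - mu) - 1e-12 for s in stats])
        assert out.set_index("contrast").loc["has_vs_other", "p"] == pytest.approx(exact)

    def test_empty_group_skipped(self):
        probs = pd.Series([0.1, 0.2], index=["s0", "s1"])
        labels = pd.Series(["has", "other"], index=probs.index)
        out = compare_probability_groups(probs, labels)
        assert list(out["contrast"]) == ["has_vs_other"]


class TestIncidenceWeighting:
    CODONS = ["12", "13", "61", "146"]

    def test_equal_weights_simple_average(self):
        freqs = pd.DataFrame(
            [[0.7, 0.1, 0.1, 0.1], [0.5, 0.3, 0.1, 0.1]], index=["A", "B"], columns=self.CODONS
        )
        out = incidence_weighted_hotspot_distribution(freqs, {"A": 1.0, "B": 1.0})
        assert np.allclose(out.values, freqs.values.mean(axis=0))

    def test_single_cancer_weight_identity(self):
        freqs = pd.DataFrame(
            [[0.7, 0.1, 0.1, 0.1], [0.5, 0.3, 0.1, 0.1]], index=["A", "B"], columns=self.CODONS
        )
        out = incidence_weighted_hotspot_distribution(freqs, {"A": 1.0, "B": 0.0})
        assert np.allclose(out.values, freqs.loc["A"].values)

    def test_reported_incidence_arithmetic(self):
        """Published yearly incidences x subtype proportions give the stated weights."""
        incidences = {"COAD": 3_870_000, "LUAD": 5_930_000, "MM": 680_000, "PAAD": 1_280_000}
        props = {"COAD": 0.95, "LUAD": 0.50, "PAAD": 0.95}
        eff = {c: incidences[c] * props.get(c, 1.0) for c in incidences}
        assert eff == {
            "COAD": 3_676_500.0, "LUAD": 2_965_000.0, "MM": 680_000, "PAAD": 1_216_000.0
        }
        freqs = pd.DataFrame(
            np.tile([0.7, 0.1, 0.1, 0.1], (4, 1)), index=list(incidences), columns=self.CODONS
        )
        out = incidence_weighted_hotspot_distribution(freqs, incidences, props)
        w = np.array([eff[c] for c in incidences], dtype=float)
        w /= w.sum()
        assert np.allclose(out.values, w @ freqs.values)

    def test_negative_weight_rejected(self):
        freqs = pd.DataFrame([[1.0, 0, 0, 0]], index=["A"], columns=self.CODONS)
        with pytest.raises(ValueError):
            incidence_weighted_hotspot_distribution(freqs, {"A": -1.0})


class TestNullCalibrationProperty:
    def test_type_one_error_controlled_under_process_null(self, broad_catalog):
        """When alleles are drawn from the per-sample probabilities, the
        observed-vs-predicted test rarely rejects."""
        from krasnet.synthetic_data import CohortSpec, generate_cohort

        rej = []
        for r in range(20):
            spec = CohortSpec(n_samples=500, catalog=broad_catalog, kras_mutant_fraction=1.0)
            _, truth = generate_cohort(spec, seed=r, emit_records=False)
            mut = truth.alleles[truth.alleles != "WT"]
            observed = mut.value_counts().to_dict()
            pred = truth.probabilities.loc[mut.index].dropna(how="all").mean(axis=0)
            out = observed_vs_predicted_test(observed, pred)
            rej.append((out["p_adj"] < 0.05).mean())
        assert np.mean(rej) <= 0.10
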