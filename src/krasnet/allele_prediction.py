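"""Predicting KRAS allele frequencies from genome-wide mutation spectra.

Under the null model that active mutational processes alone determine which
hotspot allele a tumor acquires, the probability a sample acquires a given
allele is the frequency of the allele's causative trinucleotide change(s)
among all of the sample's SNVs, normalized over a candidate allele set
(alleles observed in >= 3% of the cancer's KRAS-mutant samples by default).
Cohort-level predicted allele frequencies are the mean per-sample
probabilities, with percentile-bootstrap confidence intervals; observed
frequencies are compared per allele by a two-cell chi-squared goodness-of-fit
test with Benjamini-Hochberg adjustment across alleles.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chisquare, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .codon_spectrum import KrasAlleleMap

logger = logging.getLogger(__name__)


def candidate_alleles(
    observed_allele_counts: Mapping[str, int] | Mapping[str, Mapping[str, int]],
    threshold: float = 0.03,
    pan_cancer: bool = False,
) -> set[str]:
    """Alleles observed at >= ``threshold`` frequency among KRAS-mutant samples.

    With ``pan_cancer=True``, ``observed_allele_counts`` maps cancer label ->
    per-allele counts and the result is the union of each cancer's candidate
    set, so an allele frequent in one cancer is considered in all.
    """
    if pan_cancer:
        out: set[str] = set()
        for counts in observed_allele_counts.values():
            out |= candidate_alleles(counts, threshold)
        if not out:
            raise ValueError("no allele passes the candidate threshold in any cancer")
        return out
    counts = observed_allele_counts
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no KRAS-mutant samples in the observed counts")
    chosen = {a for a, n in counts.items() if n / total >= threshold}
    if not chosen:
        raise ValueError(
            f"no allele reaches frequency {threshold:.0%} among {total} KRAS-mutant samples"
        )
    return chosen


def per_sample_allele_probability(
    sample_spectrum: pd.Series | np.ndarray,
    allele_map: KrasAlleleMap,
    candidates: set[str] | list[str],
) -> pd.Series:
    """Probability over candidate alleles for one sample.

    The unnormalized score of an allele is the sum, over its causative
    channels, of the sample's genome-wide channel frequencies; scores are
    normalized over the candidate set. Depends only on channel frequencies,
    so it is invariant to the sample's total mutation burden. Returns NaN for
    every allele when no candidate's channels are hit (flagged undefined).
    """
    counts = np.asarray(sample_spectrum, dtype=float)
    total = counts.sum()
    candidates = sorted(candidates)
    if total == 0:
        return pd.Series(np.nan, index=candidates)
    freqs = counts / total
    scores = np.array([freqs[allele_map.channel_indices(a)].sum() for a in candidates])
    if scores.sum() == 0:
        return pd.Series(np.nan, index=candidates)
    return pd.Series(scores / scores.sum(), index=candidates)


def allele_probability_table(
    spectra: pd.DataFrame, allele_map: KrasAlleleMap, candidates: set[str] | list[str]
) -> pd.DataFrame:
    """Per-sample candidate-allele probabilities (rows sum to 1 or are NaN)."""
    rows = {
        sid: per_sample_allele_probability(spectra.loc[sid], allele_map, candidates)
        for sid in spectra.index
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    n_undef = int(table.isna().all(axis=1).sum())
    if n_undef:
        logger.info("allele_probability_table: %d samples with undefined probabilities", n_undef)
    return table


@dataclass
class AllelePredictionResult:
    """Predicted vs observed allele frequencies with CIs and tests."""

    table: pd.DataFrame  # index allele; predicted, ci_lo, ci_hi, observed_n, observed_freq, chi2, p, p_adj


def predicted_frequency(
    probability_table: pd.DataFrame, n_boot: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Mean per-sample allele probabilities with percentile-bootstrap 95% CIs.

    Samples with undefined probabilities are excluded from the mean. Resamples
    samples with replacement ``n_boot`` times; CI bounds are the 2.5th and
    97.5th percentiles of the bootstrap means.
    """
    probs = probability_table.dropna(how="all")
    if probs.shape[0] < 2:
        raise ValueError("need >= 2 samples with defined probabilities to bootstrap a CI")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; percentile CIs will be unstable", n_boot)
    rng = np.random.default_rng(seed)
    X = probs.values
    n = X.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = X[idx].mean(axis=1)  # n_boot x alleles
    lo, hi = np.percentile(boot_means, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"predicted": X.mean(axis=0), "ci_lo": lo, "ci_hi": hi}, index=probs.columns
    )


def test_observed_vs_predicted(
    observed_counts: Mapping[str, int], predicted_freqs: pd.Series
) -> pd.DataFrame:
    """Per-allele two-cell chi-squared test of observed vs predicted frequency.

    Predicted frequencies are renormalized over the tested alleles; for each
    allele the observed (allele, not-allele) split among KRAS-mutant samples
    is tested against the expected split. BH adjustment across alleles.
    """
    alleles = [a for a in predicted_freqs.index if a in observed_counts]
    n_total = sum(observed_counts[a] for a in alleles)
    pred = predicted_freqs.loc[alleles]
    pred = pred / pred.sum()
    rows = []
    for a in alleles:
        p = float(pred[a])
        exp = np.array([n_total * p, n_total * (1 - p)])
        if (exp == 0).any():
            logger.info("test_observed_vs_predicted: expected 0 for %s, skipped", a)
            rows.append({"allele": a, "chi2": np.nan, "p": np.nan})
            continue
        obs = np.array([observed_counts[a], n_total - observed_counts[a]], dtype=float)
        stat, pval = chisquare(obs, exp)
        rows.append({"allele": a, "chi2": float(stat), "p": float(pval)})
    out = pd.DataFrame(rows).set_index("allele")
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"].values, method="fdr_bh")[1]
    out["observed_n"] = [observed_counts[a] for a in out.index]
    out["observed_freq"] = out["observed_n"] / n_total
    out["predicted"] = pred
    return out


def compare_probability_groups(
    probabilities: pd.Series, group_labels: pd.Series
) -> pd.DataFrame:
    """Compare one allele's per-sample probabilities across KRAS-status groups.

    ``group_labels`` assigns each sample to "has" (carries the allele),
    "other" (different KRAS mutation), or "WT". Wilcoxon rank-sum tests of
    has-vs-other and has-vs-WT, BH-adjusted.
    """
    probabilities = probabilities.dropna()
    labels = group_labels.reindex(probabilities.index)
    groups = {g: probabilities[labels == g].values for g in ("has", "other", "WT")}
    rows = []
    for contrast in ("other", "WT"):
        x, y = groups["has"], groups[contrast]
        if len(x) == 0 or len(y) == 0:
            logger.info("compare_probability_groups: empty group for has-vs-%s, skipped", contrast)
            continue
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append({"contrast": f"has_vs_{contrast}", "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = multipletests(out["p"].values, method="fdr_bh")[1]
    return out


def incidence_weighted_hotspot_distribution(
    per_cancer_hotspot_freqs: pd.DataFrame,
    incidences: Mapping[str, float],
    cancer_proportions: Mapping[str, float] | None = None,
) -> pd.Series:
    """Hotspot-codon mutation distribution averaged across cancers by incidence.

    ``per_cancer_hotspot_freqs`` has one row per cancer and one column per
    hotspot codon, rows summing to 1. Weights are yearly incidence times the
    proportion of that tissue's cases attributable to the cancer subtype.
    """
    cancers = list(per_cancer_hotspot_freqs.index)
    props = cancer_proportions or {}
    w = np.array([incidences[c] * props.get(c, 1.0) for c in cancers], dtype=float)
    if (w < 0).any():
        raise ValueError("negative incidence weight")
    w = w / w.sum()
    return pd.Series(
        w @ per_cancer_hotspot_freqs.values, index=per_cancer_hotspot_freqs.columns
    )
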