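"""KRAS allele-specific genetic dependencies from CRISPR knockout screens.

Works on CERES-like dependency matrices (cell lines x genes; more negative =
knockout more deleterious). Cell lines with multiple activating KRAS
mutations, or an activating mutation in BRAF, EGFR, or NRAS, are removed;
alleles kept only when found in at least three eligible lines. Genes whose
dependency is explained by their own RNA expression (linear model p < 0.05
and R^2 >= 0.4) or by their own mutation status (rank-sum p < 0.05) are
filtered out before testing. Remaining genes are screened by one-way ANOVA
across allele groups (p < 0.01) followed by per-group Student's t tests
against all other lines pooled (BH-adjusted p < 0.05), and significant genes
are hierarchically clustered on standardized dependency profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import f_oneway, linregress, mannwhitneyu, ttest_ind
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: genes whose activating mutations disqualify a cell line from allele grouping
DISQUALIFYING_ONCOGENES = ("BRAF", "EGFR", "NRAS")


@dataclass
class LineMetadata:
    """Per-cell-line KRAS allele and activating-mutation annotations."""

    kras_allele: pd.Series           # line -> allele label or "WT"
    activating_mutations: pd.Series  # line -> list of "GENE:change" strings
    n_kras_activating: pd.Series | None = None  # line -> count of activating KRAS muts


def eligible_lines(
    metadata: LineMetadata, min_lines_per_allele: int = 3
) -> tuple[pd.Index, dict[str, list[str]]]:
    """Screenable lines and their allele groups.

    Removes lines with multiple activating KRAS mutations or any activating
    mutation in BRAF/EGFR/NRAS; keeps an allele group only if at least
    ``min_lines_per_allele`` eligible lines carry it ("WT" follows the same
    rule). Aborts if fewer than two groups remain.
    """
    lines = metadata.kras_allele.index
    bad = pd.Series(False, index=lines)
    for line in lines:
        muts = metadata.activating_mutations.get(line, []) or []
        genes = {m.split(":")[0] for m in muts}
        if genes & set(DISQUALIFYING_ONCOGENES):
            bad[line] = True
        n_kras = (
            metadata.n_kras_activating.get(line, None)
            if metadata.n_kras_activating is not None
            else sum(m.startswith("KRAS:") for m in muts)
        )
        if n_kras is not None and n_kras > 1:
            bad[line] = True
    ok = lines[~bad]
    groups: dict[str, list[str]] = {}
    for allele, members in metadata.kras_allele.loc[ok].groupby(metadata.kras_allele.loc[ok]):
        if len(members) >= min_lines_per_allele:
            groups[str(allele)] = list(members.index)
    if len(groups) < 2:
        raise ValueError(
            f"only {len(groups)} allele group(s) with >= {min_lines_per_allele} lines; "
            "allele-specific dependency analysis aborted"
        )
    kept = pd.Index([l for members in groups.values() for l in members])
    return kept, groups


def filter_expression_explained(
    dep_column: pd.Series,
    rna_column: pd.Series,
    p_threshold: float = 0.05,
    r2_threshold: float = 0.4,
) -> bool:
    """Keep the gene unless its own expression explains its dependency.

    Returns False (drop) iff a simple linear regression of dependency on
    expression achieves p < ``p_threshold`` and R^2 >= ``r2_threshold``.
    Constant expression keeps the gene (regression undefined).
    """
    joined = pd.concat([dep_column, rna_column], axis=1).dropna()
    if joined.shape[0] < 4:
        raise ValueError("need >= 4 lines with both dependency and expression")
    y, x = joined.iloc[:, 0].values, joined.iloc[:, 1].values
    if np.ptp(x) == 0:
        logger.info("filter_expression_explained: constant expression, keeping gene")
        return True
    fit = linregress(x, y)
    return not (fit.pvalue < p_threshold and fit.rvalue**2 >= r2_threshold)


def filter_self_mutation(
    dep_column: pd.Series, mutation_status: pd.Series, p_threshold: float = 0.05
) -> bool:
    """Keep the gene unless dependency differs by its own mutation status.

    Returns False (drop) iff a two-sided Wilcoxon rank-sum test between
    mutated and WT lines gives p < ``p_threshold``. An empty group keeps the
    gene.
    """
    status = mutation_status.reindex(dep_column.index)
    mut = dep_column[status == 1].dropna().values
    wt = dep_column[status == 0].dropna().values
    if len(mut) == 0 or len(wt) == 0:
        logger.info("filter_self_mutation: one-sided group empty, keeping gene")
        return True
    p = float(mannwhitneyu(mut, wt, alternative="two-sided").pvalue)
    return p >= p_threshold


@dataclass
class AlleleDependencyHit:
    """A gene with allele-differential dependency and its cluster label."""

    gene: str
    anova_p: float
    group_p_adj: dict[str, float] = field(default_factory=dict)
    direction: dict[str, float] = field(default_factory=dict)  # group mean - rest mean
    cluster: int | None = None


def allele_anova_and_ttests(
    dep_matrix: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    anova_threshold: float = 0.01,
    t_fdr_threshold: float = 0.05,
    pairwise: bool = False,
) -> list[AlleleDependencyHit]:
    """Screen genes for allele-differential dependency.

    One-way ANOVA per gene across allele groups; for genes with ANOVA
    p < ``anova_threshold``, Student's t tests (equal variance) of each
    group against all other lines pooled (or all group pairs when
    ``pairwise=True``), BH-adjusted over all (gene, comparison) tests;
    a hit needs at least one adjusted p < ``t_fdr_threshold``.
    """
    group_names = list(groups)
    if len(group_names) < 2 or any(len(v) < 3 for v in groups.values()):
        raise ValueError("need >= 2 allele groups of >= 3 lines each")
    anova_hits: list[tuple[str, float]] = []
    for gene in dep_matrix.columns:
        arrays = [dep_matrix.loc[list(m), gene].dropna().values for m in groups.values()]
        if any(len(a) < 2 for a in arrays):
            continue
        if all(np.ptp(a) == 0 for a in arrays):
            logger.info("allele_anova_and_ttests: zero variance everywhere for %s, skipped", gene)
            continue
        p = float(f_oneway(*arrays).pvalue)
        if p < anova_threshold:
            anova_hits.append((gene, p))
    tests: list[tuple[str, str, float, float]] = []  # gene, group, p, effect
    for gene, _ in anova_hits:
        if pairwise:
            comparisons = [
                (f"{a}|{b}", groups[a], groups[b])
                for i, a in enumerate(group_names)
                for b in group_names[i + 1 :]
            ]
        else:
            comparisons = [
                (g, groups[g], [l for h, m in groups.items() if h != g for l in m])
                for g in group_names
            ]
        for label, in_lines, out_lines in comparisons:
            x = dep_matrix.loc[list(in_lines), gene].dropna().values
            y = dep_matrix.loc[list(out_lines), gene].dropna().values
            res = ttest_ind(x, y, equal_var=True)
            tests.append((gene, label, float(res.pvalue), float(x.mean() - y.mean())))
    if not tests:
        return []
    p_adj = multipletests([t[2] for t in tests], method="fdr_bh")[1]
    by_gene: dict[str, AlleleDependencyHit] = {}
    anova_p = dict(anova_hits)
    for (gene, label, _, eff), padj in zip(tests, p_adj):
        hit = by_gene.setdefault(gene, AlleleDependencyHit(gene=gene, anova_p=anova_p[gene]))
        hit.group_p_adj[label] = float(padj)
        hit.direction[label] = eff
    return [h for h in by_gene.values() if min(h.group_p_adj.values()) < t_fdr_threshold]


def cluster_hits(dep_submatrix: pd.DataFrame, k: int = 4) -> pd.Series:
    """Hierarchically cluster hit genes on z-scored dependency profiles.

    Ward linkage on Euclidean distance of per-gene standardized profiles
    (rows = genes, columns = lines); the tree is cut to ``k`` clusters.
    Deterministic given input order; identical rows land in the same cluster
    with ties broken by first index.
    """
    n = dep_submatrix.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} hit genes")
    if k == 1:
        return pd.Series(1, index=dep_submatrix.index)
    X = dep_submatrix.values.astype(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    labels = fcluster(linkage(Z, method="ward"), t=k, criterion="maxclust")
    return pd.Series(labels, index=dep_submatrix.index)


def run_dependency_screen(
    dep_matrix: pd.DataFrame,
    metadata: LineMetadata,
    expression: pd.DataFrame | None = None,
    mutation_status: pd.DataFrame | None = None,
    anova_threshold: float = 0.01,
    t_fdr_threshold: float = 0.05,
    n_clusters: int = 4,
) -> tuple[list[AlleleDependencyHit], dict[str, list[str]]]:
    """Full screen: eligibility, expression/self-mutation filters, ANOVA+t, clustering."""
    kept, groups = eligible_lines(metadata)
    dep = dep_matrix.loc[kept]
    genes = []
    for gene in dep.columns:
        if expression is not None and gene in expression.columns:
            if not filter_expression_explained(dep[gene], expression.loc[kept, gene]):
                continue
        if mutation_status is not None and gene in mutation_status.columns:
            if not filter_self_mutation(dep[gene], mutation_status.loc[kept, gene]):
                continue
        genes.append(gene)
    hits = allele_anova_and_ttests(
        dep[genes], groups, anova_threshold=anova_threshold, t_fdr_threshold=t_fdr_threshold
    )
    if len(hits) >= 2:
        sub = dep[[h.gene for h in hits]].T  # genes x lines
        clusters = cluster_hits(sub, k=min(n_clusters, len(hits)))
        for h in hits:
            h.cluster = int(clusters[h.gene])
    return hits, groups
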