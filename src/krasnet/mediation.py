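"""Do comutation partners, rather than the KRAS allele, explain a dependency?

For each gene with an allele-specific dependency, a penalized linear model
regresses its dependency score on the gene's own RNA expression, its own
mutation status, an indicator for the specific KRAS allele (versus any other
KRAS-mutant line), and one indicator per comutation-partner gene. Partner
indicators mutated in the same lines are merged into a single predictor, and
indicators with fewer than three mutant or three WT lines are dropped. The
model is fit with elastic net regularization with the mixing parameter
constrained to [0.75, 1] (L1-dominated), the penalty chosen by K-fold
cross-validation with the one-standard-error rule. A nonzero partner
coefficient with a zero allele coefficient indicates that the partner's
mutation status, anti-correlated with the allele through reduced comutation,
mediates the apparent allele effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = (0.75, 0.80, 0.85, 0.90, 0.95, 1.0)


@dataclass
class MediationDesign:
    """Response and covariates for one (target gene, allele) mediation model."""

    response: pd.Series
    covariates: pd.DataFrame
    merge_map: dict[str, list[str]] = field(default_factory=dict)
    target_gene: str = ""
    allele: str = ""


def _merge_identical_columns(X: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Collapse identical covariate columns into one, naming by concatenation."""
    groups: dict[tuple, list[str]] = {}
    for col in X.columns:
        groups.setdefault(tuple(X[col].values.tolist()), []).append(col)
    out = {}
    merge_map = {}
    for vals, cols in groups.items():
        name = "|".join(cols)
        out[name] = list(vals)
        merge_map[name] = cols
    merged = pd.DataFrame(out, index=X.index)
    return merged, merge_map


def build_design(
    target_gene: str,
    allele: str,
    partners: list[str],
    dependency: pd.Series,
    expression: pd.Series | None,
    mutation_status: pd.DataFrame,
    allele_labels: pd.Series,
    min_group: int = 3,
) -> MediationDesign:
    """Assemble the mediation design matrix for one target gene and allele.

    Lines are restricted to KRAS-mutant lines (the allele indicator contrasts
    the specific allele against other KRAS-mutant lines). Binary indicators
    (target-gene mutation, each partner mutation) are kept only when mutated
    in >= ``min_group`` lines and WT in >= ``min_group`` lines; covariate
    columns with identical values are merged into a single predictor.
    """
    mutant_lines = allele_labels.index[allele_labels != "WT"]
    y = dependency.reindex(mutant_lines).dropna()
    lines = y.index
    if np.ptp(y.values) == 0:
        raise ValueError("dependency response is constant; mediation model undefined")
    cols: dict[str, pd.Series] = {}
    if expression is not None:
        cols[f"{target_gene}_expression"] = expression.reindex(lines)
    indicators = {f"{target_gene}_mutation": mutation_status.get(target_gene)}
    for p in partners:
        indicators[f"{p}_mutation"] = mutation_status.get(p)
    for name, col in indicators.items():
        if col is None:
            continue
        v = col.reindex(lines).fillna(0).astype(int)
        if v.sum() < min_group or (1 - v).sum() < min_group:
            logger.info("build_design: dropping %s (needs >= %d mutant and WT lines)", name, min_group)
            continue
        cols[name] = v
    allele_ind = (allele_labels.reindex(lines) == allele).astype(int)
    if allele_ind.sum() >= min_group and (1 - allele_ind).sum() >= min_group:
        cols[f"KRAS_{allele}"] = allele_ind
    else:
        logger.info("build_design: allele indicator %s dropped (unbalanced)", allele)
    X = pd.DataFrame(cols, index=lines)
    merged, merge_map = _merge_identical_columns(X)
    return MediationDesign(
        response=y, covariates=merged, merge_map=merge_map,
        target_gene=target_gene, allele=allele,
    )


@dataclass
class MediationFit:
    """Nonzero elastic-net coefficients for one mediation model."""

    coefficients: pd.Series  # nonzero only, on standardized covariates
    alpha: float             # mixing parameter (L1 fraction)
    penalty: float           # regularization strength
    seed: int
    cv_mse: float
    intercept: float = 0.0


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def fit_mediation(
    design: MediationDesign,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    n_penalties: int = 50,
    one_se: bool = True,
) -> MediationFit:
    """Elastic-net fit over a grid of L1 fractions with CV penalty selection.

    Covariates are standardized; the intercept is unpenalized. For each
    mixing parameter a log-spaced penalty path is scored by K-fold CV
    (leave-one-out fallback when lines < folds); with ``one_se`` the
    sparsest (largest) penalty within one standard error of the CV minimum
    is chosen.
    """
    if any(a < 0.75 or a > 1.0 for a in alpha_grid):
        raise ValueError("mixing parameters must lie in [0.75, 1]")
    y = design.response.values.astype(float)
    X = _standardize(design.covariates.values.astype(float))
    n = len(y)
    if n < cv_folds:
        logger.warning("fit_mediation: %d lines < %d folds, using leave-one-out", n, cv_folds)
        cv_folds = n
    folds = list(KFold(n_splits=cv_folds, shuffle=True, random_state=seed).split(X))
    yc = y - y.mean()
    results = []  # (mean_mse, se_mse, l1_ratio, penalty)
    for l1 in alpha_grid:
        lam_max = np.max(np.abs(X.T @ yc)) / (n * l1)
        penalties = np.geomspace(lam_max, lam_max * 1e-3, n_penalties)
        fold_mse = np.zeros((len(folds), n_penalties))
        for f, (tr, te) in enumerate(folds):
            for j, lam in enumerate(penalties):
                model = ElasticNet(alpha=lam, l1_ratio=l1, max_iter=5000)
                model.fit(X[tr], y[tr])
                pred = model.predict(X[te])
                fold_mse[f, j] = np.mean((y[te] - pred) ** 2)
        mean = fold_mse.mean(axis=0)
        se = fold_mse.std(axis=0, ddof=1) / np.sqrt(len(folds))
        for j, lam in enumerate(penalties):
            results.append((mean[j], se[j], l1, lam))
    best_mean, best_se, _, _ = min(results, key=lambda r: r[0])
    if one_se:
        admissible = [r for r in results if r[0] <= best_mean + best_se]
        _, _, l1_star, lam_star = max(admissible, key=lambda r: (r[3], r[2]))
        cv_mse = next(r[0] for r in results if r[2] == l1_star and r[3] == lam_star)
    else:
        cv_mse, _, l1_star, lam_star = min(results, key=lambda r: r[0])
    final = ElasticNet(alpha=lam_star, l1_ratio=l1_star, max_iter=10000)
    final.fit(X, y)
    coefs = pd.Series(final.coef_, index=design.covariates.columns)
    return MediationFit(
        coefficients=coefs[coefs != 0],
        alpha=float(l1_star),
        penalty=float(lam_star),
        seed=seed,
        cv_mse=float(cv_mse),
        intercept=float(final.intercept_),
    )
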