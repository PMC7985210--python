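"""Allele-specific comutation analysis on binary mutation matrices.

Increased comutation between a KRAS allele and another gene is detected with
a one-sided Fisher's exact test (hypergeometric enrichment tail) subject to
frequency/event-count filters. Reduced comutation (toward mutual exclusivity)
is detected with the row-column exclusivity permutation test: the observed
number of samples mutated in exactly one of the two columns is compared to
its distribution over binary matrices sampled uniformly with both row sums
(per-sample burden) and column sums (per-gene frequency) fixed, via curveball
trades. Hypermutated samples are identified from a two-component Gaussian
mixture on log10 burden and excluded before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXOME_ASSAYS = frozenset({"WES", "WGS"})


@dataclass
class BinaryMutationMatrix:
    """Samples x genes 0/1 matrix with per-sample KRAS allele and assay labels.

    ``alleles`` maps each sample to a specific hotspot allele label, "other"
    (a KRAS mutation outside the tracked alleles), or "WT". ``assay`` marks
    each sample "WES", "WGS", or "targeted"; burden-conditioned tests are
    restricted to exome/genome samples where the burden is meaningful.
    """

    matrix: pd.DataFrame
    alleles: pd.Series
    assay: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.matrix.values
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0/1")
        self.matrix = self.matrix.astype(int)
        self.alleles = self.alleles.reindex(self.matrix.index)
        if self.assay is None:
            self.assay = pd.Series("WES", index=self.matrix.index)
        else:
            self.assay = self.assay.reindex(self.matrix.index)

    @property
    def burdens(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def gene_frequency(self) -> pd.Series:
        return self.matrix.mean(axis=0)

    def subset(self, samples: Sequence[str]) -> "BinaryMutationMatrix":
        return BinaryMutationMatrix(
            self.matrix.loc[samples], self.alleles.loc[samples], self.assay.loc[samples]
        )

    def exome_only(self) -> "BinaryMutationMatrix":
        keep = self.assay.isin(EXOME_ASSAYS)
        return self.subset(self.matrix.index[keep])


@dataclass
class HypermutantCutoff:
    """Burden cutoff from a 2-component Gaussian mixture on log10 burden."""

    cutoff: float
    flagged: pd.Index
    top_fraction: float
    means: tuple[float, float]
    weights: tuple[float, float]
    fallback_used: bool = False


def fit_hypermutant_cutoff(
    burdens: pd.Series, seed: int = 0, fallback_top_fraction: float = 0.17
) -> HypermutantCutoff:
    """Split samples into normo- and hypermutated by mixture modeling.

    Fits a two-component Gaussian mixture to log10(burden + 1); the cutoff is
    the smallest observed burden whose posterior probability of belonging to
    the high-mean component exceeds 0.5. If the fit degenerates (components
    collapse), falls back to flagging the configured top fraction by quantile.
    """
    if len(burdens) < 20:
        raise ValueError("need >= 20 samples to fit a burden mixture")
    x = np.log10(burdens.values.astype(float) + 1.0).reshape(-1, 1)
    fallback = False
    cutoff = np.nan
    means = weights = (np.nan, np.nan)
    if np.ptp(x) < 1e-9:
        fallback = True
    else:
        gm = GaussianMixture(n_components=2, n_init=5, random_state=seed).fit(x)
        order = np.argsort(gm.means_.ravel())
        means = tuple(gm.means_.ravel()[order])
        weights = tuple(gm.weights_.ravel()[order])
        sds = np.sqrt(gm.covariances_.ravel()[order])
        hi = order[1]
        # components must be genuinely separated (a unimodal burden
        # distribution otherwise gets split into two overlapping halves)
        separation = (means[1] - means[0]) / np.sqrt(0.5 * (sds[0] ** 2 + sds[1] ** 2))
        if separation < 2.0 or min(weights) < 1e-3:
            fallback = True
        else:
            post_hi = gm.predict_proba(np.sort(x, axis=0))[:, hi]
            sorted_burdens = np.sort(burdens.values)
            above = (post_hi > 0.5) & (np.sort(x, axis=0).ravel() > means[0])
            if above.any():
                cutoff = float(sorted_burdens[np.argmax(above)])
            else:
                fallback = True
    if fallback:
        logger.warning("degenerate burden mixture; falling back to top-%.0f%% quantile",
                       100 * fallback_top_fraction)
        cutoff = float(np.quantile(burdens.values, 1 - fallback_top_fraction))
        flagged = burdens.index[burdens > cutoff]
    else:
        flagged = burdens.index[burdens >= cutoff]
    return HypermutantCutoff(
        cutoff=cutoff,
        flagged=flagged,
        top_fraction=len(flagged) / len(burdens),
        means=means,
        weights=weights,
        fallback_used=fallback,
    )


def expression_filter(
    gene: str,
    expression_sources: Iterable[pd.DataFrame | pd.Series],
    threshold: float = 1.0,
) -> bool:
    """Is the gene expressed in the tissue according to any source?

    Each source is genes x samples (or a per-gene median Series); the gene
    passes if its median expression in at least one source meets the
    threshold (1 TPM / 1 normalized count by default). A gene absent from
    every source is treated as not expressed.
    """
    seen = False
    for src in expression_sources:
        if gene not in src.index:
            continue
        seen = True
        vals = src.loc[gene]
        med = float(np.median(np.atleast_1d(vals.values if hasattr(vals, "values") else vals)))
        if med >= threshold:
            return True
    if not seen:
        logger.info("expression_filter: gene %s absent from all sources", gene)
    return False


@dataclass
class ComutationInteraction:
    """One allele-gene edge of the comutation network."""

    allele: str
    gene: str
    direction: str  # "increased" | "reduced"
    n_events: int   # comutation events (increased) or exclusive events (reduced)
    comutation_frequency: float
    p: float
    p_adj_set: float | None = None
    curated_sets: list[str] = field(default_factory=list)


def fisher_enrichment_p(both: int, n_carriers: int, n_gene: int, n_total: int) -> float:
    """One-sided (enrichment) Fisher's exact p for a 2x2 comutation table.

    Equals the upper hypergeometric tail P(X >= both) with population
    ``n_total``, ``n_gene`` successes, and ``n_carriers`` draws.
    """
    return float(hypergeom.sf(both - 1, n_total, n_gene, n_carriers))


def increased_comutation(
    matrix: BinaryMutationMatrix,
    allele: str,
    min_gene_freq: float = 0.01,
    min_events: int = 3,
    min_comut_freq: float = 0.10,
    p_threshold: float = 0.01,
    genes: Sequence[str] | None = None,
) -> list[ComutationInteraction]:
    """Genes comutating with a KRAS allele more often than expected.

    For each gene with overall mutation frequency >= ``min_gene_freq`` and
    either >= ``min_events`` comutation events or comutation frequency (among
    allele carriers) >= ``min_comut_freq``, computes the one-sided Fisher
    enrichment p on the carrier x mutated 2x2 table and keeps edges with
    p < ``p_threshold``.
    """
    carriers = matrix.alleles == allele
    n_carriers = int(carriers.sum())
    if n_carriers == 0:
        logger.info("increased_comutation: no carriers of %s, skipped", allele)
        return []
    M = matrix.matrix if genes is None else matrix.matrix[list(genes)]
    n_total = M.shape[0]
    gene_counts = M.values.sum(axis=0)
    both_counts = M.values[carriers.values].sum(axis=0)
    out = []
    for g, n_gene, both in zip(M.columns, gene_counts, both_counts):
        if n_gene / n_total < min_gene_freq:
            continue
        comut_freq = both / n_carriers
        if both < min_events and comut_freq < min_comut_freq:
            continue
        p = fisher_enrichment_p(int(both), n_carriers, int(n_gene), n_total)
        if p < p_threshold:
            out.append(
                ComutationInteraction(
                    allele=allele,
                    gene=str(g),
                    direction="increased",
                    n_events=int(both),
                    comutation_frequency=float(comut_freq),
                    p=p,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Fixed-margin (curveball) sampling and the row-column exclusivity test.
# ---------------------------------------------------------------------------


def _rows_as_sets(M: np.ndarray) -> list[set[int]]:
    return [set(np.flatnonzero(row)) for row in M]


def _curveball_trades(rows: list[set[int]], n_trades: int, rng: np.random.Generator) -> None:
    """In-place margin-preserving checkerboard trades on random row pairs."""
    nr = len(rows)
    if nr < 2 or n_trades <= 0:
        return
    ii = rng.integers(0, nr, size=n_trades)
    jj = rng.integers(0, nr, size=n_trades)
    for i, j in zip(ii, jj):
        if i == j:
            continue
        ri, rj = rows[i], rows[j]
        only_i = ri - rj
        only_j = rj - ri
        if not only_i or not only_j:
            continue
        pool = list(only_i | only_j)
        rng.shuffle(pool)
        shared = ri & rj
        k = len(only_i)
        rows[i] = shared | set(pool[:k])
        rows[j] = shared | set(pool[k:])


def sample_fixed_margin(
    matrix: pd.DataFrame, n_trades: int, seed: int = 0
) -> pd.DataFrame:
    """A binary matrix with the same row and column sums, after curveball trades."""
    vals = matrix.values
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("matrix entries must be 0/1")
    rng = np.random.default_rng(seed)
    rows = _rows_as_sets(vals)
    _curveball_trades(rows, n_trades, rng)
    out = np.zeros_like(vals)
    for i, s in enumerate(rows):
        out[i, list(s)] = 1
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def exclusivity_statistic(col_a: np.ndarray, col_b: np.ndarray) -> int:
    """Number of samples mutated in exactly one of the two columns."""
    return int(np.sum(np.asarray(col_a) != np.asarray(col_b)))


class _ExclusivityChain:
    """Curveball Markov chain that tracks exclusivity statistics incrementally.

    Maintains, for a reference column and a set of tracked gene columns, the
    number of rows where the gene and reference memberships differ; each
    margin-preserving trade updates only the affected counts, so reading the
    statistics after thinning costs O(1).
    """

    def __init__(self, vals: np.ndarray, ref_col: int, gene_cols: Sequence[int],
                 rng: np.random.Generator) -> None:
        self.rows = _rows_as_sets(vals)
        self.ref = ref_col
        self.gene_cols = list(gene_cols)
        self.pos = {c: k for k, c in enumerate(self.gene_cols)}
        self.in_ref = vals[:, ref_col].astype(bool).copy()
        self.in_gene = vals[:, self.gene_cols].astype(bool).copy()
        self.stats = (self.in_gene != self.in_ref[:, None]).sum(axis=0).astype(np.int64)
        self.rng = rng

    def _flip(self, r: int, c: int) -> None:
        if c == self.ref:
            old = self.in_ref[r]
            self.in_ref[r] = not old
            row = self.in_gene[r]
            self.stats += (row != self.in_ref[r]).astype(np.int64) - (row != old)
        else:
            k = self.pos.get(c)
            if k is None:
                return
            old = self.in_gene[r, k]
            new = not old
            self.stats[k] += int(new != self.in_ref[r]) - int(old != self.in_ref[r])
            self.in_gene[r, k] = new

    def trades(self, n_trades: int) -> None:
        rows = self.rows
        nr = len(rows)
        if nr < 2 or n_trades <= 0:
            return
        rng = self.rng
        ii = rng.integers(0, nr, size=n_trades)
        jj = rng.integers(0, nr, size=n_trades)
        tracked = set(self.gene_cols)
        tracked.add(self.ref)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            ri, rj = rows[i], rows[j]
            only_i = ri - rj
            only_j = rj - ri
            if not only_i or not only_j:
                continue
            pool = list(only_i | only_j)
            rng.shuffle(pool)
            shared = ri & rj
            k = len(only_i)
            new_i = shared | set(pool[:k])
            new_j = shared | set(pool[k:])
            moved = (ri - new_i) | (rj - new_j)  # columns swapped between the rows
            for c in moved:
                if c in tracked:
                    self._flip(i, c)
                    self._flip(j, c)
            rows[i] = new_i
            rows[j] = new_j


def rc_exclusivity_test(
    matrix: pd.DataFrame,
    allele_column: str,
    gene_column: str,
    n_perm: int = 10_000,
    seed: int = 0,
    burn_in: int | None = None,
    thin: int | None = None,
    tie_break: str = "conservative",
) -> tuple[float, int]:
    """Row-column exclusivity permutation test for one column pair.

    The statistic is the number of samples mutated in exactly one of the two
    columns; the null samples binary matrices uniformly with both margins
    fixed via curveball trades (burn-in of 5x the number of 1s, thinning of
    1x between draws, by default). By default permutation ties count as
    >= observed and the p-value carries the +1 correction, so it is
    conservative and never 0; ``tie_break="randomized"`` places the observed
    statistic uniformly among its ties, which makes the p-value exactly
    uniform under the fixed-margin null (used for sampler calibration).
    """
    if tie_break not in ("conservative", "randomized"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    vals = matrix.values
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("matrix entries must be 0/1")
    rng = np.random.default_rng(seed)
    ia = matrix.columns.get_loc(allele_column)
    ib = matrix.columns.get_loc(gene_column)
    observed = exclusivity_statistic(vals[:, ia], vals[:, ib])
    n_ones = int(vals.sum())
    burn_in = 5 * n_ones if burn_in is None else burn_in
    thin = n_ones if thin is None else thin
    chain = _ExclusivityChain(vals, ia, [ib], rng)
    chain.trades(burn_in)
    n_gt = 0
    n_eq = 0
    for _ in range(n_perm):
        chain.trades(thin)
        s = int(chain.stats[0])
        if s > observed:
            n_gt += 1
        elif s == observed:
            n_eq += 1
    if tie_break == "randomized":
        p = (1 + n_gt + rng.integers(0, n_eq + 1)) / (1 + n_perm)
    else:
        p = (1 + n_gt + n_eq) / (1 + n_perm)
    return float(p), observed


def reduced_comutation(
    matrix: BinaryMutationMatrix,
    allele: str,
    n_perm: int = 10_000,
    seed: int = 0,
    min_gene_freq: float = 0.02,
    min_exclusive: int = 10,
    p_threshold: float = 0.01,
    genes: Sequence[str] | None = None,
    burn_in: int | None = None,
    thin: int | None = None,
) -> list[ComutationInteraction]:
    """Genes comutating with a KRAS allele less often than expected.

    Restricted to exome/genome samples (where burden margins are meaningful).
    The allele indicator is appended as an extra column and the whole matrix
    is permuted with fixed margins; all eligible genes share the same
    permutation draws. Eligibility: gene frequency >= ``min_gene_freq`` and
    >= ``min_exclusive`` mutually exclusive events.
    """
    sub = matrix.exome_only()
    if sub.matrix.shape[0] == 0:
        logger.info("reduced_comutation: no exome/genome samples")
        return []
    carriers = (sub.alleles == allele).astype(int)
    if carriers.sum() == 0:
        logger.info("reduced_comutation: no carriers of %s, skipped", allele)
        return []
    M = sub.matrix if genes is None else sub.matrix[list(genes)]
    n_total = M.shape[0]
    freqs = M.values.mean(axis=0)
    car = carriers.values
    eligible = []
    observed: dict[str, int] = {}
    for g, f in zip(M.columns, freqs):
        if f < min_gene_freq:
            continue
        stat = int(np.sum(M[g].values != car))
        if stat < min_exclusive:
            continue
        eligible.append(g)
        observed[g] = stat
    if not eligible:
        return []

    aug = M.copy()
    aug["__KRAS_ALLELE__"] = car
    vals = aug.values
    rng = np.random.default_rng(seed)
    n_ones = int(vals.sum())
    burn_in = 5 * n_ones if burn_in is None else burn_in
    thin = n_ones if thin is None else thin
    ia = aug.columns.get_loc("__KRAS_ALLELE__")
    gene_cols = [aug.columns.get_loc(g) for g in eligible]
    chain = _ExclusivityChain(vals, ia, gene_cols, rng)
    chain.trades(burn_in)
    obs_vec = np.array([observed[g] for g in eligible])
    n_ge_vec = np.zeros(len(eligible), dtype=np.int64)
    for _ in range(n_perm):
        chain.trades(thin)
        n_ge_vec += chain.stats >= obs_vec
    n_ge = dict(zip(eligible, n_ge_vec))
    out = []
    n_carriers = int(car.sum())
    for g in eligible:
        p = (1 + n_ge[g]) / (1 + n_perm)
        if p < p_threshold:
            both = int(np.sum((M[g].values == 1) & (car == 1)))
            out.append(
                ComutationInteraction(
                    allele=allele,
                    gene=str(g),
                    direction="reduced",
                    n_events=observed[g],
                    comutation_frequency=both / n_carriers,
                    p=p,
                )
            )
    return out


def build_network(
    interactions: Iterable[ComutationInteraction],
    curated_gene_sets: Mapping[str, Sequence[str]] | None = None,
    fdr_threshold: float = 0.25,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Assemble the allele-specific comutation edge table.

    All interactions with raw p < ``p_threshold`` form the full network. For
    edges whose gene belongs to a curated set (KRAS interactors, pathway
    members, cancer genes), BH adjustment is applied within each curated
    subset and the edge is additionally required to fall below the FDR
    threshold in at least one of its sets.
    """
    edges = [i for i in interactions if i.p < p_threshold]
    rows = [
        {
            "allele": e.allele,
            "gene": e.gene,
            "direction": e.direction,
            "n_events": e.n_events,
            "comutation_frequency": e.comutation_frequency,
            "p": e.p,
        }
        for e in edges
    ]
    df = pd.DataFrame(
        rows, columns=["allele", "gene", "direction", "n_events", "comutation_frequency", "p"]
    )
    df["p_adj_set"] = np.nan
    df["curated"] = False
    if curated_gene_sets:
        keep = np.ones(len(df), dtype=bool)
        for set_name, genes in curated_gene_sets.items():
            gene_set = set(genes)
            mask = df["gene"].isin(gene_set).values
            if not mask.any():
                continue
            p_adj = multipletests(df.loc[mask, "p"].values, method="fdr_bh")[1]
            prev = df.loc[mask, "p_adj_set"].values
            df.loc[mask, "p_adj_set"] = np.fmin(prev, p_adj)
            df.loc[mask, "curated"] = True
        curated_mask = df["curated"].values
        keep[curated_mask] = df.loc[curated_mask, "p_adj_set"].values < fdr_threshold
        df = df[keep]
    return df.reset_index(drop=True)
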