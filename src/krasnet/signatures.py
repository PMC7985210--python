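"""Mutational-signature discovery, exposure fitting, and attribution.

Signatures are probability distributions over the 96 trinucleotide channels.
Discovery uses repeated NMF factorizations with model selection by silhouette
width (cosine distance) and Frobenius reconstruction error; per-sample
exposures are fit by nonnegative least squares restricted to an allow-list of
signatures; the probability that a given signature caused a specific observed
mutation in a specific sample is

    p[k, s, a] = c[s, a] * w[k, s] / sum_i c[i, a] * w[k, i]

where c is the sample's exposure to each signature and w the signature's
weight on the mutation's channel. The ratio is invariant to rescaling a
sample's exposure vector, so raw or fractional exposures give the same
attribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import normalize
from statsmodels.stats.multitest import multipletests

from .codon_spectrum import CHANNEL_LABELS, N_CHANNELS

logger = logging.getLogger(__name__)


@dataclass
class SignatureCatalog:
    """Signatures x 96 channel-probability matrix; rows sum to 1."""

    weights: pd.DataFrame  # index: signature labels, columns: channel labels

    def __post_init__(self) -> None:
        w = self.weights
        if list(w.columns) != list(CHANNEL_LABELS):
            if set(w.columns) == set(CHANNEL_LABELS):
                self.weights = w = w[list(CHANNEL_LABELS)]
            else:
                raise ValueError("catalog columns do not match the 96-channel ordering")
        if (w.values < 0).any():
            raise ValueError("negative signature weights")
        rowsums = w.values.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-8):
            raise ValueError("signature rows must sum to 1 (tolerance 1e-8)")

    @property
    def signatures(self) -> list[str]:
        return list(self.weights.index)

    @property
    def values(self) -> np.ndarray:
        return self.weights.values

    @classmethod
    def from_array(cls, w: np.ndarray, labels: list[str] | None = None) -> "SignatureCatalog":
        w = np.asarray(w, dtype=float)
        w = w / w.sum(axis=1, keepdims=True)
        labels = labels or [f"S{i + 1}" for i in range(w.shape[0])]
        return cls(pd.DataFrame(w, index=labels, columns=list(CHANNEL_LABELS)))


@dataclass
class ExposureMatrix:
    """Per-sample nonnegative signature contributions, raw and fractional."""

    raw: pd.DataFrame         # samples x signatures, NNLS solution
    fractions: pd.DataFrame   # rows sum to 1 where the sample has signal
    undefined_samples: list[str] = field(default_factory=list)

    @property
    def signatures(self) -> list[str]:
        return list(self.raw.columns)


@dataclass
class ModelSelectionReport:
    """Per-k silhouette and reconstruction error from NMF model selection."""

    silhouette: dict[int, float]
    frobenius: dict[int, float]
    chosen_k: int
    dropped_signatures: list[str] = field(default_factory=list)


def _nmf_restarts(
    V: np.ndarray, k: int, n_restarts: int, seed: int, max_iter: int = 5000, tol: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Pooled L1-normalized signature vectors from repeated NMF, plus median error."""
    sigs, errs = [], []
    for r in range(n_restarts):
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=seed + 1000 * r,
        )
        W = model.fit_transform(V)  # samples x k
        H = model.components_       # k x channels
        scale = H.sum(axis=1)
        keep = scale > 0
        sigs.append(H[keep] / scale[keep, None])
        errs.append(model.reconstruction_err_)
    return np.vstack(sigs), float(np.median(errs))


def discover_signatures(
    spectra: pd.DataFrame,
    k_range: range | list[int],
    n_restarts: int = 10,
    seed: int = 0,
    min_contribution: float = 0.05,
    stability_tolerance: float = 0.05,
) -> tuple[SignatureCatalog, ModelSelectionReport]:
    """De novo signature discovery with silhouette/Frobenius model selection.

    For each candidate k, runs ``n_restarts`` NMF factorizations from random
    initializations, pools the normalized signature vectors, clusters them
    into k groups, and scores the clustering by mean silhouette width under
    cosine distance (restart stability). The chosen k minimizes the median
    Frobenius reconstruction error among candidates whose silhouette is
    within ``stability_tolerance`` of the best — i.e., the most expressive
    model that is still as stable as the stablest one. Consensus signatures
    are cluster centroids; discovered signatures contributing less than
    ``min_contribution`` of all mutations (by pooled NNLS refit) are
    dropped.
    """
    k_range = sorted(k_range)
    n_samples = spectra.shape[0]
    if not k_range or k_range[0] < 2 or k_range[-1] >= n_samples:
        raise ValueError(f"k_range must lie within [2, n_samples={n_samples}); got {k_range}")
    V = spectra.values.astype(float)
    sil: dict[int, float] = {}
    frob: dict[int, float] = {}
    centroids: dict[int, np.ndarray] = {}
    for k in k_range:
        pooled, err = _nmf_restarts(V, k, n_restarts, seed)
        frob[k] = err
        unit = normalize(pooled)  # L2, so KMeans on Euclidean ~ cosine clustering
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(unit)
        labels = km.labels_
        if len(set(labels)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(pooled, labels, metric="cosine"))
        cents = np.vstack([pooled[labels == j].mean(axis=0) for j in range(k)])
        centroids[k] = cents / cents.sum(axis=1, keepdims=True)

    sil_max = max(sil.values())
    candidates = [k for k in k_range if sil[k] >= sil_max - stability_tolerance]
    chosen = min(candidates, key=lambda k: frob[k])

    catalog = SignatureCatalog.from_array(centroids[chosen])
    # Drop signatures explaining <5% of all mutations (pooled NNLS refit).
    exposures = fit_exposures(spectra, catalog)
    totals = exposures.raw.values.sum(axis=0)
    frac = totals / totals.sum() if totals.sum() > 0 else totals
    keep = frac >= min_contribution
    dropped = [s for s, k_ in zip(catalog.signatures, keep) if not k_]
    if dropped:
        logger.info("dropping low-contribution signatures: %s", dropped)
        catalog = SignatureCatalog(catalog.weights.loc[keep])
    report = ModelSelectionReport(
        silhouette=sil, frobenius=frob, chosen_k=chosen, dropped_signatures=dropped
    )
    return catalog, report


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return normalize(A) @ normalize(B).T


def match_to_reference(
    catalog: SignatureCatalog, reference: SignatureCatalog, min_cosine: float = 0.8
) -> pd.DataFrame:
    """Greedy best-match of discovered signatures to a reference catalog.

    Matches are assigned in decreasing order of cosine similarity, each
    reference signature used at most once; similarities below ``min_cosine``
    are labeled "novel".
    """
    if list(catalog.weights.columns) != list(reference.weights.columns):
        raise ValueError("catalogs are not on the same channel ordering")
    sim = cosine_similarity_matrix(catalog.values, reference.values) if len(reference.signatures) else np.zeros((len(catalog.signatures), 0))
    rows = []
    used: set[int] = set()
    order = []
    if sim.size:
        order = sorted(
            ((i, j) for i in range(sim.shape[0]) for j in range(sim.shape[1])),
            key=lambda ij: -sim[ij]
        )
    assigned: dict[int, tuple[int, float]] = {}
    for i, j in order:
        if i in assigned or j in used:
            continue
        if sim[i, j] >= min_cosine:
            assigned[i] = (j, sim[i, j])
            used.add(j)
    for i, sig in enumerate(catalog.signatures):
        if i in assigned:
            j, s = assigned[i]
            rows.append({"signature": sig, "match": reference.signatures[j], "cosine": s})
        else:
            best = float(sim[i].max()) if sim.size else np.nan
            rows.append({"signature": sig, "match": "novel", "cosine": best})
    return pd.DataFrame(rows)


def fit_exposures(
    spectra: pd.DataFrame | pd.Series,
    catalog: SignatureCatalog,
    allowed_signatures: list[str] | None = None,
) -> ExposureMatrix:
    """NNLS exposure fit restricted to an allow-list of signatures.

    Solves min ||counts - W'e||_2 s.t. e >= 0 over the allowed signatures;
    disallowed signatures receive exposure exactly 0. Samples with an all-zero
    spectrum get zero exposures and an undefined fractional form (flagged).
    """
    if isinstance(spectra, pd.Series):
        spectra = spectra.to_frame().T
    allowed = allowed_signatures if allowed_signatures is not None else catalog.signatures
    if not allowed:
        raise ValueError("allowed signature set is empty")
    unknown = set(allowed) - set(catalog.signatures)
    if unknown:
        raise ValueError(f"allowed signatures not in catalog: {sorted(unknown)}")
    Wt = catalog.weights.loc[allowed].values.T  # channels x allowed
    raw = np.zeros((spectra.shape[0], len(catalog.signatures)))
    col_of = {s: i for i, s in enumerate(catalog.signatures)}
    allowed_cols = [col_of[s] for s in allowed]
    undefined = []
    for i, (sid, row) in enumerate(spectra.iterrows()):
        v = row.values.astype(float)
        if v.sum() == 0:
            undefined.append(sid)
            continue
        e, _ = nnls(Wt, v)
        raw[i, allowed_cols] = e
    raw_df = pd.DataFrame(raw, index=spectra.index, columns=catalog.signatures)
    sums = raw_df.values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = raw_df.values / sums[:, None]
    frac_df = pd.DataFrame(frac, index=spectra.index, columns=catalog.signatures)
    undefined += [sid for sid, s in zip(spectra.index, sums) if s == 0 and sid not in undefined]
    if undefined:
        logger.info("fit_exposures: %d samples with undefined fractional exposures", len(undefined))
    return ExposureMatrix(raw=raw_df, fractions=frac_df, undefined_samples=undefined)


def attribution_probability(
    exposures: pd.Series | np.ndarray,
    catalog: SignatureCatalog,
    channel: str | int,
) -> pd.Series:
    """Probability each signature caused a mutation of the given channel.

    ``exposures`` is one sample's exposure vector over the catalog signatures
    (raw or fractional; the scale cancels). Raises if no active signature can
    produce the channel (zero denominator), rather than returning zeros.
    """
    if isinstance(exposures, pd.Series):
        c = exposures.reindex(catalog.signatures).values.astype(float)
    else:
        c = np.asarray(exposures, dtype=float)
        if c.shape[0] != len(catalog.signatures):
            raise ValueError("exposure vector length does not match catalog")
    k = channel if isinstance(channel, int) else list(CHANNEL_LABELS).index(channel)
    w = catalog.values[:, k]
    num = c * w
    denom = num.sum()
    if denom <= 0:
        raise ZeroDivisionError(
            "no active signature assigns weight to this channel; attribution undefined"
        )
    return pd.Series(num / denom, index=catalog.signatures)


def compare_signature_levels(
    values_by_group: dict[str, pd.DataFrame], group_a: str, group_b: str
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of signature levels between groups.

    One test per signature (columns of the group frames), Bonferroni-adjusted
    across signatures. Uses the exact null distribution for small tie-free
    samples.
    """
    a, b = values_by_group[group_a], values_by_group[group_b]
    if a.shape[0] == 0 or b.shape[0] == 0:
        logger.warning("compare_signature_levels: empty group, skipping")
        return pd.DataFrame(columns=["signature", "p", "p_adj"])
    rows = []
    for sig in a.columns:
        x, y = a[sig].values, b[sig].values
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append({"signature": sig, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].values, method="bonferroni")[1]
    return out
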