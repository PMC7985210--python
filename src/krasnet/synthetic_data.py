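"""Synthetic cohorts, mutation matrices, and dependency screens.

These generators emulate the statistical structure of the multi-consortium
inputs the analysis expects — signature-mixed trinucleotide spectra with
lognormal per-sample burdens, binary gene x sample mutation matrices with
planted co-occurrence or exclusivity, and CERES-like dependency screens with
allele-driven, comutation-driven, and expression-confounded effects — so the
whole pipeline runs and can be validated without any data download. Each
generator emits a ground-truth record sufficient to score the corresponding
pipeline stage, and is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_prediction import per_sample_allele_probability
from .codon_spectrum import (
    CHANNEL_LABELS,
    CHANNELS,
    MutationRecord,
    build_kras_allele_map,
)
from .dependency_screen import LineMetadata
from .signatures import SignatureCatalog

DEFAULT_CANDIDATE_ALLELES = (
    "G12A", "G12C", "G12D", "G12R", "G12S", "G12V", "G13D", "Q61H", "Q61L", "A146T",
)


def random_sparse_catalog(
    n_signatures: int, seed: int = 0, concentration: float = 0.08
) -> SignatureCatalog:
    """Random sparse signatures: Dirichlet draws concentrated on few channels."""
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(96, concentration), size=n_signatures)
    return SignatureCatalog.from_array(w)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic tumor cohort.

    Defaults emulate a whole-exome cohort: a handful of sparse mutational
    processes mixed per sample through a Dirichlet prior, lognormal mutation
    burdens with median ~100 SNVs, half of samples acquiring a KRAS hotspot
    allele, and no selection bias (the pure mutational-process null) unless
    ``allele_bias`` multipliers are supplied.
    """

    n_samples: int = 200
    catalog: SignatureCatalog | None = None
    n_signatures: int = 4
    dirichlet_alpha: float | Sequence[float] = 0.8
    burden_log_mean: float = np.log(100.0)
    burden_log_sigma: float = 0.6
    hypermutant_weight: float = 0.0
    hypermutant_log_shift: float = np.log(10.0)
    kras_mutant_fraction: float = 0.5
    allele_bias: Mapping[str, float] = field(default_factory=dict)
    candidate_alleles: Sequence[str] = DEFAULT_CANDIDATE_ALLELES
    assay_targeted_fraction: float = 0.0


@dataclass
class CohortTruth:
    """Generator ground truth for one synthetic cohort."""

    spectra: pd.DataFrame
    exposures: pd.DataFrame
    alleles: pd.Series          # sample -> allele label or "WT"
    probabilities: pd.DataFrame  # per-sample null allele probabilities
    catalog: SignatureCatalog
    assay: pd.Series
    hypermutant: pd.Series


def _records_from_spectrum(
    sample_id: str, counts: np.ndarray, rng: np.random.Generator, assay: str
) -> list[MutationRecord]:
    recs = []
    g = 0
    for idx in np.flatnonzero(counts):
        ch = CHANNELS[idx]
        for _ in range(int(counts[idx])):
            recs.append(
                MutationRecord(
                    sample_id=sample_id,
                    gene=f"GENE{rng.integers(1, 5000)}",
                    ref_base=ch.ref_pyrimidine,
                    alt_base=ch.alt_base,
                    five_prime=ch.five_prime,
                    three_prime=ch.three_prime,
                    variant_class="missense",
                    assay=assay,
                )
            )
            g += 1
    return recs


def generate_cohort(
    spec: CohortSpec, seed: int = 0, emit_records: bool = True
) -> tuple[list[MutationRecord], CohortTruth]:
    """Draw a synthetic cohort from the exposure/catalog mixture model.

    Per sample: exposures ~ Dirichlet, burden ~ lognormal (with an optional
    hypermutant component), channel counts ~ Multinomial(burden, exposures @
    catalog). KRAS allele assignment follows the mutational-process null —
    probability proportional to the sample's own causative-channel frequency
    — times any per-allele selection-bias multiplier, restricted to samples
    drawn as KRAS-mutant. With ``emit_records`` the cohort is also
    materialized as MAF-style mutation records (flanks taken from the channel
    on the pyrimidine strand), including the KRAS hotspot SNV itself.
    """
    rng = np.random.default_rng(seed)
    catalog = spec.catalog or random_sparse_catalog(spec.n_signatures, seed=seed + 1)
    S = len(catalog.signatures)
    alpha = (
        np.full(S, float(spec.dirichlet_alpha))
        if np.isscalar(spec.dirichlet_alpha)
        else np.asarray(spec.dirichlet_alpha, dtype=float)
    )
    n = spec.n_samples
    sample_ids = [f"SAMPLE_{i:05d}" for i in range(n)]
    exposures = rng.dirichlet(alpha, size=n)
    burdens = np.exp(rng.normal(spec.burden_log_mean, spec.burden_log_sigma, size=n))
    hyper = rng.random(n) < spec.hypermutant_weight
    burdens[hyper] *= np.exp(spec.hypermutant_log_shift)
    burdens = np.maximum(1, np.round(burdens)).astype(int)
    probs = exposures @ catalog.values  # n x 96
    spectra = np.vstack([rng.multinomial(b, p) for b, p in zip(burdens, probs)])
    spectra_df = pd.DataFrame(spectra, index=sample_ids, columns=list(CHANNEL_LABELS))
    spectra_df.index.name = "sample_id"

    amap = build_kras_allele_map()
    candidates = sorted(spec.candidate_alleles)
    prob_rows = {
        sid: per_sample_allele_probability(spectra_df.loc[sid], amap, candidates)
        for sid in sample_ids
    }
    prob_df = pd.DataFrame.from_dict(prob_rows, orient="index")
    bias = np.array([spec.allele_bias.get(a, 1.0) for a in candidates])
    alleles = pd.Series("WT", index=sample_ids)
    is_mutant = rng.random(n) < spec.kras_mutant_fraction
    for i, sid in enumerate(sample_ids):
        if not is_mutant[i]:
            continue
        p = prob_df.loc[sid].values
        if not np.isfinite(p).all() or np.nansum(p) == 0:
            continue
        p = p * bias
        p = p / p.sum()
        alleles[sid] = candidates[rng.choice(len(candidates), p=p)]

    assay = pd.Series(
        np.where(rng.random(n) < spec.assay_targeted_fraction, "targeted", "WES"),
        index=sample_ids,
    )
    records: list[MutationRecord] = []
    if emit_records:
        for i, sid in enumerate(sample_ids):
            records.extend(_records_from_spectrum(sid, spectra[i], rng, assay[sid]))
            allele = alleles[sid]
            if allele != "WT":
                options = amap[allele]
                # pick the causative substitution in proportion to the sample's
                # channel frequencies, as the null model assumes
                weights = np.array(
                    [spectra_df.loc[sid].iloc[ac.channel.index] + 1e-9 for ac in options]
                )
                ac = options[rng.choice(len(options), p=weights / weights.sum())]
                records.append(
                    MutationRecord(
                        sample_id=sid,
                        gene="KRAS",
                        ref_base=ac.channel.ref_pyrimidine,
                        alt_base=ac.channel.alt_base,
                        five_prime=ac.channel.five_prime,
                        three_prime=ac.channel.three_prime,
                        variant_class="missense",
                        protein_change=allele,
                        assay=assay[sid],
                    )
                )
    truth = CohortTruth(
        spectra=spectra_df,
        exposures=pd.DataFrame(exposures, index=sample_ids, columns=catalog.signatures),
        alleles=alleles,
        probabilities=prob_df,
        catalog=catalog,
        assay=assay,
        hypermutant=pd.Series(hyper, index=sample_ids),
    )
    return records, truth


@dataclass
class InteractionSpec:
    """Study conditions for a synthetic binary mutation matrix.

    Gene mutation probabilities follow a logistic model: per-gene baseline
    logit from the marginal frequency plus a per-sample burden offset, with
    planted (allele, gene, log-odds) interaction terms added for allele
    carriers. Defaults: 1000 samples, 30 genes at 2-20% frequency, moderate
    burden heterogeneity, allele fractions resembling a KRAS-driven cancer.
    """

    n_samples: int = 1000
    gene_freqs: Mapping[str, float] = field(
        default_factory=lambda: {f"G{i:03d}": f for i, f in enumerate(
            np.linspace(0.02, 0.20, 30))}
    )
    burden_sigma: float = 0.5
    allele_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"G12D": 0.15, "G12V": 0.10, "G13D": 0.05, "other": 0.10}
    )
    planted: Sequence[tuple[str, str, float]] = ()
    assay_targeted_fraction: float = 0.0
    # genome-wide burden model (reported alongside the gene matrix; the same
    # per-sample offset drives both, so burden and matrix row sums correlate)
    burden_log_mean: float = np.log(150.0)
    hypermutant_weight: float = 0.0
    hypermutant_log_shift: float = np.log(8.0)


def generate_mutation_matrix(
    spec: InteractionSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series, pd.Series, dict]:
    """Binary mutation matrix with planted comutation/exclusivity effects.

    Returns (matrix, alleles, assay, truth). ``truth`` records the planted
    triples and the per-sample burden offsets.
    """
    rng = np.random.default_rng(seed)
    genes = list(spec.gene_freqs)
    freqs = np.array([spec.gene_freqs[g] for g in genes], dtype=float)
    n = spec.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]

    labels = list(spec.allele_fractions)
    fracs = np.array([spec.allele_fractions[a] for a in labels])
    if fracs.sum() > 1:
        raise ValueError("allele fractions sum to more than 1")
    cum = np.concatenate([[0], np.cumsum(fracs)])
    u = rng.random(n)
    alleles = np.full(n, "WT", dtype=object)
    for k, lab in enumerate(labels):
        alleles[(u >= cum[k]) & (u < cum[k + 1])] = lab
    alleles = pd.Series(alleles, index=sample_ids)

    offsets = rng.normal(0.0, spec.burden_sigma, size=n)
    hyper = rng.random(n) < spec.hypermutant_weight
    offsets = offsets + np.where(hyper, spec.hypermutant_log_shift, 0.0)
    burdens = np.maximum(1, np.round(np.exp(spec.burden_log_mean + offsets))).astype(int)
    base_logit = np.log(freqs / (1 - freqs))
    logit = base_logit[None, :] + offsets[:, None]
    for allele, gene, lo in spec.planted:
        if gene not in genes:
            raise ValueError(f"planted gene {gene} not in gene_freqs")
        j = genes.index(gene)
        logit[:, j] += np.where(alleles.values == allele, lo, 0.0)
    P = 1.0 / (1.0 + np.exp(-logit))
    M = (rng.random((n, len(genes))) < P).astype(int)
    matrix = pd.DataFrame(M, index=sample_ids, columns=genes)
    assay = pd.Series(
        np.where(rng.random(n) < spec.assay_targeted_fraction, "targeted", "WES"),
        index=sample_ids,
    )
    truth = {
        "planted": list(spec.planted),
        "burden_offsets": pd.Series(offsets, index=sample_ids),
        "burdens": pd.Series(burdens, index=sample_ids),
        "hypermutant": pd.Series(hyper, index=sample_ids),
    }
    return matrix, alleles, assay, truth


@dataclass
class ScreenSpec:
    """Study conditions for a synthetic CRISPR dependency screen.

    Defaults: four allele groups of six lines each (mirroring a small cancer
    cell-line panel), 50 genes with mildly essential baselines, Gaussian
    score noise of 0.2, background mutation rate 20%. Planted effects:
    ``allele_effects`` shift a gene's score in one allele group;
    ``mediation_effects`` create a partner gene whose mutations are
    anti-correlated with an allele (reduced comutation) and shift the target
    gene's score; ``expression_confounded`` genes have scores driven by their
    own expression.
    """

    n_genes: int = 50
    lines_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"G12D": 6, "G12V": 6, "G13D": 6, "WT": 6}
    )
    noise_sigma: float = 0.2
    baseline_mean: float = -0.3
    baseline_sd: float = 0.3
    mutation_rate: float = 0.2
    allele_effects: Sequence[tuple[str, str, float]] = ()      # (gene, allele, shift)
    mediation_effects: Sequence[tuple[str, str, str, float]] = ()  # (gene, partner, allele, shift)
    expression_confounded: Sequence[tuple[str, float]] = ()    # (gene, slope)


@dataclass
class ScreenTruth:
    allele_effects: list
    mediation_effects: list
    expression_confounded: list
    baselines: pd.Series


def generate_screen(
    spec: ScreenSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, LineMetadata, ScreenTruth]:
    """Dependency, expression, and mutation matrices plus line metadata."""
    rng = np.random.default_rng(seed)
    genes = [f"DEP{i:03d}" for i in range(spec.n_genes)]
    lines, allele_of = [], {}
    for allele, k in spec.lines_per_group.items():
        for i in range(k):
            lid = f"LINE_{allele}_{i}"
            lines.append(lid)
            allele_of[lid] = allele
    alleles = pd.Series(allele_of)
    n = len(lines)

    baselines = pd.Series(rng.normal(spec.baseline_mean, spec.baseline_sd, len(genes)), index=genes)
    expression = pd.DataFrame(
        rng.normal(3.0, 1.0, size=(n, len(genes))), index=lines, columns=genes
    )
    mut = (rng.random((n, len(genes))) < spec.mutation_rate).astype(int)
    mutation_status = pd.DataFrame(mut, index=lines, columns=genes)

    dep = baselines.values[None, :] + rng.normal(0, spec.noise_sigma, size=(n, len(genes)))
    dep = pd.DataFrame(dep, index=lines, columns=genes)

    for gene, allele, shift in spec.allele_effects:
        dep.loc[alleles == allele, gene] += shift
    for gene, partner, allele, shift in spec.mediation_effects:
        if partner not in mutation_status.columns:
            mutation_status[partner] = 0
        carriers = alleles == allele
        p_mut = np.where(carriers.values, 0.1, 0.7)  # reduced comutation with the allele
        mutation_status[partner] = (rng.random(n) < p_mut).astype(int)
        dep[gene] = dep[gene] + shift * mutation_status[partner].values
    for gene, slope in spec.expression_confounded:
        dep[gene] = dep[gene] + slope * (expression[gene] - expression[gene].mean())

    metadata = LineMetadata(
        kras_allele=alleles,
        activating_mutations=pd.Series(
            [[f"KRAS:{a}"] if a != "WT" else [] for a in alleles], index=lines
        ),
    )
    truth = ScreenTruth(
        allele_effects=list(spec.allele_effects),
        mediation_effects=list(spec.mediation_effects),
        expression_confounded=list(spec.expression_confounded),
        baselines=baselines,
    )
    return dep, expression, mutation_status, metadata, truth
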