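"""End-to-end pipeline on synthetic cohorts: simulate through mediation.

Stages run in order — simulate, spectra, signatures, attribution, allele
prediction, comutation, dependency screen, mediation — with every random
draw derived from the configured seed, and a manifest recording the
configuration checksum and the SHA-256 of every artifact, so a rerun with
the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .allele_prediction import (
    allele_probability_table,
    candidate_alleles,
    predicted_frequency,
    test_observed_vs_predicted,
)
from .codon_spectrum import build_kras_allele_map, build_spectra
from .comutation import (
    BinaryMutationMatrix,
    build_network,
    fit_hypermutant_cutoff,
    increased_comutation,
    reduced_comutation,
)
from .dependency_screen import run_dependency_screen
from .mediation import build_design, fit_mediation
from .signatures import attribution_probability, discover_signatures, fit_exposures
from .synthetic_data import (
    CohortSpec,
    InteractionSpec,
    ScreenSpec,
    generate_cohort,
    generate_mutation_matrix,
    generate_screen,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "spectra",
    "signatures",
    "attribute",
    "predict_alleles",
    "comutation",
    "dependency",
    "mediation",
)


def run_pipeline(
    config: io.RunConfig, outdir: str | Path, skip: set[str] | None = None
) -> dict:
    """Execute every stage on the default synthetic fixture; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    skip = skip or set()
    seed = config.seed
    artifacts: dict[str, Path] = {}

    # --- simulate -----------------------------------------------------------
    if "simulate" not in skip:
        records, truth = generate_cohort(CohortSpec(n_samples=config.n_samples), seed=seed)
        io.write_maf(records, outdir / "cohort.maf.tsv")
        truth.alleles.rename("allele").to_csv(outdir / "truth_alleles.tsv", sep="\t")
        truth.exposures.to_csv(outdir / "truth_exposures.tsv", sep="\t")
        io.write_catalog(truth.catalog, outdir / "truth_catalog.tsv")
        matrix, m_alleles, m_assay, m_truth = generate_mutation_matrix(
            InteractionSpec(
                n_samples=config.n_matrix_samples,
                planted=(("G12D", "G000", 2.5), ("G12D", "G029", -3.0)),
            ),
            seed=seed + 1,
        )
        io.write_mutation_matrix(
            matrix, m_alleles, m_assay, outdir / "mutation_matrix.tsv",
            burdens=m_truth["burdens"],
        )
        dep, expr, mut, meta, s_truth = generate_screen(
            ScreenSpec(
                lines_per_group={a: config.n_lines_per_group for a in ("G12D", "G12V", "G13D", "WT")},
                allele_effects=(("DEP000", "G12D", -1.0),),
                mediation_effects=(("DEP001", "PARTNER1", "G12D", -1.0),),
                expression_confounded=(("DEP002", 0.9),),
            ),
            seed=seed + 2,
        )
        dep.rename_axis("line").to_csv(outdir / "dependency.csv")
        expr.rename_axis("line").to_csv(outdir / "expression.csv")
        mut.rename_axis("line").to_csv(outdir / "line_mutations.csv")
        meta.kras_allele.rename("kras_allele").to_csv(outdir / "line_metadata.tsv", sep="\t")
        for f in ("cohort.maf.tsv", "truth_alleles.tsv", "truth_exposures.tsv",
                  "truth_catalog.tsv", "mutation_matrix.tsv", "dependency.csv",
                  "expression.csv", "line_mutations.csv", "line_metadata.tsv"):
            artifacts[f] = outdir / f

    # --- spectra ------------------------------------------------------------
    records = io.read_maf(outdir / "cohort.maf.tsv")
    # the sample's own KRAS hotspot SNV is excluded from its genome-wide spectrum
    spectra = build_spectra([r for r in records if r.gene != "KRAS"])
    io.write_spectra(spectra, outdir / "spectra.tsv")
    artifacts["spectra.tsv"] = outdir / "spectra.tsv"

    # --- signatures ---------------------------------------------------------
    if "signatures" not in skip:
        lo, hi = config.nmf_k_range
        catalog, report = discover_signatures(
            spectra, range(lo, hi + 1), n_restarts=config.nmf_restarts, seed=seed + 3
        )
        if config.signature_exclusions:
            keep = [s for s in catalog.signatures if s not in config.signature_exclusions]
            catalog = type(catalog)(catalog.weights.loc[keep])
        io.write_catalog(catalog, outdir / "signatures.tsv")
        (outdir / "model_selection.json").write_text(
            json.dumps(
                {
                    "chosen_k": report.chosen_k,
                    "silhouette": report.silhouette,
                    "frobenius": report.frobenius,
                    "dropped": report.dropped_signatures,
                },
                indent=2, sort_keys=True,
            )
        )
        exposures = fit_exposures(spectra, catalog, config.signature_allowlist)
        exposures.fractions.to_csv(outdir / "exposures.tsv", sep="\t")
        artifacts["signatures.tsv"] = outdir / "signatures.tsv"
        artifacts["exposures.tsv"] = outdir / "exposures.tsv"

    # --- attribution --------------------------------------------------------
    catalog = io.read_catalog(outdir / "signatures.tsv")
    exposures = pd.read_csv(outdir / "exposures.tsv", sep="\t", index_col=0)
    alleles = pd.read_csv(outdir / "truth_alleles.tsv", sep="\t", index_col=0)["allele"]
    amap = build_kras_allele_map()
    rows = []
    for sid, allele in alleles.items():
        if allele == "WT" or sid not in exposures.index:
            continue
        exp_vec = exposures.loc[sid]
        if not np.isfinite(exp_vec.values).all():
            continue
        for ac in amap[allele]:
            try:
                p = attribution_probability(exp_vec, catalog, ac.channel.label)
            except ZeroDivisionError:
                continue
            rows.append({"sample_id": sid, "allele": allele, "channel": ac.channel.label,
                         **p.to_dict()})
    pd.DataFrame(rows).to_csv(outdir / "attribution.tsv", sep="\t", index=False)
    artifacts["attribution.tsv"] = outdir / "attribution.tsv"

    # --- allele prediction --------------------------------------------------
    observed = alleles[alleles != "WT"].value_counts().to_dict()
    candidates = candidate_alleles(observed, config.candidate_allele_threshold)
    probs = allele_probability_table(spectra, amap, candidates)
    pred = predicted_frequency(probs, n_boot=config.n_boot, seed=seed + 4)
    tests = test_observed_vs_predicted(observed, pred["predicted"])
    result = pred.join(tests.drop(columns=["predicted"]))
    result.rename_axis("allele").to_csv(outdir / "allele_prediction.tsv", sep="\t")
    artifacts["allele_prediction.tsv"] = outdir / "allele_prediction.tsv"

    # --- comutation ---------------------------------------------------------
    matrix, m_alleles, m_assay, m_burdens = io.read_mutation_matrix(outdir / "mutation_matrix.tsv")
    bmm = BinaryMutationMatrix(matrix, m_alleles, m_assay)
    if config.exclude_hypermutants:
        # genome-wide burden when provided; gene-matrix row sums otherwise
        burden_src = m_burdens if m_burdens is not None else bmm.burdens
        cutoff = fit_hypermutant_cutoff(burden_src, seed=seed + 5)
        keep = bmm.matrix.index.difference(cutoff.flagged)
        if len(cutoff.flagged) and len(keep) >= 20:
            bmm = bmm.subset(keep)
    interactions = []
    for allele in sorted(set(bmm.alleles) - {"WT", "other"}):
        interactions += increased_comutation(
            bmm, allele,
            min_gene_freq=config.fisher_min_gene_freq,
            min_events=config.fisher_min_events,
            min_comut_freq=config.fisher_min_comut_freq,
            p_threshold=config.comutation_p_threshold,
            genes=config.gene_allowlist,
        )
        interactions += reduced_comutation(
            bmm, allele,
            n_perm=config.n_perm, seed=seed + 6,
            min_gene_freq=config.exclusivity_min_gene_freq,
            min_exclusive=config.exclusivity_min_events,
            p_threshold=config.comutation_p_threshold,
            genes=config.gene_allowlist,
            burn_in=config.perm_burn_in, thin=config.perm_thin,
        )
    network = build_network(
        interactions, config.curated_gene_sets,
        fdr_threshold=config.gene_set_fdr, p_threshold=config.comutation_p_threshold,
    )
    network.to_csv(outdir / "comutation_network.tsv", sep="\t", index=False)
    artifacts["comutation_network.tsv"] = outdir / "comutation_network.tsv"

    # --- dependency screen --------------------------------------------------
    dep = pd.read_csv(outdir / "dependency.csv", index_col=0)
    expr = pd.read_csv(outdir / "expression.csv", index_col=0)
    mut = pd.read_csv(outdir / "line_mutations.csv", index_col=0)
    line_alleles = pd.read_csv(outdir / "line_metadata.tsv", sep="\t", index_col=0)["kras_allele"]
    from .dependency_screen import LineMetadata

    meta = LineMetadata(
        kras_allele=line_alleles,
        activating_mutations=pd.Series(
            [[f"KRAS:{a}"] if a != "WT" else [] for a in line_alleles], index=line_alleles.index
        ),
    )
    hits, groups = run_dependency_screen(
        dep, meta, expression=expr, mutation_status=mut,
        anova_threshold=config.anova_p_threshold, t_fdr_threshold=config.t_fdr_threshold,
    )
    hit_rows = [
        {"gene": h.gene, "anova_p": h.anova_p, "cluster": h.cluster,
         **{f"t_p_adj_{g}": p for g, p in h.group_p_adj.items()}}
        for h in hits
    ]
    pd.DataFrame(hit_rows).to_csv(outdir / "dependency_hits.tsv", sep="\t", index=False)
    artifacts["dependency_hits.tsv"] = outdir / "dependency_hits.tsv"

    # --- mediation ----------------------------------------------------------
    med_rows = []
    reduced_partners = network.loc[network["direction"] == "reduced"]
    for h in hits:
        for allele in groups:
            if allele == "WT":
                continue
            partners = list(reduced_partners.loc[reduced_partners["allele"] == allele, "gene"])
            partners += [c for c in mut.columns if c.startswith("PARTNER")]
            if not partners:
                continue
            try:
                design = build_design(
                    h.gene, allele, partners,
                    dependency=dep[h.gene], expression=expr.get(h.gene),
                    mutation_status=mut, allele_labels=line_alleles,
                )
                fit = fit_mediation(design, seed=seed + 7)
            except ValueError:
                continue
            for cov, coef in fit.coefficients.items():
                med_rows.append({"target_gene": h.gene, "allele": allele, "covariate": cov,
                                 "coefficient": coef, "alpha": fit.alpha, "seed": fit.seed})
    pd.DataFrame(
        med_rows, columns=["target_gene", "allele", "covariate", "coefficient", "alpha", "seed"]
    ).to_csv(outdir / "mediation.tsv", sep="\t", index=False)
    artifacts["mediation.tsv"] = outdir / "mediation.tsv"

    manifest = {
        "config_checksum": config.checksum(),
        "seed": seed,
        "checksums": {name: io.sha256_of(p) for name, p in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
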