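"""Readers and writers for the interchange formats, and run configuration.

Formats: MAF-dialect mutation TSV (required columns Tumor_Sample_Barcode,
Hugo_Symbol, Reference_Allele, Tumor_Seq_Allele2, Variant_Classification;
optional ref_context carrying the trinucleotide context and assay carrying
WES/WGS/targeted), COSMIC-v2-style signature catalog TSV (first column the
channel label, one column per signature), spectra/matrix TSVs, and a YAML
run configuration holding every analysis threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .codon_spectrum import BASES, CHANNEL_LABELS, MutationRecord
from .signatures import SignatureCatalog

logger = logging.getLogger(__name__)

MAF_REQUIRED_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
)

_VARIANT_CLASS_MAP = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "silent": "silent",
    "splice_site": "splice",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
}


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def _context_flanks(ctx: str) -> tuple[str, str]:
    """5'/3' flanking bases from an odd-length context string centered on the variant."""
    ctx = ctx.strip().upper()
    if len(ctx) >= 3 and len(ctx) % 2 == 1:
        mid = len(ctx) // 2
        return ctx[mid - 1], ctx[mid + 1]
    return "N", "N"


def read_maf(path: str | Path, strict: bool = False) -> list[MutationRecord]:
    """Read a MAF-dialect TSV into mutation records.

    Malformed rows (ref == alt, non-DNA alleles) are skipped and counted in
    lenient mode; ``strict=True`` raises on the first malformed row. A
    missing required column raises :class:`FormatError` naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in MAF_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"MAF file {path} is missing required column {col!r}")
    records = []
    n_bad = 0
    for _, row in df.iterrows():
        ref = str(row["Reference_Allele"]).upper()
        alt = str(row["Tumor_Seq_Allele2"]).upper()
        vclass = _VARIANT_CLASS_MAP.get(
            str(row["Variant_Classification"]).lower(), str(row["Variant_Classification"]).lower()
        )
        snv_like = ref in BASES and alt in BASES
        if snv_like and ref == alt:
            if strict:
                raise FormatError(f"row with Reference_Allele == Tumor_Seq_Allele2 ({ref})")
            n_bad += 1
            continue
        five, three = _context_flanks(str(row.get("ref_context", "") or ""))
        records.append(
            MutationRecord(
                sample_id=str(row["Tumor_Sample_Barcode"]),
                gene=str(row["Hugo_Symbol"]),
                ref_base=ref if snv_like else ref,
                alt_base=alt,
                five_prime=five,
                three_prime=three,
                variant_class=vclass,
                protein_change=(str(row["Protein_Change"]) if "Protein_Change" in df.columns
                                and pd.notna(row.get("Protein_Change")) else None),
                assay=str(row.get("assay", "WES") or "WES"),
            )
        )
    if n_bad:
        logger.warning("read_maf: skipped %d malformed rows", n_bad)
    return records


def write_maf(records: list[MutationRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "Tumor_Sample_Barcode": r.sample_id,
                "Hugo_Symbol": r.gene,
                "Reference_Allele": r.ref_base,
                "Tumor_Seq_Allele2": r.alt_base,
                "Variant_Classification": {
                    "missense": "Missense_Mutation",
                    "nonsense": "Nonsense_Mutation",
                    "silent": "Silent",
                    "splice": "Splice_Site",
                    "frameshift": "Frame_Shift_Del",
                }.get(r.variant_class, r.variant_class),
                "ref_context": f"{r.five_prime}{r.ref_base}{r.three_prime}",
                "Protein_Change": r.protein_change or "",
                "assay": r.assay,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_spectra(spectra: pd.DataFrame, path: str | Path) -> None:
    spectra.to_csv(path, sep="\t")


def read_spectra(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(CHANNEL_LABELS):
        raise FormatError("spectra columns do not match the 96-channel ordering")
    return df


def write_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    """COSMIC-v2-style layout: first column channel label, one column per signature."""
    catalog.weights.T.rename_axis("Type").to_csv(path, sep="\t")


def read_catalog(path: str | Path) -> SignatureCatalog:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if set(df.index) != set(CHANNEL_LABELS):
        raise FormatError("catalog rows do not cover the 96 channels")
    return SignatureCatalog(df.T[list(CHANNEL_LABELS)])


def write_mutation_matrix(
    matrix: pd.DataFrame,
    alleles: pd.Series,
    assay: pd.Series,
    path: str | Path,
    burdens: pd.Series | None = None,
) -> None:
    out = matrix.copy()
    out.insert(0, "kras_allele", alleles.reindex(matrix.index))
    out.insert(1, "assay", assay.reindex(matrix.index))
    if burdens is not None:
        out.insert(2, "burden", burdens.reindex(matrix.index))
    out.rename_axis("sample_id").to_csv(path, sep="\t")


def read_mutation_matrix(
    path: str | Path,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series | None]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("kras_allele", "assay"):
        if col not in df.columns:
            raise FormatError(f"mutation-matrix file missing column {col!r}")
    alleles = df.pop("kras_allele")
    assay = df.pop("assay")
    burdens = df.pop("burden") if "burden" in df.columns else None
    return df.astype(int), alleles, assay, burdens


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: threshold fields that a configuration file must state explicitly
REQUIRED_THRESHOLDS = (
    "candidate_allele_threshold",
    "fisher_min_gene_freq",
    "fisher_min_events",
    "fisher_min_comut_freq",
    "exclusivity_min_gene_freq",
    "exclusivity_min_events",
    "comutation_p_threshold",
    "gene_set_fdr",
    "anova_p_threshold",
    "t_fdr_threshold",
    "expression_filter_p",
    "expression_filter_r2",
)


@dataclass
class RunConfig:
    """All thresholds, counts, and seeds for a pipeline run.

    Defaults are the analysis' canonical values: 3% candidate-allele cutoff;
    increased-comutation filters of 1% gene frequency and 3 events or 10%
    comutation frequency; reduced-comutation filters of 2% gene frequency and
    10 exclusive events; p < 0.01 for comutation edges with FDR 0.25 on
    curated gene sets; ANOVA p < 0.01 and t-test FDR 0.05 for dependencies;
    expression filter p < 0.05 with R^2 >= 0.4.
    """

    cancer: str = "SYNTH"
    seed: int = 0
    candidate_allele_threshold: float = 0.03
    fisher_min_gene_freq: float = 0.01
    fisher_min_events: int = 3
    fisher_min_comut_freq: float = 0.10
    exclusivity_min_gene_freq: float = 0.02
    exclusivity_min_events: int = 10
    comutation_p_threshold: float = 0.01
    gene_set_fdr: float = 0.25
    anova_p_threshold: float = 0.01
    t_fdr_threshold: float = 0.05
    expression_filter_p: float = 0.05
    expression_filter_r2: float = 0.4
    # desk-scale permutation sizing for the end-to-end synthetic fixture; the
    # rc-exclusivity primitive itself defaults to 10,000 draws with full
    # thinning when called directly
    n_boot: int = 10_000
    n_perm: int = 2_000
    perm_burn_in: int | None = None
    perm_thin: int | None = 200
    nmf_k_range: tuple[int, int] = (2, 5)
    nmf_restarts: int = 5
    signature_exclusions: list[str] = field(default_factory=list)
    signature_allowlist: list[str] | None = None
    curated_gene_sets: dict[str, list[str]] = field(default_factory=dict)
    gene_allowlist: list[str] | None = None
    exclude_hypermutants: bool = True
    # synthetic fixture sizes for the end-to-end pipeline
    n_samples: int = 200
    n_matrix_samples: int = 600
    n_lines_per_group: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a configuration file; every threshold must be present."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown configuration fields: {sorted(unknown)}")
        missing = [k for k in REQUIRED_THRESHOLDS if k not in data]
        if missing:
            raise FormatError(f"configuration missing required threshold(s): {missing}")
        if "nmf_k_range" in data:
            data["nmf_k_range"] = tuple(data["nmf_k_range"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["nmf_k_range"] = list(d["nmf_k_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def checksum(self) -> str:
        return hashlib.sha256(repr(sorted(dataclasses.asdict(self).items())).encode()).hexdigest()
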