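"""Trinucleotide substitution channels, hotspot codon enumeration, and spectra.

Single-base substitutions are classified into the standard 96 pyrimidine-
collapsed channels: six substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 16 combinations of 5' and 3' flanking bases. Substitutions
reported on the purine strand are reverse-complemented before classification,
so channel identity is strand-invariant.

The module also packages short coding-strand sequence windows around the four
KRAS hotspot codons (12, 13, 61, 146) so that every hotspot missense allele
can be mapped to its causative channel(s) without a reference genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SNV_CLASSES = frozenset(
    {"missense", "nonsense", "silent", "splice", "missense_mutation",
     "nonsense_mutation", "silent_mutation", "splice_site"}
)


def _check_base(b: str, what: str = "base") -> str:
    if b not in BASES:
        raise ValueError(f"invalid {what} {b!r}: must be one of {BASES}")
    return b


@dataclass(frozen=True)
class SpectrumChannel:
    """One of the 96 pyrimidine-collapsed trinucleotide substitution classes."""

    ref_pyrimidine: str
    alt_base: str
    five_prime: str
    three_prime: str

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.ref_pyrimidine}>{self.alt_base}]{self.three_prime}"

    @property
    def index(self) -> int:
        return CHANNEL_INDEX[self.label]


def _all_channels() -> list[SpectrumChannel]:
    # Fixed ordering: lexicographic by (ref pyrimidine, alt, 5', 3'), C before T.
    out = []
    for ref in PYRIMIDINES:
        for alt in BASES:
            if alt == ref:
                continue
            for five in BASES:
                for three in BASES:
                    out.append(SpectrumChannel(ref, alt, five, three))
    return out


CHANNELS: tuple[SpectrumChannel, ...] = tuple(_all_channels())
CHANNEL_LABELS: tuple[str, ...] = tuple(c.label for c in CHANNELS)
CHANNEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}
N_CHANNELS = len(CHANNELS)


def classify_channel(ref: str, alt: str, five_prime: str, three_prime: str) -> SpectrumChannel:
    """Classify a substitution-in-context into its pyrimidine-collapsed channel.

    If ``ref`` is a purine the substitution and its flanks are reverse-
    complemented first, so ``classify_channel`` applied to either strand of
    the same event yields the same channel.
    """
    for b, what in ((ref, "ref"), (alt, "alt"), (five_prime, "5' flank"), (three_prime, "3' flank")):
        _check_base(b, what)
    if ref == alt:
        raise ValueError(f"ref and alt are both {ref!r}")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five_prime, three_prime = COMPLEMENT[three_prime], COMPLEMENT[five_prime]
    return CHANNELS[CHANNEL_INDEX[f"{five_prime}[{ref}>{alt}]{three_prime}"]]


@dataclass(frozen=True)
class Codon:
    """A coding-strand codon with its position in the protein."""

    bases: str
    position_label: int

    def __post_init__(self) -> None:
        if len(self.bases) != 3 or any(b not in BASES for b in self.bases):
            raise ValueError(f"invalid codon {self.bases!r}")

    @property
    def amino_acid(self) -> str:
        return str(Seq(self.bases).translate())


@dataclass(frozen=True)
class CodonSubstitution:
    """A single-nucleotide change within a codon and its protein consequence."""

    codon_pos: int  # 1..3
    ref_base: str
    alt_base: str
    aa_ref: str
    aa_alt: str
    allele_label: str

    @property
    def is_synonymous(self) -> bool:
        return self.aa_ref == self.aa_alt

    @property
    def is_nonsense(self) -> bool:
        return self.aa_alt == "*" and self.aa_ref != "*"

    @property
    def is_missense(self) -> bool:
        return not (self.is_synonymous or self.is_nonsense)


def enumerate_codon_substitutions(codon: Codon) -> list[CodonSubstitution]:
    """All nine single-nucleotide substitutions of a codon, translated.

    Synonymous and nonsense changes are included and flagged via the
    ``is_synonymous`` / ``is_nonsense`` properties.
    """
    aa_ref = codon.amino_acid
    subs = []
    for pos in range(3):
        ref = codon.bases[pos]
        for alt in BASES:
            if alt == ref:
                continue
            mutated = codon.bases[:pos] + alt + codon.bases[pos + 1 :]
            aa_alt = str(Seq(mutated).translate())
            subs.append(
                CodonSubstitution(
                    codon_pos=pos + 1,
                    ref_base=ref,
                    alt_base=alt,
                    aa_ref=aa_ref,
                    aa_alt=aa_alt,
                    allele_label=f"{aa_ref}{codon.position_label}{aa_alt}",
                )
            )
    return subs


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant with its trinucleotide context."""

    sample_id: str
    gene: str
    ref_base: str
    alt_base: str
    five_prime: str
    three_prime: str
    variant_class: str = "missense"
    protein_change: str | None = None
    assay: str = "WES"

    @property
    def is_snv(self) -> bool:
        return (
            self.ref_base in BASES
            and self.alt_base in BASES
            and self.ref_base != self.alt_base
            and self.variant_class.lower() in SNV_CLASSES
        )


def build_spectra(
    records: Iterable[MutationRecord], sample_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-sample 96-channel mutation spectra.

    Returns a samples x 96 integer DataFrame whose columns are the channel
    labels in catalog order. Records that are not classifiable SNVs (indels,
    dinucleotide changes, missing flanks) are skipped; the skip count is
    logged. Total counts equal the number of classified SNVs per sample.
    """
    counts: dict[str, list[int]] = {}
    n_skipped = 0
    for rec in records:
        if not rec.is_snv or rec.five_prime not in BASES or rec.three_prime not in BASES:
            n_skipped += 1
            continue
        ch = classify_channel(rec.ref_base, rec.alt_base, rec.five_prime, rec.three_prime)
        row = counts.setdefault(rec.sample_id, [0] * N_CHANNELS)
        row[ch.index] += 1
    if n_skipped:
        logger.info("build_spectra: skipped %d non-SNV/unclassifiable records", n_skipped)
    if sample_ids is None:
        sample_ids = list(counts)
    data = {sid: counts.get(sid, [0] * N_CHANNELS) for sid in sample_ids}
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(CHANNEL_LABELS))
    df.index.name = "sample_id"
    return df.astype(int)


# ---------------------------------------------------------------------------
# KRAS hotspot machinery.
#
# KRAS is transcribed from the reverse genomic strand; the windows below are
# coding-strand sequence (5 codons each, hotspots in the middle), taken from
# the KRAS CDS (codons 10-14, 59-63, and 144-148). Pyrimidine collapsing makes
# the resulting channel identities strand-invariant, so no genome lookup is
# needed.
# ---------------------------------------------------------------------------

#: coding-strand windows: first codon number -> 15-nt sequence
KRAS_CODING_WINDOWS: dict[int, str] = {
    10: "GGAGCTGGTGGCGTA",   # G10 A11 G12 G13 V14
    59: "GCAGGTCAAGAGGAG",   # A59 G60 Q61 E62 E63
    144: "ACATCAGCAAAAACA",  # T144 S145 A146 K147 T148
}

KRAS_HOTSPOT_CODONS = (12, 13, 61, 146)


def kras_codon(position_label: int) -> tuple[Codon, str, str]:
    """A KRAS codon plus its immediate 5' and 3' neighboring bases."""
    for start, window in KRAS_CODING_WINDOWS.items():
        if start <= position_label <= start + 4:
            off = 3 * (position_label - start)
            if off == 0 or off + 3 >= len(window):
                continue  # need one flanking base on each side
            return Codon(window[off : off + 3], position_label), window[off - 1], window[off + 3]
    raise KeyError(f"codon {position_label} not inside a packaged KRAS window")


@dataclass(frozen=True)
class AlleleChannel:
    """One causative (channel, substitution) pair for a hotspot allele."""

    channel: SpectrumChannel
    substitution: CodonSubstitution
    codon: int


@dataclass
class KrasAlleleMap:
    """Map from hotspot missense allele label to its causative channel(s)."""

    channels: dict[str, list[AlleleChannel]] = field(default_factory=dict)

    def __getitem__(self, allele: str) -> list[AlleleChannel]:
        return self.channels[allele]

    def __contains__(self, allele: str) -> bool:
        return allele in self.channels

    @property
    def alleles(self) -> list[str]:
        return sorted(self.channels)

    def channel_indices(self, allele: str) -> list[int]:
        return [ac.channel.index for ac in self.channels[allele]]


def build_kras_allele_map(include_nonsense: bool = False) -> KrasAlleleMap:
    """Enumerate every hotspot allele reachable by one substitution.

    Alleles reachable through more than one distinct nucleotide change
    (e.g., Q61H via CAA>CAC or CAA>CAT) map to multiple channels.
    """
    amap = KrasAlleleMap()
    for codon_num in KRAS_HOTSPOT_CODONS:
        codon, five_nb, three_nb = kras_codon(codon_num)
        context = five_nb + codon.bases + three_nb
        for sub in enumerate_codon_substitutions(codon):
            if sub.is_synonymous or (sub.is_nonsense and not include_nonsense):
                continue
            i = sub.codon_pos  # 1..3 -> offset 1..3 within context
            ch = classify_channel(sub.ref_base, sub.alt_base, context[i - 1], context[i + 1])
            amap.channels.setdefault(sub.allele_label, []).append(
                AlleleChannel(channel=ch, substitution=sub, codon=codon_num)
            )
    return amap
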