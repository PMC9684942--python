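"""Strand-specific intersection of line-specific SNVs with PAS footprints
and classification of the consequence for the signal.

A variant inside a 6-bp PAS footprint rewrites the sense-strand hexamer.
The outcome is classified against the ranked motif inventory:

* ``LOSS``      — the rewritten hexamer is no recognised PAS motif;
* ``MA_TO_LA``  — it is a motif of worse (larger) rank: more-abundant to
  less-abundant signal;
* ``LA_TO_MA``  — it is a motif of better (smaller) rank;
* ``RANK_TIE``  — distinct motifs of identical abundance (never produced by
  the packaged default table, whose counts strictly decrease).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple, Optional

from .atlas import ApaSite, PasSignal, classify_site_type
from .genome import GeneModel, GenomeSequence
from .motifs import MotifTable, revcomp
from .variants import LineVariantSet, Variant

__all__ = [
    "Consequence",
    "PasSnpRecord",
    "PasHit",
    "overlap_pas",
    "alt_hexamer",
    "classify_consequence",
    "annotate_line",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class Consequence(str, Enum):
    LOSS = "LOSS"
    MA_TO_LA = "MA_TO_LA"
    LA_TO_MA = "LA_TO_MA"
    RANK_TIE = "RANK_TIE"

    @property
    def label(self) -> str:
        """Rendering used in report tables."""
        return {
            Consequence.LOSS: "Loss",
            Consequence.MA_TO_LA: "MA → LA motif",
            Consequence.LA_TO_MA: "LA → MA motif",
            Consequence.RANK_TIE: "Rank tie",
        }[self]

    @classmethod
    def from_label(cls, label: str) -> "Consequence":
        for member in cls:
            if member.label == label or member.value == label:
                return member
        raise ValueError(f"unknown consequence label: {label!r}")


class PasHit(NamedTuple):
    """One SNV landing inside one PAS footprint."""

    variant: Variant
    site: ApaSite
    signal: PasSignal
    offset: int  # 0..5 within the sense hexamer


@dataclass(frozen=True)
class PasSnpRecord:
    """One variant x signal consequence row (the report-table unit)."""

    line_label: str
    variant: Variant
    site_id: str
    gene_id: Optional[str]
    gene_symbol: Optional[str]
    site_type: str
    signal: PasSignal
    offset: int
    ref_hexamer: str
    alt_hexamer: str
    consequence: Consequence

    def __post_init__(self) -> None:
        if not 0 <= self.offset <= 5:
            raise ValueError(f"offset outside hexamer: {self.offset}")
        if self.ref_hexamer == self.alt_hexamer:
            raise ValueError("variant does not change the hexamer")


def overlap_pas(
    variants: LineVariantSet | Iterable[Variant],
    sites: Iterable[ApaSite],
) -> list[PasHit]:
    """Intersect SNVs with PAS footprints, strand-aware.

    A hit is emitted for every SNV whose genomic position lies inside a
    signal footprint; overlapping footprints each yield their own hit.
    The offset is the variant's position within the *sense* hexamer:
    ``pos - footprint_start`` on plus-strand signals and
    ``footprint_end - pos`` on minus-strand signals.
    """
    by_chrom: dict[str, list[tuple[ApaSite, PasSignal]]] = {}
    for site in sites:
        for signal in site.signals:
            by_chrom.setdefault(site.chrom, []).append((site, signal))

    hits: list[PasHit] = []
    for variant in variants:
        if not variant.is_snv:
            continue
        for site, signal in by_chrom.get(variant.chrom, []):
            if signal.footprint_start <= variant.pos <= signal.footprint_end:
                if signal.strand == "+":
                    offset = variant.pos - signal.footprint_start
                else:
                    offset = signal.footprint_end - variant.pos
                hits.append(PasHit(variant, site, signal, offset))
    return hits


def alt_hexamer(hit: PasHit, genome: GenomeSequence) -> tuple[str, str]:
    """Reference and alternative sense hexamers for a footprint hit.

    The reference hexamer is the signal's sense-strand hexamer; the
    alternative substitutes the variant's alt base at the hit offset —
    complemented for minus-strand signals, since VCF alleles are plus
    strand.  The genome, the atlas hexamer and the VCF ref must agree.
    """
    variant, signal = hit.variant, hit.signal
    genome_base = genome.base(hit.site.chrom, variant.pos)
    if genome_base != variant.ref_allele:
        raise ValueError(
            f"reference mismatch at {hit.site.chrom}:{variant.pos}: "
            f"genome has {genome_base}, VCF says {variant.ref_allele}"
        )
    signal.check_against_genome(genome, hit.site.chrom)
    ref_hex = signal.hexamer
    base = variant.alt_allele if signal.strand == "+" else _COMPLEMENT[variant.alt_allele]
    alt_hex = ref_hex[: hit.offset] + base + ref_hex[hit.offset + 1 :]
    return ref_hex, alt_hex


def classify_consequence(
    ref_hexamer: str,
    alt_hexamer: str,
    table: MotifTable,
) -> Consequence:
    """Classify a hexamer substitution against the ranked motif inventory."""
    ref_rank = table.rank_of(ref_hexamer)
    if ref_rank is None:
        raise ValueError(f"reference hexamer {ref_hexamer} is not in the motif table")
    if ref_hexamer == alt_hexamer:
        raise ValueError("reference and alternative hexamers are identical")
    alt_rank = table.rank_of(alt_hexamer)
    if alt_rank is None:
        return Consequence.LOSS
    # equal abundance between distinct motifs is a genuine tie even though
    # the lexicographic rank order is deterministic
    if table.count_of(ref_hexamer) == table.count_of(alt_hexamer):
        return Consequence.RANK_TIE
    if alt_rank < ref_rank:
        return Consequence.LA_TO_MA
    return Consequence.MA_TO_LA


def annotate_line(
    variants: LineVariantSet,
    atlas_sites: Iterable[ApaSite],
    table: MotifTable,
    models: Iterable[GeneModel],
    genome: GenomeSequence,
) -> list[PasSnpRecord]:
    """Full per-line annotation: overlap, hexamer rewrite, classification.

    Expects genic-filtered atlas sites (gene ids resolved).  Output is
    sorted by (chrom, pos, site_id) and deterministic.
    """
    models = list(models)
    records: list[PasSnpRecord] = []
    for hit in overlap_pas(variants, atlas_sites):
        ref_hex, alt_hex = alt_hexamer(hit, genome)
        consequence = classify_consequence(ref_hex, alt_hex, table)
        site_type = classify_site_type(hit.site, models)
        records.append(
            PasSnpRecord(
                line_label=variants.line_label,
                variant=hit.variant,
                site_id=hit.site.site_id,
                gene_id=hit.site.gene_id,
                gene_symbol=hit.site.gene_symbol,
                site_type=site_type,
                signal=hit.signal,
                offset=hit.offset,
                ref_hexamer=ref_hex,
                alt_hexamer=alt_hex,
                consequence=consequence,
            )
        )
    records.sort(key=lambda r: (r.variant.chrom, r.variant.pos, r.site_id,
                                r.signal.footprint_start))
    return records
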