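"""Region context around an APA site: residual and de-novo PAS signals.

For a disrupted signal, the question that decides how severe the hit is:
does the window covering the APA cluster plus 60 bp upstream (gene 5')
still contain usable signals after the line's variants are applied, does a
canonical AATAAA/ATTAAA survive, and did any variant create a signal where
none was before?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .atlas import ApaSite
from .annotate import PasSnpRecord
from .genome import GenomeSequence
from .motifs import MotifTable, revcomp
from .variants import Variant

__all__ = [
    "SignalOccurrence",
    "RegionContext",
    "build_window",
    "apply_variants_to_window",
    "enumerate_signals",
    "context_for_record",
    "DEFAULT_UPSTREAM_WINDOW",
]

DEFAULT_UPSTREAM_WINDOW = 60

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class SignalOccurrence:
    """A motif-table hexamer found in a window's sense sequence."""

    hexamer: str
    start: int  # 0-based offset within the sense window sequence
    rank: int


@dataclass
class RegionContext:
    """Signals in an APA site's window before and after a line's variants."""

    site_id: str
    window_start: int
    window_end: int
    reference_signals: list[SignalOccurrence]
    surviving_signals: list[SignalOccurrence]
    de_novo_signals: list[SignalOccurrence]
    top_rank_disrupted: bool
    canonical_remaining: bool


def build_window(
    site: ApaSite,
    genome: Optional[GenomeSequence] = None,
    upstream: int = DEFAULT_UPSTREAM_WINDOW,
) -> tuple[int, int]:
    """Genomic interval covering the cluster plus ``upstream`` nt gene-5'.

    Upstream is strand-aware: left of the cluster for plus-strand sites,
    right of it for minus-strand sites.  Clamped to chromosome bounds when
    a genome is supplied.
    """
    if upstream < 0:
        raise ValueError("upstream must be >= 0")
    if site.strand == "+":
        start, end = site.cluster_start - upstream, site.cluster_end
    else:
        start, end = site.cluster_start, site.cluster_end + upstream
    if genome is not None:
        start = max(1, start)
        end = min(genome.length(site.chrom), end)
    return start, end


def apply_variants_to_window(
    genome: GenomeSequence,
    chrom: str,
    window: tuple[int, int],
    strand: str,
    variants: Iterable[Variant],
) -> str:
    """Sense-strand window sequence with SNVs substituted.

    All variants must be SNVs inside the window, at distinct positions,
    with ref alleles matching the genome.
    """
    start, end = window
    bases = list(genome.fetch(chrom, start, end))
    seen: set[int] = set()
    for variant in variants:
        if not variant.is_snv:
            raise ValueError(f"not an SNV: {variant.key}")
        if not start <= variant.pos <= end:
            raise ValueError(f"variant {variant.key} outside window [{start}, {end}]")
        if variant.pos in seen:
            raise ValueError(f"colliding variants at {chrom}:{variant.pos}")
        seen.add(variant.pos)
        idx = variant.pos - start
        if bases[idx] != variant.ref_allele:
            raise ValueError(
                f"reference mismatch at {chrom}:{variant.pos}: "
                f"genome has {bases[idx]}, variant says {variant.ref_allele}"
            )
        bases[idx] = variant.alt_allele
    seq = "".join(bases)
    return seq if strand == "+" else revcomp(seq)


def enumerate_signals(seq: str, table: MotifTable) -> list[SignalOccurrence]:
    """All motif-table hexamer occurrences in a sense sequence, 5'->3'.

    Overlapping occurrences are all reported.
    """
    seq = seq.upper()
    out: list[SignalOccurrence] = []
    for i in range(len(seq) - 5):
        hexamer = seq[i : i + 6]
        rank = table.rank_of(hexamer) if set(hexamer) <= set("ACGT") else None
        if rank is not None:
            out.append(SignalOccurrence(hexamer, i, rank))
    return out


def _sense_offset(record: PasSnpRecord, site: ApaSite, window: tuple[int, int]) -> int:
    """0-based offset of the record's signal footprint in the sense window."""
    start, end = window
    if site.strand == "+":
        return record.signal.footprint_start - start
    return end - record.signal.footprint_end


def context_for_record(
    record: PasSnpRecord,
    site: ApaSite,
    genome: GenomeSequence,
    line_variants: Iterable[Variant],
    table: MotifTable,
    upstream: int = DEFAULT_UPSTREAM_WINDOW,
) -> RegionContext:
    """Residual/de-novo signal context for one PAS-SNP record.

    ``top_rank_disrupted``: the disrupted signal was the best-ranked
    occurrence in the reference window and nothing equally good survives.
    ``canonical_remaining``: an AATAAA or ATTAAA occurrence other than the
    disrupted footprint survives the line's variants.  De-novo signals are
    (offset, hexamer) pairs present only after variant application.
    """
    if record.site_id != site.site_id:
        raise ValueError(
            f"record {record.site_id} does not belong to site {site.site_id}"
        )
    window = build_window(site, genome, upstream)
    start, end = window
    in_window = [
        v for v in line_variants if v.chrom == site.chrom and start <= v.pos <= end
    ]
    ref_seq = apply_variants_to_window(genome, site.chrom, window, site.strand, [])
    alt_seq = apply_variants_to_window(genome, site.chrom, window, site.strand, in_window)

    reference = enumerate_signals(ref_seq, table)
    surviving = enumerate_signals(alt_seq, table)
    ref_keys = {(o.start, o.hexamer) for o in reference}
    de_novo = [o for o in surviving if (o.start, o.hexamer) not in ref_keys]

    focal_offset = _sense_offset(record, site, window)
    focal_rank = table.rank_of(record.ref_hexamer)
    best_ref = min((o.rank for o in reference), default=None)
    top_rank_disrupted = (
        focal_rank is not None
        and best_ref is not None
        and focal_rank == best_ref
        and all(o.rank > focal_rank for o in surviving)
    )
    canonical_remaining = any(
        o.hexamer in ("AATAAA", "ATTAAA") and o.start != focal_offset
        for o in surviving
    )
    return RegionContext(
        site_id=site.site_id,
        window_start=start,
        window_end=end,
        reference_signals=reference,
        surviving_signals=surviving,
        de_novo_signals=de_novo,
        top_rank_disrupted=top_rank_disrupted,
        canonical_remaining=canonical_remaining,
    )
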