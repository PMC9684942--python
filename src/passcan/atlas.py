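"""APA atlas parsing and PAS-signal footprint resolution.

An APA *site* is a cluster of closely spaced observed cleavage positions,
represented by one id ``chrom:pos:strand`` where ``pos`` is the most used
cleavage coordinate.  Each site may carry one or more PAS *signal*
footprints — 6-bp genomic intervals whose sense-strand sequence is a
recognised PAS hexamer lying upstream (gene 5') of the cleavage position.

Two dialects are read: a PolyASite-2.0-style BED (0-based half-open
clusters) and an internal TSV (1-based inclusive, signals inline as
``HEXAMER@footprint_start``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

from .genome import GenomeSequence, GeneModel, classify_position, gene_at
from .motifs import MotifTable, revcomp

__all__ = [
    "PasSignal",
    "ApaSite",
    "read_atlas",
    "write_atlas",
    "scan_signal_footprints",
    "filter_genic",
    "classify_site_type",
    "DEFAULT_SIGNAL_WINDOW",
]

DEFAULT_SIGNAL_WINDOW = 40

INTERNAL_COLUMNS = [
    "chrom",
    "cleavage_pos",
    "strand",
    "cluster_start",
    "cluster_end",
    "gene_id",
    "site_type",
    "usage",
    "signals",
]


@dataclass(frozen=True)
class PasSignal:
    """A 6-bp PAS footprint: sense-strand hexamer + leftmost genomic coord."""

    hexamer: str
    footprint_start: int  # 1-based leftmost genomic coordinate
    strand: str

    @property
    def footprint_end(self) -> int:
        return self.footprint_start + 5

    def genomic_span(self) -> tuple[int, int]:
        return self.footprint_start, self.footprint_end

    def check_against_genome(self, genome: GenomeSequence, chrom: str) -> None:
        """Assert the genome slice under the footprint spells the hexamer."""
        plus = genome.fetch(chrom, self.footprint_start, self.footprint_end)
        expected = self.hexamer if self.strand == "+" else revcomp(self.hexamer)
        if plus != expected:
            raise ValueError(
                f"signal {self.hexamer}@{chrom}:{self.footprint_start}:{self.strand} "
                f"disagrees with genome slice {plus}"
            )


@dataclass
class ApaSite:
    """One APA cluster with representative cleavage site and PAS signals."""

    chrom: str
    cleavage_pos: int
    strand: str
    cluster_start: int
    cluster_end: int
    gene_id: Optional[str] = None
    gene_symbol: Optional[str] = None
    site_type: Optional[str] = None
    usage_fraction: Optional[float] = None
    signals: list[PasSignal] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand: {self.strand!r}")
        if not (self.cluster_start <= self.cleavage_pos <= self.cluster_end):
            raise ValueError(
                f"cleavage position {self.cleavage_pos} outside cluster "
                f"[{self.cluster_start}, {self.cluster_end}]"
            )

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.cleavage_pos}:{self.strand}"

    @staticmethod
    def parse_site_id(site_id: str) -> tuple[str, int, str]:
        chrom, pos, strand = site_id.rsplit(":", 2)
        return chrom, int(pos), strand


def _parse_signals(text: str, strand: str) -> list[PasSignal]:
    signals = []
    if text and text != "NA":
        for token in text.split(";"):
            hexamer, _, start = token.partition("@")
            signals.append(PasSignal(hexamer.upper(), int(start), strand))
    return signals


def _format_signals(signals: Iterable[PasSignal]) -> str:
    text = ";".join(f"{s.hexamer}@{s.footprint_start}" for s in signals)
    return text or "NA"


def read_atlas(
    path: str | Path,
    dialect: Literal["polyasite_bed", "internal_tsv"] = "internal_tsv",
) -> list[ApaSite]:
    """Read an APA atlas into 1-based ApaSite records.

    ``polyasite_bed``: tab-separated, 0-based half-open cluster interval,
    name field ``chrom:cleavage_pos:strand``, score column = usage, then
    strand and optional annotation columns (fraction, protocols, site type,
    gene id, signals).  ``internal_tsv``: the package's own 1-based dialect
    (see INTERNAL_COLUMNS), ``#`` comments allowed.
    """
    path = Path(path)
    sites: list[ApaSite] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            try:
                if dialect == "internal_tsv":
                    site = _parse_internal_row(row)
                elif dialect == "polyasite_bed":
                    site = _parse_polyasite_row(row)
                else:
                    raise ValueError(f"unknown atlas dialect: {dialect}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            sites.append(site)
    return sites


def _opt(value: str) -> Optional[str]:
    return None if value in ("", "NA", ".") else value


def _parse_internal_row(row: list[str]) -> ApaSite:
    if len(row) != len(INTERNAL_COLUMNS):
        raise ValueError(f"expected {len(INTERNAL_COLUMNS)} columns, got {len(row)}")
    chrom, cleavage, strand, cstart, cend, gene, stype, usage, signals = row
    return ApaSite(
        chrom=chrom,
        cleavage_pos=int(cleavage),
        strand=strand,
        cluster_start=int(cstart),
        cluster_end=int(cend),
        gene_id=_opt(gene),
        site_type=_opt(stype),
        usage_fraction=float(usage) if _opt(usage) else None,
        signals=_parse_signals(signals, strand),
    )


def _parse_polyasite_row(row: list[str]) -> ApaSite:
    if len(row) < 6:
        raise ValueError(f"expected >= 6 BED columns, got {len(row)}")
    chrom, bed_start, bed_end, name, score, strand = row[:6]
    start0, end0 = int(bed_start), int(bed_end)
    if end0 <= start0:
        raise ValueError(f"BED end {end0} <= start {start0}")
    _, cleavage, name_strand = ApaSite.parse_site_id(name)
    if strand not in "+-":
        raise ValueError(f"bad strand: {strand!r}")
    site_type = _opt(row[8]) if len(row) > 8 else None
    gene_id = _opt(row[9]) if len(row) > 9 else None
    signals = _parse_signals(row[10], strand) if len(row) > 10 else []
    try:
        usage = float(score)
    except ValueError as exc:
        raise ValueError(f"unparsable usage/score: {score!r}") from exc
    return ApaSite(
        chrom=chrom,
        cleavage_pos=cleavage,
        strand=strand,
        cluster_start=start0 + 1,  # BED 0-based half-open -> 1-based inclusive
        cluster_end=end0,
        gene_id=gene_id,
        site_type=site_type,
        usage_fraction=usage,
        signals=signals,
    )


def write_atlas(sites: Iterable[ApaSite], path: str | Path) -> None:
    """Write sites in the internal TSV dialect (read_atlas round-trips)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([f"#{INTERNAL_COLUMNS[0]}"] + INTERNAL_COLUMNS[1:])
        for site in sites:
            writer.writerow(
                [
                    site.chrom,
                    site.cleavage_pos,
                    site.strand,
                    site.cluster_start,
                    site.cluster_end,
                    site.gene_id or "NA",
                    site.site_type or "NA",
                    "NA" if site.usage_fraction is None else site.usage_fraction,
                    _format_signals(site.signals),
                ]
            )


def scan_signal_footprints(
    site: ApaSite,
    genome: GenomeSequence,
    table: MotifTable,
    max_upstream: int = DEFAULT_SIGNAL_WINDOW,
) -> list[PasSignal]:
    """Find PAS hexamer footprints upstream of a site's cleavage position.

    Scans the sense strand for motif-table hexamers whose footprint *ends*
    between 1 and ``max_upstream`` nt 5' of the cleavage position, returned
    in 5'->3' sense order.  Used when the atlas carries no signal
    annotations (or to rescan against a different genome/table).
    """
    n = genome.length(site.chrom)
    if site.strand == "+":
        win_start = site.cleavage_pos - max_upstream - 5
        win_end = site.cleavage_pos - 1
        if win_start < 1 or win_end > n:
            raise ValueError(
                f"scan window [{win_start}, {win_end}] exceeds {site.chrom} bounds"
            )
        seq = genome.fetch(site.chrom, win_start, win_end)
    else:
        win_start = site.cleavage_pos + 1
        win_end = site.cleavage_pos + max_upstream + 5
        if win_start < 1 or win_end > n:
            raise ValueError(
                f"scan window [{win_start}, {win_end}] exceeds {site.chrom} bounds"
            )
        seq = revcomp(genome.fetch(site.chrom, win_start, win_end))

    signals: list[PasSignal] = []
    for i in range(len(seq) - 5):
        hexamer = seq[i : i + 6]
        if hexamer not in table:
            continue
        if site.strand == "+":
            footprint_start = win_start + i
            distance = site.cleavage_pos - (footprint_start + 5)
        else:
            footprint_start = win_end - i - 5
            distance = footprint_start - site.cleavage_pos
        if 1 <= distance <= max_upstream:
            signals.append(PasSignal(hexamer, footprint_start, site.strand))
    return signals


def filter_genic(
    sites: Iterable[ApaSite],
    models: Iterable[GeneModel],
    strand_matched: bool = True,
) -> list[ApaSite]:
    """Keep sites whose cleavage position lies inside a gene span.

    Gene matching is strand-specific by default; with ``strand_matched``
    off, antisense overlap also qualifies.  Returned sites carry the
    matched ``gene_id``/``gene_symbol``.
    """
    models = list(models)
    kept: list[ApaSite] = []
    for site in sites:
        model = gene_at(models, site.chrom, site.cleavage_pos, site.strand, strand_matched)
        if model is None:
            continue
        kept.append(replace(site, gene_id=model.gene_id, gene_symbol=model.symbol))
    return kept


def classify_site_type(site: ApaSite, models: Iterable[GeneModel]) -> str:
    """Site type (TE/IN/...): atlas annotation wins, else positional call."""
    if site.gene_id is None:
        raise ValueError(f"site {site.site_id} is not genic")
    if site.site_type is not None:
        return site.site_type
    return classify_position(models, site.chrom, site.cleavage_pos, site.strand)
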