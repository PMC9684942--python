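"""Reference sequence access and gene models with region classification.

Coordinates are 1-based inclusive throughout (VCF/GTF convention); BED-style
inputs are converted at the parsing boundary, never downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "read_genome",
    "read_gene_models",
    "classify_position",
    "TERMINAL_EXON",
    "INTRONIC",
    "OTHER_EXONIC",
    "INTERGENIC",
]

TERMINAL_EXON = "TE"
INTRONIC = "IN"
OTHER_EXONIC = "other-exonic"
INTERGENIC = "intergenic"

RegionLabel = Literal["TE", "IN", "other-exonic", "intergenic"]


class GenomeSequence:
    """Per-chromosome uppercase sequences with strict 1-based slicing."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome: {chrom}")
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` on the 1-based inclusive interval [start, end]."""
        n = self.length(chrom)
        if not (1 <= start <= end <= n):
            raise ValueError(
                f"interval [{start}, {end}] out of range for {chrom} (length {n})"
            )
        return self._seqs[chrom][start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


def read_genome(path: str | Path) -> GenomeSequence:
    """Read a (multi-)FASTA into memory, case-folded to uppercase.

    Records are keyed by the first whitespace-delimited header token;
    duplicate headers and empty files are rejected.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in seqs:
            raise ValueError(f"duplicate FASTA header: {name}")
        seqs[name] = str(record.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(seqs)


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts, each a sorted list of exons.

    Exons are (start, end) 1-based inclusive, non-overlapping and sorted in
    genomic order within each transcript.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: tuple[tuple[tuple[int, int], ...], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand for {self.gene_id}: {self.strand!r}")
        for exons in self.transcripts:
            prev_end = 0
            for (s, e) in exons:
                if e < s:
                    raise ValueError(f"{self.gene_id}: exon end {e} < start {s}")
                if s <= prev_end:
                    raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
                if s < self.start or e > self.end:
                    raise ValueError(f"{self.gene_id}: exon outside gene span")
                prev_end = e

    def terminal_exon(self, exons: tuple[tuple[int, int], ...]) -> tuple[int, int]:
        """3'-most exon of a transcript, strand-aware."""
        return exons[-1] if self.strand == "+" else exons[0]

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GTF or GFF3 via gffutils (in-memory db).

    Transcripts are assembled from ``exon`` features; gene span is the hull
    of its exons unless a gene feature is present.  ``gene_name`` falls back
    to ``gene_id`` when absent.
    """
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # surface parse failures with file context
        raise ValueError(f"cannot parse gene models from {path}: {exc}") from exc

    # exon -> transcript -> gene assembly
    per_gene: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gene_ids = exon.attributes.get("gene_id")
        tx_ids = exon.attributes.get("transcript_id")
        if not gene_ids or not tx_ids:
            raise ValueError(
                f"{path}: exon at {exon.seqid}:{exon.start}-{exon.end} lacks "
                "gene_id/transcript_id attribution"
            )
        if exon.end < exon.start:
            raise ValueError(f"{path}: exon end < start at {exon.seqid}:{exon.start}")
        gid, tid = gene_ids[0], tx_ids[0]
        info = per_gene.setdefault(
            gid,
            {
                "chrom": exon.seqid,
                "strand": exon.strand,
                "symbol": (exon.attributes.get("gene_name") or [gid])[0],
                "tx": {},
            },
        )
        info["tx"].setdefault(tid, []).append((exon.start, exon.end))

    models: list[GeneModel] = []
    for gid, info in per_gene.items():
        transcripts = tuple(
            tuple(sorted(exons)) for exons in info["tx"].values()
        )
        all_exons = [iv for exons in transcripts for iv in exons]
        start = min(s for s, _ in all_exons)
        end = max(e for _, e in all_exons)
        # prefer an explicit gene feature (span, gene_name) when annotated
        try:
            gene_feat = db[gid]
        except Exception:
            gene_feat = None
        if gene_feat is not None:
            start = min(start, gene_feat.start)
            end = max(end, gene_feat.end)
            names = gene_feat.attributes.get("gene_name")
            if names:
                info["symbol"] = names[0]
        models.append(
            GeneModel(
                gene_id=gid,
                symbol=info["symbol"],
                chrom=info["chrom"],
                strand=info["strand"],
                start=start,
                end=end,
                transcripts=transcripts,
            )
        )
    if not models:
        raise ValueError(f"no exon features found in {path}")
    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return models


def classify_position(
    models: Iterable[GeneModel],
    chrom: str,
    pos: int,
    strand: str,
    strand_matched: bool = True,
) -> RegionLabel:
    """Classify a genomic position relative to gene models.

    Returns ``TE`` when the position lies in the 3'-most exon of any
    (strand-matching) transcript, ``other-exonic`` for a non-terminal exon,
    ``IN`` for a position inside a gene span but in no exon, and
    ``intergenic`` otherwise.  TE takes precedence across transcripts.
    """
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    label: RegionLabel = INTERGENIC
    for model in models:
        if model.chrom != chrom or not model.contains(pos):
            continue
        if strand_matched and model.strand != strand:
            continue
        gene_label: RegionLabel = INTRONIC
        for exons in model.transcripts:
            term = model.terminal_exon(exons)
            for (s, e) in exons:
                if s <= pos <= e:
                    if (s, e) == term:
                        return TERMINAL_EXON
                    gene_label = OTHER_EXONIC
        if label == INTERGENIC or gene_label == OTHER_EXONIC:
            label = gene_label
    return label


def gene_at(
    models: Iterable[GeneModel],
    chrom: str,
    pos: int,
    strand: str,
    strand_matched: bool = True,
) -> Optional[GeneModel]:
    """First gene model whose span contains ``pos`` (strand-matched by default)."""
    for model in models:
        if model.chrom != chrom or not model.contains(pos):
            continue
        if strand_matched and model.strand != strand:
            continue
        return model
    return None
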