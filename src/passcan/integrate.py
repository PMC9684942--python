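"""Gene-set intersection, differential-expression filtering and candidate
prioritisation.

Candidates are PAS-SNPs whose gene is differentially expressed between the
lines (>= 1.5-fold, p < 0.05 in at least one tissue) and whose consequence
weakens the signal (loss, or change to a less abundant motif).  Severity
then reflects the region context: destroying the strongest signal of the
window with nothing equally good left is HIGH; a surviving canonical
AATAAA/ATTAAA demotes the hit to LOW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotate import Consequence, PasSnpRecord
from .context import RegionContext

__all__ = [
    "GeneSet",
    "ExpressionRecord",
    "DegCall",
    "PriorityCandidate",
    "read_gene_set",
    "read_expression",
    "intersect_records",
    "common_genes",
    "deg_filter",
    "prioritise",
    "record_key",
    "load_pas_catalogue",
    "load_expression_catalogue",
    "summarise_catalogue",
]

DEFAULT_FOLD = 1.5
DEFAULT_P = 0.05

EXPRESSION_COLUMNS = ["probe_id", "gene_symbol", "tissue", "fold_change", "p_value"]


@dataclass
class GeneSet:
    """Named set of gene symbols, matched case-insensitively."""

    name: str
    symbols: set[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        self._folded = {s.casefold() for s in self.symbols}

    def __contains__(self, symbol: Optional[str]) -> bool:
        return symbol is not None and symbol.casefold() in self._folded

    def __len__(self) -> int:
        return len(self._folded)


@dataclass(frozen=True)
class ExpressionRecord:
    """One probe x tissue measurement: Fat/Lean fold change and p value."""

    probe_id: str
    gene_symbol: str
    tissue: str
    fold_change: float  # Fat / Lean ratio, > 0
    p_value: float
    adj_p: Optional[float] = None
    chrom: Optional[str] = None
    probe_start: Optional[int] = None
    probe_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"fold change must be > 0: {self.fold_change}")
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class DegCall:
    gene_symbol: str
    tissue: str
    direction: str  # "UP" | "DOWN" (Fat relative to Lean)
    fold_change: float
    p_value: float


@dataclass
class PriorityCandidate:
    record: PasSnpRecord
    context: RegionContext
    deg_evidence: list[DegCall]
    severity: str  # "HIGH" | "MODERATE" | "LOW"
    predicted_effect: str  # "UTR_LENGTH_CHANGE" | "CODING_TRUNCATION_CHANGE"

    def __post_init__(self) -> None:
        if not self.deg_evidence:
            raise ValueError("candidate requires differential-expression evidence")


def read_gene_set(path: str | Path, name: str) -> GeneSet:
    """Read a one-symbol-per-line TSV (``#`` comments allowed)."""
    symbols: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols.add(line.split("\t")[0])
    if not symbols:
        raise ValueError(f"gene set file {path} is empty")
    return GeneSet(name, symbols)


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """Read a probe-level expression TSV.

    Columns: ``probe_id gene_symbol tissue fold_change p_value`` with
    optional ``adj_p`` and probe coordinates ``chrom start end``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing expression columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        adj_p = getattr(row, "adj_p", None)
        records.append(
            ExpressionRecord(
                probe_id=str(row.probe_id),
                gene_symbol=str(row.gene_symbol),
                tissue=str(row.tissue),
                fold_change=float(row.fold_change),
                p_value=float(row.p_value),
                adj_p=None if adj_p is None or pd.isna(adj_p) else float(adj_p),
                chrom=str(row.chrom) if hasattr(row, "chrom") else None,
                probe_start=int(row.start) if hasattr(row, "start") else None,
                probe_end=int(row.end) if hasattr(row, "end") else None,
            )
        )
    return records


def intersect_records(
    records: Sequence[PasSnpRecord],
    gene_set: GeneSet,
) -> tuple[list[PasSnpRecord], int, int]:
    """Records whose gene is in the set, plus distinct SNP and gene counts."""
    hits = [r for r in records if r.gene_symbol in gene_set]
    n_snps = len({r.variant.key for r in hits})
    n_genes = len({(r.gene_symbol or "").casefold() for r in hits})
    return hits, n_snps, n_genes


def common_genes(
    fat_records: Sequence[PasSnpRecord],
    lean_records: Sequence[PasSnpRecord],
) -> list[tuple[str, set[str], set[str], bool]]:
    """Genes carrying PAS-SNPs in both lines.

    Returns (gene symbol, fat site ids, lean site ids, sites_differ) where
    ``sites_differ`` means the two lines hit disjoint APA sites.
    """
    def by_gene(records: Sequence[PasSnpRecord]) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in records:
            if r.gene_symbol:
                out.setdefault(r.gene_symbol, set()).add(r.site_id)
        return out

    fat, lean = by_gene(fat_records), by_gene(lean_records)
    shared = sorted(set(fat) & set(lean))
    return [
        (gene, fat[gene], lean[gene], fat[gene].isdisjoint(lean[gene]))
        for gene in shared
    ]


def deg_filter(
    expression: Iterable[ExpressionRecord],
    fold: float = DEFAULT_FOLD,
    p: float = DEFAULT_P,
    use_adjusted: bool = False,
) -> list[DegCall]:
    """Differential-expression calls: fold inclusive, p exclusive.

    A probe passes when max(fc, 1/fc) >= ``fold`` and its (adjusted, if
    requested) p value is < ``p``.  Direction is Fat relative to Lean.
    """
    if fold <= 0 or p <= 0:
        raise ValueError("thresholds must be positive")
    calls: list[DegCall] = []
    for rec in expression:
        pval = rec.adj_p if use_adjusted else rec.p_value
        if pval is None:
            continue
        if max(rec.fold_change, 1.0 / rec.fold_change) >= fold and pval < p:
            calls.append(
                DegCall(
                    gene_symbol=rec.gene_symbol,
                    tissue=rec.tissue,
                    direction="UP" if rec.fold_change > 1 else "DOWN",
                    fold_change=rec.fold_change,
                    p_value=pval,
                )
            )
    return calls


_SEVERITY_ORDER = {"HIGH": 0, "MODERATE": 1, "LOW": 2}
_WEAKENING = (Consequence.LOSS, Consequence.MA_TO_LA)


def _severity(context: RegionContext) -> str:
    if context.top_rank_disrupted:
        return "HIGH"
    return "LOW" if context.canonical_remaining else "MODERATE"


def prioritise(
    records: Sequence[PasSnpRecord],
    contexts: dict[str, RegionContext] | Sequence[RegionContext],
    degs: Iterable[DegCall],
    probe_coords: Optional[dict[str, tuple[str, int, int]]] = None,
) -> list[PriorityCandidate]:
    """Rank PAS-SNPs by disruption severity and expression evidence.

    A record becomes a candidate iff its gene is differentially expressed
    in at least one tissue and its consequence weakens the signal (LOSS or
    MA_TO_LA).  Severity: HIGH when the window's top-ranked signal was
    destroyed with nothing equally strong left; LOW when a canonical
    AATAAA/ATTAAA survives; MODERATE otherwise.  Predicted effect follows
    the site type: terminal-exon sites change 3' UTR length, intronic
    sites the coding potential.  Ordering: severity, then best |log fold
    change|, ties by genomic position.
    """
    if not isinstance(contexts, dict):
        raise TypeError("contexts must be a dict keyed by record_key(record)")
    degs_by_gene: dict[str, list[DegCall]] = {}
    for call in degs:
        degs_by_gene.setdefault(call.gene_symbol.casefold(), []).append(call)

    candidates: list[PriorityCandidate] = []
    for record in records:
        key = record_key(record)
        if key not in contexts:
            raise KeyError(f"missing region context for record {key}")
        if record.consequence not in _WEAKENING:
            continue
        evidence = degs_by_gene.get((record.gene_symbol or "").casefold(), [])
        if not evidence:
            continue
        context = contexts[key]
        candidates.append(
            PriorityCandidate(
                record=record,
                context=context,
                deg_evidence=sorted(
                    evidence, key=lambda c: -abs(math.log(c.fold_change))
                ),
                severity=_severity(context),
                predicted_effect=(
                    "UTR_LENGTH_CHANGE"
                    if record.site_type == "TE"
                    else "CODING_TRUNCATION_CHANGE"
                ),
            )
        )
    candidates.sort(
        key=lambda c: (
            _SEVERITY_ORDER[c.severity],
            -max(abs(math.log(e.fold_change)) for e in c.deg_evidence),
            c.record.variant.chrom,
            c.record.variant.pos,
        )
    )
    return candidates


def record_key(record: PasSnpRecord) -> tuple:
    """Stable identity for pairing a record with its region context."""
    return (
        record.line_label,
        record.variant.key,
        record.site_id,
        record.signal.footprint_start,
    )


# ---------------------------------------------------------------------------
# Catalogue aggregation (published-supplement-shaped tables)

CATALOGUE_COLUMNS = [
    "mouse_line",
    "variant_id",
    "location",
    "gene_symbol",
    "apa_id",
    "type",
    "pas",
    "pas_alt",
    "consequence",
]


def load_pas_catalogue(path: str | Path) -> pd.DataFrame:
    """Load a PAS-SNP catalogue table (TSV or XLSX) into a DataFrame.

    Expected columns are CATALOGUE_COLUMNS — the same schema the pipeline's
    ``pas_snps.tsv`` report uses.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    missing = [c for c in CATALOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: catalogue is missing columns {missing}")
    return df


def load_expression_catalogue(path: str | Path) -> pd.DataFrame:
    """Load a probe-level expression catalogue (TSV or XLSX)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    return df


def summarise_catalogue(
    catalogue: pd.DataFrame,
    gene_sets: Optional[dict[str, GeneSet]] = None,
) -> dict:
    """Aggregate a PAS-SNP catalogue into per-line and gene-set totals."""
    lines = sorted(catalogue["mouse_line"].unique())
    summary: dict = {"per_line": {}, "gene_sets": {}}
    genes_by_line: dict[str, set[str]] = {}
    for line in lines:
        sub = catalogue[catalogue["mouse_line"] == line]
        genes = {str(g).casefold() for g in sub["gene_symbol"].dropna()}
        genes_by_line[line] = genes
        summary["per_line"][line] = {
            "n_pas_snps": int(sub["variant_id"].nunique()),
            "n_genes": len(genes),
        }
    if len(lines) == 2:
        shared = genes_by_line[lines[0]] & genes_by_line[lines[1]]
        summary["n_common_genes"] = len(shared)
        summary["common_genes"] = sorted(shared)
    for name, gs in (gene_sets or {}).items():
        hits = catalogue[
            catalogue["gene_symbol"].map(lambda g: g in gs)
        ]
        summary["gene_sets"][name] = {
            "n_pas_snps": int(hits["variant_id"].nunique()),
            "n_genes": int(hits["gene_symbol"].str.casefold().nunique()),
        }
    return summary
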