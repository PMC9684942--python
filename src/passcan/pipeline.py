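"""End-to-end orchestration: annotate both lines, build region contexts,
integrate gene sets and expression, and write the report tables.

Outputs (tab-separated, UTF-8, ``NA`` for missing):

* ``pas_snps.tsv``        — one row per variant x signal consequence
* ``region_context.tsv``  — window signal counts and severity flags
* ``common_genes.tsv``    — genes with PAS-SNPs in both lines
* ``geneset_hits.tsv``    — per gene set: records whose gene is a member
* ``candidates.tsv``      — prioritised candidates with severity
* ``summary.json``        — headline counts, recomputable from the TSVs
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .atlas import (
    DEFAULT_SIGNAL_WINDOW,
    read_atlas,
    filter_genic,
    scan_signal_footprints,
)
from .annotate import Consequence, PasSnpRecord, annotate_line
from .context import DEFAULT_UPSTREAM_WINDOW, RegionContext, context_for_record
from .genome import read_gene_models, read_genome
from .integrate import (
    DEFAULT_FOLD,
    DEFAULT_P,
    GeneSet,
    common_genes,
    deg_filter,
    intersect_records,
    prioritise,
    read_expression,
    read_gene_set,
    record_key,
)
from .motifs import load_motif_table
from .variants import line_specific, read_variants

__all__ = ["RunConfig", "run_pipeline", "write_pas_table", "read_pas_table"]

logger = logging.getLogger("passcan")

PAS_TABLE_COLUMNS = [
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


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    genome: Path
    gtf: Path
    atlas: Path
    vcf_fat: Path
    vcf_lean: Path
    out_dir: Path
    motif_table: Optional[Path] = None  # packaged default when None
    atlas_dialect: str = "internal_tsv"
    expression: Optional[Path] = None
    gene_sets: dict[str, Path] = field(default_factory=dict)
    signal_window: int = DEFAULT_SIGNAL_WINDOW
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW
    fold: float = DEFAULT_FOLD
    p: float = DEFAULT_P
    use_adjusted: bool = False
    line_rule: str = "presence"
    strand_matched: bool = True
    rescan_signals: bool = False

    def __post_init__(self) -> None:
        for name in ("genome", "gtf", "atlas", "vcf_fat", "vcf_lean"):
            path = Path(getattr(self, name))
            setattr(self, name, path)
            if not path.exists():
                raise FileNotFoundError(f"--{name.replace('_', '-')}: {path}")
        self.out_dir = Path(self.out_dir)
        for value, flag in ((self.signal_window, "signal-window"),
                            (self.upstream_window, "upstream-window"),
                            (self.fold, "fold"), (self.p, "p")):
            if value <= 0:
                raise ValueError(f"--{flag} must be positive")


def record_to_row(record: PasSnpRecord) -> list[str]:
    return [
        record.line_label,
        record.variant.variant_id or "NA",
        f"{record.variant.chrom}:{record.variant.pos}",
        record.gene_symbol or "NA",
        record.site_id,
        record.site_type,
        record.ref_hexamer,
        record.alt_hexamer,
        record.consequence.label,
    ]


def write_pas_table(records: Sequence[PasSnpRecord], path: str | Path) -> None:
    """Write the consequence table in the published column layout."""
    df = pd.DataFrame(
        [record_to_row(r) for r in records], columns=PAS_TABLE_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False)


def read_pas_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PAS_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _log(stage: str, n_in: int, n_out: int) -> None:
    logger.info("%s: %d -> %d", stage, n_in, n_out)


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and write the report bundle; returns the output dir."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    table = load_motif_table(config.motif_table or "mouse-polyasite")
    genome = read_genome(config.genome)
    models = read_gene_models(config.gtf)
    sites = read_atlas(config.atlas, dialect=config.atlas_dialect)
    _log("atlas", len(sites), len(sites))

    if config.rescan_signals or not any(s.signals for s in sites):
        for site in sites:
            site.signals = scan_signal_footprints(
                site, genome, table, config.signal_window
            )
        _log("signal-rescan", len(sites), sum(bool(s.signals) for s in sites))

    genic = filter_genic(sites, models, strand_matched=config.strand_matched)
    _log("genic-filter", len(sites), len(genic))
    site_by_id = {s.site_id: s for s in genic}

    fat_all = read_variants(config.vcf_fat, "Fat")
    lean_all = read_variants(config.vcf_lean, "Lean")
    fat, lean = line_specific(fat_all, lean_all, rule=config.line_rule)
    _log("line-specific", len(fat_all) + len(lean_all), len(fat) + len(lean))

    records: list[PasSnpRecord] = []
    for line_set in (fat, lean):
        line_records = annotate_line(line_set, genic, table, models, genome)
        _log(f"annotate-{line_set.line_label}", len(line_set), len(line_records))
        records.extend(line_records)
    write_pas_table(records, out / "pas_snps.tsv")

    line_variants = {"Fat": list(fat), "Lean": list(lean)}
    contexts: dict[tuple, RegionContext] = {}
    context_rows = []
    for record in records:
        site = site_by_id[record.site_id]
        ctx = context_for_record(
            record, site, genome, line_variants[record.line_label], table,
            upstream=config.upstream_window,
        )
        contexts[record_key(record)] = ctx
        context_rows.append(
            [
                record.line_label,
                record.variant.variant_id or "NA",
                ctx.site_id,
                f"{ctx.window_start}-{ctx.window_end}",
                len(ctx.reference_signals),
                len(ctx.surviving_signals),
                len(ctx.de_novo_signals),
                ctx.top_rank_disrupted,
                ctx.canonical_remaining,
            ]
        )
    pd.DataFrame(
        context_rows,
        columns=[
            "mouse_line", "variant_id", "apa_id", "window",
            "n_reference_signals", "n_surviving_signals", "n_de_novo_signals",
            "top_rank_disrupted", "canonical_remaining",
        ],
    ).to_csv(out / "region_context.tsv", sep="\t", index=False)
    _log("region-context", len(records), len(context_rows))

    fat_records = [r for r in records if r.line_label == "Fat"]
    lean_records = [r for r in records if r.line_label == "Lean"]
    shared = common_genes(fat_records, lean_records)
    pd.DataFrame(
        [
            [gene, ";".join(sorted(fs)), ";".join(sorted(ls)), differ]
            for gene, fs, ls, differ in shared
        ],
        columns=["gene_symbol", "fat_apa_ids", "lean_apa_ids", "sites_differ"],
    ).to_csv(out / "common_genes.tsv", sep="\t", index=False)

    gene_sets: dict[str, GeneSet] = {
        name: read_gene_set(path, name) for name, path in config.gene_sets.items()
    }
    geneset_rows = []
    geneset_counts = {}
    for name, gs in gene_sets.items():
        hits, n_snps, n_genes = intersect_records(records, gs)
        geneset_counts[name] = {"n_pas_snps": n_snps, "n_genes": n_genes}
        geneset_rows += [[name] + record_to_row(r) for r in hits]
    pd.DataFrame(
        geneset_rows, columns=["gene_set"] + PAS_TABLE_COLUMNS
    ).to_csv(out / "geneset_hits.tsv", sep="\t", index=False)

    candidates = []
    degs = []
    if config.expression is not None:
        expression = read_expression(config.expression)
        degs = deg_filter(
            expression, fold=config.fold, p=config.p,
            use_adjusted=config.use_adjusted,
        )
        candidates = prioritise(records, contexts, degs)
        _log("prioritise", len(records), len(candidates))
    pd.DataFrame(
        [
            record_to_row(c.record)
            + [
                c.severity,
                c.predicted_effect,
                c.deg_evidence[0].tissue,
                c.deg_evidence[0].direction,
                c.deg_evidence[0].fold_change,
            ]
            for c in candidates
        ],
        columns=PAS_TABLE_COLUMNS
        + ["severity", "predicted_effect", "tissue", "direction", "fold_change"],
    ).to_csv(out / "candidates.tsv", sep="\t", index=False)

    summary = {
        "pas_snps_per_line": {
            label: len({r.variant.key for r in recs})
            for label, recs in (("Fat", fat_records), ("Lean", lean_records))
        },
        "genes_per_line": {
            label: len({r.gene_symbol for r in recs})
            for label, recs in (("Fat", fat_records), ("Lean", lean_records))
        },
        "n_common_genes": len(shared),
        "gene_set_hits": geneset_counts,
        "n_deg_calls": len(degs),
        "n_deg_candidate_genes": len(
            {c.record.gene_symbol for c in candidates}
        ),
        "n_prioritised_candidates": len(candidates),
        "consequence_counts": {
            c.label: sum(r.consequence is c for r in records) for c in Consequence
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def configure_logging(quiet: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.WARNING if quiet else logging.INFO)
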