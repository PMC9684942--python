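"""Deterministic synthetic input bundles with known ground truth.

No sequencing data are deposited for the Fat/Lean selection lines, so the
pipeline is validated against generated bundles that emulate the study's
inputs: a random genome with genes carrying 1–3 APA clusters each, PAS
hexamers planted ~21 nt (sd 3, truncated to [10, 40]) upstream of cleavage
sites with abundance-weighted motif choice, line-specific SNVs planted
inside and outside signal footprints with known consequence classes, and a
probe-level expression table with planted >= 1.5-fold differences.

The generator is its own oracle: every planted event is recorded in a
truth manifest, and :func:`verify_recovery` scores pipeline output against
it.  The same seed regenerates a byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .atlas import ApaSite, PasSignal, write_atlas
from .annotate import Consequence, PasSnpRecord
from .genome import GenomeSequence
from .motifs import MotifTable, load_motif_table, revcomp
from .variants import LineVariantSet, Variant

__all__ = [
    "SyntheticConfig",
    "PlantedEvent",
    "SyntheticBundle",
    "generate_bundle",
    "verify_recovery",
    "single_base_substitutions",
    "mirror_genome",
    "mirror_site",
    "mirror_variant",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"

LOSS = "LOSS"
MA_TO_LA = "MA_TO_LA"
LA_TO_MA = "LA_TO_MA"
DE_NOVO = "DE_NOVO"
NON_PAS_CONTROL = "NON_PAS_CONTROL"
PAS_CLASSES = (LOSS, MA_TO_LA, LA_TO_MA)

TISSUES = (
    "sWAT", "eWAT", "mWAT", "WAT", "BAT",
    "liver", "muscle", "adrenal gland", "thymus", "kidney",
)

# sense-local gene layout: 5' exon, intron, terminal exon
_EXON1 = (0, 599)
_INTRON = (600, 1799)
_EXON2 = (1800, 2999)
_GENE_LEN = 3000
_GENE_GAP = 500


@dataclass
class SyntheticConfig:
    """Study-condition parameters for a generated bundle."""

    seed: int = 17
    n_chroms: int = 2
    chrom_length: int = 120_000
    signal_distance_mean: float = 21.0
    signal_distance_sd: float = 3.0
    signal_distance_bounds: tuple[int, int] = (10, 40)
    apa_sites_per_gene: tuple[int, int] = (1, 3)
    events_per_line: dict[str, int] = field(
        default_factory=lambda: {
            LOSS: 8, MA_TO_LA: 7, LA_TO_MA: 7, DE_NOVO: 3, NON_PAS_CONTROL: 5,
        }
    )
    n_background_genes: int = 4
    deg_fraction: float = 0.5
    deg_fold_range: tuple[float, float] = (1.5, 3.0)
    line_labels: tuple[str, str] = ("Fat", "Lean")

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.events_per_line.values()):
            raise ValueError("event counts must be >= 0")
        lo, hi = self.signal_distance_bounds
        if not 6 <= lo <= hi:
            raise ValueError("signal distance bounds must satisfy 6 <= lo <= hi")


@dataclass
class PlantedEvent:
    """One ground-truth planted event (variant-level)."""

    line_label: str
    event_class: str
    chrom: str
    pos: int  # 1-based plus-strand variant position
    ref_allele: str
    alt_allele: str
    variant_id: str
    gene_id: str
    gene_symbol: str
    site_id: str
    ref_hexamer: Optional[str] = None
    alt_hexamer: Optional[str] = None
    expected_consequence: Optional[str] = None
    de_novo_hexamer: Optional[str] = None

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class SyntheticBundle:
    """Paths and in-memory truth for one generated bundle."""

    out_dir: Path
    genome_fasta: Path
    gtf: Path
    atlas_tsv: Path
    vcfs: dict[str, Path]
    expression_tsv: Path
    gene_set_tsv: Path
    manifest_jsonl: Path
    events: list[PlantedEvent]
    deg_truth: dict[str, dict]  # gene_id -> {symbol, deg, tissue, fold, p}


def single_base_substitutions(hexamer: str) -> Iterable[tuple[int, str, str]]:
    """All 18 (offset, new_base, new_hexamer) single-base edits."""
    for offset, old in enumerate(hexamer):
        for base in _BASES:
            if base != old:
                yield offset, base, hexamer[:offset] + base + hexamer[offset + 1 :]


def _class_moves(table: MotifTable) -> dict[str, list[tuple[str, int, str, str]]]:
    """Realisable (ref_hexamer, offset, alt_base, alt_hexamer) per class."""
    moves: dict[str, list[tuple[str, int, str, str]]] = {
        LOSS: [], MA_TO_LA: [], LA_TO_MA: [],
    }
    for ref in table.hexamers:
        for offset, base, alt in single_base_substitutions(ref):
            if alt not in table:
                moves[LOSS].append((ref, offset, base, alt))
            elif table.count_of(alt) < table.count_of(ref):
                moves[MA_TO_LA].append((ref, offset, base, alt))
            elif table.count_of(alt) > table.count_of(ref):
                moves[LA_TO_MA].append((ref, offset, base, alt))
    return moves


def _de_novo_moves(table: MotifTable) -> list[tuple[str, int, str, str]]:
    """(pre_image, offset, alt_base, motif): one edit creates a signal."""
    out = []
    for motif in table.hexamers:
        for offset, _base, pre in single_base_substitutions(motif):
            if pre not in table:
                # the edit pre -> motif restores the signal
                out.append((pre, offset, motif[offset], motif))
    return out


class _Layout:
    """Sequential, non-overlapping gene placement across chromosomes."""

    def __init__(self, config: SyntheticConfig):
        self.config = config
        self.cursor = [100] * config.n_chroms  # leave head room on each chrom
        self.next_chrom = 0

    def place_gene(self) -> tuple[str, int]:
        c = self.next_chrom
        attempts = 0
        while self.cursor[c] + _GENE_LEN + 100 > self.config.chrom_length:
            c = (c + 1) % self.config.n_chroms
            attempts += 1
            if attempts > self.config.n_chroms:
                raise ValueError(
                    "chromosomes too short for the configured gene count"
                )
        start = self.cursor[c]
        self.cursor[c] = start + _GENE_LEN + _GENE_GAP
        self.next_chrom = (c + 1) % self.config.n_chroms
        return f"chr{c + 1}", start  # 1-based genomic start


def _trunc_normal_int(rng, mean, sd, lo, hi) -> int:
    while True:
        value = int(round(rng.normal(mean, sd)))
        if lo <= value <= hi:
            return value


@dataclass
class _Gene:
    gene_id: str
    symbol: str
    chrom: str
    start: int  # 1-based genomic start of the 3000 bp span
    strand: str

    @property
    def end(self) -> int:
        return self.start + _GENE_LEN - 1

    def g(self, local: int) -> int:
        """Sense-local coordinate (0-based) -> 1-based genomic position."""
        if self.strand == "+":
            return self.start + local
        return self.end - local

    def exons_genomic(self) -> list[tuple[int, int]]:
        spans = []
        for lo, hi in (_EXON1, _EXON2):
            a, b = self.g(lo), self.g(hi)
            spans.append((min(a, b), max(a, b)))
        return sorted(spans)


def generate_bundle(config: SyntheticConfig, out_dir: str | Path) -> SyntheticBundle:
    """Write a complete input bundle plus truth manifest under ``out_dir``."""
    table = load_motif_table()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    moves = _class_moves(table)
    for cls, count in config.events_per_line.items():
        if cls in PAS_CLASSES and count > 0 and not moves[cls]:
            raise ValueError(f"event class {cls} unachievable for this motif table")
    de_novo_pool = _de_novo_moves(table)

    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = {
        c: rng.integers(0, 4, size=config.chrom_length) for c in chroms
    }

    def write_base(chrom: str, pos: int, base: str) -> None:
        genome[chrom][pos - 1] = _BASES.index(base)

    def read_seq(chrom: str, start: int, end: int) -> str:
        return "".join(_BASES[i] for i in genome[chrom][start - 1 : end])

    def plant_sense(gene: _Gene, local_start: int, sense_seq: str) -> int:
        """Plant a sense-strand sequence at a local offset; return the
        leftmost 1-based genomic coordinate of the planted footprint."""
        if gene.strand == "+":
            left = gene.g(local_start)
            for i, base in enumerate(sense_seq):
                write_base(gene.chrom, left + i, base)
            return left
        right = gene.g(local_start)
        seq = revcomp(sense_seq)
        left = right - len(sense_seq) + 1
        for i, base in enumerate(seq):
            write_base(gene.chrom, left + i, base)
        return left

    layout = _Layout(config)
    genes: list[_Gene] = []
    sites: list[ApaSite] = []
    events: list[PlantedEvent] = []
    variants: dict[str, list[Variant]] = {label: [] for label in config.line_labels}
    abundances = np.array([m.relative_abundance for m in table.motifs])
    abundances = abundances / abundances.sum()
    reserved: dict[str, list[tuple[int, int]]] = {}

    counter = {"gene": 0, "var": 0}

    def new_gene() -> _Gene:
        counter["gene"] += 1
        chrom, start = layout.place_gene()
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"simg{counter['gene']:03d}"
        gene = _Gene(gid, gid.capitalize(), chrom, start, strand)
        genes.append(gene)
        reserved[gid] = []
        return gene

    def add_site(gene: _Gene, kind: str, local_cleavage: int,
                 hexamer: str) -> tuple[ApaSite, PasSignal, int]:
        """Plant a signal for a new APA site; returns site, signal and the
        sense-local coordinate of the hexamer's first base."""
        distance = _trunc_normal_int(
            rng, config.signal_distance_mean, config.signal_distance_sd,
            *config.signal_distance_bounds,
        )
        # footprint occupies sense-local [cleavage-distance-5, cleavage-distance],
        # so its 3' end sits exactly `distance` nt upstream of the cleavage site
        local_hex_start = local_cleavage - distance - 5
        footprint_left = plant_sense(gene, local_hex_start, hexamer)
        signal = PasSignal(hexamer, footprint_left, gene.strand)
        cleavage = gene.g(local_cleavage)
        pad_left = int(rng.integers(0, 6))
        pad_right = int(rng.integers(0, 6))
        site = ApaSite(
            chrom=gene.chrom,
            cleavage_pos=cleavage,
            strand=gene.strand,
            cluster_start=cleavage - pad_left,
            cluster_end=cleavage + pad_right,
            gene_id=gene.gene_id,
            gene_symbol=gene.symbol,
            site_type=kind,
            usage_fraction=round(float(rng.uniform(0.1, 0.9)), 3),
            signals=[signal],
        )
        sites.append(site)
        reserved[gene.gene_id].append((footprint_left, footprint_left + 5))
        return site, signal, local_hex_start

    def add_extra_sites(gene: _Gene, used_kind: str) -> None:
        lo, hi = config.apa_sites_per_gene
        n_extra = int(rng.integers(lo, hi + 1)) - 1
        slots = {"TE": [2750, 2900], "IN": [800, 950]}
        offsets = slots["IN"] if used_kind == "TE" else slots["TE"]
        kind = "IN" if used_kind == "TE" else "TE"
        for k in range(min(n_extra, len(offsets))):
            hexamer = table.hexamers[
                int(rng.choice(len(table.hexamers), p=abundances))
            ]
            add_site(gene, kind, offsets[k], hexamer)

    def new_variant_id(line: str) -> str:
        counter["var"] += 1
        return f"sv{line.lower()}{counter['var']:04d}"

    def add_variant(line: str, chrom: str, pos: int, ref: str, alt: str,
                    vid: str) -> Variant:
        variant = Variant(chrom, pos, ref, alt, variant_id=vid, genotype="hom_alt")
        variants[line].append(variant)
        return variant

    de_novo_budget = {
        label: config.events_per_line.get(DE_NOVO, 0)
        for label in config.line_labels
    }

    for line in config.line_labels:
        for cls in (LOSS, MA_TO_LA, LA_TO_MA):
            for _ in range(config.events_per_line.get(cls, 0)):
                gene = new_gene()
                kind = "TE" if rng.random() < 0.5 else "IN"
                local_cleavage = int(
                    rng.integers(1950, 2850) if kind == "TE"
                    else rng.integers(750, 1650)
                )
                ref_hex, offset, alt_base, alt_hex = moves[cls][
                    int(rng.integers(len(moves[cls])))
                ]
                site, signal, local_hex_start = add_site(
                    gene, kind, local_cleavage, ref_hex
                )
                # variant position: sense offset within the footprint
                pos = (
                    signal.footprint_start + offset
                    if gene.strand == "+"
                    else signal.footprint_end - offset
                )
                genome_ref = read_seq(gene.chrom, pos, pos)
                genome_alt = alt_base if gene.strand == "+" else _COMPLEMENT[alt_base]
                vid = new_variant_id(line)
                add_variant(line, gene.chrom, pos, genome_ref, genome_alt, vid)
                events.append(
                    PlantedEvent(
                        line_label=line,
                        event_class=cls,
                        chrom=gene.chrom,
                        pos=pos,
                        ref_allele=genome_ref,
                        alt_allele=genome_alt,
                        variant_id=vid,
                        gene_id=gene.gene_id,
                        gene_symbol=gene.symbol,
                        site_id=site.site_id,
                        ref_hexamer=ref_hex,
                        alt_hexamer=alt_hex,
                        expected_consequence=cls,
                    )
                )
                # optionally co-plant a de-novo pre-image in the same window
                if cls == LOSS and de_novo_budget[line] > 0:
                    de_novo_budget[line] -= 1
                    pre, d_offset, d_base, motif = de_novo_pool[
                        int(rng.integers(len(de_novo_pool)))
                    ]
                    local_pre_start = local_hex_start - 12  # clear of the signal
                    plant_sense(gene, local_pre_start, pre)
                    d_pos = (
                        gene.g(local_pre_start) + d_offset
                        if gene.strand == "+"
                        else gene.g(local_pre_start) - d_offset
                    )
                    d_ref = read_seq(gene.chrom, d_pos, d_pos)
                    d_alt = d_base if gene.strand == "+" else _COMPLEMENT[d_base]
                    d_vid = new_variant_id(line)
                    add_variant(line, gene.chrom, d_pos, d_ref, d_alt, d_vid)
                    left = min(gene.g(local_pre_start), gene.g(local_pre_start + 5))
                    reserved[gene.gene_id].append((left, left + 5))
                    events.append(
                        PlantedEvent(
                            line_label=line,
                            event_class=DE_NOVO,
                            chrom=gene.chrom,
                            pos=d_pos,
                            ref_allele=d_ref,
                            alt_allele=d_alt,
                            variant_id=d_vid,
                            gene_id=gene.gene_id,
                            gene_symbol=gene.symbol,
                            site_id=site.site_id,
                            de_novo_hexamer=motif,
                        )
                    )
                add_extra_sites(gene, kind)

        for _ in range(config.events_per_line.get(NON_PAS_CONTROL, 0)):
            gene = new_gene()
            hexamer = table.hexamers[
                int(rng.choice(len(table.hexamers), p=abundances))
            ]
            site, _signal, _ = add_site(gene, "IN", int(rng.integers(750, 1650)),
                                        hexamer)
            # control SNV in the intron, clear of every reserved footprint
            for _attempt in range(200):
                pos = gene.g(int(rng.integers(_INTRON[0] + 60, _INTRON[1] - 60)))
                if all(
                    pos < lo - 10 or pos > hi + 10
                    for lo, hi in reserved[gene.gene_id]
                ):
                    break
            else:  # pragma: no cover - layout makes this unreachable
                raise RuntimeError("could not place control variant")
            ref = read_seq(gene.chrom, pos, pos)
            alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
            vid = new_variant_id(line)
            add_variant(line, gene.chrom, pos, ref, alt, vid)
            events.append(
                PlantedEvent(
                    line_label=line,
                    event_class=NON_PAS_CONTROL,
                    chrom=gene.chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_id=vid,
                    gene_id=gene.gene_id,
                    gene_symbol=gene.symbol,
                    site_id=site.site_id,
                )
            )

    for _ in range(config.n_background_genes):
        gene = new_gene()
        hexamer = table.hexamers[int(rng.choice(len(table.hexamers), p=abundances))]
        add_site(gene, "TE", int(rng.integers(1950, 2850)), hexamer)

    # verify every planted signal against the final genome
    genome_obj = GenomeSequence({c: read_seq(c, 1, config.chrom_length)
                                 for c in chroms})
    for site in sites:
        for signal in site.signals:
            signal.check_against_genome(genome_obj, site.chrom)

    # ----- expression table with planted fold differences -----
    event_gene_ids = sorted({e.gene_id for e in events})
    deg_truth: dict[str, dict] = {}
    for gene in genes:
        is_event_gene = gene.gene_id in event_gene_ids
        deg = bool(is_event_gene and rng.random() < config.deg_fraction)
        tissue = TISSUES[int(rng.integers(len(TISSUES)))]
        if deg:
            fold = float(rng.uniform(*config.deg_fold_range))
            if rng.random() < 0.5:
                fold = 1.0 / fold
            p = float(rng.uniform(0.001, 0.04))
        else:
            fold = float(rng.uniform(0.95, 1.05))
            p = float(rng.uniform(0.2, 0.95))
        deg_truth[gene.gene_id] = {
            "symbol": gene.symbol,
            "deg": deg,
            "tissue": tissue,
            "fold_change": round(fold, 4),
            "p_value": round(p, 5),
        }

    # ----- write files -----
    genome_fasta = out_dir / "genome.fa"
    with open(genome_fasta, "w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            seq = read_seq(c, 1, config.chrom_length)
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    gtf = out_dir / "genes.gtf"
    with open(gtf, "w") as fh:
        for gene in genes:
            attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.symbol}";'
            fh.write(
                f"{gene.chrom}\tpasscan_sim\tgene\t{gene.start}\t{gene.end}\t."
                f"\t{gene.strand}\t.\t{attrs}\n"
            )
            tx = attrs + f' transcript_id "{gene.gene_id}.t1";'
            fh.write(
                f"{gene.chrom}\tpasscan_sim\ttranscript\t{gene.start}\t{gene.end}"
                f"\t.\t{gene.strand}\t.\t{tx}\n"
            )
            for s, e in gene.exons_genomic():
                fh.write(
                    f"{gene.chrom}\tpasscan_sim\texon\t{s}\t{e}\t."
                    f"\t{gene.strand}\t.\t{tx}\n"
                )

    atlas_tsv = out_dir / "atlas.tsv"
    write_atlas(sorted(sites, key=lambda s: (s.chrom, s.cleavage_pos, s.strand)),
                atlas_tsv)

    vcf_paths: dict[str, Path] = {}
    for line in config.line_labels:
        path = out_dir / f"{line.lower()}.vcf"
        vcf_paths[line] = path
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in chroms:
                fh.write(f"##contig=<ID={c},length={config.chrom_length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                f"{line.lower()}\n"
            )
            for v in sorted(variants[line], key=lambda v: (v.chrom, v.pos)):
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref_allele}\t"
                    f"{v.alt_allele}\t.\tPASS\t.\tGT\t1/1\n"
                )

    expression_tsv = out_dir / "expression.tsv"
    with open(expression_tsv, "w") as fh:
        fh.write("probe_id\tgene_symbol\ttissue\tfold_change\tp_value\tadj_p\n")
        for i, gene in enumerate(genes, start=1):
            t = deg_truth[gene.gene_id]
            adj = min(1.0, t["p_value"] * 3) if t["deg"] else min(1.0, t["p_value"] * 2)
            fh.write(
                f"probe{i:04d}\t{t['symbol']}\t{t['tissue']}\t"
                f"{t['fold_change']}\t{t['p_value']}\t{round(adj, 5)}\n"
            )

    gene_set_tsv = out_dir / "gene_set_obesity.tsv"
    with open(gene_set_tsv, "w") as fh:
        fh.write("# synthetic obesity-related gene symbols\n")
        for gid in event_gene_ids[::2]:
            fh.write(deg_truth[gid]["symbol"] + "\n")
        fh.write("Decoy1\nDecoy2\nDecoy3\n")

    manifest_jsonl = out_dir / "truth.jsonl"
    with open(manifest_jsonl, "w") as fh:
        for event in events:
            rec = {"kind": "event", **asdict(event)}
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
        for gid in sorted(deg_truth):
            fh.write(
                json.dumps({"kind": "gene", "gene_id": gid, **deg_truth[gid]},
                           sort_keys=True)
                + "\n"
            )

    return SyntheticBundle(
        out_dir=out_dir,
        genome_fasta=genome_fasta,
        gtf=gtf,
        atlas_tsv=atlas_tsv,
        vcfs=vcf_paths,
        expression_tsv=expression_tsv,
        gene_set_tsv=gene_set_tsv,
        manifest_jsonl=manifest_jsonl,
        events=events,
        deg_truth=deg_truth,
    )


def load_manifest(path: str | Path) -> tuple[list[PlantedEvent], dict[str, dict]]:
    """Read a truth manifest written by :func:`generate_bundle`."""
    events: list[PlantedEvent] = []
    deg: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        rec = json.loads(line)
        kind = rec.pop("kind")
        if kind == "event":
            events.append(PlantedEvent(**rec))
        else:
            gid = rec.pop("gene_id")
            deg[gid] = rec
    return events, deg


def verify_recovery(
    events: Iterable[PlantedEvent],
    records: Iterable[PasSnpRecord],
) -> dict[str, Optional[float]]:
    """Score pipeline records against the planted truth.

    sensitivity: planted PAS events (LOSS/MA_TO_LA/LA_TO_MA) recovered as a
    record with the same line and variant key; precision: fraction of
    records matching some planted PAS event; consequence_agreement: over
    matched pairs.  Metrics are None when their denominator is empty.
    """
    planted = {
        (e.line_label, e.variant_key): e
        for e in events
        if e.event_class in PAS_CLASSES
    }
    records = list(records)
    matched = 0
    agreeing = 0
    matching_records = 0
    seen: set = set()
    for record in records:
        key = (record.line_label, record.variant.key)
        event = planted.get(key)
        if event is None:
            continue
        matching_records += 1
        if key not in seen:
            seen.add(key)
            matched += 1
            if record.consequence == Consequence(event.expected_consequence):
                agreeing += 1
    return {
        "sensitivity": matched / len(planted) if planted else None,
        "precision": matching_records / len(records) if records else None,
        "consequence_agreement": agreeing / matched if matched else None,
    }


# ---------------------------------------------------------------------------
# Strand-mirror helpers: reverse-complement the genome, reflect coordinates
# and flip strands.  Annotation is strand-symmetric, so records on the
# mirrored bundle carry the same (ref_hexamer, alt_hexamer, consequence).

def mirror_genome(genome: GenomeSequence) -> GenomeSequence:
    return GenomeSequence(
        {c: revcomp(genome.fetch(c, 1, genome.length(c)))
         for c in genome.chromosomes}
    )


def _reflect(pos: int, length: int) -> int:
    return length - pos + 1


def mirror_variant(variant: Variant, length: int) -> Variant:
    return Variant(
        chrom=variant.chrom,
        pos=_reflect(variant.pos, length),
        ref_allele=_COMPLEMENT[variant.ref_allele],
        alt_allele=_COMPLEMENT[variant.alt_allele],
        variant_id=variant.variant_id,
        genotype=variant.genotype,
    )


def mirror_variant_set(vs: LineVariantSet, lengths: dict[str, int]) -> LineVariantSet:
    out = LineVariantSet(vs.line_label)
    for variant in vs:
        out.add(mirror_variant(variant, lengths[variant.chrom]))
    return out


def mirror_site(site: ApaSite, length: int) -> ApaSite:
    strand = "-" if site.strand == "+" else "+"
    return ApaSite(
        chrom=site.chrom,
        cleavage_pos=_reflect(site.cleavage_pos, length),
        strand=strand,
        cluster_start=_reflect(site.cluster_end, length),
        cluster_end=_reflect(site.cluster_start, length),
        gene_id=site.gene_id,
        gene_symbol=site.gene_symbol,
        site_type=site.site_type,
        usage_fraction=site.usage_fraction,
        signals=[
            PasSignal(s.hexamer, _reflect(s.footprint_end, length), strand)
            for s in site.signals
        ],
    )
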