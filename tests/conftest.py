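from pathlib import Path

import pandas as pd
import pytest

from passcan.annotate import annotate_line
from passcan.atlas import filter_genic, read_atlas
from passcan.genome import read_gene_models, read_genome
from passcan.motifs import load_motif_table
from passcan.simulate import SyntheticConfig, generate_bundle, load_manifest
from passcan.variants import line_specific, read_variants

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def motif_table():
    return load_motif_table()


@pytest.fixture(scope="session")
def reported_consequences():
    """Published catalogue rows (common / obesity / APA gene tables)."""
    return pd.read_csv(
        DATA_DIR / "reported_pas_consequences.tsv", sep="\t", comment="#"
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle, generated once per session."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(SyntheticConfig(seed=17), out)


@pytest.fixture(scope="session")
def bundle_env(bundle, motif_table):
    """Loaded inputs plus annotation output for the default bundle."""
    genome = read_genome(bundle.genome_fasta)
    models = read_gene_models(bundle.gtf)
    sites = read_atlas(bundle.atlas_tsv)
    genic = filter_genic(sites, models)
    fat_all = read_variants(bundle.vcfs["Fat"], "Fat")
    lean_all = read_variants(bundle.vcfs["Lean"], "Lean")
    fat, lean = line_specific(fat_all, lean_all)
    records = annotate_line(fat, genic, motif_table, models, genome)
    records += annotate_line(lean, genic, motif_table, models, genome)
    events, deg_truth = load_manifest(bundle.manifest_jsonl)
    return {
        "genome": genome,
        "models": models,
        "sites": sites,
        "genic": genic,
        "fat": fat,
        "lean": lean,
        "records": records,
        "events": events,
        "deg_truth": deg_truth,
    }


def write_fasta(path: Path, sequences: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def write_vcf(path: Path, rows, sample: str | None = None,
              contigs: dict[str, int] | None = None) -> Path:
    """rows: iterable of (chrom, pos, vid, ref, alt[, gt])."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, length in (contigs or {"chr1": 100000}).items():
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if sample:
            header += f"\tFORMAT\t{sample}"
        fh.write(header + "\n")
        for row in rows:
            chrom, pos, vid, ref, alt = row[:5]
            line = f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t."
            if sample:
                gt = row[5] if len(row) > 5 else "1/1"
                line += f"\tGT\t{gt}"
            fh.write(line + "\n")
    return path
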