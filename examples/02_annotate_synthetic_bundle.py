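"""Annotate a synthetic Fat/Lean bundle and score recovery of the truth.

Generates a deterministic bundle (genome, gene models, APA atlas, two VCFs),
derives line-specific SNVs, intersects them with PAS footprints and checks
that every planted event is recovered with the expected consequence.
"""

import tempfile
from pathlib import Path

from passcan import (
    annotate_line,
    load_motif_table,
    read_gene_models,
    read_genome,
)
from passcan.atlas import filter_genic, read_atlas
from passcan.simulate import SyntheticConfig, generate_bundle, verify_recovery
from passcan.variants import line_specific, read_variants

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_bundle(SyntheticConfig(seed=17), Path(tmp))
    table = load_motif_table()
    genome = read_genome(bundle.genome_fasta)
    models = read_gene_models(bundle.gtf)
    sites = filter_genic(read_atlas(bundle.atlas_tsv), models)
    fat, lean = line_specific(
        read_variants(bundle.vcfs["Fat"], "Fat"),
        read_variants(bundle.vcfs["Lean"], "Lean"),
    )
    records = annotate_line(fat, sites, table, models, genome)
    records += annotate_line(lean, sites, table, models, genome)

    print(f"planted events: {len(bundle.events)} "
          f"(PAS hits, de-novo creations and non-PAS controls)")
    print(f"PAS-SNP records: {len(records)}")
    for record in records[:3]:
        print(f"  {record.line_label} {record.variant.variant_id} "
              f"{record.site_id} {record.ref_hexamer}->{record.alt_hexamer} "
              f"{record.consequence.label}")
    metrics = verify_recovery(bundle.events, records)
    print(f"recovery: sensitivity={metrics['sensitivity']}, "
          f"precision={metrics['precision']}, "
          f"agreement={metrics['consequence_agreement']}")

# sensitivity/precision/agreement of 1.0 mean every planted footprint hit was
# found, nothing spurious was reported, and every consequence class matched.
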