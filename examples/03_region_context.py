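"""Scan the APA cluster + 60 bp upstream window around a disrupted signal.

Builds a one-gene genome where a weak AGTAAA signal is destroyed while a
canonical AATAAA sits nearby, and shows the residual-signal flags the
prioritisation stage consumes.
"""

import tempfile
from pathlib import Path

from passcan import annotate_line, context_for_record, load_motif_table, read_genome
from passcan.atlas import ApaSite, PasSignal
from passcan.variants import LineVariantSet, Variant

table = load_motif_table()
cleavage = 250

seq = list("C" * 400)
seq[223:229] = "AGTAAA"   # focal signal, ends 21 nt upstream of cleavage
seq[209:215] = "AATAAA"   # canonical signal, ends 35 nt upstream
with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "toy.fa"
    fasta.write_text(">chr1\n" + "".join(seq) + "\n")
    genome = read_genome(fasta)

site = ApaSite(
    chrom="chr1", cleavage_pos=cleavage, strand="+",
    cluster_start=cleavage - 5, cluster_end=cleavage + 5,
    gene_id="g1", gene_symbol="Toy1", site_type="TE",
    signals=[PasSignal("AGTAAA", 224, "+")],
)
variants = LineVariantSet("Fat")
variants.add(Variant("chr1", 229, "A", "G", "v1"))  # AGTAAA -> AGTAAG

(record,) = annotate_line(variants, [site], table, [], genome)
ctx = context_for_record(record, site, genome, list(variants), table)

print(f"consequence: {record.consequence.label}")
print(f"window {ctx.window_start}-{ctx.window_end}: "
      f"{len(ctx.reference_signals)} reference signals, "
      f"{len(ctx.surviving_signals)} surviving, "
      f"{len(ctx.de_novo_signals)} de novo")
print(f"top_rank_disrupted={ctx.top_rank_disrupted}, "
      f"canonical_remaining={ctx.canonical_remaining}")

# canonical_remaining=True: the intact AATAAA can still direct cleavage, so
# this loss would be ranked LOW by the prioritisation rule.
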