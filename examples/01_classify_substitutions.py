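"""Classify single-base PAS hexamer substitutions against the motif ranking.

Loads the packaged mouse PAS inventory and classifies a few substitutions
observed in the Fat/Lean selection lines: a change to a hexamer outside the
inventory is a Loss; otherwise the rank order decides whether the signal
became weaker (MA -> LA) or stronger (LA -> MA).
"""

from passcan import classify_consequence, load_motif_table

table = load_motif_table()
print(f"motif inventory: {len(table)} hexamers, "
      f"rank 1 = {table.hexamers[0]}, rank 2 = {table.hexamers[1]}")

examples = [
    ("AATAAA", "AATACA"),  # canonical signal weakened
    ("AGTAAA", "AATAAA"),  # weak signal strengthened to canonical
    ("TATAAA", "TATAAG"),  # no recognised signal remains
    ("AATAAT", "AATATT"),
]
for ref, alt in examples:
    consequence = classify_consequence(ref, alt, table)
    print(f"{ref} -> {alt}: {consequence.label}  "
          f"(ranks {table.rank_of(ref)} -> {table.rank_of(alt)})")

# Each line shows the reference hexamer, the variant hexamer, and the
# consequence class the pipeline would report for a SNV causing that edit.
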