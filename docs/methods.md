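# Methods

## Model

A polyadenylation signal (PAS) is modelled as exact membership in a small
ranked inventory of DNA hexamers. The packaged default
(`src/passcan/data/pas_motifs_mouse.tsv`) is the 18-hexamer inventory
annotated by the PolyASite 2.0 mouse atlas — the 12 classical signals plus
the 6 of the extended inventory — with AATAAA ranked first and ATTAAA
second. Counts in the file are representative occurrence totals chosen to
reproduce the atlas abundance ordering; consequence classification depends
only on the rank order (strictly decreasing counts), never on absolute
counts, so the table can equally be re-derived from any loaded atlas with
`derive_motif_table_from_atlas`. Probabilistic or position-weight-matrix
signal models are out of scope by design: the classification semantics
(Loss / MA → LA / LA → MA) are defined on exact hexamer identity.

Classification compares motif abundances: a substitution to a hexamer
outside the inventory is `LOSS`; otherwise the direction of the count
difference gives `MA_TO_LA` or `LA_TO_MA`. Two distinct hexamers with
equal counts yield the explicit `RANK_TIE` category rather than an
arbitrary direction; with the default table this cannot occur (counts are
strictly decreasing), but atlas-derived tables can tie. Rank assignment
itself breaks count ties lexicographically so ranks are always a dense,
deterministic 1..N.

## Coordinates and strand

All internal coordinates are 1-based inclusive (VCF/GTF convention);
PolyASite-style BED input is converted at the parsing boundary. A signal
footprint is stored by its leftmost genomic base plus the sense-strand
hexamer; the invariant `genome[footprint] == hexamer` (or its reverse
complement on minus-strand genes) is checked whenever a genome is at hand.
Variant alleles are plus-strand (as in VCF) and complemented when applied
to minus-strand hexamers. The variant's offset inside the hexamer is
counted in sense orientation: `pos − footprint_start` on plus,
`footprint_end − pos` on minus. "Upstream" always means gene-5′: left of
the cluster for plus-strand sites, right of it for minus-strand sites.

## Windows and parameters

| parameter | default | meaning |
| --- | --- | --- |
| `signal_window` | 40 nt | maximal footprint-end-to-cleavage distance accepted when rescanning signals (atlas annotations, when present, win; `--rescan` forces scanning). Signals sit ~20 nt upstream; 40 nt bounds the search without clipping the tail of the placement distribution. The atlas itself does not state a maximal accepted distance, so this is a declared choice. |
| `upstream_window` | 60 nt | region-context window = APA cluster plus this much gene-5′ sequence, measured from the cluster edge (not the representative cleavage site). |
| `fold` | 1.5 | expression filter, inclusive (`max(fc, 1/fc) ≥ 1.5`). |
| `p` | 0.05 | expression filter, exclusive (`p < 0.05`); raw p by default, adjusted p behind `--use-adjusted` so borderline candidates are not silently dropped. |
| `line_rule` | presence | line specificity by key presence/absence; `hom_fixed` additionally requires a homozygous-alternate genotype in the owning line. Both are offered because selection lines are expected to be near-fixed but genotype fields are not always available. |
| `strand_matched` | on | genic filter requires the site and gene on the same strand; a flag admits antisense overlap. |

Gene spans are taken as annotated, with no downstream extension;
transcripts can in reality extend past annotation (APA sites downstream of
genes exist), so this is surfaced as the genic-filter flag rather than
hidden.

## Region context and prioritisation

For each PAS-SNP record the window sequence is rescanned (sense strand)
before and after substituting the focal line's SNVs. De-novo signals are
(window-offset, hexamer) pairs present only after substitution — a
positional comparison, so one edit that simultaneously destroys a signal
and creates an overlapping one registers both events. Flags:

* `top_rank_disrupted` — the disrupted signal had the window's best rank
  and no surviving signal matches it;
* `canonical_remaining` — an AATAAA/ATTAAA occurrence other than the
  disrupted footprint survives.

The published prioritisation was a manual, visual step; this package
formalises its three stated ingredients into a deterministic rule: a
candidate needs (1) a weakening consequence (`LOSS` or `MA_TO_LA`), and
(2) differential expression of the host gene in ≥1 tissue; (3) severity is
HIGH on `top_rank_disrupted`, LOW on `canonical_remaining`, MODERATE
otherwise, with HIGH taking precedence when both flags are set. Ranking is
by severity, then best |log fold change|, then genomic position. The
predicted effect follows the site type: terminal-exon sites change 3′ UTR
length, intronic sites truncate or extend the coding product. Probe
coordinates, when supplied, only annotate candidates (probe 5′/3′ of the
signal); they never remove one, because no decision rule for them was ever
stated.

## Synthetic data

The generator emulates the study conditions rather than any particular
genome: i.i.d. uniform ACGT background, 3 kb two-exon genes (5′ exon,
intron, terminal exon) tiled with 500 bp gaps on random strands, 1–3 APA
clusters per gene, and one PAS hexamer per cluster planted with its 3′ end
at a truncated-normal distance (mean 21 nt, sd 3, bounds [10, 40]) upstream
of the cleavage position, chosen abundance-weighted from the motif table.
Per line it plants 8 LOSS, 7 MA → LA and 7 LA → MA footprint SNVs (each in
its own gene so classes are individually addressable), 3 de-novo creations
(a one-edit pre-image of a motif placed in a LOSS gene's window, converted
by a second SNV of the same line), and 5 non-PAS control SNVs kept ≥10 bp
from any footprint — 60 planted events total, 44 of them PAS-footprint
hits. Expression tables plant ≥1.5-fold differences at p < 0.05 for half
of the event genes. Accidental background motifs are permitted; scoring
matches on variant keys, so they cannot corrupt recovery metrics.

What the generator does **not** emulate: linkage structure, read-level
noise, genotype uncertainty, multi-sample cohorts, cluster-usage
quantification, or microarray noise. Perfect recovery on these bundles
therefore demonstrates that the deterministic annotation logic is exact —
coordinates, strands, offsets, classification — not that the pipeline is
robust to upstream calling errors in real data.

Mirror utilities (reverse-complemented genome with reflected coordinates
and flipped strands) support the strand-symmetry property tests: the
multiset of (ref, alt, consequence) must be invariant under mirroring.

## Numerical and degenerate-input choices

* Ties in motif counts: lexicographic rank order, `RANK_TIE` consequence.
* Recovery metrics are `None` (not 0 or 1) when a denominator is empty.
* Colliding SNVs at one position in a window, reference-allele mismatches
  between VCF/atlas/genome, and out-of-bounds windows are hard errors, not
  warnings — silent repair could misattribute a consequence.
* MNVs and indels are excluded from the core path (`snv_only` default);
  the catalogue semantics are defined for single-base edits.
* Reports render consequences with the published strings ("Loss",
  "MA → LA motif", "LA → MA motif", plus "Rank tie").

## Problem sizes

Tests and the acceptance script run on bundles of two 120 kb chromosomes,
58 genes and 60 planted events per bundle (ten seeds in the acceptance
suite), and on 1,000 random 200-nt sequences for the scanning oracle —
sizes at which every check is exact and the full suite runs in seconds.

## Known limitations

* The genic filter uses annotated gene spans only; PAS-SNPs in unannotated
  3′ extensions are missed unless the antisense/span flags are relaxed.
* The motif inventory's absolute counts are representative, not measured;
  analyses that need true genome-wide abundances should load them from an
  atlas export.
* Candidate prioritisation formalises a published manual procedure; on
  real catalogues its candidate set should be reviewed, not taken as a
  definitional reproduction of expert judgement.
* The two-line contrast assumes one VCF per line (pooled or representative
  sample); cohort-level allele-frequency contrasts are out of scope.
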