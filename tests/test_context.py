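import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from passcan.annotate import annotate_line
from passcan.atlas import ApaSite, PasSignal
from passcan.context import (
    apply_variants_to_window,
    build_window,
    context_for_record,
    enumerate_signals,
)
from passcan.genome import GenomeSequence, read_genome
from passcan.motifs import revcomp
from passcan.variants import LineVariantSet, Variant

from conftest import write_fasta


def _site(strand, cluster, cleavage=None, signals=()):
    start, end = cluster
    return ApaSite(
        chrom="chr1", cleavage_pos=cleavage or (start + end) // 2,
        strand=strand, cluster_start=start, cluster_end=end,
        gene_id="g1", gene_symbol="Alpha", site_type="TE",
        signals=list(signals),
    )


class TestBuildWindow:
    def test_plus_strand_extends_left(self):
        assert build_window(_site("+", (200, 240))) == (140, 240)

    def test_minus_strand_extends_right(self):
        assert build_window(_site("-", (200, 240))) == (200, 300)

    def test_zero_upstream_is_cluster(self):
        assert build_window(_site("+", (200, 240)), upstream=0) == (200, 240)

    def test_clamped_to_chromosome(self):
        genome = GenomeSequence({"chr1": "ACGT" * 60})
        assert build_window(_site("+", (30, 50), cleavage=40), genome) == (1, 50)
        assert build_window(_site("-", (200, 230), cleavage=210), genome) == (200, 240)


class TestApplyVariants:
    @pytest.fixture
    def genome(self, tmp_path):
        return read_genome(
            write_fasta(tmp_path / "g.fa", {"chr1": "ACGTACGTACGTACGTACGT"})
        )

    def test_no_variants_is_reference(self, genome):
        assert apply_variants_to_window(genome, "chr1", (5, 10), "+", []) == "ACGTAC"

    def test_minus_strand_returns_sense(self, genome):
        assert apply_variants_to_window(genome, "chr1", (5, 10), "-", []) == revcomp(
            "ACGTAC"
        )

    def test_single_snv_changes_one_base(self, genome):
        out = apply_variants_to_window(
            genome, "chr1", (5, 10), "+", [Variant("chr1", 7, "G", "A")]
        )
        assert out == "ACATAC"

    def test_colliding_variants_rejected(self, genome):
        vs = [Variant("chr1", 7, "G", "A"), Variant("chr1", 7, "G", "C")]
        with pytest.raises(ValueError, match="[Cc]ollid"):
            apply_variants_to_window(genome, "chr1", (5, 10), "+", vs)

    def test_out_of_window_variant_rejected(self, genome):
        with pytest.raises(ValueError, match="outside"):
            apply_variants_to_window(
                genome, "chr1", (5, 10), "+", [Variant("chr1", 15, "C", "A")]
            )

    def test_ref_mismatch_rejected(self, genome):
        with pytest.raises(ValueError, match="mismatch"):
            apply_variants_to_window(
                genome, "chr1", (5, 10), "+", [Variant("chr1", 7, "T", "A")]
            )


class TestEnumerateSignals:
    def test_single_hexamer(self, motif_table):
        (occ,) = enumerate_signals("AATAAA", motif_table)
        assert (occ.hexamer, occ.start, occ.rank) == ("AATAAA", 0, 1)

    def test_overlapping_occurrences_all_reported(self, motif_table):
        # AATAAA at 0 and ATTAAA nowhere; TAAATAAA gives AATAAA at 3 only
        occs = enumerate_signals("AATAAATAAA", motif_table)
        assert [(o.hexamer, o.start) for o in occs] == [
            ("AATAAA", 0),
            ("AATAAA", 4),
        ]

    def test_sequence_without_signals_is_empty(self, motif_table):
        assert enumerate_signals("CGCGCGCGCG", motif_table) == []

    @settings(deadline=None, max_examples=200)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    def test_matches_sliding_window_oracle(self, motif_table, seq):
        got = [(o.start, o.hexamer) for o in enumerate_signals(seq, motif_table)]
        oracle = [
            (i, seq[i : i + 6])
            for i in range(max(0, len(seq) - 5))
            if seq[i : i + 6] in motif_table
        ]
        assert got == oracle


def _scenario(tmp_path, strand, window_hexamers, focal_idx, variant_alt,
              extra_variants=()):
    """Build a one-site genome where `window_hexamers` are planted in the
    cluster+60 window and the focal signal's last base is substituted."""
    chrom_len = 400
    cleavage = 250
    cluster = (cleavage - 5, cleavage + 5)
    seq = list("C" * chrom_len)
    signals = []
    positions = {}
    for k, (hexamer, dist) in enumerate(window_hexamers):
        # footprint ends `dist` nt upstream of cleavage (plus strand)
        start = cleavage - dist - 5
        seq[start - 1 : start + 5] = list(hexamer)
        positions[k] = start
        signals.append(PasSignal(hexamer, start, "+"))
    genome = read_genome(
        write_fasta(tmp_path / "g.fa", {"chr1": "".join(seq)})
    )
    site = _site(strand, cluster, cleavage=cleavage,
                 signals=[signals[focal_idx]])
    focal_start = positions[focal_idx]
    ref_base = genome.base("chr1", focal_start + 5)
    vs = LineVariantSet("Fat")
    vs.add(Variant("chr1", focal_start + 5, ref_base, variant_alt, "v_focal"))
    for variant in extra_variants:
        vs.add(variant)
    return genome, site, vs, positions


class TestContextForRecord:
    def _annotate(self, genome, site, vs, motif_table):
        (record,) = annotate_line(vs, [site], motif_table, [], genome)
        return record

    def test_sole_top_signal_destroyed(self, tmp_path, motif_table):
        genome, site, vs, _ = _scenario(
            tmp_path, "+", [("TATAAA", 21)], 0, "G"  # TATAAA -> TATAAG, loss
        )
        record = self._annotate(genome, site, vs, motif_table)
        ctx = context_for_record(record, site, genome, list(vs), motif_table)
        assert ctx.top_rank_disrupted is True
        assert ctx.canonical_remaining is False
        assert ctx.de_novo_signals == []

    def test_intact_canonical_demotes_the_hit(self, tmp_path, motif_table):
        genome, site, vs, _ = _scenario(
            tmp_path, "+", [("AGTAAA", 21), ("AATAAA", 35)], 0, "G"
            # AGTAAA -> AGTAAG loss, canonical AATAAA survives nearby
        )
        record = self._annotate(genome, site, vs, motif_table)
        ctx = context_for_record(record, site, genome, list(vs), motif_table)
        assert ctx.top_rank_disrupted is False
        assert ctx.canonical_remaining is True

    def test_de_novo_creation_detected(self, tmp_path, motif_table):
        genome, site, vs, positions = _scenario(
            tmp_path, "+", [("TATAAA", 21), ("AATGAA", 35)], 0, "G",
        )
        # second variant converts the AATGAA occurrence into AATAAA
        pre_start = positions[1]
        vs.add(Variant("chr1", pre_start + 3, "G", "A", "v_denovo"))
        record = self._annotate(genome, site, vs, motif_table)
        ctx = context_for_record(record, site, genome, list(vs), motif_table)
        de_novo = [o.hexamer for o in ctx.de_novo_signals]
        assert de_novo == ["AATAAA"]
        # the created canonical signal also rescues the region
        assert ctx.canonical_remaining is True

    def test_no_variants_means_no_change(self, tmp_path, motif_table):
        genome, site, vs, _ = _scenario(tmp_path, "+", [("TATAAA", 21)], 0, "G")
        record = self._annotate(genome, site, vs, motif_table)
        ctx = context_for_record(record, site, genome, [], motif_table)
        assert ctx.surviving_signals == ctx.reference_signals
        assert ctx.de_novo_signals == []

    def test_flags_recomputable_from_signal_lists(self, tmp_path, motif_table):
        genome, site, vs, _ = _scenario(
            tmp_path, "+", [("AGTAAA", 21), ("AATAAA", 35)], 0, "G"
        )
        record = self._annotate(genome, site, vs, motif_table)
        ctx = context_for_record(record, site, genome, list(vs), motif_table)
        focal_rank = motif_table.rank_of(record.ref_hexamer)
        best_ref = min(o.rank for o in ctx.reference_signals)
        recomputed_top = focal_rank == best_ref and all(
            o.rank > focal_rank for o in ctx.surviving_signals
        )
        assert recomputed_top == ctx.top_rank_disrupted

    def test_record_site_mismatch_rejected(self, tmp_path, motif_table):
        genome, site, vs, _ = _scenario(tmp_path, "+", [("TATAAA", 21)], 0, "G")
        record = self._annotate(genome, site, vs, motif_table)
        other = _site("+", (100, 120))
        with pytest.raises(ValueError):
            context_for_record(record, other, genome, [], motif_table)
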