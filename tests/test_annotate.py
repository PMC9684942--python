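from collections import Counter

import pytest

from passcan.annotate import (
    Consequence,
    PasHit,
    alt_hexamer,
    annotate_line,
    classify_consequence,
    overlap_pas,
)
from passcan.atlas import ApaSite, PasSignal
from passcan.genome import read_genome
from passcan.motifs import revcomp
from passcan.variants import LineVariantSet, Variant
from passcan.simulate import (
    mirror_genome,
    mirror_site,
    mirror_variant_set,
    single_base_substitutions,
)

from conftest import write_fasta


def _site(strand, footprint_start, hexamer="AATAAA", cleavage=None):
    if cleavage is None:
        cleavage = footprint_start + 26 if strand == "+" else footprint_start - 21
    return ApaSite(
        chrom="chr1", cleavage_pos=cleavage, strand=strand,
        cluster_start=cleavage - 3, cluster_end=cleavage + 3,
        gene_id="g1", gene_symbol="Alpha", site_type="TE",
        signals=[PasSignal(hexamer, footprint_start, strand)],
    )


def _variants(*specs):
    vs = LineVariantSet("Fat")
    for chrom, pos, ref, alt in specs:
        vs.add(Variant(chrom, pos, ref, alt))
    return vs


class TestOverlapPas:
    def test_plus_strand_footprint_boundaries(self):
        site = _site("+", 101)
        inside = _variants(("chr1", 101, "A", "C"), ("chr1", 106, "A", "G"))
        hits = overlap_pas(inside, [site])
        assert [(h.variant.pos, h.offset) for h in hits] == [(101, 0), (106, 5)]

    def test_positions_flanking_footprint_miss(self):
        site = _site("+", 101)
        outside = _variants(("chr1", 100, "A", "C"), ("chr1", 107, "A", "G"))
        assert overlap_pas(outside, [site]) == []

    def test_minus_strand_offset_counts_from_sense_end(self):
        site = _site("-", 101)
        hits = overlap_pas(_variants(("chr1", 102, "T", "C")), [site])
        assert [(h.variant.pos, h.offset) for h in hits] == [(102, 4)]

    def test_overlapping_footprints_each_hit(self):
        site = _site("+", 101)
        site.signals.append(PasSignal("ATTAAA", 103, "+"))
        hits = overlap_pas(_variants(("chr1", 104, "A", "G")), [site])
        assert len(hits) == 2
        assert sorted(h.offset for h in hits) == [1, 3]

    def test_empty_inputs_give_empty_output(self):
        assert overlap_pas(_variants(), []) == []


class TestAltHexamer:
    def test_plus_strand_substitution(self, tmp_path):
        seq = "C" * 100 + "AATAAA" + "C" * 100
        genome = read_genome(write_fasta(tmp_path / "g.fa", {"chr1": seq}))
        site = _site("+", 101)
        (hit,) = overlap_pas(_variants(("chr1", 105, "A", "C")), [site])
        assert alt_hexamer(hit, genome) == ("AATAAA", "AATACA")

    def test_minus_strand_complements_the_alt(self, tmp_path):
        # sense AATACA on the minus strand appears as TGTATT on plus
        seq = "C" * 100 + revcomp("AATACA") + "C" * 100
        genome = read_genome(write_fasta(tmp_path / "g.fa", {"chr1": seq}))
        site = _site("-", 101, hexamer="AATACA")
        (hit,) = overlap_pas(_variants(("chr1", 102, "G", "A")), [site])
        assert hit.offset == 4
        assert alt_hexamer(hit, genome) == ("AATACA", "AATATA")

    def test_reference_mismatch_is_error(self, tmp_path):
        seq = "C" * 100 + "AATAAA" + "C" * 100
        genome = read_genome(write_fasta(tmp_path / "g.fa", {"chr1": seq}))
        site = _site("+", 101)
        (hit,) = overlap_pas(_variants(("chr1", 105, "G", "C")), [site])
        with pytest.raises(ValueError, match="mismatch"):
            alt_hexamer(hit, genome)


class TestClassifyConsequence:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("AATAAA", "AATACA", Consequence.MA_TO_LA),
            ("AGTAAA", "AATAAA", Consequence.LA_TO_MA),
            ("TATAAA", "TATAAG", Consequence.LOSS),
            ("ATTACA", "ATTAAA", Consequence.LA_TO_MA),
            ("AATAAT", "AATATT", Consequence.LOSS),
        ],
    )
    def test_catalogue_examples(self, motif_table, ref, alt, expected):
        assert classify_consequence(ref, alt, motif_table) == expected

    def test_unknown_reference_rejected(self, motif_table):
        with pytest.raises(ValueError):
            classify_consequence("ATAAAA", "AATAAA", motif_table)

    def test_identical_hexamers_rejected(self, motif_table):
        with pytest.raises(ValueError):
            classify_consequence("AATAAA", "AATAAA", motif_table)

    def test_exhaustive_substitutions_match_rank_oracle(self, motif_table):
        """Every motif x 18 single-base edits agrees with direct count
        comparison (the brute-force oracle)."""
        checked = 0
        for ref in motif_table.hexamers:
            ref_count = motif_table.count_of(ref)
            for _offset, _base, alt in single_base_substitutions(ref):
                got = classify_consequence(ref, alt, motif_table)
                alt_count = motif_table.count_of(alt)
                if alt_count is None:
                    expected = Consequence.LOSS
                elif alt_count > ref_count:
                    expected = Consequence.LA_TO_MA
                elif alt_count < ref_count:
                    expected = Consequence.MA_TO_LA
                else:
                    expected = Consequence.RANK_TIE
                assert got == expected, (ref, alt)
                checked += 1
        assert checked == len(motif_table) * 18


class TestAnnotateLine:
    def test_bundle_records_match_truth_manifest(self, bundle_env):
        truth = {
            (e.line_label, e.variant_key): e
            for e in bundle_env["events"]
            if e.expected_consequence is not None
        }
        records = bundle_env["records"]
        assert {(r.line_label, r.variant.key) for r in records} == set(truth)
        for record in records:
            event = truth[(record.line_label, record.variant.key)]
            assert record.ref_hexamer == event.ref_hexamer
            assert record.alt_hexamer == event.alt_hexamer
            assert record.consequence == Consequence(event.expected_consequence)
            assert record.site_id == event.site_id
            assert record.gene_symbol == event.gene_symbol

    def test_records_sorted_and_deterministic(self, bundle_env, motif_table):
        records = bundle_env["records"]
        fat_records = [r for r in records if r.line_label == "Fat"]
        keys = [(r.variant.chrom, r.variant.pos) for r in fat_records]
        assert keys == sorted(keys)
        again = annotate_line(
            bundle_env["fat"], bundle_env["genic"], motif_table,
            bundle_env["models"], bundle_env["genome"],
        )
        assert again == fat_records

    def test_each_record_belongs_to_one_line(self, bundle_env):
        fat_keys = {r.variant.key for r in bundle_env["records"]
                    if r.line_label == "Fat"}
        lean_keys = {r.variant.key for r in bundle_env["records"]
                     if r.line_label == "Lean"}
        assert not fat_keys & lean_keys

    def test_strand_mirrored_bundle_gives_same_consequences(
        self, bundle_env, motif_table
    ):
        genome = bundle_env["genome"]
        lengths = {c: genome.length(c) for c in genome.chromosomes}
        mirrored_sites = [
            mirror_site(s, lengths[s.chrom]) for s in bundle_env["genic"]
        ]
        m_genome = mirror_genome(genome)
        multiset = Counter()
        mirrored_multiset = Counter()
        for line in ("fat", "lean"):
            vs = bundle_env[line]
            records = annotate_line(vs, bundle_env["genic"], motif_table,
                                    bundle_env["models"], genome)
            multiset.update(
                (r.ref_hexamer, r.alt_hexamer, r.consequence) for r in records
            )
            m_vs = mirror_variant_set(vs, lengths)
            # mirrored sites keep their gene/type annotations, so gene models
            # are not re-consulted for the site-type call
            m_records = annotate_line(m_vs, mirrored_sites, motif_table,
                                      [], m_genome)
            mirrored_multiset.update(
                (r.ref_hexamer, r.alt_hexamer, r.consequence) for r in m_records
            )
        assert multiset == mirrored_multiset
        assert sum(multiset.values()) > 0
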