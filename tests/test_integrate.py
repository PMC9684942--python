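import pytest

from passcan.annotate import Consequence, PasSnpRecord
from passcan.atlas import PasSignal
from passcan.context import RegionContext, SignalOccurrence
from passcan.integrate import (
    DegCall,
    ExpressionRecord,
    GeneSet,
    common_genes,
    deg_filter,
    intersect_records,
    load_pas_catalogue,
    prioritise,
    read_gene_set,
    record_key,
    summarise_catalogue,
)
from passcan.variants import Variant


def _record(line="Fat", pos=100, gene="Car8", site_id="chr1:200:+",
            site_type="TE", consequence=Consequence.LOSS,
            ref_hex="TATAAA", alt_hex="TATAAG"):
    return PasSnpRecord(
        line_label=line,
        variant=Variant("chr1", pos, "A", "G", variant_id=f"v{pos}"),
        site_id=site_id,
        gene_id=gene.lower(),
        gene_symbol=gene,
        site_type=site_type,
        signal=PasSignal(ref_hex, pos - 3, "+"),
        offset=3,
        ref_hexamer=ref_hex,
        alt_hexamer=alt_hex,
        consequence=consequence,
    )


def _context(record, top=True, canonical=False):
    return RegionContext(
        site_id=record.site_id,
        window_start=1,
        window_end=100,
        reference_signals=[SignalOccurrence(record.ref_hexamer, 10, 3)],
        surviving_signals=(
            [SignalOccurrence("AATAAA", 40, 1)] if canonical else []
        ),
        de_novo_signals=[],
        top_rank_disrupted=top,
        canonical_remaining=canonical,
    )


def _expr(gene, tissue="WAT", fc=2.0, p=0.01, adj_p=None):
    return ExpressionRecord("p1", gene, tissue, fc, p, adj_p=adj_p)


class TestGeneSet:
    def test_read_and_collapse(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("# comment\nCar8\nLat\ncar8\n")
        gs = read_gene_set(path, "obesity")
        assert len(gs) == 2
        assert "CAR8" in gs and "lat" in gs

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("# only comments\n")
        with pytest.raises(ValueError):
            read_gene_set(path, "obesity")


class TestIntersectRecords:
    def test_counts_distinct_snps_and_genes(self):
        records = [
            _record(pos=100, gene="Abcc6"),
            _record(pos=110, gene="Col4a1"),
            _record(pos=120, gene="Lhfpl3"),
            _record(pos=130, gene="Lhfpl3"),
            _record(pos=140, gene="Npc1"),
            _record(pos=150, gene="NotInSet"),
        ]
        gs = GeneSet("obesity", {"abcc6", "COL4A1", "Lhfpl3", "Npc1"})
        hits, n_snps, n_genes = intersect_records(records, gs)
        assert (n_snps, n_genes) == (5, 4)
        assert all(r.gene_symbol != "NotInSet" for r in hits)

    def test_empty_set_gives_zero(self):
        hits, n_snps, n_genes = intersect_records([], GeneSet("x", {"A"}))
        assert (hits, n_snps, n_genes) == ([], 0, 0)


class TestCommonGenes:
    def test_disjoint_sites_flagged(self):
        fat = [_record(line="Fat", gene="Tenm4", site_id="chr1:10:+")]
        lean = [_record(line="Lean", gene="Tenm4", site_id="chr1:90:+")]
        ((gene, f_sites, l_sites, differ),) = common_genes(fat, lean)
        assert gene == "Tenm4" and differ is True

    def test_shared_site_not_flagged(self):
        fat = [_record(line="Fat", gene="Tenm4", site_id="chr1:10:+")]
        lean = [_record(line="Lean", gene="Tenm4", site_id="chr1:10:+")]
        ((_, _, _, differ),) = common_genes(fat, lean)
        assert differ is False

    def test_single_line_gene_absent(self):
        fat = [_record(line="Fat", gene="OnlyFat")]
        assert common_genes(fat, []) == []


class TestDegFilter:
    def test_boundary_fold_inclusive_p_exclusive(self):
        kept = deg_filter([_expr("A", fc=1.5, p=0.049)])
        assert len(kept) == 1
        assert deg_filter([_expr("A", fc=1.49, p=0.01)]) == []
        assert deg_filter([_expr("A", fc=1.5, p=0.05)]) == []

    def test_down_regulation_via_reciprocal(self):
        (call,) = deg_filter([_expr("A", fc=0.60, p=0.01)])
        assert call.direction == "DOWN"

    def test_adjusted_p_switch(self):
        expr = [_expr("A", fc=2.0, p=0.01, adj_p=0.2)]
        assert len(deg_filter(expr)) == 1
        assert deg_filter(expr, use_adjusted=True) == []

    def test_monotone_in_fold_threshold(self):
        expr = [_expr("A", fc=1.6), _expr("B", fc=2.4), _expr("C", fc=0.5)]
        folds = [1.0, 1.5, 2.0, 2.5, 3.0]
        sizes = [len(deg_filter(expr, fold=f)) for f in folds]
        assert sizes == sorted(sizes, reverse=True)


class TestPrioritise:
    def _setup(self, record, **ctx_kw):
        contexts = {record_key(record): _context(record, **ctx_kw)}
        return contexts

    def test_loss_in_deg_gene_with_top_disruption_is_high(self):
        record = _record()
        contexts = self._setup(record, top=True, canonical=False)
        degs = deg_filter([_expr("Car8")])
        (cand,) = prioritise([record], contexts, degs)
        assert cand.severity == "HIGH"
        assert cand.predicted_effect == "UTR_LENGTH_CHANGE"

    def test_canonical_remaining_is_low(self):
        record = _record(site_type="IN")
        contexts = self._setup(record, top=False, canonical=True)
        (cand,) = prioritise([record], contexts, deg_filter([_expr("Car8")]))
        assert cand.severity == "LOW"
        assert cand.predicted_effect == "CODING_TRUNCATION_CHANGE"

    def test_strengthening_consequence_is_not_a_candidate(self):
        record = _record(consequence=Consequence.LA_TO_MA,
                         ref_hex="AGTAAA", alt_hex="AATAAA")
        contexts = self._setup(record)
        assert prioritise([record], contexts, deg_filter([_expr("Car8")])) == []

    def test_non_deg_gene_is_not_a_candidate(self):
        record = _record()
        contexts = self._setup(record)
        assert prioritise([record], contexts, deg_filter([_expr("Other")])) == []

    def test_missing_context_is_error(self):
        record = _record()
        with pytest.raises(KeyError):
            prioritise([record], {}, deg_filter([_expr("Car8")]))

    def test_ranking_severity_then_fold(self):
        high = _record(pos=300, gene="Car8")
        low = _record(pos=100, gene="Lat")
        contexts = {
            record_key(high): _context(high, top=True, canonical=False),
            record_key(low): _context(low, top=False, canonical=True),
        }
        degs = deg_filter([_expr("Car8", fc=1.6), _expr("Lat", fc=3.0)])
        ranked = prioritise([high, low], contexts, degs)
        assert [c.record.gene_symbol for c in ranked] == ["Car8", "Lat"]


class TestCatalogueAggregation:
    def test_summary_counts(self, tmp_path, reported_consequences):
        path = tmp_path / "catalogue.tsv"
        reported_consequences.to_csv(path, sep="\t", index=False)
        catalogue = load_pas_catalogue(path)
        gene_sets = {
            "obesity": GeneSet(
                "obesity",
                {"Abcc6", "Col4a1", "Lhfpl3", "Npc1", "Lsamp", "Ppargc1a"},
            ),
            "apa": GeneSet(
                "apa",
                {"Mnat1", "Polr2c", "Snd1", "Eny2", "Ints11", "Dhx15", "Eif3e"},
            ),
        }
        summary = summarise_catalogue(catalogue, gene_sets)
        # the transcribed common/obesity/APA rows: 21 + 7 + 7 variants
        assert summary["per_line"]["Fat"]["n_pas_snps"] == 19
        assert summary["per_line"]["Lean"]["n_pas_snps"] == 16
        assert summary["n_common_genes"] == 8
        assert summary["gene_sets"]["obesity"] == {
            "n_pas_snps": 7, "n_genes": 6,
        }
        assert summary["gene_sets"]["apa"] == {"n_pas_snps": 7, "n_genes": 7}

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError):
            load_pas_catalogue(path)
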