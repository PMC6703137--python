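"""Evidence integration: QTL intersection, cis windows, DE overlays, the matrix."""

import pytest

from sepfun.errors import ParameterError
from sepfun.integrate import (
    build_evidence_matrix,
    filter_cytokine_qtl,
    intersect_eqtl,
    map_cis_genes,
    overlay_patient_de,
    overlay_pbmc_de,
)
from sepfun.loci import clump_loci
from sepfun.types import DERecord, GeneModel, GwasVariant, Locus, ProxySet, QTLRecord


def locus(rsid="rsL", pos=1_000_000, chrom="chr1", p=1e-6):
    v = GwasVariant(rsid, chrom, pos, p, "s")
    return Locus(v, (v,))


class TestIntersectEqtl:
    def test_fixture_reproduces_locus_and_gene_counts(self, fixture_loci, locus_fixture):
        _, eqtl, _ = locus_fixture
        hits = intersect_eqtl(fixture_loci, None, eqtl)
        assert len(hits) == 13
        genes = {g for m in hits.values() for g in m}
        assert len(genes) == 45
        assert len(hits["rs12490944"]) == 14
        assert len(hits["rs41461846"]) == 10
        assert len(hits["rs3844280"]) == 5

    def test_empty_catalog(self, fixture_loci):
        assert intersect_eqtl(fixture_loci, None, []) == {}

    def test_proxy_hit_counts_for_the_locus(self):
        loc = locus("rsLead")
        proxies = {"rsLead": ProxySet("rsLead", (("rsProxy", 1.0, 1.0),))}
        catalog = [QTLRecord("rsProxy", "eqtl", "GENE1", 1e-8)]
        hits = intersect_eqtl([loc], proxies, catalog)
        assert hits == {"rsLead": {"GENE1": catalog}}
        # without the proxy set the lead misses
        assert intersect_eqtl([loc], None, catalog) == {}

    def test_threshold_is_strict(self):
        loc = locus("rsLead")
        catalog = [QTLRecord("rsLead", "eqtl", "G", 1.829e-5)]
        assert intersect_eqtl([loc], None, catalog, p_max=1.829e-5) == {}

    def test_wrong_qtl_type_rejected(self):
        with pytest.raises(ParameterError):
            intersect_eqtl([locus()], None, [QTLRecord("rs1", "cytokine", "IL6_x_y_z", 0.01)])


class TestMapCisGenes:
    FLANK = 100_000

    def gene(self, start, end, chrom="chr1", name="G"):
        return GeneModel(name, name, chrom, start, end)

    def test_gene_ending_at_window_start_excluded(self):
        loc = locus(pos=1_000_001)  # 0-based 1_000_000
        g = self.gene(800_000, 900_000)  # ends exactly at window start
        assert map_cis_genes(loc, [g], self.FLANK) == []

    def test_gene_containing_lead_included(self):
        loc = locus(pos=1_000_001)
        g = self.gene(999_000, 1_001_000)
        assert map_cis_genes(loc, [g], 10) == [g]

    def test_offsets_around_flank(self):
        # genes at -150 kb, -50 kb, +99 kb from the lead; flank 100 kb keeps 2
        loc = locus(pos=1_000_001)
        g1 = self.gene(850_000, 855_000, name="far_left")
        g2 = self.gene(950_000, 955_000, name="near_left")
        g3 = self.gene(1_099_000, 1_104_000, name="near_right")
        got = map_cis_genes(loc, [g1, g2, g3], self.FLANK)
        assert [g.symbol for g in got] == ["near_left", "near_right"]

    def test_other_chromosome_never_cis(self):
        loc = locus(pos=1_000_001, chrom="chr2")
        assert map_cis_genes(loc, [self.gene(999_000, 1_001_000)], self.FLANK) == []


class TestOverlayPbmcDe:
    def test_inclusive_boundaries(self):
        de = [DERecord("G", "LPS_4h", 1.0, 0.05)]
        assert set(overlay_pbmc_de({"G"}, de)) == {"G"}

    def test_subthreshold_fold_change_excluded(self):
        de = [DERecord("G", c, 0.9, 0.001) for c in ("a", "b", "c")]
        assert overlay_pbmc_de({"G"}, de) == {}

    def test_or_over_conditions_and_both_directions(self):
        de = [
            DERecord("G", "a", 0.1, 0.9),
            DERecord("G", "b", -2.0, 0.01),  # suppressed counts too
            DERecord("H", "a", 3.0, 0.2),  # FDR fails
        ]
        assert set(overlay_pbmc_de({"G", "H"}, de)) == {"G"}


class TestOverlayPatientDe:
    def test_or_over_cohorts(self):
        disc = []
        valid = [DERecord("G", "severe_vs_mild", 1.0, 0.01)]  # FC=2 > 1.5
        assert set(overlay_patient_de({"G"}, disc, valid)) == {"G"}

    def test_fc_boundary_is_strict(self):
        import math

        lfc = math.log2(1.5)
        rec = [DERecord("G", "c", lfc, 0.01)]
        assert overlay_patient_de({"G"}, rec, []) == {}

    def test_down_regulation_counts(self):
        rec = [DERecord("G", "c", -1.0, 0.01)]
        assert set(overlay_patient_de({"G"}, rec, [])) == {"G"}


class TestFilterCytokineQtl:
    def test_fixture_nominal_and_bonferroni_tiers(self, fixture_loci, locus_fixture):
        _, _, cyt = locus_fixture
        hits = filter_cytokine_qtl(fixture_loci, None, cyt, 0.05, 39)
        assert len({h.locus_id for h in hits}) == 9
        assert len({h.trait.split("_")[0] for h in hits}) == 6
        bonf = {h.locus_id for h in hits if h.passes_bonferroni}
        assert bonf == {"rs2237499", "rs13380717"}

    def test_exact_bonferroni_threshold_not_the_rounded_one(self, fixture_loci, locus_fixture):
        # a p-value between 0.0012 (printed, rounded) and 0.05/39 (exact)
        loc = locus("rsQ")
        p_between = 0.00125
        assert 0.0012 < p_between < 0.05 / 39
        hits = filter_cytokine_qtl(
            [loc], None, [QTLRecord("rsQ", "cytokine", "IL6_LPS100ng_PBMC_24h", p_between)],
            0.05, 39,
        )
        assert hits[0].passes_bonferroni

    def test_empty_catalog(self, fixture_loci):
        assert filter_cytokine_qtl(fixture_loci, None, [], 0.05, 39) == []

    def test_n_tests_validation(self, fixture_loci):
        with pytest.raises(ParameterError):
            filter_cytokine_qtl(fixture_loci, None, [], 0.05, 0)


class TestBuildEvidenceMatrix:
    def test_disjoint_union(self):
        eqtl = {"L1": {"A": [QTLRecord("rs1", "eqtl", "A", 1e-8)],
                       "B": [QTLRecord("rs1", "eqtl", "B", 1e-8)],
                       "C": [QTLRecord("rs1", "eqtl", "C", 1e-8)]}}
        cis_de = {"L2": {"D": [DERecord("D", "c", 2.0, 0.01)],
                         "E": [DERecord("E", "c", 2.0, 0.01)]}}
        rows = build_evidence_matrix(eqtl, cis_de, {}, [])
        assert len(rows) == 5
        assert [(r.locus_id, r.gene) for r in rows] == sorted(
            [("L1", "A"), ("L1", "B"), ("L1", "C"), ("L2", "D"), ("L2", "E")]
        )

    def test_gene_in_both_classes_one_row_both_flags(self):
        eqtl = {"L1": {"A": [QTLRecord("rs1", "eqtl", "A", 1e-8)]}}
        cis_de = {"L1": {"A": [DERecord("A", "c", 2.0, 0.01)]}}
        (row,) = build_evidence_matrix(eqtl, cis_de, {}, [])
        assert row.has_eqtl and row.has_pbmc_de

    def test_annotations_do_not_add_rows(self):
        # patient DE and cytokine hits alone cannot prioritize a gene
        rows = build_evidence_matrix({}, {}, {"X": [DERecord("X", "c", 2.0, 0.01)]}, [])
        assert rows == []

    def test_every_flag_has_provenance(self):
        eqtl = {"L1": {"A": [QTLRecord("rs1", "eqtl", "A", 1e-8)]}}
        cis_de = {"L1": {"A": [DERecord("A", "c", 2.0, 0.01)]}}
        patient = {"A": [DERecord("A", "sev", 1.2, 0.001)]}
        (row,) = build_evidence_matrix(eqtl, cis_de, patient, [])
        classes = {p.evidence_class for p in row.provenance}
        assert {"eqtl", "pbmc_de", "patient_de"} <= classes

    def test_monotone_in_evidence(self):
        # removing a catalog record never adds a gene
        eqtl_two = {"L1": {"A": [QTLRecord("rs1", "eqtl", "A", 1e-8)],
                           "B": [QTLRecord("rs1", "eqtl", "B", 1e-8)]}}
        eqtl_one = {"L1": {"A": [QTLRecord("rs1", "eqtl", "A", 1e-8)]}}
        genes_two = {r.gene for r in build_evidence_matrix(eqtl_two, {}, {}, [])}
        genes_one = {r.gene for r in build_evidence_matrix(eqtl_one, {}, {}, [])}
        assert genes_one <= genes_two
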