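"""Generator structure: founder-model LD, determinism, manifest recovery."""

import numpy as np
import pytest

from sepfun import io as catalog_io
from sepfun.errors import CapacityError, ParameterError
from sepfun.integrate import (
    filter_cytokine_qtl,
    intersect_eqtl,
    map_cis_genes,
    overlay_patient_de,
    overlay_pbmc_de,
)
from sepfun.ld import compute_ld, select_proxies
from sepfun.loci import clump_loci, filter_suggestive
from sepfun.simulate import (
    headline_preset,
    simulate_haplotype_panel,
    simulate_study,
)


class TestHaplotypePanel:
    def test_degenerate_single_founder_guard(self):
        # one founder, no mutation: every column would be monomorphic, so the
        # resampling guard must have produced polymorphic columns throughout
        panel = simulate_haplotype_panel(10, 2, 5, n_founders=1, mutation_rate=0.0, seed=0)
        freqs = panel.haplotypes.mean(axis=0)
        assert ((freqs > 0) & (freqs < 1)).all()

    def test_two_founders_no_mutation_gives_dprime_one(self):
        panel = simulate_haplotype_panel(25, 3, 6, n_founders=2, mutation_rate=0.0, seed=3)
        blocks = [list(range(b * 6, (b + 1) * 6)) for b in range(3)]
        for block in blocks:
            for i in block:
                for j in block:
                    if i >= j:
                        continue
                    ld = compute_ld(panel.haplotypes[:, i], panel.haplotypes[:, j])
                    assert ld.dprime == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_identical(self):
        a = simulate_haplotype_panel(10, 2, 4, seed=42)
        b = simulate_haplotype_panel(10, 2, 4, seed=42)
        assert a.variant_ids == b.variant_ids
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_blocks_are_separated_beyond_clump_window(self):
        panel = simulate_haplotype_panel(5, 3, 4, seed=1)
        gaps = np.diff(panel.positions)
        assert (gaps[gaps > 10_000] > 1_000_000).all()

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            simulate_haplotype_panel(0, 1, 1)
        with pytest.raises(ParameterError):
            simulate_haplotype_panel(1, 1, 1, mutation_rate=0.6)


def run_all_stages(study, n_tests):
    """Drive every pipeline stage from the emitted files."""
    variants = catalog_io.read_gwas_table(study.gwas, "simulated")
    panel = catalog_io.read_haplotype_panel(study.panel)
    loci = clump_loci(filter_suggestive(variants, 1e-5))
    proxy_sets = {loc.locus_id: select_proxies(loc.locus_id, panel) for loc in loci}
    eqtl = catalog_io.read_qtl_catalog(study.eqtl, "eqtl")
    cyt = catalog_io.read_qtl_catalog(study.cytokine, "cytokine")
    genes = catalog_io.read_gene_annotation(study.genes, "bed")
    pbmc = catalog_io.read_de_table(study.pbmc_de)
    disc = catalog_io.read_de_table(study.patient_de_discovery)
    valid = catalog_io.read_de_table(study.patient_de_validation)
    eqtl_hits = intersect_eqtl(loci, proxy_sets, eqtl)
    cis = {loc.locus_id: {g.symbol for g in map_cis_genes(loc, genes)} for loc in loci}
    all_cis = set().union(*cis.values()) if cis else set()
    pbmc_hits = overlay_pbmc_de(all_cis, pbmc)
    cyt_hits = filter_cytokine_qtl(loci, proxy_sets, cyt, 0.05, n_tests)
    eqtl_genes = {g for m in eqtl_hits.values() for g in m}
    prioritized = eqtl_genes | set(pbmc_hits)
    patient_hits = overlay_patient_de(prioritized, disc, valid)
    return dict(
        loci=loci, proxy_sets=proxy_sets, eqtl_hits=eqtl_hits, cis=cis,
        pbmc_hits=pbmc_hits, cyt_hits=cyt_hits, patient_hits=patient_hits,
        prioritized=prioritized,
    )


@pytest.fixture(scope="module")
def study(tmp_path_factory):
    panel = simulate_haplotype_panel(40, 12, 7, seed=9)
    return simulate_study(panel, 10, 0.3, 0.2, 0.5, seed=9,
                          out_dir=tmp_path_factory.mktemp("sim"),
                          n_cis_de_only=2)


class TestSimulateStudy:
    def test_manifest_predicts_every_stage(self, study):
        """Planted truth is recovered exactly at each stage (recall & precision 1)."""
        sim, manifest = study
        got = run_all_stages(sim, n_tests=10)
        assert [loc.locus_id for loc in got["loci"]] == manifest.lead_rsids
        for lead, proxies in manifest.planted_proxies.items():
            assert sorted(r for r, _, _ in got["proxy_sets"][lead].proxies) == proxies
        assert {
            loc: sorted(genes) for loc, genes in (
                (k, v.keys()) for k, v in got["eqtl_hits"].items()
            )
        } == manifest.expected_eqtl_genes
        for lead, genes in manifest.expected_cis_genes.items():
            assert got["cis"][lead] == set(genes)
        assert sorted(got["pbmc_hits"]) == manifest.expected_pbmc_de_genes
        assert sorted(
            (h.locus_id, h.trait, h.passes_bonferroni) for h in got["cyt_hits"]
        ) == sorted((l, t, b) for l, t, _, b in manifest.expected_cytokine_hits)
        assert sorted(got["patient_hits"]) == manifest.expected_patient_de_genes
        assert sorted(got["prioritized"]) == manifest.expected_prioritized

    def test_fraction_counts(self, study):
        _, manifest = study
        assert len(manifest.planted_loci) == 10
        assert len(manifest.expected_eqtl_genes) == 3  # round(10 * 0.3)
        assert len(manifest.expected_cytokine_hits) == 2  # round(10 * 0.2)

    def test_all_files_parse_through_catalog_io(self, study):
        sim, _ = study
        assert len(catalog_io.read_gwas_table(sim.gwas, "s")) > 0
        assert catalog_io.read_haplotype_panel(sim.panel).n_variants == 84
        assert len(catalog_io.read_gene_annotation(sim.genes, "bed")) > 0
        assert len(catalog_io.read_gmt(sim.pathways)) > 0

    def test_zero_fractions_empty_evidence(self, tmp_path):
        panel = simulate_haplotype_panel(20, 4, 5, seed=2)
        sim, manifest = simulate_study(panel, 4, 0.0, 0.0, 0.0, seed=2, out_dir=tmp_path)
        got = run_all_stages(sim, n_tests=4)
        assert manifest.expected_prioritized == []
        assert got["prioritized"] == set()
        assert got["cyt_hits"] == []

    def test_saturated_de_overlap(self, tmp_path):
        panel = simulate_haplotype_panel(20, 6, 5, seed=4)
        _, manifest = simulate_study(panel, 5, 0.6, 0.0, 1.0, seed=4, out_dir=tmp_path)
        eqtl_genes = {g for gs in manifest.expected_eqtl_genes.values() for g in gs}
        assert eqtl_genes <= set(manifest.expected_pbmc_de_genes)

    def test_capacity_error(self, tmp_path):
        panel = simulate_haplotype_panel(10, 2, 5, seed=0)
        with pytest.raises(CapacityError):
            simulate_study(panel, 3, 0.5, 0.0, 0.0, seed=0, out_dir=tmp_path)


class TestPaperShapePreset:
    def test_count_skeleton(self, preset_study):
        _, manifest = preset_study
        assert len(manifest.planted_loci) == 39
        assert len(manifest.expected_eqtl_genes) == 13
        assert sum(len(v) for v in manifest.expected_eqtl_genes.values()) == 45
        assert len(manifest.expected_prioritized) == 55
        assert len(manifest.expected_cytokine_hits) == 9
        assert sum(1 for *_, b in manifest.expected_cytokine_hits if b) == 2
        assert len(manifest.expected_patient_de_genes) == 7

    def test_shape_invariant_across_seeds(self, preset_study, tmp_path):
        _, m17 = preset_study
        _, m99 = headline_preset(99, tmp_path)
        assert len(m99.planted_loci) == len(m17.planted_loci)
        assert len(m99.expected_prioritized) == len(m17.expected_prioritized)
        # but the variant namespace differs
        assert set(m99.lead_rsids) != set(m17.lead_rsids)
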