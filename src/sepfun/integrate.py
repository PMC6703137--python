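"""Multi-evidence gene prioritization at GWAS loci.

Four evidence classes are intersected with each independent locus:

* whole-blood cis-eQTLs (any SNP in the locus snp_set, lead or proxy, with an
  expression association below the catalog's genome-wide FDR-0.05 cutoff,
  P < 1.829e-5);
* differential expression of cis-window genes (lead +- 100 kb by default) in
  pathogen-stimulated PBMCs (FDR <= 0.05 and |log2FC| >= 1, i.e. >= 2-fold in
  either direction, in at least one stimulation condition);
* differential expression between severe and mild sepsis patients
  (|FC| > 1.5 strictly, FDR < 0.05, in either the discovery or the
  validation cohort);
* cytokine QTLs from stimulated PBMCs (nominal P < 0.05 per locus x trait,
  with an exact Bonferroni threshold 0.05/n_tests for the stringent tier).

A gene is *prioritized* when it has an eQTL link or is a cis-window gene
that responds to PBMC stimulation; patient DE and cytokine evidence are
annotations on top of that set, not inclusion criteria. Every flag carries
provenance back to the record that set it.
"""

from __future__ import annotations

from .errors import ParameterError
from .types import (
    DERecord,
    EvidenceRow,
    GeneModel,
    Locus,
    LocusCytokineHit,
    Provenance,
    ProxySet,
    QTLRecord,
)

EQTL_P_MAX = 1.829e-5  # FDR<0.05 cutoff of the whole-blood cis-eQTL catalog
CIS_FLANK_BP = 100_000  # half of the 200 kb cis window around a lead SNP


def _snp_set(locus: Locus, proxy_sets: dict[str, ProxySet] | None) -> set[str]:
    rsids = {m.rsid for m in locus.members}
    if proxy_sets and locus.locus_id in proxy_sets:
        rsids.update(proxy_sets[locus.locus_id].snp_set)
    return rsids


def intersect_eqtl(
    loci: list[Locus],
    proxy_sets: dict[str, ProxySet] | None,
    catalog: list[QTLRecord],
    p_max: float = EQTL_P_MAX,
) -> dict[str, dict[str, list[QTLRecord]]]:
    """Map each locus to the genes its SNP set regulates in the eQTL catalog.

    Returns {locus_id: {gene: [records]}}; a locus hits a gene iff any SNP
    of its snp_set (members plus proxies) carries an eQTL for that gene
    with pvalue < p_max. Loci without hits are absent from the result.
    """
    bad = [r for r in catalog if r.qtl_type != "eqtl"]
    if bad:
        raise ParameterError(
            f"intersect_eqtl needs an eqtl catalog; found qtl_type "
            f"{bad[0].qtl_type!r} for {bad[0].snp_rsid}"
        )
    by_snp: dict[str, list[QTLRecord]] = {}
    for rec in catalog:
        if rec.pvalue < p_max:
            by_snp.setdefault(rec.snp_rsid, []).append(rec)
    hits: dict[str, dict[str, list[QTLRecord]]] = {}
    for locus in loci:
        genes: dict[str, list[QTLRecord]] = {}
        for rsid in sorted(_snp_set(locus, proxy_sets)):
            for rec in by_snp.get(rsid, ()):
                genes.setdefault(rec.phenotype, []).append(rec)
        if genes:
            hits[locus.locus_id] = genes
    return hits


def map_cis_genes(
    locus: Locus, genes: list[GeneModel], flank_bp: int = CIS_FLANK_BP
) -> list[GeneModel]:
    """Genes overlapping the half-open window lead +- flank_bp (strand-agnostic).

    The lead's 1-based position is converted to 0-based once so the window
    and the gene intervals share the BED convention.
    """
    if flank_bp <= 0:
        raise ParameterError(f"flank_bp must be positive, got {flank_bp}")
    pos0 = locus.lead.pos - 1
    lo, hi = pos0 - flank_bp, pos0 + flank_bp
    return [
        g
        for g in genes
        if g.chrom == locus.lead.chrom and g.overlaps(lo, hi)
    ]


def overlay_pbmc_de(
    genes: set[str],
    de: list[DERecord],
    fdr_max: float = 0.05,
    abs_log2fc_min: float = 1.0,
) -> dict[str, list[DERecord]]:
    """Genes responding to PBMC stimulation in at least one condition.

    Thresholds are inclusive (FDR <= fdr_max, |log2FC| >= abs_log2fc_min)
    and both directions count. Returns {gene: passing records}.
    """
    hits: dict[str, list[DERecord]] = {}
    for rec in de:
        if (
            rec.gene in genes
            and rec.fdr <= fdr_max
            and abs(rec.log2fc) >= abs_log2fc_min
        ):
            hits.setdefault(rec.gene, []).append(rec)
    return hits


def overlay_patient_de(
    genes: set[str],
    de_discovery: list[DERecord],
    de_validation: list[DERecord],
    fc_min: float = 1.5,
    fdr_max: float = 0.05,
) -> dict[str, list[DERecord]]:
    """Genes differentially expressed between severe and mild patients.

    A gene passes with |FC| > fc_min (strict, on the linear scale) and
    FDR < fdr_max in the discovery OR the validation cohort.
    """
    hits: dict[str, list[DERecord]] = {}
    for rec in list(de_discovery) + list(de_validation):
        if rec.gene in genes and rec.fold_change > fc_min and rec.fdr < fdr_max:
            hits.setdefault(rec.gene, []).append(rec)
    return hits


def filter_cytokine_qtl(
    loci: list[Locus],
    proxy_sets: dict[str, ProxySet] | None,
    catalog: list[QTLRecord],
    nominal_p: float = 0.05,
    n_tests: int = 39,
) -> list[LocusCytokineHit]:
    """Locus x cytokine-trait hits at nominal significance, flagged for Bonferroni.

    One hit per (locus, trait) pair with the minimal p-value over the locus
    snp_set; ``passes_bonferroni`` uses the exact threshold nominal_p / n_tests.
    """
    if n_tests < 1:
        raise ParameterError(f"n_tests must be >= 1, got {n_tests}")
    bad = [r for r in catalog if r.qtl_type != "cytokine"]
    if bad:
        raise ParameterError(
            f"filter_cytokine_qtl needs a cytokine catalog; found qtl_type "
            f"{bad[0].qtl_type!r} for {bad[0].snp_rsid}"
        )
    bonferroni_p = nominal_p / n_tests
    by_snp: dict[str, list[QTLRecord]] = {}
    for rec in catalog:
        by_snp.setdefault(rec.snp_rsid, []).append(rec)
    hits: list[LocusCytokineHit] = []
    for locus in loci:
        best: dict[str, float] = {}
        for rsid in _snp_set(locus, proxy_sets):
            for rec in by_snp.get(rsid, ()):
                if rec.pvalue < nominal_p:
                    prev = best.get(rec.phenotype)
                    if prev is None or rec.pvalue < prev:
                        best[rec.phenotype] = rec.pvalue
        for trait in sorted(best):
            p = best[trait]
            hits.append(
                LocusCytokineHit(
                    locus_id=locus.locus_id,
                    trait=trait,
                    pvalue=p,
                    passes_nominal=True,
                    passes_bonferroni=p < bonferroni_p,
                )
            )
    return hits


def build_evidence_matrix(
    eqtl_hits: dict[str, dict[str, list[QTLRecord]]],
    cis_de_hits: dict[str, dict[str, list[DERecord]]],
    patient_de_hits: dict[str, list[DERecord]],
    cytokine_hits: list[LocusCytokineHit],
    pbmc_de_genes: dict[str, list[DERecord]] | None = None,
) -> list[EvidenceRow]:
    """Combine the evidence classes into the prioritized-gene table.

    Inclusion: a (locus, gene) pair enters the table iff the gene has an
    eQTL link at that locus or is a cis-window gene that passed the PBMC DE
    overlay there. ``pbmc_de_genes`` (defaulting to the union of
    ``cis_de_hits``) additionally flags eQTL genes that also respond to
    stimulation. Rows are sorted by (locus, gene).
    """
    if pbmc_de_genes is None:
        pbmc_de_genes = {}
        for gene_map in cis_de_hits.values():
            for gene, recs in gene_map.items():
                pbmc_de_genes.setdefault(gene, []).extend(recs)
    cytokine_loci = {h.locus_id for h in cytokine_hits}
    cytokine_prov: dict[str, list[Provenance]] = {}
    for h in cytokine_hits:
        cytokine_prov.setdefault(h.locus_id, []).append(
            Provenance("cytokine", f"{h.locus_id}:{h.trait}", h.pvalue)
        )

    pairs: set[tuple[str, str]] = set()
    for locus_id, gene_map in eqtl_hits.items():
        pairs.update((locus_id, gene) for gene in gene_map)
    for locus_id, gene_map in cis_de_hits.items():
        pairs.update((locus_id, gene) for gene in gene_map)

    rows: list[EvidenceRow] = []
    for locus_id, gene in sorted(pairs):
        prov: list[Provenance] = []
        has_eqtl = gene in eqtl_hits.get(locus_id, {})
        if has_eqtl:
            for rec in eqtl_hits[locus_id][gene]:
                prov.append(Provenance("eqtl", f"{rec.snp_rsid}:{gene}", rec.pvalue))
        has_pbmc_de = gene in pbmc_de_genes
        if has_pbmc_de:
            for rec in pbmc_de_genes[gene]:
                prov.append(Provenance("pbmc_de", f"{gene}:{rec.contrast}", rec.fdr))
        has_patient_de = gene in patient_de_hits
        if has_patient_de:
            for rec in patient_de_hits[gene]:
                prov.append(
                    Provenance("patient_de", f"{gene}:{rec.contrast}", rec.fdr)
                )
        locus_cyt = locus_id in cytokine_loci
        if locus_cyt:
            prov.extend(cytokine_prov[locus_id])
        rows.append(
            EvidenceRow(
                gene=gene,
                locus_id=locus_id,
                has_eqtl=has_eqtl,
                has_pbmc_de=has_pbmc_de,
                has_patient_de=has_patient_de,
                locus_has_cytokine_qtl=locus_cyt,
                provenance=tuple(prov),
            )
        )
    return rows
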