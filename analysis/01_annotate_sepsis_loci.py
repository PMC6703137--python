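#!/usr/bin/env python
"""Annotate the 39 suggestive sepsis GWAS loci from the packaged QTL table.

The packaged fixture carries, per lead SNP of the three sepsis GWAS
(survival in two adult cohorts, onset in premature infants), the catalogued
whole-blood cis-eQTL genes and stimulated-PBMC cytokine QTL traits. This
driver clumps the leads into independent loci, intersects them with both
catalogs at the catalog thresholds, and reports the aggregate counts.
"""

import json
from pathlib import Path

from sepfun import io as catalog_io
from sepfun.integrate import build_evidence_matrix, filter_cytokine_qtl, intersect_eqtl
from sepfun.loci import clump_loci, filter_suggestive
from sepfun.pipeline import summarize_counts

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "sepsis_loci"
OUT.mkdir(parents=True, exist_ok=True)

leads, eqtl, cytokine = catalog_io.load_locus_qtl_fixture()
variants = catalog_io.fixture_lead_gwas()
loci = clump_loci(filter_suggestive(variants, 1e-5))
catalog_io.write_loci_table(loci, OUT / "loci.tsv")
print(f"{len(variants)} suggestive lead SNPs -> {len(loci)} independent loci")

eqtl_hits = intersect_eqtl(loci, None, eqtl, p_max=1.829e-5)
genes = sorted({g for m in eqtl_hits.values() for g in m})
with open(OUT / "eqtl_genes.tsv", "w") as fh:
    fh.write("locus\tgene\tp\n")
    for locus in sorted(eqtl_hits):
        for gene, recs in sorted(eqtl_hits[locus].items()):
            fh.write(f"{locus}\t{gene}\t{min(r.pvalue for r in recs)!r}\n")
print(
    f"{len(eqtl_hits)} loci regulate {len(genes)} unique genes in whole blood; "
    "busiest loci: "
    + ", ".join(
        f"{rs} ({len(eqtl_hits[rs])} genes)"
        for rs in sorted(eqtl_hits, key=lambda r: -len(eqtl_hits[r]))[:3]
    )
)

cyt_hits = filter_cytokine_qtl(loci, None, cytokine, nominal_p=0.05, n_tests=len(loci))
catalog_io.write_cytokine_hits(cyt_hits, OUT / "cytokine_hits.tsv")
cyt_loci = {h.locus_id for h in cyt_hits}
bonf = {h.locus_id for h in cyt_hits if h.passes_bonferroni}
cytokines = {h.trait.split("_")[0] for h in cyt_hits}
print(
    f"{len(cyt_loci)} loci alter production of {len(cytokines)} cytokines "
    f"at nominal P < 0.05; {len(bonf)} loci ({', '.join(sorted(bonf))}) "
    f"survive Bonferroni at 0.05/{len(loci)}"
)

evidence = build_evidence_matrix(eqtl_hits, {}, {}, cyt_hits)
summary = summarize_counts(evidence, loci, cyt_hits, n_input_snps=len(variants))
summary.to_json(OUT / "summary.json")
print(
    f"{summary.pct_eqtl_loci_int}% of loci have eQTL genes, "
    f"{summary.pct_cytokine_loci_int}% affect cytokine production "
    f"(summary -> {(OUT / 'summary.json').relative_to(ROOT)})"
)
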