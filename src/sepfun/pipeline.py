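"""End-to-end orchestration and summary counts.

``run_pipeline`` drives clump -> proxies -> integrate -> score -> enrich ->
report from a flat config mapping (or YAML file) and writes deterministic
TSV/JSON outputs; ``summarize_counts`` reduces the evidence table to the
aggregate counts and percentages the annotation reports (fraction of loci
with eQTL genes, with cytokine effects, prioritized gene totals, ...).
Percentages are reported at one decimal (round half-up) and as the nearest
integer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import yaml

from . import io as catalog_io
from .errors import ParameterError, PipelineStageError, SepfunError
from .integrate import (
    build_evidence_matrix,
    filter_cytokine_qtl,
    intersect_eqtl,
    map_cis_genes,
    overlay_patient_de,
    overlay_pbmc_de,
)
from .ld import select_proxies
from .loci import clump_loci, filter_suggestive
from .scores import pathway_enrichment, score_genes_in_windows
from .types import EvidenceRow, Locus, LocusCytokineHit

log = logging.getLogger("sepfun")


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PipelineSummary:
    """Aggregate counts of one pipeline run."""

    n_input_snps: int
    n_loci: int
    n_proxies: int
    n_eqtl_loci: int
    n_eqtl_genes: int
    n_pbmc_de_of_eqtl: int
    n_prioritized: int
    n_patient_de: int
    n_cytokine_loci_nominal: int
    n_cytokine_loci_bonferroni: int
    pct_eqtl_loci: float  # 1 decimal, round half-up
    pct_eqtl_loci_int: int
    pct_cytokine_loci: float
    pct_cytokine_loci_int: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def percent(count: int, denominator: int) -> tuple[float, int]:
    """100 * count / denominator as (1-decimal half-up, nearest integer)."""
    if denominator <= 0:
        raise ParameterError("percentage denominator must be positive")
    value = 100.0 * count / denominator
    return _round_half_up(value, 1), int(_round_half_up(value, 0))


def summarize_counts(
    evidence: list[EvidenceRow],
    loci: list[Locus],
    cytokine_hits: list[LocusCytokineHit],
    n_input_snps: int = 0,
    n_proxies: int = 0,
) -> PipelineSummary:
    """Reduce the evidence matrix to the report's aggregate counts."""
    if not loci:
        raise ParameterError("cannot summarize with zero loci")
    n_loci = len(loci)
    eqtl_loci = {r.locus_id for r in evidence if r.has_eqtl}
    eqtl_genes = {r.gene for r in evidence if r.has_eqtl}
    pbmc_of_eqtl = {r.gene for r in evidence if r.has_eqtl and r.has_pbmc_de}
    prioritized = {r.gene for r in evidence}
    patient = {r.gene for r in evidence if r.has_patient_de}
    cyt_nominal = {h.locus_id for h in cytokine_hits}
    cyt_bonf = {h.locus_id for h in cytokine_hits if h.passes_bonferroni}
    pct_eqtl, pct_eqtl_int = percent(len(eqtl_loci), n_loci)
    pct_cyt, pct_cyt_int = percent(len(cyt_nominal), n_loci)
    return PipelineSummary(
        n_input_snps=n_input_snps,
        n_loci=n_loci,
        n_proxies=n_proxies,
        n_eqtl_loci=len(eqtl_loci),
        n_eqtl_genes=len(eqtl_genes),
        n_pbmc_de_of_eqtl=len(pbmc_of_eqtl),
        n_prioritized=len(prioritized),
        n_patient_de=len(patient),
        n_cytokine_loci_nominal=len(cyt_nominal),
        n_cytokine_loci_bonferroni=len(cyt_bonf),
        pct_eqtl_loci=pct_eqtl,
        pct_eqtl_loci_int=pct_eqtl_int,
        pct_cytokine_loci=pct_cyt,
        pct_cytokine_loci_int=pct_cyt_int,
    )


DEFAULT_CONFIG = {
    "suggestive_p_max": 1e-5,  # strict '<'; 9.99e-5 is the permissive variant
    "clump_window_bp": 1_000_000,
    "r2_min": 0.95,
    "dprime_min": 1.0,
    "proxy_window_bp": 500_000,
    "snp_set": "proxies",  # or "lead"
    "eqtl_p_max": 1.829e-5,
    "flank_bp": 100_000,
    "pbmc_fdr_max": 0.05,
    "pbmc_abs_log2fc_min": 1.0,
    "patient_fc_min": 1.5,
    "patient_fdr_max": 0.05,
    "cytokine_nominal_p": 0.05,
    "n_tests": None,  # default: number of independent loci
    "score_method": "sum_chi2_satterthwaite",
    "score_mc_reps": 100_000,
    "score_flank_bp": 100_000,
    "enrich_alpha": 0.05,
    "seed": 0,
}


def run_pipeline(config) -> tuple[PipelineSummary, dict[str, Path]]:
    """Run the full annotation from a config mapping or YAML file path.

    The config names the input files (``gwas`` as a list of {path, study}
    mappings, ``panel``, ``eqtl``, ``cytokine``, ``genes``, ``pbmc_de``,
    ``patient_de_discovery``, ``patient_de_validation``, optional ``gmt``)
    plus ``out_dir``; every threshold has the catalog default and is logged.
    Gene scoring and pathway enrichment run when ``panel``/``gmt`` are
    present. A fixed ``seed`` makes every output byte-identical across runs.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **config}
    for key in sorted(DEFAULT_CONFIG):
        log.info("config %s = %r", key, cfg[key])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except SepfunError as exc:
            raise PipelineStageError(name, str(exc)) from exc

    # clump ----------------------------------------------------------------
    gwas_specs = cfg["gwas"]
    if isinstance(gwas_specs, (str, Path)):
        gwas_specs = [{"path": gwas_specs, "study": "study"}]
    variants = []
    for spec in gwas_specs:
        variants.extend(
            stage("clump", catalog_io.read_gwas_table, spec["path"], spec["study"])
        )
    suggestive = stage(
        "clump", filter_suggestive, variants, cfg["suggestive_p_max"]
    )
    if not suggestive:
        raise PipelineStageError("clump", "no suggestive SNPs below threshold")
    loci = stage("clump", clump_loci, suggestive, cfg["clump_window_bp"])
    outputs["loci"] = out_dir / "loci.tsv"
    catalog_io.write_loci_table(loci, outputs["loci"])
    log.info("clump: %d suggestive SNPs -> %d independent loci", len(suggestive), len(loci))

    # proxies ----------------------------------------------------------------
    proxy_sets = {}
    panel = None
    if cfg.get("panel"):
        panel = stage("proxies", catalog_io.read_haplotype_panel, cfg["panel"])
        if cfg["snp_set"] == "proxies":
            for locus in loci:
                if locus.locus_id in panel._index:
                    proxy_sets[locus.locus_id] = stage(
                        "proxies",
                        select_proxies,
                        locus.locus_id,
                        panel,
                        cfg["r2_min"],
                        cfg["dprime_min"],
                        cfg["proxy_window_bp"],
                    )
            outputs["proxies"] = out_dir / "proxies.tsv"
            catalog_io.write_proxy_table(proxy_sets, outputs["proxies"])
    n_proxies = sum(len(ps.proxies) for ps in proxy_sets.values())
    log.info("proxies: %d proxies for %d leads", n_proxies, len(proxy_sets))

    # integrate --------------------------------------------------------------
    eqtl_catalog = stage(
        "integrate", catalog_io.read_qtl_catalog, cfg["eqtl"], "eqtl"
    )
    cyt_catalog = stage(
        "integrate", catalog_io.read_qtl_catalog, cfg["cytokine"], "cytokine"
    )
    genes = stage(
        "integrate",
        catalog_io.read_gene_annotation,
        cfg["genes"],
        cfg.get("genes_dialect", "bed"),
    )
    pbmc_de = stage("integrate", catalog_io.read_de_table, cfg["pbmc_de"])
    patient_disc = stage(
        "integrate", catalog_io.read_de_table, cfg["patient_de_discovery"]
    )
    patient_valid = stage(
        "integrate", catalog_io.read_de_table, cfg["patient_de_validation"]
    )

    eqtl_hits = stage(
        "integrate", intersect_eqtl, loci, proxy_sets, eqtl_catalog, cfg["eqtl_p_max"]
    )
    cis_de_hits = {}
    all_cis_genes: set[str] = set()
    for locus in loci:
        cis = {g.symbol for g in map_cis_genes(locus, genes, cfg["flank_bp"])}
        all_cis_genes |= cis
        de_here = overlay_pbmc_de(
            cis, pbmc_de, cfg["pbmc_fdr_max"], cfg["pbmc_abs_log2fc_min"]
        )
        if de_here:
            cis_de_hits[locus.locus_id] = de_here
    eqtl_gene_set = {g for m in eqtl_hits.values() for g in m}
    pbmc_de_genes = overlay_pbmc_de(
        all_cis_genes | eqtl_gene_set,
        pbmc_de,
        cfg["pbmc_fdr_max"],
        cfg["pbmc_abs_log2fc_min"],
    )
    n_tests = cfg["n_tests"] or len(loci)
    cytokine_hits = stage(
        "integrate",
        filter_cytokine_qtl,
        loci,
        proxy_sets,
        cyt_catalog,
        cfg["cytokine_nominal_p"],
        n_tests,
    )
    outputs["cytokine_hits"] = out_dir / "cytokine_hits.tsv"
    catalog_io.write_cytokine_hits(cytokine_hits, outputs["cytokine_hits"])
    prioritized_pool = eqtl_gene_set | {
        g for m in cis_de_hits.values() for g in m
    }
    patient_hits = overlay_patient_de(
        prioritized_pool,
        patient_disc,
        patient_valid,
        cfg["patient_fc_min"],
        cfg["patient_fdr_max"],
    )
    evidence = stage(
        "integrate",
        build_evidence_matrix,
        eqtl_hits,
        cis_de_hits,
        patient_hits,
        cytokine_hits,
        pbmc_de_genes,
    )
    outputs["evidence"] = out_dir / "evidence.tsv"
    catalog_io.write_evidence_table(evidence, outputs["evidence"])
    log.info("integrate: %d evidence rows", len(evidence))

    # score / enrich ---------------------------------------------------------
    if panel is not None:
        scores = stage(
            "score",
            score_genes_in_windows,
            variants,
            panel,
            genes,
            cfg["score_flank_bp"],
            cfg["score_method"],
            cfg["score_mc_reps"],
            cfg["seed"],
        )
        outputs["scores"] = out_dir / "scores.tsv"
        catalog_io.write_gene_scores(scores, outputs["scores"])
        if cfg.get("gmt"):
            pathways = stage("enrich", catalog_io.read_gmt, cfg["gmt"])
            universe = {s.gene for s in scores}
            results = stage(
                "enrich",
                pathway_enrichment,
                scores,
                pathways,
                universe,
                cfg["enrich_alpha"],
            )
            outputs["pathways"] = out_dir / "pathways.tsv"
            catalog_io.write_pathway_results(results, outputs["pathways"])

    # report -----------------------------------------------------------------
    summary = stage(
        "report",
        summarize_counts,
        evidence,
        loci,
        cytokine_hits,
        len(variants),
        n_proxies,
    )
    outputs["summary"] = out_dir / "summary.json"
    summary.to_json(outputs["summary"])
    return summary, outputs
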