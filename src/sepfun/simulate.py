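"""Synthetic study generator with a ground-truth manifest.

Every input the annotation pipeline consumes can be generated here with
planted, exactly predictable structure:

* a phased haplotype panel from a block-copy founder model — within each LD
  block every haplotype copies one of a few founder haplotypes and then
  mutates each allele with a small probability, which yields strong
  intra-block LD (D' = 1 at mutation rate 0) and independent blocks;
* a GWAS table whose planted lead SNPs are far below the suggestive
  threshold and whose background SNPs are far above it;
* eQTL / cytokine-QTL catalogs with planted links well below the relevant
  significance cutoffs and decoy records well above them;
* gene models placed inside or outside the cis window on purpose, and DE
  tables whose planted effects clear the fold-change/FDR filters with a
  wide margin while decoys miss them by a wide margin.

Because the margins are sharp (roughly an order of magnitude on either side
of every threshold) the emitted :class:`TruthManifest` predicts every
pipeline stage's output exactly, which is what makes end-to-end recovery
tests non-flaky. ``headline_preset`` instantiates the study geometry the
pipeline is meant to reproduce: 39 independent loci, 13 of them with eQTL
genes totalling 45, 9 with nominal cytokine hits (2 surviving Bonferroni),
12 of the 45 eQTL genes responding to PBMC stimulation plus 10 cis-window
genes with stimulation response only, for 55 prioritized genes, 7 of which
differ between severe and mild patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import CapacityError, ParameterError
from . import io as catalog_io
from .types import DERecord, GeneModel, GwasVariant, HaplotypePanel, QTLRecord

SUGGESTIVE_P = 1e-5
EQTL_P_MAX = 1.829e-5
NOMINAL_P = 0.05

_TRAITS = (
    "IL6_LPS100ng_PBMC_24h",
    "IL1b_LPS100ng_PBMC_24h",
    "TNFA_Calbicansconidia_PBMC_24h",
    "IFNy_Calbicanshyphae_PBMC_7days",
    "IL17_Calbicansconidia_PBMC_7days",
    "IL22_Calbicansconidia_PBMC_7days",
)
_PBMC_CONTRASTS = (
    "Paeruginosa_4h",
    "Paeruginosa_24h",
    "Spneumoniae_4h",
    "Spneumoniae_24h",
    "Calbicans_4h",
    "Calbicans_24h",
)

_BLOCK_SPACING = 2_000_000  # bp between block starts; > clump window, > proxy window
_SNP_SPACING = 1_000


def simulate_haplotype_panel(
    n_individuals: int,
    n_blocks: int,
    snps_per_block: int,
    n_founders: int = 4,
    mutation_rate: float = 0.01,
    seed: int | None = None,
) -> HaplotypePanel:
    """Block-copy founder model for phased haplotypes on one chromosome.

    Each of the ``2 * n_individuals`` haplotypes copies one of ``n_founders``
    random founder haplotypes per block, then flips each allele with
    probability ``mutation_rate``. Blocks are independent and separated by
    ``2 Mb``; SNPs within a block are 1 kb apart. Monomorphic columns are
    made polymorphic by flipping one random haplotype's allele (a minimal
    perturbation that preserves the at-most-three-haplotype-classes
    structure, hence D' = 1, within a block).
    """
    if min(n_individuals, n_blocks, snps_per_block, n_founders) < 1:
        raise ParameterError("all counts must be >= 1")
    if not (0.0 <= mutation_rate < 0.5):
        raise ParameterError("mutation_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    blocks = []
    for _ in range(n_blocks):
        founders = rng.integers(0, 2, size=(n_founders, snps_per_block), dtype=np.int8)
        assignment = rng.integers(0, n_founders, size=n_hap)
        block = founders[assignment].copy()
        if mutation_rate > 0:
            flips = rng.random(block.shape) < mutation_rate
            block[flips] ^= 1
        blocks.append(block)
    hap = np.concatenate(blocks, axis=1)
    # resampling guard: force every column polymorphic
    for j in range(hap.shape[1]):
        col = hap[:, j]
        if col.min() == col.max():
            col[rng.integers(0, n_hap)] ^= 1
    id_base = int(rng.integers(1_000_000, 9_000_000))
    ids, positions = [], []
    for b in range(n_blocks):
        base = 500_000 + b * _BLOCK_SPACING
        for j in range(snps_per_block):
            ids.append(f"rs{id_base + b * snps_per_block + j}")
            positions.append(base + j * _SNP_SPACING)
    return HaplotypePanel(ids, positions, "chr1", hap)


def _blocks_of(panel: HaplotypePanel, gap_bp: int = 1_000_000) -> list[list[int]]:
    """Partition panel variant indices into blocks at position gaps > gap_bp."""
    blocks: list[list[int]] = [[0]]
    for i in range(1, panel.n_variants):
        if panel.positions[i] - panel.positions[i - 1] > gap_bp:
            blocks.append([])
        blocks[-1].append(i)
    return blocks


@dataclass
class TruthManifest:
    """Everything needed to predict each pipeline stage's output exactly."""

    seed: int
    n_tests: int
    planted_loci: list[tuple[str, str, int, float]]  # (rsid, chrom, pos, p)
    planted_proxies: dict[str, list[str]]  # lead -> proxy rsids
    planted_eqtl_links: list[tuple[str, str, float]]  # (snp rsid, gene, p)
    planted_cytokine_links: list[tuple[str, str, float]]  # (snp rsid, trait, p)
    planted_de_genes: dict[str, list[tuple[str, float, float]]]  # contrast -> rows
    expected_eqtl_genes: dict[str, list[str]]  # locus -> genes
    expected_cis_genes: dict[str, list[str]]  # locus -> genes inside the flank
    expected_cytokine_hits: list[tuple[str, str, float, bool]]  # + bonferroni flag
    expected_pbmc_de_genes: list[str]
    expected_patient_de_genes: list[str]
    expected_prioritized: list[str]
    locus_of_gene: dict[str, str] = field(default_factory=dict)

    @property
    def lead_rsids(self) -> list[str]:
        return [rsid for rsid, _, _, _ in self.planted_loci]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=list)


@dataclass
class SimulatedStudy:
    """Paths of the emitted input files, all parseable with ``sepfun.io``."""

    out_dir: Path
    gwas: Path
    panel: Path
    eqtl: Path
    cytokine: Path
    genes: Path
    pbmc_de: Path
    patient_de_discovery: Path
    patient_de_validation: Path
    pathways: Path
    manifest: Path


def simulate_study(
    panel: HaplotypePanel,
    n_planted_loci: int,
    eqtl_fraction: float,
    cytokine_fraction: float,
    de_overlap_fraction: float,
    seed: int,
    out_dir,
    *,
    eqtl_genes_per_locus: list[int] | None = None,
    n_proxies_per_locus: int = 2,
    n_cis_de_only: int = 0,
    n_bonferroni: int | None = None,
    n_patient_de: int | None = None,
    patient_up: int = 1,
    n_tests: int | None = None,
    flank_bp: int = 100_000,
) -> tuple[SimulatedStudy, TruthManifest]:
    """Plant a full study on top of a haplotype panel and write its inputs.

    One planted locus occupies one LD block of the panel: its middle SNP
    becomes the lead (suggestive GWAS p ~ U(1e-9, 1e-6); every other panel
    SNP gets a background p ~ U(1e-4, 1)), ``n_proxies_per_locus``
    neighbouring columns are overwritten with exact copies of the lead
    column (r2 = 1, D' = 1 proxies), and the remaining block columns are
    perturbed until their r2 with the lead is below 0.5, so the proxy set
    is exactly the planted one. eQTL / cytokine links alternate between the
    lead and its first proxy so both intersection paths are exercised.
    """
    for name, frac in (
        ("eqtl_fraction", eqtl_fraction),
        ("cytokine_fraction", cytokine_fraction),
        ("de_overlap_fraction", de_overlap_fraction),
    ):
        if not (0.0 <= frac <= 1.0):
            raise ParameterError(f"{name} must be in [0, 1], got {frac}")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blocks = _blocks_of(panel)
    if n_planted_loci > len(blocks):
        raise CapacityError(
            f"{n_planted_loci} planted loci requested but panel has only "
            f"{len(blocks)} LD blocks"
        )
    hap = panel.haplotypes.copy()
    n_hap = hap.shape[0]

    # --- plant loci, proxies, and LD structure -----------------------------
    locus_blocks = blocks[:n_planted_loci]
    leads: list[tuple[str, int]] = []  # (rsid, column index)
    proxies: dict[str, list[str]] = {}
    for block in locus_blocks:
        lead_idx = block[len(block) // 2]
        lead_rsid = panel.variant_ids[lead_idx]
        if hap[:, lead_idx].min() == hap[:, lead_idx].max():
            hap[rng.integers(0, n_hap), lead_idx] ^= 1
        others = [i for i in block if i != lead_idx]
        if len(others) < n_proxies_per_locus:
            raise CapacityError(
                f"block of {lead_rsid} too small for {n_proxies_per_locus} proxies"
            )
        proxy_idx = sorted(others, key=lambda i: abs(i - lead_idx))[
            :n_proxies_per_locus
        ]
        for i in proxy_idx:
            hap[:, i] = hap[:, lead_idx]
        for i in others:
            if i in proxy_idx:
                continue
            _decorrelate(hap, i, lead_idx, rng)
        leads.append((lead_rsid, lead_idx))
        proxies[lead_rsid] = [panel.variant_ids[i] for i in sorted(proxy_idx)]
    planted_panel = HaplotypePanel(
        list(panel.variant_ids), list(panel.positions), panel.chrom, hap
    )

    # --- GWAS table --------------------------------------------------------
    lead_cols = {idx for _, idx in leads}
    gwas: list[GwasVariant] = []
    planted_loci: list[tuple[str, str, int, float]] = []
    for j, (rsid, pos) in enumerate(zip(panel.variant_ids, panel.positions)):
        if j in lead_cols:
            p = float(10 ** rng.uniform(-9, -6))
        else:
            p = float(10 ** rng.uniform(-4, 0))
        gwas.append(GwasVariant(rsid, panel.chrom, pos, p, "simulated"))
        if j in lead_cols:
            planted_loci.append((rsid, panel.chrom, pos, p))

    # --- eQTL links and gene placement -------------------------------------
    k_eqtl = int(round(n_planted_loci * eqtl_fraction))
    if eqtl_genes_per_locus is None:
        eqtl_genes_per_locus = [1] * k_eqtl
    if len(eqtl_genes_per_locus) != k_eqtl:
        raise ParameterError(
            f"eqtl_genes_per_locus has {len(eqtl_genes_per_locus)} entries, "
            f"expected {k_eqtl} (= round(n_planted_loci * eqtl_fraction))"
        )
    order = rng.permutation(n_planted_loci)
    eqtl_locus_pos = [int(i) for i in order[:k_eqtl]]
    gene_models: list[GeneModel] = []
    eqtl_records: list[QTLRecord] = []
    eqtl_links: list[tuple[str, str, float]] = []
    expected_eqtl: dict[str, list[str]] = {}
    expected_cis: dict[str, list[str]] = {}
    locus_of_gene: dict[str, str] = {}
    slot_used: dict[str, int] = {}
    gene_counter = 0

    def place_gene(lead_rsid: str, lead_pos: int) -> GeneModel:
        # slots tile lead +- flank: slot g starts at lead - 0.9*flank + g*0.12*flank
        nonlocal gene_counter
        g = slot_used.get(lead_rsid, 0)
        slot_used[lead_rsid] = g + 1
        if g > 14:
            raise CapacityError(f"too many cis genes planted at {lead_rsid}")
        start = (lead_pos - 1) - 90_000 + g * 12_000
        name = f"GENE{gene_counter:04d}"
        gene_counter += 1
        model = GeneModel(name, name, panel.chrom, start, start + 5_000, "+")
        locus_of_gene[name] = lead_rsid
        return model

    for locus_i, n_genes in zip(eqtl_locus_pos, eqtl_genes_per_locus):
        lead_rsid, lead_idx = leads[locus_i]
        lead_pos = panel.positions[lead_idx]
        genes_here = []
        for g in range(n_genes):
            model = place_gene(lead_rsid, lead_pos)
            gene_models.append(model)
            snp = lead_rsid if g % 2 == 0 else proxies[lead_rsid][0]
            p = EQTL_P_MAX / 10.0
            eqtl_records.append(QTLRecord(snp, "eqtl", model.symbol, p))
            eqtl_links.append((snp, model.symbol, p))
            genes_here.append(model.symbol)
        expected_eqtl[lead_rsid] = genes_here
        expected_cis.setdefault(lead_rsid, []).extend(genes_here)

    # decoy eQTL records (p 10x above threshold) and far genes outside the flank
    for locus_i, (lead_rsid, lead_idx) in enumerate(leads):
        lead_pos = panel.positions[lead_idx]
        far = GeneModel(
            f"FARGENE{locus_i:04d}",
            f"FARGENE{locus_i:04d}",
            panel.chrom,
            (lead_pos - 1) + flank_bp + 50_000,
            (lead_pos - 1) + flank_bp + 55_000,
            "+",
        )
        gene_models.append(far)
        eqtl_records.append(
            QTLRecord(lead_rsid, "eqtl", f"DECOY{locus_i:04d}", EQTL_P_MAX * 10.0)
        )

    # cis genes with stimulation response but no eQTL link, on eQTL-free loci
    non_eqtl_loci = [i for i in range(n_planted_loci) if i not in set(eqtl_locus_pos)]
    host_loci = non_eqtl_loci if non_eqtl_loci else list(range(n_planted_loci))
    if n_cis_de_only > len(host_loci) * 15:
        raise CapacityError("too many cis-DE-only genes for the available loci")
    cis_de_only_genes: list[str] = []
    for g in range(n_cis_de_only):
        lead_rsid, lead_idx = leads[host_loci[g % len(host_loci)]]
        model = place_gene(lead_rsid, panel.positions[lead_idx])
        gene_models.append(model)
        cis_de_only_genes.append(model.symbol)
        expected_cis.setdefault(lead_rsid, []).append(model.symbol)

    # --- cytokine QTL links -------------------------------------------------
    n_tests = n_planted_loci if n_tests is None else n_tests
    k_cyt = int(round(n_planted_loci * cytokine_fraction))
    if n_bonferroni is None:
        n_bonferroni = 1 if k_cyt else 0
    if n_bonferroni > k_cyt:
        raise ParameterError("n_bonferroni cannot exceed the cytokine locus count")
    bonferroni_p = NOMINAL_P / n_tests
    cyt_locus_pos = [int(i) for i in rng.permutation(n_planted_loci)[:k_cyt]]
    cytokine_records: list[QTLRecord] = []
    cytokine_links: list[tuple[str, str, float]] = []
    expected_cyt: list[tuple[str, str, float, bool]] = []
    for rank, locus_i in enumerate(cyt_locus_pos):
        lead_rsid, _ = leads[locus_i]
        trait = _TRAITS[rank % len(_TRAITS)]
        strong = rank < n_bonferroni
        p = bonferroni_p / 10.0 if strong else 0.005
        snp = lead_rsid if rank % 2 == 0 else proxies[lead_rsid][0]
        cytokine_records.append(QTLRecord(snp, "cytokine", trait, p))
        cytokine_links.append((snp, trait, p))
        expected_cyt.append((lead_rsid, trait, p, strong))
        # decoy trait well above nominal significance
        cytokine_records.append(
            QTLRecord(lead_rsid, "cytokine", _TRAITS[(rank + 1) % len(_TRAITS)], 0.5)
        )

    # --- DE tables ----------------------------------------------------------
    all_eqtl_genes = [g for genes in expected_eqtl.values() for g in genes]
    k_de = int(round(len(all_eqtl_genes) * de_overlap_fraction))
    de_eqtl_genes = [all_eqtl_genes[int(i)] for i in rng.permutation(len(all_eqtl_genes))[:k_de]]
    pbmc_de_genes = sorted(de_eqtl_genes) + cis_de_only_genes
    pbmc_records: list[DERecord] = []
    planted_de: dict[str, list[tuple[str, float, float]]] = {}
    for i, gene in enumerate(pbmc_de_genes):
        contrast = _PBMC_CONTRASTS[i % len(_PBMC_CONTRASTS)]
        lfc = 2.0 if i % 3 else -2.0  # both directions count
        pbmc_records.append(DERecord(gene, contrast, lfc, 0.001))
        planted_de.setdefault(contrast, []).append((gene, lfc, 0.001))
    # decoy PBMC records: sub-threshold fold change / FDR, plus a far gene
    for i, gene in enumerate(g for g in all_eqtl_genes if g not in set(de_eqtl_genes)):
        contrast = _PBMC_CONTRASTS[i % len(_PBMC_CONTRASTS)]
        pbmc_records.append(DERecord(gene, contrast, 0.2, 0.9))
    for locus_i in range(min(3, n_planted_loci)):
        pbmc_records.append(DERecord(f"FARGENE{locus_i:04d}", _PBMC_CONTRASTS[0], 2.0, 0.001))

    prioritized = sorted(set(all_eqtl_genes) | set(pbmc_de_genes))
    if n_patient_de is None:
        n_patient_de = min(len(prioritized), max(1, len(prioritized) // 8)) if prioritized else 0
    if n_patient_de > len(prioritized):
        raise ParameterError("n_patient_de cannot exceed the prioritized gene count")
    patient_genes = [
        prioritized[int(i)] for i in rng.permutation(len(prioritized))[:n_patient_de]
    ]
    disc: list[DERecord] = []
    valid: list[DERecord] = []
    for i, gene in enumerate(patient_genes):
        lfc = 1.2 if i < patient_up else -1.2  # |FC| = 2.3 > 1.5
        rec = DERecord(gene, "severe_vs_mild", lfc, 0.001)
        (disc if i % 2 == 0 else valid).append(rec)
        cohort = "patient_discovery" if i % 2 == 0 else "patient_validation"
        planted_de.setdefault(cohort, []).append((gene, lfc, 0.001))
    for i, gene in enumerate(g for g in prioritized if g not in set(patient_genes)):
        rec = DERecord(gene, "severe_vs_mild", 0.3, 0.5)  # |FC| = 1.23 < 1.5
        (disc if i % 2 == 0 else valid).append(rec)

    # --- pathways -----------------------------------------------------------
    universe = sorted(g.symbol for g in gene_models)
    pathways: dict[str, set[str]] = {}
    if prioritized:
        pathways["ADHERENS_JUNCTION"] = set(prioritized[: min(8, len(prioritized))])
    for i in range(5):
        take = rng.permutation(len(universe))[: min(10, len(universe))]
        pathways[f"CONTROL_PATHWAY_{i}"] = {universe[int(j)] for j in take}

    # --- write everything ---------------------------------------------------
    study = SimulatedStudy(
        out_dir=out_dir,
        gwas=out_dir / "gwas.tsv",
        panel=out_dir / "panel.vcf",
        eqtl=out_dir / "eqtl.tsv",
        cytokine=out_dir / "cqtl.tsv",
        genes=out_dir / "genes.bed",
        pbmc_de=out_dir / "pbmc_de.tsv",
        patient_de_discovery=out_dir / "patient_de_discovery.tsv",
        patient_de_validation=out_dir / "patient_de_validation.tsv",
        pathways=out_dir / "pathways.gmt",
        manifest=out_dir / "manifest.json",
    )
    catalog_io.write_gwas_table(gwas, study.gwas)
    catalog_io.write_haplotype_panel(planted_panel, study.panel, fmt="vcf")
    catalog_io.write_qtl_catalog(eqtl_records, study.eqtl)
    catalog_io.write_qtl_catalog(cytokine_records, study.cytokine)
    catalog_io.write_gene_bed(gene_models, study.genes)
    catalog_io.write_de_table(pbmc_records, study.pbmc_de)
    catalog_io.write_de_table(disc, study.patient_de_discovery)
    catalog_io.write_de_table(valid, study.patient_de_validation)
    catalog_io.write_gmt(pathways, study.pathways)

    manifest = TruthManifest(
        seed=seed,
        n_tests=n_tests,
        planted_loci=sorted(planted_loci, key=lambda t: t[2]),
        planted_proxies=proxies,
        planted_eqtl_links=eqtl_links,
        planted_cytokine_links=cytokine_links,
        planted_de_genes=planted_de,
        expected_eqtl_genes={k: sorted(v) for k, v in expected_eqtl.items()},
        expected_cis_genes={k: sorted(v) for k, v in expected_cis.items()},
        expected_cytokine_hits=expected_cyt,
        expected_pbmc_de_genes=sorted(set(pbmc_de_genes)),
        expected_patient_de_genes=sorted(set(patient_genes)),
        expected_prioritized=prioritized,
        locus_of_gene=locus_of_gene,
    )
    manifest.to_json(study.manifest)
    return study, manifest


def _decorrelate(hap: np.ndarray, j: int, lead_idx: int, rng) -> None:
    """Perturb column j until its r2 with the lead column is sharply below 0.5."""
    n = hap.shape[0]
    for _ in range(50):
        col = hap[:, j].astype(float)
        lead = hap[:, lead_idx].astype(float)
        polymorphic = 0.0 < col.mean() < 1.0
        if polymorphic:
            r = np.corrcoef(col, lead)[0, 1]
            if r * r < 0.5:
                return
        flips = rng.random(n) < 0.5
        hap[flips, j] ^= 1
    raise RuntimeError("failed to decorrelate a non-proxy column")  # pragma: no cover


def headline_preset(seed: int, out_dir) -> tuple[SimulatedStudy, TruthManifest]:
    """A synthetic study with the headline geometry of the sepsis annotation.

    39 independent suggestive loci; 13 loci with cis-eQTL genes totalling 45
    (per-locus counts matching the published distribution, led by 14, 10 and
    5 genes at single loci); 9 loci with nominal cytokine-QTL hits across 6
    cytokines, 2 of them surviving the 0.05/39 Bonferroni threshold; 12 of
    the 45 eQTL genes plus 10 cis-only genes responding to PBMC stimulation
    (55 prioritized genes in total); and 7 prioritized genes differentially
    expressed between severe and mild patients (1 up, 6 down).
    """
    rng = np.random.default_rng(seed)
    panel = simulate_haplotype_panel(
        n_individuals=60,
        n_blocks=39,
        snps_per_block=8,
        n_founders=4,
        mutation_rate=0.02,
        seed=int(rng.integers(2**31)),
    )
    return simulate_study(
        panel,
        n_planted_loci=39,
        eqtl_fraction=13 / 39,
        cytokine_fraction=9 / 39,
        de_overlap_fraction=12 / 45,
        seed=int(rng.integers(2**31)),
        out_dir=out_dir,
        eqtl_genes_per_locus=[14, 10, 5, 3, 2, 2, 2, 2, 1, 1, 1, 1, 1],
        n_cis_de_only=10,
        n_bonferroni=2,
        n_patient_de=7,
        patient_up=1,
        n_tests=39,
    )
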