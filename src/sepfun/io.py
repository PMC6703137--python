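"""Readers and writers for every external format the pipeline touches.

Formats: TSV tables (GWAS, QTL catalogs, DE tables, evidence), phased VCF or
plain haplotype-matrix TSV, BED6 / GFF3 gene models, MEME-minimal PWMs, GMT
pathway sets, FASTA probes. Also exposes the packaged study fixtures (the
per-locus QTL evidence table and the rs4957796 EMSA probe sequences).

All writers are deterministic: identical input produces byte-identical
output. All readers reject malformed input with a named error rather than
silently dropping rows.
"""

from __future__ import annotations

import importlib.resources
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    BiallelicError,
    CoordinateError,
    DuplicateRecordError,
    FormatError,
    MotifMatrixError,
    PhasingError,
)
from .types import (
    AlleleProbePair,
    DERecord,
    EvidenceRow,
    GeneModel,
    GwasVariant,
    HaplotypePanel,
    Provenance,
    PWM,
    QTLRecord,
)

# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    for col in cols:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_gwas_table(path, study: str) -> list[GwasVariant]:
    """Read a GWAS summary table (columns rsid, chrom, pos, p) for one study."""
    df = _read_tsv(path)
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty file, expected header rsid/chrom/pos/p")
    _require_columns(df, ("rsid", "chrom", "pos", "p"), path)
    variants: list[GwasVariant] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            pos = int(row.pos)
            p = float(row.p)
        except ValueError as exc:
            raise FormatError(f"{path} row {i}: unparseable pos/p ({exc})") from None
        if not (0.0 < p <= 1.0):
            raise FormatError(f"{path} row {i}: p-value {p} outside (0, 1]")
        key = (row.chrom, pos)
        if key in seen:
            raise DuplicateRecordError(f"{path} row {i}: duplicate (chrom, pos) {key}")
        seen.add(key)
        variants.append(GwasVariant(row.rsid, row.chrom, pos, p, study))
    return variants


def write_gwas_table(variants: list[GwasVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tp\n")
        for v in variants:
            fh.write(f"{v.rsid}\t{v.chrom}\t{v.pos}\t{v.pvalue!r}\n")


def read_qtl_catalog(path, qtl_type: str) -> list[QTLRecord]:
    """Read a QTL catalog (columns snp, phenotype, p, optional fdr).

    Rows whose phenotype is empty or the literal "No" record the absence of
    any hit for that SNP and are skipped.
    """
    df = _read_tsv(path)
    if df.empty and df.columns.empty:
        return []
    _require_columns(df, ("snp", "phenotype", "p"), path)
    has_fdr = "fdr" in df.columns
    records: list[QTLRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pheno = row.phenotype.strip()
        if pheno in ("", "No", "no", "NA"):
            continue
        try:
            p = float(row.p)
        except ValueError:
            raise FormatError(f"{path} row {i}: malformed p-value {row.p!r}") from None
        fdr = None
        if has_fdr and row.fdr.strip() not in ("", "NA"):
            try:
                fdr = float(row.fdr)
            except ValueError:
                raise FormatError(f"{path} row {i}: malformed fdr {row.fdr!r}") from None
        records.append(QTLRecord(row.snp, qtl_type, pheno, p, fdr))
    return records


def write_qtl_catalog(records: list[QTLRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("snp\tphenotype\tp\tfdr\n")
        for r in records:
            fdr = "" if r.fdr is None else repr(r.fdr)
            fh.write(f"{r.snp_rsid}\t{r.phenotype}\t{r.pvalue!r}\t{fdr}\n")


def read_de_table(path) -> list[DERecord]:
    """Read a differential-expression table (gene, contrast, log2fc, fdr)."""
    df = _read_tsv(path)
    if df.empty and df.columns.empty:
        return []
    _require_columns(df, ("gene", "contrast", "log2fc", "fdr"), path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                DERecord(row.gene, row.contrast, float(row.log2fc), float(row.fdr))
            )
        except ValueError:
            raise FormatError(f"{path} row {i}: malformed numeric field") from None
    return records


def write_de_table(records: list[DERecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcontrast\tlog2fc\tfdr\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.contrast}\t{r.log2fc!r}\t{r.fdr!r}\n")


# ---------------------------------------------------------------------------
# Gene models


def read_gene_annotation(path, dialect: str) -> list[GeneModel]:
    """Read gene models from BED6 (0-based half-open) or GFF3 (1-based inclusive).

    All coordinates are normalized to 0-based half-open; output is stably
    sorted by (chrom, start). A file whose lines do not parse under the
    declared dialect (e.g. GFF3 lines under ``dialect="bed"``) is rejected.
    """
    if dialect not in ("bed", "gff3"):
        raise FormatError(f"unknown gene annotation dialect {dialect!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "bed":
                genes.append(_parse_bed_line(fields, path, lineno))
            else:
                gene = _parse_gff3_line(fields, path, lineno)
                if gene is not None:
                    genes.append(gene)
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _parse_bed_line(fields, path, lineno) -> GeneModel:
    if not (3 <= len(fields) <= 6):
        raise FormatError(f"{path} line {lineno}: expected 3-6 BED columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise FormatError(
            f"{path} line {lineno}: BED columns 2-3 must be integers "
            "(is this a GFF3 file?)"
        ) from None
    name = fields[3] if len(fields) > 3 else f"{fields[0]}:{start}-{end}"
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "unknown"
    return GeneModel(name, name, fields[0], start, end, strand)


def _parse_gff3_line(fields, path, lineno) -> GeneModel | None:
    if len(fields) != 9:
        raise FormatError(
            f"{path} line {lineno}: expected 9 GFF3 columns (is this a BED file?)"
        )
    if fields[2] != "gene":
        return None
    try:
        start1, end1 = int(fields[3]), int(fields[4])
    except ValueError:
        raise FormatError(f"{path} line {lineno}: GFF3 columns 4-5 must be integers") from None
    attrs = {}
    for item in fields[8].split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    gene_id = attrs.get("ID", f"{fields[0]}:{start1}-{end1}")
    symbol = attrs.get("Name", attrs.get("gene_name", gene_id))
    strand = fields[6] if fields[6] in ("+", "-") else "unknown"
    # GFF3 is 1-based inclusive; convert to 0-based half-open.
    if start1 > end1:
        raise CoordinateError(f"{path} line {lineno}: start > end")
    return GeneModel(gene_id, symbol, fields[0], start1 - 1, end1, strand)


def write_gene_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Haplotype panels (phased VCF or matrix TSV)


def read_haplotype_panel(path) -> HaplotypePanel:
    """Read phased biallelic haplotypes from a single-chromosome VCF or matrix TSV.

    VCF genotypes must be phased (``0|1``); unphased or multiallelic records
    are rejected. The matrix TSV dialect has columns rsid, chrom, pos and one
    column per haplotype (h0, h1, ...), one row per variant.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _read_panel_vcf(path)
    return _read_panel_tsv(path)


def _read_panel_vcf(path: Path) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids, positions, columns = [], [], []
    chrom = None
    for v in vcf:
        if len(v.ALT) != 1:
            raise BiallelicError(
                f"{path}: {v.ID or v.POS} has {len(v.ALT)} ALT alleles; "
                "only biallelic records are supported"
            )
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise FormatError(f"{path}: panel must span a single chromosome")
        col = []
        for g in v.genotypes:  # [allele_a, allele_b, phased]
            if len(g) < 3 or not g[2]:
                raise PhasingError(
                    f"{path}: unphased genotype at {v.CHROM}:{v.POS} "
                    f"({v.ID or '.'}); phased '0|1'-style GT required"
                )
            a, b = g[0], g[1]
            if a not in (0, 1) or b not in (0, 1):
                raise FormatError(f"{path}: missing/invalid allele at {v.CHROM}:{v.POS}")
            col.extend((a, b))
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        positions.append(v.POS)
        columns.append(col)
    if not ids:
        raise FormatError(f"{path}: no variant records")
    return HaplotypePanel(ids, positions, chrom, np.array(columns, dtype=np.int8).T)


def _read_panel_tsv(path: Path) -> HaplotypePanel:
    df = _read_tsv(path)
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty haplotype matrix")
    _require_columns(df, ("rsid", "chrom", "pos"), path)
    hap_cols = [c for c in df.columns if c not in ("rsid", "chrom", "pos")]
    if not hap_cols:
        raise FormatError(f"{path}: no haplotype columns")
    chroms = set(df["chrom"])
    if len(chroms) != 1:
        raise FormatError(f"{path}: panel must span a single chromosome")
    try:
        mat = df[hap_cols].astype(np.int8).to_numpy().T
    except ValueError:
        raise FormatError(f"{path}: haplotype entries must be 0/1 integers") from None
    return HaplotypePanel(
        list(df["rsid"]), [int(p) for p in df["pos"]], chroms.pop(), mat
    )


def write_haplotype_panel(panel: HaplotypePanel, path, fmt: str = "vcf") -> None:
    """Write a panel as a phased VCF (REF=A, ALT=G placeholders) or matrix TSV."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            heads = "\t".join(f"h{i}" for i in range(panel.n_haplotypes))
            fh.write(f"rsid\tchrom\tpos\t{heads}\n")
            for j, (rsid, pos) in enumerate(zip(panel.variant_ids, panel.positions)):
                alleles = "\t".join(str(int(a)) for a in panel.haplotypes[:, j])
                fh.write(f"{rsid}\t{panel.chrom}\t{pos}\t{alleles}\n")
        return
    if fmt != "vcf":
        raise FormatError(f"unknown panel format {fmt!r}")
    if panel.n_haplotypes % 2 != 0:
        raise FormatError("VCF output needs an even number of haplotypes")
    n_samples = panel.n_haplotypes // 2
    samples = [f"S{i:04d}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, (rsid, pos) in enumerate(zip(panel.variant_ids, panel.positions)):
            col = panel.haplotypes[:, j]
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples))
            fh.write(f"{panel.chrom}\t{pos}\t{rsid}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# MEME minimal PWMs
#
# Hand-parsed: the format is a handful of lines per motif, and we must
# preserve the printed probabilities exactly and reject rows whose sum
# deviates from 1 by more than 1e-3 (renormalizing smaller deviations).

_ROW_SUM_TOL = 1e-3


def read_pwm(path) -> list[PWM]:
    """Read letter-probability motifs from a MEME-minimal file."""
    background = np.full(4, 0.25)
    pwms: list[PWM] = []
    motif_id = None
    rows: list[list[float]] = []
    in_background = False

    def flush():
        nonlocal motif_id, rows
        if motif_id is not None:
            if not rows:
                raise MotifMatrixError(f"{path}: motif {motif_id} has no matrix rows")
            pwms.append(PWM(motif_id, np.array(rows), background.copy()))
        motif_id, rows = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if in_background:
                if line and line[0] in "ACGT":
                    toks = line.split()
                    freqs = dict(zip(toks[::2], (float(x) for x in toks[1::2])))
                    background = np.array([freqs.get(b, 0.0) for b in "ACGT"])
                    if not math.isclose(background.sum(), 1.0, abs_tol=1e-6):
                        raise MotifMatrixError(f"{path}: background must sum to 1")
                in_background = False
                continue
            if line.lower().startswith("background letter frequencies"):
                in_background = True
                continue
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path} line {lineno}: MOTIF line without id")
                motif_id = parts[1]
                continue
            if line.lower().startswith("letter-probability matrix"):
                continue
            if motif_id is not None and line:
                toks = line.split()
                if len(toks) != 4:
                    raise MotifMatrixError(
                        f"{path} line {lineno}: expected 4 probabilities, got {len(toks)}"
                    )
                row = [float(t) for t in toks]
                s = sum(row)
                if abs(s - 1.0) > _ROW_SUM_TOL:
                    raise MotifMatrixError(
                        f"{path} line {lineno}: row sums to {s:.4f}, "
                        f"deviating from 1 by more than {_ROW_SUM_TOL}"
                    )
                rows.append([x / s for x in row])
    flush()
    return pwms


def write_pwm(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip("ACGT", bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                "nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# GMT pathway sets


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT pathway definitions: name, description, member genes."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path} line {lineno}: GMT needs name, description, >=1 gene"
                )
            pathways[fields[0]] = set(g for g in fields[2:] if g)
    return pathways


def write_gmt(pathways: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\tna\t{genes}\n")


# ---------------------------------------------------------------------------
# Evidence table


_EVIDENCE_COLUMNS = (
    "locus",
    "gene",
    "has_eqtl",
    "has_pbmc_de",
    "has_patient_de",
    "locus_has_cytokine_qtl",
    "provenance",
)


def write_evidence_table(rows: list[EvidenceRow], path) -> None:
    """Write the prioritized-gene evidence matrix as a deterministic TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(_EVIDENCE_COLUMNS) + "\n")
        for r in sorted(rows, key=lambda r: (r.locus_id, r.gene)):
            prov = ";".join(
                f"{p.evidence_class}|{p.source_key}|{p.value!r}" for p in r.provenance
            )
            fh.write(
                "\t".join(
                    (
                        r.locus_id,
                        r.gene,
                        str(r.has_eqtl).lower(),
                        str(r.has_pbmc_de).lower(),
                        str(r.has_patient_de).lower(),
                        str(r.locus_has_cytokine_qtl).lower(),
                        prov,
                    )
                )
                + "\n"
            )


def read_evidence_table(path) -> list[EvidenceRow]:
    df = _read_tsv(path)
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty evidence table")
    _require_columns(df, _EVIDENCE_COLUMNS, path)
    rows = []
    for row in df.itertuples(index=False):
        prov = tuple(
            Provenance(*item.split("|")[:2], float(item.split("|")[2]))
            for item in row.provenance.split(";")
            if item
        )
        rows.append(
            EvidenceRow(
                gene=row.gene,
                locus_id=row.locus,
                has_eqtl=row.has_eqtl == "true",
                has_pbmc_de=row.has_pbmc_de == "true",
                has_patient_de=row.has_patient_de == "true",
                locus_has_cytokine_qtl=row.locus_has_cytokine_qtl == "true",
                provenance=prov,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Pipeline intermediates (loci, proxy sets, cytokine hits, gene scores)


def write_loci_table(loci, path) -> None:
    from .types import Locus  # noqa: F401  (documentation of the row type)

    with open(path, "w") as fh:
        fh.write("locus\tchrom\tlead_pos\tlead_p\tmembers\n")
        for loc in loci:
            members = ";".join(
                f"{m.rsid}:{m.pos}:{m.pvalue!r}:{m.study}" for m in loc.members
            )
            fh.write(
                f"{loc.locus_id}\t{loc.lead.chrom}\t{loc.lead.pos}\t"
                f"{loc.lead.pvalue!r}\t{members}\n"
            )


def read_loci_table(path):
    from .types import Locus

    df = _read_tsv(path)
    _require_columns(df, ("locus", "chrom", "lead_pos", "lead_p", "members"), path)
    loci = []
    for row in df.itertuples(index=False):
        members = []
        for item in row.members.split(";"):
            rsid, pos, p, study = item.rsplit(":", 3)
            members.append(GwasVariant(rsid, row.chrom, int(pos), float(p), study))
        lead = next(m for m in members if m.rsid == row.locus)
        loci.append(Locus(lead, tuple(members)))
    return loci


def write_proxy_table(proxy_sets: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("lead\tproxy\tr2\tdprime\n")
        for lead in sorted(proxy_sets):
            ps = proxy_sets[lead]
            if not ps.proxies:
                fh.write(f"{lead}\t.\t\t\n")
            for rsid, r2, dprime in ps.proxies:
                fh.write(f"{lead}\t{rsid}\t{r2!r}\t{dprime!r}\n")


def read_proxy_table(path) -> dict:
    from .types import ProxySet

    df = _read_tsv(path)
    _require_columns(df, ("lead", "proxy", "r2", "dprime"), path)
    acc: dict[str, list] = {}
    for row in df.itertuples(index=False):
        acc.setdefault(row.lead, [])
        if row.proxy and row.proxy != ".":
            acc[row.lead].append((row.proxy, float(row.r2), float(row.dprime)))
    return {lead: ProxySet(lead, tuple(proxies)) for lead, proxies in acc.items()}


def write_cytokine_hits(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\ttrait\tp\tpasses_bonferroni\n")
        for h in sorted(hits, key=lambda h: (h.locus_id, h.trait)):
            fh.write(
                f"{h.locus_id}\t{h.trait}\t{h.pvalue!r}\t"
                f"{str(h.passes_bonferroni).lower()}\n"
            )


def read_cytokine_hits(path):
    from .types import LocusCytokineHit

    df = _read_tsv(path)
    _require_columns(df, ("locus", "trait", "p", "passes_bonferroni"), path)
    return [
        LocusCytokineHit(
            row.locus, row.trait, float(row.p), True, row.passes_bonferroni == "true"
        )
        for row in df.itertuples(index=False)
    ]


def write_gene_scores(scores, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tn_snps\tstatistic\tp\tmethod\n")
        for s in sorted(scores, key=lambda s: (s.pvalue, s.gene)):
            fh.write(
                f"{s.gene}\t{len(s.snp_rsids)}\t{s.statistic!r}\t{s.pvalue!r}\t"
                f"{s.method}\n"
            )


def read_gene_scores(path):
    from .types import GeneScore

    df = _read_tsv(path)
    _require_columns(df, ("gene", "n_snps", "statistic", "p", "method"), path)
    return [
        GeneScore(
            row.gene,
            tuple(f"snp{i}" for i in range(int(row.n_snps))),
            float(row.statistic),
            float(row.p),
            row.method,
        )
        for row in df.itertuples(index=False)
    ]


def write_pathway_results(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\tn_genes\toverlap\tp\tq\n")
        for r in results:
            fh.write(
                f"{r.pathway}\t{r.n_genes}\t{r.overlap}\t{r.pvalue!r}\t{r.qvalue!r}\n"
            )


# ---------------------------------------------------------------------------
# Packaged fixtures


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("sepfun.data") / name)


def table2_fixture_path() -> Path:
    """Path of the packaged per-locus QTL evidence table (39 sepsis loci)."""
    return _data_path("table2_fixture.tsv")


def probes_fasta_path() -> Path:
    """Path of the packaged rs4957796 EMSA probe sequences."""
    return _data_path("table1_probes.fasta")


def load_locus_qtl_fixture(path=None):
    """Load the packaged locus/QTL evidence table.

    Returns ``(leads, eqtl_records, cytokine_records)`` where ``leads`` is an
    ordered list of (study, lead_rsid) pairs covering all 39 loci (including
    those with no catalogued QTL) and the record lists are typed QTLRecords
    keyed by lead rsID.
    """
    path = table2_fixture_path() if path is None else path
    df = _read_tsv(path)
    _require_columns(df, ("study", "lead_snp", "qtl_type", "phenotype", "pvalue"), path)
    leads: list[tuple[str, str]] = []
    seen: set[str] = set()
    eqtl: list[QTLRecord] = []
    cytokine: list[QTLRecord] = []
    for row in df.itertuples(index=False):
        if row.lead_snp not in seen:
            seen.add(row.lead_snp)
            leads.append((row.study, row.lead_snp))
        if row.qtl_type == "none":
            continue
        rec = QTLRecord(row.lead_snp, row.qtl_type, row.phenotype, float(row.pvalue))
        (eqtl if row.qtl_type == "eqtl" else cytokine).append(rec)
    return leads, eqtl, cytokine


def fixture_lead_gwas(pvalue: float = 1e-6) -> list[GwasVariant]:
    """The 39 fixture lead SNPs as GwasVariants with synthetic coordinates.

    The source table carries rsIDs only, so deterministic placeholder
    positions are assigned: one chromosome per study, leads 2 Mb apart, so
    every lead clumps into its own independent locus.
    """
    leads, _, _ = load_locus_qtl_fixture()
    study_idx: dict[str, int] = {}
    counters: dict[str, int] = {}
    variants = []
    for study, rsid in leads:
        if study not in study_idx:
            study_idx[study] = len(study_idx) + 1
            counters[study] = 0
        pos = 1_000_000 + 2_000_000 * counters[study]
        counters[study] += 1
        variants.append(GwasVariant(rsid, f"chr{study_idx[study]}", pos, pvalue, study))
    return variants


def load_probe_pairs(path=None) -> dict[str, AlleleProbePair]:
    """Load the EMSA probe FASTA into sense/antisense allele pairs.

    The packaged probes carry the rs4957796 risk allele T (sense strand) at
    0-based offset 16 versus the alternative allele C.
    """
    path = probes_fasta_path() if path is None else path
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    required = {
        "probe_sense_T",
        "probe_sense_C",
        "probe_antisense_T",
        "probe_antisense_C",
    }
    missing = required - set(seqs)
    if missing:
        raise FormatError(f"{path}: missing probe records {sorted(missing)}")

    def pair(ref_id, alt_id):
        ref, alt = seqs[ref_id], seqs[alt_id]
        offset = next(i for i, (a, b) in enumerate(zip(ref, alt)) if a != b)
        return AlleleProbePair(ref, alt, offset, ref[offset], alt[offset])

    return {
        "sense": pair("probe_sense_T", "probe_sense_C"),
        "antisense": pair("probe_antisense_T", "probe_antisense_C"),
    }
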