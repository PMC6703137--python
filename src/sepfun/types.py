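"""Core domain types shared across the pipeline.

Coordinate conventions
----------------------
Gene intervals are 0-based half-open everywhere inside the package (BED
convention); GFF3 input is converted at the I/O boundary. Variant positions
are 1-based base-pair coordinates (VCF convention). The only place the two
meet is cis-window lookup, which converts the variant position once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, SequenceError

VALID_BASES = frozenset("ACGT")
ALPHABET = "ACGT"


@dataclass(frozen=True)
class GwasVariant:
    """One suggestive GWAS association."""

    rsid: str
    chrom: str
    pos: int  # 1-based bp
    pvalue: float
    study: str

    def __post_init__(self):
        if not self.rsid:
            raise DomainError("rsid must be non-empty")
        if self.pos < 1:
            raise DomainError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if not (0.0 < self.pvalue <= 1.0):
            raise DomainError(
                f"{self.rsid}: p-value must be in (0, 1], got {self.pvalue}"
            )


@dataclass(frozen=True)
class QTLRecord:
    """A SNP -> molecular phenotype association.

    ``qtl_type`` is ``"eqtl"`` (phenotype = gene symbol, whole-blood
    expression) or ``"cytokine"`` (phenotype = compound
    cytokine_stimulus_cell_time label, e.g. ``IL6_LPS100ng_PBMC_24h``,
    kept opaque and split on underscores only for reporting).
    """

    snp_rsid: str
    qtl_type: str
    phenotype: str
    pvalue: float
    fdr: float | None = None

    def __post_init__(self):
        if self.qtl_type not in ("eqtl", "cytokine"):
            raise DomainError(f"unknown qtl_type {self.qtl_type!r}")
        if not (0.0 < self.pvalue <= 1.0):
            raise DomainError(
                f"{self.snp_rsid}/{self.phenotype}: p-value must be in (0, 1]"
            )

    @property
    def cytokine(self) -> str:
        """Leading token of a compound cytokine label (reporting only)."""
        return self.phenotype.split("_")[0]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 0-based half-open."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self):
        from .errors import CoordinateError

        if not self.chrom:
            raise CoordinateError(f"{self.gene_id}: empty chrom")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise CoordinateError(f"{self.gene_id}: bad strand {self.strand!r}")

    def overlaps(self, start: int, end: int) -> bool:
        """Half-open interval overlap on this gene's chromosome."""
        return self.start < end and self.end > start


@dataclass(frozen=True)
class DERecord:
    """One differential-expression result (gene x contrast)."""

    gene: str
    contrast: str
    log2fc: float
    fdr: float

    def __post_init__(self):
        if not (0.0 <= self.fdr <= 1.0):
            raise DomainError(f"{self.gene}/{self.contrast}: FDR must be in [0, 1]")

    @property
    def fold_change(self) -> float:
        """Unsigned linear fold change, 2**|log2fc| (always >= 1)."""
        return float(2.0 ** abs(self.log2fc))


@dataclass
class HaplotypePanel:
    """Phased haplotypes on one chromosome.

    ``haplotypes`` is a (2 * n_individuals) x n_variants {0,1} matrix; row
    2i and 2i+1 are the two phased haplotypes of individual i.
    """

    variant_ids: list[str]
    positions: list[int]  # 1-based bp, strictly increasing
    chrom: str
    haplotypes: np.ndarray

    def __post_init__(self):
        from .errors import FormatError

        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise FormatError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[1] != len(self.variant_ids):
            raise FormatError("column count must equal number of variant ids")
        if len(self.positions) != len(self.variant_ids):
            raise FormatError("positions and variant_ids must have equal length")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise FormatError("haplotype entries must be 0 or 1")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise FormatError("positions must be strictly increasing")
        self._index = {rsid: i for i, rsid in enumerate(self.variant_ids)}

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def index_of(self, rsid: str) -> int:
        from .errors import VariantLookupError

        try:
            return self._index[rsid]
        except KeyError:
            raise VariantLookupError(f"variant {rsid!r} not in panel") from None

    def column(self, rsid: str) -> np.ndarray:
        return self.haplotypes[:, self.index_of(rsid)]

    def position_of(self, rsid: str) -> int:
        return self.positions[self.index_of(rsid)]


@dataclass(frozen=True)
class PWM:
    """A position probability matrix over A, C, G, T with background."""

    motif_id: str
    probs: np.ndarray  # L x 4
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        from .errors import MotifMatrixError

        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise MotifMatrixError(f"{self.motif_id}: probs must be L x 4, L >= 1")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise MotifMatrixError(f"{self.motif_id}: rows must sum to 1 +- 1e-9")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise MotifMatrixError(f"{self.motif_id}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]


# ---------------------------------------------------------------------------
# Locus / LD types


@dataclass(frozen=True)
class Locus:
    """An independent GWAS locus: the lead SNP and all merged members."""

    lead: GwasVariant
    members: tuple[GwasVariant, ...]

    def __post_init__(self):
        if self.lead not in self.members:
            raise DomainError("lead must be a member of its locus")
        if any(m.chrom != self.lead.chrom for m in self.members):
            raise DomainError("all locus members must share one chromosome")
        if any(m.pvalue < self.lead.pvalue for m in self.members):
            raise DomainError("lead must have the minimal p-value in its locus")

    @property
    def locus_id(self) -> str:
        return self.lead.rsid

    @property
    def span(self) -> tuple[str, int, int]:
        pos = [m.pos for m in self.members]
        return (self.lead.chrom, min(pos), max(pos))


@dataclass(frozen=True)
class LDResult:
    """Pairwise haplotype LD between two variants."""

    rsid_a: str
    rsid_b: str
    d: float
    dprime: float
    r2: float
    n_haplotypes: int


@dataclass(frozen=True)
class ProxySet:
    """Proxies of one lead SNP at given r2 / D' thresholds."""

    lead_rsid: str
    proxies: tuple[tuple[str, float, float], ...]  # (rsid, r2, dprime)

    @property
    def snp_set(self) -> list[str]:
        """Lead plus proxies — the SNP set used for catalog intersection."""
        return [self.lead_rsid] + [rsid for rsid, _, _ in self.proxies]


# ---------------------------------------------------------------------------
# Evidence types


@dataclass(frozen=True)
class Provenance:
    """Pointer from an evidence flag back to the record that set it."""

    evidence_class: str  # eqtl | pbmc_de | patient_de | cytokine
    source_key: str
    value: float  # the p-value or FDR that passed the filter


@dataclass(frozen=True)
class EvidenceRow:
    """Per-gene evidence flags with provenance; one row of the prioritization table."""

    gene: str
    locus_id: str
    has_eqtl: bool
    has_pbmc_de: bool
    has_patient_de: bool
    locus_has_cytokine_qtl: bool
    provenance: tuple[Provenance, ...] = ()

    def __post_init__(self):
        if not (
            self.has_eqtl
            or self.has_pbmc_de
            or self.has_patient_de
            or self.locus_has_cytokine_qtl
        ):
            raise DomainError(f"{self.gene}: emitted row must carry some evidence")


@dataclass(frozen=True)
class LocusCytokineHit:
    """A locus x cytokine-trait association passing at least nominal significance."""

    locus_id: str
    trait: str
    pvalue: float
    passes_nominal: bool
    passes_bonferroni: bool

    def __post_init__(self):
        if self.passes_bonferroni and not self.passes_nominal:
            raise DomainError("Bonferroni-significant implies nominally significant")


# ---------------------------------------------------------------------------
# Gene / pathway score types


@dataclass(frozen=True)
class GeneScore:
    """LD-aware combined association statistic for one gene's SNP window."""

    gene: str
    snp_rsids: tuple[str, ...]
    statistic: float  # sum of per-SNP 1-df chi-square statistics
    pvalue: float
    method: str  # sum_chi2_mc | sum_chi2_satterthwaite

    def __post_init__(self):
        if self.statistic < 0:
            raise DomainError("statistic must be >= 0")
        if not (0.0 < self.pvalue <= 1.0):
            raise DomainError("gene p-value must be in (0, 1]")


@dataclass(frozen=True)
class PathwayResult:
    pathway: str
    n_genes: int
    overlap: int
    pvalue: float
    qvalue: float

    def __post_init__(self):
        if self.overlap > self.n_genes:
            raise DomainError("overlap cannot exceed pathway size")
        if not (0.0 <= self.qvalue <= 1.0):
            raise DomainError("qvalue must be in [0, 1]")


# ---------------------------------------------------------------------------
# Motif types


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass(frozen=True)
class AlleleProbePair:
    """Two probe sequences differing by one base (the SNP alleles)."""

    ref_seq: str
    alt_seq: str
    snp_offset: int  # 0-based index of the differing base
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        for name, seq in (("ref_seq", self.ref_seq), ("alt_seq", self.alt_seq)):
            if not set(seq) <= VALID_BASES:
                raise SequenceError(f"{name} contains non-ACGT characters")
        if len(self.ref_seq) != len(self.alt_seq):
            raise DomainError("probe sequences must have equal length")
        diffs = [
            i for i, (a, b) in enumerate(zip(self.ref_seq, self.alt_seq)) if a != b
        ]
        if diffs != [self.snp_offset]:
            raise DomainError(
                f"sequences must differ exactly at snp_offset {self.snp_offset}, "
                f"found differences at {diffs}"
            )
        if self.ref_seq[self.snp_offset] != self.ref_allele:
            raise DomainError("ref_seq base at snp_offset must equal ref_allele")
        if self.alt_seq[self.snp_offset] != self.alt_allele:
            raise DomainError("alt_seq base at snp_offset must equal alt_allele")

    def swapped(self) -> "AlleleProbePair":
        return AlleleProbePair(
            ref_seq=self.alt_seq,
            alt_seq=self.ref_seq,
            snp_offset=self.snp_offset,
            ref_allele=self.alt_allele,
            alt_allele=self.ref_allele,
        )


@dataclass(frozen=True)
class AlleleImpact:
    """How one motif's best match over the SNP changes between alleles (bits)."""

    motif_id: str
    best_ref_score: float
    best_alt_score: float
    best_window: tuple[int, str]  # (start, strand) of the best alt-allele window

    @property
    def delta(self) -> float:
        return self.best_alt_score - self.best_ref_score
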