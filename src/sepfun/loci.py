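"""Suggestive-SNP selection and distance-based locus clumping.

Suggestive associations (by default P < 1e-5, configurable down to the more
permissive 9.99e-5 some studies use) are merged into independent loci by
transitive single-linkage: two SNPs belong to one locus whenever they are
connected by a chain of same-chromosome pairs each at most ``window_bp``
apart (default 1 Mb). The lead SNP of a locus is its lowest-P member, with
deterministic tie-breaking by position then rsID.
"""

from __future__ import annotations

from itertools import groupby

from .errors import DomainError, EmptyInputError
from .types import GwasVariant, Locus


def filter_suggestive(
    variants: list[GwasVariant], p_max: float = 1e-5
) -> list[GwasVariant]:
    """Keep variants with pvalue strictly below ``p_max``, preserving order."""
    if not (0.0 < p_max < 1.0):
        raise DomainError(f"p_max must be in (0, 1), got {p_max}")
    return [v for v in variants if v.pvalue < p_max]


def _lead(members: list[GwasVariant]) -> GwasVariant:
    return min(members, key=lambda v: (v.pvalue, v.pos, v.rsid))


def clump_loci(
    variants: list[GwasVariant], window_bp: int = 1_000_000
) -> list[Locus]:
    """Merge variants into independent loci by transitive <=window_bp linkage.

    On a sorted chromosome, the connected components of the pairwise
    <=window graph are exactly the runs where consecutive positions are at
    most ``window_bp`` apart, so a single sorted sweep suffices. Output is
    sorted by (chrom, lead position); within each locus members are sorted
    by position.
    """
    if not variants:
        raise EmptyInputError("clump_loci requires at least one variant")
    if window_bp <= 0:
        raise DomainError(f"window_bp must be positive, got {window_bp}")
    loci: list[Locus] = []
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.rsid))
    for _, group in groupby(ordered, key=lambda v: v.chrom):
        run: list[GwasVariant] = []
        for v in group:
            if run and v.pos - run[-1].pos > window_bp:
                loci.append(Locus(_lead(run), tuple(run)))
                run = []
            run.append(v)
        loci.append(Locus(_lead(run), tuple(run)))
    loci.sort(key=lambda loc: (loc.lead.chrom, loc.lead.pos))
    return loci
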