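"""Pairwise linkage disequilibrium from phased haplotypes, and proxy-SNP search.

Classical two-locus haplotype statistics: with allele-1 frequencies p_A and
p_B and joint frequency p_AB,

    D   = p_AB - p_A * p_B
    D'  = |D| / D_max,  D_max = min(p_A q_B, q_A p_B) if D > 0
                               else min(p_A p_B, q_A q_B)
    r^2 = D^2 / (p_A q_A p_B q_B)

All statistics are undefined for monomorphic variants; those raise
``MonomorphicVariantError`` rather than returning NaN, so undefined LD can
never propagate silently into a proxy set.

Proxy selection replaces a browser LD lookup with an explicit computation:
every panel variant within ``window_bp`` of the lead that reaches r^2 >=
r2_min and D' >= dprime_min (D' compared with absolute tolerance 1e-9, since
it is a ratio of haplotype counts) is a proxy.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError, MonomorphicVariantError, ShapeError
from .types import HaplotypePanel, LDResult, ProxySet

DPRIME_TOL = 1e-9


def compute_ld(col_a, col_b, rsid_a: str = "a", rsid_b: str = "b") -> LDResult:
    """Haplotype-count LD between two phased {0,1} columns of equal length."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("columns must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise DomainError("need at least 2 haplotypes")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise DomainError("haplotype columns must contain only 0/1")
    p_a = a.mean()
    p_b = b.mean()
    for rsid, p in ((rsid_a, p_a), (rsid_b, p_b)):
        if p in (0.0, 1.0):
            raise MonomorphicVariantError(
                f"LD undefined: variant {rsid!r} is monomorphic"
            )
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    d_max = min(p_a * q_b, q_a * p_b) if d > 0 else min(p_a * p_b, q_a * q_b)
    dprime = abs(d) / d_max if d != 0 else 0.0
    r2 = d * d / (p_a * q_a * p_b * q_b)
    # ratios of counts can exceed 1 by a few ulp
    return LDResult(
        rsid_a, rsid_b, float(d), float(min(dprime, 1.0)), float(min(r2, 1.0)), n
    )


def ld_matrix(panel: HaplotypePanel, rsids: list[str]) -> np.ndarray:
    """Signed haplotype correlation matrix r for the given variants.

    Unit diagonal by construction; every variant must be polymorphic. The
    caller adds a small diagonal jitter before Cholesky factorization.
    """
    idx = [panel.index_of(r) for r in rsids]
    cols = panel.haplotypes[:, idx].astype(float)
    sd = cols.std(axis=0)
    for rsid, s in zip(rsids, sd):
        if s == 0:
            raise MonomorphicVariantError(
                f"correlation undefined: variant {rsid!r} is monomorphic"
            )
    centered = (cols - cols.mean(axis=0)) / sd
    r = centered.T @ centered / cols.shape[0]
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def select_proxies(
    lead: str,
    panel: HaplotypePanel,
    r2_min: float = 0.95,
    dprime_min: float = 1.0,
    window_bp: int = 500_000,
) -> ProxySet:
    """All panel variants in LD with ``lead`` above both thresholds.

    Monomorphic candidate variants cannot carry the association signal and
    are skipped; a monomorphic lead raises.
    """
    lead_col = panel.column(lead)
    lead_pos = panel.position_of(lead)
    if lead_col.mean() in (0.0, 1.0):
        raise MonomorphicVariantError(f"lead {lead!r} is monomorphic")
    proxies = []
    for rsid, pos in zip(panel.variant_ids, panel.positions):
        if rsid == lead or abs(pos - lead_pos) > window_bp:
            continue
        col = panel.column(rsid)
        if col.mean() in (0.0, 1.0):
            continue
        ld = compute_ld(lead_col, col, lead, rsid)
        if ld.r2 >= r2_min and ld.dprime >= dprime_min - DPRIME_TOL:
            proxies.append((rsid, ld.r2, ld.dprime))
    return ProxySet(lead, tuple(proxies))
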