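"""LD-aware gene association scores and pathway enrichment.

The gene statistic is the sum of per-SNP 1-df chi-square statistics obtained
by inverting each two-sided GWAS p-value,

    T = sum_i  Q_chi2_1(1 - p_i).

Under the null the SNP z-scores are multivariate normal with the LD
correlation matrix R of the gene's SNP window, so T is distributed as a
quadratic form sum_j lambda_j chi2_1 with lambda_j the eigenvalues of R.
Two estimators of P[T_null >= T] are provided:

* ``sum_chi2_mc`` — Monte Carlo over z ~ N(0, R) with the add-one estimator
  (k + 1) / (n + 1), which cannot return 0;
* ``sum_chi2_satterthwaite`` — a scaled chi-square a * chi2_nu matched to
  the first two moments (a = sum lambda^2 / sum lambda,
  nu = (sum lambda)^2 / sum lambda^2).

Summing chi-squares while sampling the null from R is what makes the score
robust to LD: adding a perfect proxy doubles both T and the null, leaving
the p-value unchanged, where a naive independence combination would not.

Pathway enrichment is a hypergeometric upper-tail test of the overlap
between the significant-gene set and each pathway within the scored gene
universe, with Benjamini-Hochberg q-values across pathways.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ParameterError, ShapeError
from .types import GeneScore, PathwayResult

JITTER = 1e-8


def snp_to_chi2(p: float) -> float:
    """Invert a two-sided p-value to its 1-df chi-square statistic."""
    if not (0.0 < p <= 1.0):
        raise DomainError(f"p-value must be in (0, 1], got {p}")
    return float(stats.chi2.isf(p, df=1))


def gene_score(
    p_values,
    R,
    method: str = "sum_chi2_mc",
    mc_reps: int = 100_000,
    seed: int | None = None,
    gene: str = "",
    snp_rsids=None,
) -> GeneScore:
    """Score one gene's SNP window against its LD-aware null."""
    p_values = np.asarray(p_values, dtype=float)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    m = p_values.size
    if m < 1:
        raise ShapeError("need at least one SNP p-value")
    if R.shape != (m, m):
        raise ShapeError(f"R must be {m}x{m} to match {m} p-values, got {R.shape}")
    T = float(sum(snp_to_chi2(p) for p in p_values))
    if method == "sum_chi2_mc":
        pvalue = _mc_pvalue(T, R, mc_reps, seed)
    elif method == "sum_chi2_satterthwaite":
        pvalue = _satterthwaite_pvalue(T, R)
    else:
        raise ParameterError(f"unknown gene-score method {method!r}")
    rsids = tuple(snp_rsids) if snp_rsids is not None else tuple(
        f"snp{i}" for i in range(m)
    )
    return GeneScore(gene, rsids, T, pvalue, method)


def _mc_pvalue(T: float, R: np.ndarray, mc_reps: int, seed) -> float:
    if mc_reps < 1:
        raise ParameterError("mc_reps must be >= 1")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R + JITTER * np.eye(R.shape[0]))
    z = rng.standard_normal((mc_reps, R.shape[0])) @ L.T
    exceed = int(np.count_nonzero((z * z).sum(axis=1) >= T))
    return (exceed + 1) / (mc_reps + 1)


def _satterthwaite_pvalue(T: float, R: np.ndarray) -> float:
    lam = np.linalg.eigvalsh(R + JITTER * np.eye(R.shape[0]))
    lam = np.clip(lam, 0.0, None)
    s1, s2 = lam.sum(), (lam * lam).sum()
    scale = s2 / s1
    df = s1 * s1 / s2
    p = float(stats.chi2.sf(T / scale, df=df))
    return max(p, np.nextafter(0.0, 1.0))


def mc_standard_error(pvalue: float, mc_reps: int) -> float:
    """Binomial standard error of a Monte Carlo p-value estimate."""
    return float(np.sqrt(pvalue * (1.0 - pvalue) / mc_reps))


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DomainError("all p-values must be in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def pathway_enrichment(
    scores: list[GeneScore],
    pathways: dict[str, set[str]],
    gene_universe: set[str],
    alpha: float = 0.05,
    top_n: int | None = None,
) -> list[PathwayResult]:
    """Hypergeometric enrichment of significant genes within each pathway.

    The significant set is genes with score p-value < ``alpha`` (or the
    ``top_n`` lowest p-values if given). Pathways are restricted to the
    scored universe; the upper-tail p is P[X >= overlap] for X
    hypergeometric(|universe|, |pathway|, |selected|). Results are sorted
    by p-value then name, with BH q-values over the tested pathways.
    """
    universe = set(gene_universe)
    if not universe:
        raise ParameterError("gene universe must be non-empty")
    in_universe = [s for s in scores if s.gene in universe]
    if top_n is not None:
        if top_n < 1:
            raise ParameterError("top_n must be >= 1")
        selected = {
            s.gene for s in sorted(in_universe, key=lambda s: (s.pvalue, s.gene))[:top_n]
        }
    else:
        selected = {s.gene for s in in_universe if s.pvalue < alpha}
    results = []
    names = sorted(pathways)
    pvals = []
    for name in names:
        members = pathways[name] & universe
        overlap = len(members & selected)
        # P[X >= overlap], X ~ Hypergeom(M=|universe|, K=|members|, N=|selected|)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(selected))
        )
        pvals.append(min(p, 1.0))
        results.append((name, len(members), overlap))
    qvals = bh_adjust(pvals)
    out = [
        PathwayResult(name, n_genes, overlap, p, q)
        for (name, n_genes, overlap), p, q in zip(results, pvals, qvals)
    ]
    out.sort(key=lambda r: (r.pvalue, r.pathway))
    return out


def score_genes_in_windows(
    variants,
    panel,
    genes,
    flank_bp: int = 100_000,
    method: str = "sum_chi2_satterthwaite",
    mc_reps: int = 100_000,
    seed: int | None = None,
) -> list[GeneScore]:
    """Score every gene against the GWAS SNPs within gene +- flank_bp.

    Convenience driver over :func:`gene_score`: for each gene, SNPs present
    in both the GWAS table and the haplotype panel that fall inside the
    flanked gene interval form the window; the LD matrix comes from the
    panel. Genes with no eligible (polymorphic) window SNPs are skipped.
    Seeds for per-gene Monte Carlo runs are drawn from one generator seeded
    with ``seed``, so a fixed seed gives bit-identical results.
    """
    from .ld import ld_matrix

    rng = np.random.default_rng(seed)
    p_by_rsid = {v.rsid: v.pvalue for v in variants}
    out: list[GeneScore] = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.symbol)):
        if g.chrom != panel.chrom:
            continue
        window: list[str] = []
        for rsid, pos in zip(panel.variant_ids, panel.positions):
            if rsid not in p_by_rsid:
                continue
            if g.start - flank_bp <= pos - 1 < g.end + flank_bp:
                col = panel.column(rsid)
                if 0.0 < col.mean() < 1.0:
                    window.append(rsid)
        if not window:
            continue
        R = ld_matrix(panel, window)
        out.append(
            gene_score(
                [p_by_rsid[r] for r in window],
                R,
                method=method,
                mc_reps=mc_reps,
                seed=int(rng.integers(2**31)),
                gene=g.symbol,
                snp_rsids=window,
            )
        )
    return out
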