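"""Gene scores against closed forms and cross-method checks; enrichment oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from sepfun.errors import DomainError, ParameterError, ShapeError
from sepfun.scores import (
    bh_adjust,
    gene_score,
    mc_standard_error,
    pathway_enrichment,
    snp_to_chi2,
)
from sepfun.types import GeneScore

MC_REPS = 100_000


class TestSnpToChi2:
    def test_p_one_maps_to_zero(self):
        assert snp_to_chi2(1.0) == 0.0

    @pytest.mark.parametrize(
        "z", [1.0, 2.0, 2.5]
    )
    def test_two_sided_z_inversion(self, z):
        # two-sided p for |Z|=z maps back to z^2
        p = 2 * stats.norm.sf(z)
        assert snp_to_chi2(p) == pytest.approx(z * z, rel=1e-10)

    def test_round_trip(self):
        for p in (0.3173, 0.0455, 1e-8):
            q = snp_to_chi2(p)
            assert stats.chi2.sf(q, 1) == pytest.approx(p, rel=1e-10)

    def test_domain(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(DomainError):
                snp_to_chi2(bad)


class TestGeneScore:
    def test_single_snp_identity(self):
        s = gene_score([0.01], np.eye(1), mc_reps=MC_REPS, seed=11)
        assert s.pvalue == pytest.approx(0.01, abs=3 * mc_standard_error(0.01, MC_REPS))

    def test_two_independent_snps_chi2_closed_form(self):
        s = gene_score([0.0455, 0.0455], np.eye(2), mc_reps=MC_REPS, seed=12)
        expected = math.exp(-s.statistic / 2)  # chi2_2 survival at T
        assert s.statistic == pytest.approx(8.0, abs=1e-4)
        assert s.pvalue == pytest.approx(expected, abs=3 * mc_standard_error(expected, MC_REPS))

    def test_duplicate_snp_invariance_under_perfect_ld(self):
        # the LD-aware null makes a perfect proxy a no-op
        R = np.ones((2, 2))
        s = gene_score([0.01, 0.01], R, mc_reps=MC_REPS, seed=13)
        assert s.pvalue == pytest.approx(0.01, abs=3 * mc_standard_error(0.01, MC_REPS))

    def test_satterthwaite_matches_mc_on_random_psd(self):
        rng = np.random.default_rng(5)
        for _ in range(4):
            m = rng.integers(2, 6)
            a = rng.standard_normal((m, 2 * m))
            R = np.corrcoef(a)
            ps = rng.uniform(0.001, 0.9, m)
            mc = gene_score(ps, R, "sum_chi2_mc", mc_reps=MC_REPS, seed=int(rng.integers(1e6)))
            sat = gene_score(ps, R, "sum_chi2_satterthwaite")
            # Satterthwaite is a two-moment approximation: allow its own
            # ~10-15% relative error on top of the MC noise
            tol = 3 * mc_standard_error(max(sat.pvalue, 1e-3), MC_REPS) + 0.15 * sat.pvalue + 5e-3
            assert abs(mc.pvalue - sat.pvalue) < tol

    def test_fixed_seed_is_bit_identical(self):
        a = gene_score([0.02, 0.3], np.eye(2), mc_reps=5000, seed=7)
        b = gene_score([0.02, 0.3], np.eye(2), mc_reps=5000, seed=7)
        assert a == b

    def test_add_one_estimator_never_zero(self):
        s = gene_score([1e-300], np.eye(1), mc_reps=100, seed=1)
        assert s.pvalue == pytest.approx(1 / 101)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            gene_score([0.1, 0.2], np.eye(3))


def hypergeom_oracle(M, K, N, k):
    """Exact upper tail P[X >= k] by summation of binomial coefficients."""
    total = 0.0
    for x in range(k, min(K, N) + 1):
        total += math.comb(K, x) * math.comb(M - K, N - x) / math.comb(M, N)
    return total


class TestPathwayEnrichment:
    def _scores(self, sig, nonsig):
        out = [GeneScore(g, ("s",), 10.0, 0.001, "sum_chi2_mc") for g in sig]
        out += [GeneScore(g, ("s",), 0.1, 0.9, "sum_chi2_mc") for g in nonsig]
        return out

    def test_exact_hypergeometric_example(self):
        universe = {f"G{i}" for i in range(100)}
        selected = [f"G{i}" for i in range(5)]
        rest = sorted(universe - set(selected))
        pathway = {"P": set(selected[:2]) | set(rest[:8])}  # 10 genes, overlap 2
        (res,) = pathway_enrichment(
            self._scores(selected, rest), pathway, universe
        )
        assert res.overlap == 2 and res.n_genes == 10
        assert res.pvalue == pytest.approx(hypergeom_oracle(100, 10, 5, 2), rel=1e-9)
        assert res.pvalue == pytest.approx(0.0769, abs=5e-4)

    def test_pathway_equal_to_selected_set_is_most_extreme(self):
        universe = {f"G{i}" for i in range(30)}
        selected = [f"G{i}" for i in range(4)]
        rest = sorted(universe - set(selected))
        pws = {"exact": set(selected), "mixed": {selected[0]} | set(rest[:3])}
        results = pathway_enrichment(self._scores(selected, rest), pws, universe)
        by_name = {r.pathway: r for r in results}
        assert by_name["exact"].pvalue < by_name["mixed"].pvalue
        assert results[0].pathway == "exact"  # sorted by p

    def test_zero_overlap_gives_p_one(self):
        universe = {"A", "B", "C", "D"}
        res = pathway_enrichment(
            self._scores(["A"], ["B", "C", "D"]), {"P": {"B", "C"}}, universe
        )
        assert res[0].pvalue == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ParameterError):
            pathway_enrichment([], {"P": {"A"}}, set())

    def test_calibration_under_random_selection(self):
        # with a random selected set, the hypergeometric p is superuniform in
        # distribution; check the empirical CDF never exceeds uniform grossly
        rng = np.random.default_rng(42)
        universe = [f"G{i}" for i in range(40)]
        pathway = {"P": set(universe[:10])}
        pvals = []
        for _ in range(1000):
            chosen = list(rng.choice(universe, size=8, replace=False))
            rest = [g for g in universe if g not in chosen]
            (res,) = pathway_enrichment(
                self._scores(chosen, rest), pathway, set(universe)
            )
            pvals.append(res.pvalue)
        pvals = np.sort(pvals)
        # discrete test: P[p <= t] <= t (superuniformity), allow MC slack
        for t in (0.05, 0.2, 0.5):
            assert (pvals <= t).mean() <= t + 0.05


class TestBhAdjust:
    def test_m_equals_one_identity(self):
        assert bh_adjust([0.01]) == [0.01]

    def test_step_up_hand_computation(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_equal_p_fixed_point(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_order_preserving_mapping(self):
        p = [0.04, 0.01, 0.03, 0.02]
        q = bh_adjust(p)
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_domain_validation(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])
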