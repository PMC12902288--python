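"""Windowed diversity statistics, neutrality tests, LD decay and the
selection scan, each against brute-force site-level oracles."""


import numpy as np
import pytest

from introflow import coalsim, genotypes, popgen

from conftest import make_gm

M = genotypes.MISSING


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_pop_stats(calls1, calls2):
    """Site-by-site pi, Dxy and Hudson FST for two dosage matrices."""
    def freq(col):
        col = col[col != M]
        n = 2 * len(col)
        return (col.sum() / n if n else np.nan), n

    pis1, pis2, dxys, hws, hbs = [], [], [], [], []
    for j in range(calls1.shape[1]):
        p1, n1 = freq(calls1[:, j])
        p2, n2 = freq(calls2[:, j])
        if n1 >= 2:
            pis1.append(2 * p1 * (1 - p1) * n1 / (n1 - 1))
        if n2 >= 2:
            pis2.append(2 * p2 * (1 - p2) * n2 / (n2 - 1))
        if n1 >= 1 and n2 >= 1:
            dxys.append(p1 * (1 - p2) + p2 * (1 - p1))
        if n1 >= 2 and n2 >= 2:
            hws.append(0.5 * (2 * p1 * (1 - p1) * n1 / (n1 - 1)
                              + 2 * p2 * (1 - p2) * n2 / (n2 - 1)))
            hbs.append(p1 * (1 - p2) + p2 * (1 - p1))
    fst = 1 - np.mean(hws) / np.mean(hbs) if hbs and np.mean(hbs) > 0 else np.nan
    return (np.mean(pis1) if pis1 else np.nan,
            np.mean(pis2) if pis2 else np.nan,
            np.mean(dxys) if dxys else np.nan, fst)


def brute_tajima(calls):
    """Tajima's D recomputed from the 1989 definitions on complete sites."""
    complete = (calls != M).all(axis=0)
    sub = calls[:, complete]
    n = 2 * sub.shape[0]
    d = sub.sum(axis=0)
    s = int(((d > 0) & (d < n)).sum())
    if s == 0:
        return np.nan
    k_hat = (d * (n - d)).sum() / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k_hat - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


# ---------------------------------------------------------------------------


class TestWindowDiversity:
    def test_fixed_difference_limit(self):
        """Populations fixed for different alleles: Dxy = 1, FST = 1,
        within-pop pi = 0."""
        calls = np.vstack([np.zeros((4, 6)), np.full((4, 6), 2)]).astype(np.int8)
        gm = make_gm(calls)
        wins = [genotypes.WindowSpec("chr1", 0, 100)]
        ws = popgen.window_diversity(gm, windows=wins)[0]
        assert ws.dxy["pop1|pop2"] == 1.0
        assert ws.fst["pop1|pop2"] == 1.0
        assert ws.pi["pop1"] == 0.0
        assert ws.pi["pop2"] == 0.0

    def test_identical_frequency_vectors_have_near_zero_fst(self):
        """Identical sample frequencies: Dxy = mean 2p(1-p); Hudson FST is
        exactly 1 - n/(n-1) (the unbiased within-heterozygosity slightly
        exceeds the between-heterozygosity on identical samples), which
        vanishes with sample size."""
        block = np.array([[0, 1], [1, 2], [2, 0], [1, 1]], dtype=np.int8)
        calls = np.vstack([block, block])
        gm = make_gm(calls)
        wins = [genotypes.WindowSpec("chr1", 0, 100)]
        ws = popgen.window_diversity(gm, windows=wins)[0]
        n = 8  # alleles per population
        assert ws.fst["pop1|pop2"] == pytest.approx(1 - n / (n - 1), rel=1e-12)
        p = block.sum(axis=0) / 8
        expected_dxy = np.mean(2 * p * (1 - p))
        assert ws.dxy["pop1|pop2"] == pytest.approx(expected_dxy, rel=1e-12)

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(6, 20)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.15] = M
        gm = make_gm(calls, pops=["a"] * 3 + ["b"] * 3)
        wins = [genotypes.WindowSpec("chr1", 0, 1000)]
        ws = popgen.window_diversity(gm, windows=wins)[0]
        pi_a, pi_b, dxy, fst = brute_pop_stats(calls[:3], calls[3:])
        assert ws.pi["a"] == pytest.approx(pi_a, rel=1e-12)
        assert ws.pi["b"] == pytest.approx(pi_b, rel=1e-12)
        assert ws.dxy["a|b"] == pytest.approx(dxy, rel=1e-12)
        assert ws.fst["a|b"] == pytest.approx(fst, rel=1e-12)
        assert ws.tajima_d["a"] == pytest.approx(brute_tajima(calls[:3]), rel=1e-12)

    def test_empty_window_retained_with_zero_sites(self):
        calls = np.ones((4, 3), dtype=np.int8)
        gm = make_gm(calls, positions=[10, 20, 30])
        wins = [genotypes.WindowSpec("chr1", 5000, 6000)]
        ws = popgen.window_diversity(gm, windows=wins)[0]
        assert ws.n_sites == 0
        assert ws.pi == {}

    def test_fst_symmetric_and_label_flip_invariant(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(8, 15)).astype(np.int8)
        gm = make_gm(calls, pops=["a"] * 4 + ["b"] * 4)
        gm_flip = make_gm((2 - calls).astype(np.int8), pops=["a"] * 4 + ["b"] * 4)
        wins = [genotypes.WindowSpec("chr1", 0, 1000)]
        ws = popgen.window_diversity(gm, windows=wins)[0]
        wsf = popgen.window_diversity(gm_flip, windows=wins)[0]
        assert ws.fst["a|b"] == pytest.approx(wsf.fst["a|b"], rel=1e-12)
        assert ws.pi["a"] == pytest.approx(wsf.pi["a"], rel=1e-12)
        assert ws.dxy["a|b"] == pytest.approx(wsf.dxy["a|b"], rel=1e-12)

    def test_weir_cockerham_estimator_available(self):
        calls = np.vstack([np.zeros((4, 6)), np.full((4, 6), 2)]).astype(np.int8)
        gm = make_gm(calls)
        wins = [genotypes.WindowSpec("chr1", 0, 100)]
        ws = popgen.window_diversity(gm, windows=wins, fst_estimator="wc")[0]
        assert ws.fst["pop1|pop2"] == pytest.approx(1.0)


class TestTajima:
    def test_singleton_heavy_fixture_is_negative_and_matches_oracle(self):
        # 4 samples (8 haplotypes); every site a derived singleton
        calls = np.zeros((4, 12), dtype=np.int8)
        calls[0, :] = 1
        sc = popgen.site_counts(calls)
        d = popgen.tajimas_d(sc)
        assert d < 0
        assert d == pytest.approx(brute_tajima(calls), rel=1e-12)

    def test_balanced_frequencies_are_positive(self):
        calls = np.zeros((4, 10), dtype=np.int8)
        calls[:2, :] = 2  # derived count 4 of 8 everywhere
        sc = popgen.site_counts(calls)
        d = popgen.tajimas_d(sc)
        assert d > 0
        assert d == pytest.approx(brute_tajima(calls), rel=1e-12)

    def test_no_segregating_sites_is_missing(self):
        sc = popgen.SiteCounts(n=8, s=0, eta=0, eta_e=0, pi_abs=0.0)
        assert np.isnan(popgen.tajimas_d(sc))

    def test_small_sample_rejected(self):
        sc = popgen.SiteCounts(n=2, s=3, eta=3, eta_e=1, pi_abs=1.0)
        with pytest.raises(ValueError):
            popgen.tajimas_d(sc)

    def test_neutral_expectation_near_zero(self):
        """Mean Tajima's D over neutral constant-size replicates ~ 0."""
        model = coalsim.DemographicModel(demes={"X": 10_000.0}, mutation_rate=5e-8)
        vals = []
        for seed in range(220):
            ds = coalsim.simulate(model, {"X": 4}, n_loci=6,
                                  locus_length=2000, seed=seed)
            sc = popgen.site_counts(ds.genotypes())
            if sc is not None and sc.s > 0:
                vals.append(popgen.tajimas_d(sc))
        vals = np.array(vals)
        assert len(vals) >= 200
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 3 * se


class TestFuLi:
    def test_all_external_mutations_give_negative_d(self):
        calls = np.zeros((5, 40), dtype=np.int8)
        calls[0, :] = 1  # all derived singletons: eta_e = eta
        sc = popgen.site_counts(calls)
        assert sc.eta_e == sc.eta == 40
        assert popgen.fu_li(sc, "D") < 0
        assert popgen.fu_li(sc, "F") < 0

    def test_no_external_mutations_give_positive_d(self):
        calls = np.zeros((5, 30), dtype=np.int8)
        calls[:2, :] = 2  # derived count 4: internal mutations only
        sc = popgen.site_counts(calls)
        assert sc.eta_e == 0
        assert popgen.fu_li(sc, "D") > 0

    def test_zero_eta_is_missing(self):
        sc = popgen.SiteCounts(n=10, s=0, eta=0, eta_e=0, pi_abs=0.0)
        assert np.isnan(popgen.fu_li(sc, "D"))

    def test_starred_variants_defined_without_polarization(self):
        calls = np.zeros((5, 30), dtype=np.int8)
        calls[0, :15] = 1
        calls[1:, 15:] = 1  # ancestral singleton on the other side
        sc = popgen.site_counts(calls, derived_is_alt=False)
        assert np.isfinite(popgen.fu_li(sc, "D*"))
        assert np.isfinite(popgen.fu_li(sc, "F*"))
        with pytest.raises(ValueError, match="polarized"):
            popgen.fu_li(sc, "D")

    def test_formulas_match_independent_recomputation(self):
        """Cross-check D and F on a mixed fixture against a from-scratch
        implementation of the published normalizing constants."""
        calls = np.zeros((5, 24), dtype=np.int8)
        calls[0, :10] = 1          # 10 singletons
        calls[:2, 10:18] = 2       # 8 mid-frequency sites
        calls[:4, 18:24] = 1       # 6 at 4/10
        sc = popgen.site_counts(calls)
        n, eta, eta_e = sc.n, sc.eta, sc.eta_e
        an = sum(1 / i for i in range(1, n))
        bn = sum(1 / i**2 for i in range(1, n))
        cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
        vd = 1 + an**2 / (bn + an**2) * (cn - (n + 1) / (n - 1))
        ud = an - 1 - vd
        d_oracle = (eta - an * eta_e) / np.sqrt(ud * eta + vd * eta**2)
        assert popgen.fu_li(sc, "D") == pytest.approx(d_oracle, rel=1e-12)
        an1 = an + 1 / n
        vf = (cn + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) / (an**2 + bn)
        uf = (1 + (n + 1) / (3 * (n - 1))
              - 4 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))) / an - vf
        f_oracle = (sc.pi_abs - eta_e) / np.sqrt(uf * eta + vf * eta**2)
        assert popgen.fu_li(sc, "F") == pytest.approx(f_oracle, rel=1e-12)


class TestLdDecay:
    def test_duplicated_site_has_r2_one(self):
        col = np.array([0, 1, 2, 1, 0, 2], dtype=np.int8)
        calls = np.column_stack([col, col])
        gm = make_gm(calls, positions=[100, 700], pops=["p"] * 6)
        curve = popgen.ld_decay(gm, "p", max_dist_bp=5000, bin_width=500)
        b = 600 // 500
        assert curve.mean_r2[b] == pytest.approx(1.0)

    def test_r2_invariant_under_dosage_flip(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
        gm = make_gm(calls, positions=np.arange(6) * 300, pops=["p"] * 10)
        gmf = make_gm((2 - calls).astype(np.int8),
                      positions=np.arange(6) * 300, pops=["p"] * 10)
        a = popgen.ld_decay(gm, "p")
        b = popgen.ld_decay(gmf, "p")
        np.testing.assert_allclose(a.mean_r2, b.mean_r2, equal_nan=True,
                                   atol=1e-12)

    def test_pairwise_r2_matches_brute_force(self):
        calls = np.array([[0, 2], [1, 1], [2, 0], [2, 2]], dtype=np.int8)
        gm = make_gm(calls, positions=[0, 900], pops=["p"] * 4)
        curve = popgen.ld_decay(gm, "p", bin_width=1000)
        r = np.corrcoef(calls[:, 0], calls[:, 1])[0, 1]
        assert curve.mean_r2[0] == pytest.approx(r * r, rel=1e-12)

    def test_unlinked_equilibrium_sites_decay_to_1_over_n(self):
        """Mean r^2 between independent sites ~ 1/n for n samples."""
        rng = np.random.default_rng(9)
        n, s = 40, 60
        p = rng.uniform(0.2, 0.8, size=s)
        calls = (rng.random((n, s)) < p).astype(np.int8) + \
                (rng.random((n, s)) < p).astype(np.int8)
        gm = make_gm(calls.astype(np.int8), positions=np.arange(s) * 50,
                     pops=["p"] * n)
        curve = popgen.ld_decay(gm, "p", max_dist_bp=3000, bin_width=3000)
        mean_r2 = np.nansum(curve.mean_r2 * curve.n_pairs) / curve.n_pairs.sum()
        assert mean_r2 == pytest.approx(1.0 / n, rel=0.5)

    def test_half_decay_definition(self):
        curve = popgen.LDDecayCurve(
            bin_edges=np.array([0, 100, 200, 300]),
            mean_r2=np.array([0.8, 0.5, 0.3]),
            n_pairs=np.array([10, 10, 10]),
            half_decay_bp=np.nan,
        )
        # recompute with the library's rule: first bin mean <= max/2
        mids = [50, 150, 250]
        below = [m for m, r in zip(mids, curve.mean_r2) if r <= 0.4]
        assert below[0] == 250


class TestSelectionScan:
    def test_shared_leaders_are_the_outliers(self):
        n = 100
        fst = np.zeros(n)
        pi1 = np.ones(n)
        pi2 = np.ones(n)
        lead = [3, 17, 42, 66, 91]
        fst[lead] = np.linspace(0.8, 0.9, 5)
        pi1[lead] = 10.0  # high ratio group1/group2
        res = popgen.selection_scan(fst, pi1, pi2, quantile=0.95)
        assert sorted(res["outliers"].tolist()) == lead

    def test_disjoint_leaders_give_empty_intersection(self):
        n = 100
        fst = np.zeros(n)
        pi1 = np.ones(n)
        pi2 = np.ones(n)
        fst[:5] = 1.0
        pi1[5:10] = 10.0
        res = popgen.selection_scan(fst, pi1, pi2, quantile=0.95, mode="both")
        assert len(res["outliers"]) == 0
        res_u = popgen.selection_scan(fst, pi1, pi2, quantile=0.95, mode="either")
        assert len(res_u["outliers"]) == 10

    def test_zero_denominator_windows_excluded_and_counted(self):
        fst = np.linspace(0, 1, 20)
        pi1 = np.ones(20)
        pi2 = np.ones(20)
        pi2[[4, 9]] = 0.0
        res = popgen.selection_scan(fst, pi1, pi2)
        assert res["n_ratio_excluded"] == 2
        assert np.isnan(res["log10_pi_ratio"][4])

    def test_engineered_sweep_region_recovered(self):
        """A region with depressed diversity in one group and elevated FST
        tops both rankings."""
        rng = np.random.default_rng(4)
        n = 60
        fst = rng.uniform(0.0, 0.2, n)
        pi1 = rng.uniform(0.008, 0.012, n)
        pi2 = rng.uniform(0.008, 0.012, n)
        sweep = [30, 31]
        fst[sweep] = 0.9
        pi2[sweep] = 0.0005  # swept (low diversity) in group 2
        res = popgen.selection_scan(fst, pi1, pi2, quantile=0.95)
        assert set(sweep) <= set(res["outliers"].tolist())
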