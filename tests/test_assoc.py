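"""Animal model: NRM oracle, REML recovery, GWAS calibration, FDR formula."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from awmnet import assoc, simpop
from awmnet.core import Pedigree
from tests.conftest import make_genotypes


def ped_from_rows(rows):
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "role"])
    for col in ("lineage", "mtdna", "cg", "origin", "birth_year"):
        df[col] = ""
    return Pedigree(df)


class TestNRM:
    def test_unrelated_founders_identity(self):
        ped = ped_from_rows(
            [("a", "0", "0", "sire"), ("b", "0", "0", "sire")]
        )
        a, order = assoc.pedigree_nrm(ped)
        np.testing.assert_array_equal(a, np.eye(2))

    def test_textbook_relationships(self):
        ped = ped_from_rows(
            [
                ("s", "0", "0", "sire"),
                ("d1", "0", "0", "sire"),
                ("d2", "0", "0", "sire"),
                ("k1", "s", "d1", "sib"),
                ("k2", "s", "d2", "sib"),
            ]
        )
        a, order = assoc.pedigree_nrm(ped)
        sub = assoc.nrm_submatrix(a, order, ["s", "k1", "k2"])
        assert sub[0, 1] == pytest.approx(0.5)  # parent-offspring
        assert sub[1, 2] == pytest.approx(0.25)  # half sibs
        assert sub[1, 1] == pytest.approx(1.0)

    def test_random_pedigree_matches_recursive_oracle(self):
        rng = np.random.default_rng(30)
        rows = [(f"f{i}", "0", "0", "sire") for i in range(6)]
        animals = [f"f{i}" for i in range(6)]
        parents = {a: ("0", "0") for a in animals}
        for i in range(14):
            s, d = rng.choice(animals, 2, replace=False)
            name = f"x{i}"
            rows.append((name, s, d, "sib"))
            parents[name] = (s, d)
            animals.append(name)
        a, order = assoc.pedigree_nrm(ped_from_rows(rows))

        def kin(u, v, memo={}):
            if u == "0" or v == "0":
                return 0.0
            key = (u, v) if u <= v else (v, u)
            if key in memo:
                return memo[key]
            iu, iv = animals.index(u), animals.index(v)
            if iu > iv:
                u, v = v, u
            su, du = parents[v if animals.index(u) < animals.index(v) else u]
            # a(u,v) for u older: 0.5*(a(u,s_v)+a(u,d_v)); a(u,u)=1+0.5 a(s,d)
            if u == v:
                s, d = parents[u]
                val = 1.0 + 0.5 * kin(s, d)
            else:
                young = u if animals.index(u) > animals.index(v) else v
                old = v if young is u else u
                s, d = parents[young]
                val = 0.5 * (kin(old, s) + kin(old, d))
            memo[key] = val
            return val

        sub = assoc.nrm_submatrix(a, order, animals)
        for i, u in enumerate(animals):
            for j, v in enumerate(animals):
                assert sub[i, j] == pytest.approx(kin(u, v), abs=1e-12)

    def test_halfsib_family_exact_quarter(self, small_pop):
        _, ped, _ = small_pop
        a, order = assoc.pedigree_nrm(ped)
        grp = ped.sibs[ped.sibs["sire"] == ped.sires["animal"].iloc[0]]
        dams = grp["dam"]
        sub = assoc.nrm_submatrix(a, order, list(grp["animal"]))
        off = sub[np.triu_indices_from(sub, k=1)]
        if dams.nunique() == len(dams):
            np.testing.assert_allclose(off, 0.25)

    def test_cycle_detected(self):
        ped = ped_from_rows(
            [("a", "b", "0", "sib"), ("b", "a", "0", "sib")]
        )
        with pytest.raises(ValueError, match="cycle"):
            assoc.pedigree_nrm(ped)


class TestContemporaryGroups:
    def test_single_group_centering(self):
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        g = pd.Series(["x", "x", "x"], index=list("abc"))
        adj = assoc.adjust_contemporary_groups(y, g)
        np.testing.assert_allclose(adj, [-1, 0, 1])

    def test_centered_groups_unchanged(self):
        y = pd.Series([-1.0, 1.0, -2.0, 2.0], index=list("abcd"))
        g = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        adj = assoc.adjust_contemporary_groups(y, g)
        np.testing.assert_allclose(adj, y)

    def test_group_mean_oracle_exact(self):
        rng = np.random.default_rng(31)
        y = pd.Series(rng.normal(size=100),
                      index=[f"a{i}" for i in range(100)])
        g = pd.Series(rng.choice(["u", "v", "w"], 100), index=y.index)
        adj = assoc.adjust_contemporary_groups(y, g)
        for grp in "uvw":
            assert adj[g == grp].mean() == pytest.approx(0.0, abs=1e-12)
            expect = y[g == grp] - y[g == grp].mean()
            np.testing.assert_allclose(adj[g == grp], expect)

    def test_singleton_group_warned(self):
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        g = pd.Series(["x", "x", "solo"], index=list("abc"))
        with pytest.warns(UserWarning, match="singleton"):
            adj = assoc.adjust_contemporary_groups(y, g)
        assert adj["c"] == 0.0


def _halfsib_A(rng, n_sires, per_sire):
    rows = [(f"s{i}", "0", "0", "sire") for i in range(n_sires)]
    k = 0
    for i in range(n_sires):
        for _ in range(per_sire):
            rows.append((f"x{k}", f"s{i}", f"d{k}", "sib"))
            k += 1
    ped = ped_from_rows(rows)
    a, order = assoc.pedigree_nrm(ped)
    animals = [f"x{j}" for j in range(k)]
    return assoc.nrm_submatrix(a, order, animals), animals


def _sample_mvn(rng, a_mat, sg2, se2):
    n = a_mat.shape[0]
    l = np.linalg.cholesky(a_mat + 1e-10 * np.eye(n))
    return math.sqrt(sg2) * (l @ rng.standard_normal(n)) + math.sqrt(
        se2
    ) * rng.standard_normal(n)


class TestREML:
    def test_recovers_moderate_h2(self):
        # a single half-sib realization carries limited information
        # (SE(h2) ~ 0.13 at 40 families x 20 sibs), so check the mean of
        # replicates and the per-replicate z-scores
        a_mat, _ = _halfsib_A(np.random.default_rng(0), 40, 20)  # n = 800
        ests, zs = [], []
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            y = _sample_mvn(rng, a_mat, 0.5, 0.5)
            vc = assoc.reml_animal_model(y, None, a_mat)
            ests.append(vc.h2)
            zs.append((vc.h2 - 0.5) / vc.se_h2)
        assert abs(np.mean(ests) - 0.5) < 0.1
        assert np.max(np.abs(zs)) < 3.0

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(33)
        a_mat, _ = _halfsib_A(rng, 25, 20)  # n = 500
        y = rng.standard_normal(500)
        vc = assoc.reml_animal_model(y, None, a_mat)
        assert vc.h2 < 0.05

    def test_no_residual_boundary_flag(self):
        # strongly identified covariance (spread eigenvalues) so that a
        # zero-residual simulation drives gamma to the optimizer boundary
        rng = np.random.default_rng(34)
        n = 120
        q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        a_mat = q @ np.diag(np.linspace(0.2, 5.0, n)) @ q.T
        a_mat = (a_mat + a_mat.T) / 2
        y = _sample_mvn(rng, a_mat, 1.0, 1e-10)
        vc = assoc.reml_animal_model(y, None, a_mat)
        assert vc.h2 > 0.95
        assert vc.boundary

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            assoc.reml_animal_model(np.array([0.0, 1.0]), None, bad)


class TestSNPAssociation:
    def _setup(self, rng, n_sires=10, per_sire=20, n_snps=100, h2=0.3):
        a_mat, animals = _halfsib_A(rng, n_sires, per_sire)
        n = len(animals)
        geno = make_genotypes(
            rng.binomial(2, rng.uniform(0.2, 0.5, n_snps), (n, n_snps)).astype(
                float
            ),
            samples=animals,
        )
        y = _sample_mvn(rng, a_mat, h2, 1 - h2)
        return a_mat, geno, y, np.arange(n)

    def test_allele_flip_negates_effect(self):
        rng = np.random.default_rng(35)
        a_mat, geno, y, idx = self._setup(rng, n_snps=20)
        res1 = assoc.snp_association(y, None, a_mat, geno, idx)
        flipped = make_genotypes(2.0 - geno.dosages, samples=geno.samples)
        res2 = assoc.snp_association(y, None, a_mat, flipped, idx)
        np.testing.assert_allclose(res1["effect"], -res2["effect"], atol=1e-10)
        np.testing.assert_allclose(res1["p"], res2["p"], atol=1e-12)

    def test_null_pvalues_uniform_and_lambda(self):
        rng = np.random.default_rng(36)
        a_mat, geno, y, idx = self._setup(rng, 25, 20, n_snps=2000, h2=0.4)
        res = assoc.snp_association(y, None, a_mat, geno, idx)
        p = res["p"].dropna().to_numpy()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01
        lam = assoc.genomic_inflation(p)
        assert 0.9 <= lam <= 1.1

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(37)
        a_mat, animals = _halfsib_A(rng, 40, 20)
        n = len(animals)
        geno = make_genotypes(
            rng.binomial(2, 0.4, (n, 50)).astype(float), samples=animals
        )
        beta = 0.5  # half a phenotypic SD per allele
        y = _sample_mvn(rng, a_mat, 0.3, 0.7) + beta * geno.dosages[:, 7]
        res = assoc.snp_association(y, None, a_mat, geno, np.arange(n))
        row = res.iloc[7]
        assert abs(row["effect"] - beta) < 2 * row["se"]
        assert row["p"] < 1e-6

    def test_monomorphic_flagged(self):
        rng = np.random.default_rng(38)
        a_mat, geno, y, idx = self._setup(rng, n_snps=5)
        geno.dosages[:, 2] = 2.0
        res = assoc.snp_association(y, None, a_mat, geno, idx)
        assert bool(res.iloc[2]["monomorphic"])
        assert np.isnan(res.iloc[2]["effect"])

    def test_gls_matches_exact_lrt_oracle(self):
        """Fixed-V Wald p-values track full per-SNP ML re-estimation."""
        rng = np.random.default_rng(39)
        a_mat, geno, y, idx = self._setup(rng, 10, 20, n_snps=40, h2=0.4)
        y = y + 0.3 * geno.dosages[:, 0]  # one modest signal
        res = assoc.snp_association(y, None, a_mat, geno, idx)
        d, u = np.linalg.eigh(a_mat)
        yr = u.T @ y
        ones = u.T @ np.ones(len(y))

        def ml_loglik(gamma, yv, xv):
            v = gamma * d + 1.0
            w = 1.0 / v
            xtwx = xv.T @ (xv * w[:, None])
            beta = np.linalg.solve(xtwx, xv.T @ (yv * w))
            r = yv - xv @ beta
            n = len(yv)
            s2 = float(r @ (r * w)) / n
            return -0.5 * (n * math.log(s2) + np.log(v).sum() + n)

        def fit(xv):
            f = lambda lg: -ml_loglik(math.exp(lg), yr, xv)
            r = optimize.minimize_scalar(f, bounds=(-10, 10), method="bounded")
            return -r.fun

        ll0 = fit(ones[:, None])
        for s in range(0, 40, 4):
            g = u.T @ geno.dosages[:, s]
            ll1 = fit(np.column_stack([ones, g]))
            lrt = max(0.0, 2 * (ll1 - ll0))
            p_lrt = stats.chi2.sf(lrt, 1)
            p_wald = res.iloc[s]["p"]
            assert abs(-np.log10(p_wald) - (-np.log10(p_lrt))) < 0.2


class TestFDR:
    from hypothesis import given, settings
    from hypothesis import strategies as hs

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        hs.floats(min_value=1e-6, max_value=0.049),
        hs.integers(min_value=1, max_value=999),
    )
    def test_nonnegative_and_decreasing_in_hits(self, p, a):
        """More significant tests at a fixed cutoff always lower the FDR."""
        t = 1000
        f1 = assoc.fdr_at_threshold(p, a, t)
        f2 = assoc.fdr_at_threshold(p, min(a + 1, t), t)
        assert f1 >= 0
        assert f2 <= f1 + 1e-12

    def test_threshold_equal_rate_gives_one(self):
        assert assoc.fdr_at_threshold(0.05, 50, 1000) == pytest.approx(1.0)

    def test_worked_closed_form(self):
        got = assoc.fdr_at_threshold(0.001, 100, 1000)
        assert got == pytest.approx(0.001 * 0.9 / (0.1 * 0.999))
        assert got == pytest.approx(0.009009, abs=1e-6)

    def test_random_sets_match_direct_formula(self):
        rng = np.random.default_rng(40)
        for _ in range(20):
            t = int(rng.integers(100, 10_000))
            p = float(rng.uniform(1e-5, 0.05))
            a = int(rng.integers(1, t))
            frac = a / t
            assert assoc.fdr_at_threshold(p, a, t) == pytest.approx(
                p * (1 - frac) / (frac * (1 - p))
            )

    def test_zero_significant_flagged(self):
        with pytest.warns(UserWarning):
            assert assoc.fdr_at_threshold(0.001, 0, 1000) == 1.0


class TestPhenotypeCorrelations:
    def test_self_and_anticorrelation(self):
        rng = np.random.default_rng(41)
        y1 = rng.normal(size=100)
        df = pd.DataFrame({"a": y1, "b": -y1})
        corr, n = assoc.phenotype_correlations(df)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert n.loc["a", "b"] == 100

    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(
            {"a": rng.normal(size=600), "b": rng.normal(size=600)}
        )
        corr, _ = assoc.phenotype_correlations(df)
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_pairwise_complete_with_missing(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, np.nan], "b": [1.0, 2.0, np.nan, 4.0]}
        )
        corr, n = assoc.phenotype_correlations(df)
        assert n.loc["a", "b"] == 2
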