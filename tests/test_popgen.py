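import itertools

import numpy as np
import pandas as pd
import pytest

import provgall as pg
from provgall.errors import (
    ConfigurationError,
    InvalidCoordinateError,
    StructureError,
    UndefinedCorrelationError,
    UndefinedPairError,
    UnderdeterminedFitError,
)


def _geno_table(pop_genos):
    """Build a GenotypeTable from {pop: [(a1, a2), ...]} at one locus."""
    rows = []
    for pop, genos in pop_genos.items():
        for i, (a1, a2) in enumerate(genos):
            rows.append((f"{pop}-I{i}", pop, "L01", a1, a2))
    return pg.GenotypeTable(
        pd.DataFrame(rows, columns=["individual", "provenance", "locus", "allele1", "allele2"])
    )


def _wc_oracle_biallelic(genos1, genos2):
    """Direct two-population Weir-Cockerham theta for one biallelic locus.

    Scalar evaluation of the a/b/c variance components, written out
    term by term, independent of the package implementation.
    """
    theta_num = theta_den = 0.0
    for allele in (1, 2):
        n1, n2 = len(genos1), len(genos2)
        p1 = sum((g[0] == allele) + (g[1] == allele) for g in genos1) / (2 * n1)
        p2 = sum((g[0] == allele) + (g[1] == allele) for g in genos2) / (2 * n2)
        h1 = sum((g[0] == allele) != (g[1] == allele) for g in genos1) / n1
        h2 = sum((g[0] == allele) != (g[1] == allele) for g in genos2) / n2
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        theta_num += a
        theta_den += a + b + c
    return theta_num / theta_den


class TestWeirCockerham:
    TOY1 = [(1, 1)] * 3 + [(1, 2)] * 4 + [(2, 2)] * 3
    TOY2 = [(1, 1)] * 6 + [(1, 2)] * 2 + [(2, 2)] * 2

    def test_matches_hand_oracle_on_toy(self):
        g = _geno_table({"A": self.TOY1, "B": self.TOY2})
        theta = pg.wc_theta(g)
        oracle = _wc_oracle_biallelic(self.TOY1, self.TOY2)
        assert theta == pytest.approx(oracle, abs=1e-10)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        genos = {
            pop: [tuple(rng.choice([1, 2], 2, p=[0.6, 0.4])) for _ in range(300)]
            for pop in ("A", "B")
        }
        g = _geno_table(genos)
        assert abs(pg.wc_theta(g)) < 0.02

    def test_fixed_different_alleles_is_one(self):
        g = _geno_table({"A": [(1, 1)] * 10, "B": [(2, 2)] * 10})
        assert pg.wc_theta(g) == pytest.approx(1.0)

    def test_invariant_to_allele_relabeling_and_order(self):
        g = _geno_table({"A": self.TOY1, "B": self.TOY2})
        relabel = {1: 7, 2: 3}
        shuffled = g.calls.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["allele1"] = shuffled["allele1"].map(relabel)
        shuffled["allele2"] = shuffled["allele2"].map(relabel)
        assert pg.wc_theta(pg.GenotypeTable(shuffled)) == pytest.approx(
            pg.wc_theta(g), abs=1e-12
        )

    def test_split_half_of_one_population_near_zero(self, small_genotypes):
        calls = small_genotypes.calls
        one = calls[calls["provenance"] == calls["provenance"].iloc[0]].copy()
        inds = sorted(one["individual"].unique())
        half = set(inds[: len(inds) // 2])
        one["provenance"] = np.where(one["individual"].isin(half), "H1", "H2")
        assert abs(pg.wc_theta(pg.GenotypeTable(one))) < 0.05

    def test_no_shared_locus_raises(self):
        rows = [("a1", "A", "L01", 1, 2), ("a2", "A", "L01", 1, 1),
                ("b1", "B", "L02", 1, 2), ("b2", "B", "L02", 2, 2)]
        g = pg.GenotypeTable(pd.DataFrame(
            rows, columns=["individual", "provenance", "locus", "allele1", "allele2"]))
        with pytest.raises(UndefinedPairError):
            pg.pairwise_fst(g)

    def test_pairwise_matrix_shape(self, small_genotypes):
        fst = pg.pairwise_fst(small_genotypes)
        assert fst.values.shape == (8, 8)
        assert np.allclose(fst.values, fst.values.T)
        assert np.all(np.diag(fst.values) == 0.0)


class TestGreatCircle:
    def test_identical_points_zero(self):
        d = pg.great_circle_distance([10.0, 10.0], [20.0, 20.0])
        assert d[0, 1] == 0.0

    def test_antipodal_on_equator(self):
        d = pg.great_circle_distance([0.0, 0.0], [0.0, 180.0])
        assert d[0, 1] == pytest.approx(np.pi * 6371.0, rel=1e-12)

    def test_exact_symmetry(self):
        rng = np.random.default_rng(2)
        d = pg.great_circle_distance(rng.uniform(-80, 80, 15), rng.uniform(-170, 170, 15))
        assert np.array_equal(d, d.T)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidCoordinateError):
            pg.great_circle_distance([95.0, 0.0], [0.0, 0.0])


class TestMantel:
    def _random_sym(self, rng, n):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return m

    def test_self_correlation(self):
        rng = np.random.default_rng(3)
        A = self._random_sym(rng, 8)
        r, p = pg.mantel_test(A, A, n_perm=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_exact_enumeration_matches_independent_oracle(self):
        rng = np.random.default_rng(4)
        A, B = self._random_sym(rng, 4), self._random_sym(rng, 4)
        r_obs, p = pg.mantel_test(A, B, exact=True)
        iu = np.triu_indices(4, 1)
        r_oracle = np.corrcoef(A[iu], B[iu])[0, 1]
        count = total = 0
        for perm in itertools.permutations(range(4)):
            idx = np.array(perm)
            rp = np.corrcoef(A[iu], B[np.ix_(idx, idx)][iu])[0, 1]
            count += rp >= r_oracle - 1e-12
            total += 1
        assert r_obs == pytest.approx(r_oracle, abs=1e-12)
        assert p == pytest.approx(count / total)

    def test_agrees_with_scikit_bio(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(5)
        A, B = self._random_sym(rng, 10), self._random_sym(rng, 10)
        r, p = pg.mantel_test(A, B, n_perm=999, seed=2)
        r_sk, p_sk, _ = skbio_mantel(A, B, method="pearson",
                                     permutations=999, alternative="greater")
        assert r == pytest.approx(float(r_sk), abs=1e-12)
        assert abs(p - float(p_sk)) < 0.05

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(6)
        n_rep = 200
        rejections = 0
        for i in range(n_rep):
            A, B = self._random_sym(rng, 6), self._random_sym(rng, 6)
            _, p = pg.mantel_test(A, B, n_perm=99, seed=1000 + i)
            rejections += p <= 0.05
        # binomial 99% envelope around 0.05 at 200 replicates
        assert 1 <= rejections <= 20

    def test_constant_matrix_rejected(self):
        A = np.zeros((5, 5))
        with pytest.raises(UndefinedCorrelationError):
            pg.mantel_test(A, A, n_perm=99)


class TestGeoFst:
    def _linear_setup(self, n=6):
        rng = np.random.default_rng(7)
        lat = rng.uniform(40, 55, n)
        lon = rng.uniform(-5, 30, n)
        dist = pg.great_circle_distance(lat, lon)
        fst_vals = 0.002 + 1e-5 * dist
        np.fill_diagonal(fst_vals, 0.0)
        fst = pg.PairwiseFstMatrix(labels=[f"P{i}" for i in range(n)], values=fst_vals)
        return fst, dist

    def test_noiseless_line_is_interpolated_exactly(self):
        fst, dist = self._linear_setup()
        model = pg.fit_geo_fst(fst, dist)
        pred = pg.predict_geo_fst(model, dist, fst.labels)
        iu = np.triu_indices(len(fst.labels), 1)
        assert np.max(np.abs(pred.values[iu] - fst.values[iu])) < 1e-10
        assert model.intercept == pytest.approx(0.002, abs=1e-10)

    def test_prediction_covers_unsampled_provenances(self):
        """17 genotyped of 20 labels -> complete symmetric 20x20 output."""
        fst, dist = self._linear_setup(17)
        d20 = pg.great_circle_distance(
            np.linspace(40, 55, 20), np.linspace(-5, 30, 20)
        )
        model = pg.fit_geo_fst(fst, dist)
        pred = pg.predict_geo_fst(model, d20, [f"Q{i}" for i in range(20)])
        assert pred.values.shape == (20, 20)
        assert np.allclose(pred.values, pred.values.T)
        assert np.all(np.isfinite(pred.values))

    def test_too_few_pairs_rejected(self):
        fst = pg.PairwiseFstMatrix(labels=["A", "B"], values=np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(UnderdeterminedFitError):
            pg.fit_geo_fst(fst, np.array([[0, 100.0], [100.0, 0]]))


class TestBuildCovariance:
    def test_identity_is_exact(self):
        cov = pg.build_covariance(None, "identity", labels=list("abcd"))
        assert np.array_equal(cov.matrix, np.eye(4))
        assert not cov.psd_repair_applied

    def test_zero_fst_gives_all_ones_rank_one(self):
        fst = pg.PairwiseFstMatrix(labels=list("abcd"), values=np.zeros((4, 4)))
        cov = pg.build_covariance(fst, "one_minus_fst")
        assert np.allclose(cov.matrix, np.ones((4, 4)), atol=1e-8)
        assert np.linalg.matrix_rank(cov.matrix, tol=1e-6) == 1

    def test_random_fst_matrices_become_psd(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            f = rng.uniform(-0.05, 0.4, (n, n))
            f = (f + f.T) / 2
            np.fill_diagonal(f, 0.0)
            fst = pg.PairwiseFstMatrix(labels=[str(i) for i in range(n)], values=f)
            cov = pg.build_covariance(fst, "one_minus_fst")
            assert cov.min_eigenvalue() >= -1e-10
            assert np.allclose(cov.matrix, cov.matrix.T)

    def test_intercept_clamping_keeps_covariance_in_unit_interval(self):
        f = np.array([[0.0, -0.05], [-0.05, 0.0]])
        fst = pg.PairwiseFstMatrix(labels=["a", "b"], values=f)
        cov = pg.build_covariance(fst, "one_minus_fst")
        assert cov.matrix[0, 1] == pytest.approx(1.0)

    def test_missing_source_rejected(self):
        with pytest.raises(ConfigurationError):
            pg.build_covariance(None, "one_minus_fst")
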