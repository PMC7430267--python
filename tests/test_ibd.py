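"""Mantel tests, OLS isolation-by-distance fits, and the independent-pair bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mitoibd import (
    Alignment,
    DistanceMatrix,
    IBDFit,
    SampleTable,
    compare_taxa,
    count_site_pairs,
    fit_ibd,
    independent_pair_bootstrap,
    k80_distance,
    mantel_test,
    ols_ibd_fit,
    population_distance_matrices,
)


def _dm(values, units="km", labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"p{i}" for i in range(len(values))]
    return DistanceMatrix(labels, values, units=units)


def _random_dm(rng, n, labels=None):
    raw = rng.random((n, n))
    vals = (raw + raw.T) / 2
    np.fill_diagonal(vals, 0.0)
    return _dm(vals, labels=labels)


class TestPopulationMatrices:
    def test_one_identical_sequence_per_population(self):
        aln = Alignment.from_sequences(["a", "b"], ["ACGT" * 5, "ACGT" * 5])
        table = SampleTable(
            pd.DataFrame(
                {
                    "sample_id": ["a", "b"],
                    "population": ["1", "2"],
                    "clade": ["A", "A"],
                    "latitude": [33.0, 34.0],
                    "longitude": [-117.0, -117.0],
                }
            )
        )
        gen, geo = population_distance_matrices(aln, table)
        assert gen.values[0, 1] == 0.0
        assert geo.values[0, 1] == pytest.approx(111.195080, abs=1e-4)

    def test_mean_of_cross_pairs(self, random_alignment):
        aln = random_alignment(n_samples=4, n_sites=100, seed=9)
        table = SampleTable(
            pd.DataFrame(
                {
                    "sample_id": aln.sample_ids,
                    "population": ["1", "1", "2", "2"],
                    "clade": ["A"] * 4,
                    "latitude": [33, 33, 34, 34],
                    "longitude": [-117] * 4,
                }
            )
        )
        gen, _ = population_distance_matrices(aln, table)
        cross = [
            k80_distance(count_site_pairs(aln.sequence(a), aln.sequence(b)))
            for a in aln.sample_ids[:2]
            for b in aln.sample_ids[2:]
        ]
        assert gen.values[0, 1] == pytest.approx(np.mean(cross))


class TestMantel:
    def test_affine_relation_gives_r_one(self, rng):
        d1 = _random_dm(rng, 6)
        v2 = 3.0 * d1.values + 0.2
        np.fill_diagonal(v2, 0.0)
        d2 = _dm(v2, labels=d1.labels)
        r, p = mantel_test(d1, d2, n_permutations=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_invariant_to_common_relabeling_and_offsets(self, rng):
        d1, d2 = _random_dm(rng, 7), _random_dm(rng, 7)
        r0, _ = mantel_test(d1, d2, n_permutations=9, seed=1)
        perm = rng.permutation(7)
        relabel = lambda d: _dm(
            d.values[np.ix_(perm, perm)], labels=[d.labels[i] for i in perm]
        )
        r1, _ = mantel_test(relabel(d1), relabel(d2), n_permutations=9, seed=1)
        assert r1 == pytest.approx(r0)
        off = d2.values + 0.7
        np.fill_diagonal(off, 0.0)
        r2, _ = mantel_test(d1, _dm(off, labels=d2.labels), n_permutations=9, seed=1)
        assert r2 == pytest.approx(r0)

    @pytest.mark.parametrize("n", [4, 5])
    def test_p_matches_exhaustive_enumeration(self, rng, n):
        """Permutation p at 9,999 draws matches full n! enumeration."""
        d1, d2 = _random_dm(rng, n), _random_dm(rng, n)
        iu = np.triu_indices(n, k=1)
        x = d1.values[iu]
        r_obs = np.corrcoef(x, d2.values[iu])[0, 1]
        rs = []
        for perm in itertools.permutations(range(n)):
            y = d2.values[np.ix_(perm, perm)][iu]
            rs.append(np.corrcoef(x, y)[0, 1])
        exact_p = np.mean([r >= r_obs - 1e-12 for r in rs])
        _, p = mantel_test(d1, d2, n_permutations=9_999, seed=2)
        # +1-corrected permutation p fluctuates around the enumeration value
        se = np.sqrt(exact_p * (1 - exact_p) / 9_999)
        assert abs(p - exact_p) < 4 * se + 2e-4

    def test_matches_skbio_oracle(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d1, d2 = _random_dm(rng, 8), _random_dm(rng, 8)
        r, p = mantel_test(d1, d2, n_permutations=999, seed=3)
        r_sk, p_sk, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values, d1.labels),
            skbio_distance.DistanceMatrix(d2.values, d2.labels),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        assert r == pytest.approx(r_sk, abs=1e-12)
        assert p == pytest.approx(p_sk, abs=0.05)

    def test_zero_variance_error(self):
        flat = _dm(np.ones((4, 4)) - np.eye(4))
        other = _random_dm(np.random.default_rng(0), 4, labels=flat.labels)
        with pytest.raises(ValueError, match="zero variance"):
            mantel_test(flat, other, n_permutations=9)

    def test_needs_three_labels(self):
        d = _dm(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="at least 3"):
            mantel_test(d, d)


class TestOLSFit:
    def test_exact_line(self):
        geo = _dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        gen = _dm(
            np.array([[0, 2e-4, 4e-4], [2e-4, 0, 2e-4], [4e-4, 2e-4, 0]]),
            units="substitutions/site",
        )
        slope, intercept = ols_ibd_fit(gen, geo)
        assert slope == pytest.approx(2e-4)
        assert intercept == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations(self, rng):
        n = 5
        geo = _random_dm(rng, n)
        gen = _random_dm(rng, n, labels=geo.labels)
        slope, intercept = ols_ibd_fit(gen, geo)
        iu = np.triu_indices(n, k=1)
        x, y = geo.values[iu], gen.values[iu]
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert slope == pytest.approx(beta[0])
        assert intercept == pytest.approx(beta[1])

    def test_constant_geography_error(self):
        geo = _dm(np.ones((3, 3)) - np.eye(3))
        gen = _random_dm(np.random.default_rng(1), 3, labels=geo.labels)
        with pytest.raises(ValueError, match="constant geographic"):
            ols_ibd_fit(gen, geo)


class TestIndependentPairBootstrap:
    def _linear_pair(self, rng, n=10, b=2e-4):
        x = np.sort(rng.uniform(0, 300, n))
        geo = np.abs(x[:, None] - x[None, :])
        gen = b * geo
        return (
            _dm(gen, units="substitutions/site"),
            _dm(geo, units="km"),
        )

    def test_noiseless_line_gives_degenerate_ci(self, rng):
        gen, geo = self._linear_pair(rng)
        boot = independent_pair_bootstrap(gen, geo, 200, seed=0)
        assert np.allclose(boot.slopes, 2e-4)
        assert boot.slope_ci[0] == pytest.approx(boot.slope_ci[1])
        assert boot.slope_ci[0] == pytest.approx(2e-4)

    def test_reproducible_from_seed(self, rng):
        gen, geo = self._linear_pair(rng)
        b1 = independent_pair_bootstrap(gen, geo, 100, seed=5)
        b2 = independent_pair_bootstrap(gen, geo, 100, seed=5)
        assert np.array_equal(b1.slopes, b2.slopes)

    def test_minimum_population_count(self):
        gen = _dm(np.zeros((3, 3)), units="substitutions/site")
        geo = _random_dm(np.random.default_rng(2), 3, labels=gen.labels)
        with pytest.raises(ValueError, match="at least 4"):
            independent_pair_bootstrap(gen, geo, 10)

    def test_ci_widens_with_noise(self, rng):
        """CI width grows (in expectation) with the noise scale."""
        widths = []
        for sigma in (0.0, 2e-3, 8e-3):
            w = []
            for rep in range(5):
                r = np.random.default_rng(100 + rep)
                x = np.sort(r.uniform(0, 300, 16))
                geo = np.abs(x[:, None] - x[None, :])
                eps = r.normal(0, sigma, geo.shape)
                eps = (eps + eps.T) / 2
                gen = np.clip(2e-4 * geo + eps, 0, None)
                np.fill_diagonal(gen, 0)
                boot = independent_pair_bootstrap(
                    _dm(gen, units="substitutions/site"),
                    _dm(geo, units="km"),
                    300,
                    seed=rep,
                )
                w.append(boot.slope_ci[1] - boot.slope_ci[0])
            widths.append(np.mean(w))
        assert widths[0] < widths[1] < widths[2]

    def test_not_anticonservative_under_independent_noise(self):
        """Coverage of the generating slope with independent tip + pair noise."""
        rng = np.random.default_rng(11)
        n, b = 20, 2e-4
        cover = 0
        N = 60
        for rep in range(N):
            x = np.sort(rng.uniform(0, 300, n))
            geo = np.abs(x[:, None] - x[None, :])
            tip = rng.normal(0, 0.004, n)
            eps = rng.normal(0, 0.002, (n, n))
            eps = (eps + eps.T) / 2
            gen = np.clip(0.005 + b * geo + tip[:, None] + tip[None, :] + eps, 0, None)
            np.fill_diagonal(gen, 0)
            boot = independent_pair_bootstrap(
                _dm(gen, units="substitutions/site"), _dm(geo, units="km"), 300, seed=rep
            )
            cover += boot.slope_ci[0] <= b <= boot.slope_ci[1]
        assert cover / N >= 0.93


class TestComparisonAndFit:
    def _fit(self, slope_ci, intercept_ci=(0.0, 1.0), label="t"):
        return IBDFit(
            label=label,
            n_populations=10,
            mantel_r=0.5,
            mantel_p=0.01,
            n_permutations=999,
            slope=float(np.mean(slope_ci)),
            intercept=0.5,
            bootstrap_replicates=100,
            slope_ci=slope_ci,
            intercept_ci=intercept_ci,
        )

    def test_identical_fits_overlap(self):
        f = self._fit((1.0, 2.0))
        cmp = compare_taxa(f, f)
        assert cmp.slope_cis_overlap and cmp.intercept_cis_overlap

    def test_disjoint_slope_cis(self):
        # e.g. (1.670-3.174) vs (-0.049-0.310), in 1e-4 units
        a = self._fit((1.670e-4, 3.174e-4), label="major")
        b = self._fit((-0.049e-4, 0.310e-4), label="lugubris")
        assert not compare_taxa(a, b).slope_cis_overlap

    def test_touching_intervals_overlap(self):
        a = self._fit((1.0, 2.0))
        b = self._fit((2.0, 3.0))
        assert compare_taxa(a, b).slope_cis_overlap

    def test_fit_ibd_deterministic_and_validated(self, rng):
        x = np.sort(rng.uniform(0, 300, 12))
        geo = np.abs(x[:, None] - x[None, :])
        eps = rng.normal(0, 1e-3, geo.shape)
        eps = (eps + eps.T) / 2
        gen = np.clip(2e-4 * geo + eps, 0, None)
        np.fill_diagonal(gen, 0)
        gen_dm = _dm(gen, units="substitutions/site")
        geo_dm = _dm(geo, units="km")
        f1 = fit_ibd(gen_dm, geo_dm, n_permutations=99, n_replicates=100, seed=4)
        f2 = fit_ibd(gen_dm, geo_dm, n_permutations=99, n_replicates=100, seed=4)
        assert (f1.mantel_r, f1.mantel_p, f1.slope_ci) == (
            f2.mantel_r,
            f2.mantel_p,
            f2.slope_ci,
        )
        assert f1.slope_ci[0] <= f1.slope <= f1.slope_ci[1]
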