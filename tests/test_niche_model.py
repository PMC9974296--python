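"""Ellipsoid niche models, suitability maps, overlap and similarity tests."""

import numpy as np
import pytest

from gorget import niche_model as nm
from gorget.niche_model import (
    EnvRasterStack,
    Grid,
    OccurrenceSet,
    background_similarity_test,
    env_pca,
    extract_env,
    fit_mve,
    read_ascii_grid,
    schoeners_D,
    suitability_map,
    write_ascii_grid,
)
from gorget.synthetic_data import NicheGenSpec, gen_niche_system


@pytest.fixture(scope="module")
def identical_system():
    spec = NicheGenSpec(
        niche_centre={"A": [0.5, 0, 0, 0.5], "B": [0.5, 0, 0, 0.5]},
        niche_cov={"A": np.eye(4) * 0.3, "B": np.eye(4) * 0.3},
        n_occurrences=100,
        seed=21,
    )
    return gen_niche_system(spec)


class TestRasterIO:
    def test_round_trip(self, tmp_path, rng):
        grid = Grid(nrows=5, ncols=7, xll=-3.0, yll=10.0, cellsize=0.5)
        data = rng.normal(size=(5, 7))
        data[0, 0] = np.nan
        p = tmp_path / "layer.asc"
        write_ascii_grid(p, data, grid)
        back, g2 = read_ascii_grid(p)
        assert g2 == grid
        np.testing.assert_allclose(back, data, atol=1e-6, equal_nan=True)


class TestExtractEnv:
    @staticmethod
    def stack():
        grid = Grid(nrows=4, ncols=5, xll=0.0, yll=0.0, cellsize=1.0)
        a = np.arange(20, dtype=float).reshape(4, 5)
        return EnvRasterStack(layers={"a": a, "b": 2 * a}, grid=grid)

    def test_cell_centre_exact(self):
        stack = self.stack()
        occ = OccurrenceSet("sp", np.array([2.5]), np.array([0.5]))
        out = extract_env(occ, stack)
        # lat 0.5 is the bottom row (row 3), col 2 -> value 17
        np.testing.assert_array_equal(out.env, [[17.0, 34.0]])

    def test_off_grid_points_dropped_and_counted(self):
        stack = self.stack()
        occ = OccurrenceSet("sp", np.array([2.5, 99.0]), np.array([0.5, 0.5]))
        out = extract_env(occ, stack)
        assert len(out) == 1 and out.n_dropped == 1

    def test_all_points_off_grid_error(self):
        stack = self.stack()
        occ = OccurrenceSet("sp", np.array([99.0]), np.array([99.0]))
        with pytest.raises(ValueError):
            extract_env(occ, stack)

    def test_matches_direct_indexing_oracle(self, rng):
        stack = self.stack()
        lon = rng.uniform(0, 5, 100)
        lat = rng.uniform(0, 4, 100)
        out = extract_env(OccurrenceSet("sp", lon, lat), stack)
        col = np.floor(lon).astype(int).clip(0, 4)
        row = (3 - np.floor(lat).astype(int)).clip(0, 3)
        np.testing.assert_array_equal(out.env[:, 0], stack.layers["a"][row, col])


class TestFitMVE:
    def test_centre_recovers_sample_mean(self, rng):
        X = rng.normal(loc=[1.0, -2.0, 0.5], scale=1.0, size=(200, 3))
        model = fit_mve(X, seed=0)
        se = 1.0 / np.sqrt(200)
        assert np.all(np.abs(model.centre - X.mean(axis=0)) < 3 * se + 0.2)

    def test_robust_to_gross_outliers(self, rng):
        X = rng.normal(size=(100, 3))
        contaminated = X.copy()
        contaminated[:10] += 20.0
        robust = fit_mve(contaminated, seed=1)
        classical = fit_mve(contaminated, method="classical")
        clean_mean = X[10:].mean(axis=0)
        assert np.linalg.norm(robust.centre - clean_mean) < np.linalg.norm(
            classical.centre - clean_mean
        )

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(80, 4))
        m1 = fit_mve(X, seed=7)
        m2 = fit_mve(X, seed=7)
        np.testing.assert_array_equal(m1.centre, m2.centre)
        np.testing.assert_array_equal(m1.shape, m2.shape)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_mve(rng.normal(size=(4, 3)))


class TestSuitability:
    @staticmethod
    def simple_model():
        return nm.MVEModel(
            centre=np.array([0.0, 0.0]),
            shape=np.diag([4.0, 9.0]),
            coverage=0.9,
            t_cover=4.0,
            t90=4.0,
        )

    def test_centre_cell_has_unit_suitability(self):
        model = self.simple_model()
        assert model.mahalanobis_sq([[0.0, 0.0]])[0] == 0.0

    def test_hand_arithmetic_mahalanobis(self):
        model = self.simple_model()
        d2 = model.mahalanobis_sq([[2.0, 3.0]])[0]
        assert d2 == pytest.approx(2.0)  # 4/4 + 9/9

    def test_binary_map_covers_90pct_of_occurrences(self, identical_system):
        stack, occ, _ = identical_system
        model = fit_mve(occ["A"].env, seed=3)
        smap = suitability_map(model, stack)
        rows, cols = stack.grid.cell_of(occ["A"].lon, occ["A"].lat)
        frac = smap.binary[rows, cols].mean()
        assert frac >= 0.9

    def test_affine_rescaling_invariance(self, identical_system):
        """Rescaling an environmental layer and refitting leaves the
        Mahalanobis suitability surface unchanged."""
        stack, occ, _ = identical_system
        m1 = fit_mve(occ["A"].env, seed=5)
        s1 = suitability_map(m1, stack)
        layers2 = dict(stack.layers)
        layers2["env0"] = 10.0 * layers2["env0"] + 3.0
        stack2 = EnvRasterStack(layers=layers2, grid=stack.grid)
        env2 = occ["A"].env.copy()
        env2[:, 0] = 10.0 * env2[:, 0] + 3.0
        m2 = fit_mve(env2, seed=5)
        s2 = suitability_map(m2, stack2)
        np.testing.assert_allclose(s1.suitability, s2.suitability, atol=1e-8)


class TestSchoenersD:
    def test_self_overlap_is_one(self, rng):
        m = np.abs(rng.normal(size=(10, 10)))
        assert schoeners_D(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_binary_maps_zero(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        a[0, 0] = 1.0
        b[3, 3] = 1.0
        assert schoeners_D(a, b) == 0.0

    def test_two_cell_hand_arithmetic(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.5, 0.5]])
        assert schoeners_D(a, b) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        a = np.abs(rng.normal(size=(6, 6)))
        b = np.abs(rng.normal(size=(6, 6)))
        assert schoeners_D(a, b) == pytest.approx(schoeners_D(b, a), abs=1e-12)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            schoeners_D(np.zeros((3, 3)), np.ones((3, 3)))


class TestBackgroundSimilarity:
    def test_identical_niches_detected_similar(self, identical_system):
        stack, occ, poly = identical_system
        res = background_similarity_test(
            occ["A"], occ["B"], poly["A"], stack, n_reps=99, seed=5
        )
        assert res.p_value <= 0.05
        assert res.D_observed > np.percentile(res.null, 95)

    def test_distant_niches_not_similar(self):
        spec = NicheGenSpec(
            niche_centre={"A": [-0.9, 0, 0, 0], "B": [0.9, 0, 0, 0]},
            niche_cov={"A": np.eye(4) * 0.09, "B": np.eye(4) * 0.09},
            n_occurrences=40,
            seed=11,
        )
        stack, occ, poly = gen_niche_system(spec)
        res = background_similarity_test(
            occ["A"], occ["B"], poly["A"], stack, n_reps=99, seed=5
        )
        assert res.p_value > 0.05

    def test_seed_reproducibility(self, identical_system):
        stack, occ, poly = identical_system
        r1 = background_similarity_test(
            occ["A"], occ["B"], poly["A"], stack, n_reps=99, seed=9
        )
        r2 = background_similarity_test(
            occ["A"], occ["B"], poly["A"], stack, n_reps=99, seed=9
        )
        np.testing.assert_array_equal(r1.null, r2.null)


class TestEnvPCA:
    def test_loadings_orthonormal_and_variance_sums(self, rng):
        X = rng.normal(size=(50, 4))
        _, load, var = env_pca([X])
        np.testing.assert_allclose(
            load.to_numpy().T @ load.to_numpy(), np.eye(4), atol=1e-10
        )
        assert var.sum() == pytest.approx(100.0)

    def test_separation_along_constructed_axis(self, rng):
        a = rng.normal(size=(60, 3))
        b = rng.normal(size=(60, 3))
        # correlate the two nuisance variables so they share one component,
        # leaving the separating variable its own axis
        a[:, 2] = 0.8 * a[:, 0] + 0.2 * a[:, 2]
        b[:, 2] = 0.8 * b[:, 0] + 0.2 * b[:, 2]
        b[:, 1] += 6.0  # separate the niches along the second variable only
        scores, load, _ = env_pca([a, b], names=["x", "y", "z"])
        pc = load.loc["y"].abs().idxmax()  # the component carrying y
        s = scores[pc].to_numpy()
        gap = abs(s[:60].mean() - s[60:].mean())
        within = 0.5 * (s[:60].std() + s[60:].std())
        assert gap > 3 * within
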