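import numpy as np
import pytest
from scipy import linalg

from pheegmark.fda import (
    classification_grid,
    classify,
    cross_validate,
    fit_fda,
    two_axis_projection,
)
from pheegmark.features import build_feature_table


def make_gaussians(rng, n_per_class, delta, dim=2):
    mu1 = np.zeros(dim)
    mu2 = np.zeros(dim)
    mu2[0] = -delta
    X = np.vstack(
        [rng.standard_normal((n_per_class, dim)) + mu1,
         rng.standard_normal((n_per_class, dim)) + mu2]
    )
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return X, y


class TestFitFDA:
    def test_isotropic_symmetric_case(self):
        # exact per-class sample covariance = identity by construction
        a = np.sqrt(1.5)
        base = np.array([[a, 0], [-a, 0], [0, a], [0, -a]])
        X = np.vstack([base + [1.0, 0.0], base + [0.0, 0.0]])
        y = np.array(["c1"] * 4 + ["c2"] * 4)
        m = fit_fda(X, y)
        w_unit = m.w / np.linalg.norm(m.w)
        assert abs(abs(w_unit[0]) - 1.0) < 1e-12
        assert m.s1 == pytest.approx(m.s2)
        assert m.z0 == pytest.approx(float(m.w @ ([0.5, 0.0])), abs=1e-12)

    def test_direction_matches_generalized_eigen_oracle(self, rng):
        X, y = make_gaussians(rng, 60, delta=1.0, dim=5)
        X += rng.standard_normal(5)  # common offset
        m = fit_fda(X, y)
        vals, vecs = linalg.eigh(m.S_B, m.S_W)
        top = vecs[:, np.argmax(vals)]
        cos = abs(m.w @ top) / (np.linalg.norm(m.w) * np.linalg.norm(top))
        assert cos > 1 - 1e-8

    def test_duplicating_samples_preserves_model(self, rng):
        X, y = make_gaussians(rng, 20, delta=2.0, dim=3)
        m1 = fit_fda(X, y)
        m2 = fit_fda(np.vstack([X, X]), np.concatenate([y, y]))
        d1 = m1.w / np.linalg.norm(m1.w)
        d2 = m2.w / np.linalg.norm(m2.w)
        assert np.allclose(d1, d2 * np.sign(d1[0] * d2[0]))
        # z0 is scale-dependent through w; compare on the normalised axis
        assert m2.z0 / np.linalg.norm(m2.w) == pytest.approx(
            m1.z0 / np.linalg.norm(m1.w), rel=1e-6
        )

    def test_singular_scatter_triggers_recorded_ridge(self, rng):
        X, y = make_gaussians(rng, 20, delta=2.0, dim=3)
        X = np.column_stack([X, X[:, 0]])  # duplicated feature -> singular S_W
        m = fit_fda(X, y)
        assert m.ridge > 0

    def test_invalid_inputs(self, rng):
        X, y = make_gaussians(rng, 10, delta=1.0)
        with pytest.raises(ValueError):
            fit_fda(X, np.array(["a"] * 20))
        with pytest.raises(ValueError):
            fit_fda(np.zeros((20, 2)), y)
        Xb = X.copy()
        Xb[0, 0] = np.inf
        with pytest.raises(ValueError):
            fit_fda(Xb, y)

    def test_orthonormal_map_equivariance(self, rng):
        X, y = make_gaussians(rng, 40, delta=1.5, dim=4)
        Q = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        m1 = fit_fda(X, y)
        m2 = fit_fda(X @ Q, y)
        assert np.array_equal(classify(m1, X), classify(m2, X @ Q))
        # scaling features likewise leaves decisions unchanged
        scale = np.array([1.0, 10.0, 0.1, 5.0])
        m3 = fit_fda(X * scale, y)
        assert np.array_equal(classify(m1, X), classify(m3, X * scale))


class TestClassify:
    def test_class_means_and_boundary(self, rng):
        from pheegmark.fda import FDAModel

        X, y = make_gaussians(rng, 50, delta=4.0)
        m = fit_fda(X, y)
        assert classify(m, m.mu1)[0] == m.classes[0]
        # a projection exactly at the threshold goes to class 1 (">= z0")
        toy = FDAModel(
            w=np.array([1.0, 0.0]), z0=0.5, classes=("c1", "c2"),
            mu1=np.array([1.0, 0.0]), mu2=np.array([0.0, 0.0]),
            S1=np.eye(2), S2=np.eye(2), s1=1.0, s2=1.0,
        )
        assert classify(toy, np.array([[0.5, 7.0]]))[0] == "c1"
        assert classify(toy, np.array([[0.5 - 1e-9, 7.0]]))[0] == "c2"

    def test_separated_training_accuracy(self, rng):
        X, y = make_gaussians(rng, 200, delta=6.0, dim=3)
        m = fit_fda(X, y)
        assert np.mean(classify(m, X) == y) == 1.0

    def test_dimension_mismatch(self, rng):
        X, y = make_gaussians(rng, 10, delta=1.0)
        m = fit_fda(X, y)
        with pytest.raises(ValueError):
            classify(m, np.zeros((3, 5)))


class TestCrossValidate:
    def test_separable_classes_reach_100(self, rng):
        X, y = make_gaussians(rng, 50, delta=10.0)
        cv = cross_validate(X, y, k=10, seed=0)
        assert cv.mean_rate == 100.0

    def test_permuted_labels_sit_at_chance(self):
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X, _ = make_gaussians(rng, 100, delta=2.0)
            y = np.array(["a", "b"] * 100)
            y = y[rng.permutation(200)]
            rates.append(cross_validate(X, y, k=10, seed=seed).mean_rate)
        rates = np.asarray(rates)
        sem = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - 50.0) < 3 * sem + 1e-9

    def test_reproducible_and_fold_partition(self, rng):
        X, y = make_gaussians(rng, 30, delta=1.0)
        cv1 = cross_validate(X, y, k=10, seed=42)
        cv2 = cross_validate(X, y, k=10, seed=42)
        assert cv1.mean_rate == cv2.mean_rate
        assert np.array_equal(cv1.fold_assignments, cv2.fold_assignments)
        folds = cv1.fold_assignments[0]
        assert sorted(np.unique(folds)) == list(range(10))
        assert np.bincount(folds).max() - np.bincount(folds).min() <= 1


@pytest.fixture(scope="module")
def planted_table():
    from pheegmark.synthetic import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(
        n_animals_per_strain=4, n_channels=2, n_days=2,
        step_s=10.0, duration_s=3660.0, noise_sd=0.1,
        spike_rate=0.0, outlier_curve_rate=0.0, seed=31,
    )
    cfg.dose_slope_effects[0, :, 3] = 0.25  # Theta slope only, strain SHR
    ds, _ = generate_dataset(cfg)
    return build_feature_table(ds, smoothing_window=None)


class TestClassificationGrid:
    def test_planted_theta_signal_tops_the_grid(self, planted_table):
        grid = classification_grid(
            planted_table, objectives=(("SHR", "WKY"),),
            k=8, seed=0, n_repeats=2, include_all_bands=False,
        )
        rows = grid[grid["day"] == "ALL"].set_index("band")["mean_rate"]
        assert rows.idxmax() == "Theta"

    def test_all_all_cell_dimensions(self, planted_table):
        grid = classification_grid(
            planted_table, objectives=(("SHR", "WIS"),), k=4, seed=1, n_repeats=1
        )
        cell = grid[(grid["band"] == "ALL") & (grid["day"] == "ALL")]
        assert int(cell["n_features"].iloc[0]) == 2 * 9 * 2  # days x bands x params

    def test_exchangeable_classes_stay_at_chance(self):
        from pheegmark.synthetic import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(
            n_animals_per_strain=5, n_channels=2, n_days=1, bands=("Theta", "Alpha"),
            baseline_power_per_band={"Theta": 15.0, "Alpha": 8.0},
            step_s=10.0, duration_s=3660.0, noise_sd=0.1,
            spike_rate=0.0, outlier_curve_rate=0.0, seed=17,
        )
        ds, _ = generate_dataset(cfg)
        table = build_feature_table(ds, smoothing_window=None)
        grid = classification_grid(
            table, objectives=(("SHR", "WKY"),), k=5, seed=3, n_repeats=10,
            include_all_bands=False, include_all_days=False,
        )
        for _, row in grid.iterrows():
            assert abs(row["mean_rate"] - 50.0) <= 3 * max(row["sem"], 1.0) + 20.0


def test_two_axis_projection_separates_strains(small_noisy_dataset):
    ds, _ = small_noisy_dataset
    table = build_feature_table(ds, smoothing_window=None)
    proj = two_axis_projection(table, seed=0)
    assert set(proj.columns) >= {"strain", "x", "y", "train"}
    assert len(proj) == 3 * 3 * 2
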