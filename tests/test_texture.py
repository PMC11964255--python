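import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from collafib import synthetic, texture
from collafib.constants import PX_SIZE_NM


def _image(heights, px=PX_SIZE_NM, id="t"):
    return texture.AFMImage(heights=heights, px_size_nm=px, id=id)


def _roi(pixels):
    return texture.ROI(pixels=pixels)


class TestPatchImage:
    def test_510_square_yields_100(self):
        rois = texture.patch_image(_image(np.zeros((510, 510))))
        assert len(rois) == 100
        assert rois[0].origin == (0, 0)
        assert rois[-1].origin == (459, 459)

    def test_51_square_is_identity(self):
        h = np.arange(51 * 51, dtype=float).reshape(51, 51)
        rois = texture.patch_image(_image(h))
        assert len(rois) == 1
        np.testing.assert_array_equal(rois[0].pixels, h)

    def test_non_multiple_cropped(self):
        # floor(520/51) * floor(515/51) = 10 * 10
        rois = texture.patch_image(_image(np.zeros((520, 515))))
        assert len(rois) == 100

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            texture.patch_image(_image(np.zeros((40, 40))))

    def test_row_major_order(self):
        h = np.zeros((102, 102))
        h[0:51, 51:102] = 7.0
        rois = texture.patch_image(h_img := _image(h))
        assert rois[1].pixels.max() == 7.0
        assert rois[0].pixels.max() == 0.0


class TestExtractFeatures:
    def test_constant_patch_all_zero(self):
        fv = texture.extract_features(_roi(np.full((51, 51), 3.5)))
        assert np.all(fv.values == 0.0)

    def test_banded_roi_has_larger_spectral_peak(self):
        base = dict(field_size_um=1.0, n_fibrils=3, orientation_mode="aligned",
                    aligned_axis_deg=0.0, seed=5)
        banded, _ = synthetic.generate_fibril_image(
            synthetic.PhantomImageConfig(dband_depth=0.8, **base))
        plain, _ = synthetic.generate_fibril_image(
            synthetic.PhantomImageConfig(dband_depth=0.0, **base))
        i = texture.FEATURE_NAMES.index("dband_peak_logscore")
        fb = texture.extract_features(_roi(banded.heights)).values[i]
        fp = texture.extract_features(_roi(plain.heights)).values[i]
        assert fb > fp

    def test_rot90_invariance_of_radial_features(self):
        img, _ = synthetic.generate_fibril_image(
            synthetic.PhantomImageConfig(field_size_um=1.0, n_fibrils=5, seed=2))
        a = texture.extract_features(_roi(img.heights)).values
        b = texture.extract_features(_roi(np.rot90(img.heights).copy())).values
        invariant = [f"psd_bin_{i}" for i in range(6)] + [
            "dband_power_frac", "dband_peak_logscore",
            "coherence_mean", "coherence_p90", "orientation_circvar",
            "grad_pooled_mean", "height_std", "height_span",
        ]
        for name in invariant:
            i = texture.FEATURE_NAMES.index(name)
            assert a[i] == pytest.approx(b[i], rel=1e-6, abs=1e-9), name

    def test_all_finite_on_noise(self):
        rng = np.random.default_rng(0)
        fv = texture.extract_features(_roi(rng.normal(size=(51, 51))))
        assert np.all(np.isfinite(fv.values))
        assert len(fv.values) == len(texture.FEATURE_NAMES)

    def test_translation_invariance_for_periodic_texture(self):
        # pure periodic texture: shifting by a period leaves features nearly
        # unchanged (boundary effects only)
        x = np.arange(70)
        grid = 10.0 * (1 + np.sin(2 * np.pi * x / 10.0))[None, :] * np.ones((70, 1))
        a = texture.extract_features(_roi(grid[:51, 0:51].copy())).values
        b = texture.extract_features(_roi(grid[:51, 10:61].copy())).values
        np.testing.assert_allclose(a, b, rtol=0.05, atol=1e-6)


def _clouds(n=30, sep=10.0, seed=0, d=4):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n, d))
    b = rng.normal(sep, 1.0, (n, d))
    X = np.vstack([a, b])
    y = [False] * n + [True] * n
    return X, y


class TestTrainMetricClassifier:
    def test_separable_clouds_perfect_training_accuracy(self):
        X, y = _clouds()
        clf = texture.train_metric_classifier(X, y, "clarity")
        assert np.array_equal(clf.predict(X), np.asarray(y))

    def test_single_class_rejected_naming_metric(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match="dbanding"):
            texture.train_metric_classifier(X, [True] * 5, "dbanding")

    def test_retraining_is_deterministic(self):
        X, y = _clouds(seed=3)
        c1 = texture.train_metric_classifier(X, y, "clarity")
        c2 = texture.train_metric_classifier(X.copy(), list(y), "clarity")
        np.testing.assert_array_equal(c1.projection_weights, c2.projection_weights)
        assert c1.decision_threshold == c2.decision_threshold

    def test_permuted_labels_approach_majority_rate(self):
        """Labels independent of features: training accuracy tends to the
        majority-class rate as n grows (permutation simulation, 500 ROIs)."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(500, 8))
        y = rng.random(500) < 0.6  # 60% majority
        clf = texture.train_metric_classifier(X, y, "clarity")
        acc = float((clf.predict(X) == y).mean())
        majority = max(y.mean(), 1 - y.mean())
        assert abs(acc - majority) < 0.07

    def test_covariance_positive_definite(self):
        X, y = _clouds(n=3, d=10, seed=1)  # n < d: needs the ridge
        clf = texture.train_metric_classifier(X, y, "clarity")
        eigvals = np.linalg.eigvalsh(clf.pooled_covariance)
        assert np.all(eigvals > 0)

    def test_tie_breaks_positive(self):
        clf = texture.TrainedMetricClassifier(
            metric="clarity", class_means=np.zeros((2, 1)),
            pooled_covariance=np.eye(1), priors=np.array([0.5, 0.5]),
            projection_weights=np.array([1.0]), decision_threshold=2.0,
            ridge=0.0,
        )
        assert bool(clf.predict(np.array([[2.0]]))[0]) is True


class TestLooConsistency:
    def test_separable_is_100(self):
        X, y = _clouds()
        rep = texture.loo_consistency(X, y, "clarity")
        assert rep.consistency_pct == 100.0
        assert rep.threshold_pct == 0.0

    def test_threshold_complement_of_paper_value(self):
        rep = texture.ConsistencyReport(metric="dbanding", consistency_pct=86.0, n_rois=3000)
        assert rep.threshold_pct == 14.0

    def test_matches_brute_force_oracle_small_n(self):
        """Independent oracle: explicit enumeration of all single-holdout
        fits through the public training API."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 3))
        X[4:] += 1.0
        y = [False] * 4 + [True] * 4
        rep = texture.loo_consistency(X, y, "clarity")
        correct = 0
        for i in range(8):
            keep = [j for j in range(8) if j != i]
            clf = texture.train_metric_classifier(X[keep], [y[j] for j in keep], "clarity")
            correct += bool(clf.predict(X[i:i + 1])[0]) == y[i]
        assert rep.consistency_pct == pytest.approx(100.0 * correct / 8)

    @given(st.floats(min_value=0.0, max_value=100.0))
    def test_threshold_plus_consistency_is_100(self, pct):
        rep = texture.ConsistencyReport(metric="clarity", consistency_pct=pct, n_rois=10)
        assert rep.threshold_pct + rep.consistency_pct == 100.0


class TestLabelAgreement:
    def test_identical_is_100(self):
        rep = texture.label_agreement([True, False, True], [True, False, True], "clarity")
        assert rep.consistency_pct == 100.0

    def test_complementary_is_0(self):
        rep = texture.label_agreement([True, False], [False, True], "clarity")
        assert rep.consistency_pct == 0.0

    def test_half_agreeing_700(self):
        a = [True] * 700
        b = [True] * 350 + [False] * 350
        rep = texture.label_agreement(a, b, "clarity")
        assert rep.consistency_pct == 50.0
        assert rep.n_rois == 700

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            texture.label_agreement([True], [True, False], "clarity")


class TestPrevalenceTable:
    @staticmethod
    def _trivial_classifiers():
        clfs = {}
        for i, metric in enumerate(texture.METRICS):
            d = len(texture.FEATURE_NAMES)
            clfs[metric] = texture.TrainedMetricClassifier(
                metric=metric, class_means=np.zeros((2, d)),
                pooled_covariance=np.eye(d), priors=np.array([0.5, 0.5]),
                projection_weights=np.zeros(d), decision_threshold=-1.0,
                ridge=0.0,
            )
        return clfs

    def test_all_positive_is_100(self):
        feats = np.zeros((5, len(texture.FEATURE_NAMES)))
        prev = texture.prevalence_table(self._trivial_classifiers(), features=feats)
        for metric in texture.METRICS:
            assert prev[metric] == 100.0
        assert prev["linearity_kinked"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            texture.prevalence_table(self._trivial_classifiers(), rois=[])

    def test_pooling_is_count_weighted_mean(self):
        rng = np.random.default_rng(1)
        d = len(texture.FEATURE_NAMES)
        clfs = self._trivial_classifiers()
        w = rng.normal(size=d)
        clfs["clarity"].projection_weights = w
        clfs["clarity"].decision_threshold = 0.0
        a = rng.normal(size=(30, d))
        b = rng.normal(size=(70, d))
        pa = texture.prevalence_table(clfs, features=a)["clarity"]
        pb = texture.prevalence_table(clfs, features=b)["clarity"]
        pooled = texture.prevalence_table(clfs, features=np.vstack([a, b]))["clarity"]
        assert pooled == pytest.approx((30 * pa + 70 * pb) / 100.0)


class TestChangeTable:
    THRESHOLDS = {"dbanding": 14.0, "clarity": 16.0,
                  "random_orientation": 6.0, "linearity": 7.0}

    def test_ws_fibril_clarity_change(self):
        ctrl = {"clarity": 69.0, "dbanding": 73.0, "random_orientation": 97.0,
                "linearity": 92.0}
        irr = {"clarity": 41.0, "dbanding": 57.0, "random_orientation": 95.0,
               "linearity": 83.0}
        rows = {r.metric: r for r in texture.change_table(ctrl, irr, self.THRESHOLDS)}
        assert rows["clarity"].change_pct == pytest.approx(-28.0)
        assert rows["dbanding"].change_pct == pytest.approx(-16.0)
        assert rows["linearity"].change_pct == pytest.approx(9.0)  # kinked% bookkeeping
        flagged = sum(r.exceeds for r in rows.values())
        assert flagged == 3
        assert not rows["random_orientation"].exceeds

    def test_identical_prevalences_no_exceedance(self):
        prev = {m: 50.0 for m in texture.METRICS}
        rows = texture.change_table(prev, dict(prev), self.THRESHOLDS)
        assert all(r.change_pct == 0.0 and not r.exceeds for r in rows)

    def test_missing_metric_rejected(self):
        with pytest.raises(KeyError):
            texture.change_table({"clarity": 10.0}, {"clarity": 10.0}, self.THRESHOLDS)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=8, max_size=8))
    def test_antisymmetry(self, vals):
        a = dict(zip(texture.METRICS, vals[:4]))
        b = dict(zip(texture.METRICS, vals[4:]))
        fwd = texture.change_table(a, b, self.THRESHOLDS)
        rev = texture.change_table(b, a, self.THRESHOLDS)
        for rf, rr in zip(fwd, rev):
            assert rf.change_pct == pytest.approx(-rr.change_pct)


class TestConsistencyGain:
    def test_dbanding_gain(self):
        assert texture.consistency_gain(84.0, 59.0) == 25.0


class TestClassifierPersistence:
    def test_json_round_trip_replays_predictions(self):
        X, y = _clouds(seed=11)
        clf = texture.train_metric_classifier(X, y, "clarity")
        restored = texture.classifiers_from_json(
            texture.classifiers_to_json({"clarity": clf}))["clarity"]
        np.testing.assert_array_equal(clf.predict(X), restored.predict(X))
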