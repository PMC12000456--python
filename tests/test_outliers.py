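"""IQR bounds, feature extraction and dataset-level rejection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cystodx.data import DatasetManifest
from cystodx.fixtures import FixtureConfig, generate_dataset
from cystodx.outliers import (
    IQROutlierFilter,
    compute_iqr_bounds,
    extract_feature,
    feature_scalar,
    filter_outliers,
)


def oracle_quartile(values, p):
    """Independent sort-and-interpolate percentile at position p*(n-1)."""
    v = sorted(values)
    pos = p * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


class TestExtractFeature:
    def test_uniform_half(self):
        assert extract_feature(np.full((8, 8, 3), 0.5)) == pytest.approx(0.5)

    def test_checkerboard(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        img = np.repeat(board[:, :, None], 3, axis=2).astype(float)
        assert extract_feature(img) == pytest.approx(0.5)

    def test_all_black(self):
        assert extract_feature(np.zeros((8, 8, 3))) == 0.0

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown feature"):
            extract_feature(np.zeros((8, 8, 3)), "banana")

    def test_embedding_is_vector_reduced_to_norm(self):
        img = np.random.default_rng(0).random((32, 32, 3))
        vec = extract_feature(img, "embedding")
        assert vec.ndim == 1 and len(vec) > 1
        assert feature_scalar(img, "embedding") == pytest.approx(np.linalg.norm(vec))


class TestIQRBounds:
    def test_constant_vector(self):
        b = compute_iqr_bounds([1, 1, 1, 1])
        assert b.q1 == b.q3 == b.lower == b.upper == 1
        assert b.iqr == 0

    def test_hand_example(self):
        b = compute_iqr_bounds([2, 4, 6, 8, 10, 12, 14, 16])
        assert b.q1 == pytest.approx(5.5)
        assert b.q3 == pytest.approx(12.5)
        assert b.iqr == pytest.approx(7.0)
        assert b.lower == pytest.approx(-5.0)
        assert b.upper == pytest.approx(23.0)

    def test_default_multiplier(self):
        assert compute_iqr_bounds([1, 2, 3, 4]).multiplier == 1.5

    def test_too_few_or_nonfinite(self):
        with pytest.raises(ValueError):
            compute_iqr_bounds([1, 2, 3])
        with pytest.raises(ValueError):
            compute_iqr_bounds([1, 2, np.nan, 4])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=50),
           st.floats(0.1, 3.0))
    def test_matches_independent_oracle(self, values, mult):
        b = compute_iqr_bounds(values, mult)
        q1 = oracle_quartile(values, 0.25)
        q3 = oracle_quartile(values, 0.75)
        assert b.q1 == pytest.approx(q1, abs=1e-12 * max(1, abs(q1)))
        assert b.q3 == pytest.approx(q3, abs=1e-12 * max(1, abs(q3)))
        assert b.lower == pytest.approx(q1 - mult * (q3 - q1), rel=1e-12, abs=1e-9)
        assert b.upper == pytest.approx(q3 + mult * (q3 - q1), rel=1e-12, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=50))
    def test_invariants(self, values):
        b = compute_iqr_bounds(values)
        assert b.q1 <= b.q3
        assert b.iqr == b.q3 - b.q1
        assert b.lower <= b.upper


@pytest.fixture(scope="module")
def outlier_fixture(tmp_path_factory):
    cfg = FixtureConfig(n_per_class=25, outlier_fraction=0.1, seed=5)
    return generate_dataset(cfg, tmp_path_factory.mktemp("ofx"))


class TestFilterOutliers:
    def test_five_value_example(self, tmp_path):
        # features [0.5]*4 + [0.9]: quartiles of the sorted 5 values collapse
        # to 0.5, so the bright image is the only rejection
        from cystodx.data import ManifestRecord, save_image

        paths = []
        for i, v in enumerate([0.5, 0.5, 0.5, 0.5, 0.9]):
            p = tmp_path / f"im{i}.png"
            save_image(np.full((8, 8, 3), v), p)
            paths.append(str(p))
        m = DatasetManifest([ManifestRecord(p, "HGC", "train") for p in paths])
        report = filter_outliers(m)
        assert len(report.kept) == 4
        assert len(report.rejected) == 1
        assert report.rejected[0].reason == "above_upper"
        assert report.rejected[0].image_path == paths[4]

    def test_identical_features_keep_all(self, tmp_path):
        from cystodx.data import ManifestRecord, save_image

        paths = []
        for i in range(6):
            p = tmp_path / f"im{i}.png"
            save_image(np.full((8, 8, 3), 0.5), p)
            paths.append(str(p))
        m = DatasetManifest([ManifestRecord(p, "LGC", "train") for p in paths])
        report = filter_outliers(m)
        assert len(report.kept) == 6 and not report.rejected

    def test_partition_property(self, outlier_fixture):
        report = filter_outliers(outlier_fixture)
        kept_paths = {r.image_path for r in report.kept.records}
        rej_paths = {r.image_path for r in report.rejected}
        all_paths = {r.image_path for r in outlier_fixture.records}
        assert kept_paths | rej_paths == all_paths
        assert not kept_paths & rej_paths
        for r in report.rejected:
            assert r.feature_value < report.bounds.lower or \
                r.feature_value > report.bounds.upper

    def test_recovers_injected_outliers(self, outlier_fixture):
        report = filter_outliers(outlier_fixture, multiplier=1.5)
        truth = {r.image_path for r in outlier_fixture.records if r.is_outlier_truth}
        rejected = {r.image_path for r in report.rejected}
        assert truth <= rejected
        clean_rejected = rejected - truth
        n_clean = len(outlier_fixture) - len(truth)
        assert len(clean_rejected) / n_clean <= 0.05

    def test_multiplier_monotonicity(self, outlier_fixture):
        prev = None
        for mult in (0.5, 1.0, 1.5, 2.5, 4.0):
            rejected = {r.image_path
                        for r in filter_outliers(outlier_fixture, multiplier=mult).rejected}
            if prev is not None:
                assert rejected <= prev
            prev = rejected

    def test_empty_manifest(self):
        with pytest.raises(ValueError):
            filter_outliers(DatasetManifest([]))


class TestIQROutlierFilterEstimator:
    def test_sklearn_style_fit_predict(self):
        x = np.array([0.5, 0.51, 0.49, 0.5, 0.52, 0.99])
        f = IQROutlierFilter().fit(x)
        assert list(f.predict(x)) == [1, 1, 1, 1, 1, -1]

    def test_get_set_params(self):
        f = IQROutlierFilter(multiplier=2.0)
        assert f.get_params()["multiplier"] == 2.0
        f.set_params(multiplier=1.0)
        assert f.multiplier == 1.0

    def test_unfitted_predict_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            IQROutlierFilter().predict(np.ones(4))
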