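"""Multigranularity padded scanning: window geometry and forest features."""

import numpy as np
import pytest

from grainrisk import MultiGrainScanner, ScanConfig, pad_and_slice, scan_output_count


def brute_force_windows(x, k, s, padded):
    """Independent enumerator over the explicitly padded vector."""
    x = list(x)
    if padded:
        x = [0.0] * (k - 1) + x + [0.0] * (k - 1)
    return [x[i : i + k] for i in range(0, len(x) - k + 1, s)]


class TestWindowGeometry:
    @pytest.mark.parametrize(
        "M, k, s, padded, expected",
        [
            (10, 3, 1, False, 8),   # M - k + 1
            (10, 3, 1, True, 12),   # (M + k - 2)/s + 1
            (33, 5, 2, True, 19),
            (2, 2, 1, True, 3),
        ],
    )
    def test_window_counts(self, M, k, s, padded, expected):
        assert scan_output_count(M, k, s, padded) == expected

    def test_count_matches_brute_force_over_grid(self):
        for M in range(2, 41):
            for k in range(2, min(M, 10) + 1):
                for s in (1, 2, 3):
                    for padded in (True, False):
                        expected = len(brute_force_windows(range(M), k, s, padded))
                        assert scan_output_count(M, k, s, padded) == expected, (M, k, s, padded)

    def test_padded_contents_match_brute_force_over_grid(self):
        rng = np.random.default_rng(0)
        for M in range(2, 41, 3):
            x = rng.normal(size=M)
            for k in range(2, min(M, 10) + 1):
                for s in (1, 2, 3):
                    expected = brute_force_windows(x, k, s, True)
                    got = pad_and_slice(x, k, s)
                    np.testing.assert_allclose(got, expected)

    def test_pad_and_slice_examples(self):
        np.testing.assert_array_equal(
            pad_and_slice([1, 2], 2, 1), [[0, 1], [1, 2], [2, 0]]
        )
        np.testing.assert_array_equal(
            pad_and_slice([5], 3, 1), [[0, 0, 5], [0, 5, 0], [5, 0, 0]]
        )

    def test_equal_coverage_with_padding(self):
        # with stride 1 and padding every original index is in exactly k windows
        for M in (2, 7, 20):
            for k in (2, 3, 8):
                counts = np.zeros(M)
                for start in range(scan_output_count(M, k, 1, True)):
                    for offset in range(k):
                        orig = start + offset - (k - 1)
                        if 0 <= orig < M:
                            counts[orig] += 1
                assert np.all(counts == k), (M, k)

    def test_unpadded_boundary_deficit(self):
        # without padding the first feature is sampled exactly once
        M, k = 12, 4
        counts = np.zeros(M)
        for start in range(scan_output_count(M, k, 1, False)):
            counts[start : start + k] += 1
        assert counts[0] == 1
        assert counts[M - 1] == 1
        assert np.all(counts[k - 1 : M - k + 1] == k)

    def test_window_longer_than_unpadded_vector_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            scan_output_count(4, 6, 1, padded=False)

    @pytest.mark.parametrize("bad", [dict(M=0, k=2), dict(M=5, k=1), dict(M=5, k=2, s=0)])
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(ValueError):
            scan_output_count(bad["M"], bad["k"], bad.get("s", 1), True)


def _toy_problem(n=200, M=12, seed=0, n_classes=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, M))
    y = np.clip(np.digitize(X[:, 0], [-0.5, 0.5]), 0, n_classes - 1)
    return X, y


class TestScanner:
    CFG = ScanConfig(windows=(2, 4), stride=1, n_classes=3, n_estimators=10)

    def test_transformed_width_is_sum_over_granularities(self):
        X, y = _toy_problem()
        sc = MultiGrainScanner(self.CFG).fit(X, y, seed=1)
        S = sc.transform(X)
        expected = sum(
            scan_output_count(12, k, 1, True) * 3 * 2 for k in (2, 4)
        )
        assert S.shape == (200, expected)
        assert sc.output_width() == expected

    def test_probability_blocks_sum_to_one(self):
        X, y = _toy_problem()
        sc = MultiGrainScanner(self.CFG).fit(X, y, seed=1)
        S = sc.transform(X[:5])
        blocks = S.reshape(5, -1, 3)
        np.testing.assert_allclose(blocks.sum(axis=2), 1.0, atol=1e-9)

    def test_duplicated_sample_gets_identical_rows(self):
        X, y = _toy_problem()
        sc = MultiGrainScanner(self.CFG).fit(X, y, seed=1)
        S = sc.transform(np.vstack([X[0], X[0]]))
        np.testing.assert_array_equal(S[0], S[1])

    def test_deterministic_under_seed(self):
        X, y = _toy_problem()
        S1 = MultiGrainScanner(self.CFG).fit_transform(X, y, seed=5)
        S2 = MultiGrainScanner(self.CFG).fit_transform(X, y, seed=5)
        np.testing.assert_array_equal(S1, S2)

    def test_width_mismatch_rejected(self):
        X, y = _toy_problem()
        sc = MultiGrainScanner(self.CFG).fit(X, y, seed=1)
        with pytest.raises(ValueError, match="width mismatch"):
            sc.transform(X[:, :5])

    def test_missing_class_rejected(self):
        X, y = _toy_problem()
        with pytest.raises(ValueError, match="lack classes"):
            MultiGrainScanner(self.CFG).fit(X, (y == 0).astype(int), seed=1)

    def test_informative_windows_score_above_chance(self):
        # label is a function of feature 0 only: windows containing it learn
        X, y = _toy_problem(n=400)
        sc = MultiGrainScanner(
            ScanConfig(windows=(3,), stride=1, n_classes=3, n_estimators=20)
        ).fit(X, y, seed=1)
        S = sc.transform(X)
        # first granularity, first forest, windows covering feature 0
        P = 3
        probs = S.reshape(400, -1, P)
        window_hit = probs[np.arange(400), 0, y]  # first window contains index 0
        chance = np.mean([np.mean(y == c) for c in range(3)])
        assert window_hit.mean() > chance

    def test_oof_transform_matches_inference_shape_and_normalization(self):
        X, y = _toy_problem()
        sc = MultiGrainScanner(self.CFG)
        S_train = sc.fit_transform_oof(X, y, seed=2)
        S_new = sc.transform(X[:7])
        assert S_train.shape[1] == S_new.shape[1] == sc.output_width()
        np.testing.assert_allclose(
            S_train.reshape(len(X), -1, 3).sum(axis=2), 1.0, atol=1e-9
        )

    def test_clipping_of_long_windows(self):
        X, y = _toy_problem(M=3)
        cfg = ScanConfig(windows=(2, 8), stride=1, n_classes=3, n_estimators=5)
        sc = MultiGrainScanner(cfg).fit(X, y, seed=0)
        assert sc._granularities() == [2, 3]  # 8 clipped to M=3
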