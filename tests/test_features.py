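"""Hjorth descriptors, feature vectors and mutual-information ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emorec as er
from emorec._errors import DegenerateSignalError, InvalidArgumentError
from emorec.features import mutual_information


def hjorth_oracle(y):
    """Naive re-implementation straight from the variance definitions."""
    y = np.asarray(y, dtype=float)
    var = lambda x: np.mean((x - np.mean(x)) ** 2)
    d1, d2 = np.diff(y), np.diff(np.diff(y))
    activity = var(y)
    mobility = np.sqrt(var(d1) / var(y))
    complexity = np.sqrt(var(d2) / var(d1)) / mobility
    return activity, mobility, complexity


class TestHjorth:
    def test_alternating_signal_matches_closed_form(self):
        y = np.tile([1.0, -1.0], 100)
        triple = er.hjorth(y)
        expected = hjorth_oracle(y)
        np.testing.assert_allclose(triple.as_tuple(), expected, rtol=1e-12)
        assert triple.activity == 1.0
        # (2, 1) is the mean-free idealisation; finite length leaves a
        # O(1/n) bias because the odd-length difference has non-zero mean.
        assert triple.mobility == pytest.approx(2.0, abs=1e-3)
        assert triple.complexity == pytest.approx(1.0, abs=1e-3)

    def test_sine_closed_forms(self):
        """Unit 10 Hz sine at 128 Hz: activity 1/2, mobility 2 sin(pi f/fs)."""
        fs, f = 128.0, 10.0
        t = np.arange(int(4 * fs)) / fs
        triple = er.hjorth(np.sin(2 * np.pi * f * t))
        assert triple.activity == pytest.approx(0.5, rel=0.01)
        assert triple.mobility == pytest.approx(2 * np.sin(np.pi * f / fs), rel=0.01)
        assert triple.complexity == pytest.approx(1.0, rel=0.01)

    def test_constant_signal_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            er.hjorth(np.full(50, 5.0))

    def test_too_short_signal_rejected(self):
        with pytest.raises(InvalidArgumentError):
            er.hjorth([1.0, 2.0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(rng.integers(5, 51))
        np.testing.assert_allclose(
            er.hjorth(y).as_tuple(), hjorth_oracle(y), rtol=1e-12, atol=1e-12
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(min_value=0.01, max_value=100).filter(lambda v: abs(v) > 1e-6),
        c=st.floats(min_value=-1e3, max_value=1e3),
        seed=st.integers(0, 100),
    )
    def test_scale_and_shift_laws(self, a, c, seed):
        """hjorth(a*y + c): activity scales by a^2; mobility/complexity unchanged."""
        y = np.random.default_rng(seed).standard_normal(64)
        base = er.hjorth(y)
        scaled = er.hjorth(a * y + c)
        assert scaled.activity == pytest.approx(a**2 * base.activity, rel=1e-9)
        assert scaled.mobility == pytest.approx(base.mobility, rel=1e-9)
        assert scaled.complexity == pytest.approx(base.complexity, rel=1e-9)


class TestFeatureVectors:
    def epoch(self, n_samples=192, fill=None, seed=0):
        if fill is not None:
            data = np.full((14, n_samples), fill)
        else:
            data = np.random.default_rng(seed).standard_normal((14, n_samples))
        return er.Epoch(data=data)

    def test_filtered_full_epoch_has_2688_values(self):
        assert len(er.filtered_feature(self.epoch())) == 2688

    def test_filtered_scales_with_epoch_length(self):
        assert len(er.filtered_feature(self.epoch(96))) == 1344

    def test_filtered_zero_epoch_is_zero_vector(self):
        fv = er.filtered_feature(self.epoch(fill=0.0))
        assert len(fv) == 2688 and np.all(fv.values == 0)

    def test_filtered_is_channel_major(self):
        epoch = self.epoch()
        fv = er.filtered_feature(epoch)
        np.testing.assert_array_equal(fv.values[:192], epoch.data[0])
        np.testing.assert_array_equal(fv.values[192:384], epoch.data[1])

    def test_filtered_rejects_wrong_montage(self):
        small = er.Epoch(data=np.zeros((3, 192)), montage=er.Montage(("A", "B", "C")))
        with pytest.raises(InvalidArgumentError):
            er.filtered_feature(small)

    def test_hjorth_feature_lengths(self):
        parts = er.decompose(self.epoch())
        full = er.hjorth_feature(parts)
        six = er.hjorth_feature(parts, er.FRONTAL_CENTRAL_6)
        assert len(full) == 168 and full.family == "hjorth14"
        assert len(six) == 72 and six.family == "hjorth6"

    def test_hjorth_feature_names_follow_layout(self):
        parts = er.decompose(self.epoch())
        fv = er.hjorth_feature(parts)
        assert fv.feature_names[0] == "AF3_delta_activity"
        assert fv.feature_names[1] == "AF3_delta_mobility"
        assert fv.feature_names[3] == "AF3_theta_activity"
        assert fv.feature_names[12] == "F7_delta_activity"
        assert fv.feature_names[-1] == "AF4_beta_complexity"

    def test_zero_decomposition_uses_sentinels_with_warning(self):
        parts = er.decompose(self.epoch(fill=0.0))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fv = er.hjorth_feature(parts)
        assert np.all(fv.values == 0)

    def test_unknown_subset_channel_rejected(self):
        parts = er.decompose(self.epoch())
        bad = er.ChannelSubset("bad", ("AF3", "XX", "F3", "F4", "AF4", "FC5"))
        with pytest.raises(InvalidArgumentError):
            er.hjorth_feature(parts, bad)

    def test_frontal_subset_is_six_montage_channels(self):
        assert len(er.FRONTAL_CENTRAL_6.channels) == 6
        assert set(er.FRONTAL_CENTRAL_6.channels) <= set(
            er.DEFAULT_MONTAGE.channel_names
        )

    def test_feature_csv_roundtrip(self, tmp_path):
        X = np.random.default_rng(0).standard_normal((5, 4))
        labels = [er.EmotionLabel.HAPPY, er.EmotionLabel.CALM, None,
                  er.EmotionLabel.SAD, er.EmotionLabel.SCARED]
        path = tmp_path / "features.csv"
        er.features.write_feature_csv(path, X, labels, ("a", "b", "c", "d"))
        X2, labels2, names = er.features.read_feature_csv(path)
        np.testing.assert_allclose(X2, X, rtol=1e-9)
        assert labels2 == labels and names == ("a", "b", "c", "d")


def mi_oracle(x_binned, y):
    """Exhaustive contingency-table mutual information (nats)."""
    n = len(y)
    total = 0.0
    for xv in set(x_binned):
        for yv in set(y):
            pxy = sum(1 for a, b in zip(x_binned, y) if a == xv and b == yv) / n
            if pxy == 0:
                continue
            px = sum(1 for a in x_binned if a == xv) / n
            py = sum(1 for b in y if b == yv) / n
            total += pxy * np.log(pxy / (px * py))
    return total


class TestMutualInformationRanking:
    def test_estimator_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 4, 60)
        x = y + 0.1 * rng.standard_normal(60)
        from emorec.features import _equal_frequency_bins

        binned = _equal_frequency_bins(x, 8)
        assert mutual_information(x, y) == pytest.approx(
            mi_oracle(list(binned), list(y)), rel=1e-9
        )

    def test_class_copy_feature_ranks_first(self):
        rng = np.random.default_rng(42)
        y = rng.integers(0, 4, 200)
        X = np.column_stack([y.astype(float)]
                            + [rng.standard_normal(200) for _ in range(20)])
        assert er.mi_rank(X, y)[0] == 0

    def test_constant_features_rank_in_index_order(self):
        y = np.tile([0, 1], 20)
        X = np.ones((40, 5))
        np.testing.assert_array_equal(er.mi_rank(X, y), np.arange(5))

    def test_duplicated_informative_features_tie_by_index(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 4, 200)
        noise = rng.standard_normal((200, 3))
        X = np.column_stack([noise[:, 0], y.astype(float), y.astype(float),
                             noise[:, 1], noise[:, 2]])
        ranking = er.mi_rank(X, y)
        assert list(ranking[:2]) == [1, 2]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 4, 100)
        X = rng.standard_normal((100, 10))
        X[:, 3] = y
        perm = rng.permutation(100)
        np.testing.assert_array_equal(er.mi_rank(X, y), er.mi_rank(X[perm], y[perm]))

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            er.mi_rank(np.random.default_rng(0).standard_normal((20, 3)), np.zeros(20))

    def test_agrees_with_knn_estimator_on_top_feature(self):
        """Independent cross-check with sklearn's kNN-based MI estimator."""
        from sklearn.feature_selection import mutual_info_classif

        rng = np.random.default_rng(9)
        y = rng.integers(0, 4, 300)
        X = rng.standard_normal((300, 10))
        X[:, 6] = y + 0.05 * rng.standard_normal(300)
        sk_top = int(np.argmax(mutual_info_classif(X, y, random_state=0)))
        assert er.mi_rank(X, y)[0] == sk_top == 6
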