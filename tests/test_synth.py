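"""Synthetic EEG generator and CSV round-trip."""

import itertools

import numpy as np
import pytest

import emorec as er
from emorec._errors import InvalidArgumentError, ParseError

from conftest import band_power_fraction

FRONTAL = ("AF3", "F3", "F4", "AF4")
BAND_EDGES = {"delta": (0.5, 4), "theta": (4, 8), "alpha": (8, 13), "beta": (13, 30)}


class TestGenerator:
    def test_shape_follows_duration_and_rate(self):
        rec = er.generate_recording("happy", 15, seed=7)
        assert rec.data.shape == (14, 1920)
        assert rec.sampling_rate == 128
        assert np.all(np.isfinite(rec.data))

    @pytest.mark.parametrize("duration,expected", [(1.5, 192), (0.25, 32), (2.0, 256)])
    def test_sample_count_rounds_duration(self, duration, expected):
        assert er.generate_recording("calm", duration, seed=1).n_samples == expected

    def test_equal_seeds_bit_identical(self):
        a = er.generate_recording("calm", 1.5, seed=1)
        b = er.generate_recording("calm", 1.5, seed=1)
        assert np.array_equal(a.data, b.data)

    def test_different_seeds_and_labels_differ(self):
        base = er.generate_recording("calm", 1.5, seed=1)
        other_seed = er.generate_recording("calm", 1.5, seed=2)
        other_label = er.generate_recording("sad", 1.5, seed=1)
        assert not np.array_equal(base.data, other_seed.data)
        assert not np.array_equal(base.data, other_label.data)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(InvalidArgumentError):
            er.generate_recording("happy", 0, seed=1)
        with pytest.raises(InvalidArgumentError):
            er.generate_recording("happy", -3, seed=1)

    def test_calm_has_higher_frontal_alpha_fraction_than_scared(self):
        calm = er.generate_recording("calm", 60, seed=3)
        scared = er.generate_recording("scared", 60, seed=3)
        assert band_power_fraction(calm, 8, 13, FRONTAL) > band_power_fraction(
            scared, 8, 13, FRONTAL
        )

    def test_every_class_pair_spectrally_separable(self):
        """For each label pair some (band, channel) mean power differs >= 3 SE.

        This separability is what makes downstream classification tests
        meaningful rather than vacuous.
        """
        n_rec = 20
        powers = {}  # label -> (n_rec, n_bands, n_channels)
        for label in er.EmotionLabel:
            per_rec = []
            for i in range(n_rec):
                rec = er.generate_recording(label, 2.0, seed=1000 + i)
                from scipy.signal import welch

                freqs, psd = welch(rec.data, fs=128, nperseg=128)
                per_rec.append(
                    [
                        psd[:, (freqs >= lo) & (freqs <= hi)].sum(axis=1)
                        for lo, hi in BAND_EDGES.values()
                    ]
                )
            powers[label] = np.asarray(per_rec)
        for a, b in itertools.combinations(er.EmotionLabel, 2):
            diff = np.abs(powers[a].mean(axis=0) - powers[b].mean(axis=0))
            se = np.sqrt(
                powers[a].var(axis=0, ddof=1) / n_rec
                + powers[b].var(axis=0, ddof=1) / n_rec
            )
            assert np.any(diff >= 3 * se), f"{a} and {b} are not separable"


class TestCsvRoundTrip:
    def test_roundtrip_preserves_everything(self, tmp_path):
        rec = er.generate_recording("scared", 2.0, seed=11)
        path = tmp_path / "rec.csv"
        er.write_csv(rec, path)
        back = er.read_csv(path)
        assert back.sampling_rate == rec.sampling_rate
        assert back.montage.channel_names == rec.montage.channel_names
        assert back.label == rec.label
        assert back.seed == rec.seed
        np.testing.assert_allclose(back.data, rec.data, atol=1e-6)

    def test_wrong_channel_count_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# fs=128\n" + ",".join(er.DEFAULT_MONTAGE.channel_names[:13])
                        + "\n" + ",".join(["0.0"] * 13) + "\n")
        with pytest.raises(ParseError):
            er.read_csv(path)

    def test_empty_data_section_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("# fs=128\n" + ",".join(er.DEFAULT_MONTAGE.channel_names) + "\n")
        with pytest.raises(ParseError, match="empty data"):
            er.read_csv(path)

    def test_non_numeric_cell_names_line(self, tmp_path):
        path = tmp_path / "nan.csv"
        row = ["1.0"] * 14
        bad = ["1.0"] * 13 + ["oops"]
        path.write_text(
            "# fs=128\n"
            + ",".join(er.DEFAULT_MONTAGE.channel_names)
            + "\n" + ",".join(row) + "\n" + ",".join(bad) + "\n"
        )
        with pytest.raises(ParseError, match="line 4"):
            er.read_csv(path)

    def test_inconsistent_row_length_names_line(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text(
            "# fs=128\n"
            + ",".join(er.DEFAULT_MONTAGE.channel_names)
            + "\n" + ",".join(["1.0"] * 14) + "\n" + ",".join(["1.0"] * 12) + "\n"
        )
        with pytest.raises(ParseError, match="line 4"):
            er.read_csv(path)

    def test_missing_rate_header_rejected(self, tmp_path):
        path = tmp_path / "norate.csv"
        path.write_text(",".join(er.DEFAULT_MONTAGE.channel_names) + "\n"
                        + ",".join(["1.0"] * 14) + "\n")
        with pytest.raises(ParseError, match="fs"):
            er.read_csv(path)


class TestTypes:
    def test_montage_needs_unique_channels(self):
        with pytest.raises(InvalidArgumentError):
            er.Montage(("AF3", "AF3"))

    def test_recording_rejects_channel_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            er.EEGRecording(data=np.zeros((3, 10)))

    def test_recording_rejects_non_finite(self):
        data = np.zeros((14, 10))
        data[0, 0] = np.nan
        with pytest.raises(InvalidArgumentError):
            er.EEGRecording(data=data)

    def test_exactly_four_emotion_labels(self):
        assert {l.value for l in er.EmotionLabel} == {"happy", "calm", "sad", "scared"}

    def test_profile_gains_must_be_non_negative(self):
        with pytest.raises(InvalidArgumentError):
            er.ClassSpectralProfile({"alpha": -np.ones(14)})
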