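"""Conditioning-chain checks: filter response, referencing, rectification,
window extraction and the fixed stage order."""

import numpy as np
import pytest
from scipy import signal

from cmcoherence import (
    PreprocessConfig,
    Session,
    average_reference,
    extract_segments,
    filter_channels,
    preprocess,
    rectify,
)
from cmcoherence.preprocessing import bandpass_sos, normalize_segments

FS = 2048.0


def _tone_session(freq_hz, n_s=8.0):
    t = np.arange(int(n_s * FS)) / FS
    x = np.sin(2 * np.pi * freq_hz * t)
    return Session(
        channels={"C4": x.copy(), "APB": x.copy(), "FDI": x.copy(),
                  "FORCE": np.zeros_like(x)},
        fs_hz=FS,
        trial_onsets_s=[1.0],
    )


class TestFilter:
    @pytest.mark.parametrize(
        "freq,check",
        [
            (2.0, lambda r: r < 0.10),   # stop-band tone strongly attenuated
            (20.0, lambda r: abs(r - 1.0) < 0.05),  # pass-band preserved
        ],
    )
    def test_tone_attenuation(self, freq, check):
        cfg = PreprocessConfig()
        out = filter_channels(_tone_session(freq), cfg)
        mid = slice(int(2 * FS), int(6 * FS))  # avoid edge transients
        r = np.std(out.channels["C4"][mid]) / np.std(
            _tone_session(freq).channels["C4"][mid]
        )
        assert check(r)
        # oracle: forward-backward response |H|^2 at the tone frequency
        sos = bandpass_sos(cfg.hp_hz, cfg.lp_hz, FS)
        _, h = signal.sosfreqz(sos, worN=np.array([freq]), fs=FS)
        assert abs(r - np.abs(h[0]) ** 2) < 0.03

    def test_zero_in_zero_out_and_force_untouched(self):
        sess = _tone_session(20.0)
        sess.channels["APB"] = np.zeros_like(sess.channels["APB"])
        sess.channels["FORCE"] = np.full(sess.n_samples, 5.5)
        out = filter_channels(sess, PreprocessConfig())
        np.testing.assert_array_equal(out.channels["APB"], 0.0)
        np.testing.assert_array_equal(out.channels["FORCE"], 5.5)

    def test_invalid_corners_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(hp_hz=100.0, lp_hz=5.0)


class TestAverageReference:
    def _eeg_session(self, rng):
        n = 1024
        return Session(
            channels={
                "C3": rng.standard_normal(n),
                "C4": rng.standard_normal(n),
                "Cz": rng.standard_normal(n),
                "APB": rng.standard_normal(n),
            },
            fs_hz=FS,
            trial_onsets_s=[],
        )

    def test_rereferenced_channels_sum_to_zero(self, rng):
        sess = self._eeg_session(rng)
        out = average_reference(sess, ["C3", "C4", "Cz"])
        total = sum(out.channels[c] for c in ("C3", "C4", "Cz"))
        np.testing.assert_allclose(total, 0.0, atol=1e-12)
        np.testing.assert_array_equal(out.channels["APB"],
                                      sess.channels["APB"])

    def test_identical_channels_become_zero(self, rng):
        x = rng.standard_normal(512)
        sess = Session(channels={"A": x.copy(), "B": x.copy()}, fs_hz=FS,
                       trial_onsets_s=[])
        out = average_reference(sess, ["A", "B"])
        np.testing.assert_allclose(out.channels["A"], 0.0, atol=1e-12)

    def test_single_channel_is_noop(self, rng):
        sess = self._eeg_session(rng)
        out = average_reference(sess, ["C4"])
        np.testing.assert_array_equal(out.channels["C4"],
                                      sess.channels["C4"])

    def test_unknown_channel_rejected(self, rng):
        with pytest.raises(KeyError):
            average_reference(self._eeg_session(rng), ["C4", "Oz"])


class TestRectify:
    def test_examples(self):
        np.testing.assert_array_equal(rectify([-1.0, 2.0, -3.0]),
                                      [1.0, 2.0, 3.0])
        x = np.array([0.0, 1.5, 2.0])
        np.testing.assert_array_equal(rectify(x), x)

    def test_folded_normal_mean(self, rng):
        # |N(0, sigma)| has mean sigma * sqrt(2/pi)
        sigma = 1.7
        x = rectify(sigma * rng.standard_normal(1_000_000))
        expected = sigma * np.sqrt(2 / np.pi)
        assert abs(x.mean() - expected) / expected < 0.02


class TestExtractSegments:
    def test_default_protocol_dimensions(self, default_session):
        segs = extract_segments(default_session, PreprocessConfig(),
                                ("C4", "APB"))
        assert (segs.L, segs.T) == (150, 4096)

    def test_segments_demeaned_and_normalized(self, short_session):
        segs = extract_segments(short_session, PreprocessConfig(),
                                ("C4", "APB"))
        assert np.abs(segs.x_segments.mean(axis=1)).max() < 1e-12
        for m in (segs.x_segments, segs.y_segments):
            pooled_var = np.mean(m**2) - np.mean(m) ** 2
            assert abs(pooled_var - 1.0) < 1e-6

    def test_windows_are_half_open_sample_slices(self):
        # a ramp channel makes the extracted indices directly readable
        n = int(8 * FS)
        x = np.arange(n, dtype=float)
        sess = Session(
            channels={"C4": x, "APB": x.copy(), "FORCE": np.zeros(n)},
            fs_hz=FS,
            trial_onsets_s=[0.5, 3.5],
        )
        cfg = PreprocessConfig(rectify_emg=False, demean_segments=False,
                               window_start_s=0.85, window_len_s=2.0)
        segs = extract_segments(sess, cfg, ("C4", "APB"))
        T = int(round(2.0 * FS))
        expected = np.stack(
            [x[int(round((o + 0.85) * FS)):][:T] for o in (0.5, 3.5)]
        )
        np.testing.assert_allclose(
            segs.x_segments, normalize_segments(expected), rtol=1e-12
        )

    def test_out_of_record_trials_dropped(self, caplog):
        n = int(8 * FS)
        rng = np.random.default_rng(0)
        sess = Session(
            channels={"C4": rng.standard_normal(n),
                      "APB": rng.standard_normal(n)},
            fs_hz=FS,
            trial_onsets_s=[0.5, 3.0, 6.5],  # last window exceeds record
        )
        segs = extract_segments(sess, PreprocessConfig(), ("C4", "APB"))
        assert segs.L == 2
        assert "dropped" in caplog.text

    def test_too_few_trials_rejected(self, rng):
        n = int(4 * FS)
        sess = Session(
            channels={"C4": rng.standard_normal(n),
                      "APB": rng.standard_normal(n)},
            fs_hz=FS,
            trial_onsets_s=[0.5, 3.9],
        )
        with pytest.raises(ValueError, match="usable trial"):
            extract_segments(sess, PreprocessConfig(), ("C4", "APB"))


class TestPipelineOrder:
    def test_preprocess_applies_stages_in_fixed_order(self, short_session):
        cfg = PreprocessConfig()
        got = preprocess(short_session, cfg, ("C4", "APB"))
        # manual chain: filter -> (average reference: no-op, one EEG chan)
        # -> rectify EMG -> segment -> demean -> normalize
        filtered = filter_channels(short_session, cfg)
        manual = extract_segments(filtered, cfg, ("C4", "APB"))
        np.testing.assert_array_equal(got.x_segments, manual.x_segments)
        np.testing.assert_array_equal(got.y_segments, manual.y_segments)

    def test_rectification_order_matters(self, short_session):
        # rectifying before demean/normalize is not the same as after:
        # the chain's result must differ from a rectify-last variant
        cfg = PreprocessConfig()
        chain = preprocess(short_session, cfg, ("C4", "APB"))
        cfg_off = PreprocessConfig(rectify_emg=False)
        variant = preprocess(short_session, cfg_off, ("C4", "APB"))
        wrong = normalize_segments(np.abs(variant.y_segments))
        assert not np.allclose(chain.y_segments, wrong)
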