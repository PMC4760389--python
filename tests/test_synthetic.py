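"""Generator checks: spectral confinement, determinism, force protocol,
closed-form coherence and its trivial limits."""

import logging

import numpy as np
import pytest
from scipy import signal

from cmcoherence import (
    DriveModelParams,
    ProtocolParams,
    SegmentSet,
    coherence,
    estimate_spectra,
    gain_for_band_coherence,
    generate_common_drive,
    generate_session,
    pool_records,
    simulate_segment_set,
    theoretical_coherence,
)

FS = 2048.0


class TestCommonDrive:
    def test_zero_mean_unit_variance(self):
        c = generate_common_drive(DriveModelParams(seed=1), FS, 60.0)
        assert abs(c.mean()) < 1e-12
        assert abs(c.var() - 1.0) < 1e-12

    def test_band_confinement_by_periodogram(self):
        # direct periodogram of a 60 s realization; the 4th-order Butterworth
        # skirts hold ~3% of total power just outside the corners
        c = generate_common_drive(DriveModelParams(seed=2), FS, 60.0)
        f, pxx = signal.periodogram(c, fs=FS)
        out = (f < 15.0) | (f > 30.0)
        assert pxx[out].sum() / pxx.sum() < 0.05

    def test_seeded_determinism(self):
        p = DriveModelParams(seed=7)
        a = generate_common_drive(p, FS, 5.0)
        b = generate_common_drive(p, FS, 5.0)
        np.testing.assert_array_equal(a, b)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            generate_common_drive(
                DriveModelParams(band_lo_hz=15, band_hi_hz=2000), FS, 5.0
            )
        with pytest.raises(ValueError):
            DriveModelParams(band_lo_hz=-1.0)


class TestSessionGeneration:
    def test_session_determinism_and_stream_separation(self, default_drive,
                                                       short_protocol):
        s1 = generate_session(default_drive, short_protocol, "S01", "pre")
        s2 = generate_session(default_drive, short_protocol, "S01", "pre")
        for name in s1.channels:
            np.testing.assert_array_equal(s1.channels[name],
                                          s2.channels[name])
        s3 = generate_session(default_drive, short_protocol, "S01", "post")
        assert not np.array_equal(s1.channels["C4"], s3.channels["C4"])

    def test_trial_count_and_channel_roles(self, short_session,
                                           short_protocol):
        assert len(short_session.trial_onsets_s) == short_protocol.n_trials
        assert set(short_session.channels) == {"C4", "APB", "FDI", "FORCE"}

    def test_force_plateau_level(self, default_session, default_protocol):
        # tracking noise is low-passed, so the plateau mean is checked against
        # the correlated-noise scale, not sd/sqrt(N)
        fs = default_session.fs_hz
        force = default_session.channels["FORCE"]
        vals = []
        for onset in default_session.trial_onsets_s:
            s = int(round((onset + default_protocol.ramp_rise_s + 0.2) * fs))
            e = int(round((onset + default_protocol.ramp_rise_s
                           + default_protocol.plateau_s - 0.2) * fs))
            vals.append(force[s:e].mean())
        assert abs(np.mean(vals) - default_protocol.plateau_n) < 0.02

    def test_zero_gain_gives_no_coherence(self):
        p = DriveModelParams(g_eeg=0.0, g_apb=0.0, g_fdi=0.0, seed=11)
        segs = simulate_segment_set(p, ("C4", "APB"), 150, 1024, FS)
        res = coherence(estimate_spectra(segs))
        frac = np.mean(res.coh[1:] > res.cl95)
        assert frac < 0.10  # ~5% expected by chance

    def test_modulation_mode_clipping_warns(self, caplog, short_protocol):
        p = DriveModelParams(emg_mode="modulation", g_apb=0.8, g_fdi=0.8,
                             seed=3)
        with caplog.at_level(logging.WARNING):
            sess = generate_session(p, short_protocol)
        assert "clipping" in caplog.text

    def test_modulation_mode_couples_after_rectification(self, short_protocol):
        # qualitative check: rectified modulated EMG is coherent with EEG
        # in the drive band, and more so at larger depth
        from cmcoherence import PreprocessConfig, preprocess

        cfg = PreprocessConfig()  # rectify on
        fracs = []
        for depth in (0.2, 0.6):
            p = DriveModelParams(emg_mode="modulation", g_eeg=0.3,
                                 g_apb=depth, g_fdi=depth, seed=5)
            prot = ProtocolParams(n_blocks=1, trials_per_block=50)
            segs = preprocess(generate_session(p, prot), cfg, ("C4", "APB"))
            res = coherence(estimate_spectra(segs))
            band = (res.freqs_hz >= 15) & (res.freqs_hz <= 30)
            fracs.append(np.mean(res.coh[band] > res.cl95))
        assert fracs[1] > 0.5
        assert fracs[1] >= fracs[0]


class TestTheoreticalCoherence:
    def test_noiseless_limit_is_one_in_band(self):
        p = DriveModelParams(noise_sd_eeg=1e-12, noise_sd_apb=1e-12)
        assert theoretical_coherence(p, ("C4", "APB"), 22.5) > 0.999

    def test_zero_gain_is_zero_everywhere(self):
        p = DriveModelParams(g_eeg=0.0)
        f = np.array([5.0, 22.5, 100.0])
        np.testing.assert_allclose(
            theoretical_coherence(p, ("C4", "APB"), f), 0.0
        )

    def test_out_of_band_coherence_negligible(self):
        assert theoretical_coherence(DriveModelParams(), ("C4", "APB"),
                                     60.0) < 1e-3

    def test_modulation_mode_unsupported(self):
        p = DriveModelParams(emg_mode="modulation")
        with pytest.raises(ValueError):
            theoretical_coherence(p, ("C4", "APB"), 22.5)

    def test_gain_for_band_coherence_inverts(self):
        p = DriveModelParams()
        g = gain_for_band_coherence(0.3, p)
        p2 = DriveModelParams(g_eeg=g, g_apb=g)
        assert abs(theoretical_coherence(p2, ("C4", "APB"), 22.5) - 0.3) < 1e-9

    def test_recovery_against_simulation(self):
        # pooled estimate over 8 records vs the closed form at band centre,
        # within the asymptotic 95% band of the estimator
        g = gain_for_band_coherence(0.25, DriveModelParams())
        p = DriveModelParams(g_eeg=g, g_apb=g, g_fdi=g, seed=21)
        rng = np.random.default_rng(21)
        specs = [
            estimate_spectra(
                simulate_segment_set(p, ("C4", "APB"), 100, 2048, FS, rng=rng)
            )
            for _ in range(8)
        ]
        pe = pool_records(specs)
        i = int(np.argmin(np.abs(pe.freqs_hz - 22.5)))
        theo = theoretical_coherence(p, ("C4", "APB"), 22.5)
        z = np.arctanh(np.sqrt(theo))
        half = 1.96 / np.sqrt(2 * pe.n_total)
        lo, hi = np.tanh(z - half) ** 2, np.tanh(z + half) ** 2
        assert lo < pe.coh[i] < hi


class TestMonotonicity:
    def test_estimated_coherence_monotone_in_gain(self):
        # 4-point gain grid; pooled records per point make ordering decisive
        gains = [0.0, 0.05, 0.1, 0.2]
        rng = np.random.default_rng(31)
        means = []
        for g in gains:
            p = DriveModelParams(g_eeg=g, g_apb=g, g_fdi=g)
            specs = [
                estimate_spectra(
                    simulate_segment_set(p, ("C4", "APB"), 100, 2048, FS,
                                         rng=rng)
                )
                for _ in range(6)
            ]
            pe = pool_records(specs)
            band = (pe.freqs_hz >= 15) & (pe.freqs_hz <= 30)
            means.append(float(np.mean(pe.coh[band])))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_coherence_invariant_to_delay(self):
        # same seed, different conduction delay: coherence magnitude agrees
        # within sampling noise at matched realizations
        g = gain_for_band_coherence(0.4, DriveModelParams())
        band_means = []
        for delay in (0.0, 0.011):
            p = DriveModelParams(g_eeg=g, g_apb=g, delay_apb_s=delay, seed=9)
            segs = simulate_segment_set(p, ("C4", "APB"), 150, 2048, FS,
                                        rng=np.random.default_rng(9))
            res = coherence(estimate_spectra(segs))
            band = (res.freqs_hz >= 16) & (res.freqs_hz <= 29)
            band_means.append(float(np.mean(res.coh[band])))
        assert abs(band_means[0] - band_means[1]) < 0.03
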