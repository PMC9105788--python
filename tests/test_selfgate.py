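"""Self-gating: projection profiles, band-pass filtering and PCA coil
selection."""

import numpy as np
import pytest

import pulmophase as pp
from pulmophase.selfgate import (CARDIAC_BAND, RESP_BAND, GatingFailure,
                                 ProjectionProfile, bandpass,
                                 extract_resp_signal, projection_profiles)


def ideal_fft_filter(x, dt_ms, band):
    """Oracle: brick-wall FFT mask band-pass."""
    spec = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(x.size, d=dt_ms / 1000)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0
    return np.fft.irfft(spec, n=x.size)


class TestBandpass:
    def test_separates_respiratory_from_cardiac(self):
        dt = 150.0  # ms
        t = np.arange(1200) * dt / 1000
        x = np.sin(2 * np.pi * 0.25 * t) + np.sin(2 * np.pi * 1.2 * t)
        out = bandpass(x, dt, (0.1, 0.5))
        ref = ideal_fft_filter(x, dt, (0.1, 0.5))
        assert np.corrcoef(out, ref)[0, 1] > 0.99
        assert np.corrcoef(out, np.sin(2 * np.pi * 0.25 * t))[0, 1] > 0.99

    def test_dc_removed(self):
        out = bandpass(np.full(600, 3.7), 150.0, RESP_BAND)
        assert np.abs(out).max() < 1e-8

    def test_slow_drift_attenuated_20db(self):
        dt = 150.0
        t = np.arange(4000) * dt / 1000
        drift = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(drift, dt, RESP_BAND)
        core = slice(500, -500)  # exclude filter edge transients
        atten = np.abs(out[core]).max() / np.abs(drift).max()
        assert atten < 10 ** (-20 / 20)

    def test_inband_passed_within_1db(self):
        dt = 150.0
        t = np.arange(4000) * dt / 1000
        x = np.sin(2 * np.pi * 0.25 * t)
        out = bandpass(x, dt, RESP_BAND)
        core = slice(500, -500)
        gain = np.abs(out[core]).max()
        assert 10 ** (-1 / 20) < gain < 10 ** (1 / 20)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 1000.0, (0.1, 0.6))  # fs = 1 Hz


class TestProjectionProfiles:
    def test_slab_object_peaks_at_slab_position(self, static_stack):
        # replace k-centers with the analytic transform of a one-slab
        # object: profile must peak at that slab for every view-group
        stack = static_stack["stack"]
        nz = stack.protocol.nz
        slab = np.zeros(nz)
        slab[5] = 1.0
        kz = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(slab)))
        data = stack.data.copy()
        data[:, :, 0, :] = kz[None, :, None]
        from pulmophase.rawio import RadialStack
        mod = RadialStack(data=data, traj=stack.traj,
                          protocol=stack.protocol)
        prof = projection_profiles(mod)
        assert np.all(prof.values.argmax(axis=0) == 5)

    def test_static_phantom_profiles_time_invariant(self, static_stack):
        prof = projection_profiles(static_stack["stack"])
        air = static_stack["protocol"].segments()["air"]
        p_air = prof.values[:, air, :]
        spread = p_air.std(axis=1) / (p_air.mean(axis=1) + 1e-12)
        assert spread.max() < 1e-6

    def test_requires_center_out(self, static_stack):
        from pulmophase.rawio import RadialStack
        from pulmophase.trajectory import Trajectory
        s = static_stack["stack"]
        t = s.traj
        bad = Trajectory(angles=t.angles, kz_order=t.kz_order,
                         k_radial=t.k_radial + 1.0, timestamps=t.timestamps)
        with pytest.raises(ValueError):
            projection_profiles(RadialStack(s.data, bad, s.protocol))


def synth_profile(dt=40.0, n=600, nz=8, seed=0):
    """Three coils: respiratory 0.25 Hz, cardiac 1.2 Hz only, pure noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt / 1000
    z = np.arange(nz)
    resp = np.sin(2 * np.pi * 0.25 * t)
    card = np.sin(2 * np.pi * 1.2 * t)
    base = np.exp(-((z - 4.0) ** 2) / 8.0)
    vals = np.empty((nz, n, 3))
    vals[:, :, 0] = base[:, None] * (1 + 0.3 * resp) + \
        0.01 * rng.standard_normal((nz, n))
    vals[:, :, 1] = base[:, None] * (1 + 0.3 * card) + \
        0.01 * rng.standard_normal((nz, n))
    vals[:, :, 2] = 1.0 + 0.3 * rng.standard_normal((nz, n))
    return ProjectionProfile(values=vals, dz=20.0, dt=dt), resp


class TestExtractRespSignal:
    def test_good_coil_selection(self):
        prof, resp = synth_profile()
        sig = extract_resp_signal(prof)
        assert sig.good_coils == (0,)
        assert abs(np.corrcoef(sig.amplitude, resp)[0, 1]) > 0.95

    def test_duplicated_coil_redundancy(self):
        prof, resp = synth_profile()
        dup = ProjectionProfile(
            values=np.concatenate([prof.values, prof.values[:, :, :1]],
                                  axis=2), dz=prof.dz, dt=prof.dt)
        a = extract_resp_signal(prof).amplitude
        b = extract_resp_signal(dup).amplitude
        c = np.corrcoef(a, b)[0, 1]
        assert abs(c) > 0.999

    def test_all_noise_raises_gating_failure(self):
        rng = np.random.default_rng(5)
        vals = 1 + 0.001 * rng.standard_normal((8, 600, 2))
        prof = ProjectionProfile(values=vals, dz=20.0, dt=40.0)
        with pytest.raises(GatingFailure):
            extract_resp_signal(prof)
        # fallback path still yields a signal of the right length
        sig = extract_resp_signal(prof, fallback_single_coil=True)
        assert sig.amplitude.size == 600 and len(sig.good_coils) == 1

    def test_phantom_signal_tracks_true_diaphragm(self, desk_run):
        resp = desk_run["result"].resp
        truth = desk_run["gt"].resp_trace
        assert abs(np.corrcoef(resp.amplitude, truth)[0, 1]) > 0.9

    def test_spectral_peak_matches_phantom_frequency(self, desk_run):
        resp = desk_run["result"].resp
        f_true = desk_run["gt"].resp_freq
        df = resp.fs / resp.amplitude.size
        assert abs(resp.dominant_freq() - f_true) <= max(df, 0.05 * f_true)

    def test_scale_invariance_of_bin_assignments(self, desk_run):
        from pulmophase.binning import sliding_window_bins
        from pulmophase.rawio import RadialStack
        stack = desk_run["stack"]
        scaled = RadialStack(data=stack.data * 3.0, traj=stack.traj,
                             protocol=stack.protocol)
        a = extract_resp_signal(projection_profiles(stack))
        b = extract_resp_signal(projection_profiles(scaled))
        an = a.amplitude / np.abs(a.amplitude).max()
        bn = b.amplitude / np.abs(b.amplitude).max()
        if np.corrcoef(an, bn)[0, 1] < 0:
            bn = -bn
        assert np.allclose(an, bn, atol=1e-4)
        views = np.arange(600)
        sb = pp.RespSignal(amplitude=bn, dt=a.dt)
        sa = pp.RespSignal(amplitude=an, dt=a.dt)
        for ba, bb in zip(sliding_window_bins(sa, views, 186, 18),
                          sliding_window_bins(sb, views, 186, 18)):
            assert np.array_equal(ba.member_views, bb.member_views)

    def test_enhancement_drift_does_not_corrupt_ordering(self):
        """Two phantoms identical except that one has the oxygen
        enhancement switched off: the slow wash-in intensity drift must
        leave the amplitude ordering of the view-groups (hence the bin
        assignments) essentially unchanged."""
        from scipy.stats import spearmanr

        from pulmophase.binning import sliding_window_bins
        from pulmophase.trajectory import ProtocolParams

        p = ProtocolParams(n_views=600, nz=8, n_read=32, matrix=32,
                           fov_xy=320.0, fov_z=160.0, tr=5.0, te=0.14,
                           fa=8.0, segment_bounds=(0, 200, 400, 600))
        from pulmophase.phantom import LUNG_TISSUE_AIR
        base = dict(matrix=32, nz=8, noise_sigma=0.0, seed=9)
        cfg_enh = pp.PhantomConfig(**base)
        cfg_flat = pp.PhantomConfig(**base, lung_o2=LUNG_TISSUE_AIR)
        sig = {}
        for name, cfg in (("enh", cfg_enh), ("flat", cfg_flat)):
            stack, _ = pp.simulate_kspace(cfg, p)
            sig[name] = extract_resp_signal(projection_profiles(stack))
        a, b = sig["enh"].amplitude, sig["flat"].amplitude
        if np.corrcoef(a, b)[0, 1] < 0:
            b = -b
        for seg in (slice(0, 200), slice(400, 600)):
            rho = spearmanr(a[seg], b[seg]).statistic
            assert rho > 0.99
        # bin assignments on the oxygen segment barely move
        views = np.arange(400, 600)
        bins_a = sliding_window_bins(
            pp.RespSignal(amplitude=a, dt=sig["enh"].dt), views, 62, 6)
        bins_b = sliding_window_bins(
            pp.RespSignal(amplitude=b, dt=sig["flat"].dt), views, 62, 6)
        diff = sum(np.setdiff1d(x.member_views, y.member_views).size
                   for x, y in zip(bins_a, bins_b))
        total = sum(len(x) for x in bins_a)
        assert diff / total < 0.05
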