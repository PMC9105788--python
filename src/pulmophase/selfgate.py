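"""Self-gated respiratory signal extraction from spoke k-centers.

Because every center-out spoke starts at k = 0, the first sample of each
spoke is the (coil-weighted) projection integral of the instantaneous
object.  Fourier-transforming the Nz k-center samples of one view-group
along kz yields a 1D projection of the object onto the z
(superior-inferior) axis, one profile every Nz x TR.  Respiration (0.1-0.5
Hz) and cardiac motion (0.6-3.0 Hz) modulate these profiles at separable
frequencies; per-coil band-pass filtering plus PCA over z isolates the
respiratory component, and the most mutually consistent component among
the 'good' coils becomes the representative respiratory trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .rawio import RadialStack

__all__ = [
    "ProjectionProfile",
    "RespSignal",
    "RESP_BAND",
    "CARDIAC_BAND",
    "projection_profiles",
    "bandpass",
    "extract_resp_signal",
    "GatingFailure",
]

RESP_BAND = (0.1, 0.5)
CARDIAC_BAND = (0.6, 3.0)


class GatingFailure(RuntimeError):
    """No coil carried a usable respiratory component."""


@dataclass
class ProjectionProfile:
    """z-projection magnitude per (z, view-group, coil).

    dz is the slice spacing (mm) and dt the temporal spacing Nz x TR (ms).
    Each coil is normalized so its temporal-mean profile has unit energy,
    which removes coil gain and the slow oxygen-enhancement drift from the
    inter-coil comparison.
    """

    values: np.ndarray  # (nz, n_views, n_coils)
    dz: float
    dt: float

    @property
    def n_views(self) -> int:
        return self.values.shape[1]


@dataclass
class RespSignal:
    """One respiratory amplitude per view-group; larger = more inspired,
    end-expiration = minimum amplitude."""

    amplitude: np.ndarray
    dt: float                      # ms
    band: tuple = RESP_BAND
    good_coils: tuple = ()
    diag_components: np.ndarray | None = None  # per-coil leading PCs

    @property
    def fs(self) -> float:
        """Sampling rate, Hz."""
        return 1000.0 / self.dt

    def dominant_freq(self) -> float:
        """Frequency (Hz) of the spectral peak of the amplitude trace."""
        a = self.amplitude - self.amplitude.mean()
        spec = np.abs(np.fft.rfft(a))
        freqs = np.fft.rfftfreq(a.size, d=self.dt / 1000.0)
        return float(freqs[np.argmax(spec)])


def projection_profiles(stack: RadialStack) -> ProjectionProfile:
    """Form z-projection profiles from the k-center sample of every spoke."""
    k0 = stack.traj.k_radial[0]
    if not np.isclose(k0, 0.0):
        raise ValueError("spokes are not center-out: first sample has |k| "
                         f"= {k0}, expected 0")
    centers = stack.data[:, :, 0, :]  # (view, kz, coil)
    prof = np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(centers, axes=1), axis=1), axes=1)
    prof = np.abs(prof).transpose(1, 0, 2).astype(float)  # (z, view, coil)
    mean_energy = np.sqrt((prof.mean(axis=1) ** 2).sum(axis=0))  # per coil
    mean_energy[mean_energy == 0] = 1.0
    prof = prof / mean_energy[None, None, :]
    p = stack.protocol
    return ProjectionProfile(values=prof, dz=p.fov_z / p.nz, dt=p.view_dt)


def bandpass(series: np.ndarray, dt: float, band: tuple = RESP_BAND) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis.

    ``dt`` in ms, ``band`` in Hz; the upper edge must sit below Nyquist.
    """
    series = np.asarray(series, dtype=float)
    fs = 1000.0 / dt
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at/above Nyquist {fs / 2} Hz")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    padlen = min(series.shape[-1] - 1, 3 * 8 * 10)
    return sps.sosfiltfilt(sos, series, axis=-1, padlen=padlen)


def _inband_fraction(x: np.ndarray, dt: float, band: tuple) -> tuple[float, float]:
    """(spectral peak frequency, in-band energy fraction) of a zero-mean
    series; DC excluded."""
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=dt / 1000.0)
    spec[0] = 0.0
    total = spec.sum()
    if total == 0:
        return 0.0, 0.0
    inband = spec[(freqs >= band[0]) & (freqs <= band[1])].sum()
    return float(freqs[np.argmax(spec)]), float(inband / total)


def _diaphragm_edge_track(values: np.ndarray) -> np.ndarray:
    """Per-view z centroid of the profile's gradient magnitude — a crude
    superior-inferior diaphragm-position surrogate used only to fix the
    sign convention."""
    grad = np.abs(np.diff(values, axis=0))  # (nz-1, n_views)
    z = np.arange(grad.shape[0]) + 0.5
    wsum = grad.sum(axis=0)
    wsum[wsum == 0] = 1.0
    return (z[:, None] * grad).sum(axis=0) / wsum


def extract_resp_signal(profile: ProjectionProfile,
                        band: tuple = RESP_BAND,
                        energy_threshold: float = 0.5,
                        fallback_single_coil: bool = False) -> RespSignal:
    """PCA-based respiratory trace extraction with 'good'-coil selection.

    Per coil the profile time courses are band-passed, PCA is run over z
    positions, and the leading component kept.  A coil is 'good' when that
    component's spectral peak lies in the respiratory band and its in-band
    energy fraction reaches ``energy_threshold``.  The representative
    signal is the good-coil component with the highest mean absolute
    Pearson correlation to the others (the medoid); its sign is oriented
    to correlate positively with the diaphragm-edge surrogate so that
    end-expiration sits at the amplitude minimum.
    """
    vals = profile.values
    nz, nt, nc = vals.shape
    if nt < 64:
        raise ValueError("need at least 64 view-groups for spectral gating")
    fs = 1000.0 / profile.dt
    # amplitude refinement: the band-passed PC is used to *select* the
    # respiratory component; the reported amplitude projects the
    # slow-detrended raw profile onto the PC weights and keeps harmonics
    # up to the cardiac band edge, preserving the monotone relation
    # between amplitude and diaphragm position
    f_harm = 0.5 * (band[1] + CARDIAC_BAND[0])
    sos_tr = sps.butter(4, band[0], btype="lowpass", fs=fs, output="sos")
    sos_hm = (sps.butter(4, f_harm, btype="lowpass", fs=fs, output="sos")
              if f_harm < fs / 2 else None)
    comps = np.empty((nc, nt))
    peak_ok = np.zeros(nc, dtype=bool)
    for c in range(nc):
        filt = bandpass(vals[:, :, c], profile.dt, band)  # filter along time
        filt = filt - filt.mean(axis=1, keepdims=True)
        # leading principal component over z positions
        u, s, vt = np.linalg.svd(filt, full_matrices=False)
        detr = vals[:, :, c] - sps.sosfiltfilt(sos_tr, vals[:, :, c], axis=1)
        amp = u[:, 0] @ detr
        # 'good' coil: the *unfiltered* projection onto the PC weights is
        # itself dominated by respiratory-band energy (band-limited noise
        # would trivially pass if judged after filtering)
        f_pk, frac = _inband_fraction(amp, profile.dt, band)
        peak_ok[c] = (band[0] <= f_pk <= band[1]) and frac >= energy_threshold
        if sos_hm is not None:
            amp = sps.sosfiltfilt(sos_hm, amp)
        # keep orientation consistent with the band-passed component
        if np.dot(amp, s[0] * vt[0]) < 0:
            amp = -amp
        comps[c] = amp
    good = np.flatnonzero(peak_ok)
    if good.size == 0:
        if not fallback_single_coil:
            raise GatingFailure(
                "no coil shows a dominant respiratory-band component; "
                "check the band or pass fallback_single_coil=True")
        fracs = [_inband_fraction(comps[c], profile.dt, band)[1]
                 for c in range(nc)]
        good = np.array([int(np.argmax(fracs))])

    # medoid under absolute Pearson correlation
    g = comps[good]
    gn = (g - g.mean(axis=1, keepdims=True))
    gn /= np.linalg.norm(gn, axis=1, keepdims=True)
    corr = np.abs(gn @ gn.T)
    medoid = int(np.argmax(corr.mean(axis=1)))
    rep = g[medoid].copy()

    # align every good component to the medoid and average? No: keep the
    # medoid itself (most common signal), only fix its global sign.
    edge = _diaphragm_edge_track(vals[:, :, good[medoid]])
    edge_f = bandpass(edge, profile.dt, band)
    if np.std(edge_f) > 0 and np.corrcoef(rep, edge_f)[0, 1] < 0:
        rep = -rep
    return RespSignal(amplitude=rep, dt=profile.dt, band=tuple(band),
                      good_coils=tuple(int(c) for c in good),
                      diag_components=comps)
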