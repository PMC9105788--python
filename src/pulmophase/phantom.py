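"""Dynamic digital lung phantom and stack-of-stars k-space simulator.

Emulates the continuous free-breathing air -> oxygen wash-in -> oxygen
protocol: a procedural thorax (body ellipse, two lung ellipsoids clipped by
a moving diaphragm dome, heart, aorta, liver, intrapulmonary vessels) whose
lung-parenchyma T1/T2* shorten as inhaled oxygen washes in, sampled spoke
by spoke along the golden-angle trajectory through multi-coil sensitivities
with additive complex Gaussian noise.  Ground truth (diaphragm trace, lung
mask, voxelwise true PSE) is returned for every downstream stage.

Coordinate convention: x = left-right, y = anterior-posterior,
z = superior-inferior (the Cartesian kz axis).  z increases toward the
head; inspiration pulls the diaphragm dome toward -z, enlarging the lungs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physics import LUNG_AIR, LUNG_O2, SequenceParams, TissueParams, spgr_signal
from .rawio import RadialStack
from .trajectory import ProtocolParams, Trajectory, make_trajectory

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "LUNG_TISSUE_AIR",
    "LUNG_TISSUE_O2",
    "desk_protocol",
    "oxygen_fraction_at",
    "render_frame",
    "coil_sensitivities",
    "simulate_kspace",
]

# non-enhancing reference tissues (T1/T2* in ms)
SOFT_TISSUE = TissueParams(t1=900.0, t2s=30.0)
LIVER = TissueParams(t1=800.0, t2s=25.0)
BLOOD = TissueParams(t1=1600.0, t2s=60.0)
# lung parenchyma: the air/oxygen relaxation pair at the low proton
# density (~0.3) that makes lungs dark on UTE images
LUNG_TISSUE_AIR = TissueParams(t1=LUNG_AIR.t1, t2s=LUNG_AIR.t2s, m0=0.3)
LUNG_TISSUE_O2 = TissueParams(t1=LUNG_O2.t1, t2s=LUNG_O2.t2s, m0=0.3)


def desk_protocol(n_views: int = 1800) -> ProtocolParams:
    """Desk-scale analogue of the in-vivo protocol: matrix 64, nz 8,
    equal air / wash-in / oxygen thirds, same TR/TE/FA."""
    third = n_views // 3
    return ProtocolParams(
        n_views=n_views, nz=8, n_read=64, matrix=64,
        fov_xy=320.0, fov_z=160.0, tr=5.0, te=0.14, fa=8.0,
        segment_bounds=(0, third, 2 * third, n_views),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Anatomy, motion, wash-in, coil and noise parameters.

    resp_freq in [0.1, 0.5] Hz and cardiac_freq in [0.6, 3.0] Hz keep the
    two motions inside their physiological bands so the band-pass gating
    chain can separate them.  ``washin_tau`` is the oxygen wash-in time
    constant in seconds; None resolves to a quarter of the wash-in segment
    duration (four time constants to plateau, as in vivo where 3-5 min
    suffices).  ``resp_jitter`` adds fractional cycle-to-cycle period
    variability; ``o2_amp_scale`` rescales breathing depth in the oxygen
    segment to exercise air/oxygen state matching.
    """

    matrix: int = 64
    nz: int = 8
    resp_freq: float = 0.25
    resp_amp: float = 30.0          # diaphragm excursion, mm
    cardiac_freq: float = 1.2
    cardiac_amp: float = 0.05       # relative heart/vessel modulation
    washin_tau: float | None = None  # s
    n_coils: int = 8
    noise_sigma: float = 0.0        # complex-noise std / peak |k-center|
    seed: int = 0
    resp_jitter: float = 0.0
    o2_amp_scale: float = 1.0
    lung_air: TissueParams = LUNG_TISSUE_AIR
    lung_o2: TissueParams = LUNG_TISSUE_O2

    def __post_init__(self) -> None:
        if not (0.1 <= self.resp_freq <= 0.5):
            raise ValueError("resp_freq must lie in the 0.1-0.5 Hz band")
        if not (0.6 <= self.cardiac_freq <= 3.0):
            raise ValueError("cardiac_freq must lie in the 0.6-3.0 Hz band")
        if self.washin_tau is not None and self.washin_tau <= 0:
            raise ValueError("washin_tau must be positive")


@dataclass
class GroundTruth:
    """Per-view diaphragm trace (mm), end-expiration label/mask volumes and
    the voxelwise PSE implied by the tissue T1/T2* change."""

    resp_trace: np.ndarray          # diaphragm displacement per view-group, mm
    view_times: np.ndarray          # ms, view-group centers
    lung_mask: np.ndarray           # bool, parenchyma at end-expiration
    pse_true: np.ndarray            # %, 0 outside enhancing tissue
    coil_sens: np.ndarray           # (x, y, z, coil) complex
    resp_freq: float = 0.0
    washin_tau_s: float = 0.0


def _resolve_tau(cfg: PhantomConfig, p: ProtocolParams) -> float:
    if cfg.washin_tau is not None:
        return float(cfg.washin_tau)
    seg = p.segments()["washin"]
    dur_s = (seg.stop - seg.start) * p.view_dt / 1000.0
    return max(dur_s / 4.0, 1e-6)


def oxygen_fraction_at(t: float, p: ProtocolParams, washin_tau: float) -> float:
    """Alveolar oxygen replacement fraction at time ``t`` (ms).

    0 during the air segment, single-exponential rise with time constant
    ``washin_tau`` (s) through wash-in, continuing toward 1 in the oxygen
    segment (the mask stays on, so the exponential does not reset).
    """
    seg = p.segments()["washin"]
    t_start = seg.start * p.view_dt
    if t <= t_start or seg.stop == seg.start:
        return 0.0
    return float(1.0 - np.exp(-(t - t_start) / (washin_tau * 1000.0)))


def _diaphragm_displacement(cfg: PhantomConfig, t_ms: np.ndarray,
                            p: ProtocolParams) -> np.ndarray:
    """Raised-cosine breathing: 0 at end-expiration, resp_amp at
    end-inspiration.  Optional cycle-period jitter and oxygen-segment
    amplitude rescale."""
    t = np.atleast_1d(np.asarray(t_ms, dtype=float)) / 1000.0
    if cfg.resp_jitter > 0:
        rng = np.random.default_rng(cfg.seed + 77)
        # smooth frequency modulation: random walk over ~1-cycle knots
        total_s = p.n_spokes * p.tr / 1000.0
        n_knots = max(int(total_s * cfg.resp_freq) + 2, 4)
        f_knots = cfg.resp_freq * (1.0 + cfg.resp_jitter *
                                   rng.standard_normal(n_knots))
        knot_t = np.linspace(0, total_s, n_knots)
        dense_t = np.linspace(0, total_s, 4096)
        f_dense = np.interp(dense_t, knot_t, f_knots)
        phase_dense = np.concatenate(
            [[0.0], np.cumsum(0.5 * (f_dense[1:] + f_dense[:-1]) *
                              np.diff(dense_t))])
        phase = np.interp(t, dense_t, phase_dense)
    else:
        phase = cfg.resp_freq * t
    d = cfg.resp_amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    if cfg.o2_amp_scale != 1.0:
        o2_start_ms = p.segments()["oxygen"].start * p.view_dt
        d = np.where(t * 1000.0 >= o2_start_ms, d * cfg.o2_amp_scale, d)
    return d


def _grids(cfg: PhantomConfig, p: ProtocolParams):
    n, nz = cfg.matrix, cfg.nz
    x = (np.arange(n) - n / 2) * p.fov_xy / n
    z = (np.arange(nz) + 0.5) * p.fov_z / nz
    return np.meshgrid(x, x, z, indexing="ij")  # xx, yy, zz in mm


def _soft_inside(q: np.ndarray, width: float) -> np.ndarray:
    """Anti-aliased indicator for implicit region q <= 1 (q = normalized
    quadratic form); width ~ one voxel in q units."""
    return np.clip((1.0 - q) / max(width, 1e-9) + 0.5, 0.0, 1.0)


def _interp_tissue(cfg: PhantomConfig, f: float) -> TissueParams:
    a, b = cfg.lung_air, cfg.lung_o2
    return TissueParams(t1=a.t1 + f * (b.t1 - a.t1),
                        t2s=a.t2s + f * (b.t2s - a.t2s),
                        m0=a.m0)


def _anatomy(cfg: PhantomConfig, p: ProtocolParams, displacement_mm: float):
    """Return per-tissue soft coverage maps at a given diaphragm
    displacement (mm inferior of the end-expiration dome)."""
    xx, yy, zz = _grids(cfg, p)
    fx, fz = p.fov_xy, p.fov_z
    w = 2.5 * p.voxel_xy / fx  # edge softness in normalized units

    body = _soft_inside((xx / (0.45 * fx)) ** 2 + (yy / (0.35 * fx)) ** 2, w)

    lungs = np.zeros_like(body)
    vessels = np.zeros_like(body)
    dome_apex = 0.40 * fz - displacement_mm
    for sx in (-1.0, 1.0):
        cx = sx * 0.20 * fx
        q = ((xx - cx) / (0.15 * fx)) ** 2 + (yy / (0.24 * fx)) ** 2 + \
            ((zz - 0.62 * fz) / (0.42 * fz)) ** 2
        lung = _soft_inside(q, w)
        # diaphragm dome: paraboloid surface under each lung
        r2 = ((xx - cx) / (0.15 * fx)) ** 2 + (yy / (0.24 * fx)) ** 2
        z_dome = dome_apex - 0.08 * fz * np.clip(r2, 0, 1.5)
        above = np.clip((zz - z_dome) / (1.2 * p.fov_z / cfg.nz) + 0.5, 0, 1)
        lung = lung * above
        lungs = np.maximum(lungs, lung)
        for (ox, oy) in ((0.0, 0.06), (0.05, -0.08), (-0.06, 0.0)):
            qv = ((xx - cx - ox * fx) / (0.018 * fx)) ** 2 + \
                 ((yy - oy * fx) / (0.018 * fx)) ** 2
            vessels = np.maximum(vessels, _soft_inside(qv, 8 * w) * lung)

    heart = _soft_inside(((xx - 0.03 * fx) / (0.10 * fx)) ** 2 +
                         ((yy - 0.05 * fx) / (0.09 * fx)) ** 2 +
                         ((zz - 0.55 * fz) / (0.28 * fz)) ** 2, w)
    aorta = _soft_inside((xx / (0.025 * fx)) ** 2 +
                         ((yy + 0.12 * fx) / (0.025 * fx)) ** 2, 8 * w) * body
    liver_region = np.clip((dome_apex + 0.02 * fz - zz) /
                           (1.2 * p.fov_z / cfg.nz) + 0.5, 0, 1) * body

    parenchyma = lungs * (1.0 - vessels)
    return {
        "body": body, "liver": liver_region, "lung": parenchyma,
        "vessel": vessels * lungs, "heart": heart, "aorta": aorta,
    }


def render_frame(cfg: PhantomConfig, t: float, oxygen_fraction: float,
                 p: ProtocolParams | None = None) -> np.ndarray:
    """Complex object volume (matrix, matrix, nz) at time ``t`` ms.

    Tissue magnitudes are spoiled-GRE steady-state signals at the protocol
    TR/TE/FA; lung parenchyma T1/T2* are interpolated between the air and
    oxygen values by ``oxygen_fraction``; the diaphragm dome is displaced
    by the breathing trace and heart/vessel intensity carries the cardiac
    modulation.  Deterministic given (cfg, t, oxygen_fraction).
    """
    if p is None:
        p = desk_protocol()
    if not (0.0 <= t <= p.n_spokes * p.tr):
        raise ValueError(f"t={t} ms outside protocol duration")
    seq = SequenceParams(tr=p.tr, te=p.te, fa=p.fa)
    d = float(_diaphragm_displacement(cfg, np.array([t]), p)[0])
    maps = _anatomy(cfg, p, d)

    s_lung = spgr_signal(_interp_tissue(cfg, oxygen_fraction), seq)
    s = {
        "body": spgr_signal(SOFT_TISSUE, seq),
        "liver": spgr_signal(LIVER, seq),
        "lung": s_lung,
        "vessel": spgr_signal(BLOOD, seq),
        "heart": spgr_signal(BLOOD, seq),
        "aorta": spgr_signal(BLOOD, seq),
    }
    card = 1.0 + cfg.cardiac_amp * np.sin(2 * np.pi * cfg.cardiac_freq * t / 1000.0)

    # paint back-to-front: body, then liver/lungs carve it, vessels on top
    vol = s["body"] * maps["body"]
    for name in ("liver", "lung"):
        vol = vol * (1 - maps[name]) + s[name] * maps[name]
    for name in ("heart", "aorta", "vessel"):
        amp = s[name] * (card if name in ("heart", "vessel") else 1.0)
        vol = vol * (1 - maps[name]) + amp * maps[name]
    return vol.astype(np.complex128)


def coil_sensitivities(cfg: PhantomConfig, p: ProtocolParams) -> np.ndarray:
    """Smooth complex Gaussian coil profiles on a ring around the torso,
    (x, y, z, coil)."""
    xx, yy, zz = _grids(cfg, p)
    fx = p.fov_xy
    sens = np.empty(xx.shape + (cfg.n_coils,), dtype=np.complex128)
    for c in range(cfg.n_coils):
        th = 2 * np.pi * c / cfg.n_coils
        cx, cy = 0.55 * fx * np.cos(th), 0.45 * fx * np.sin(th)
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mag = np.exp(-r2 / (2 * (0.35 * fx) ** 2))
        ph = 2 * np.pi * (0.1 * (xx * np.sin(th) - yy * np.cos(th)) / fx)
        sens[..., c] = mag * np.exp(1j * ph)
    norm = np.sqrt((np.abs(sens) ** 2).sum(-1, keepdims=True))
    return sens / norm.max()


def _ground_truth(cfg: PhantomConfig, p: ProtocolParams, traj: Trajectory,
                  tau_s: float) -> GroundTruth:
    view_times = (np.arange(p.n_views) + 0.5) * p.view_dt
    resp = _diaphragm_displacement(cfg, view_times, p)
    frame0 = np.abs(render_frame(cfg, 0.0, 0.0, p))
    frame1 = np.abs(render_frame(cfg, 0.0, 1.0, p))
    pse = np.zeros_like(frame0)
    nz_mask = frame0 > 1e-6 * frame0.max()
    pse[nz_mask] = 100.0 * (frame1[nz_mask] - frame0[nz_mask]) / frame0[nz_mask]
    maps = _anatomy(cfg, p, 0.0)
    lung_mask = (maps["lung"] > 0.5) & (maps["vessel"] < 0.25)
    return GroundTruth(
        resp_trace=resp, view_times=view_times, lung_mask=lung_mask,
        pse_true=pse, coil_sens=coil_sensitivities(cfg, p),
        resp_freq=cfg.resp_freq, washin_tau_s=tau_s,
    )


def simulate_kspace(cfg: PhantomConfig, p: ProtocolParams | None = None
                    ) -> tuple[RadialStack, GroundTruth]:
    """Forward-simulate the full continuous protocol.

    Each view-group's nz spokes are sampled from the object rendered at the
    group's center time: coil weighting, Cartesian FFT along z, then exact
    in-plane Fourier evaluation at the spoke's radial sample locations.
    Complex Gaussian noise is scaled by the peak k-center magnitude.  Fully
    reproducible from ``cfg.seed``.
    """
    if p is None:
        p = desk_protocol()
    if cfg.matrix != p.matrix or cfg.nz != p.nz:
        raise ValueError("phantom grid must match protocol matrix/nz")
    tau = _resolve_tau(cfg, p)
    traj = make_trajectory(p)
    gt = _ground_truth(cfg, p, traj, tau)
    sens = gt.coil_sens
    n, nz, nc = p.matrix, p.nz, cfg.n_coils
    nk = traj.k_radial.size
    frac = (np.arange(n) - n // 2) / n  # spatial coords, fraction of FOV
    data = np.empty((p.n_views, nz, nk, nc), dtype=np.complex64)

    for v in range(p.n_views):
        t_v = (v + 0.5) * p.view_dt
        f_o2 = oxygen_fraction_at(t_v, p, tau)
        obj = render_frame(cfg, t_v, f_o2, p)
        hyb = np.fft.fftshift(
            np.fft.fft(np.fft.ifftshift(obj[..., None] * sens, axes=2), axis=2),
            axes=2)
        th = np.deg2rad(traj.angles[v])
        proj = (np.cos(th) * frac[:, None] + np.sin(th) * frac[None, :]).ravel()
        enc = np.exp(-2j * np.pi * traj.k_radial[:, None] * proj[None, :])
        # (nk, n*n) @ (n*n, nz*nc) -> (nk, nz*nc)
        samp = enc @ hyb.reshape(n * n, nz * nc)
        data[v] = samp.reshape(nk, nz, nc).transpose(1, 0, 2)

    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        peak = np.abs(data[:, :, 0, :]).max()
        sd = cfg.noise_sigma * peak
        noise = rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        data = (data + (sd / np.sqrt(2)) * noise).astype(np.complex64)

    stack = RadialStack(data=data, traj=traj, protocol=p,
                        provenance=f"phantom-seed{cfg.seed}")
    return stack, gt
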