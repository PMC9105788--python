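"""Golden-angle stack-of-stars sampling pattern and density compensation.

The acquisition rotates a center-out radial spoke in-plane by the golden
angle 180/phi = 111.246 degrees between *view-groups*, acquiring all Nz
Cartesian kz partitions at one azimuth before rotating.  Any consecutive
window of view-groups therefore covers the in-plane k-space near-uniformly,
which is what permits retrospective respiratory binning; the self-gating
time unit is one view-group, Nz x TR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "GOLDEN_ANGLE_INCREMENT",
    "ProtocolParams",
    "Trajectory",
    "make_trajectory",
    "density_weights",
    "angular_shares",
    "uniformity_metric",
]

# 180 / golden ratio; the scanner implements the 3-decimal rounding
GOLDEN_ANGLE_DEG = 180.0 / ((1.0 + np.sqrt(5.0)) / 2.0)
GOLDEN_ANGLE_INCREMENT = round(GOLDEN_ANGLE_DEG, 3)  # 111.246


@dataclass(frozen=True)
class ProtocolParams:
    """Acquisition protocol description.

    ``segment_bounds`` are view-group indices delimiting the continuous
    air / wash-in / oxygen protocol: segment k spans
    ``[segment_bounds[k], segment_bounds[k+1])``.
    """

    n_views: int
    nz: int
    n_read: int
    matrix: int
    fov_xy: float
    fov_z: float
    tr: float = 5.0
    te: float = 0.14
    fa: float = 8.0
    segment_bounds: tuple = ()
    n_pre: int = 0     # discarded pre-samples at the spoke start
    n_ramp: int = 0    # samples acquired during gradient ramp-up

    def __post_init__(self) -> None:
        for name in ("n_views", "nz", "n_read", "matrix"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.segment_bounds:
            b = tuple(self.segment_bounds)
            if list(b) != sorted(b) or b[-1] > self.n_views:
                raise ValueError("segment_bounds must be ordered and <= n_views")
        if self.n_pre + self.n_ramp >= self.n_read:
            raise ValueError("pre/ramp samples exhaust the readout")

    @classmethod
    def in_vivo(cls) -> "ProtocolParams":
        """The free-breathing continuous-protocol scan: 4800 view-groups of
        30 partitions (1600 air / 1600 wash-in / 1600 oxygen), 256 matrix,
        294-point center-out spokes, TE/TR = 0.14/5 ms, FA 8 deg."""
        return cls(
            n_views=4800, nz=30, n_read=294, matrix=256,
            fov_xy=496.0, fov_z=250.0, tr=5.0, te=0.14, fa=8.0,
            segment_bounds=(0, 1600, 3200, 4800), n_pre=24, n_ramp=60,
        )

    @property
    def voxel_xy(self) -> float:
        """In-plane voxel size, mm."""
        return self.fov_xy / self.matrix

    @property
    def n_spokes(self) -> int:
        return self.n_views * self.nz

    @property
    def view_dt(self) -> float:
        """Self-gating temporal resolution Nz x TR, ms."""
        return self.nz * self.tr

    @property
    def total_time_s(self) -> float:
        return self.n_spokes * self.tr / 1000.0

    def segments(self) -> dict:
        """Return {'air': slice, 'washin': slice, 'oxygen': slice} of
        view-group indices."""
        b = self.segment_bounds or (0, self.n_views, self.n_views, self.n_views)
        return {
            "air": slice(b[0], b[1]),
            "washin": slice(b[1], b[2]),
            "oxygen": slice(b[2], b[3]),
        }


@dataclass(frozen=True)
class Trajectory:
    """Sampling geometry of one stack-of-stars acquisition.

    angles : per-view-group azimuth, degrees in [0, 360)
    kz_order : acquisition order of partitions within a view-group
    k_radial : center-out radial coordinate per retained readout sample,
        cycles/FOV in [0, matrix/2]
    timestamps : acquisition time of each spoke (view-major), ms
    """

    angles: np.ndarray
    kz_order: np.ndarray
    k_radial: np.ndarray
    timestamps: np.ndarray

    @property
    def n_views(self) -> int:
        return self.angles.size

    @property
    def nz(self) -> int:
        return self.kz_order.size


def _radial_profile(p: ProtocolParams) -> np.ndarray:
    """Center-out |k| per retained sample (pre-samples dropped).

    During gradient ramp-up the gradient grows linearly so k grows
    quadratically; after ``n_ramp`` samples it grows linearly, reaching
    matrix/2 cycles/FOV at the spoke end.
    """
    n = p.n_read - p.n_pre
    i = np.arange(n, dtype=float)
    nr = min(p.n_ramp, n - 1)
    k = np.empty(n)
    if nr > 0:
        # quadratic over the ramp, C1-continuous into the linear part
        k[: nr + 1] = 0.5 * i[: nr + 1] ** 2 / nr
        k[nr:] = 0.5 * nr + (i[nr:] - nr)
    else:
        k = i.copy()
    k *= (p.matrix / 2.0) / k[-1]
    return k


def make_trajectory(p: ProtocolParams) -> Trajectory:
    """Build the deterministic golden-angle stack-of-stars trajectory."""
    v = np.arange(p.n_views, dtype=float)
    angles = np.mod(v * GOLDEN_ANGLE_INCREMENT, 360.0)
    kz_order = np.arange(p.nz)  # sequential bottom-to-top
    k_radial = _radial_profile(p)
    timestamps = np.arange(p.n_spokes, dtype=float) * p.tr
    return Trajectory(angles=angles, kz_order=kz_order,
                      k_radial=k_radial, timestamps=timestamps)


def density_weights(traj: Trajectory, n_spokes: int | None = None) -> np.ndarray:
    """Annular (ramp) density-compensation weights for one spoke.

    Each sample owns the annulus between midpoints to its radial
    neighbours, divided by the number of spokes sharing the disc; the k=0
    sample owns the central disc (strictly positive weight).  Beyond the
    radius where the angular spoke spacing exceeds one grid cell
    (``n_spokes / (2 pi)`` cycles/FOV) the ramp is capped flat: the data
    are genuinely undersampled there and further amplification only raises
    noise/streaks.  Summed over all spokes and samples the weights
    approximate the k-space area covered, in grid-cell units.
    """
    k = np.asarray(traj.k_radial, dtype=float)
    if k.size == 0:
        raise ValueError("empty spoke: no radial samples")
    if n_spokes is None:
        n_spokes = traj.n_views
    if n_spokes < 1:
        raise ValueError("need at least one spoke")
    edges = np.empty(k.size + 1)
    edges[0] = 0.0
    edges[1:-1] = 0.5 * (k[:-1] + k[1:])
    edges[-1] = 2.0 * k[-1] - edges[-2]  # symmetric outer half-annulus
    area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    r_nyq = n_spokes / (2.0 * np.pi)
    if k[-1] > r_nyq:
        # flat cap at the weight of the Nyquist-radius annulus
        cap = np.interp(r_nyq, k, area)
        area = np.minimum(area, cap)
    return area / n_spokes


def angular_shares(angles) -> np.ndarray:
    """Per-spoke angular Voronoi share, normalized to mean 1.

    Amplitude-sorted view subsets are not exactly uniform in angle; each
    spoke's density weight is scaled by the fraction of the half-circle it
    owns (half the gap to each angular neighbour, spokes at theta and
    theta+180 equivalent) so that clustered spokes are not over-counted.
    """
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    if a.size == 1:
        return np.ones(1)
    h = np.mod(a, 180.0)
    order = np.argsort(h)
    hs = h[order]
    gaps = np.diff(np.concatenate([hs, [hs[0] + 180.0]]))
    share = np.empty_like(hs)
    share = 0.5 * (gaps + np.roll(gaps, 1))
    out = np.empty_like(share)
    out[order] = share / (180.0 / a.size)
    return out


def uniformity_metric(angles) -> float:
    """Largest angular gap (degrees) between spoke directions on the
    half-circle; spokes at theta and theta+180 are equivalent for
    coverage."""
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    h = np.sort(np.mod(a, 180.0))
    gaps = np.diff(np.concatenate([h, [h[0] + 180.0]]))
    return float(gaps.max())
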