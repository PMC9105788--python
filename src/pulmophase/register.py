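"""Non-rigid demons registration.

Intensity-driven Thirion demons: each iteration computes the force

    du = (m(x+u) - f) * grad f / (|grad f|^2 + (m(x+u) - f)^2)

smooths the update with a Gaussian (fluid regularization), accumulates it
into the displacement field and smooths the field (diffusion
regularization), over a coarse-to-fine multiresolution pyramid.  The
hyperoxic volume is warped onto its matched normoxic volume before PSE
mapping so that residual respiratory-position mismatch does not masquerade
as enhancement.  Histogram matching is deliberately off by default: the
oxygen-induced intensity difference is the signal of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .recon import VolumeImage

__all__ = ["DisplacementField", "demons_register", "warp"]


@dataclass
class DisplacementField:
    """Per-voxel 3D displacement in mm on the fixed image grid."""

    vectors: np.ndarray   # (x, y, z, 3)
    spacing: tuple

    def magnitude_mm(self) -> np.ndarray:
        return np.sqrt((self.vectors ** 2).sum(-1))


def _normalize(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    lo, hi = a.min(), a.max()
    return (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)


def warp(moving: np.ndarray, disp_vox: np.ndarray) -> np.ndarray:
    """Resample ``moving`` through a displacement field given in voxels
    (pull-back warp, linear interpolation)."""
    grids = np.meshgrid(*[np.arange(s) for s in moving.shape], indexing="ij")
    coords = [g + disp_vox[..., i] for i, g in enumerate(grids)]
    return ndimage.map_coordinates(moving, coords, order=1, mode="nearest")


def _demons_level(fixed: np.ndarray, moving: np.ndarray, u: np.ndarray,
                  iters: int, sigma_fluid: float, sigma_diffusion: float,
                  step_cap: float = 1.0) -> np.ndarray:
    """One pyramid level.  Returns the field with the lowest observed MSE:
    an intensity-only difference (e.g. genuine oxygen enhancement with no
    motion) yields no MSE-reducing displacement, and keeping the best
    field instead of the last prevents the drift that would flatten it."""
    grad = np.stack(np.gradient(fixed), axis=-1)
    g2 = (grad ** 2).sum(-1)
    best_u, best_mse = u.copy(), np.inf
    n_bad = 0
    for _ in range(iters):
        warped = warp(moving, u)
        diff = warped - fixed
        mse = float((diff ** 2).mean())
        if mse < best_mse * (1.0 - 1e-6):
            best_mse, best_u, n_bad = mse, u.copy(), 0
        else:
            n_bad += 1
            if mse > 1.1 * best_mse:
                warnings.warn("demons diverging at this level; stopping early")
                break
            if n_bad >= 3:
                break
        denom = g2 + diff ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            du = -(diff[..., None] * grad) / denom[..., None]
        du[denom < 1e-12] = 0.0
        np.clip(du, -step_cap, step_cap, out=du)
        if sigma_fluid > 0:
            for i in range(3):
                du[..., i] = ndimage.gaussian_filter(du[..., i], sigma_fluid)
        u = u + du
        if sigma_diffusion > 0:
            for i in range(3):
                u[..., i] = ndimage.gaussian_filter(u[..., i], sigma_diffusion)
    return best_u


def demons_register(fixed: VolumeImage, moving: VolumeImage,
                    levels: int = 3, iters: int = 50,
                    sigma_fluid: float = 1.0, sigma_diffusion: float = 1.0
                    ) -> tuple[DisplacementField, VolumeImage]:
    """Register ``moving`` onto ``fixed``; returns the displacement field
    (mm) and the warped moving volume.

    sigma_fluid / sigma_diffusion are Gaussian std in voxels of the update
    and field smoothing.  ``levels`` coarse-to-fine downsampling stages
    (factor 2 in-plane; the slice direction is only downsampled while more
    than 4 slices remain).
    """
    if fixed.voxels.shape != moving.voxels.shape:
        raise ValueError("fixed/moving grids differ "
                         f"{fixed.voxels.shape} vs {moving.voxels.shape}")
    if not np.allclose(fixed.spacing, moving.spacing):
        raise ValueError("fixed/moving voxel spacings differ")
    f0 = _normalize(fixed.voxels)
    m0 = _normalize(moving.voxels)

    factors = []
    for lev in range(levels - 1, -1, -1):
        s = 2 ** lev
        fz = s if fixed.voxels.shape[2] / s >= 4 else 1
        factors.append((s, s, fz))

    u = None
    for (sx, sy, sz) in factors:
        f = ndimage.zoom(f0, (1 / sx, 1 / sy, 1 / sz), order=1)
        m = ndimage.zoom(m0, (1 / sx, 1 / sy, 1 / sz), order=1)
        if u is None:
            u = np.zeros(f.shape + (3,), dtype=float)
        else:
            new = np.empty(f.shape + (3,), dtype=float)
            zoom = [f.shape[i] / u.shape[i] for i in range(3)]
            for i in range(3):
                new[..., i] = ndimage.zoom(u[..., i], zoom, order=1) * zoom[i]
            u = new
        u = _demons_level(f, m, u, iters, sigma_fluid, sigma_diffusion)

    warped = warp(m0, u)
    # rescale warped intensities back to the moving volume's range
    lo, hi = moving.voxels.min(), moving.voxels.max()
    warped_img = warped * (hi - lo) + lo
    disp_mm = u * np.asarray(fixed.spacing)[None, None, None, :]
    field = DisplacementField(vectors=disp_mm, spacing=fixed.spacing)
    out = VolumeImage(voxels=warped_img, spacing=moving.spacing,
                      oxygen_state=moving.oxygen_state,
                      resp_state=fixed.resp_state, n_spokes=moving.n_spokes)
    return field, out
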