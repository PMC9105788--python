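"""Shared fixtures: phantom simulations reused across test modules."""

from __future__ import annotations

import time

import numpy as np
import pytest
from scipy import ndimage

import pulmophase as pp


@pytest.fixture(scope="session")
def desk_run():
    """Full desk-scale study: simulate the continuous protocol (matrix 64,
    nz 8, 600+600+600 view-groups, 8 coils, moderate noise) and run the
    complete pipeline with the ground-truth lung mask."""
    p = pp.desk_protocol(1800)
    cfg = pp.PhantomConfig(noise_sigma=0.002, seed=1)
    stack, gt = pp.simulate_kspace(cfg, p)
    mask = pp.MaskVolume(ndimage.binary_erosion(gt.lung_mask),
                         provenance="ground-truth")
    t0 = time.time()
    result = pp.run_pipeline(stack, pp.RunConfig(), mask=mask)
    runtime = time.time() - t0
    return {"protocol": p, "phantom_cfg": cfg, "stack": stack, "gt": gt,
            "mask": mask, "result": result, "pipeline_seconds": runtime}


@pytest.fixture(scope="session")
def static_stack():
    """Noiseless motionless phantom at desk scale (fewer views): isolates
    reconstruction accuracy from gating/binning."""
    p = pp.ProtocolParams(n_views=600, nz=8, n_read=64, matrix=64,
                          fov_xy=320.0, fov_z=160.0, tr=5.0, te=0.14, fa=8.0,
                          segment_bounds=(0, 200, 400, 600))
    cfg = pp.PhantomConfig(noise_sigma=0.0, resp_amp=0.0, cardiac_amp=0.0,
                           seed=3)
    stack, gt = pp.simulate_kspace(cfg, p)
    return {"protocol": p, "phantom_cfg": cfg, "stack": stack, "gt": gt}


def edge_rise_width(vol: pp.VolumeImage, x: int, y: int,
                    lo: float = 0.1, hi: float = 0.9) -> float:
    """10-90% rise width (mm) of the liver->lung intensity drop along z
    through column (x, y); smaller = sharper diaphragm."""
    prof = vol.voxels[x, y, :].astype(float)
    dz = vol.spacing[2]
    bright = prof.max()
    dark = prof.min()
    norm = (prof - dark) / (bright - dark)
    # first falling edge: from bright liver (low z) to dark lung
    j0 = int(np.argmax(norm))
    seg = norm[j0:]
    z = np.arange(seg.size) * dz

    def crossing(level):
        below = np.flatnonzero(seg <= level)
        if below.size == 0:
            return z[-1]
        j = below[0]
        if j == 0:
            return 0.0
        f = (seg[j - 1] - level) / (seg[j - 1] - seg[j])
        return z[j - 1] + f * dz

    return abs(crossing(lo) - crossing(hi))
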