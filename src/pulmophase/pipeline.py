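"""End-to-end orchestration: gating -> binning -> matching -> reconstruction
-> registration -> low-pass -> PSE maps and summaries.

``run_pipeline`` consumes a :class:`~pulmophase.rawio.RadialStack` (from a
scanner export or the synthetic phantom) and emits the average-phase and
four state-resolved PSE maps plus per-stage QC, deterministically for a
given configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import binning, pse, recon, register, selfgate
from .rawio import RadialStack

logger = logging.getLogger("pulmophase")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

_STATE_NAMES = ("i", "ii", "iii", "iv")


@dataclass
class RunConfig:
    """All pipeline parameters with protocol defaults.

    window/step of None resolve per segment to ``step = n // 32`` and
    ``window = n - (n_phases - 1) * step``, which reproduces the 450/50
    sliding window on a 1600-view segment and scales proportionally at
    desk scale.  ``n_avg_views`` (None -> half the segment) sets how many
    view-groups at the start of the air segment / end of the oxygen
    segment form the non-phase-resolved average volumes.
    """

    band: tuple = selfgate.RESP_BAND
    energy_threshold: float = 0.5
    n_phases: int = 24
    window: int | None = None
    step: int | None = None
    n_states: int = 4
    n_avg_views: int | None = None
    target_dz: float | None = None     # mm; None keeps native kz spacing
    lowpass_res: float = 10.0          # mm, in-plane Gaussian low-pass
    demons_levels: int = 3
    demons_iters: int = 50
    sigma_fluid: float = 1.0
    sigma_diffusion: float = 1.0
    mask_erode: int = 1
    floor_frac: float = 1e-6
    seed: int = 0

    def resolve_window(self, n: int) -> tuple[int, int]:
        step = self.step if self.step is not None else max(n // 32, 1)
        window = (self.window if self.window is not None
                  else n - (self.n_phases - 1) * step)
        if window <= 0 or window > n:
            raise ValueError(f"unusable window {window} for segment of {n}")
        return window, step

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["band"] = list(d["band"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Everything the pipeline produces, plus per-stage QC."""

    resp: selfgate.RespSignal
    state_match: binning.StateMatch
    air_volumes: dict            # 'average', 'i'..'iv' -> VolumeImage
    o2_volumes: dict             # registered, same keys
    pse_maps: dict               # same keys -> PSEMap
    mask: pse.MaskVolume
    qc: dict

    def summary_table(self):
        import pandas as pd
        rows = [{"state": k, "mpse": v.mpse,
                 "n_spokes_air": self.air_volumes[k].n_spokes,
                 "n_spokes_o2": self.o2_volumes[k].n_spokes,
                 "n_mask": v.mask.count}
                for k, v in self.pse_maps.items()]
        return pd.DataFrame(rows)


def run_pipeline(stack: RadialStack, cfg: RunConfig | None = None,
                 mask: pse.MaskVolume | None = None,
                 out_dir=None) -> PipelineResult:
    """Run the full phase-resolved oxygen-enhancement analysis.

    ``mask`` may come from phantom ground truth; otherwise a
    threshold-derived lung mask is computed from the air average volume.
    Results and QC are written under ``out_dir`` when given.
    """
    cfg = cfg or RunConfig()
    p = stack.protocol
    qc: dict = {"stages": []}

    def stage(name, **info):
        logger.info("stage %s: %s", name, json.dumps(info, default=str))
        qc["stages"].append({"stage": name, **info})

    # 1. self-gating
    profile = selfgate.projection_profiles(stack)
    try:
        resp = selfgate.extract_resp_signal(
            profile, band=cfg.band, energy_threshold=cfg.energy_threshold)
    except selfgate.GatingFailure:
        logger.warning("no good coils; falling back to single best coil")
        resp = selfgate.extract_resp_signal(
            profile, band=cfg.band, energy_threshold=cfg.energy_threshold,
            fallback_single_coil=True)
    stage("selfgate", good_coils=list(resp.good_coils),
          dominant_freq_hz=resp.dominant_freq())

    # 2. per-segment sliding-window binning
    segs = p.segments()
    air_views = np.arange(segs["air"].start, segs["air"].stop)
    o2_views = np.arange(segs["oxygen"].start, segs["oxygen"].stop)
    if air_views.size == 0 or o2_views.size == 0:
        raise ValueError("protocol must define non-empty air and oxygen segments")
    w_a, s_a = cfg.resolve_window(air_views.size)
    w_o, s_o = cfg.resolve_window(o2_views.size)
    air_bins = binning.sliding_window_bins(resp, air_views, w_a, s_a, "air")
    o2_bins = binning.sliding_window_bins(resp, o2_views, w_o, s_o, "oxygen")
    air_states = binning.select_representative_states(air_bins, cfg.n_states)
    stage("binning", n_air_bins=len(air_bins), n_o2_bins=len(o2_bins),
          window_air=w_a, step_air=s_a)

    # 3. diaphragm-position state matching
    air_pos = [binning.bin_diaphragm_position(profile, b) for b in air_states]
    o2_pos = [binning.bin_diaphragm_position(profile, b) for b in o2_bins]
    match = binning.match_states(air_states, air_pos, o2_bins, o2_pos)
    stage("matching",
          air_phases=[b.phase_index for b, _ in match.pairs],
          o2_phases=[b.phase_index for _, b in match.pairs],
          score_mm=[float(s) for s in match.matching_score])

    # 4. reconstruction: averages + matched states
    n_avg = cfg.n_avg_views or air_views.size // 2
    avg_air_bin = binning.PhaseBin(0, air_views[:n_avg], (0, 0), "air")
    avg_o2_bin = binning.PhaseBin(0, o2_views[-n_avg:], (0, 0), "oxygen")
    air_vols = {"average": recon.reconstruct_volume(
        stack, avg_air_bin, cfg.target_dz, "air", "average")}
    o2_vols = {"average": recon.reconstruct_volume(
        stack, avg_o2_bin, cfg.target_dz, "oxygen", "average")}
    for name, (ab, ob) in zip(_STATE_NAMES, match.pairs):
        air_vols[name] = recon.reconstruct_volume(stack, ab, cfg.target_dz,
                                                  "air", name)
        o2_vols[name] = recon.reconstruct_volume(stack, ob, cfg.target_dz,
                                                 "oxygen", name)
    stage("recon", volumes=list(air_vols) + list(o2_vols))

    # 5. mask
    if mask is None:
        mask = pse.threshold_lung_mask(air_vols["average"], erode=cfg.mask_erode)
    stage("mask", provenance=mask.provenance, n_voxels=mask.count)

    # 6. registration + low-pass + PSE per state
    maps = {}
    reg_o2 = {}
    for name in air_vols:
        fixed, moving = air_vols[name], o2_vols[name]
        _, warped = register.demons_register(
            fixed, moving, levels=cfg.demons_levels, iters=cfg.demons_iters,
            sigma_fluid=cfg.sigma_fluid, sigma_diffusion=cfg.sigma_diffusion)
        air_lp = pse.gaussian_lowpass(fixed, cfg.lowpass_res)
        o2_lp = pse.gaussian_lowpass(warped, cfg.lowpass_res)
        reg_o2[name] = warped
        maps[name] = pse.pse_map(air_lp, o2_lp, mask,
                                 floor_frac=cfg.floor_frac)
    stage("pse", mpse={k: round(v.mpse, 3) for k, v in maps.items()})

    result = PipelineResult(resp=resp, state_match=match,
                            air_volumes=air_vols, o2_volumes=reg_o2,
                            pse_maps=maps, mask=mask, qc=qc)
    if out_dir is not None:
        _write_outputs(result, cfg, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, cfg: RunConfig, out: Path) -> None:
    import nibabel as nib

    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    def save_nii(vol, name):
        aff = np.diag(list(vol.spacing) + [1.0])
        nib.save(nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32),
                                 aff), out / name)

    for k, v in result.air_volumes.items():
        save_nii(v, f"air_{k}.nii.gz")
    for k, v in result.o2_volumes.items():
        save_nii(v, f"o2reg_{k}.nii.gz")
    for k, m in result.pse_maps.items():
        aff = np.diag(list(result.air_volumes[k].spacing) + [1.0])
        nib.save(nib.Nifti1Image(
            np.nan_to_num(m.values).astype(np.float32), aff),
            out / f"pse_{k}.nii.gz")
    result.summary_table().to_csv(out / "summary.csv", index=False)
    (out / "qc.json").write_text(json.dumps(result.qc, indent=2, default=str))
    np.savetxt(out / "resp_signal.csv",
               np.column_stack([np.arange(result.resp.amplitude.size),
                                np.arange(result.resp.amplitude.size) *
                                result.resp.dt,
                                result.resp.amplitude]),
               delimiter=",", header="view_index,time_ms,amplitude",
               comments="")
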