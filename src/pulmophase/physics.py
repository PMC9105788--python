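"""Spoiled gradient-echo (UTE) steady-state signal model.

Oxygen dissolved in blood and lung water is weakly paramagnetic: breathing
100% O2 shortens the T1 (and, less usefully, the T2*) of lung parenchyma by
several percent.  Under a rapidly repeated, perfectly spoiled excitation the
longitudinal magnetization settles into the Ernst steady state, so the
oxygen-induced T1 change maps into a flip-angle-dependent signal change.
This module provides the closed-form steady-state signal, the Ernst angle,
and the percent-signal-enhancement (PSE) sweep over flip angle used to
choose the acquisition flip angle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "TissueParams",
    "SequenceParams",
    "LUNG_AIR",
    "LUNG_O2",
    "spgr_signal",
    "ernst_angle",
    "pse_vs_flip_angle",
]


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of one tissue.

    Parameters
    ----------
    t1 : float
        Longitudinal relaxation time, ms.
    t2s : float
        Apparent transverse relaxation time T2*, ms.
    m0 : float
        Equilibrium magnetization, arbitrary units.
    """

    t1: float
    t2s: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t1 > 0 and self.t2s > 0 and self.m0 > 0):
            raise ValueError("t1, t2s and m0 must all be positive")
        if self.t2s > self.t1:
            raise ValueError(f"t2s ({self.t2s} ms) must not exceed t1 ({self.t1} ms)")

    def scaled(self, t1_factor: float = 1.0, t2s_factor: float = 1.0) -> "TissueParams":
        """Return a copy with T1/T2* multiplied by the given factors."""
        return replace(self, t1=self.t1 * t1_factor, t2s=self.t2s * t2s_factor)


@dataclass(frozen=True)
class SequenceParams:
    """Spoiled-GRE sequence timing and excitation.

    Parameters
    ----------
    tr : float
        Repetition time, ms.
    te : float
        Echo time, ms.  Zero is permitted for idealized analyses.
    fa : float
        Flip angle, degrees, in (0, 90].
    """

    tr: float
    te: float
    fa: float

    def __post_init__(self) -> None:
        if not (0 <= self.te < self.tr):
            raise ValueError(f"require 0 <= te < tr, got te={self.te}, tr={self.tr}")
        if not (0 < self.fa <= 90):
            raise ValueError(f"flip angle must lie in (0, 90], got {self.fa}")


# Phantom-derived tissue pairs mimicking the lung air -> 100% O2 change
# (7.2% T1 and 10.6% T2 reduction).
LUNG_AIR = TissueParams(t1=1391.9, t2s=83.68)
LUNG_O2 = TissueParams(t1=1292.3, t2s=74.84)


def spgr_signal(tissue: TissueParams, seq: SequenceParams) -> float:
    """Steady-state spoiled-GRE signal amplitude.

    Closed-form fixed point of the excitation/relaxation recursion under
    perfect spoiling::

        S = m0 * sin(a) * (1 - E1) / (1 - E1 cos(a)) * exp(-TE/T2*)

    with ``E1 = exp(-TR/T1)``.  Units follow ``tissue.m0``.
    """
    a = np.deg2rad(seq.fa)
    e1 = np.exp(-seq.tr / tissue.t1)
    mz = tissue.m0 * (1.0 - e1) / (1.0 - e1 * np.cos(a))
    return float(mz * np.sin(a) * np.exp(-seq.te / tissue.t2s))


def ernst_angle(t1: float, tr: float) -> float:
    """Flip angle (degrees) maximizing the spoiled steady-state signal.

    ``arccos(exp(-TR/T1))``; the optimum is independent of TE and M0.
    """
    if t1 <= 0 or tr <= 0:
        raise ValueError("t1 and tr must be positive")
    return float(np.degrees(np.arccos(np.exp(-tr / t1))))


def pse_vs_flip_angle(
    air: TissueParams,
    o2: TissueParams,
    seq_base: SequenceParams,
    fa_grid=None,
) -> pd.DataFrame:
    """Sweep flip angle and tabulate signals and percent signal enhancement.

    PSE = 100 * (S_O2 - S_air) / S_air at each grid point.  The default grid
    is integer degrees 1..90.

    Returns
    -------
    pandas.DataFrame with columns ``fa``, ``s_air``, ``s_o2``, ``pse``.
    """
    if fa_grid is None:
        fa_grid = np.arange(1, 91, dtype=float)
    fa_grid = np.asarray(fa_grid, dtype=float)
    if fa_grid.size == 0:
        raise ValueError("fa_grid must be non-empty")
    if np.any(fa_grid <= 0) or np.any(fa_grid > 90):
        raise ValueError("flip angles must lie in (0, 90]")

    s_air = np.array([spgr_signal(air, replace(seq_base, fa=f)) for f in fa_grid])
    s_o2 = np.array([spgr_signal(o2, replace(seq_base, fa=f)) for f in fa_grid])
    if np.any(s_air == 0):
        raise ZeroDivisionError("S_air vanished at a grid point; PSE undefined")
    pse = 100.0 * (s_o2 - s_air) / s_air
    return pd.DataFrame({"fa": fa_grid, "s_air": s_air, "s_o2": s_o2, "pse": pse})
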