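"""Amplitude-resorted sliding-window respiratory phase segmentation.

Within one protocol segment the view-groups are resorted by respiratory
amplitude; overlapping windows over the resorted order define finely
spaced motion states with identical spoke counts (the default splits 1600
resorted view-groups into 24 phases of 450 with a 50-view step).  Four
representative states spanning end-expiration to end-inspiration are
picked from the phases, and each air state is matched to the oxygen phase
with the closest diaphragm position, since breathing depth and rate may
differ between the two segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .selfgate import ProjectionProfile, RespSignal

__all__ = [
    "PhaseBin",
    "StateMatch",
    "sliding_window_bins",
    "select_representative_states",
    "bin_diaphragm_position",
    "match_states",
]


@dataclass(frozen=True)
class PhaseBin:
    """One respiratory phase: an ordered subset of view-group indices.

    phase_index is 1-based, ordered end-expiration (1, lowest amplitude)
    to end-inspiration (highest).
    """

    phase_index: int
    member_views: np.ndarray        # absolute view-group indices
    amplitude_range: tuple
    segment: str = "air"

    def __len__(self) -> int:
        return self.member_views.size


@dataclass
class StateMatch:
    """Air/oxygen pairing of the four representative states, end-expiration
    (state i) to end-inspiration (state iv), with per-pair diaphragm
    position discrepancy in mm."""

    pairs: list                     # [(air PhaseBin, o2 PhaseBin), ...]
    matching_score: np.ndarray      # mm per pair


def sliding_window_bins(resp: RespSignal, views=None, window: int = 450,
                        step: int = 50, segment: str = "air") -> list[PhaseBin]:
    """Resort view-groups by amplitude and cut overlapping rank windows.

    ``views`` selects the segment's absolute view-group indices (defaults
    to all).  Requires ``(n - window) % step == 0`` so the windows tile the
    resorted order exactly; bin k holds resorted ranks
    ``(k-1)*step + 1 .. (k-1)*step + window`` (1-based).
    """
    if views is None:
        views = np.arange(resp.amplitude.size)
    views = np.asarray(views)
    amp = resp.amplitude[views]
    n = views.size
    if window > n:
        raise ValueError(f"window {window} exceeds segment size {n}")
    if (n - window) % step != 0:
        valid = [w for w in range(step, n + 1, step) if (n - w) % step == 0]
        raise ValueError(
            f"(n - window) = {n - window} not divisible by step {step}; "
            f"valid windows for this segment include {valid[:8]}")
    order = np.argsort(amp, kind="stable")  # ties broken by acquisition order
    n_bins = (n - window) // step + 1
    bins = []
    for k in range(n_bins):
        ranks = order[k * step: k * step + window]
        members = views[ranks]
        a = amp[ranks]
        bins.append(PhaseBin(phase_index=k + 1, member_views=members,
                             amplitude_range=(float(a.min()), float(a.max())),
                             segment=segment))
    return bins


def select_representative_states(bins: list[PhaseBin], k: int = 4) -> list[PhaseBin]:
    """Pick k bins spaced as evenly as possible from end-expiration to
    end-inspiration (24 bins, k=4 -> phase indices 1, 9, 16, 24)."""
    n = len(bins)
    if k > n:
        raise ValueError(f"cannot select {k} states from {n} bins")
    idx = np.unique(np.round(np.linspace(0, n - 1, k)).astype(int))
    return [bins[i] for i in idx]


def bin_diaphragm_position(profile: ProjectionProfile, bin_: PhaseBin) -> float:
    """Diaphragm position (mm) of one phase: z of the maximum
    superior-inferior gradient of the bin-averaged projection profile,
    refined to sub-slice precision by parabolic interpolation."""
    mean_prof = profile.values[:, bin_.member_views, :].mean(axis=(1, 2))
    grad = np.abs(np.diff(mean_prof))
    j = int(np.argmax(grad))
    # parabolic vertex through (j-1, j, j+1)
    if 0 < j < grad.size - 1:
        y0, y1, y2 = grad[j - 1], grad[j], grad[j + 1]
        denom = y0 - 2 * y1 + y2
        off = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        off = float(np.clip(off, -0.5, 0.5))
    else:
        off = 0.0
    return (j + 0.5 + off) * profile.dz


def match_states(air_states: list[PhaseBin], air_positions,
                 o2_bins: list[PhaseBin], o2_positions) -> StateMatch:
    """Match each air state to the oxygen phase at the nearest diaphragm
    position, keeping the chosen oxygen phase indices monotone.

    Solved by dynamic programming over ordered assignments; if the
    unconstrained nearest-neighbour choice is already monotone it is
    returned unchanged.  A degenerate DP (fewer oxygen bins than states)
    falls back to the identity-ordered assignment with a warning.
    """
    air_positions = np.asarray(air_positions, dtype=float)
    o2_positions = np.asarray(o2_positions, dtype=float)
    ns, nb = len(air_states), len(o2_bins)
    if ns == 0:
        raise ValueError("no air states to match")
    if nb < ns:
        warnings.warn("fewer oxygen phases than air states; falling back "
                      "to ordered assignment")
        chosen = list(range(min(ns, nb))) + [nb - 1] * max(0, ns - nb)
    else:
        cost = np.abs(air_positions[:, None] - o2_positions[None, :])
        # DP: dp[i, j] = best total cost assigning states 0..i with
        # state i -> bin j, bins strictly increasing
        dp = np.full((ns, nb), np.inf)
        back = np.zeros((ns, nb), dtype=int)
        dp[0] = cost[0]
        for i in range(1, ns):
            best_prev = np.minimum.accumulate(dp[i - 1])
            arg_prev = np.zeros(nb, dtype=int)
            b = 0
            for j in range(nb):
                if dp[i - 1, j] < dp[i - 1, b]:
                    b = j
                arg_prev[j] = b
            for j in range(i, nb):
                dp[i, j] = cost[i, j] + best_prev[j - 1]
                back[i, j] = arg_prev[j - 1]
        j = int(np.argmin(dp[-1]))
        chosen = [j]
        for i in range(ns - 1, 0, -1):
            j = int(back[i, j])
            chosen.append(j)
        chosen = chosen[::-1]
    pairs = [(air_states[i], o2_bins[chosen[i]]) for i in range(ns)]
    score = np.array([abs(air_positions[i] - o2_positions[chosen[i]])
                      for i in range(ns)])
    return StateMatch(pairs=pairs, matching_score=score)
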