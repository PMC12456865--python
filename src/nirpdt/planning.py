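"""Threshold-based multi-session treatment planning.

Cell death is scored per voxel: a tumor voxel dies once its accumulated
photodynamic dose reaches the apoptosis threshold (8.6e17 photons/cm^3).
Sessions are identical — the optical properties do not change as voxels
die — so the dose accumulates linearly and the number of sessions needed
by a voxel is ceil(threshold / PD_session).  The whole tumor is treated
after the maximum over voxels; voxels with zero per-session dose are
reported explicitly as unreachable.

Floating-point note: "reaches the threshold" is evaluated with a 1e-12
relative epsilon so that a dose of exactly threshold/n accumulated over n
sessions kills at session n despite rounding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dose import PDVolume

__all__ = ["SessionPlan", "sessions_to_kill", "kill_map", "plan_treatment",
           "UNREACHABLE"]

#: Sentinel in per-voxel session arrays for voxels that can never be killed.
UNREACHABLE = -1

_EPS = 1e-12


@dataclass
class SessionPlan:
    """Sessions-to-death per tumor voxel and the whole-tumor count.

    ``sessions_per_voxel`` is aligned with ``tumor_indices`` (the (k, 3)
    voxel indices of the tumor); ``n_complete`` is the maximum, or None
    when some voxel is unreachable.  ``kill_fraction_by_session[i]`` is the
    cumulative fraction of tumor voxels dead after session i + 1.
    """

    sessions_per_voxel: np.ndarray
    tumor_indices: np.ndarray
    n_complete: int | None
    kill_fraction_by_session: list[float]

    @property
    def n_unreachable(self) -> int:
        return int(np.count_nonzero(self.sessions_per_voxel == UNREACHABLE))

    def histogram(self) -> dict[int, int]:
        """Voxel count per sessions-to-death value."""
        vals, counts = np.unique(self.sessions_per_voxel, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "n_complete": self.n_complete,
            "n_tumor_voxels": int(self.sessions_per_voxel.size),
            "n_unreachable": self.n_unreachable,
            "kill_fraction_by_session": self.kill_fraction_by_session,
            "histogram": {str(k): v for k, v in self.histogram().items()},
        }, indent=1))
        return path


def sessions_to_kill(pd_session: float, threshold: float) -> int | None:
    """Sessions needed for one voxel; None when the dose never accumulates."""
    if pd_session < 0:
        raise ValueError("per-session dose must be non-negative")
    if pd_session == 0:
        return None
    return max(1, math.ceil(threshold * (1.0 - _EPS) / pd_session))


def kill_map(pd_vol: PDVolume, n_sessions: int,
             threshold: float | None = None) -> np.ndarray:
    """Boolean volume of voxels dead after ``n_sessions`` identical sessions."""
    if n_sessions < 0:
        raise ValueError("session count must be non-negative")
    threshold = threshold if threshold is not None else pd_vol.params.threshold_photons_cm3
    if n_sessions == 0:
        return np.zeros(pd_vol.shape, dtype=bool)
    return pd_vol.tumor_mask & (n_sessions * pd_vol.pd >= threshold * (1.0 - _EPS))


def plan_treatment(pd_vol: PDVolume,
                   threshold: float | None = None) -> SessionPlan:
    """Per-voxel sessions-to-death and the whole-tumor irradiation count."""
    threshold = threshold if threshold is not None else pd_vol.params.threshold_photons_cm3
    idx = np.argwhere(pd_vol.tumor_mask)
    if idx.shape[0] == 0:
        raise ValueError("tumor mask is empty; nothing to plan")
    pd = pd_vol.pd[tuple(idx.T)]
    sessions = np.full(pd.shape, UNREACHABLE, dtype=np.int64)
    pos = pd > 0
    sessions[pos] = np.maximum(
        1, np.ceil(threshold * (1.0 - _EPS) / pd[pos]).astype(np.int64))

    if np.all(pos):
        n_complete: int | None = int(sessions.max())
    else:
        n_complete = None

    fractions: list[float] = []
    horizon = n_complete if n_complete is not None else (
        int(sessions[pos].max()) if pos.any() else 0)
    total = sessions.size
    for n in range(1, horizon + 1):
        fractions.append(float(np.count_nonzero((sessions != UNREACHABLE)
                                                & (sessions <= n)) / total))
    return SessionPlan(sessions_per_voxel=sessions, tumor_indices=idx,
                       n_complete=n_complete,
                       kill_fraction_by_session=fractions)
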