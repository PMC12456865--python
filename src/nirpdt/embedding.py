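"""Tumor embedding: place a spherical DCIS surrogate entirely inside ducts.

Early-stage disease is modelled as ductal carcinoma in situ (DCIS), which
stays confined to the milk ducts.  Embedding therefore follows four rules:
(1) the tumor is a sphere, 7 mm in diameter by default; (2) its depth — the
beam-axis distance from the outer skin surface to the tumor's upper face —
must lie in 15–25 mm, the standard clinical range; (3) every tumor voxel
must be a duct voxel; (4) among feasible sites, the one closest to the skin
wins.  Phantoms with no feasible site are marked ineligible rather than
raising.

Sphere membership is by voxel-centre inclusion, which matches the analytic
volume (pi/6) d^3 to within 2 % at 0.33 mm pitch.  Depth is measured along
the beam axis through the tumor centre column to the *outer* skin surface
(the air interface), since the irradiated surface is the dosimetric
reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .phantom import LabeledVolume, TissueLabel

DEFAULT_DIAMETER_MM = 7.0
DEFAULT_DEPTH_RANGE_MM = (15.0, 25.0)


@dataclass
class TumorSpec:
    """One embedded tumor: centre voxel, size, depth and member voxels."""

    center_voxel: tuple[int, int, int]
    diameter_mm: float
    depth_mm: float
    voxel_ids: np.ndarray  # (k, 3) int indices

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_ids.shape[0])

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "center_voxel": list(self.center_voxel),
            "diameter_mm": self.diameter_mm,
            "depth_mm": self.depth_mm,
            "n_voxels": self.n_voxels,
        }, indent=1))
        return path


def sphere_offsets(diameter_mm: float, pitch_mm: float) -> np.ndarray:
    """(m, 3) integer voxel offsets whose centres lie within the sphere."""
    if diameter_mm <= 0 or pitch_mm <= 0:
        raise ValueError("diameter and pitch must be positive")
    r = diameter_mm / 2.0
    m = int(np.floor(r / pitch_mm))
    rng = np.arange(-m, m + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    inside = (dx * dx + dy * dy + dz * dz) * pitch_mm ** 2 <= r * r + 1e-12
    return np.stack([dx[inside], dy[inside], dz[inside]], axis=1)


def voxelize_sphere(center: tuple[int, int, int], diameter_mm: float,
                    pitch_mm: float, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel indices of a sphere centred on ``center``'s voxel centre.

    Raises if any member voxel falls outside the grid (clipped sphere).
    """
    offs = sphere_offsets(diameter_mm, pitch_mm)
    ids = offs + np.asarray(center, dtype=np.intp)
    if (ids < 0).any() or (ids >= np.asarray(grid_shape)).any():
        raise ValueError(
            f"sphere of diameter {diameter_mm} mm at {center} is clipped by the grid")
    return ids


def _skin_entry_map(vol: LabeledVolume) -> np.ndarray:
    """Per-column index of the first non-air voxel along +z; -1 if the
    column misses the breast silhouette."""
    non_air = vol.labels != int(TissueLabel.AIR)
    hit = non_air.any(axis=2)
    first = np.argmax(non_air, axis=2)
    return np.where(hit, first, -1)


def tumor_depth(vol: LabeledVolume, voxel_ids: np.ndarray) -> float:
    """Beam-axis depth (mm) of a tumor's upper face below the outer skin.

    Measured along the column through the tumor centre: from the outer skin
    surface (upper face of the first non-air voxel) to the upper face of the
    shallowest tumor voxel.
    """
    ids = np.asarray(voxel_ids)
    cx = int(round(float(np.mean(ids[:, 0]))))
    cy = int(round(float(np.mean(ids[:, 1]))))
    entry = _skin_entry_map(vol)
    z0 = int(entry[cx, cy])
    if z0 < 0:
        raise ValueError("beam-axis column through the tumor centre misses the skin")
    z_top = int(ids[:, 2].min())
    return (z_top - z0) * vol.pitch_mm


def find_candidate_sites(vol: LabeledVolume,
                         diameter_mm: float = DEFAULT_DIAMETER_MM,
                         depth_range_mm: tuple[float, float] = DEFAULT_DEPTH_RANGE_MM,
                         ) -> list[tuple[tuple[int, int, int], float]]:
    """Centres whose voxelized sphere is 100 % duct at an in-range depth.

    Feasibility is computed by convolving the non-duct indicator with the
    sphere footprint (zero overlap means the sphere fits); results are
    sorted by depth ascending.  An empty list is a valid outcome.
    """
    offs = sphere_offsets(diameter_mm, vol.pitch_mm)
    m = int(np.abs(offs).max())
    dz_top = int(offs[(offs[:, 0] == 0) & (offs[:, 1] == 0), 2].min())

    duct = vol.labels == int(TissueLabel.DUCT)
    if not duct.any():
        return []
    k = 2 * m + 1
    kernel = np.zeros((k, k, k), dtype=np.float32)
    kernel[offs[:, 0] + m, offs[:, 1] + m, offs[:, 2] + m] = 1.0
    overlap = fftconvolve((~duct).astype(np.float32), kernel, mode="same")
    feasible = overlap < 0.5
    # exclude centres whose sphere would clip the grid (zero-padded edges)
    feasible[:m, :, :] = feasible[-m:, :, :] = False
    feasible[:, :m, :] = feasible[:, -m:, :] = False
    feasible[:, :, :m] = feasible[:, :, -m:] = False

    entry = _skin_entry_map(vol)
    lo, hi = depth_range_mm
    sites: list[tuple[tuple[int, int, int], float]] = []
    for cx, cy, cz in np.argwhere(feasible):
        z0 = entry[cx, cy]
        if z0 < 0:
            continue
        depth = (cz + dz_top - z0) * vol.pitch_mm
        if lo - 1e-9 <= depth <= hi + 1e-9:
            sites.append(((int(cx), int(cy), int(cz)), float(depth)))
    sites.sort(key=lambda s: s[1])
    return sites


def embed_tumor(vol: LabeledVolume,
                diameter_mm: float = DEFAULT_DIAMETER_MM,
                depth_range_mm: tuple[float, float] = DEFAULT_DEPTH_RANGE_MM,
                ) -> tuple[LabeledVolume, TumorSpec | None]:
    """Embed a tumor at the shallowest feasible duct site.

    Ties in depth break toward the smallest lateral distance to the breast
    apex axis, then lexicographic voxel index.  Returns the (copied) volume
    with DUCT voxels relabelled TUMOR plus the :class:`TumorSpec`, or the
    unchanged volume and ``None`` when the phantom is ineligible.
    """
    sites = find_candidate_sites(vol, diameter_mm, depth_range_mm)
    if not sites:
        return vol, None

    entry = _skin_entry_map(vol)
    valid = entry >= 0
    z0_min = int(entry[valid].min())
    apex_cols = np.argwhere(valid & (entry == z0_min))
    apex_xy = apex_cols.mean(axis=0)

    def key(site):
        (cx, cy, cz), depth = site
        lat2 = (cx - apex_xy[0]) ** 2 + (cy - apex_xy[1]) ** 2
        return (depth, lat2, (cx, cy, cz))

    center, depth = min(sites, key=key)
    ids = voxelize_sphere(center, diameter_mm, vol.pitch_mm, vol.shape)
    out = vol.copy()
    sel = tuple(ids.T)
    assert np.all(out.labels[sel] == int(TissueLabel.DUCT))
    out.labels[sel] = int(TissueLabel.TUMOR)
    spec = TumorSpec(center_voxel=tuple(int(c) for c in center),
                     diameter_mm=diameter_mm, depth_mm=depth, voxel_ids=ids)
    return out, spec


def tumor_mask(vol: LabeledVolume) -> np.ndarray:
    """Boolean mask of TUMOR voxels."""
    return vol.labels == int(TissueLabel.TUMOR)
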