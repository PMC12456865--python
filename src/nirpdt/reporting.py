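"""Report helpers: depth profiles, tumor fluence summaries, cross-section maps.

One-decimal values in reports use half-up rounding, matching the
arithmetic convention of the summary statistics this package reproduces
(e.g. mean adjacent-plane fluence differences (11.6 + 8.3)/2 -> 10.0 and
(12.4 + 9.3)/2 -> 10.9).
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .transport import FluenceVolume


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), robust to float repr noise."""
    # pre-round far below the target digit to recover the intended decimal
    snapped = repr(round(float(x), ndigits + 6))
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(snapped).quantize(q, rounding=ROUND_HALF_UP))


def depth_profile(fluence: FluenceVolume, mask: np.ndarray, axis: int = 2):
    """Mean fluence over masked voxels per depth plane along ``axis``.

    Planes are voxel-aligned (thickness = pitch) and labelled at the
    plane's upper face.  Returns a DataFrame with columns ``depth_mm`` and
    ``mean_fluence_mW_cm2`` for planes where the mask is non-empty.
    """
    import pandas as pd

    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fluence.phi.shape:
        raise ValueError("mask and fluence shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    other = tuple(i for i in range(3) if i != axis)
    counts = mask.sum(axis=other)
    sums = np.where(mask, fluence.phi, 0.0).sum(axis=other)
    planes = np.nonzero(counts)[0]
    return pd.DataFrame({
        "depth_mm": planes * fluence.pitch_mm,
        "mean_fluence_mW_cm2": sums[planes] / counts[planes],
    })


def adjacent_plane_differences(plane_means: Sequence[float]) -> tuple[np.ndarray, float]:
    """Successive decreases between adjacent plane means and their mean.

    For plane means [29.9, 18.3, 10.0] the differences are [11.6, 8.3]
    with mean 9.95 (reported as 10.0 after half-up rounding).
    """
    means = np.asarray(plane_means, dtype=float)
    if means.size < 2:
        raise ValueError("need at least two plane means")
    diffs = -np.diff(means)
    return diffs, float(diffs.mean())


def tumor_fluence_summary(fluence: FluenceVolume, mask: np.ndarray) -> dict[str, float]:
    """Mean / min / max fluence over the tumor voxels, mW/cm^2."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("tumor mask is empty")
    vals = fluence.phi[mask]
    return {"mean": float(vals.mean()), "min": float(vals.min()),
            "max": float(vals.max())}


def fluence_range(means: Sequence[float]) -> float:
    """Max minus min of per-phantom mean tumor fluences."""
    means = np.asarray(means, dtype=float)
    if means.size == 0:
        raise ValueError("no phantom means given")
    return float(means.max() - means.min())


def render_maps(volumes: Mapping[str, np.ndarray], slice_axis: int,
                slice_index: int, outdir: str | Path, pitch_mm: float,
                cmap: str = "viridis") -> list[Path]:
    """Deterministic cross-section PNGs with a JSON normalization sidecar.

    Integer (label/kill) volumes use a fixed categorical colormap; float
    volumes use ``cmap`` with the recorded vmin/vmax.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    label_cmap = ListedColormap(
        ["black", "peachpuff", "khaki", "lightsteelblue", "crimson"])
    written: list[Path] = []
    for name, vol in volumes.items():
        vol = np.asarray(vol)
        if not 0 <= slice_index < vol.shape[slice_axis]:
            raise ValueError(
                f"slice {slice_index} out of bounds for axis {slice_axis} "
                f"of volume {name!r} with shape {vol.shape}")
        img = np.take(vol, slice_index, axis=slice_axis)
        categorical = np.issubdtype(vol.dtype, np.integer) or vol.dtype == bool
        fig, ax = plt.subplots(figsize=(4, 4), dpi=120)
        if categorical:
            ax.imshow(img.T.astype(float), cmap=label_cmap, vmin=0, vmax=4,
                      origin="lower", interpolation="nearest")
            meta = {"vmin": 0, "vmax": 4, "cmap": "tissue-labels"}
        else:
            vmin, vmax = float(img.min()), float(img.max())
            ax.imshow(img.T, cmap=cmap, vmin=vmin, vmax=vmax,
                      origin="lower", interpolation="nearest")
            meta = {"vmin": vmin, "vmax": vmax, "cmap": cmap}
        ax.set_xlabel("x (voxels)")
        ax.set_ylabel("z (voxels)" if slice_axis != 2 else "y (voxels)")
        ax.set_title(name)
        png = outdir / f"{name}.png"
        fig.savefig(png, metadata={"Software": None})
        plt.close(fig)
        meta.update({"slice_axis": slice_axis, "slice_index": slice_index,
                     "pitch_mm": pitch_mm})
        side = outdir / f"{name}.json"
        side.write_text(json.dumps(meta, indent=1))
        written.extend([png, side])
    return written
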