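"""Labeled voxel breast phantoms: container, I/O, density, BI-RADS classification.

A digital breast phantom is a 3-D grid of tissue labels (air, skin, fat, milk
duct, and — after embedding — tumor) at an isotropic voxel pitch.  Axis 2 of
the label array is the slice-stacking/body axis; the treatment beam travels
along it in the +z direction.  The canonical cohort geometry is 500^3 voxels
at 0.33 mm pitch, but any grid size is first-class.

Breast density is the duct fraction of the fibroglandular interior,
``n_duct / (n_duct + n_fat)``; skin, air and tumor voxels never enter the
ratio.  BreastCT-derived densities systematically underestimate mammographic
density, so classification multiplies the raw density by 2.5 (capped at
100 %) before applying the BI-RADS composition bins.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


class TissueLabel(enum.IntEnum):
    """Integer tissue codes used throughout the package."""

    AIR = 0
    SKIN = 1
    FAT = 2
    DUCT = 3
    TUMOR = 4


#: Default label legend, name -> integer code.
DEFAULT_LEGEND: dict[str, int] = {t.name: int(t) for t in TissueLabel}

#: Canonical full-scale grid (cohort geometry); tests use smaller grids.
DEFAULT_SHAPE: tuple[int, int, int] = (500, 500, 500)
DEFAULT_PITCH_MM: float = 0.33

#: BI-RADS composition classes in increasing density order.
BIRADS_CLASSES = ("fatty", "scattered", "heterogeneous", "extremely_dense")

#: Multiplier applied to raw (CT-derived) density before classification.
DENSITY_ADJUSTMENT = 2.5


@dataclass
class LabeledVolume:
    """3-D voxel grid of :class:`TissueLabel` codes with isotropic pitch.

    Parameters
    ----------
    labels
        ``(nx, ny, nz)`` array of small integers; axis 2 is the beam axis.
    pitch_mm
        Isotropic voxel edge length in millimetres.
    origin
        Physical coordinate (mm) of the corner of voxel (0, 0, 0).
    """

    labels: np.ndarray
    pitch_mm: float = DEFAULT_PITCH_MM
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3-D, got ndim={self.labels.ndim}")
        if min(self.labels.shape) < 1:
            raise ValueError(f"all dimensions must be positive, got {self.labels.shape}")
        if not self.pitch_mm > 0:
            raise ValueError(f"pitch_mm must be positive, got {self.pitch_mm}")
        valid = {int(t) for t in TissueLabel}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown label codes {sorted(present - valid)}")
        self.labels = self.labels.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis."""
        return tuple(n * self.pitch_mm for n in self.shape)  # type: ignore[return-value]

    def count(self, label: TissueLabel) -> int:
        return int(np.count_nonzero(self.labels == int(label)))

    def label_counts(self) -> dict[str, int]:
        """Voxel count per tissue label (partition of the grid)."""
        return {t.name: self.count(t) for t in TissueLabel}

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(self.labels.copy(), self.pitch_mm, self.origin)


@dataclass
class PhantomRecord:
    """Bookkeeping row for one phantom: density, class, embedding outcome."""

    id: str
    raw_density: float
    adjusted_density_pct: float = field(default=0.0)
    birads_class: str = field(default="fatty")
    eligible: bool | None = None
    tumor_depth_mm: float | None = None

    @classmethod
    def from_density(cls, id: str, raw_density: float) -> "PhantomRecord":
        pct, klass = classify_breast(raw_density)
        return cls(id=id, raw_density=raw_density,
                   adjusted_density_pct=pct, birads_class=klass)


# ---------------------------------------------------------------------------
# density and classification
# ---------------------------------------------------------------------------

def compute_breast_density(vol: LabeledVolume) -> float:
    """Duct fraction of the fibroglandular interior.

    Returns ``n_duct / (n_duct + n_fat)``.  Skin, air and tumor voxels are
    excluded from both numerator and denominator, so density must be computed
    (and frozen on the record) *before* a tumor is embedded.
    """
    n_duct = vol.count(TissueLabel.DUCT)
    n_fat = vol.count(TissueLabel.FAT)
    if n_duct + n_fat == 0:
        raise ValueError("volume has no fat or duct voxels; density undefined")
    return n_duct / (n_duct + n_fat)


def classify_breast(raw_density: float) -> tuple[float, str]:
    """Adjusted percent density and BI-RADS composition class.

    ``adjusted = min(100, 250 * raw_density)``; bins are half-open
    [0,25) fatty, [25,50) scattered, [50,75) heterogeneous, with the top bin
    [75,100] closed.
    """
    if not 0.0 <= raw_density <= 1.0:
        raise ValueError(f"raw density must lie in [0, 1], got {raw_density}")
    adjusted = min(100.0, 100.0 * DENSITY_ADJUSTMENT * raw_density)
    if adjusted < 25.0:
        klass = "fatty"
    elif adjusted < 50.0:
        klass = "scattered"
    elif adjusted < 75.0:
        klass = "heterogeneous"
    else:
        klass = "extremely_dense"
    return adjusted, klass


def select_representative(group: Sequence[PhantomRecord]) -> PhantomRecord:
    """Member whose raw density is closest to the group mean.

    Ties break toward the lowest id.  When tumor depths are recorded the
    group must be a single depth bin (simulations are run per depth group on
    the phantom of average glandular density).
    """
    if len(group) == 0:
        raise ValueError("cannot select a representative from an empty group")
    depths = {r.tumor_depth_mm for r in group if r.tumor_depth_mm is not None}
    if len(depths) > 1:
        raise ValueError(f"group mixes tumor depths {sorted(depths)}")
    mean = float(np.mean([r.raw_density for r in group]))
    # distances snapped to 12 decimals so float noise cannot mask a tie
    return min(group, key=lambda r: (round(abs(r.raw_density - mean), 12), r.id))


def records_to_dataframe(records: Iterable[PhantomRecord]):
    """Records as a pandas DataFrame with the canonical column order."""
    import pandas as pd

    rows = [
        {
            "id": r.id,
            "raw_density": r.raw_density,
            "adjusted_density_pct": r.adjusted_density_pct,
            "birads_class": r.birads_class,
            "eligible": r.eligible,
            "tumor_depth_mm": r.tumor_depth_mm,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["id", "raw_density", "adjusted_density_pct",
                                       "birads_class", "eligible", "tumor_depth_mm"])


# ---------------------------------------------------------------------------
# nearest-neighbour resampling
# ---------------------------------------------------------------------------

def resample_iso(vol: LabeledVolume, target_pitch_mm: float) -> LabeledVolume:
    """Nearest-neighbour resampling to a new isotropic pitch.

    The output grid covers the same physical extent (within one voxel per
    axis); each output voxel takes the label of the input voxel containing
    its centre, so no new labels can appear.
    """
    if not target_pitch_mm > 0:
        raise ValueError(f"target pitch must be positive, got {target_pitch_mm}")
    if target_pitch_mm == vol.pitch_mm:
        return vol.copy()
    new_shape = tuple(
        max(1, int(round(n * vol.pitch_mm / target_pitch_mm))) for n in vol.shape
    )
    idx = []
    for ax, n_new in enumerate(new_shape):
        centers = (np.arange(n_new) + 0.5) * target_pitch_mm
        src = np.floor(centers / vol.pitch_mm).astype(np.intp)
        idx.append(np.clip(src, 0, vol.shape[ax] - 1))
    out = vol.labels[np.ix_(*idx)]
    return LabeledVolume(out, target_pitch_mm, vol.origin)


# ---------------------------------------------------------------------------
# I/O: NIfTI volumes and PNG/TIFF slice stacks with JSON sidecars
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _legend_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".legend.json")
    return path.with_suffix(".legend.json")


def save_labeled_volume(vol: LabeledVolume, path: str | Path,
                        legend: Mapping[str, int] | None = None) -> Path:
    """Write a labeled volume as NIfTI with a JSON legend sidecar."""
    import nibabel as nib

    path = Path(path)
    legend = dict(legend or DEFAULT_LEGEND)
    affine = np.diag([vol.pitch_mm, vol.pitch_mm, vol.pitch_mm, 1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.labels.astype(np.uint8), affine)
    img.header.set_zooms((vol.pitch_mm,) * 3)
    nib.save(img, str(path))
    sidecar = {"pitch_mm": vol.pitch_mm, "labels": legend, "origin": list(vol.origin)}
    _legend_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _load_nifti(path: Path, legend: Mapping[str, int] | None) -> LabeledVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], atol=1e-6):
        raise ValueError(f"anisotropic voxels {zooms}; resample first")
    pitch = float(zooms[0])
    if not pitch > 0:
        raise ValueError("missing or invalid pitch metadata in NIfTI header")
    _check_legend(data, legend)
    return LabeledVolume(data.astype(np.uint8), pitch)


def _check_legend(data: np.ndarray, legend: Mapping[str, int] | None) -> None:
    legend = dict(legend or DEFAULT_LEGEND)
    allowed = set(legend.values())
    present = set(np.unique(data).tolist())
    if not present <= allowed:
        raise ValueError(f"pixel values {sorted(present - allowed)} not in legend")


def load_label_stack(path: str | Path,
                     legend: Mapping[str, int] | None = None) -> LabeledVolume:
    """Load a labeled phantom from NIfTI or an ordered 2-D slice stack.

    A directory is treated as a stack of single-channel PNG/TIFF label
    images ordered by filename, stacked along axis 2, with a mandatory
    ``stack.json`` sidecar declaring ``pitch_mm`` (and optionally the
    legend).  A file is loaded as NIfTI; the pitch comes from the header and
    the legend from ``<name>.legend.json`` if present.
    """
    path = Path(path)
    if path.is_dir():
        return _load_slice_stack(path, legend)
    if not any(path.name.endswith(s) for s in _NIFTI_SUFFIXES):
        raise ValueError(f"unsupported volume container: {path.name}")
    if legend is None:
        lp = _legend_path(path)
        if lp.exists():
            legend = json.loads(lp.read_text())["labels"]
    return _load_nifti(path, legend)


def _load_slice_stack(path: Path, legend: Mapping[str, int] | None) -> LabeledVolume:
    from PIL import Image

    sidecar_path = path / "stack.json"
    if not sidecar_path.exists():
        raise ValueError(f"slice stack {path} lacks a stack.json sidecar with pitch_mm")
    sidecar = json.loads(sidecar_path.read_text())
    if "pitch_mm" not in sidecar:
        raise ValueError("stack.json must declare pitch_mm")
    pitch = float(sidecar["pitch_mm"])
    legend = legend or sidecar.get("labels") or DEFAULT_LEGEND

    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not files:
        raise ValueError(f"no PNG/TIFF slices found in {path}")
    slices = []
    shape2d = None
    for f in files:
        arr = np.asarray(Image.open(f))
        if arr.ndim != 2:
            raise ValueError(f"slice {f.name} is not single-channel")
        if shape2d is None:
            shape2d = arr.shape
        elif arr.shape != shape2d:
            raise ValueError(
                f"slice {f.name} has shape {arr.shape}, expected {shape2d}")
        slices.append(arr)
    data = np.stack(slices, axis=2)
    _check_legend(data, legend)
    return LabeledVolume(data.astype(np.uint8), pitch)


def save_slice_stack(vol: LabeledVolume, path: str | Path,
                     legend: Mapping[str, int] | None = None) -> Path:
    """Write a volume as a PNG slice stack (axis 2) plus stack.json sidecar."""
    from PIL import Image

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n = vol.shape[2]
    width = max(4, len(str(n)))
    for k in range(n):
        Image.fromarray(vol.labels[:, :, k]).save(path / f"slice_{k:0{width}d}.png")
    sidecar = {"pitch_mm": vol.pitch_mm, "labels": dict(legend or DEFAULT_LEGEND)}
    (path / "stack.json").write_text(json.dumps(sidecar, indent=1))
    return path
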