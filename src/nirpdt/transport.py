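"""Voxel Monte Carlo light transport at 808 nm: public API.

Packets are launched uniformly over the beam field on the z = 0 grid face
travelling along +z (the body axis), with specular Fresnel reflection at
the air entry, Henyey–Greenstein scattering, continuous absorption
weighting along voxel traversals, Fresnel reflection/refraction at voxel
faces where the refractive index changes (toggleable), and Russian
roulette termination below a weight of 1e-4 with survival probability 0.1.

The per-voxel fluence rate is recovered from absorption scoring,
phi = A / (mu_a V), scaled so that the source delivers
``irradiance x field area``; every tissue has mu_a > 0 so the estimator is
defined everywhere except in air, which scores zero.  A conservation
ledger (launched = absorbed + reflected + transmitted + roulette) is
attached to every run and holds to 1e-6.
"""

from __future__ import annotations

import json
import math
import uuid
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .optics import OpticalVolume

__all__ = [
    "BeamSpec",
    "FluenceVolume",
    "run_transport",
    "sample_free_path",
    "sample_hg_cosine",
    "fresnel_reflectance",
    "hg_cdf",
]

#: Default session irradiance, mW/cm^2 (within the skin MPE at 808 nm).
DEFAULT_IRRADIANCE_MW_CM2 = 330.0


@dataclass
class BeamSpec:
    """Collimated beam entering the z = 0 face along the body axis.

    ``field`` selects the illuminated footprint: ``"full"`` (entire entry
    face, the default — broad-field illumination), ``("rect", (x0, x1, y0,
    y1))`` in mm, or ``("disc", (cx, cy, radius))`` in mm.  The wavelength
    is bookkeeping only; the optics table carries the physics.
    """

    irradiance_mW_cm2: float = DEFAULT_IRRADIANCE_MW_CM2
    field: object = "full"
    wavelength_nm: float = 808.0

    def __post_init__(self) -> None:
        if not self.irradiance_mW_cm2 > 0:
            raise ValueError("irradiance must be positive")

    def resolve(self, shape: tuple[int, int, int], pitch_mm: float
                ) -> tuple[int, float, float, float, float, float]:
        """(kind, f0..f3, area_cm2) for the kernel; validates the footprint."""
        lx, ly = shape[0] * pitch_mm, shape[1] * pitch_mm
        if self.field == "full":
            return _kernels.FIELD_FULL, 0.0, lx, 0.0, ly, lx * ly / 100.0
        kind, params = self.field  # type: ignore[misc]
        if kind == "rect":
            x0, x1, y0, y1 = params
            x0c, x1c = max(0.0, x0), min(lx, x1)
            y0c, y1c = max(0.0, y0), min(ly, y1)
            if x1c <= x0c or y1c <= y0c:
                raise ValueError("beam field does not intersect the grid")
            return _kernels.FIELD_RECT, x0c, x1c, y0c, y1c, \
                (x1c - x0c) * (y1c - y0c) / 100.0
        if kind == "disc":
            cx, cy, r = params
            if r <= 0:
                raise ValueError("disc radius must be positive")
            if cx - r < 0 or cx + r > lx or cy - r < 0 or cy + r > ly:
                raise ValueError("disc beam field extends outside the grid")
            return _kernels.FIELD_DISC, cx, cy, r, 0.0, math.pi * r * r / 100.0
        raise ValueError(f"unknown beam field kind {kind!r}")


@dataclass
class FluenceVolume:
    """Per-voxel fluence rate phi (mW/cm^2) with its conservation ledger."""

    phi: np.ndarray
    ledger: dict[str, float]
    n_photons: int
    seed: int
    pitch_mm: float
    run_id: str = field(default_factory=lambda: uuid.uuid4().hex)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.phi.shape  # type: ignore[return-value]

    def conservation_error(self) -> float:
        led = self.ledger
        return abs(led["absorbed"] + led["reflected"] + led["transmitted"]
                   + led["roulette"] - led["launched"])

    def save(self, path: str | Path) -> Path:
        """Write phi as 32-bit NIfTI plus a JSON ledger sidecar."""
        import nibabel as nib

        path = Path(path)
        affine = np.diag([self.pitch_mm] * 3 + [1.0])
        img = nib.Nifti1Image(self.phi.astype(np.float32), affine)
        img.header.set_zooms((self.pitch_mm,) * 3)
        nib.save(img, str(path))
        meta = dict(self.ledger)
        meta.update({"n_photons": self.n_photons, "seed": self.seed,
                     "run_id": self.run_id, "pitch_mm": self.pitch_mm})
        name = path.name
        for suf in (".nii.gz", ".nii"):
            if name.endswith(suf):
                side = path.with_name(name[: -len(suf)] + ".ledger.json")
                break
        else:
            side = path.with_suffix(".ledger.json")
        side.write_text(json.dumps(meta, indent=1))
        return path


# ---------------------------------------------------------------------------
# elementary kernels, exposed for validation
# ---------------------------------------------------------------------------

def sample_free_path(mu_t_cm: float, u: float) -> float:
    """Exponential free path s = -ln(u)/mu_t in cm; mean 1/mu_t."""
    if not mu_t_cm > 0:
        raise ValueError("mu_t must be positive")
    return -math.log(u) / mu_t_cm


def sample_hg_cosine(g: float, u: float) -> float:
    """Inverse-CDF Henyey–Greenstein scattering cosine; g = 0 is isotropic."""
    if not -1.0 <= g <= 1.0:
        raise ValueError("anisotropy g must lie in [-1, 1]")
    return float(_kernels.hg_cosine(g, u))


def fresnel_reflectance(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarized Fresnel reflectance; total internal reflection gives 1."""
    if n1 < 1.0 or n2 < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if not 0.0 < cos_incident <= 1.0:
        raise ValueError("cos_incident must lie in (0, 1]")
    r, _ = _kernels.fresnel_unpolarized(n1, n2, cos_incident)
    return float(r)


def hg_cdf(cos_theta: np.ndarray, g: float) -> np.ndarray:
    """Analytic Henyey–Greenstein CDF P(mu <= cos_theta), for g != 0."""
    c = np.asarray(cos_theta, dtype=float)
    if abs(g) < 1e-8:
        return (c + 1.0) / 2.0
    return (1.0 - g * g) / (2.0 * g) * (
        1.0 / np.sqrt(1.0 + g * g - 2.0 * g * c) - 1.0 / (1.0 + g))


# ---------------------------------------------------------------------------
# transport driver
# ---------------------------------------------------------------------------

def run_transport(optvol: OpticalVolume,
                  beam: BeamSpec | None = None,
                  n_photons: int = 10 ** 6,
                  seed: int = 0,
                  internal_fresnel: bool = True,
                  roulette_threshold: float = 1e-4,
                  roulette_survive: float = 0.1) -> FluenceVolume:
    """Run the Monte Carlo transport and score per-voxel fluence rate.

    Parameters
    ----------
    optvol
        Labeled volume with optical properties (from :func:`assign_optics`).
    beam
        Beam geometry and irradiance; defaults to a full-face 330 mW/cm^2
        beam along +z.
    n_photons
        Packet count; the standard error of scored fluence falls as
        1/sqrt(n_photons).
    internal_fresnel
        Honour refractive-index mismatches at voxel faces (and the entry
        surface).  Disable for absorption-only Beer–Lambert validation.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    beam = beam or BeamSpec()
    kind, f0, f1, f2, f3, area_cm2 = beam.resolve(optvol.shape, optvol.pitch_mm)

    dep = np.zeros(optvol.shape, dtype=np.float64)
    absorbed, reflected, transmitted, roulette_net = _kernels.transport_kernel(
        optvol.labels,
        optvol.mu_a / 10.0,  # cm^-1 -> mm^-1
        optvol.mu_s / 10.0,
        optvol.n,
        optvol.g,
        optvol.pitch_mm,
        n_photons,
        seed,
        internal_fresnel,
        optvol.ambient_n,
        kind, f0, f1, f2, f3,
        roulette_threshold, roulette_survive,
        dep,
    )

    # phi = absorbed power density / mu_a, normalized to the source power
    p0 = beam.irradiance_mW_cm2 * area_cm2 / n_photons  # mW per unit weight
    v_cm3 = (optvol.pitch_mm / 10.0) ** 3
    mua_vox = optvol.voxel_mu_a()
    phi = np.zeros_like(dep)
    np.divide(dep * p0, mua_vox * v_cm3, out=phi, where=mua_vox > 0)

    ledger = {
        "launched": 1.0,
        "absorbed": absorbed / n_photons,
        "reflected": reflected / n_photons,
        "transmitted": transmitted / n_photons,
        "roulette": roulette_net / n_photons,
    }
    fv = FluenceVolume(phi=phi, ledger=ledger, n_photons=n_photons,
                       seed=seed, pitch_mm=optvol.pitch_mm)
    err = fv.conservation_error()
    if err > 1e-6:
        raise RuntimeError(f"energy conservation violated: ledger error {err:.3e}")
    return fv
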