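"""Per-tissue optical properties at 808 nm and their mapping onto voxels.

The default table holds the breast-tissue coefficients at the 808-nm
excitation wavelength: absorption and scattering coefficients in cm^-1,
refractive index, and Henyey–Greenstein anisotropy.  The tumor row already
includes the photosensitizer loading: the UCQR absorption coefficient
(0.38 cm^-1, from a 75 mg/kg intratumoral concentration and the quantum-dot
molar absorptivity) is added to the 0.10 cm^-1 tissue baseline, giving
0.48 cm^-1.  Air is transparent (mu_a = mu_s = 0, n = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import LabeledVolume, TissueLabel

#: UCQR (nanoparticle construct) absorption coefficient in the tumor, cm^-1.
UCQR_MU_A_CM = 0.38
#: Baseline tumor-tissue absorption before nanoparticle loading, cm^-1.
TUMOR_BASE_MU_A_CM = 0.10


@dataclass(frozen=True)
class OpticalProperties:
    """(mu_a, mu_s, n, g) of one tissue; coefficients in cm^-1."""

    mu_a: float
    mu_s: float
    n: float
    g: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("absorption and scattering coefficients must be >= 0")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy must lie in [-1, 1]")


def _default_table() -> dict[TissueLabel, OpticalProperties]:
    return {
        TissueLabel.AIR: OpticalProperties(0.0, 0.0, 1.0, 0.0),
        TissueLabel.SKIN: OpticalProperties(1.35, 196.0, 1.37, 0.9),
        TissueLabel.FAT: OpticalProperties(0.09, 108.0, 1.45, 0.9),
        TissueLabel.DUCT: OpticalProperties(0.06, 114.0, 1.42, 0.9),
        TissueLabel.TUMOR: OpticalProperties(
            TUMOR_BASE_MU_A_CM + UCQR_MU_A_CM, 98.0, 1.45, 0.9),
    }


@dataclass
class OpticsTable:
    """Mapping from tissue label to optical properties, plus the ambient
    refractive index outside the grid (air, n = 1)."""

    properties: dict[TissueLabel, OpticalProperties] = field(default_factory=_default_table)
    ambient_n: float = 1.0

    def replace(self, label: TissueLabel, **kwargs) -> "OpticsTable":
        """New table with one tissue's properties partially overridden."""
        props = dict(self.properties)
        old = props[label]
        props[label] = OpticalProperties(
            mu_a=kwargs.get("mu_a", old.mu_a),
            mu_s=kwargs.get("mu_s", old.mu_s),
            n=kwargs.get("n", old.n),
            g=kwargs.get("g", old.g),
        )
        return OpticsTable(props, self.ambient_n)


@dataclass
class OpticalVolume:
    """Labels plus per-label coefficient lookup tables (cm^-1) and pitch."""

    labels: np.ndarray
    mu_a: np.ndarray   # cm^-1, indexed by label code
    mu_s: np.ndarray
    n: np.ndarray
    g: np.ndarray
    pitch_mm: float
    ambient_n: float = 1.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def voxel_mu_a(self) -> np.ndarray:
        """Per-voxel absorption coefficient volume, cm^-1."""
        return self.mu_a[self.labels]


def assign_optics(vol: LabeledVolume, table: OpticsTable | None = None) -> OpticalVolume:
    """Map the optics table onto a labeled volume.

    Every label present in the volume must be mapped; air is transparent.
    """
    table = table or OpticsTable()
    present = set(int(v) for v in np.unique(vol.labels))
    mapped = {int(k) for k in table.properties}
    if not present <= mapped:
        raise ValueError(f"labels {sorted(present - mapped)} have no optical properties")
    n_codes = max(mapped) + 1
    mu_a = np.zeros(n_codes)
    mu_s = np.zeros(n_codes)
    n_idx = np.ones(n_codes)
    g = np.zeros(n_codes)
    for lab, props in table.properties.items():
        mu_a[int(lab)] = props.mu_a
        mu_s[int(lab)] = props.mu_s
        n_idx[int(lab)] = props.n
        g[int(lab)] = props.g
    return OpticalVolume(vol.labels, mu_a, mu_s, n_idx, g,
                         vol.pitch_mm, table.ambient_n)
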