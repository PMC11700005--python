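"""Periodic sphere-lattice substrates for diffusion Monte Carlo.

Tissue is modelled as an infinite simple-cubic ("square-packed") lattice of
identical spheres of radius ``r`` (cells) embedded in an extracellular bath.
The unit cell is a cube of pitch ``L`` containing one sphere, so the
intracellular volume fraction is ``v_in = (4/3) pi r^3 / L^3`` with the
non-overlap bound ``v_in <= pi/6``.  Membrane permeability is parameterized
by the first-order exchange rate ``k`` (s^-1) of intracellular water, related
to the surface permeability ``kappa`` through the sphere surface-to-volume
ratio, ``k = kappa * S/V_in = 3 kappa / r``.

Units: lengths in um, times in ms, diffusivity in um^2/ms, exchange rate
``k`` in s^-1 at the API boundary (converted internally to ms^-1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Compartment",
    "SphereLattice",
    "lattice_from_vin",
    "classify_point",
    "classify_points",
    "SubstrateGrid",
    "VIN_MAX",
]

#: close-packing limit of the simple-cubic sphere lattice
VIN_MAX = math.pi / 6.0

#: intrinsic diffusivity used throughout the simulation battery (um^2/ms)
D0_DEFAULT = 2.0


class Compartment(IntEnum):
    EXTRA = 0
    INTRA = 1


@dataclass(frozen=True)
class SphereLattice:
    """Simple-cubic lattice of permeable spheres.

    Attributes
    ----------
    radius_um : sphere radius r.
    vin : intracellular volume fraction.
    pitch_um : lattice pitch L (derived from ``vin``).
    k_per_s : first-order intracellular exchange rate k.
    d0_um2_per_ms : intrinsic diffusivity, equal in both compartments.
    kappa_um_per_ms : membrane permeability, ``kappa = k r / 3``.
    """

    radius_um: float
    vin: float
    pitch_um: float
    k_per_s: float
    d0_um2_per_ms: float
    kappa_um_per_ms: float

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius_um}")
        if not 0 < self.vin <= VIN_MAX + 1e-12:
            raise ValueError(
                f"vin={self.vin} outside (0, pi/6]; spheres would overlap"
            )
        if self.pitch_um < 2 * self.radius_um - 1e-9:
            raise ValueError("pitch below sphere diameter: overlapping spheres")
        if self.k_per_s < 0:
            raise ValueError("exchange rate k must be >= 0")
        if self.d0_um2_per_ms <= 0:
            raise ValueError("intrinsic diffusivity must be positive")

    @property
    def substrate_id(self) -> str:
        return f"r{self.radius_um:g}_vin{self.vin:g}_k{self.k_per_s:g}"

    def to_dict(self) -> dict:
        return {
            "radius_um": self.radius_um,
            "vin": self.vin,
            "pitch_um": self.pitch_um,
            "k_per_s": self.k_per_s,
            "d0_um2_per_ms": self.d0_um2_per_ms,
            "kappa_um_per_ms": self.kappa_um_per_ms,
        }


def lattice_from_vin(
    radius_um: float,
    vin: float,
    k_per_s: float = 0.0,
    d0: float = D0_DEFAULT,
) -> SphereLattice:
    """Build a :class:`SphereLattice` from radius and volume fraction.

    The pitch follows from ``vin = (4/3) pi r^3 / L^3``:
    ``L = r * (4 pi / (3 vin))**(1/3)``.  Permeability is derived from the
    exchange rate via ``kappa = k r / 3`` (unit-converted to um/ms).
    """
    if not radius_um > 0:
        raise ValueError(f"sphere radius must be positive, got {radius_um}")
    if not 0 < vin <= VIN_MAX + 1e-12:
        raise ValueError(
            f"vin={vin} not in (0, {VIN_MAX:.4f}]: simple-cubic spheres would overlap"
        )
    pitch = radius_um * (4.0 * math.pi / (3.0 * vin)) ** (1.0 / 3.0)
    k_per_ms = k_per_s * 1e-3
    kappa = k_per_ms * radius_um / 3.0
    return SphereLattice(
        radius_um=radius_um,
        vin=vin,
        pitch_um=pitch,
        k_per_s=k_per_s,
        d0_um2_per_ms=d0,
        kappa_um_per_ms=kappa,
    )


def _wrap_to_cell(xyz: np.ndarray, pitch: float) -> np.ndarray:
    """Map positions into the primary cell [-L/2, L/2)^3 centred on a sphere."""
    return (xyz + pitch / 2.0) % pitch - pitch / 2.0


def classify_points(lattice: SphereLattice, xyz_um: np.ndarray) -> np.ndarray:
    """Vectorized compartment labels for an (n, 3) array of points."""
    pts = np.atleast_2d(np.asarray(xyz_um, dtype=float))
    local = _wrap_to_cell(pts, lattice.pitch_um)
    inside = np.einsum("ij,ij->i", local, local) < lattice.radius_um**2
    return np.where(inside, int(Compartment.INTRA), int(Compartment.EXTRA)).astype(
        np.int8
    )


def classify_point(lattice: SphereLattice, xyz_um: Sequence[float]) -> Compartment:
    """Label a single point INTRA/EXTRA with periodic wrapping."""
    return Compartment(int(classify_points(lattice, np.asarray(xyz_um))[0]))


@dataclass
class SubstrateGrid:
    """The r x v_in x k simulation matrix.

    Defaults reproduce the simulated battery: 10 linearly spaced radii
    2-20 um, volume fractions {0.11, 0.30, 0.52} and exchange rates
    {0, 1, 2, 8, 20} s^-1.  Radius spacing is configurable because only the
    range, not the spacing, is fixed by the study design.
    """

    radii_um: tuple = tuple(float(r) for r in range(2, 21, 2))
    vins: tuple = (0.11, 0.30, 0.52)
    ks_per_s: tuple = (0.0, 1.0, 2.0, 8.0, 20.0)
    d0: float = D0_DEFAULT

    def lattices(self) -> list[SphereLattice]:
        return [
            lattice_from_vin(r, v, k, self.d0)
            for r, v, k in itertools.product(self.radii_um, self.vins, self.ks_per_s)
        ]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "radii_um": list(self.radii_um),
                    "vins": list(self.vins),
                    "ks_per_s": list(self.ks_per_s),
                    "d0": self.d0,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "SubstrateGrid":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            radii_um=tuple(d["radii_um"]),
            vins=tuple(d["vins"]),
            ks_per_s=tuple(d["ks_per_s"]),
            d0=float(d.get("d0", D0_DEFAULT)),
        )
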