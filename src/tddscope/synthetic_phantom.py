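"""Synthetic DW-image generator emulating the stem-in-water-bath phantom.

Generates NIfTI image sets (plus JSON sidecar) for a protocol: cylindrical
"stem" regions embedded in a free-water bath, each region driven either by a
free diffusivity (Gaussian signal ``exp(-b D)``) or by simulated signal-table
rows from the Monte Carlo engine (restricted / exchanging microstructure).
This makes the full image pipeline testable end-to-end with no acquisition:
ROI-mean contrasts from the generated images must round-trip to the scalar
contrast of the driving signals within noise + filter tolerance.

The generator emulates ideal spin-echo EPI magnitude images with optional
multiplicative Gaussian noise; scanner artifacts (distortion, ghosting,
relaxation contrast) are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .image_pipeline import DwImageSet, VolumeMeta
from .pgse_waveforms import ProtocolSpec

__all__ = ["PhantomRegion", "PhantomSpec", "generate_phantom", "cylinder_mask"]


@dataclass(frozen=True)
class PhantomRegion:
    """One labelled region and its signal source.

    Exactly one of ``free_diffusivity_mm2_per_s`` or ``signal_table`` must be
    given.  A signal table must contain columns (waveform_id, b, signal)
    covering every non-zero-b volume of the protocol.
    """

    name: str
    mask_fn: object  # callable (grid shape, voxel size) -> bool array
    free_diffusivity_mm2_per_s: Optional[float] = None
    signal_table: Optional[pd.DataFrame] = None
    s0: float = 1000.0

    def signal(self, waveform_id: str, b: float) -> float:
        if b == 0:
            return 1.0
        if self.free_diffusivity_mm2_per_s is not None:
            return float(np.exp(-b * self.free_diffusivity_mm2_per_s))
        if self.signal_table is None:
            raise ValueError(f"region {self.name!r} has no signal source")
        t = self.signal_table
        row = t[
            (t.waveform_id == waveform_id) & np.isclose(t.b, b, rtol=1e-3)
        ]
        if len(row) != 1:
            raise ValueError(
                f"region {self.name!r}: no unique signal for ({waveform_id}, b={b})"
            )
        return float(row.signal.iloc[0])


def cylinder_mask(center_xy, radius_mm):
    """Axis-aligned (z) cylinder mask factory in physical mm coordinates."""

    def fn(shape, voxel_size_mm):
        x = (np.arange(shape[0]) + 0.5) * voxel_size_mm[0]
        y = (np.arange(shape[1]) + 0.5) * voxel_size_mm[1]
        dx = x[:, None] - center_xy[0]
        dy = y[None, :] - center_xy[1]
        disc = dx**2 + dy**2 <= radius_mm**2
        return np.repeat(disc[:, :, None], shape[2], axis=2)

    return fn


def _everything(shape, voxel_size_mm):
    return np.ones(shape, dtype=bool)


@dataclass
class PhantomSpec:
    """Phantom geometry and noise description.

    Default grid matches the acquisition resolution (3 x 3 mm in-plane, 5 mm
    slices, 64 x 64 x 16 voxels).  Regions are painted in order, later
    regions overwriting earlier ones, so a full-grid water background plus
    stems yields disjoint labels.
    """

    regions: Sequence[PhantomRegion]
    shape: tuple = (64, 64, 16)
    voxel_size_mm: tuple = (3.0, 3.0, 5.0)
    noise_sigma_frac: float = 0.0
    seed: int = 0

    @classmethod
    def water_bath(
        cls,
        stems: Sequence[PhantomRegion] = (),
        water_d_mm2_per_s: float = 2.0e-3,
        **kw,
    ) -> "PhantomSpec":
        bath = PhantomRegion(
            "water", _everything, free_diffusivity_mm2_per_s=water_d_mm2_per_s
        )
        return cls(regions=[bath, *stems], **kw)


def generate_phantom(
    spec: PhantomSpec,
    protocol: ProtocolSpec,
    b_values: Optional[Sequence[float]] = None,
    n_dir: Optional[int] = None,
) -> DwImageSet:
    """Generate a DW image set for ``protocol`` from a phantom spec.

    One volume per (waveform, b, direction): directions are synthetic labels
    (the simulated substrates are isotropic on average), b = 0 volumes carry
    the region S0.  Intensities are ``region signal * (1 + noise)``; bit
    reproducibility is guaranteed by the spec seed.
    """
    if b_values is None:
        b_values = protocol.b_values
    if n_dir is None:
        n_dir = protocol.n_dir
    labels = np.full(spec.shape, -1, dtype=int)
    for i, region in enumerate(spec.regions):
        mask = region.mask_fn(spec.shape, spec.voxel_size_mm)
        labels[mask] = i
    if (labels < 0).any():
        raise ValueError("phantom regions do not cover the grid")
    wf_names = [f"WF{i}" for i in range(1, len(protocol.wf_timings) + 1)]
    timings = dict(zip(wf_names, protocol.wf_timings))
    dirs = _direction_set(n_dir)
    vols = []
    meta = []
    for wid in wf_names:
        d, D = timings[wid]
        td = D - d / 3.0
        base = np.zeros(spec.shape)
        for i, region in enumerate(spec.regions):
            base[labels == i] = region.s0
        vols.append(base)
        meta.append(VolumeMeta(b=0.0, waveform_id=wid, td_ms=td))
        for b in b_values:
            for direction in dirs:
                vol = np.zeros(spec.shape)
                for i, region in enumerate(spec.regions):
                    vol[labels == i] = region.s0 * region.signal(wid, b)
                vols.append(vol)
                meta.append(
                    VolumeMeta(
                        b=float(b), waveform_id=wid, td_ms=td, direction=direction
                    )
                )
    data = np.stack(vols, axis=-1)
    if spec.noise_sigma_frac > 0:
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0xFA4])
        s0map = np.zeros(spec.shape)
        for i, region in enumerate(spec.regions):
            s0map[labels == i] = region.s0
        data = data + spec.noise_sigma_frac * s0map[..., None] * rng.standard_normal(
            data.shape
        )
    return DwImageSet(
        data=data,
        meta=meta,
        voxel_size_mm=spec.voxel_size_mm,
    )


def _direction_set(n_dir: int) -> list:
    """n_dir unit vectors (synthetic labels; isotropic substrates)."""
    golden = (1 + 5**0.5) / 2
    out = []
    for i in range(n_dir):
        z = 1 - 2 * (i + 0.5) / n_dir
        phi = 2 * np.pi * i / golden
        s = np.sqrt(max(0.0, 1 - z * z))
        out.append((round(s * np.cos(phi), 6), round(s * np.sin(phi), 6), round(z, 6)))
    return out
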