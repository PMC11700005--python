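"""Time-dependent diffusion (TDD) contrast statistics and summaries.

The TDD contrast at a fixed b-value is the difference of two b0-normalized
DW signals acquired at a long and a short effective diffusion time,

    TDD = S_b(t_d2)/S0(t_d2) - S_b(t_d1)/S0(t_d1),      t_d2 > t_d1.

Positive contrast indicates dominating restricted diffusion (signal rises
with t_d as the apparent diffusivity falls), negative contrast dominating
diffusional exchange.  Contrast values are dimensionless in [-1, 1] and are
reported in percentage points where noted.

This module also evaluates the cylinder restriction resolution limit: in the
long-pulse (Neuman) regime the intracylinder attenuation is
``-ln S = (7/768) gamma^2 G^2 delta d^4 / D0``, so the smallest diameter whose
attenuation exceeds a noise floor ``sigma`` is

    d_min = (768 sigma D0 / (7 gamma^2 G_max^2 delta))^(1/4).

The formula is derived for cylinders and therefore slightly optimistic for
the spherical geometries simulated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .pgse_waveforms import GAMMA_RAD_PER_S_PER_T, ProtocolSpec

__all__ = [
    "ContrastResult",
    "tdd_contrast",
    "contrast_pair",
    "contrast_grid",
    "exchange_dilution",
    "resolution_limit",
]

_TOL = 1e-9


@dataclass(frozen=True)
class ContrastResult:
    """Scalar TDD contrast for one substrate and waveform pair."""

    contrast: float  # dimensionless, in [-1, 1]
    se: float
    b: float
    pair: tuple  # (long-td waveform id, short-td waveform id)
    substrate_id: str = ""

    @property
    def percent(self) -> float:
        return 100.0 * self.contrast


def tdd_contrast(S2_over_S02: float, S1_over_S01: float) -> float:
    """TDD contrast = S_b(t_d2)/S0(t_d2) - S_b(t_d1)/S0(t_d1).

    Inputs are b0-normalized signals of the long- and short-t_d acquisitions
    at the same b-value.  Values may exceed 1 marginally through noise.
    """
    for s in (S2_over_S02, S1_over_S01):
        if not -0.1 <= s <= 1.5:
            raise ValueError(f"normalized signal {s} outside plausible range")
    return S2_over_S02 - S1_over_S01


def contrast_pair(
    table: pd.DataFrame,
    pair: tuple = ("WF3", "WF1"),
    b: Optional[float] = None,
    substrate_id: Optional[str] = None,
) -> ContrastResult:
    """TDD contrast from two rows of a signal table.

    Validates the pairing: both waveforms at the same b-value and the first
    member at the longer effective diffusion time.
    """
    sel = table
    if substrate_id is not None:
        sel = sel[sel.substrate_id == substrate_id]
    if b is not None:
        sel = sel[np.isclose(sel.b, b, rtol=1e-3)]
    rows = {}
    for wid in pair:
        r = sel[sel.waveform_id == wid]
        if len(r) != 1:
            raise ValueError(
                f"expected exactly one row for waveform {wid!r}, found {len(r)}"
            )
        rows[wid] = r.iloc[0]
    long_, short_ = rows[pair[0]], rows[pair[1]]
    if abs(long_.b - short_.b) > 1e-3 * max(long_.b, 1.0):
        raise ValueError(
            f"pair b mismatch: {long_.b} vs {short_.b} s/mm^2"
        )
    if long_.td_ms <= short_.td_ms:
        raise ValueError(
            f"pair ordering: td({pair[0]})={long_.td_ms} must exceed "
            f"td({pair[1]})={short_.td_ms}"
        )
    c = tdd_contrast(float(long_.signal), float(short_.signal))
    se = float(math.hypot(long_.se, short_.se))
    return ContrastResult(
        contrast=c,
        se=se,
        b=float(long_.b),
        pair=pair,
        substrate_id=str(long_.substrate_id) if substrate_id is None else substrate_id,
    )


def contrast_grid(
    table: pd.DataFrame,
    pair: tuple = ("WF3", "WF1"),
    b: Optional[float] = None,
) -> pd.DataFrame:
    """TDD contrast per substrate over a battery signal table.

    The signal table must carry ``r_um``, ``vin`` and ``k_per_s`` columns (as
    produced by the battery runner).  Missing waveform pairs are reported in
    the ``gap`` column rather than silently skipped.
    """
    req = {"r_um", "vin", "k_per_s"}
    if not req <= set(table.columns):
        raise ValueError(f"battery table must carry columns {sorted(req)}")
    out = []
    for sid, sub in table.groupby("substrate_id", sort=False):
        meta = sub.iloc[0]
        try:
            res = contrast_pair(sub, pair=pair, b=b)
            row = {
                "substrate_id": sid,
                "r_um": meta.r_um,
                "vin": meta.vin,
                "k_per_s": meta.k_per_s,
                "b": res.b,
                "pair": f"{pair[0]}-{pair[1]}",
                "contrast": res.contrast,
                "se": res.se,
                "gap": "",
            }
        except ValueError as err:
            row = {
                "substrate_id": sid,
                "r_um": meta.r_um,
                "vin": meta.vin,
                "k_per_s": meta.k_per_s,
                "b": b,
                "pair": f"{pair[0]}-{pair[1]}",
                "contrast": np.nan,
                "se": np.nan,
                "gap": str(err),
            }
        out.append(row)
    return pd.DataFrame(out)


def exchange_dilution(
    grid: pd.DataFrame, baseline_k: float = 0.0
) -> pd.DataFrame:
    """Mean contrast decrease per exchange rate, in percentage points.

    For each k > baseline, averages ``contrast(k=0) - contrast(k)`` over the
    (r, vin) cells present for both.  Unmatched cells are excluded with a
    warning count in the output.
    """
    g = grid.dropna(subset=["contrast"])
    base = g[g.k_per_s == baseline_k].set_index(["r_um", "vin"])["contrast"]
    rows = []
    for k, sub in g[g.k_per_s != baseline_k].groupby("k_per_s"):
        sub = sub.set_index(["r_um", "vin"])
        matched = sub.index.intersection(base.index)
        diff = base.loc[matched] - sub.loc[matched, "contrast"]
        rows.append(
            {
                "k_per_s": k,
                "mean_decrease_pp": 100.0 * float(diff.mean()),
                "n_cells": len(matched),
                "n_unmatched": len(sub) - len(matched),
            }
        )
    return pd.DataFrame(rows)


def resolution_limit(
    G_max_mT_per_m: float,
    d0_um2_per_ms: float = 2.0,
    sigma_noise: float = 0.02,
    delta_ms: float = 27.0,
) -> float:
    """Minimum detectable restriction radius (um) for a PGSE protocol.

    Evaluates the cylinder resolution-limit formula (module docstring) with
    the protocol's maximum gradient and the lobe duration of its contrast
    pair, at fractional noise level ``sigma_noise``; returns the radius
    ``d_min / 2``.  Monotone: vanishing noise resolves arbitrarily small
    restrictions.
    """
    if G_max_mT_per_m <= 0 or d0_um2_per_ms <= 0 or delta_ms <= 0:
        raise ValueError("gradient, diffusivity and delta must be positive")
    if sigma_noise < 0:
        raise ValueError("noise level must be >= 0")
    gamma = GAMMA_RAD_PER_S_PER_T  # rad/s/T
    G = G_max_mT_per_m * 1e-3  # T/m
    delta_s = delta_ms * 1e-3
    d0 = d0_um2_per_ms * 1e-9  # m^2/s
    d_min_m = (768.0 * sigma_noise * d0 / (7.0 * gamma**2 * G**2 * delta_s)) ** 0.25
    return 0.5 * d_min_m * 1e6


def protocol_resolution_limit(
    protocol: ProtocolSpec, sigma_noise: float = 0.02, d0: float = 2.0
) -> float:
    """Resolution limit of a protocol preset (uses its contrast-pair delta)."""
    return resolution_limit(
        protocol.G_max, d0, sigma_noise, protocol.resolution_delta_ms
    )
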