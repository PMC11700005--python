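"""Square-wave PGSE diffusion encodings and protocol-constrained optimization.

A pulsed-gradient spin-echo (PGSE) encoding is modelled as two ideal
rectangular gradient lobes of amplitude ``G`` and duration ``delta`` whose
leading edges are ``Delta`` apart (the second lobe is sign-inverted by the
refocusing pulse).  For these waveforms

* diffusion weighting  ``b = gamma^2 G^2 delta^2 (Delta - delta/3)``,
* effective diffusion time  ``t_d = Delta - delta/3``,

with ``gamma = 267.513e6 rad s^-1 T^-1`` the proton gyromagnetic ratio.
Slew-rate ramps are neglected (documented simplification); the minimum echo
time is modelled as ``TE = Delta + delta + readout_margin``.

Two clinical protocol presets are shipped: a conventional 1.5 T scanner
(G_max = 45 mT/m, b = {1250, 2500} s/mm^2) and a 1.5 T MRI-Linac
(G_max = 15 mT/m, b = {250, 500, 750, 1000} s/mm^2), each with the three
frozen optimized timings WF1/WF2/WF3 used downstream, so results do not
depend on re-running the grid search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "GAMMA_RAD_PER_S_PER_T",
    "PgseWaveform",
    "ProtocolSpec",
    "b_value",
    "g_for_b",
    "effective_diffusion_time",
    "waveform_for_b",
    "enumerate_grid",
    "select_optimized_waveforms",
    "CONVENTIONAL_1P5T",
    "MRI_LINAC_1P5T",
    "PROTOCOLS",
]

#: proton gyromagnetic ratio (rad s^-1 T^-1)
GAMMA_RAD_PER_S_PER_T = 267.513e6

# gamma in phase units of the simulation frame: rad / (ms * (mT/m) * um)
_GAMMA_SIM = GAMMA_RAD_PER_S_PER_T * 1e-3 * 1e-9


def effective_diffusion_time(delta_ms: float, Delta_ms: float) -> float:
    """Effective diffusion time t_d = Delta - delta/3 (ms)."""
    if delta_ms > Delta_ms:
        raise ValueError(f"delta={delta_ms} must not exceed Delta={Delta_ms}")
    return Delta_ms - delta_ms / 3.0


def b_value(G_mT_per_m: float, delta_ms: float, Delta_ms: float) -> float:
    """Diffusion weighting b = gamma^2 G^2 delta^2 (Delta - delta/3) in s/mm^2."""
    td = effective_diffusion_time(delta_ms, Delta_ms)
    b_ms_um2 = (_GAMMA_SIM * G_mT_per_m) ** 2 * delta_ms**2 * td
    return b_ms_um2 * 1e3  # ms/um^2 -> s/mm^2


def g_for_b(b_s_per_mm2: float, delta_ms: float, Delta_ms: float) -> float:
    """Gradient amplitude (mT/m) achieving ``b`` at the given timings."""
    td = effective_diffusion_time(delta_ms, Delta_ms)
    if b_s_per_mm2 < 0:
        raise ValueError("b must be >= 0")
    if b_s_per_mm2 == 0:
        return 0.0
    b_sim = b_s_per_mm2 * 1e-3
    return math.sqrt(b_sim / (delta_ms**2 * td)) / _GAMMA_SIM


@dataclass(frozen=True)
class PgseWaveform:
    """One square-wave PGSE encoding."""

    G_mT_per_m: float
    delta_ms: float
    Delta_ms: float
    direction: tuple = (1.0, 0.0, 0.0)
    name: str = ""

    def __post_init__(self) -> None:
        if self.delta_ms < 0 or self.Delta_ms < 0 or self.G_mT_per_m < 0:
            raise ValueError("waveform parameters must be non-negative")
        if self.delta_ms > self.Delta_ms:
            raise ValueError(
                f"delta={self.delta_ms} exceeds Delta={self.Delta_ms}"
            )
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be a non-zero vector")
        object.__setattr__(self, "direction", tuple(d / n))

    @property
    def b_s_per_mm2(self) -> float:
        return b_value(self.G_mT_per_m, self.delta_ms, self.Delta_ms)

    @property
    def td_ms(self) -> float:
        return effective_diffusion_time(self.delta_ms, self.Delta_ms)

    @property
    def encoding_ms(self) -> float:
        """Duration of the encoding block, Delta + delta."""
        return self.Delta_ms + self.delta_ms

    def te_ms(self, readout_margin_ms: float = 0.0) -> float:
        """Minimum echo time implied by this encoding."""
        return self.encoding_ms + readout_margin_ms

    def sign_raster(self, dt_ms: float, n_steps: Optional[int] = None) -> np.ndarray:
        """Effective gradient polarity per time step (int8), spin-echo convention.

        The second lobe is negated.  Lobe edges must fall on the raster.
        """
        for edge in (self.delta_ms, self.Delta_ms, self.encoding_ms):
            k = edge / dt_ms
            if abs(k - round(k)) > 1e-6:
                raise ValueError(
                    f"lobe edge at {edge} ms does not align with dt={dt_ms} ms"
                )
        n1 = int(round(self.delta_ms / dt_ms))
        n2 = int(round(self.Delta_ms / dt_ms))
        n3 = n2 + n1
        if n_steps is None:
            n_steps = n3
        if n_steps < n3:
            raise ValueError("raster shorter than the encoding block")
        s = np.zeros(n_steps, dtype=np.int8)
        s[:n1] = 1
        s[n2:n3] = -1
        return s

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "G_mT_per_m": self.G_mT_per_m,
            "delta_ms": self.delta_ms,
            "Delta_ms": self.Delta_ms,
            "direction": list(self.direction),
            "b_s_per_mm2": self.b_s_per_mm2,
            "td_ms": self.td_ms,
        }


def waveform_for_b(
    b_s_per_mm2: float, delta_ms: float, Delta_ms: float, name: str = ""
) -> PgseWaveform:
    """Waveform at the given timings with G solved from the b formula."""
    return PgseWaveform(
        G_mT_per_m=g_for_b(b_s_per_mm2, delta_ms, Delta_ms),
        delta_ms=delta_ms,
        Delta_ms=Delta_ms,
        name=name,
    )


@dataclass(frozen=True)
class ProtocolSpec:
    """Hardware and sequence constraints of one acquisition protocol.

    ``wf_timings`` holds the frozen optimized (delta, Delta) pairs in ms for
    WF1, WF2, WF3 (short reference, delta-driven, Delta-driven).
    ``min_gap_ms`` is the smallest allowed Delta - delta (time for the
    refocusing pulse between the lobes).  ``resolution_delta_ms`` is the lobe
    duration entering the restriction resolution-limit formula (the delta
    shared by the TDD31 pair).
    """

    name: str
    G_max: float  # mT/m
    te_max_ms: float
    b_values: tuple  # s/mm^2, excluding b=0
    n_dir: int = 6
    readout_margin_ms: float = 6.0
    min_gap_ms: float = 8.0
    wf_timings: tuple = ()
    resolution_delta_ms: float = 0.0

    def waveforms(self, b: float) -> tuple:
        """Frozen WF1/WF2/WF3 waveforms with G solved for the requested b."""
        if b not in self.b_values:
            raise ValueError(f"b={b} not part of protocol {self.name}")
        out = []
        for i, (d, D) in enumerate(self.wf_timings, start=1):
            wf = waveform_for_b(b, d, D, name=f"WF{i}")
            if wf.G_mT_per_m > self.G_max + 1e-9:
                raise ValueError(
                    f"{wf.name} needs G={wf.G_mT_per_m:.1f} mT/m > G_max={self.G_max}"
                )
            out.append(wf)
        return tuple(out)

    @property
    def b_max(self) -> float:
        return max(self.b_values)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "name": self.name,
                    "G_max": self.G_max,
                    "te_max_ms": self.te_max_ms,
                    "b_values": list(self.b_values),
                    "n_dir": self.n_dir,
                    "readout_margin_ms": self.readout_margin_ms,
                    "min_gap_ms": self.min_gap_ms,
                    "wf_timings": [list(t) for t in self.wf_timings],
                    "resolution_delta_ms": self.resolution_delta_ms,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "ProtocolSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["b_values"] = tuple(d["b_values"])
        d["wf_timings"] = tuple(tuple(t) for t in d["wf_timings"])
        return cls(**d)


#: conventional 1.5 T scanner protocol (patients + phantom)
CONVENTIONAL_1P5T = ProtocolSpec(
    name="conventional-1.5T",
    G_max=45.0,
    te_max_ms=135.0,
    b_values=(1250.0, 2500.0),
    wf_timings=((27.0, 35.0), (54.0, 62.0), (27.0, 89.0)),
    resolution_delta_ms=27.0,
)

#: 1.5 T MRI-Linac protocol (phantom)
MRI_LINAC_1P5T = ProtocolSpec(
    name="mri-linac-1.5T",
    G_max=15.0,
    te_max_ms=135.0,
    b_values=(250.0, 500.0, 750.0, 1000.0),
    wf_timings=((42.0, 50.0), (54.0, 62.0), (42.0, 75.0)),
    resolution_delta_ms=42.0,
)

PROTOCOLS = {p.name: p for p in (CONVENTIONAL_1P5T, MRI_LINAC_1P5T)}
#: convenience aliases accepted by the CLI
PROTOCOLS["conventional"] = CONVENTIONAL_1P5T
PROTOCOLS["mri-linac"] = MRI_LINAC_1P5T


def enumerate_grid(
    protocol: ProtocolSpec,
    b_target: float,
    delta_range: tuple = (5.0, 60.0),
    Delta_max: Optional[float] = None,
    step_ms: float = 1.0,
    return_infeasible: bool = False,
):
    """All feasible (delta, Delta) grid waveforms achieving ``b_target``.

    G is solved from the b formula and capped at ``G_max``; the echo-time
    constraint ``Delta + delta + readout_margin <= te_max`` and the minimum
    lobe gap are enforced.  ``b_target = 0`` degenerates to the single null
    waveform.  With ``return_infeasible`` the flagged infeasible cells
    (timing, reason) are returned alongside the feasible list.
    """
    if b_target == 0:
        out = [PgseWaveform(0.0, 0.0, 0.0, name="b0")]
        return (out, []) if return_infeasible else out
    if Delta_max is None:
        Delta_max = protocol.te_max_ms - protocol.readout_margin_ms
    out = []
    infeasible = []
    n_lo = int(round(delta_range[0] / step_ms))
    n_hi = int(round(delta_range[1] / step_ms))
    for i in range(n_lo, n_hi + 1):
        delta = i * step_ms
        Delta = delta + protocol.min_gap_ms
        while Delta <= Delta_max:
            te = delta + Delta + protocol.readout_margin_ms
            if te > protocol.te_max_ms:
                infeasible.append({"delta_ms": delta, "Delta_ms": Delta, "reason": "te"})
            else:
                G = g_for_b(b_target, delta, Delta)
                if G <= protocol.G_max + 1e-9:
                    out.append(
                        PgseWaveform(
                            G, delta, Delta, name=f"d{delta:g}_D{Delta:g}"
                        )
                    )
                else:
                    infeasible.append(
                        {"delta_ms": delta, "Delta_ms": Delta, "reason": "G_max"}
                    )
            Delta += step_ms
    if return_infeasible:
        return out, infeasible
    if not out:
        raise ValueError(
            f"no feasible waveform reaches b={b_target} s/mm^2 under "
            f"G_max={protocol.G_max} mT/m, TE<={protocol.te_max_ms} ms"
        )
    return out


def select_optimized_waveforms(
    signal_map: dict,
    protocol: ProtocolSpec,
    b_target: float,
) -> tuple[PgseWaveform, PgseWaveform, PgseWaveform]:
    """Pick (WF1, WF2, WF3) from a simulated signal map over the grid.

    ``signal_map`` maps (delta, Delta) -> normalized signal S_b/S0 for the
    target geometry.  WF1 is the shortest-t_d feasible waveform at the minimum
    lobe gap (the common reference); WF2 maximizes |S - S(WF1)| over the
    same-gap branch with longer delta (delta-driven contrast, COM effect);
    WF3 maximizes it over the same-delta branch with longer Delta
    (Delta-driven contrast).  Ties break toward shorter echo time.
    """
    grid = enumerate_grid(protocol, b_target)
    by_timing = {(w.delta_ms, w.Delta_ms): w for w in grid}
    gap = protocol.min_gap_ms
    ref_branch = [w for w in grid if abs(w.Delta_ms - w.delta_ms - gap) < 1e-9]
    if not ref_branch:
        raise ValueError("no waveform on the minimum-gap branch is feasible")
    wf1 = min(ref_branch, key=lambda w: (w.td_ms, w.encoding_ms))
    s1 = signal_map[(wf1.delta_ms, wf1.Delta_ms)]

    def best(cands):
        scored = [
            (abs(signal_map[(w.delta_ms, w.Delta_ms)] - s1), -w.encoding_ms, w)
            for w in cands
            if (w.delta_ms, w.Delta_ms) in signal_map
        ]
        if not scored:
            raise ValueError("signal map does not cover the candidate branch")
        return max(scored, key=lambda t: (t[0], t[1]))[2]

    wf2 = best(
        [w for w in ref_branch if w.delta_ms > wf1.delta_ms]
    )
    wf3 = best(
        [
            w
            for w in grid
            if abs(w.delta_ms - wf1.delta_ms) < 1e-9 and w.Delta_ms > wf1.Delta_ms
        ]
    )
    wf1 = replace(wf1, name="WF1")
    wf2 = replace(wf2, name="WF2")
    wf3 = replace(wf3, name="WF3")
    return wf1, wf2, wf3
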