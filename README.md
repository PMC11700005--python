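# tddscope

Time-dependent diffusion MRI (TDD-MRI) probes tissue microstructure beyond
the apparent diffusion coefficient: **restricted diffusion** inside cells
lowers the apparent diffusivity as the diffusion time grows, while
**transmembrane water exchange** raises it. Both effects matter in tumors —
cell size and density, and membrane permeability, are candidate quantitative
imaging biomarkers for radiotherapy guidance — but modelling them jointly
requires long acquisitions and fragile fits. `tddscope` implements the
model-free alternative: the **TDD contrast**, a difference of two
b-matched, b0-normalized PGSE signals at a short and a long effective
diffusion time t_d = Δ − δ/3,

```
TDD = S_b(t_d,2)/S0(t_d,2) − S_b(t_d,1)/S0(t_d,1),     t_d,2 > t_d,1
```

whose sign separates dominating restriction (+) from dominating exchange (−).
The package is for physicists evaluating whether that contrast is measurable
on clinical hardware — a conventional 1.5 T scanner (G_max = 45 mT/m) or a
1.5 T MRI-Linac (G_max = 15 mT/m) — and for processing the resulting images.

It provides:

* a Monte Carlo random-walk simulator of water diffusion in square-packed
  lattices of permeable spheres (radius 2–20 µm, intracellular volume
  fraction up to π/6, exchange rate k = 3κ/r), with streamed spin-phase
  accumulation for square-wave PGSE encodings;
* PGSE waveform algebra (b = γ²G²δ²(Δ − δ/3)), grid enumeration under
  G_max/TE constraints, waveform optimization, and the frozen
  WF1/WF2/WF3 protocol presets for both scanners;
* the TDD contrast statistic, substrate-grid summaries, exchange-dilution
  averages, and the cylinder restriction resolution limit
  r_min = ½·(768 σ D0 / (7 γ² G² δ))^¼;
* closed-form oracles (Karger two-compartment exchange, Murday–Cotts /
  van Gelderen sphere signal) used for validation;
* a voxel-wise image pipeline (direction geometric means with
  background-gradient cancellation, b0 normalization, median filtering,
  TDD contrast and ADC maps, Tukey-fence ROI statistics) on NIfTI volumes
  with JSON sidecars, plus Monte Carlo noise propagation;
* a synthetic stem-in-water phantom generator so the whole pipeline runs
  with no acquisition, and a `tddscope` CLI orchestrating all of it.

## Worked example

Simulate the densest substrate at the contrast-optimal cell size for the
conventional scanner and compute the Δ-driven contrast (TDD31, b = 2500
s/mm², WF3: δ/Δ = 27/89 ms vs WF1: 27/35 ms):

```python
from tddscope import (CONVENTIONAL_1P5T, contrast_pair, lattice_from_vin,
                      simulate_signals)

lat = lattice_from_vin(radius_um=12.0, vin=0.52, k_per_s=0.0)   # impermeable
wf1, _, wf3 = CONVENTIONAL_1P5T.waveforms(2500.0)
table = simulate_signals(lat, [wf1, wf3], n_walkers=20_000, dt_ms=2e-3, seed=11)
print(table[["waveform_id", "td_ms", "signal", "se"]].round(4).to_string(index=False))
res = contrast_pair(table, pair=("WF3", "WF1"), b=2500.0)
print(f"TDD31 = {res.percent:+.2f}% +- {100 * res.se:.2f}")
```

prints

```
waveform_id  td_ms  signal     se
        WF1   26.0  0.2133 0.0048
        WF3   80.0  0.3653 0.0045
TDD31 = +15.20% +- 0.66
```

The 12 µm cells retain ~15 percentage points more normalized signal at
t_d = 80 ms than at 26 ms: strong, positive (restriction-dominated) contrast,
far above typical map noise. Repeating this on an r = 2 µm, k = 20 s⁻¹
substrate flips the sign (exchange-dominated), and at 15 mT/m the same
contrasts shrink by roughly a factor of three — the feasibility question the
simulation battery quantifies. A scalar feasibility anchor:

```python
from tddscope import resolution_limit
resolution_limit(45.0, 2.0, 0.02, 27.0)   # -> 2.89 um minimum detectable radius
```

## Reproduction script

`scripts/acceptance.py` recomputes the headline simulation results from
scratch at desk scale (2×10⁴ walkers per substrate, Δt = 2×10⁻³ ms; the
production profile of 10⁵ walkers at Δt = 10⁻⁴ ms is available via
`profile="full"`): it runs the radius × exchange-rate battery at
v_in = 0.52 for both protocols' TDD31 pairs, then reports the no-exchange
contrast maxima and their radii, the most negative (exchange-dominated)
contrasts at r = 2 µm, the mean k = 20 s⁻¹ contrast dilution, the
cancer-cell-size contrast bound at 15 mT/m, and both resolution limits:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(~10 minutes on one CPU). See `docs/methods.md` for the model, its
assumptions, numerical choices, and known limitations.
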