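# Methods

`tddscope` quantifies the two time-dependent effects in the diffusion-weighted
MR signal of tissue — restricted diffusion inside cells and transmembrane
water exchange — through a model-free contrast between two acquisitions with
matched b-value but different effective diffusion time, and asks whether that
contrast is measurable under clinical gradient constraints (45 mT/m on a
conventional 1.5 T scanner, 15 mT/m on a 1.5 T MRI-Linac).

## The TDD contrast

For two square-wave PGSE encodings at the same b with effective diffusion
times t_d1 < t_d2 (t_d = Δ − δ/3),

    TDD = S_b(t_d2)/S0(t_d2) − S_b(t_d1)/S0(t_d1).

Restriction makes the apparent diffusivity fall with diffusion time, so the
longer-t_d signal is higher and the contrast positive; exchange lets
intracellular water escape over time, raising apparent diffusivity and making
the contrast negative. The b0 normalization cancels receiver gain and T2
differences between the acquisitions, so the statistic is comparable across
subjects without model fitting.

## Tissue model and Monte Carlo engine

Tissue is a simple-cubic lattice of identical spheres (radius r, one sphere
per cubic cell of pitch L), so the intracellular volume fraction is
v_in = (4π/3) r³/L³ with non-overlap bound π/6. Membrane permeability κ is
parameterized by the intracellular first-order escape rate k = 3κ/r (sphere
surface-to-volume relation). Intrinsic diffusivity D0 is equal in both
compartments.

Walkers take fixed-length steps l = √(6 D0 Δt) in uniformly random
directions. A step segment is processed piecewise against the sphere surface
of the current periodic cell and the cell faces: face hits wrap periodically
(with image bookkeeping so unwrapped displacements remain available); sphere
hits either transmit the walker (probability p_t) or reflect it specularly,
and the remaining path is re-examined, so one step may interact several times
— necessary in dense lattices where the extracellular gaps are narrower than
a step. A warning is raised when l > 0.2 r (membrane model marginal) or
l > r (invalid).

The transmission probability is p_t = c κ l / D0. Matching the one-sided
walker flux onto a plane wall (c l / (4 Δt) per unit area for fixed-length
isotropic steps) to the membrane flux κ c gives c = 2/3. The constant is
verified by a first-passage experiment on a reference substrate
(r = 5 µm, k = 8 s⁻¹): the survival curve of initially intracellular walkers
(walkers that have never crossed; re-entries do not reset the flag) must
decay at the nominal k. The shipped constant reproduces k within ~1%, well
inside the 10% calibration band, and `calibrate_transmission()` re-runs the
check.

Spin phases are accumulated in-stream: φ = γ Σ_t G_eff(t) x(t) Δt with the
second lobe negated and x the unwrapped position projected on the gradient
axis. The kernel accumulates position sums over the time segments delimited
by the union of all waveform lobe edges; per-waveform phases are recombined
afterwards, so the cost per step is independent of the number of waveforms
and no trajectory is ever materialized. The ensemble signal is the magnitude
of the complex mean |⟨e^{iφ}⟩| (the real-part mean differs only at MC-error
level for these symmetric substrates); its standard error comes from the
delta method on the phasor projections.

Randomness: one master seed deterministically derives per-substrate seeds and
per-walker xorshift64* streams, so results are independent of iteration order
and chunking.

## Validation oracles

* Free medium: MSD = 6 D0 t, phase variance 2 b D0, signal exp(−b D0) on all
  protocol waveforms (verifies b bookkeeping end to end).
* Impermeable sphere: long-time per-axis displacement variance 2r²/5; the
  intracellular signal matches the Gaussian-phase-distribution
  (Murday–Cotts / van Gelderen) series within 3% + MC error at clinical
  timings.
* Exchange: the two-compartment Karger model (validated itself against a
  matrix-exponential solution of the two-site master equation) fitted to
  engine signals on an exchange-dominated substrate recovers k within 25%.
* The center-of-mass effect emerges rather than being hard-coded: at fixed b
  and t_d, lengthening δ raises the small-sphere signal in both the engine
  and the GPD oracle.

## Waveforms and protocols

Waveforms are ideal rectangles (no slew ramps): b = γ²G²δ²(Δ − δ/3). The echo
time is modelled as TE = Δ + δ + margin with a 6 ms readout margin, and a
minimum lobe gap Δ − δ = 8 ms accounts for the refocusing pulse. The grid
search enumerates integer-ms (δ, Δ) cells, solves G from b and keeps cells
with G ≤ G_max and TE ≤ 135 ms; raising G_max can only add cells.

The waveform-selection objective is: WF1 = the feasible minimum-t_d waveform
at the minimum gap (the common reference); WF2 = the same-gap branch member
(δ and Δ raised together) maximizing |S − S(WF1)| for a designated reference
geometry — the δ-driven, COM-effect contrast; WF3 = the same-δ branch member
(Δ raised alone) maximizing it — the Δ-driven contrast probing long diffusion
times. With this rule WF1 reproduces the shipped protocol timings exactly.
Because a published protocol should not depend on re-optimization, both
protocol presets (conventional: 27/35, 54/62, 27/89 ms at b ≤ 2500 s/mm²;
MRI-Linac: 42/50, 54/62, 42/75 ms at b ≤ 1000 s/mm²) are shipped frozen, and
the battery and acceptance computations use the frozen timings.

Simulation uses a single gradient axis. The default axis is a lattice axis;
`axis=` can select e.g. the cell diagonal. At the smallest radii and highest
density the extracellular space of a square-packed lattice is a network of
narrow channels that is most conductive along the lattice axes, so the
exchange-dominated contrast at r = 2 µm depends noticeably on this
(unstated-in-the-source) orientation convention; the lattice-axis default
makes that cell's negative contrast a percentage point or two stronger than
the diagonal choice.

## Resolution limit

The smallest restriction radius distinguishable from free water at noise
level σ uses the long-pulse (Neuman-regime) cylinder attenuation
−ln S = (7/768) γ²G²δ d⁴/D0, inverted at the detection threshold σ:

    d_min = (768 σ D0 / (7 γ² G_max² δ))^¼,   r_min = d_min/2,

evaluated with the δ shared by the protocol's TDD31 pair (27 ms conventional,
42 ms MRI-Linac). At σ = 2%, D0 = 2.0 µm²/ms this gives r_min = 2.9 µm and
4.5 µm. The formula is derived for cylinders and is slightly optimistic for
spheres.

## Image pipeline and noise

Map computation mirrors a clinical processing chain on co-registered 4-D
volumes: geometric mean over the six directions (opposite-polarity pairs
combined multiplicatively first, cancelling background-gradient cross
terms), b0 normalization per waveform, 3-D median filtering, voxel-wise TDD
contrast per b, voxel-wise ADC per waveform by ordinary least squares of
−ln(S/S0) on b, and ROI statistics with Tukey fences
(Q1 − 1.5·IQR, Q3 + 1.5·IQR; type-7 quantiles). "Half the acquisition voxel
size" as a median kernel is below one voxel at 3×3×5 mm resolution, so the
kernel is a 3×3×3 neighbourhood on the native grid; an optional supersampled
mode filters on a voxel-replicated grid instead. Non-positive or
zero-S0 voxels are masked (NaN) rather than clamped, and masks propagate.

Noise propagation resamples the four signals entering the contrast
(Gaussian on normalized signals by default, high-SNR regime; Rician mode
available), processes the replicates like data, and reports the contrast SD;
a delta-method closed form serves as the small-σ oracle. The noise level
itself is estimated from ≥3 repeated b0 volumes as the voxel-wise SD over
repetitions (ROI-averaged, with a leave-one-out table to flag outlier
replicates). Reference in-vivo noise levels depend on patient data and are
treated as inputs, not reproduction targets.

## Synthetic phantom

The generator emulates the stem-in-water-bath validation object: cylindrical
regions in a free-water background (D = 2.0e−3 mm²/s, room temperature, equal
to the simulation D0 for consistency), each region driven either by a free
diffusivity or by simulator signal-table rows, at the acquisition geometry
(64×64×16 voxels, 3×3×5 mm), with optional multiplicative Gaussian noise and
bit-reproducible seeding. It does not model scanner artifacts, relaxation
contrast, or intra-voxel cell-size distributions, so a green round-trip test
establishes pipeline correctness, not acquisition realism.

## Reduced preset and known limitations

The published battery scale (10⁵ walkers, Δt = 10⁻⁴ ms, 250 ms) exceeds
desk scale; tests and the acceptance script run 2×10⁴ walkers at
Δt = 2×10⁻³ ms (l ≈ 0.155 µm), which reproduces free diffusion exactly and
restricted variance within ~2%. Consequences observed at this scale, with
the battery at the densest simulated volume fraction (v_in = 0.52, the only
density that reproduces the published contrast magnitudes):

* the no-exchange contrast peak at 45 mT/m is statistically flat between
  r = 12 and 14 µm (neighbouring cells differ by less than the MC error of
  their difference), so the reported argmax can land on either;
* the exchange-dominated r = 2 µm cell is systematically more negative than
  the published −7.28% (≈ −8 to −9% depending on sampling); this is
  converged in Δt and traces to the gradient-axis/lattice-orientation
  convention above, and it propagates into the 45 mT/m exchange-dilution
  mean (≈ 10 pp vs the published 7.99 pp), whose averaging set is
  additionally under-specified in the source;
* exchange-dilution means are averaged over the 10 standard radii at
  v_in = 0.52 with the TDD31 pair, per the stated default; averaging over
  the lower densities as well would scale the means down roughly with v_in.

Polydisperse radius mixtures, hexagonal packings, oscillating gradients,
surface relaxation, compartmental T2, and perfusion are out of scope.
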