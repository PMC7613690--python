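# Methods

This note documents the models, parameters, and numerical choices behind
`aistrack`, and what the synthetic benchmarks do and do not establish.

## Neuron models

**Ball-and-stick.** A 16 µm spherical soma (single equivalent-area
compartment), a 1 mm cylindrical dendrite (2 µm diameter) opposite a 1 mm
cylindrical axon (1 µm diameter). A contiguous 30 µm span of the proximal
axon is tagged as the AIS; its proximal edge sits `d_ais` ∈ [5, 40] µm from
the soma surface. Moving the AIS relabels a sub-span of the axon — total
cable length and diameters never change.

**Synthetic detailed model.** A procedural stand-in for reconstructed
neurons: a 14 µm soma, six primary dendrites (0.4–0.8 µm radius, 120–350 µm,
60 % bifurcating) fanning over the hemisphere opposite the axon and rising
from the substrate at slope 0.15, a 5 µm tapering hillock (2 → 0.6 µm), the
30 µm AIS, and a 500 µm straight axon along the substrate at a configurable
planar angle. The polarized, substrate-hugging axon reflects how neurites
organize on planar arrays and keeps the proximal-axon field the dominant
contributor to the footprint near the AIS — the physical premise that makes
extracellular AIS tracking possible in the first place. An isotropic coplanar
arbor, by contrast, superimposes a large relocation-independent dendritic
far-field on every electrode; that configuration degrades (and with strong
contamination defeats) kernel transfer, which is worth remembering when
interpreting real recordings of strongly multipolar cells. Deterministic per
seed.

**SWC import.** Standard 7-column SWC; structure ids map 1 → soma,
2 → axon, 3/4 → dendrite. Radii ≤ 0.1 µm are interpolated from path
neighbors and each path's radii are smoothed with a 15-sample moving average
(both can be disabled). A 30 µm AIS is carved out of the first axonal path at
`d_ais` from the soma surface.

## Biophysics

Channel densities (pS/µm²), identical across models:

| region   | g_Na | g_K  | g_Kv7 |
|----------|------|------|-------|
| soma     | 50   | 100  | 1     |
| AIS      | 7000 | 2000 | 7     |
| dendrite | 20   | 0.3  | 1     |
| axon     | 300  | 100  | 0     |
| hillock  | 50   | 100  | 1     |

E_Na = 55 mV, E_K = −98 mV. The plain-axon and hillock rows are package
defaults (densities sufficient for active propagation, far below the AIS hot
zone); the others are the standard AIS-enriched cortical distribution.
Passive: Ra = 150 Ω·cm, c_m = 1 µF/cm², g_leak = 1/30000 S/cm²,
E_leak = −80 mV — standard cortical values.

Kinetics are HH-style: transient Na (m³h, Traub-type rate functions),
delayed-rectifier K (n⁴), and a slow non-inactivating Kv7/M current
(Yamada-type). Recovery from Na inactivation is deliberately slowed (α_h
scaled ×0.15): axonal Na channels reprime over many milliseconds, and this
limits the response to a 20 ms current step to one or two APs instead of an
unphysiological >300 Hz train. Single-spike responses also keep the cutout
windows (3 / 5.5 ms) free of second spikes, which matters for the LTI kernel
abstraction. With these kinetics the ball-and-stick peak dV/dt is ≈1140 mV/ms
at the AIS midpoint vs. ≈210 mV/ms at the soma (ratio ≈5.5); absolute values
depend on the exact rate functions, the ratio robustly exceeds 2.

## Simulation and forward model

Spatial discretization ≤ 5 µm per compartment along the AIS and proximal
axon (coarser distally: 25 µm; dendrites 40–50 µm). Time step 2⁻⁵ ms
(32 kHz sampling), 30 ms simulations, 20 ms somatic current step from t = 2 ms.
The stimulus amplitude is fixed per model at 1.5 × rheobase, located by
bisection within [0.3, 2] nA; subthreshold runs are flagged, not raised.

Integration is a staggered implicit scheme: gates advance by exponential
integration at the current voltage, then the voltage solves the
backward-Euler linear system (dense solve; compartment counts are ≤ ~200).
Per-compartment transmembrane current (capacitive + ionic) is recovered from
Kirchhoff's law as net axial inflow plus stimulus, which conserves current to
machine precision — the extracellular field therefore has no spurious
monopole.

Extracellular potentials use the line-source approximation for cylindrical
compartments and a point source for the soma, in a homogeneous medium of
conductivity σ = 0.3 S/m (configurable). The probe is a 30 × 30 lattice at
17.5 µm pitch (electrodes treated as points; pitch ≫ electrode size), the
central 12 × 12 block is analyzed, and the neuron sits 10 µm above the plane
(soma membrane ≈ 2 µm from the substrate). Rigid rotation/translation leaves
intracellular dynamics unchanged, so grid runners solve the cable equations
once per AIS position and recompute only the electrode transfer matrix per
placement — this is what makes the 384-placement reduced grid a seconds-scale
computation.

Grids: full ball-and-stick = 4 offsets × 360 angles (1°) × 36 AIS positions;
full detailed = 4 × 72 (5°) × 18 positions (2 µm steps). The reduced grid
(tests, examples) is 2 offsets × 24 angles (15°) × 8 positions (5 µm steps);
the kernel-library grid is 2 × 48 (7.5°) × 15 positions (2.5 µm steps),
because position estimation needs finer angular and positional resolution
than classification does.

## Features and datasets

Cutout windows are 96 samples (3 ms) for the ball-and-stick profile and 177
samples (≈5.5 ms) for detailed profiles. The window is anchored on the
electrode with the *earliest trough*: the first electrode whose trace crosses
the detection floor (−10 µV default; ties broken by deeper trough, then lower
id), with the trough taken as the local minimum within 1 ms of the crossing.
One third of the window precedes the trough. Anchoring on the first
floor-crossing rather than the global minimum keeps all footprints of a
family aligned on the same (first) spike. The floor only guards against
subthreshold runs in noiseless simulations; its value simply has to sit well
below the few-µV subthreshold scale and above zero.

Per electrode: trough amplitude (relative to the mean of the first 10
samples), latency to the footprint's earliest trough, half-width at
half-trough (linear interpolation at the crossings; windows that never
recross are flagged), peak-to-peak, and finite-difference slopes at the two
half-amplitude crossings. The top 26 electrodes by |trough amplitude| are
selected and ordered by latency (ties: deeper trough, then lower id).

Δ-vectors are electrode-wise feature differences (comparison − baseline) over
the baseline's 26-electrode ordering; the baseline is always `d_ais` = 5 µm
and valid vectors carry magnitude `d_ais − 5`. Sham vectors permute the
comparison's electrode rows (seeded; identity permutations redrawn) before
subtraction and are labeled invalid; one sham per valid vector keeps the
detector's chance level at 0.5.

## Machine learning

**Diagonal NCA.** Per-feature nonnegative weights under a weighted-L1
distance; stochastic gradient ascent (batch 128, 40 epochs, decaying step)
maximizes the expected leave-one-out soft-nearest-neighbor accuracy minus
λ Σw² with λ = 3·10⁻⁵; weights are clipped at zero each step and features
below 10 % of the maximum weight are dropped. Self-pairs are excluded by
index, not by zero distance (collapsed weights would otherwise mask
everything). Initialization w = 1/√p keeps initial distances O(1) after
z-scoring. The selected-feature count varies with data and seed (≈40–55 of
156 on the reduced grid) and is not a target quantity.

**Detector.** Random forest, 100 trees, √p features per split, trained on
z-scored NCA-selected features; 60/20/20 train/validation/hold-out split,
seeded. **Regressor.** Single hidden layer of 100 ReLU units (Adam, early
stopping on the validation fold, ≤500 epochs), trained on Δ-amplitude
features only of valid pairs; targets z-scored internally. Both report
hold-out metrics exclusively. Label-permutation controls collapse both to
chance, confirming the signal is not leakage.

## Kernel method

Kernels are length-25 causal FIRs solving `y = X h` by least squares
(`scipy.linalg.lstsq`); when cond(XᵀX) > 10⁸ the ridge form
(XᵀX + δI)⁻¹Xᵀy with δ = 0.01 is used. The library stores
H[offset, θ, d_ais, m] for the 26 baseline-ordered electrodes of each
(offset, θ) family, always fit against that family's 5 µm baseline.

Position estimation, given a baseline/relocated footprint pair of an
arbitrary neuron: for each candidate `d_ais`, each target electrode is
matched to the library electrode with the lowest normalized RMS prediction
error over all angles (errors averaged over stored offsets); the error-curve
entry is the amplitude-weighted mean over electrodes evaluated at a single
common angle, minimized over that angle. Two details matter:

- *Common-angle evaluation.* Matching each electrode independently at its
  privately best angle lets the richer kernel dictionaries at large `d_ais`
  fit any target (the error curve then decreases monotonically and every
  estimate saturates at 40 µm). Choosing m* over all angles but scoring the
  footprint at one shared angle penalizes orientation-inconsistent matches
  and restores a convex error curve.
- *Amplitude weighting.* The normalized RMS error divides by the estimated
  waveform's range, so weak electrodes (a few µV) contribute mostly
  normalization noise; weighting electrodes by baseline trough amplitude
  stabilizes the curve without changing the per-electrode cost.

A candidate at 5 µm (the identity transformation, scored directly) anchors
the no-relocation end. A cubic polynomial is fit to the curve by ordinary
least squares; the estimate is the minimizing root of its derivative clamped
to the tested interval, flagged non-convex when only a boundary minimum
exists. Reported recovery numbers average estimates over replicate placements
(4 soma offsets × 2 rotations), the scaled-down version of averaging over
jittered positions and rotations.

On the shipped benchmark (ball-and-stick library at 7.5°/2.5 µm; polarized
branched targets), per-position mean estimates track the identity line with
≈2 µm mean absolute error over true positions 11–39 µm. Individual
single-placement estimates scatter by ±5–10 µm — the replicate average is
part of the method, not a cosmetic.

## Degenerate inputs and tie-breaks

Flat waveforms in the normalized RMS error return an infinite sentinel rather
than raising; footprints with no suprathreshold trough raise a dedicated
`NoSpikeError`; a constant regression target and sub-50-row training sets are
refused; single-class NCA labelings are refused; nearest-electrode and
electrode-ordering ties resolve deterministically (lowest index / deeper
trough → lower id).

## What the synthetic benchmarks show — and don't

All results are simulation-to-simulation: the same solver and forward model
generate both the kernel library and the "unknown" targets, with morphology,
orientation, and jitter varied. They establish that the inference chain is
correct and self-consistent, that footprint changes carry enough information
to detect and quantify AIS relocation under ideal recording conditions, and
that ball-and-stick kernels transfer across morphologies whose proximal-axon
field dominates the footprint. They do not address recording noise, spike
sorting errors, electrode drift, multi-neuron superposition, concurrent AIS
length/density changes, or biological channel-kinetics diversity — all of
which would only degrade the reported numbers. The detector's perfect
reduced-grid scores should be read as "the classes are cleanly separable in
the noiseless feature space", not as a field-condition claim.
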