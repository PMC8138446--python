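# Methods

This note documents the models behind `liverheart`, their assumptions, the
defaults that matter, and the limits of what the synthetic-data tests can
show about real recordings.

## 1. Liver-chip transport model

### Geometry and reduction

The liver chip is a stack: a 5,560 × 560 × 100 µm cell chamber on glass, a
15-µm track-etched PET membrane (5.6 % porosity, 3-µm pores), a 100-µm
media channel perfused at 20 µL/h, and a 3.5-mm PDMS slab whose outer
surfaces face incubator air. At this flow rate the channel Reynolds number
is ~10⁻², so the flow is plane Poiseuille and is written down analytically
(`device.channel_hydraulics`): mean velocity Q/(w·h) ≈ 9.9·10⁻⁵ m/s, wall
shear 6µQ/(w·h²) ≈ 0.046 dyn/cm² — two orders of magnitude below the
5 dyn/cm² level known to impair hepatocyte synthetic function — residence
time ≈ 56 s, Péclet number ≈ 3.

Transport is solved on a 2-D longitudinal (x–z) cross-section with the
width direction averaged out. Because the membrane's flow resistance is
orders of magnitude above the channel's, there is no advection below the
membrane: species move into and inside the cell chamber by diffusion only.

### Oxygen physics

Oxygen partial pressure is continuous at the media/PDMS interface while
concentration jumps by the Henry partition coefficient
k = c_sat,PDMS / c_sat,media = 1.11/0.173 ≈ 6.42. The solver therefore uses
a media-equivalent variable u (aqueous concentration at equal partial
pressure): aqueous layers carry permeability D and capacity 1, the
membrane φD and φ (straight cylindrical pores, tortuosity 1), the PDMS
D_PDMS·k and k. In u the field is continuous and the ambient-saturated
PDMS exterior sits at exactly the media saturation 0.173 mol/m³, which
makes the zero-uptake equilibrium uniform — a useful exactness check.

Cellular uptake is the Michaelis–Menten sink
−V_O2max·ρ_cell·c/(K_m·S_cell + c), applied over the whole cell chamber at
the published density ρ_cell = 6.44·10¹³ m⁻³ (V_O2max = 1.04·10⁻¹⁶
mol/s/cell; K_m·S_cell ≈ 7.7·10⁻³ mol/m³). The published cell count
(9,812) and density are mutually inconsistent over the 100-µm chamber by
about a factor two; we keep the density (the quantity that enters the
PDE) and note that the per-cell OCR and total-uptake invariants are
checked against the printed constants directly.

### Side-wall supply (a deliberate departure)

A width-averaged model cannot see the PDMS on either side of the 0.56-mm
channels, but in 3-D those walls deliver several times more ambient oxygen
than the 1-D through-roof path: a lumped-conductance estimate puts the
top-only steady chamber oxygen at ~0.10 mol/m³, far from the measured-model
value of 0.16. The wall paths are real physics ("roof **and** walls"), so
the default model represents them by a linear volumetric exchange
κ·(u_amb − u) in the stack, with κ from the classical conduction shape
factor of a duct buried below a plane surface, S = 2π/acosh(2z_d/d_eq)
(equal-perimeter cylinder, axis depth z_d ≈ 3.6 mm), minus the w/L roof
share that the mesh already resolves. κ ≈ 0.29 s⁻¹ at the defaults. With
this term the steady chamber level is ≈ 0.156 mol/m³; it is switched off
together with PDMS permeation (`side_walls=False` / `pdms_flux=False`).

### Numerics

Conservative finite volumes on a tensor grid (default nx = 120; 6/3/6/12
rows per layer), harmonic-mean interface permeabilities, first-order upwind
advection with the parabolic velocity profile renormalized so the discrete
flow rate is exact, implicit Euler in time. The discrete operator is an
M-matrix, so the scheme is unconditionally stable and positivity-preserving
at the cell Péclet number of ~3. The Michaelis–Menten nonlinearity is
handled by damped Newton (sparse LU per iteration, relative residual
10⁻¹²); the linear wash-in problem reuses one LU for all steps. Steady
chamber means change by ~0.01 % under simultaneous nx and nz doubling, and
the reported depletion/wash-in times by <1 s, so the default grid is
effectively converged; the acceptance computations use nx = 120 and
dt = 2 s. Depletion and uniformity times are linearly interpolated between
steps. The hypoxia threshold is not a measured constant; the default is the
Michaelis constant in concentration units (≈7.7·10⁻³ mol/m³), configurable.

Verification: a dense direct solve with outer fixed-point iteration on the
sink reproduces the Newton solution to <10⁻⁶ on coarse grids; with flow and
uptake off and two Dirichlet faces, the solver matches the piecewise-linear
multi-layer slab solution to machine precision; single-step mass balance
(accumulation vs boundary fluxes minus uptake integral, recomputed
independently from the field) closes to <10⁻⁸.

## 2. Cardiac action-potential metrics

Traces are detrended by a rolling 10th-percentile baseline (2-s window),
peaks found by prominence (40 % of range), and beat windows bounded at
midpoints between successive peaks — the midpoint, unlike the inter-beat
minimum, always contains the full repolarization (an ideal square pulse's
minimum falls exactly on its falling edge). Activation is the maximum
upstroke derivative (50 %-upstroke selectable); the diastolic baseline is
the median of the last tenth of the pre-activation interval, robust to
drift; APDx is measured from activation to the first crossing of
(1 − x/100) of the per-beat amplitude on the repolarizing flank, with
sub-sample linear interpolation (10-ms frame periods would otherwise
quantize APDs). Rate correction is Fridericia's cube-root law with RR in
seconds, so 60 BPM is the identity, and triangulation is
(cAPD80 − cAPD30)/cAPD80. A beat that never repolarizes to the requested
level yields NaN with the row flagged, not an exception; cAPD30 > cAPD80
is rejected as a segmentation failure.

The per-beat RR convention: beat i uses the interval ending at its
activation; the first beat borrows the following interval.

## 3. Hill dose-response fits

`response = floor + (ceiling − floor)/(1 + 10^(slope·(log10 EC50 − log10 d)))`,
fitted in (log10 EC50, floor, ceiling) by bounded least squares with a
deterministic multi-start over the observed log-dose range; the slope is
fixed at 1 by default ("three parameters") and can be freed. Zero doses
cannot enter the log-dose regression and are dropped with a warning; a flat
response returns a no-fit flag rather than a spurious EC50. Standard errors
come from the Gauss–Newton covariance with a delta-method transform for the
EC50. The margin of safety is EC50/ETPC.

## 4. Motion tracking

Exhaustive-search block matching: 8 × 8 blocks, sum of absolute differences
(SSD selectable), square window of radius 7 px by default (the radius and
cost of the original in-house software are unpublished; both are
configurable). Ties are broken toward the smallest displacement magnitude,
then lexicographically — iteration order implements the priority, so the
result is deterministic and the returned cost is the true window minimum by
construction. Blocks are tiled without overlap by default (stride
configurable); blocks with intensity variance below threshold report
missing vectors instead of noise. Blocks near the frame border search a
clipped window; a true shift beyond the radius clamps to the window edge
with elevated cost and is flagged. Beat rate: the mean-speed series is
smoothed over 0.1 s (integer-pixel staircases otherwise alias into spurious
peaks), peaks are picked by prominence, and with two speed peaks per beat
(contraction + relaxation) the inter-beat interval is the median spacing of
peaks one beat apart. The lag default of 5 frames corresponds to 50 ms at
the 100-Hz recordings it was designed for; the frame rate is a parameter,
never hard-coded.

## 5. Liver metabolism kinetics

f(t) = A·(1 − e^(−t/τ))·1/(1 + I/K_i), in percent metabolized. The
saturating exponential was chosen because the 3/6/24-h calibration series
is visibly sub-first-order (no single rate constant passes through
2.66/6.19/9.33 %); the competitive factor reflects ketoconazole's known
mechanism against CYP3A4 — the source data never state a kinetic law, so
the form is swappable. Joint calibration on both arms by bounded least
squares with a deterministic multi-start gives A ≈ 9.9 %, τ ≈ 7.3 h,
K_i ≈ 3.7 µM (inhibition factor ≈ 0.27 at 10 µM, consistent with the
~0.35 relative-clearance observations within ±0.10). A nested-grid SSE
search agrees with the optimizer to <1 % per parameter. The fit does not
pass exactly through the three uninhibited points — no curve of this
family can, since f(6)/f(3) = 2.33 exceeds the form's bound of 2 — and the
residuals are reported. Mass balance of the liver stage
(parent + metabolized = dose) holds by construction.

## 6. Synthetic data

Generators are pure functions of (spec, seed) via one explicit
`numpy.random.Generator`; reruns are byte-identical.

* **AP traces**: half-cosine upstroke (maximum derivative exactly at the
  nominal activation time), flat plateau, then a monotone PCHIP flank
  pinned to the 30/80/90 % crossings — the configured APDs are exact
  properties of the continuous waveform, no root finding. Linear baseline
  drift and additive Gaussian noise on top. Defaults: 30 BPM,
  APD30/80/90 = 200/400/450 ms, 500 Hz sampling.
* **Contraction videos**: a Gaussian-smoothed random texture rigidly
  translated by amp·sin²(πt/period) (integer-rounded per frame; truth
  series returned), giving two speed peaks per cycle half a period apart.
* **Dose-response tables**: Hill means with multiplicative Gaussian noise.
* **Metabolism series**: the kinetic model above ± additive noise.

What these do *not* emulate: photobleaching and shot noise statistics of
real dye recordings, motion artefacts in the voltage channel, non-rigid
tissue deformation, optical PSF/illumination structure, and
electrophysiologically mechanistic AP shapes (no ion-channel ODEs).
Passing recovery tests therefore demonstrates correctness of the metric
definitions and implementations, not robustness to every real-world
artefact.

## 7. The coupling pipeline

Arms: direct (PDMS-corrected dose to the heart), liver (dose passes the
liver stage first), liver+inhibitor (liver stage with 10 µM inhibitor).
Dose correction uses the fixed 64 % absorbed fraction by default, with the
measured percent-remaining table (log-dose interpolated) as the explicit
alternative — the report's provenance block records which was used, and
kinetic parameters have no silent defaults. Each arm's dose maps through a
Hill curve for the vehicle-normalized cAPD90 (floor = 1); the prolongation
flag fires when the predicted increase exceeds 10 % over vehicle. The
model arms carry no biological replicates, so this threshold stands in for
significance; real per-beat metric sets go through a standard two-sample
test (`compare_to_vehicle`). The curve's ceiling is not a published
number; the default 1.35 (~35 % maximal prolongation, typical of strong
hERG-blocking drugs at saturating dose) was fixed once.

**Known limitation.** With the dish-culture calibration above, the
uninhibited 8-h liver stage removes only ~7 % of the dose, so the
liver and liver+inhibitor arms differ by ~1 nM out of ~17 and every
monotone dose-response maps them to nearly identical predictions: the
experimentally observed pattern — prolongation abolished by liver passage
and restored by ketoconazole — is not reproducible from those kinetics.
Reproducing it requires near-complete uninhibited first-pass extraction
(e.g. A ≈ 95 %, τ ≈ 2 h), under which the pipeline does produce the
direct = prolonged / liver = protected / liver+inhibitor = prolonged
ordering (demonstrated in the test suite). The package keeps the
dish-calibrated kinetics as the default and treats the gap as a real
discrepancy between the calibration data and the coupled-system
observation, not something to be tuned away.

## 8. Degenerate inputs and tie-breaks, in one place

Zero flow → hydraulics flagged `no_flow`, residence time ∞. Flat voltage
trace → empty beat list with a warning. Non-repolarizing beat → NaN APD,
flagged. Flat dose-response → no-fit flag. Flat image block → missing
motion vector. Fewer than peaks_per_beat+1 speed peaks → NaN beat rate.
Block-match ties → smallest |d|, then lexicographic. Doses outside the
absorption table → clamped with a warning. Zero-dose rows in a Hill fit →
dropped with a warning.
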