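# Methods

`calsense` simulates, images and analyses calcein-AM (CAM) metabolic
activity sensing in bacterial monolayer microcolonies, end to end: an
agent-based forward model of per-cell CAM kinetics under scripted
perfusion protocols, a synthetic fluorescence time-lapse renderer with
ground-truth masks, watershed segmentation, overlap-based lineage
tracking, kinetic trace analysis and viability phenotyping.  This note
records the model, its assumptions, the numerical choices and what the
synthetic benchmarks do and do not demonstrate.

## The cell model

CAM is a membrane-permeant, non-fluorescent ester.  Inside a cell,
co-factor-independent esterases hydrolyse it to calcein, a fluorescent
polyanion that is retained by intact membranes and actively secreted by
an energy-dependent transporter.  Each cell carries five states: area
`a` (µm²), intracellular CAM amount `C`, calcein amount `F` (both in
AU·µm², so `f = F/a` is the mean single-cell fluorescence in AU), an
energy level `e ∈ [0, 1]`, and an esterase capacity `κ`.

```
C' = uptake − conversion          conversion = k_cat · κ · C
F' = conversion − efflux          efflux     = k_eff_max · ψ · e · F
e' = energy_recovery·(1−e)        (carbon available)
   = −energy_decay·e              (carbon absent, or post-resupply collapse)
```

Uptake is saturable in the extracellular CAM dose `s` through
`σ(s) = [s/(Km+s)] / [s_ref/(Km+s_ref)]` (normalised to 1 at the
reference dose s_ref = 46.3 µM, Km = 5 µM — doses of 46–139 µM differ
by <7 %, i.e. no further signal gain above the reference dose), and
runs through two product-inhibited routes:

```
uptake = a · σ(s) · φ · max(1 − C/(a·c_cap), 0) ·
         [ k_load · 1{carbon} · max(f_eq(a, pH) − f, 0)
         + k_conv · (1 − e)   · max(f_max − f, 0) ]
```

* The **fast loading route** (`k_load = ln2/10.6 ≈ 0.0654 min⁻¹`)
  relaxes the cell toward a feast set-point `f_eq` and is active while
  carbon is present.  It makes freshly seeded cells light up with a
  half-time of ~10.6 min and gives feast-phase cells a stable moderate
  fluorescence.
* The **starvation route** (`k_conv = 0.0025 min⁻¹`) ramps in as the
  energy level falls and relaxes the cell toward a much higher
  saturation `f_max`.  With efflux energy-gated off, this produces the
  slow, near-linear famine-phase accumulation whose apparent
  first-order constant is `k_conv`.

A single-route model cannot produce both observed timescales (minutes
for naive loading, hours for famine accumulation); the two-route form
is the minimal linear structure that does.  The feast set-point scales
mildly with cell size, `f_eq ∝ (a / a_div)^0.3`, representing the
larger esterase complement of bigger cells; this reproduces the
positive correlation between cell area and mean fluorescence seen in
balanced growth (r ≈ 0.6 in simulated feast colonies).  `φ` and `ψ`
are per-cell lognormal factors (CV 0.15, mean 1) on uptake/conversion
and efflux.

Efflux is strictly energy-gated: carbon famine collapses `e` within
minutes (`energy_decay = 0.2 min⁻¹`) and shuts secretion off, while
iron famine (carbon still present) leaves `e ≈ 1` and secretion
running — the discriminating signature of the two starvations in the
extracellular signal.  On carbon re-supply `e` recovers within a few
minutes (`energy_recovery = 0.5 min⁻¹`; ATP pools equilibrate much
faster than growth resumes).

Default calibration: `k_eff_max = 0.005 min⁻¹ = 2 × k_conv`,
`f_eq = 430 AU`, `f_max = 3000 AU`, maximal growth rates
0.97 / 1.02 / 0.78 h⁻¹ at pH 7.0 / 7.4 / 6.6 in BHI and 0.60 h⁻¹ in
CGXII + 4 % glucose.  The conversion step `k_cat = 2 min⁻¹` with pool
ceiling `c_cap = 1000 AU` keeps the internal CAM pool non-limiting, so
the apparent kinetics are governed by the uptake routes.

## Growth, division, death

Area grows exponentially at the phase's maximal rate when both carbon
and iron are available, gated by: a seeding lag (30 min), a re-feeding
lag after famines longer than 2 h (120 min), chamber crowding (growth
halts when summed area exceeds 80 % of the 40 × 40 µm chamber), and
antibiotic arrest.  Division triggers at a noisy critical area
(2.4 µm², CV 10 %); daughters split area and amounts proportionally
with 5 % partition noise (with zero noise the split conserves
everything exactly).  Carbon famine permits occasional reductive
division (0.1 h⁻¹, producing smaller descendants) while iron famine
blocks division entirely.  Lysis is a Poisson hazard (0.005 h⁻¹
baseline); a lysed cell instantly loses its calcein, remains visible in
the phase channel for one final frame, and disappears.

Antibiotic pulses are phenomenological: ampicillin (cell-wall
synthesis) arrests growth for the exposure plus 2 h, raises the lysis
hazard ten-fold and triples division asymmetry; chloramphenicol
(protein synthesis) arrests growth and erodes the conversion capacity
`κ` at 0.01 min⁻¹ during exposure, with recovery after washout.

At the famine-to-feast backshift a fraction of cells (10 %) fails to
resume growth, split evenly into three dormant subtypes: *typical*
(normal efflux), *delayed efflux* (efflux constant × 0.4) and *late
increase* (energetic collapse 3 h after re-supply, which both stops
efflux and re-opens the starvation conversion route, so fluorescence
climbs again).  2 % of founders are esterase-free "dark" cells.  These
fractions are not measured quantities; they exist to give the
phenotype classifier a labelled ground truth.

## Extracellular calcein

Each site is a stirred pool `dC/dt = input − w·C` (exact exponential
update; steady state input/w).  The chamber pool receives the colony's
total efflux into its 1 µm-high volume with a slow diffusive washout
(0.02 min⁻¹, ~35 min residence for a dead-end chamber); the supply
channel integrates the efflux of 400 upstream chambers into its
10 µm-high volume with a flow-driven washout (0.5 min⁻¹ at the
reference 300 nL/min; washouts scale with flow).  Measured signals
scale with fluid height, so the channel reads ~10× its concentration —
which is why the supply channel is brighter than the chamber entrance
(modelled as a 0.5 mixing fraction of the chamber interior).

## Imaging

Cells are rasterised as spherocylinders (width 0.8 µm, length from
area) at 0.065 µm/px; fluorescence pixels are `gain × f + background +
site signal`, blurred with a Gaussian PSF (σ = 1.2 px ≈ 78 nm, typical
for a high-NA objective at violet emission) and corrupted with additive
Gaussian read noise (σ = 5 counts on a 15-count background).  Poisson
shot noise is omitted.  A negative-contrast phase-like channel renders
every physically present cell regardless of calcein load, and the
noiseless label mask is kept as ground truth.  Photobleaching
multiplies every cell's calcein by (1 − 0.0015) per exposed frame
(loss < 0.2 %/frame), logged so that
`uptake = cam + calcein + efflux + bleached` stays exact; applying it
as a post-hoc attenuation is exact for non-secreting cells and a
second-order approximation otherwise.  An optional reporter mode maps
cumulative excitation dose to a phototoxicity (ROS) signal with a
threshold above which growth arrests.

Colony geometry is maintained by a soft-repulsion relaxation of
circle-chain rod approximations (target surface gap 0.15 µm), run
every 2 simulated minutes with per-contact-averaged, step-capped
displacements so that crowded colonies rearrange smoothly
(frame-to-frame displacements stay below ~1 µm, as they must for
overlap tracking to be meaningful).

## Quantification, tracking, phenotyping

Segmentation thresholds the phase channel at half of its robust
cell/background contrast (for a symmetric PSF the half-contrast contour
sits on the true edge), adds bright fluorescence pixels, and splits
touching rods by watershed on the distance transform seeded from its
deep cores (rods share one width, so pixels deeper than ~0.55 × the
half-width form one elongated core per rod).  Regions under 0.5 µm²
are discarded.  On synthetic frames this yields mean IoU ≈ 0.95 and
per-frame count error ≈ 4 %.

Tracking exploits sessility: with masks available, each region claims
the previous-frame region it overlaps most; a region claimed by two
whose areas sum to its own (±30 %) is a division; one-frame dropouts
are bridged in place, and a "division" one frame after a neighbouring
track vanished is re-interpreted as a segmentation merge-flicker and
bridged instead.  Without masks a greedy nearest-centroid fallback
(gate 2 µm/frame) is used.  On ground-truth masks the reconstruction
is exact; through the full segmentation path lineage-edge accuracy and
division precision/recall stay ≥ 0.95 on the benchmark scenes.

Phenotyping assigns each track ≥ 3 frames exactly one label — growing;
non-growing but metabolically active (sustained fluorescence, flagged
if > 1.5 × colony median); non-viable lysed (a ≥ 50 % one-frame drop
to below the detection floor, permanent); non-viable dark (never
fluorescent, never growing) — using only relative thresholds (colony
medians and a noise-based floor of background + 3σ), since absolute AU
are instrument-specific.  Post-resupply subtypes compare each
non-growing cell's efflux fit against the colony median (delayed if
< 0.5 ×) and its late trace against its own post-backshift minimum
(late increase if it climbs back above 1.5 ×).

## Estimators

* **Apparent growth rate** μ_app: least-squares slope of ln(summed
  colony area) over sliding windows of 10 frame intervals (80 min,
  minimal medium) or 6 (48 min, complex medium); exact on noiseless
  exponentials; μ_max is the window maximum.
* **Conversion constant**: traces are first corrected for the
  calibrated photobleaching attenuation (the arrested-cell bleaching
  assay measures exactly this per-exposure loss; over a 12 h famine the
  uncorrected attenuation exceeds 10 % and would bias the fit).  The
  saturation level F∞ is estimated once from the whole famine segment
  by a three-parameter exponential fit, then held fixed in sliding
  50-min window fits of `F∞ − (F∞ − F0)e^(−kt)`; the reported constant
  is the window maximum.  Fixing F∞ is what makes a 50-min window of a
  slow rise identifiable (the window itself is nearly linear).
* **Efflux constant**: per tracked cell, `F_res + (F0 − F_res)e^(−kt)`
  over exactly the first 50 min of re-established feast, excluding the
  frame acquired at the switch timestamp (it still reflects the famine
  state).  Cells below 0.5 × the colony-median constant belong to the
  delayed-efflux phenotype and are reported as such, not averaged into
  the colony's typical secretion constant; the mirrored upper bound
  (2 ×) removes unstable fits.  The colony value is the mean of the
  remaining cells.
* **Loading half-time** t₅₀: a saturating fit `P(1 − e^(−k(t−t0)))`
  with a short free onset lag supplies the plateau; t₅₀ is the raw
  trace's linearly interpolated crossing of P/2.
* **Bleaching per frame**: per-cell log-linear slope across frames of
  growth-arrested, efflux-inhibited cells (growing cells are rejected —
  dilution confounds bleaching), averaged and reported in %/frame.
* **SNR**: mean over detected cells of mean single-cell fluorescence
  divided by the mean cell-proximity background, after discarding
  regions below the detection floor (a lysed husk is segmentable but
  carries no calcein signal).

All nonlinear fits use bounded multi-start least squares (log-spaced
rate starts, tolerances 1e-11).  Degenerate inputs (flat traces) return
k = 0 rather than failing; decreasing famine traces and rising
post-backshift traces emit warnings (efflux not shut off / delayed
efflux) instead of silent numbers.

## Numerical choices

Fixed-step RK4 at dt = 0.1 min on (C, F, ∫uptake, ∫efflux, e); the
cumulative fluxes share the tableau, so the mass-balance identity
holds to rounding at any step size, and the trajectory agrees with an
adaptive reference integrator to < 1e-6 relative.  All randomness
flows from one `numpy` PCG64 generator per colony; identical
(parameters, protocol, seed) reruns are bitwise identical.  Times are
minutes internally; growth rates are reported in h⁻¹.

## Problem sizes

The shipped benchmarks use: 5 famine colonies of 4 founders
(feast 4 h, famine 12 h, feast restored 2 h; 136 frames at 8 min)
through the full simulate→render→segment→track→fit pipeline for the
rate constants; single-founder 5-h BHI colonies for growth rates; 8
naive cells at 2.4-s sampling for 30 min for t₅₀ (trace-level — a
half-time estimate gains nothing from rasterising 750 frames); 85
arrested cells over 100 exposed frames for bleaching; 11 rendered
reference frames for SNR.

## What the synthetic benchmarks show — and what they don't

Passing tests demonstrate that the estimation pipeline is *internally
consistent*: it recovers the constants that generated the data, through
rendering, segmentation and tracking, at realistic noise.  They do not
validate the biological model against real images — no raw imagery is
bundled — and several simplifications matter for transfer to real
data: no Poisson shot noise, no illumination drift or registration
error, perfectly rod-shaped cells of uniform width, instantaneous
medium switching, no spatial nutrient gradients in the chamber, and a
phenomenological (not mechanistic) treatment of CAM transport,
antibiotic action and dormancy fractions.  The segmentation and
tracking parameters are justified only by performance on these
synthetic scenes.
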