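# Methods

This note documents the models implemented in `paintspt`, their assumptions,
the defaults and why, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Synthetic two-channel SPT data (`paintspt.simulate`)

The generator emulates a dual-color TIRF acquisition of membrane proteins on
a supported lipid bilayer or a live-cell membrane:

- **Geometry and motion.** A square field of view (default 70 µm side) with
  reflecting boundaries; reflecting rather than periodic boundaries preserve
  the surface density while mimicking a finite imaged region (the choice is
  recorded in the output metadata). Molecules perform 2D Brownian motion with
  per-frame Gaussian steps of per-axis variance 2·D·dt. Defaults: monomer
  D = 0.093 µm²/s, frame interval dt = 0.08 s (12.5 fps live-cell preset;
  0.04 s for the 25 fps in vitro preset), surface density 0.1 µm⁻² per
  channel.
- **Dimers.** A configurable fraction of molecules is assigned to
  hetero-labeled dimers (one molecule per channel) that move as a single
  unit at D_dimer = (1 − slowdown)·D_mono, default slowdown 0.28. *Static*
  mode keeps the assignment for the whole movie and is the default test
  mode — equilibrium titration analysis only needs equilibrium fractions.
  *Kinetic* mode adds exponential dissociation with a mean lifetime and
  optional proximity re-association (capture radius, default off so that
  measured lifetimes are not confounded by rebinding). The in-dimer label
  separation defaults to 0 µm (point dimer) and is configurable to ~0.05 µm.
- **Label visibility.** DNA-PAINT docking strands carry `n_sites = 9`
  independently bindable imager sites (one per sequence repeat — an upper
  bound, deliberately configurable since the physical simultaneous occupancy
  of a 75-nt strand is not known). Each site is an exact event-driven
  3-state continuous-time Markov chain: empty → fluorescent-bound at
  k_on·c (defaults 2×10⁶ M⁻¹s⁻¹ × 40 nM), fluorescent → empty at k_off
  (0.5 s⁻¹), fluorescent → bleached-bound at k_bleach (0.1 s⁻¹), and
  bleached → empty at k_off (a bleached imager blocks its site until it
  unbinds; the solution reservoir is infinite, matching a 40 nM bulk
  supply). The reported per-frame bound count is the *fluorescent* count,
  which is what step-wise intensity traces measure. Sites start from the
  stationary law by default (imagers pre-equilibrate before acquisition
  starts); an all-empty start is available. A molecule is localizable in a
  frame iff ≥1 fluorescent imager is bound at the frame time. Single-dye
  labels are visible until one exponential bleaching time (default rate
  1/30 s⁻¹, a typical organic-dye survival at SPT excitation powers; the
  rate is a free parameter, not a measured constant).
- **Localization and registration.** Each visible molecule emits exactly one
  localization with isotropic Gaussian noise σ_loc (default 25 nm, a single
  value per channel inside the reported 20–30 nm band; photon-count-dependent
  precision is not modeled). Channel-2 localizations additionally pass
  through `apply_misregistration`: a global affine transform (default
  identity) plus an isotropic residual with per-axis σ = σ_reg/√2, so the
  RMS *radial* registration error equals σ_reg (default 32 nm). Whether the
  quoted 32 nm is per-axis or radial is ambiguous; the package treats it as
  radial RMS by default and exposes `reg_convention="per_axis"` — both
  conventions keep the false-negative rate orders of magnitude below any
  practical concern.
- **Sampling.** Frame f is sampled at t = f·dt for both positions and
  visibility; motion blur within the exposure is not modeled. (Sampling at
  frame starts rather than midpoints makes t = 0 exactly "all dyes visible",
  which is the natural initial condition for survival analysis; the two
  conventions differ only by an immaterial half-frame shift.)
- **Determinism.** All randomness flows from one `numpy` Generator seeded by
  `SimulationConfig.seed` (recorded in output metadata); identical configs
  give bit-identical outputs.

What the generator does **not** emulate: camera noise and PSF rendering,
spot localization itself (its output tables are the input contract),
photon-dependent precision, optical distortion fields (only the residual
registration error), cell-shaped geometries, imager depletion, and
ligand-binding kinetics (equilibrium only). Passing tests therefore validate
the estimators under idealized Gaussian noise and Markovian photophysics,
not the upstream localization software or optics of a real microscope.

## Trajectory linking and filtering (`paintspt.linking`)

Per frame, active track heads are matched one-to-one to new localizations by
minimizing total squared displacement among candidates within `r_max`
(Hungarian algorithm; maximum cardinality first, then minimum cost, with
deterministic tie-breaking). Optimal rather than greedy assignment removes
input-order dependence and is testable against brute-force enumeration.
Unmatched heads stay alive for `memory` frames (default 6, mirroring the
colocalization gap-closing constant) before the track terminates; unmatched
localizations open new tracks. `r_max` defaults to 3·√(4·D_max·dt) with
D_max = 1 µm²/s — three sigma of the expected frame step at the fastest
plausible mobility.

Track filtering rejects tracks with fewer than 10 localizations or a lag-1
diffusion estimate below 0.01 µm²/s (immobile molecules). Track duration is
(last − first + 1) frames: closed gaps count toward duration but not toward
the localization count. The lag-1 estimator used for filtering is biased
upward by σ_loc²/dt, which only makes the immobility filter more permissive.

Survival analysis reports both per-frame alive counts (normalized to the
first frame) and the duration-threshold curve S(T) = fraction of tracks with
duration ≥ T. τ₁/₂ is where the mid-jump empirical survival crosses 0.5,
by linear interpolation (for durations {2,4,6,8} s this gives the median,
5 s); when the crossing sits at the maximum duration the value is flagged as
movie-censored.

## Co-diffusion detection (`paintspt.codiffusion`)

Cross-channel pairing is one-to-one within R = 300 nm, minimizing total
distance — a localization can join at most one pair, so one molecule cannot
be assigned to two dimers (whether published pipelines used one-to-one or
nearest-neighbor-with-reuse pairing is generally unstated; one-to-one is the
conservative choice). Pairs are grouped by the (track-ch1, track-ch2) pair;
gaps ≤ 6 frames are closed; episodes with ≥ 10 colocalized frames are
accepted ("duration exceeded 10 frames" is implemented as n_coloc ≥ 10,
consistent with the track filter rejecting tracks of *less than* 10 frames;
a strict `>` switch exists). Durations in seconds use (end − start + 1)·dt —
closed gap frames count. Events are keyed on track identities: if the
tracker breaks or swaps a track, the event ends and re-pairing starts a new
event; no identity guessing is performed.

Both the median and the mean of interaction durations are reported, since
summaries are quoted either way in the literature. In kinetic-dimer
simulations, detected durations are shortened by the ≥10-frame acceptance
rule and movie censoring, and — because 2D Brownian motion is recurrent —
dissociated partners re-encounter each other and generate additional short
events; the genuine initial-dimer episodes are those starting at frame 0 in
a fully pre-dimerized simulation.

The detected dimer fraction per frame is f(t) = 2·N_pairs(t) / (N_ch1(t) +
N_ch2(t)), counting only colocalized frames of accepted events; the movie
value is the mean over frames with at least one visible track and the
uncertainty the SD over frames.

**False-negative rate.** For a truly co-located pair the per-axis coordinate
difference is Gaussian with variance σ₁² + σ₂² + σ_reg²/2 (radial
convention; σ_reg² in the per-axis convention), so the apparent separation
is Rayleigh (or Rice for a finite in-dimer separation, evaluated with the
Marcum-Q/`scipy.stats.rice` tail) and the miss probability is
exp(−R²/2σ_ax²). Defaults use the worst quoted precision (30 nm).

**Chance co-diffusion.** The false-positive rate is estimated by running the
full pipeline on independent (zero-dimer) simulations. In the static limit
the expected cross-channel pairs per molecule per frame is the Poisson area
fraction πR²ρ (≈ 0.028 at 0.1 µm⁻²). Accepted-event rates decrease with
mobility on the mobile branch (D ≳ 0.01 µm²/s) because faster diffusion
breaks chance colocalization before the 10-frame acceptance threshold; note
the D = 0 case is not the maximum of that curve for long movies — a frozen
geometry caps the event count at the initial overlap, whereas slowly mobile
molecules keep accruing new encounters, each long-lived enough to be
accepted. The immobility filter is disabled inside this estimator so that
the D = 0 analytic limit stays meaningful.

## Diffusion estimation (`paintspt.diffusion`)

Time-averaged MSD per track skips gap frames; the ensemble MSD is the
count-weighted combination. The ensemble D comes from a weighted linear fit
MSD(τ) = 4Dτ + b over lags 1–4 with a free intercept — few enough lags to
avoid the variance blow-up at long lags, with the intercept absorbing the
4σ_loc² noise offset (a negative fitted intercept is possible within noise
and flagged). Per-track D for population comparisons uses the same fit per
track; per-track filtering uses lag-1 without intercept. Population slowdown
is 100·(1 − median/median) with a seeded bootstrap percentile CI; medians
match the box-plot convention for per-track D distributions and are robust
to the heavy right tail of short-track estimates.

## Dimerization equilibrium and titration fitting (`paintspt.dimer_model`)

Model and solution are given in the module docstring and README. Choices
worth recording:

- The ligand reservoir is undepleted (chamber volume ≫ surface amounts).
- The quadratic root is evaluated in the cancellation-free form
  2ρ/(c₁ + √(c₁² + 4aρ)), so mass conservation holds to ~1e−15 relative and
  L = 0 gives exactly f = 0; the saturation ratio L/K_B is clipped at 1e100
  only to keep extreme optimizer trials finite (f is ≈0 long before the clip
  matters).
- β is fixed at 0.5 (equimolar two-color labeling makes half of all dimers
  hetero-colored and thus observable) and ρ_tot is fixed from the measured
  track density; both trade off against K_X if fitted, so fixing them is an
  identifiability decision.
- No statistical symmetry factor is inserted into K_X (it is defined as the
  crosslinking of a ligand-bound monomer with a free monomer), making the
  convention explicit when comparing fitted constants across publications.
- Fitting is weighted least squares in (log₁₀K_B, log₁₀K_X) — positivity by
  construction — with 10 multistarts: one heuristic start (K_B at the
  observed peak concentration, K_X at ρ_tot) plus seeded log-uniform draws
  from K_B ∈ [1e−13, 1e−6] M, K_X ∈ [1e−5, 1e2] µm⁻²; Levenberg–Marquardt
  with tight tolerances; the best converged start is reported. Standard
  errors come from the Gauss–Newton curvature, delta-transformed to the
  linear scale; R² is the weighted coefficient of determination. All-zero
  data raise a non-identifiability error; if no start converges the error
  carries diagnostics.
- `peak_ligand` locates the maximum on a log grid (±6 decades around K_B)
  refined by bounded scalar minimization.

## I/O and pipeline (`paintspt.io`, `paintspt.pipeline`, `paintspt.cli`)

Coordinates are micrometers with origin at the lower-left, frames 0-based,
times in seconds; every file carries a header/metadata block declaring this
plus the configuration echo and seed, which suffices to reproduce any output
bit-identically. CSV is the canonical interchange; HDF5 mirrors it. Pixel
units convert via the effective pixel size 0.108 µm when declared. The
pipeline runs simulate (or load) → link → filter → codiffuse → diffusion →
optional titration fit, aborts with stage-tagged diagnostics, and skips the
fit stage with an explicit reason when no titration data exist or the
configuration contains no dimers.

## Problem sizes used in the validation suite

The test suite and acceptance script run entirely on synthetic data at desk
scale, chosen as the smallest sizes at which the Monte-Carlo error bands are
decisively tighter than the tolerances being checked: diffusion round trips
use 200–500 tracks × 100 frames; survival and lifetime round trips use
80–130 molecules over 120–200 s movies; photophysics laws use single-strand
traces sampled well past the site relaxation time; the false-negative-rate
cross-check draws 10⁷ pairs. The acceptance script reports, for each
quantity, the problem size actually used.

## Known limitations

- The tracker is nearest-assignment with memory, not a motion-model (Kalman)
  or multiple-hypothesis tracker; dense scenes with crossing molecules can
  swap identities, which ends co-diffusion events early (by design, events
  never survive a track break).
- Interaction-duration statistics conflate true dissociation with label
  gaps longer than 6 frames and with tracker breaks; in DNA-PAINT mode long
  dark periods of a docking strand can split long events.
- The equilibrium model ignores doubly-ligand-bound dimers and any
  cooperativity; the antibody case is fitted with the same two-constant
  model rather than a bivalent two-site microscopic model.
- MSD fitting assumes free Brownian motion; anomalous diffusion, confinement
  and state switching are out of scope.
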