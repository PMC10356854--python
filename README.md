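# paintspt

Quantitative analysis of **dual-color DNA-PAINT single-particle tracking
(SPT)** experiments on membrane proteins, for single-molecule biophysicists
who want to measure protein–protein interactions in membranes: detecting
**co-diffusion** of two differently labeled molecules as the operational
readout of dimerization, estimating diffusion coefficients, comparing
label-survival between exchangeable DNA-PAINT imagers and conventional
single dyes, and extracting **2D dissociation constants** from
ligand-titration curves. A synthetic-data simulator generates two-channel
localization tables with the statistical structure the analysis assumes, so
every estimator can be validated by generative round trips.

## The models at the core

**Co-diffusion detection.** Localizations from the two color channels are
paired frame by frame (one-to-one, optimal assignment) when their distance is
below *R* = 300 nm; pair sequences on the same track pair are merged across
gaps of at most *G*max = 6 frames and accepted as true interactions when they
contain at least *N*min = 10 colocalized frames. For a truly co-located pair
the apparent separation *r* is Rayleigh distributed with per-axis variance
σ² = σ₁² + σ₂² + σ²reg-term, so the false-negative rate of the radius
threshold is the analytic tail P(*r* > *R*) = exp(−*R*²/2σ²) — about 10⁻⁷ %
at 30 nm precision and 32 nm registration error, i.e. the threshold
essentially never misses a true dimer.

**Diffusion.** The time-averaged MSD of a 2D Brownian track with static
localization noise is MSD(τ) = 4*D*τ + 4σ²loc; *D* comes from a weighted
line fit over lags 1–4 with a free intercept (the noise offset), while track
filtering (≥10 localizations, *D* ≥ 0.01 µm²/s) uses the quick lag-1
estimator. Dimer slowdown is reported as 100·(1 − median *D*dimer / median
*D*mono) with a bootstrap confidence interval.

**Dimerization equilibrium.** Membrane monomers M bind a bivalent ligand B
from solution (K_B, molar) and a ligand-bound monomer crosslinks a free
monomer into a dimer (K_X, µm⁻²). With total density ρ and undepleted
ligand, the free monomer density solves *a*m² + (1 + L/K_B)m − ρ = 0 with
*a* = 2(L/K_B)/K_X, giving a bell-shaped ("hook effect") dimer fraction
f(L) whose maximum approaches L = K_B in the weak-crosslinking limit.
`DimerTitrationModel.fit()` recovers (K_B, K_X) by weighted least squares in
log space with seeded multistart.

**DNA-PAINT photophysics.** Each docking strand exposes 9 independent imager
sites simulated as an exact 3-state continuous-time Markov chain (empty /
fluorescent / bleached-but-bound); a molecule is localizable whenever at
least one fluorescent imager is bound, which keeps observable counts stable
for minutes, while single dyes bleach irreversibly after an exponential time.

## Worked example

```python
import numpy as np
from paintspt import (SimulationConfig, DyeKinetics, simulate_membrane,
                      link_frames, filter_tracks, pair_localizations,
                      link_codiffusion, PairingParams, dimer_fraction,
                      estimate_D, DimerTitrationModel, DimerModelParams,
                      detected_fraction)

# two-channel movie: 30 x 30 um, 0.1 molecules/um^2 per channel,
# 30% of molecules in hetero-labeled dimers, 150 frames at 12.5 fps
cfg = SimulationConfig(fov_side=30.0, n_frames=150, dt=0.08,
                       density_per_channel=0.1, dimer_fraction=0.3,
                       label_model="single_dye",
                       photophysics=DyeKinetics(k_bleach_dye=0.0), seed=7)
truth, locs1, locs2 = simulate_membrane(cfg)
ts1 = filter_tracks(link_frames(locs1, dt=cfg.dt))
ts2 = filter_tracks(link_frames(locs2, dt=cfg.dt))
pairs = pair_localizations(locs1, locs2, R=0.300)
events = link_codiffusion(pairs, ts1, ts2, PairingParams())
frac = dimer_fraction(events, ts1, ts2)
est = estimate_D(ts1)
print(f"tracks: {ts1.n_tracks} + {ts2.n_tracks}, accepted events: {len(events)}")
print(f"detected dimer fraction: {frac.fraction:.3f} +/- {frac.sd:.3f}")
print(f"ensemble D (ch1): {est.D:.4f} um^2/s, intercept {est.intercept:.5f} um^2")

# titration fit round trip at K_B = 0.85 nM, K_X = 0.026 um^-2
L = np.logspace(-13, -7, 12)
y = detected_fraction(L, DimerModelParams(K_B=0.85e-9, K_X=0.026,
                                          rho_tot=0.1, beta=0.5))
print(DimerTitrationModel(L, y, rho_tot=0.1, beta=0.5).fit(seed=1).summary())
```

prints

```
tracks: 90 + 90, accepted events: 42
detected dimer fraction: 0.305 +/- 0.009
ensemble D (ch1): 0.0849 um^2/s, intercept 0.00198 um^2
Dimerization titration fit (weighted least squares, multistart)
================================================================
  observations: 12
  rho_tot (fixed): 0.1 um^-2    beta (fixed): 0.5
  converged starts: 10/10    R^2 = 1.0000
----------------------------------------------------------------
  K_B = 8.5e-10 M  (+/- 2.7e-25)
  K_X = 0.026 um^-2  (+/- 5.6e-18)
================================================================
```

The detected dimer fraction (0.305) recovers the generative 30% (chance
colocalizations add a small excess); the ensemble *D* estimate sits near the
simulated 0.093 µm²/s with an intercept close to 4σ²loc = 0.0025 µm²; and
the noiseless titration fit returns the generating constants exactly.

A command-line interface mirrors the library
(`paintspt simulate|link|codiffuse|diffusion|fit-titration|run`), each
subcommand a pure function of its inputs, config and seed.

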