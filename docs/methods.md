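# Methods

## Model and assumptions

The WPGAP circuit couples a wave-pinning GTPase module (active `u`,
inactive `v`) to a GAP module (active `G`, inactive `g`).  Activation is
basal (`b`) plus Hill-type self-positive feedback (`γ`, `K`, `n`);
inactivation is basal (`σ`) plus GAP-mediated (`e·G`); GAP activation is
driven by active GTPase (`c·u·g`) and reversed at rate `d`.  All
concentrations are surface densities on the ventral membrane
(molecules/μm²); no synthesis or degradation, so both pool totals are
conserved.  Polarization requires the inactive (cytosolic) species to
diffuse much faster than the membrane-bound active form; the baseline
uses Du = 0.04 μm²/s (single-particle-tracking scale for membrane-bound
Cdc42) and 100×Du for the three cytosolic species.

Baseline kinetics (spot regime): b=1, γ=20, K=200, n=2, σ=10, c=0.05,
d=10, e=10, T=808, Tg=10.  The spatially modulated ("representative")
set: b=2×10⁻³, σ=0.4, d=43.0, e=31.3, with logistic profiles
γ(r): 0.005→9.6 (decay 2.04 μm⁻¹) and c(r): 0.005→0.08 (decay 13 μm⁻¹),
midpoints at the IgG disk edge (r₀, default 2.0 μm).  Hole geometries
negate both decay rates.

## Numerics

Strang splitting: pointwise reaction kinetics by classic RK4 (RK2 in the
documented `fast` mode used for parameter-search evaluations), linear
diffusion by unconditionally stable schemes —

* rectangle (periodic x, no-flux y): exact eigenmode propagator
  exp(−Dk²dt) under an rFFT×DCT-II transform;
* disk (periodic φ, no-flux at r=R): Fourier collocation in φ; per
  angular mode, conservative second-order finite differences in r on a
  cell-centered grid (no node at the origin; the inner face flux vanishes
  identically, which keeps the operator regular at r→0), advanced by
  TR-BDF2.  TR-BDF2 rather than Crank–Nicolson because the near-origin
  modes with eigenvalues ~m²/r² are huge: CN's amplification factor
  approaches −1 there and leaves initialization noise ringing at the
  disk center, while L-stable TR-BDF2 damps it outright.

Both diffusion schemes preserve the area-weighted mean of every field
exactly, and the reaction substep moves mass only between u↔v and G↔g
pointwise, so conservation holds to machine precision (asserted at 10⁻⁵
in tests, observed ~10⁻¹³).  The nonlinearity is evaluated pointwise in
physical space (collocation); no dealiasing is applied — the
grid-refinement checks below stand in for it.

Time step: dt = 0.025 s for the baseline set.  The representative set is
stiffer (d = 43 s⁻¹, d·dt ≈ 1 at 0.025), which distorts noise-driven
spot nucleation: disk-1.75 μm runs give ~6 spots at dt = 0.025 but 8–9
at dt = 0.01, unchanged at dt = 0.005 and across grids 128×64 → 512×256.
All spatially modulated runs therefore default to dt = 0.01.  Spot
counts of *seeded* rosettes are robust to both dt values and to grid
refinement (8 spots at 128×64 and 256×128, dt 0.01 and 0.025); counts
nucleated from noise are the one quantity that is not dt-robust, which
is why the integrator default is the converged value.

Grids: 256×128 (φ×r) is the full-fidelity setting; 128×64 gives
identical spot counts for the 4 μm domain and is the experiment default.
The 7.5 μm domain (5 μm disks) uses 256×160 — radial resolution must
stay ≳ 5 cells per spot diameter or spots artificially merge.
Parameter-search evaluations use 48×48, RK2, t = 15 s, seeded.  At that
coarse angular resolution the seeded pattern settles into a rotationally
symmetric ring rather than discrete spots; a ring is octant-uniform, so
the self-generated reference remains nearly self-consistent (score of
the generating parameters ≈ 0.14) and parameter recovery is well posed.
Rosette discreteness itself is always assessed at full resolution.

Steady states of the well-mixed system integrate the reduced (u, G) ODEs
(v, g eliminated by conservation) from fully inactive pools to t = 1000 s
(LSODA, rtol 10⁻¹⁰); with multistable kinetics the result is the branch
reached from the inactive state, which is the branch the initialization
protocol wants.

## Initialization (synthetic-data protocol)

Fields start at the homogeneous steady state computed with the basal
(far-field) values of any spatially varying rate.  Activation noise
converts δ ~ U(0, f·v_ss) per grid point from v to u — f = 0.2 unseeded,
f = 0.1 seeded — keeping totals exact.  Seeded runs additionally convert
a rosette-shaped field (n = 8 Gaussian bumps, ring at r₀ + 0.2 μm,
peak-normalized, scaled by 0.1·v_ss).  The seed spot width σ = 0.3 μm is
the package's choice: seeds narrower than the emergent 0.31 μm spots
(e.g. σ = 0.15) diffuse below the ignition threshold before the positive
feedback engages, and no seed amplitude printed in the protocol then
ignites.  GAP pools are initialized clean by default (flag to add noise).

The generator emulates the *statistical structure* of the study's inputs
— white per-pixel conversion noise, rosette-shaped seeds, reference
radial profiles — not microscopy: no point-spread function, camera noise
or experimental image fixtures.  Passing tests therefore validate the
model's self-consistency and its printed simulation-derived numbers, not
agreement with raw imaging data.

Seeding convention: disk/hole-size sweeps and timecourses run unseeded
(noise only) — seeding is reserved for parameter-search evaluations,
where it shortens the horizon needed per candidate; this follows the
stated purpose of the seed in the original protocol.

## Quantification

Spots: threshold at (max+min)/2 of the field; polar fields are first
resampled to a uniform 128×128 raster (bilinear in (φ, r), periodic in
φ) so labeling sees no seam; 8-connected components; per-spot moments
give centroid, axes and eccentricity.  Effective radius = mean of the
major/minor *semi*-axis lengths: with that reading the baseline spots'
radius (≈0.31 μm), their area (π·0.31² ≈ 0.30 μm²) and the ~240
molecules per spot implied by the in-spot total GTPase density (~900
molecules/μm²) are mutually consistent.  Spot "concentration" counts
total GTPase u+v — the quantity comparable to particle-based polarity
models, which count all clustered molecules.

Rosette classification (package-defined, config-exposed): ≥3 spots, ≥80%
of centroids within ±0.5 μm of the ring radius, no angular gap ≥120°;
"ring" = one component covering ≥70% of the annulus circumference;
"spots-everywhere" = ≥3 spots with >20% of centroids off-annulus.
Regime labels for sweeps use mask fraction, component count/size and
bounded-complement count; the maze/holes boundary is heuristic and the γ
sweep resolves low → spots → holes → high without a separate maze
plateau.

Score: nine components — RMS discrepancy (per radial bin, 32 bins) of
the angular-mean profile, plus RMS discrepancies of the radial standard
deviation in each of eight octants — averaged into one scalar; the
mean-absolute norm is available as an option.  Octant boundaries are
fixed at angle 0; rotation tolerance is a tested property, so alignment
is unnecessary.

## Parameter search

EA: generational GA, population 100 × 100 generations at full scale
(scaled down in tests), tournament size 3, uniform crossover at rate
0.5, mutation at rate 0.3 as Gaussian steps in log space (rates are
positive scale parameters; additive steps sized to the decade-wide
bounds cannot refine), single-slot elitism.  All candidates within a
generation share one initialization-noise seed (common random numbers).
Bounds default to [0.1×, 10×] the representative values.

DRAM: Gaussian proposals with covariance adapted to the chain history
(sd = 2.4²/dim) every 100 steps, one delayed-rejection stage at 1/5
scale, and the error variance s² of the sum-of-squares likelihood
exp(−SS/2s²) Gibbs-sampled from its conjugate inverse-gamma posterior
(prior S20 = N0 = 0.015, n = 9 residuals).  This makes the chain
self-annealing: s² tracks the current misfit, so the sampler explores
broadly from a mediocre start and tightens as it descends.  Burn-in
defaults to all but the last 5000 steps (scaled runs: stated per run).
Diagnostics: Geweke first-10%-vs-last-50% z-test with spectral (Bartlett)
variance estimates, and split-chain Gelman–Rubin R̂.

## Known limitations

* Noise-driven *ignition thresholds* are shifted relative to the
  reference values the analysis targets: the 3-spot disk threshold sits
  at ≈0.28–0.30 μm (reference 0.24), and the hole-geometry bistable band
  spans ≈1.8–2.8 μm (reference 1.7–2.0) with certain formation only from
  ≈3.0 μm.  These
  boundaries are converged in dt and grid here, and the qualitative
  structure (sharp disk threshold; never/bistable/always hole phases)
  is intact; marginal-ignition radii are the least robust quantities of
  the analysis, sensitive to discretization details of the
  initialization noise.
* The weakest posterior anti-correlation (γ_km vs e) is at the edge of
  resolution for desk-scale chains (hundreds of effective samples).
* 3D geometry, membrane deformation and mechanochemical coupling are out
  of scope, as are experimental-image analysis pipelines.
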