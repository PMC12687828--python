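# Methods

Notation: distances in µm, time in s, forces in pN. D_PP, D_PC, D_CC are
pole-to-pole, pole-to-chromosome and chromosome-to-chromosome distances.
Cell size is the cube root of cell volume.

## 1. Trajectory quantification

**Distances.** Euclidean distances between tracked points are computed in
physical units from voxel indices and anisotropic voxel spacing.

**Sub-pixel peak refinement.** Intensity peaks along a kymograph profile
are refined by least-squares fitting of a Gaussian with offset,
a·exp(−((x−b)/c)²)+d, in a window of ±5 peak widths around the initial
position. A fit is reported non-convergent when the optimizer fails or
the fitted amplitude does not exceed 3 local noise SDs.

**Anaphase onset (AO).** The chromosome-separation series is scanned for
the first frame followed by three consecutive increases; a robust noise
scale is estimated from the pre-rise differences (MAD-based fallback when
the pre-rise segment is short), the rise is required to persist above
3σ, and the onset is refined as the last frame at or below
baseline + 3σ, with the baseline the median of the pre-rise segment. AO
is the time origin of all trajectory fits.

**Trait fits.** Pole separation is fit with the four-parameter sigmoid

    D_PP(t) = L1 + L2 / (1 + exp(−(t − t0)/τ)),

giving final spindle length FL_PP = L1 + L2 (exact identity of the fitted
parameters) and elongation rate ER_PP = 60·L2/(4τ) µm/min, the slope at
the inflection. Chromosome separation for t ≥ AO is fit with

    D_CC(t) = a (1 − e^(−t/k)),

giving final separation a and segregation rate SR_CC = 60·a/k µm/min, the
initial slope. Both fits report convergence flags; initial guesses are
derived from quartiles, range and the discrete derivative of the series.

**Stage averages.** Trajectories of one stage are aligned on AO (t = 0),
binned on the common frame grid and summarized by mean ± SD per bin.

## 2. Scaling statistics

**Stage-level regression.** Fitted traits are averaged per stage and the
stage means regressed on mean cell size by OLS (optionally WLS); the
slope is reported with its 95% confidence interval.

**Size-uncertainty propagation.** For volume V with SD σ_V, the size
uncertainty is σ_V / (3 V^(2/3)) (first-order propagation of the cube
root), accurate to a few percent against Monte-Carlo for CV ≤ 15%.

**Breakpoint fit.** Elongation rate vs size is fit with the continuous
two-segment model y = c + s_low·min(x−b, 0) + s_high·max(x−b, 0). For
each candidate breakpoint b on a grid (midpoints of sorted unique sizes
by default) the remaining parameters are solved in closed form by linear
least squares; the b minimizing the SSE is returned. The two-segment fit
is labelled *distinct* when its SSE is below 0.99 of the single-line SSE.

**Variance components.** Trait variance is decomposed with the balanced
two-level nested random-effects model value = µ + stage + lineage(stage)
+ noise. The default estimator is expected-mean-squares method of
moments: σ̂e = MSE, σ̂L = (MSB − MSE)/n, σ̂S = (MSA − MSB)/(b·n), with
negative estimates truncated at zero and flagged. A REML estimate via a
mixed linear model is available as a cross-check, and bootstrap standard
errors are computed by resampling lineages within stages.

## 3. Perturbation analyses

**Ablation velocimetry.** Distance traces are re-timed with t = 0 at the
cut. Separation velocities are OLS slopes in fixed windows, (−8, 0] s
before (half-open, so the cut frame belongs to "before") and (4, 12) s
after (open), each requiring ≥ 3 samples. Relative displacement curves
subtract each series' value at the last pre-cut frame and average across
cuts on the first series' time grid.

**Microtubule classes.** With the spindle frame defined by the two
centriole positions and the two chromatid-plate centres, a segment whose
endpoints both lie axially strictly between the plate planes is
*mid-spindle*; otherwise a segment with an endpoint within 1.5 µm of a
centriole is *interpolar*; all remaining segments are *other*.
Mid-spindle takes precedence, and the partition is exhaustive, mutually
exclusive and invariant under rigid motions.

## 4. Cortical-pulling model

Two asters at x₁, x₂ inside a spherical cell of radius R. Astral
microtubules nucleate at rate N_T·λ, grow at V_g and undergo catastrophe
at rate λ, giving an exponential length distribution with mean V_g/λ.
Cortical motors (density ρ, capture size r, detachment rate κ, force f0)
bind at most one microtubule each, creating competition between asters.

**Surface field.** The cortex carries per-aster binding probabilities
P_i(Y, t) evolving as dP_i/dt = Ω_i(1 − P1 − P2) − κP_i with impingement
rate

    Ω(d) = N_T λ r² / (4 d²) · exp(−λ d / V_g),

where d is the pole–patch distance. The stationary solution is
P_i* = Ω_i/(κ + Ω1 + Ω2), which always satisfies P1* + P2* < 1.

**Forces and motion.** The pull on pole i is the cortex quadrature
F_i = ρ f0 Σ P_i ξ̂ dA with ξ̂ the unit vector pole → patch. Pole motion
balances drag η and a viscous pole–chromosome coupling ν along the
spindle axis ŝ: η ẋ + ν((ẋ − ċ)·ŝ)ŝ = F, solved in closed form per
component (axial (F∥ + ν ċ∥)/(η + ν), transverse F⊥/η). Chromosome
separation is not mechanistic: the plate-to-plate distance follows the
measured program Δc(t) = 6.2(1 − e^(−t/29)) µm, plates rigidly straddling
the pole midpoint along ŝ; plate velocities enter the force balance by
lagged finite differences (analytic initial rate at the first step).

**Cortex quadrature.** The sphere is discretized with Gauss–Legendre
nodes in cos θ crossed with a uniform azimuthal grid aligned with the
initial spindle axis. The weights sum to 4πR² to machine precision and
the rule is azimuthally symmetric, so on-axis configurations generate no
spurious transverse force (lateral drift < 10⁻⁶·R over a full
simulation); the smooth integrands converge well below 0.1% already at
500 patches.

**Time stepping.** Positions advance by explicit Euler. The surface
field defaults to an exact frozen-rate exponential integrator: over one
step with rates held fixed, the free fraction u = 1 − P1 − P2 relaxes
analytically at rate κ + Ω_T and each P_i follows in closed form. This
scheme is unconditionally stable and preserves 0 ≤ P_i, P1 + P2 ≤ 1
without clipping — necessary because Ω grows large (stiff) as a pole
approaches the cortex. The explicit Euler field update is retained as an
option; it enforces the stability bound dt·(κ + max Ω_T) < 0.5 and
counts any probability clips. At a stable dt the two schemes agree; the
trace is converged to < 10⁻⁶ relative between dt = 0.1 and 0.05 s and
between 500 and 2000 patches.

**Parameters.** Global defaults: N_T = 5000, V_g = 1 µm/s, ρ = 0.12 µm⁻²,
r = 1.5 µm, κ = 1/20 s⁻¹, f0 = 5 pN, η = 450 pN·s/µm, ν = 50 pN·s/µm.
Per-stage geometry and catastrophe rate (stage: R, D_PP(0), λ):
2: 23.0, 13.0, 0.038 · 4: 18.0, 11.2, 0.086 · 8: 14.0, 9.0, 0.164 ·
16: 11.0, 7.5, 0.332 · 32: 9.0, 6.4, 0.615 · 64: 7.3, 5.4, 0.945.

## 5. Catastrophe-rate inference

λ is the sole free parameter; all other parameters stay at their global
defaults. For a candidate λ the stage is simulated, the simulated D_PP
curve is linearly interpolated at the target time points, and the misfit
is ε(λ) = Σ_i (L_i − L_i^sim(λ))². ε is minimized by seeded differential
evolution (strategy best/1/bin, mutation 0.7, crossover 0.9,
population 50, ≤ 15 generations, tolerance 0.01, no polish) over
λ ∈ [0.001, 10] s⁻¹. Inference fidelity is 500 patches, dt = 0.1 s,
300 s horizon, targets sampled at the 10.3 s imaging frame interval.
Self-consistency recovery (simulate at the stage λ, re-infer) returns the
generating rate to ≪ 1% at both the 8- and 64-cell configurations;
the acceptance criterion is 5%.

## 6. Synthetic generators

All generators take explicit seeds and expose their ground truth.
Trajectories superpose Gaussian noise on the closed-form models (the
chromosome trace is exactly zero before AO). Atlases draw per-cell
volumes lognormally (10% CV) around stage means that halve each division
round, set traits linearly in size with Gaussian trait noise, and derive
per-cell trajectory parameters realizing those traits. Kymograph
profiles, ablation series, microtubule sets (with construction-guaranteed
labels) and balanced nested variance tables follow the corresponding
measurement settings.
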