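# Methods note

This note records the surrogate model, the parameter conventions, the
fidelity of the synthetic generators, the numerical choices in the solver
chain, and the known limitations. Energies are in kcal/mol, lengths in Å,
`k_B T` = 0.5962 kcal/mol at 300 K throughout.

## 1. Surrogate surfaces

**Direct transfer (1D).** The proton-transfer coordinate
`D = d_DH − d_AH` moves on

```
U(D) = −A₁ exp(−(D−p₁)²/2w²) − A₂ exp(−(D−p₂)²/2w²) + s·D + c + wall(D)
```

two negative Gaussians (width w = 0.30 Å) on a linear ramp, plus a
quadratic confinement wall (stiffness 200 kcal/mol/Å²) outside ±1.8 Å that
keeps the Markov chain on the domain without affecting the windowed range
(±1.7 Å). The five free parameters (two depths, two centres, ramp slope)
are solved by `scipy.optimize.root` on five analytic residuals: zero
gradient at the prescribed reactant (−1.2 Å) and product (+1.2 Å) positions
and at their midpoint, and the two target energy differences (reaction
energy and barrier height). A post-solve shape check requires exactly three
interior critical points; the additive constant is set so the reactant
minimum is at zero. Targets with `barrier − reaction energy < 0.15` are
rejected (`CalibrationError`): they have no resolvable product valley.

**Water-mediated transfer (2D).** The biased coordinate D1 (donor → water)
drags a freely relaxing coordinate D2 (water → acceptor):

```
U(D1, D2) = g(D1) + ½ κ (D2 − μ(D1))² + wall(D2),   μ(D1) = tanh(D1/0.25)
```

with g a calibrated 1D surface and constant channel stiffness
κ = 100 kcal/mol/Å². With constant κ the marginal free energy along D1
equals g(D1) plus a constant *exactly*, so 2D calibration reduces to the 1D
problem and the 1D oracle remains exact. D1-dependent κ(D1) is supported
only to validate the marginalization quadrature against the closed-form
Gaussian integral `g(D1) + ½ k_B T ln κ(D1)`.

## 2. Sampling protocol

Windows follow the dragging/restart protocol: from the starting restraint
centre (−1.2 Å for an amino-acid acceptor, −1.0 Å for water) the centre
steps by 0.1 Å down to −1.7 Å and, restarting from the initial coordinates,
up to +1.7 Å — 35 windows with k = 150 kcal/mol/Å². The time mapping is
500 Monte-Carlo sweeps per ps of the emulated dynamics: 1 250 sweeps of
drag equilibration per step, then per window 25 000 equilibration and
25 000 production sweeps. Proposals are Gaussian (σ = 0.05 Å, 30–50 %
acceptance in the stiff windows); Metropolis acceptance on the surrogate
energy plus window bias. Equilibrium sampling is all a PMF requires, so no
Langevin integrator or force field is involved.

On the 2D surface the D1 update is *sheared along the channel centre*:
the proposal is `(D1+δ, D2+μ(D1+δ)−μ(D1))`. The map has unit Jacobian and
is an involution under δ → −δ, so the Gaussian proposal stays symmetric and
plain Metropolis acceptance remains exact (the channel deviation
`D2 − μ(D1)` is invariant; a separate unsheared D2 update samples the
channel width). Without the shear, D2 must co-diffuse along the curved
channel and D1 mixing throttles: the seed-to-seed standard deviation of the
recovered 2D reaction energy drops from 0.15 to 0.04 kcal/mol with the
sheared move, with no change in the mean.

The mass-scaled positional restraint `U(x) = p Σ kᵢ mᵢ (xᵢ − x_ref,i)²`
(no ½ factor) with pre-factor p decaying from 1.0 by 0.25 every 10 ps
is implemented and acts during equilibration sweeps only.

All per-window seeds derive from one master seed through
`numpy.random.SeedSequence`; identical seeds give bitwise-identical runs.

## 3. WHAM

The standard self-consistent equations are iterated in log space
(`scipy.special.logsumexp`) to `max|ΔFᵢ| < 10⁻⁷ kcal/mol`, with
`ConvergenceError` (carrying the final residual) past the iteration cap.

Two discretization details matter at this stiffness. First, with
k = 150 kcal/mol/Å² the biased distributions are narrow (σ ≈ 0.06 Å) and
the PMF can change by several k_BT across one 0.05 Å reporting bin, so a
single-bin bias-factor treatment leaves a visible within-bin averaging
bias. The solve therefore runs on internal fine sub-bins (reporting width
/ 10) with bin-centre bias factors, and the value at each reporting-bin
centre is read off a count-weighted local quadratic fit of the converged
fine-bin log-densities over a ±1.5-reporting-bin span — pooling counts
across the span so sparsely populated fine bins do not inject log-count
noise. Second, the reactant minimum (−1.2 Å) falls on a bin *edge*; gauging
the profile on the lowest grid value would shift it by the within-bin rise
of the stiff well (~0.07 kcal/mol), so `PMFProfile.rezeroed()` gauges on
the parabolic vertex through the minimum bin and its neighbours.

The histogram `span` (default ±1.75 Å) is the analysis range: the grid is
bounded by it and samples outside are excluded, the same histogram-bounds
semantics as command-line WHAM tools. Beyond the outermost restraint centre
only confinement-wall tail strays exist; their fine bins hold O(1) counts
on a steep profile and the zero-truncation bias of a log-density fit there
is uncontrolled (observed up to 0.19 kcal/mol before the range was bounded).

The support is the largest contiguous run of occupied reporting bins;
isolated strays are trimmed, and `DisconnectedSupportError` is raised when
more than 1 % of samples fall outside the block or a window has no
in-support samples. Reporting bins outside the support are NaN, never
interpolated. Adjacent-window overlap (shared probability mass) is
available as a diagnostic.

Verified accuracy: on 20 randomly calibrated surfaces with 10⁵ i.i.d.
Boltzmann samples per window (an exact-sampling oracle that shares no code
with the Metropolis chain), the worst |WHAM − analytic| over all reporting
bins with ≥ 100 pooled counts is 0.08 kcal/mol.

## 4. Energetics extraction

The reactant is the D < 0 minimum of the largest finite block of the PMF;
the product is located in three tiers — deepest D > 0 local minimum
("clear"), curvature-sign-change shoulder with |dF/dD| < 0.5 kcal/mol/Å
("shoulder"), or the right endpoint ("endpoint") — because direct-transfer
profiles often lack a product valley. The barrier is the maximum between
them. Extremum energies are refined by a three-point parabola to remove
binning quantization; a profile with no interior maximum yields barrier 0
and a `NoBarrierWarning`. Tables report to 0.1 kcal/mol.

## 5. Synthetic generators and their fidelity

- **Ornstein–Uhlenbeck distances**: exact discretization
  `x_{t+1} = μ + a(x_t − μ) + σ√(1−a²) ε`, started from the stationary law,
  so the stationary mean/SD are exact at every step and the lag-1
  autocorrelation is exactly `a = exp(−1/τ)`. The default relaxation time
  is 2 frames — the largest value consistent with the generator's stated
  single-run bands (mean ±0.01 at n = 10⁴, correlation ±0.03 at n = 5000)
  read as ≳2.5σ containment.
- **Correlated distance/water-count pairs**: a standardized latent OU pair
  with correlation ρ* drives both channels; the count channel is the
  clipped integer rounding of an affine transform. ρ* is found by monotone
  bisection on the *quadrature-computed population* correlation of the
  emitted pair (Gaussian conditioning plus 1D quadrature over the rounding
  transform), so the population correlation matches the target
  deterministically; rounding adds ~1/12 to the count variance, which the
  calibration accounts for.
- **Hydrogen-bond event chains**: two-state Markov chain with geometric
  on-dwell (`q_off = 1/dwell`) and `q_on` fixed by stationarity, started
  from the stationary law; occupancy/dwell combinations implying a rate
  above 1 are rejected as parameter errors. Note that occupancy 0.99 forces
  a mean bonded dwell of at least 99 frames.
- **Boltzmann window oracle**: i.i.d. inverse-CDF draws from
  `exp(−(U + bias)/k_BT)` on a dense grid — an exact sampler, independent
  of the Metropolis code path, used to validate WHAM in isolation.
- **Structure fixtures**: multi-model Cα-only PDB files on a smooth
  synthetic backbone with per-region isotropic jitter (model 0 is the
  unperturbed reference), for testing superposition and per-region RMSD
  with known expectation `RMSD ≈ σ√3`.

## 6. Verification summary

- Calibration round-trips: recovered (reaction energy, barrier) within
  0.05 kcal/mol across the published targets and 15 random ones.
- Full-chain recoveries (fixed seeds): direct path 17.68/18.88 vs
  17.6/18.7; 2D water-mediated reaction energy 15.94 vs 16.0; asymmetric
  low-ΔG path barrier 16.12 vs 16.1.
- Sampler stationarity: total-variation distance to the quadrature
  Boltzmann distribution < 0.02 over 21 states at 10⁶ sweeps.
- Invariances: WHAM output is invariant under window permutation and under
  per-window additive bias offsets (gauge), and the solver residual
  decreases monotonically with iteration budget.

## 7. Limitations

- The surrogate is a caricature: no solvent, no protein degrees of freedom,
  no quantum effects; agreement with the calibration targets validates the
  *statistical* chain, not the chemistry.
- The 2D channel uses constant stiffness so the 1D oracle stays exact;
  strongly D1-dependent channel widths would add a `½k_BT ln κ(D1)` term
  that the calibration does not target (the quadrature oracle handles it,
  the calibrator does not).
- The PMF is only reported over the analysis span (±1.75 Å); the
  confinement-wall region beyond the outermost window is deliberately out
  of scope.
- Monte-Carlo "time" has no dynamical meaning; only equilibrium averages
  (and therefore the PMF) are meaningful.
- Stochastic recovery tests are seed-dependent by nature; tolerances are
  sized so fixed-seed runs sit several standard errors inside the bands,
  but extreme seeds can land outside (≈1–2 % for the tightest correlation
  band).
- The crystal-distance measurement chain is exercised on a synthetic
  stand-in structure with the same atom labelling, since the original
  crystal-structure file is not redistributable with this repository.
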