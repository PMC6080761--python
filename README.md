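# protonpmf

Umbrella-sampling / WHAM free-energy inference on surrogate proton-transfer
landscapes, with the trajectory statistics that accompany such a study.

## What this is

Proton transfer from a retinal Schiff base to a nearby carboxylate — the
photochemical first step in channelrhodopsins such as the C1C2 chimaera — is
usually characterized by a potential of mean force (PMF) along the
proton-transfer coordinate

```
D = d_DH − d_AH        (donor–hydrogen minus acceptor–hydrogen distance, Å)
```

computed by QM/MM umbrella sampling: the system is restrained in a ladder of
harmonic windows `E = ½ k (D − D_ref)²`, each window is sampled at
equilibrium, and the window histograms are stitched into one unbiased PMF by
the weighted histogram analysis method (WHAM). The reaction energy
(product minus reactant free energy) and barrier height are then read off the
profile.

A full QM/MM setup cannot run at desk scale, so this package replaces the
molecular system with **analytic surrogate surfaces whose exact PMF is
known**, and keeps every statistical step of the real pipeline:

- **Surfaces** (`surfaces.py`) — a 1D double-well (direct transfer) and a
  coupled 2D landscape (water-mediated transfer, where the biased coordinate
  drags a freely relaxing second proton). `calibrate_surface` solves for
  surface parameters that reproduce a target (reaction energy, barrier
  height) pair; `analytic_pmf` is the exact oracle, by quadrature
  marginalization in 2D.
- **Sampling** (`sampling.py`, `_kernels.py`) — the window
  dragging/restart protocol (35 windows, `D_ref` from −1.7 to +1.7 Å in
  0.1 Å steps, k = 150 kcal/mol/Å², start at −1.2 Å for an amino-acid
  acceptor or −1.0 Å for water) run with Metropolis Monte-Carlo (numba
  kernels), plus the decaying mass-scaled positional restraint used during
  equilibration.
- **WHAM** (`wham.py`) — log-space self-consistent solve on internal fine
  sub-bins with a count-weighted local quadratic read-out at the 0.05 Å
  reporting resolution, connected-support detection, overlap diagnostics.
- **Energetics** (`energetics.py`) — reactant/intermediate/product state
  assignment with parabolic sub-bin refinement and a three-tier product
  locator (valley / shoulder / endpoint), reported in the study's table
  layout.
- **Trajectory statistics** (`trajectory.py`) — hydrogen-bond occupancies,
  water-count statistics, Pearson correlation with moving-average smoothing,
  distance histograms and percentiles, Kabsch-superposed per-region RMSD,
  and interatomic distance measurements on PDB structures.
- **Synthetic generators** (`synth.py`) — Ornstein–Uhlenbeck distance
  series, correlated distance/water-count pairs with a calibrated population
  correlation, two-state hydrogen-bond event chains, i.i.d. Boltzmann window
  samples (an exact-sampling oracle independent of the Metropolis code), and
  multi-model structure fixtures — all with known ground truth, so every
  estimator is testable.

Because the surfaces are calibrated to published pathway energetics, the
pipeline's acceptance test is concrete: run the full umbrella + WHAM +
extraction chain and recover the calibration targets within stated
tolerances.

## Worked example

Run the full chain on the default configuration (direct transfer, reaction
energy 17.6 kcal/mol, barrier 18.7 kcal/mol; 35 windows × 25 000 production
sweeps):

```python
from protonpmf import run_pathway
from protonpmf.io import default_config_path, load_config

config = load_config(default_config_path())
result = run_pathway(config, seed=1)
en = result.energetics
print(f"windows sampled : {len(result.series)}")
print(f"WHAM iterations : {result.pmf.iterations}")
print(f"reaction energy : {en.reaction_energy:.2f} kcal/mol  (target 17.6)")
print(f"barrier height  : {en.barrier_height:.2f} kcal/mol  (target 18.7)")
print(f"reactant / barrier / product at D = "
      f"{en.reactant_d:+.2f} / {en.barrier_d:+.2f} / {en.product_d:+.2f} Å")
```

Output (about 40 s on one CPU):

```
windows sampled : 35
WHAM iterations : 4259
reaction energy : 17.68 kcal/mol  (target 17.6)
barrier height  : 18.88 kcal/mol  (target 18.7)
reactant / barrier / product at D = -1.20 / -0.06 / +1.17 Å
```

The same run from the command line:

```bash
$ protonpmf run-all --seed 1 --out runs/path1
runs/path1/energetics.tsv

$ cat runs/path1/energetics.tsv
# config_hash=64e93a46f0aa seed=1 version=0.1.0
Path	Proton Transfer	Final Acceptor	Monomer	E162 Protonated	Reaction Energy	Barrier Height
1	direct	E162	1	-	17.7	18.9
```

`runs/path1/` also contains the per-window time series (`windows/`) and the
PMF table (`pmf.tsv`). The stages are available individually —
`simulate`, `wham`, `features`, `analyze`, `synth` — and every CLI result is
byte-identical to the corresponding library call with the same seed and
configuration. Exit codes: 0 success, 2 usage, 3 configuration error,
4 input/format error, 5 numerical failure.

## Reproduction

Recompute the headline quantities from scratch (surface calibration,
umbrella sampling, WHAM, extraction, synthetic-data estimation):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Values obtained with seed 1 (about 12 min on one CPU), against their targets:

| id | quantity | target | tolerance | seed-1 value |
|----|----------|--------|-----------|--------------|
| t2 | Path 1 reaction energy (kcal/mol) | 17.6 | 0.3 | 17.5621 |
| t3 | Path 1 barrier height (kcal/mol) | 18.7 | 0.3 | 18.7012 |
| t4 | Path 5 reaction energy, 2D water-mediated (kcal/mol) | 16.0 | 0.4 | 15.9405 |
| t5 | Path 22 barrier height (kcal/mol) | 16.1 | 0.4 | 16.1240 |
| t6 | Pearson r, correlated pair (n = 5000) | 0.63 | 0.03 | 0.6462 |
| t7 | OU distance mean (Å, n = 10⁴) | 5.1 | 0.02 | 5.1002 |
| t8 | H-bond occupancy (%, n = 5000) | 99 | 1 | 99 |
| t9 | water-count mean (n = 10⁴) | 6.0 | 0.05 | 5.9997 |

The targets are stochastic recoveries, so other seeds give slightly
different values inside the same bands (seeds 7 and 42 were verified as
well).

Run the test suite (about 2 min after the numba kernels are compiled):

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one end-to-end test per acceptance
criterion — window bookkeeping, the three pathway recoveries, WHAM/oracle
equivalence on 20 random surfaces, sampler stationarity in total variation,
statistical recovery over 20 seeds, and the crystal-distance measurement
chain — while the other modules test each component against analytic ground
truth.

## Notes

`docs/methods.md` describes the surrogate model, the numerical choices in
the WHAM solver, the fidelity of the synthetic generators and the known
limitations.
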