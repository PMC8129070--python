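# chromocg

Multiscale coarse-grained chromatin modelling in Python: a chemically
specific residue/base-pair model of nucleosome arrays, a minimal
nucleosome-resolution model, Debye-length Hamiltonian replica-exchange
sampling, umbrella-sampling/WHAM free-energy pipelines, direct-coexistence
phase-behaviour machinery, and the structural observables used to
characterise chromatin ensembles (unwrapped base pairs, contact orientation
classes, valency, sedimentation coefficients, binding time series, ...).

## Model summary

**Chemically specific level.** One bead per amino acid (charge, size and
contact propensity from a packaged, versioned residue table; histone tails
flexible, globular cores held by a 7.5 Å elastic network at
20 kcal/mol/Å²). One oriented rigid body per DNA base pair carrying two
phosphate charge sites; DNA elasticity is harmonic in the six helical
parameters (shift, slide, rise, tilt, roll, twist) with sequence-dependent
step tables. Non-bonded terms: Debye–Hückel screened electrostatics
(energy-shifted at `max(35 Å, 4λ_D)`) and Kim–Hummer-form contact
interactions (which also carry the DNA excluded volume through purely
repulsive entries), with non-bonded interactions omitted between directly
bonded sites. Nucleosomes breathe by default; `apply_non_breathing` ties
the wrapped DNA into the core elastic network.

**Minimal level.** One 12×12×12 Å oriented bead per 5 bp of DNA, one
28×28×20 Å ellipsoid per histone core, 5-bp helical-parameter elasticity
fitted by Gaussian statistics (mean + kT·inverse covariance), and
orientation-modulated nucleosome–nucleosome/nucleosome–DNA wells fitted to
PMF tables. Breathing states are inherited from higher-resolution
snapshots (bound-span rule) or realised geometrically via per-nucleosome
wrap lengths.

**Sampling.** BAOAB Langevin dynamics with rigid-body quaternion rotation
for the DNA bodies, deterministic per seed; Hamiltonian replica exchange
over a ladder of Debye lengths (geometric 8–15 Å, 16 replicas by default)
with the standard Metropolis exchange rule and even/odd neighbour
alternation.

## CLI

```bash
chromocg defaults                          # print the full default config
chromocg build --n-nucleosomes 12 --nrl 165 --output-dir runs
chromocg run --config cfg.yaml             # Langevin run -> HDF5 + XYZ
chromocg remd --config cfg.yaml --n-sweeps 20
chromocg umbrella --config cfg.yaml        # umbrella windows over end-to-end
chromocg wham --windows-dir runs/umbrella  # PMF reconstruction
chromocg minimal-fit --seed 1              # 5-bp helical-parameter fit
chromocg slab --n-arrays 8                 # reduced direct-coexistence run
chromocg analyze --trajectory ... --topology ...
chromocg plot --table runs/wham/pmf.tsv --kind pmf
```

Every subcommand reads a single YAML config (flags override keys), writes
versioned outputs plus a manifest (input hashes, seed, code version), and
seeds every stochastic stage explicitly: same config + same seed gives
byte-identical trajectories and tables.

## Package layout

| module | contents |
| --- | --- |
| `chromocg.model_build` | residue/histone/DNA builders, elastic networks, idealized superhelix nucleosome (radius 41.9 Å, pitch 25.9 Å, left-handed), arrays, non-breathing constraint, miniature fixtures |
| `chromocg.energetics` | Debye length/Debye–Hückel, Kim–Hummer tables, helical-step algebra (mid-frame convention), step stiffness tables, `EnergyModel` energies/forces |
| `chromocg.sampling` | BAOAB Langevin (points + rigid bodies), replica ladders, exchange rule, `run_debye_remd` |
| `chromocg.free_energy` | umbrella windows and biased runs, WHAM, umbrella integration, force–extension, barrier extraction, grossfield-style text IO |
| `chromocg.minimal_model` | 5-bp mapping, Gaussian helical fits, anisotropic-well fitting, minimal energies, pivot Monte Carlo |
| `chromocg.phase_behavior` | slab construction, density profiles, coexistence densities, critical-point fit (β = 0.325 + rectilinear diameters), connectivity, reduced slab MC |
| `chromocg.structure_analysis` | unwrapped-bp counter, nucleosome axes and FF/FS/SS classes, neighbour histograms, valency, per-residue contact fractions, Kirkwood sedimentation, Rg autocorrelation, binding series |
| `chromocg.io` / `chromocg.cli` | topology/trajectory/PDB/FASTA/config formats, manifests, `chromocg` command |

Units: kcal/mol, Å, elementary charges, degrees for helical angles;
k_B T(300 K) = 0.5961 kcal/mol; 1 k_B T/Å = 41.4 pN. Harmonic convention
`E = k (r − r0)²` for bonds and springs; umbrella biases use
`E = ½ k (r − c)²`.
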