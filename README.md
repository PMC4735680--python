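# cgmem

Coarse-grained membrane / ionic-liquid modelling toolkit:

* **Force field & model** (`cgmem.forcefield`) — bead types, a complete
  symmetric Mie pair table (9-6 for pairs without water, 12-4 for pairs with
  water, both normalized so ε is the literal well depth), screened Coulomb
  electrostatics (relative permittivity, default 16), harmonic bonded terms,
  analytic forces and virial, periodic neighbor lists.
* **Toy dynamics** (`cgmem.dynamics`) — velocity-Verlet / BAOAB Langevin
  integrator, semi-isotropic Berendsen barostat (Lx=Ly coupled, Lz
  independent), energy minimizer, checkpointed trajectory driver.
* **PMF estimation** (`cgmem.pmf`) — WHAM reconstruction of 1-D free-energy
  profiles from umbrella windows, bulk anchoring, bootstrap errors, and
  derivative-free refinement of cation–lipid cross-interaction ε scalings by
  matching a computed profile to a reference (PMF matching). Refined
  per-bead-type scalings transfer unchanged to longer-tail cations built
  from the same bead types.
* **Bilayer analysis** (`cgmem.membrane`) — grid-local leaflet assignment,
  inserted-cations-per-lipid time series with plateau (saturation)
  detection, leaflet height-field reconstruction from phosphate beads, 2-D
  undulation spectra `S(q) = L² ⟨|ĥ(q)|²⟩`, and Helfrich bending-modulus
  fits `S(q) = k_B T / (κ q⁴)` with block-averaged errors.
* **Synthetic data** (`cgmem.synth`) — exact Helfrich surface sampler with
  known κ, Metropolis umbrella-window sampler for analytic potentials, and a
  toy bilayer builder with prescribed insertion structure and ground-truth
  labels.
* **IO & CLI** (`cgmem.gro`, `cgmem.tables`, `cgmem.params_io`, `cgmem.cli`)
  — GRO coordinates/trajectories, TSV profiles/spectra/series, CSV+JSON
  surfaces, YAML parameter files, and a `cgmem` command with run manifests.

## CLI

All commands write a `manifest.json` (options, seed, version, input hashes)
next to their outputs.

```bash
cgmem synth-helfrich --kappa-e20 22.6 --frames 500 --out runs/helfrich
cgmem synth-umbrella --centers -2:2:24 --n 2000 --out runs/umbrella
cgmem wham --windows runs/umbrella/windows.tsv --z-grid -2:2:81 --out runs/wham
cgmem match --ref ref_pmf.tsv --base cg_pmf.tsv --out runs/match
cgmem synth-bilayer --lipids 64 --cations 38 --inserted-upper 0.59375 --out runs/sys
cgmem simulate --conf runs/sys/system.gro --params runs/sys/params.yaml \
    --steps 5000 --out runs/sim
cgmem insertions --traj runs/sim/traj.gro --params runs/sys/params.yaml --out runs/ins
cgmem undulation --traj runs/sim/traj.gro --params runs/sys/params.yaml --out runs/und
cgmem report --dirs runs/ins --dirs runs/und --out runs/report.json
```

## Conventions

Units: nm, ps, amu, kJ/mol, e; k_B = 0.0083144621 kJ/mol/K. Coordinates are
wrapped box coordinates with the minimum-image convention; nonbonded
interactions are cut off at 1.5 nm (potential shifted to zero there).
Fourier convention for height fields: `ĥ(q) = fft2(h)/N²`; the q = 0 mode is
excluded and radial bins group modes of exactly equal |q|.
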