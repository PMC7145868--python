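# topplekit

Trajectory-analysis toolkit for studying how the substrate-binding subunit
(S-component) of an energy-coupling factor (ECF) transporter *topples* in
the lipid bilayer. ECF transporters import micronutrients by rotating the
S-component roughly 90° within the membrane; the surrounding bilayer —
its local curvature, thinning and lipid composition — is an active player
in that mechanism. This package provides the computations a simulator
needs to quantify that picture from coarse-grained (or atomistic)
trajectories:

- **Orientation statistics** (`topplekit.orientation`): the tilt angle of
  helix 5 against the bilayer normal, classification of toppled
  (75°–125°, bounds inclusive) vs canonical orientations, and the
  replica-stability statistic — the fraction of replicas that stay
  toppled for more than 50% of their frames, with a binomial standard
  deviation `sqrt(p̂(1−p̂)/n)`.
- **Membrane maps** (`topplekit.membrane`): leaflet assignment from
  phosphate beads, per-leaflet degree-4 polynomial surface fits z(x, y),
  frame-averaged bilayer-thickness maps (z_upper − z_lower) and
  Monge-patch mean-curvature maps
  H = [(1+z_y²)z_xx − 2 z_x z_y z_xy + (1+z_x²)z_yy] / [2(1+z_x²+z_y²)^{3/2}].
- **Lipid fingerprints** (`topplekit.fingerprint`): contact analysis at a
  0.7 nm headgroup cutoff, annular-shell censuses, the
  depletion–enrichment index D–E(L) = ratio(L)_shell / ratio(L)_bulk per
  lipid type, per-residue contact occupancies and binding-site grouping,
  and 2-D headgroup density maps.
- **Free energy** (`topplekit.free_energy`): the dissociation reaction
  coordinate (COM–COM distance between EcfT and the bottom of the
  S-component), umbrella-window validation, WHAM estimation of the 1-D
  potential of mean force, and moving-block bootstrap error bars.
- **Synthetic data** (`topplekit.synthetic`): generators with known ground
  truth for every stage — deformed bilayers with prescribed thickness
  fields, helical bead clouds with exact tilt, two-state Markov tilt
  dynamics, shell-enriched lipid placements, and Boltzmann-sampled
  umbrella windows — so each analysis can be validated end to end without
  multi-microsecond simulations.

The per-stage analyses are scikit-learn-style estimators
(`ToppledStabilityClassifier`, `MembraneMapper`,
`DepletionEnrichmentAnalyzer`, `WhamEstimator`) with `fit` and
trailing-underscore fitted attributes; module-level functions
(`stability_summary`, `thickness_map`, `de_index`, `wham`, …) wrap them.

## Worked example

```python
import numpy as np
import topplekit as tk

# Boltzmann-sample the published umbrella design (51 windows spaced
# 0.1 nm, K = 2500 kJ/mol/nm^2, 303 K) from a known harmonic potential,
# then recover it with WHAM + bootstrap errors.
ws = tk.make_umbrella_samples(tk.PotentialSpec(seed=1))
est = tk.WhamEstimator(n_boot=50, seed=1).fit(ws)
x, F = est.bin_centers_, est.free_energy_
ok = np.isfinite(F) & (np.abs(x) <= 1.0)
ana = 0.5 * 100.0 * x**2
rms = np.sqrt(np.mean(((F - F[ok].min()) - (ana - ana[ok].min()))[ok] ** 2))
print(f"PMF recovered over {ok.sum()} bins, rms error {rms:.2f} kJ/mol")
```

prints

```
PMF recovered over 100 bins, rms error 0.22 kJ/mol
```

i.e. the free-energy profile reconstructed from half a million biased
samples deviates from the generating potential by ~0.2 kJ/mol (well under
0.1 kT) across the central nanometre of the reaction coordinate.

## Command line

One executable with subcommands mirroring the library stages:

```sh
topplekit --config cfg.yaml --seed 7 --out-dir out synth bilayer
topplekit --config cfg.yaml --seed 7 --out-dir out maps \
    --traj out/bilayer.traj --struct out/bilayer.gro --topo out/bilayer_topology.tsv
```

`synth {bilayer,tilt,shell,umbrella}` generate inputs; `orient`, `maps`,
`fingerprint` and `pmf` analyse them. All tabular outputs are TSV with a
commented header naming columns and units.

### Trajectory table dialect

Multi-frame trajectories use a plain whitespace table (binary formats are
out of scope). Grammar:

```
trajectory  := { comment | frame }*
comment     := "#" <any text> NEWLINE
frame       := "FRAME" time_ps box_x box_y box_z NEWLINE row{N}
row         := x y z NEWLINE          # nm, one row per particle,
                                      # template (structure file) order
```

Particle labels come from the template structure (GRO/PDB); particle
count and order must match it in every frame. Selections are given either
as GROMACS-style index files (`[ group ]` with 1-based particle ids) or
as a mini-language (`resid 69-75,127-133`, `resname POPE and name PO4`).
Umbrella windows are two-column `time_ps coordinate_nm` files with a
`# center_nm= ... force_constant_kj_mol_nm2= ...` header, listed by a
manifest TSV.

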