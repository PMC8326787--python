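# pentagate

Quantitative structural analysis of pH-dependent gating in pentameric
ligand-gated ion channels (pLGICs), built around the proton-gated prokaryotic
channel GLIC. Given five-chain coordinate models (PDB) and/or MD trajectory
frame sets (DCD/XTC/TRR + PDB topology), the package measures the standard
observables used to characterise gating:

- **Pore geometry** — the fivefold channel axis (total-least-squares line
  through pore-lining Cα ring centroids), per-residue Cα/Cβ radius profiles
  with M2 prime notation (residue 233 = 9′, i.e. prime = residue − 224), the
  9′ hydrophobic-gate radius, and pore hydration (water count between the 9′
  and 13′ rings).
- **Superposition & RMSD** — Kabsch least-squares fits, model-to-model RMSD
  over configurable selections (ECD 17–192, TMD 196–314, "non-loop" Cα), and
  per-frame trajectory RMSD.
- **Quaternary descriptors** — ECD spread, the radius of gyration of Cα
  20–190 about the channel axis (R_g⊥ = √⟨r⊥²⟩); and domain twist, the
  circular-mean dihedral through the four centres of mass
  (ECDᵢ, ECD, TMD, TMDᵢ) over the five subunits i.
- **Interfacial electrostatics** — Na⁺ coordination of the E35 proton sensor
  (distinct ions within 5 Å of carboxylate oxygens, sampled every 10 ns),
  intrasubunit E243–K248 salt-bridge occupancy (N–O ≤ 4 Å), intersubunit
  E35–T158 Cα distances across all five interfaces, and percentile-bootstrap
  median ± CI summaries over replicates.
- **Loop PCA** — principal components of M2–M3 loop Cα coordinates
  (E243–P250), one observation per subunit in a common subunit frame, with
  trajectory projection and 2-D Gaussian KDE landscapes.

A first-class synthetic-data module generates exact C5 pentamers and mock
trajectories with prescribed spread, twist, ring radii, two-state
(formed/broken) contact dynamics, diffusing cations, and pore/bulk waters —
with the generating values returned as ground truth — so the entire pipeline
is testable with no downloads.

## Worked example

```python
import pentagate as pg

spec = pg.SyntheticSpec(twist_deg=10.0, n_waters_in_pore=12,
                        n_waters_bulk=20, n_ions=6, seed=1)
model = pg.generate_pentamer(spec)
axis = pg.estimate_pore_axis(model)
print(f"gate radius (I233 CB, 9'): {pg.gate_radius(model, axis):.3f} A")
print(f"ECD spread (Ca 20-190):    {pg.ecd_spread(model, axis):.3f} A")
print(f"domain twist:              {pg.domain_twist(model):.3f} deg")
print(f"pore waters (9'-13'):      {pg.water_occupancy(model, axis)}")

tspec = pg.SyntheticSpec(n_frames=2000, contact_k_on=0.14,
                         contact_k_off=0.26, seed=2,
                         n_residues_per_chain=261)
traj, truth = pg.generate_trajectory(tspec)
series = pg.salt_bridge_series(traj)
frac = pg.contact_fraction(series)
stat = pg.bootstrap_median_ci(series.values.mean(axis=0), seed=3)
print(f"E243-K248 contact fraction: {frac:.3f} (stationary 0.350)")
print(f"per-subunit median [95% CI]: {stat.median:.3f} "
      f"[{stat.ci_low:.3f}, {stat.ci_high:.3f}]")
```

prints

```
gate radius (I233 CB, 9'): 2.900 A
ECD spread (Ca 20-190):    25.000 A
domain twist:              10.000 deg
pore waters (9'-13'):      12
E243-K248 contact fraction: 0.358 (stationary 0.350)
per-subunit median [95% CI]: 0.361 [0.330, 0.379]
```

The static observables recover the generating parameters exactly (the model
is a noiseless C5 construction); the contact fraction recovers the two-state
process's stationary probability k_on/(k_on+k_off) = 0.35 to within
sampling error over 2000 frames × 5 subunits.

On real deposits the same calls apply directly, e.g.
`pg.gate_radius(pg.read_pdb("6ZGD.pdb"), axis)` for the closed-state 9′
constriction, or `pg.extract_loop_observations([...five models...])`
followed by `pg.fit_pca` for the loop-conformation landscape.

## Command line

```sh
pentagate synth --out fixture/ --seed 5          # synthetic PDB + DCD + truth
pentagate gate --model fixture/model.pdb          # 9' gate radius
pentagate pore --model fixture/model.pdb          # Ca radius profile CSV
pentagate rmsd --ref a.pdb --mobile b.pdb         # superposed RMSD
pentagate descriptors --traj t.dcd --top m.pdb    # spread/twist series
pentagate contacts --traj t.dcd --top m.pdb --pair 243:248 --cutoff 4.0
pentagate ions --traj t.dcd --top m.pdb --residue 35 --cutoff 5.0
pentagate pca fit --models a.pdb b.pdb c.pdb --loop 243-250
pentagate run --config analysis.yaml              # full pipeline + manifest
```

`pentagate run` consumes a flat YAML config whose defaults encode all
standard constants (selections, 5 Å ion cutoff, 4 Å salt-bridge cutoff,
6 Å hydration radius, last-300 ns window, 10 ns stride, bootstrap settings);
a minimal config lists only input paths. Outputs are deterministic given the
config and seed, and a manifest records the config hash.

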