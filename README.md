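# gpcrkit

Analysis toolkit for 7-transmembrane-receptor (GPCR) molecular-dynamics
trajectories and docked ligand pose ensembles:

- **Trajectory I/O** — multi-MODEL PDB files as trajectories, with a small
  selection language (`chain R and resid 54-80 and name CA`).
- **TM geometry** — per-helix rotation-angle time series against a
  reference frame (rigid-motion invariant, with a swing/twist cross-check
  estimator), Kabsch superposition/RMSD, inter-chain center-of-mass
  distance series, backbone φ/ψ dihedrals and Ramachandran
  favored/allowed/outlier summaries (coarse polygonal region map; not
  identical to MolProbity's contours).
- **Contacts** — hydrogen-bond, hydrophobic and salt-bridge detection from
  residue/atom-name typing with configurable cutoffs (3.5 / 3.9 / 4.0 Å
  defaults), Asp–Arg "arginine cage" presence series and X/blank contact
  time-tables.
- **Clustering** — pairwise-RMSD matrices, GROMOS (greedy neighbor-count)
  conformational clustering with representative frames, and per-ligand
  docking-pose clustering at a 2 Å cutoff.
- **Consensus pharmacophore** — rule-based feature typing (HAc, HDn, Arm,
  Hph, PIn, NIn), deterministic PAM k-medoids (BUILD + SWAP) per feature
  type with silhouette-based k selection, consensus elements with support
  counts and 5 Å receptor-residue annotation, and model-to-model
  comparison.
- **Synthetic fixtures** — ideal helices/bundles, rotation schedules,
  receptor–ligand approach trajectories with planted contacts, and pose
  libraries with planted feature clusters; every generator is
  deterministic under a seed and returns its ground truth.

## CLI

```bash
# generate fixtures with planted ground truth
gpcrkit simulate --preset rotation --seed 1 --out fixtures
gpcrkit simulate --preset approach --seed 1 --out fixtures
gpcrkit simulate --preset poses    --seed 1 --out fixtures

# trajectory workflow: rotation series, arginine cage, contacts,
# COM distances, GROMOS clusters, Ramachandran summary
gpcrkit activation --traj fixtures/approach_fixture.pdb \
    --receptor-chain R --ligand-chain Q --out activation_out

# pose workflow: pose clustering, features, consensus model(s),
# 5 Å residue annotation; repeat --receptor for model comparison
gpcrkit pharmacophore --poses fixtures/pose_library.sdf \
    --receptor fixtures/rotation_fixture.pdb --out pharmacophore_out
```

Both workflows accept `--config run.yaml` for cutoffs, TM segment tables,
strides and thresholds; every effective setting is recorded in
`manifest.json`, and reruns with the same config and seed are
byte-identical.

The default TM segment table (residues 54–80, 90–110, 126–147, 170–189,
213–233, 256–277, 299–321, with optional 148–150 and 234–235 extensions)
ships as `gpcrkit.geometry.cxcr3_segments()` and can be overridden per
run.

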