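# trajscape

Comparative conformational-dynamics analysis of molecular-dynamics
ensembles of membrane receptors (GPCRs in particular), built for the
question: *given the same receptor bound to two different ligands, where
and how does its dynamic behavior differ?*

The package computes four complementary per-ensemble readouts on a shared
analyzed frame set, plus the static structure-comparison measurements used
alongside them:

- **Surface topography** `F_k` — for atom *k*, the time average of the mean
  local contact density over its neighborhood Ω<sub>k</sub>(t) (heavy atoms
  within *d* of *k*):

  `F_k = ⟨ N_Ω⁻¹ Σ_{i∈Ω_k(t)} Σ_{j≠i} A_i exp(−B_i r_ij(t)) ⟩_t`

  High values mark deep, narrow pockets (including transient, cryptic
  ones); low values mark hills and protuberances. Averaged per residue and
  exportable into the B-factor column for surface heatmaps.

- **Local flexibility** `H_K` — the width (population standard deviation
  over frames) of `G_K(t)`, the RMS displacement of the sidechain (or
  backbone) atoms of residue *K*'s environment after an optimal rigid
  superposition of the environment's Cα atoms onto the reference frame.
  Because the superposition is local, `H` isolates genuine local disorder
  from global tumbling and inter-domain motion.

- **Interaction-persistence networks** — per-frame polar contacts (sidechain
  donor/acceptor minimum distance < δ_AD = 3.0 Å) and nonpolar contacts
  (sidechain carbon minimum distance < δ_CC = 4.8 Å), aggregated into
  edges weighted by persistence: the fraction of analyzed frames in which
  the contact exists, a proxy for interaction strength. Distance-only
  ("soft") criteria, no angular terms; ligand halogens count as polar
  partners by default. Includes a salt-bridge report for named Asp/Glu ↔
  Arg/Lys/His pairs.

- **Conformational substates** — a modified DBSCAN on the matrix of
  pairwise superposed Cα-RMSDs: greedily extract the densest ball of
  radius R = 1.2 Å (the centroid is a medoid frame, clusters are spherical
  by construction), keep substates while their density p_i exceeds 5% of
  all sampled frames, and classify the remainder as thermal noise.

- **Structure comparison** — Kabsch superposition RMSD over author-numbered
  atom pairings, inter-structure domain rotation angles (quaternion
  extraction, stable near 0°/180°), ligand contact shells at a distance
  cutoff, and minimum inter-selection distances.

A synthetic-data module generates α-helical bundles and ensembles with
planted ground truth — substate mixtures, per-residue fluctuation
profiles, exact contact occupancies, and rigid domain rotations — so every
estimator is validated by parameter recovery without any external data.

## Worked example

Recover a planted two-substate mixture (weights 0.6/0.4, 5 Å inter-centroid
Cα-RMSD, 0.3 Å within-state jitter, 500 frames):

```python
import numpy as np
import trajscape as ts
from trajscape.model_io import select

st = ts.make_bundle(4, 10, seed=1)                 # 4-helix bundle, 40 residues
mobile = select(st, "resid 1-10 or resid 21-30")   # the region that switches state
truth = ts.SubstateTruth(2, [0.6, 0.4], centroid_displacement=5.0, within_sigma=0.3)
ens, truth = ts.make_substate_ensemble(st, truth, 500, seed=9, mobile=mobile)

mat = ts.pairwise_rmsd(ens, select(st, "calpha"))
part = ts.cluster_substates(mat, ts.ClusterParams(radius=1.2, min_density=0.05))
print("n_substates:", len(part.substates))
for i, s in enumerate(part.substates):
    print(f"substate {i}: centroid frame {s.centroid_frame}, density {s.density:.3f}")
print(f"noise fraction: {part.noise_fraction:.3f}")
print("realized weights:", np.bincount(truth.labels) / 500)
```

prints

```
n_substates: 2
substate 0: centroid frame 0, density 0.598
substate 1: centroid frame 2, density 0.402
noise fraction: 0.000
realized weights: [0.598 0.402]
```

The two recovered densities match the realized state frequencies exactly
(every frame is assigned to the correct state), and nothing falls into
noise because the planted separation (5 Å) dwarfs both the clustering
radius and the within-state jitter.

## Command line

```
trajscape simulate|topography|flexibility|interactions|substates|compare|report
```

`report --config cfg.yaml` runs all four dynamic readouts on one ensemble
and writes CSV/TSV/JSON outputs plus B-factor-encoded PDBs, with every
non-universal default (neighborhood radii, contact kernel parameters,
burn-in) echoed into `report.json` so no result depends on a hidden
choice. Ensembles are read from multi-model PDB files (DCD/XTC work as an
optional adapter when MDAnalysis is installed); analysis covers the frames
after the configurable burn-in fraction (default: the last half).

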