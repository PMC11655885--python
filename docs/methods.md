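# Methods

## Scope and data model

All dynamic metrics consume an `Ensemble`: an ordered set of frames over
one topology, in Å, with author residue numbering preserved verbatim
(structural biology literature addresses residues that way, e.g. S123,
W356, and renumbering would silently break cross-references). Analysis
runs on the frames after a configurable burn-in fraction, default 0.5 —
the convention of analyzing the equilibrated last half of a production
trajectory. Pooling several runs is done by concatenating their analyzed
frames into a single ensemble. All distance criteria everywhere use heavy
atoms only: experimental depositions generally lack hydrogens, and a
heavy-atom convention keeps simulated and experimental inputs comparable.

## Surface topography F

For atom k, frame t: Ω_k(t) is the set of heavy atoms within d of atom k
(membership uses ≤ d; k itself is included by default, controlled by a
flag). Each neighborhood atom i contributes its contact density
Σ_{j≠i over all heavy atoms} A_i·exp(−B_i·r_ij); F_k is the time average
of the neighborhood mean. The exponential kernel is the functional form
used for fast analytic estimates of solvent-accessible surface area; the
per-element parameters (A, B) and the radius d are not universal
constants. Defaults: d = 6.0 Å (commensurate with first-shell heavy-atom
contact distances), uniform A = 1, B = 0.5 Å⁻¹. Uniform parameters
preserve the concavity *ordering*, which is what comparative heatmaps
use; a per-element table can be supplied when calibrated contact-model
parameters are available. Every output embeds a digest of the parameters
used. If a neighborhood is empty in some frame (possible only when
self-inclusion is off), that frame contributes 0 and a warning is logged.

F depends only on pairwise distances, so it is exactly invariant to rigid
motion, and the time average is additive over ensemble concatenation with
frame-count weights — both are tested properties. Whether to restrict F
to surface atoms is left to the caller's selection; the functional itself
is defined for any atom.

## Local flexibility H

The environment Ω_{K,0} of residue K is fixed in the reference frame
(first analyzed frame by default): the sidechain (or backbone) heavy atoms
of all residues having ≥ 1 heavy atom within d (default 6.0 Å) of ≥ 1
heavy atom of K. Glycine contributes its Cα in sidechain mode. Per frame,
the Cα atoms of the environment residues are superposed onto the
reference by a Kabsch fit; H_K is the population (1/N) standard deviation
over frames of G_K(t), the RMS of the per-atom displacements after that
fit. The ddof convention is configurable. An environment of fewer than 3
residues (or 3 Cα) makes the fit ill-posed and raises; the map variant
records such residues as missing with a warning rather than failing.

Two properties define the statistic's meaning and are enforced by tests:
a per-frame global rigid motion is removed exactly (H = 0 on rigid-jitter
ensembles), and H is invariant to frame order (it is a distribution
width, not a time-series statistic). Note that H measures the *joint*
disorder of a residue's environment, not the residue's own amplitude in
isolation; recovering a planted per-residue σ ranking therefore assumes
the profile varies on spatial scales no finer than d. H is computed
nonparametrically; no normality of displacements is assumed or tested.

## Interaction networks

Polar contacts: minimum distance between sidechain donor/acceptor atoms
of two partners strictly < 3.0 Å. Nonpolar contacts: minimum sidechain
carbon–carbon distance strictly < 4.8 Å. Strict inequality is the
documented convention at both cutoffs. Donor/acceptor typing uses a
residue-template table (Ser OG, Thr OG1, Tyr OH, Asn OD1/ND2, Gln
OE1/NE2, Asp OD1/OD2, Glu OE1/OE2, Lys NZ, Arg NE/NH1/NH2, His ND1/NE2,
Trp NE1; Cys SG excluded by default). The `include-backbone` scope adds
backbone N/O to the polar set only — nonpolar contacts remain defined on
sidechain carbons. Ligand and water groups type their N/O atoms (and
halogens F/Cl/Br/I when the flag is on) as polar partners and all their
carbons as nonpolar partners; halogen bonding is deliberately folded into
the generic polar class with no σ-hole geometry. There is no angular term
anywhere: a donor–acceptor pair at 2.9 Å with terrible geometry counts,
by design, and a test asserts exactly that. Persistence is the fraction
of analyzed (post-burn-in) frames with ≥ 1 qualifying atom pair;
`mean_min_distance` averages the per-frame minimum over the frames where
the edge is present. Unknown residue templates produce a warning and skip
the residue, not a crash.

## Conformational substates

The metric is the minimum Cα-RMSD over rigid superpositions between two
frames, on a caller-supplied selection (typically the region of interest
with highly mobile loops excluded — the selection is explicit and never
guessed). Clustering is a modified DBSCAN suited to a precomputed
distance matrix with a spherical-cluster constraint: repeatedly take the
unassigned frame with the most unassigned frames within R (ties broken by
lowest frame index, making the partition deterministic), cut out that
ball as one substate whose centroid is the medoid frame, and stop when
the densest remaining ball's density is ≤ the gate. Defaults R = 1.2 Å
(frames within R of a centroid are structural fluctuation around it) and
gate p_i > 5% of all sampled frames; everything unassigned is thermal
noise. The spherical constraint (every member < R from its centroid),
the partition property (substates + noise cover all frames, densities sum
to 1), descending densities, and permutation equivariance are all tested
invariants. Densities are measured against all sampled frames, including
eventual noise. No kinetics between substates are modeled.

## Structure comparison

Superposition is a least-squares rigid fit (Kabsch via SVD, proper
rotation enforced); the residual is recomputed explicitly from the
transformed coordinates because the closed-form singular-value identity
loses half the significant digits to cancellation near zero RMSD.
Degenerate (coincident/collinear) point sets raise. Cross-structure atom
pairing intersects (chain, residue number, atom name); unmatched atoms
are dropped with a logged count. The domain-rotation angle first aligns
the two structures on the core pairing, then extracts the residual
rotation carrying one domain onto the other; the angle comes from the
quaternion magnitude, stable near 0° and 180°. Ligand contact shells
report each residue with ≥ 1 heavy atom within the cutoff (default 4 Å,
inclusive) of ≥ 1 ligand heavy atom, sorted by minimum distance; minimum
distances resolve exact ties to the lowest index pair.

## Synthetic ensembles and what they do (not) show

The generators emulate the statistical structure of pooled equilibrated
MD ensembles of a helical membrane protein: an idealized α-helical bundle
(rise 1.5 Å, 100°/residue, Cα–Cα ≈ 3.8 Å, one Cβ-like sidechain
pseudo-atom per residue, 0.02 Å seeded jitter so superpositions are never
degenerate) plays the receptor. Study conditions planted by default:

- substate mixtures: two states with weights 0.6/0.4, inter-centroid
  no-fit Cα-RMSD 5 Å over the mobile region, within-state jitter 0.3 Å,
  500 frames — separation ≫ both R and the jitter, as expected for
  well-resolved substates. Centroids are realized as mutually orthogonal
  random per-residue displacement fields: a non-rigid deformation, so an
  optimal superposition cannot absorb it (a rigid translation would be
  removed entirely and the planted states would be invisible to the
  metric). Orthogonality makes every pairwise centroid distance exactly
  the requested value. State labels are drawn from the weights, so
  realized frequencies carry binomial sampling noise (σ ≈ 0.022 at 500
  frames); recovery is judged against the planted weights within a band
  that accommodates it.
- fluctuation profiles: per-residue Gaussian amplitudes in 0.2–1.0 Å,
  500 frames. Frame 0 is emitted as the unperturbed reference
  conformation (the H statistic anchors its environment at t = 0; a noisy
  reference perturbs environment membership and breaks exact σ-scaling of
  H). An optional global rigid jitter (≤ 15°, ≤ 3 Å) exercises the local
  superposition.
- contact occupancies: exact frame counts (round(occupancy × n_frames)
  contact frames in a seeded random order), not Bernoulli draws, so
  persistence assertions are exact.
- domain rotations: exact rigid rotations of a selection about an axis
  through its centroid.

None of this is physical: no force field, membrane, solvent, or
correlated motions, and contacts toggle between exactly two distances.
Passing recovery tests therefore demonstrates estimator correctness —
that each statistic measures what it is defined to measure under its own
generative model — not robustness to force-field artifacts, sampling
error, or conformational heterogeneity beyond the planted kind. Checks
against deposited experimental structures cover the static geometry path
separately and require a one-time download of the coordinate files.

## Numerical choices and problem sizes

Neighborhood membership uses ≤ at the radius; contact criteria use strict
< at their cutoffs (different sources, both documented above). The
trace argument in angle extraction never enters an arccos (quaternions
instead). Pairwise RMSD matrices are computed with a batched SVD over
frames. Tests and the acceptance script run on bundles of 40–140 residues
and ensembles of 100–1000 frames, sizes at which every planted effect is
resolvable in seconds while brute-force oracles (double loops, rotation
grid searches) remain feasible as independent cross-checks.

## Known limitations

- The A/B contact-kernel table ships as a uniform default; absolute F
  values are not calibrated to solvent-accessible surface areas.
- H mixes a residue's own disorder with its environment's; profiles
  varying faster than the environment radius are smoothed (see above).
- Water and lipid partners are supported only as generic hetero groups;
  no lipid-specific typing.
- The substate extractor is greedy; for strongly overlapping balls a
  globally optimal ball cover could differ, though on separated planted
  mixtures the partition is exact.
- Ballesteros–Weinstein generic numbering is not computed; residues are
  addressed by author numbering only.
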