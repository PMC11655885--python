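"""Synthetic structures and ensembles with planted ground truth.

These generators emulate the statistical structure of long MD ensembles of
a helical membrane receptor — a mixture of discrete conformational
substates, per-residue Gaussian fluctuation amplitudes, and on/off
donor–acceptor contact occupancies — without any physics.  Each generator
returns the truth object needed to score the corresponding estimator, and
is bit-reproducible for a fixed integer seed.

Scale conventions follow the target application: an ensemble stands in for
pooled production trajectories (the deposited systems pool six independent
100 ns runs per complex and analyze the equilibrated half), so generated
ensembles carry ``burn_in_fraction = 0`` — they represent frames already
past burn-in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._geometry import rotation_about_axis
from .model_io import Atom, AtomIndexSet, Ensemble, Structure

__all__ = [
    "SubstateTruth",
    "OccupancySchedule",
    "make_bundle",
    "make_substate_ensemble",
    "make_fluctuation_ensemble",
    "make_interaction_ensemble",
    "make_rotated_complex",
]


@dataclass
class SubstateTruth:
    """Planted mixture of discrete conformational substates.

    ``centroid_displacement`` is the (no-fit) Cα-RMSD between any two
    emitted centroids.  It is realized by mutually orthogonal random
    per-residue displacement fields over the mobile selection — a non-rigid
    deformation, so a subsequent optimal superposition cannot absorb it the
    way it would a global translation.  Separability against a clustering
    radius R requires the inter-centroid scale to dominate the within-state
    jitter.
    """

    n_states: int
    weights: Sequence[float]
    centroid_displacement: float = 5.0
    within_sigma: float = 0.3
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.n_states,) or np.any(w < 0):
            raise ValueError("weights must be n_states non-negative fractions")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {w.sum()})")
        self.weights = w


@dataclass
class OccupancySchedule:
    """One planted donor–acceptor contact with a target occupancy.

    In "contact" frames the pair sits at ``contact_distance`` (< 3 Å, i.e.
    inside a polar-contact criterion); otherwise at ``apart_distance``.
    """

    donor_atom: int
    acceptor_atom: int
    occupancy: float
    contact_distance: float = 2.8
    apart_distance: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if not self.contact_distance < 3.0 < self.apart_distance:
            raise ValueError("need contact_distance < 3 Å < apart_distance")


def make_bundle(n_helices: int, residues_per_helix: int, seed: int = 0) -> Structure:
    """An idealized α-helical bundle standing in for a 7TM receptor.

    Helices (rise 1.5 Å, 100° per residue) are arranged on a circle; each
    residue carries backbone N/CA/C/O plus one Cβ-like sidechain
    pseudo-atom (element C).  A small seeded jitter (0.02 Å) breaks exact
    symmetry so superposition problems are never degenerate.
    """
    if n_helices < 1 or residues_per_helix < 4:
        raise ValueError("need n_helices >= 1 and residues_per_helix >= 4")
    rng = np.random.default_rng(seed)
    rise, twist = 1.5, np.radians(100.0)
    r_ca = 2.28  # gives consecutive Cα–Cα ≈ 3.8 Å
    if n_helices == 1:
        centers = np.zeros((1, 2))
    else:
        spacing = 10.0  # Å between neighboring helix axes
        r_bundle = spacing / (2.0 * np.sin(np.pi / n_helices))
        ang = 2.0 * np.pi * np.arange(n_helices) / n_helices
        centers = np.stack([r_bundle * np.cos(ang), r_bundle * np.sin(ang)], axis=1)

    def helix_point(center: np.ndarray, phi: float, radius: float, z: float) -> np.ndarray:
        return np.array([center[0] + radius * np.cos(phi), center[1] + radius * np.sin(phi), z])

    atoms: list[Atom] = []
    serial = 0
    resnum = 0
    for h in range(n_helices):
        c = centers[h]
        for i in range(residues_per_helix):
            resnum += 1
            phi = i * twist
            z = i * rise
            ca = helix_point(c, phi, r_ca, z)
            n = helix_point(c, phi - np.radians(30.0), 1.6, z - 0.6)
            cc = helix_point(c, phi + np.radians(30.0), 1.6, z + 0.6)
            o = helix_point(c, phi + np.radians(35.0), 2.0, z + 1.2)
            # sidechain pseudo-atom points away from the helix axis
            radial = (ca - np.array([c[0], c[1], z]))
            radial /= np.linalg.norm(radial)
            cb = ca + 1.5 * radial
            for name, element, pos in (("N", "N", n), ("CA", "C", ca), ("C", "C", cc),
                                       ("O", "O", o), ("CB", "C", cb)):
                serial += 1
                atoms.append(Atom(serial=serial, name=name, element=element,
                                  residue_name="ALA", residue_number=resnum,
                                  chain_id="A", coordinates=pos + rng.normal(0.0, 0.02, 3)))
    return Structure(atoms)


def _orthogonal_fields(k: int, n_residues: int, rng: np.random.Generator) -> np.ndarray:
    """k per-residue displacement fields (k, n_residues, 3), pairwise
    orthogonal as flat vectors and of equal norm, so any two differ by the
    same Frobenius distance."""
    if k > 3 * n_residues:
        raise ValueError(f"cannot plant {k} states over {n_residues} mobile residues")
    g = rng.normal(size=(k, 3 * n_residues))
    q, _ = np.linalg.qr(g.T)  # columns orthonormal
    return q.T.reshape(k, n_residues, 3)


def make_substate_ensemble(
    structure: Structure,
    truth: SubstateTruth,
    n_frames: int,
    seed: int = 0,
    mobile: AtomIndexSet | None = None,
) -> tuple[Ensemble, SubstateTruth]:
    """Sample frames from a planted mixture of substates.

    Each frame is one centroid (drawn by the truth weights) plus iid
    Gaussian jitter of width ``within_sigma`` on the mobile selection;
    atoms outside the mobile selection are bit-identical across all frames
    and centroids.  Returns the ensemble and a copy of the truth with the
    per-frame labels filled in.

    Centroid construction: every residue of the mobile selection gets one
    rigid displacement vector per state (all its atoms move together), the
    per-state fields are mutually orthogonal with equal norms, and the
    scale is set so that the no-fit Cα-RMSD over the mobile residues
    between any two centroids equals ``centroid_displacement`` exactly.
    Mobile residues must each contain a Cα atom.
    """
    if n_frames < truth.n_states:
        raise ValueError("need n_frames >= n_states")
    rng = np.random.default_rng(seed)
    base = structure.coordinates
    mob = np.arange(structure.n_atoms) if mobile is None else np.asarray(mobile.indices)
    if mob.size == 0:
        raise ValueError("mobile selection is empty")

    mob_res = np.unique(structure.atom_residue_index[mob])
    has_ca = all(
        any(structure.atoms[i].name == "CA" for i in structure.residue_atom_indices(r))
        for r in mob_res
    )
    if not has_ca:
        raise ValueError("every mobile residue needs a Cα atom (displacement scale is a Cα-RMSD)")
    res_pos = {int(r): p for p, r in enumerate(mob_res)}

    centroids = np.repeat(base[None], truth.n_states, axis=0)
    if truth.n_states > 1 and truth.centroid_displacement > 0:
        fields = _orthogonal_fields(truth.n_states, len(mob_res), rng)
        # orthonormal fields differ by Frobenius distance sqrt(2); rescale so
        # the per-residue (= per-Cα) RMS difference equals the requested value
        scale = truth.centroid_displacement * np.sqrt(len(mob_res) / 2.0)
        fields *= scale
        for s in range(truth.n_states):
            for i in mob:
                centroids[s, i] += fields[s, res_pos[int(structure.atom_residue_index[i])]]

    labels = rng.choice(truth.n_states, size=n_frames, p=truth.weights)
    frames = centroids[labels].copy()
    if truth.within_sigma > 0:
        jitter = rng.normal(0.0, truth.within_sigma, size=(n_frames, mob.size, 3))
        frames[:, mob] += jitter
    out = SubstateTruth(truth.n_states, truth.weights.copy(), truth.centroid_displacement,
                        truth.within_sigma, labels=labels)
    out.centroids = centroids  # emitted centroid coordinates, for scoring
    return Ensemble(structure, frames, burn_in_fraction=0.0), out


def make_fluctuation_ensemble(
    structure: Structure,
    sigma_profile: Sequence[float],
    n_frames: int,
    seed: int = 0,
    mode: str = "all",
    rigid_jitter: bool = False,
) -> Ensemble:
    """Frames = structure + per-atom iid Gaussian noise with that residue's σ.

    Frame 0 is the unperturbed reference conformation itself (local
    fluctuation statistics anchor their environment at t = 0, so emitting
    the reference first makes planted-σ recovery well defined); noise is
    applied from frame 1 on.  ``mode="sidechain"`` perturbs only
    non-backbone atoms (backbone stays rigid); ``mode="backbone"`` the
    reverse; ``mode="all"`` perturbs every atom.  ``rigid_jitter``
    additionally applies a random global rigid rotation (up to ~15°) and
    translation (up to ~3 Å) per frame — frame 0 included — to exercise
    superposition steps downstream.
    """
    sigma = np.asarray(sigma_profile, dtype=float)
    if sigma.shape != (structure.n_residues,):
        raise ValueError(f"sigma_profile must have one value per residue ({structure.n_residues})")
    if np.any(sigma < 0):
        raise ValueError("sigma values must be non-negative")
    if mode not in ("all", "sidechain", "backbone"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    base = structure.coordinates
    per_atom_sigma = sigma[structure.atom_residue_index].copy()
    if mode != "all":
        backbone = np.array([a.name in ("N", "CA", "C", "O") for a in structure.atoms])
        keep = ~backbone if mode == "sidechain" else backbone
        per_atom_sigma[~keep] = 0.0
    frames = base[None] + rng.normal(size=(n_frames, structure.n_atoms, 3)) * per_atom_sigma[None, :, None]
    frames[0] = base  # frame 0 is the reference conformation
    if rigid_jitter:
        center = base.mean(axis=0)
        for t in range(n_frames):
            axis = rng.normal(size=3)
            angle = rng.uniform(-15.0, 15.0)
            R = rotation_about_axis(axis, angle)
            shift = rng.uniform(-3.0, 3.0, size=3)
            frames[t] = (frames[t] - center) @ R.T + center + shift
    return Ensemble(structure, frames, burn_in_fraction=0.0)


def make_interaction_ensemble(
    structure: Structure,
    schedule: OccupancySchedule | Sequence[OccupancySchedule],
    n_frames: int,
    seed: int = 0,
) -> Ensemble:
    """Plant on/off donor–acceptor contacts with exact occupancies.

    Exactly ``round(occupancy * n_frames)`` frames (chosen in a seeded
    random order) place the acceptor at ``contact_distance`` from the
    donor; the rest at ``apart_distance``.  Occupancies are thus exact
    frame counts, not Bernoulli draws, so persistence assertions can be
    exact.  Each schedule must move a distinct acceptor atom.
    """
    schedules = [schedule] if isinstance(schedule, OccupancySchedule) else list(schedule)
    acceptors = [s.acceptor_atom for s in schedules]
    if len(set(acceptors)) != len(acceptors):
        raise ValueError("each schedule must have a distinct acceptor atom")
    base = structure.coordinates
    frames = np.repeat(base[None], n_frames, axis=0)
    rng = np.random.default_rng(seed)
    for s in schedules:
        for idx in (s.donor_atom, s.acceptor_atom):
            if not 0 <= idx < structure.n_atoms:
                raise ValueError(f"atom index {idx} out of range [0, {structure.n_atoms})")
        direction = base[s.acceptor_atom] - base[s.donor_atom]
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        n_contact = int(round(s.occupancy * n_frames))
        order = rng.permutation(n_frames)
        contact_frames = order[:n_contact]
        frames[:, s.acceptor_atom] = base[s.donor_atom] + s.apart_distance * direction
        frames[contact_frames, s.acceptor_atom] = base[s.donor_atom] + s.contact_distance * direction
    return Ensemble(structure, frames, burn_in_fraction=0.0)


def make_rotated_complex(
    structure: Structure,
    domain_selection: AtomIndexSet,
    angle: float,
    axis: Sequence[float],
) -> Structure:
    """Rigidly rotate a domain about an axis through the domain centroid.

    Test fixture for domain-rotation measurements (e.g. a fusion domain
    swinging outward relative to the receptor core); all atoms outside the
    domain are unchanged.
    """
    if not 0.0 <= angle <= 180.0:
        raise ValueError("angle must lie in [0, 180] degrees")
    R = rotation_about_axis(np.asarray(axis, dtype=float), angle)
    idx = np.asarray(domain_selection.indices)
    if idx.size == 0:
        raise ValueError("domain selection is empty")
    coords = structure.coordinates.copy()
    center = coords[idx].mean(axis=0)
    coords[idx] = (coords[idx] - center) @ R.T + center
    return structure.with_coordinates(coords)


def truth_to_json(truth: SubstateTruth, path: str) -> None:
    """Write a SubstateTruth (with labels) as a JSON truth file."""
    payload = {
        "n_states": truth.n_states,
        "weights": list(map(float, truth.weights)),
        "centroid_displacement": truth.centroid_displacement,
        "within_sigma": truth.within_sigma,
        "labels": None if truth.labels is None else [int(x) for x in truth.labels],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
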