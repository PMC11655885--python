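"""Conformational substates via density-based clustering on a Cα-RMSD metric.

The metric between two frames is the minimum RMSD over rigid
superpositions of a chosen Cα selection (typically the intracellular
portion of the receptor with the highly mobile third intracellular loop
excluded).  Substates are extracted with a modified DBSCAN suited to a
precomputed distance matrix and a spherical-cluster constraint:

1. for every unassigned frame, count the unassigned frames within the
   radius R of it (the frame itself included);
2. the frame with the largest count becomes the next substate centroid
   (ties go to the lowest frame index), and its R-ball is removed as one
   cluster — clusters are therefore spherical by construction, with the
   centroid a medoid (an actual frame);
3. repeat while the densest remaining ball has density above the gate.

The density p_i of a substate is its member count relative to the total
number of sampled frames.  No minimum density constrains cluster
formation itself; the gate p_i > min_density (default 5%) decides which
balls count as substates, and everything left over is classified as
thermal noise.  The default radius is R = 1.2 Å: frames within R of a
centroid are treated as structural fluctuations around it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._geometry import batched_rmsd_to
from .maps import params_digest
from .model_io import AtomIndexSet, Ensemble

__all__ = ["ClusterParams", "Substate", "SubstatePartition", "pairwise_rmsd", "cluster_substates"]


@dataclass(frozen=True)
class ClusterParams:
    radius: float = 1.2
    min_density: float = 0.05
    stride: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.min_density < 1.0:
            raise ValueError("min_density must lie in [0, 1)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def digest(self) -> str:
        return params_digest(self)


@dataclass(frozen=True)
class Substate:
    centroid_frame: int
    member_frames: np.ndarray
    density: float


@dataclass
class SubstatePartition:
    """Disjoint spherical clusters plus a noise set covering all sampled frames."""

    substates: list[Substate]
    noise_frames: np.ndarray
    n_frames: int
    params_digest: str = ""

    def __post_init__(self) -> None:
        seen: set[int] = set()
        total = 0
        prev = 1.1
        for s in self.substates:
            members = set(int(i) for i in s.member_frames)
            if seen & members:
                raise ValueError("substates are not disjoint")
            if int(s.centroid_frame) not in members:
                raise ValueError("centroid must be a member of its substate")
            seen |= members
            total += len(members)
            if s.density > prev + 1e-12:
                raise ValueError("substates must be sorted by descending density")
            prev = s.density
        if seen & set(int(i) for i in self.noise_frames):
            raise ValueError("noise overlaps a substate")
        total += len(self.noise_frames)
        if total != self.n_frames:
            raise ValueError("substates + noise must cover all sampled frames")

    @property
    def densities(self) -> np.ndarray:
        return np.array([s.density for s in self.substates])

    @property
    def noise_fraction(self) -> float:
        return len(self.noise_frames) / self.n_frames

    def labels(self) -> np.ndarray:
        """Per-frame assignment: substate index, or -1 for noise."""
        out = np.full(self.n_frames, -1, dtype=int)
        for i, s in enumerate(self.substates):
            out[s.member_frames] = i
        return out

    def to_json(self, path: str) -> None:
        payload = {
            "n_frames": self.n_frames,
            "params_digest": self.params_digest,
            "substates": [
                {
                    "centroid_frame": int(s.centroid_frame),
                    "density": s.density,
                    "member_frames": [int(i) for i in s.member_frames],
                }
                for s in self.substates
            ],
            "noise_frames": [int(i) for i in self.noise_frames],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def pairwise_rmsd(
    ensemble: Ensemble, selection: AtomIndexSet, stride: int = 1
) -> np.ndarray:
    """Symmetric matrix of minimum (superposed) RMSDs between analyzed frames.

    Entry (s, t) is the Cα-RMSD after the optimal rigid superposition of
    frame t's selected atoms onto frame s's; frames are the analyzed
    (post-burn-in) set, subsampled by ``stride``.
    """
    idx = np.asarray(selection.indices)
    if idx.size < 3:
        raise ValueError("selection must contain at least 3 atoms")
    coords = ensemble.analyzed_frames[::stride, idx]
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sampled frames")
    mat = np.zeros((n, n))
    for s in range(n - 1):
        mat[s, s + 1:] = batched_rmsd_to(coords[s], coords[s + 1:])
    mat += mat.T
    return mat


def cluster_substates(matrix: np.ndarray, params: ClusterParams | None = None) -> SubstatePartition:
    """Greedy densest-ball extraction on a precomputed distance matrix.

    Deterministic: ties in ball density are broken by the lowest frame
    index, so identical inputs always yield the identical partition.
    """
    params = params or ClusterParams()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(matrix < 0):
        raise ValueError("distances must be non-negative")
    n = matrix.shape[0]
    within = matrix < params.radius  # strict: d < R counts as fluctuation around the centroid
    unassigned = np.ones(n, dtype=bool)
    substates: list[Substate] = []
    while unassigned.any():
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = 0
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        density = counts[centroid] / n
        if density <= params.min_density:
            break
        members = np.flatnonzero(within[centroid] & unassigned)
        substates.append(Substate(centroid_frame=centroid, member_frames=members,
                                  density=float(density)))
        unassigned[members] = False
    noise = np.flatnonzero(unassigned)
    return SubstatePartition(substates, noise_frames=noise, n_frames=n,
                             params_digest=params.digest)
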