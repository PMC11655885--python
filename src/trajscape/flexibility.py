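"""Local flexibility of residues over an ensemble.

For a residue K the statistic H_K is the width of the distribution of
local displacement amplitudes, computed against the residue's own rigid
environment rather than against a global fit, so that H isolates genuinely
local disorder:

1. In the reference frame, collect the environment Ω_{K,0}: the
   mode atoms (sidechain or backbone) of every residue having at least one
   heavy atom within a distance d of at least one heavy atom of K.
2. For each analyzed frame t, rigidly superpose the Cα atoms of the
   environment residues onto the reference frame (Kabsch fit).
3. With that local fit applied, r_i(t) = |R̂ r_i(t) − r_i(0)| for every
   atom i ∈ Ω_{K,0}, and G_K(t) = RMS of the r_i.
4. H_K = standard deviation (population convention) of G_K(t) over the
   analyzed frames.

A rigid global motion of a frame is removed exactly by step 2, so an
ensemble differing from its reference only by rigid motions has H = 0.
The environment is treated as a disordered local neighborhood with random
atomic fluctuations; H is a nonparametric width and assumes nothing about
the displacement distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ._geometry import batched_kabsch
from .maps import ResidueScalarMap, params_digest
from .model_io import BACKBONE_NAMES, AtomIndexSet, Ensemble

__all__ = ["FluctuationParams", "residue_fluctuation", "fluctuation_map"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FluctuationParams:
    environment_radius: float = 6.0
    mode: str = "sidechain"
    reference_frame: int = 0  # index into the analyzed frames
    ddof: int = 0  # population standard deviation by default

    def __post_init__(self) -> None:
        if self.environment_radius <= 0:
            raise ValueError("environment_radius must be positive")
        if self.mode not in ("sidechain", "backbone"):
            raise ValueError(f"mode must be 'sidechain' or 'backbone', got {self.mode!r}")

    @property
    def digest(self) -> str:
        return params_digest(self)


def _mode_atoms(structure, residue_index: int, mode: str) -> np.ndarray:
    """Heavy atoms of one residue in the requested mode; for a residue with
    no sidechain heavy atom (glycine), the Cα stands in."""
    idx = structure.residue_atom_indices(residue_index)
    heavy = structure.heavy_mask
    if mode == "backbone":
        sel = [i for i in idx if heavy[i] and structure.atoms[i].name in BACKBONE_NAMES]
    else:
        sel = [i for i in idx if heavy[i] and structure.atoms[i].name not in BACKBONE_NAMES
               and structure.atoms[i].name != "OXT"]
        if not sel:
            sel = [i for i in idx if structure.atoms[i].name == "CA"]
    return np.array(sel, dtype=int)


def _resolve_residue(structure, K) -> int:
    if isinstance(K, (int, np.integer)):
        if not 0 <= K < structure.n_residues:
            raise ValueError(f"residue index {K} out of range")
        return int(K)
    chain, num = K
    return structure.residue_index(chain, num)


def _environment(ensemble: Ensemble, res_index: int, params: FluctuationParams):
    """(omega_atoms, calpha_atoms, n_contributing_residues) at the reference frame."""
    top = ensemble.topology
    ref = ensemble.analyzed_frames[params.reference_frame]
    heavy = top.heavy_mask
    k_atoms = [i for i in top.residue_atom_indices(res_index) if heavy[i]]
    if not k_atoms:
        raise ValueError(f"residue {top.residue_keys[res_index]} has no heavy atoms")
    heavy_idx = np.flatnonzero(heavy)
    dists = cdist(ref[heavy_idx], ref[k_atoms]).min(axis=1)
    near = heavy_idx[dists <= params.environment_radius]
    residues = np.unique(top.atom_residue_index[near])
    omega = np.concatenate([_mode_atoms(top, r, params.mode) for r in residues]) \
        if residues.size else np.array([], dtype=int)
    calpha = [i for r in residues for i in top.residue_atom_indices(r)
              if top.atoms[i].name == "CA" and heavy[i]]
    return omega, np.array(calpha, dtype=int), residues.size


def residue_fluctuation(ensemble: Ensemble, K, params: FluctuationParams | None = None) -> float:
    """H for one residue; K is a residue index or a (chain_id, resnum) pair.

    Raises if fewer than 3 residues contribute to the environment (the
    local superposition would be ill-posed).
    """
    params = params or FluctuationParams()
    top = ensemble.topology
    res_index = _resolve_residue(top, K)
    frames = ensemble.analyzed_frames
    if len(frames) < 2:
        raise ValueError("fluctuation width is undefined on fewer than 2 analyzed frames")
    if not 0 <= params.reference_frame < len(frames):
        raise ValueError("reference_frame outside the analyzed frames")
    omega, calpha, n_res = _environment(ensemble, res_index, params)
    key = top.residue_keys[res_index]
    if n_res < 3 or len(calpha) < 3:
        raise ValueError(
            f"residue {key}: environment has {n_res} contributing residues "
            f"({len(calpha)} Cα); local superposition is ill-posed"
        )
    if omega.size == 0:
        raise ValueError(f"residue {key}: no {params.mode} atoms in the environment")
    ref = frames[params.reference_frame]
    rot, trans = batched_kabsch(ref[calpha], frames[:, calpha])
    moved = np.einsum("tik,tmk->tmi", rot, frames[:, omega]) + trans[:, None]
    disp2 = np.sum((moved - ref[omega][None]) ** 2, axis=2)
    g = np.sqrt(np.mean(disp2, axis=1))
    return float(np.std(g, ddof=params.ddof))


def fluctuation_map(
    ensemble: Ensemble, selection: AtomIndexSet, params: FluctuationParams | None = None
) -> ResidueScalarMap:
    """H per residue represented in the selection.

    Residues whose environment is ill-posed are recorded as missing with a
    warning rather than aborting the whole map.
    """
    params = params or FluctuationParams()
    idx = np.asarray(selection.indices)
    if idx.size == 0:
        raise ValueError("selection is empty")
    top = ensemble.topology
    entries: dict[tuple[str, int, str], float] = {}
    skipped = []
    for r in np.unique(top.atom_residue_index[idx]):
        key = top.residue_keys[r]
        try:
            entries[key] = residue_fluctuation(ensemble, int(r), params)
        except ValueError as exc:
            skipped.append(key)
            logger.warning("flexibility: skipping residue %s: %s", key, exc)
    if not entries:
        raise ValueError("no residue in the selection yielded a well-posed environment")
    return ResidueScalarMap(entries, metric_name=f"flexibility_{params.mode}",
                            params_digest=params.digest)
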