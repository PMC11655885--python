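"""Static structure–structure measurements.

Optimal superposition RMSD (e.g. receptor Cα of a cryo-EM model onto a
crystal structure), the rotation angle of a domain between two structures
(e.g. a fusion domain swinging outward relative to the receptor core),
ligand contact shells at a distance cutoff, and minimum inter-selection
distances.  All distance criteria use heavy atoms only, since deposited
models generally lack hydrogens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._geometry import apply_rigid, kabsch, rotation_angle_deg
from .model_io import AtomIndexSet, Structure

__all__ = [
    "SuperpositionResult",
    "ContactTable",
    "match_atoms",
    "superpose",
    "domain_rotation",
    "ligand_contacts",
    "min_distance",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # Å
    rmsd: float  # Å, over the matched atoms after the transform
    n_atoms_used: int

    def __post_init__(self) -> None:
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation determinant {det} != +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map mobile-frame coordinates into the reference frame."""
        return apply_rigid(self.rotation, self.translation, coords)


@dataclass
class ContactTable:
    """Residues in contact with a ligand, sorted by ascending distance."""

    rows: pd.DataFrame  # chain, resid, resname, min_distance, atom_a, atom_b
    cutoff: float

    def __post_init__(self) -> None:
        if len(self.rows) and self.rows["min_distance"].max() > self.cutoff:
            raise ValueError("contact table contains a distance beyond the cutoff")

    def __len__(self) -> int:
        return len(self.rows)

    def residues(self) -> list[tuple[str, int, str]]:
        return [(r.chain, r.resid, r.resname) for r in self.rows.itertuples()]

    def to_csv(self, path: str) -> None:
        self.rows.to_csv(path, index=False)


def match_atoms(
    mobile: Structure,
    reference: Structure,
    name: str = "CA",
) -> tuple[AtomIndexSet, AtomIndexSet]:
    """Pair atoms across two structures by (chain, residue number, atom name).

    Unmatched atoms are dropped (their count is logged), so structures with
    different constructs or disordered termini can still be superposed on
    their common core.
    """
    def keyed(st: Structure) -> dict:
        out = {}
        for i, a in enumerate(st.atoms):
            if a.name == name and not a.is_hydrogen:
                out[(a.chain_id, a.residue_number, a.name)] = i
        return out

    ka, kb = keyed(mobile), keyed(reference)
    common = sorted(set(ka) & set(kb))
    dropped = (len(ka) - len(common)) + (len(kb) - len(common))
    if dropped:
        logger.info("match_atoms: dropped %d unmatched %s atoms", dropped, name)
    expr = f"matched name {name}"
    return (AtomIndexSet(np.array([ka[k] for k in common], dtype=int), expr),
            AtomIndexSet(np.array([kb[k] for k in common], dtype=int), expr))


def superpose(
    mobile: Structure,
    reference: Structure,
    mobile_selection: AtomIndexSet,
    reference_selection: AtomIndexSet,
) -> SuperpositionResult:
    """Least-squares rigid superposition over matched atom selections.

    The two index sets must be equal-length and index-matched (use
    :func:`match_atoms` to build them from author numbering).
    """
    ia, ib = np.asarray(mobile_selection.indices), np.asarray(reference_selection.indices)
    if len(ia) != len(ib):
        raise ValueError(f"selections must be matched: {len(ia)} vs {len(ib)} atoms")
    R, t, rmsd = kabsch(mobile.coordinates[ia], reference.coordinates[ib])
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms_used=len(ia))


def domain_rotation(
    struct_a: Structure,
    struct_b: Structure,
    align_pairing: tuple[AtomIndexSet, AtomIndexSet],
    domain_pairing: tuple[AtomIndexSet, AtomIndexSet],
) -> float:
    """Rotation angle (degrees, in [0, 180]) of a domain between two structures.

    Structure b is first superposed onto a over the alignment pairing
    (e.g. all receptor Cα); the residual optimal rotation carrying a's
    domain atoms onto b's (transformed) domain atoms is then extracted and
    its angle returned via a quaternion magnitude, which is stable near 0°
    and 180°.
    """
    sel_a_align, sel_b_align = align_pairing
    sel_a_dom, sel_b_dom = domain_pairing
    fit = superpose(struct_b, struct_a, sel_b_align, sel_a_align)
    b_dom = fit.apply(struct_b.coordinates[np.asarray(sel_b_dom.indices)])
    a_dom = struct_a.coordinates[np.asarray(sel_a_dom.indices)]
    if len(a_dom) != len(b_dom):
        raise ValueError("domain pairings must be matched")
    R, _, _ = kabsch(a_dom, b_dom)
    return rotation_angle_deg(R)


def ligand_contacts(
    structure: Structure,
    ligand_selection: AtomIndexSet,
    cutoff: float = 4.0,
    include_hetero_partners: bool = False,
) -> ContactTable:
    """Residues with any heavy atom within ``cutoff`` of any ligand heavy atom.

    Reports each contact residue once with its minimum distance and the
    closest atom pair.  Waters and other het groups are excluded from the
    contact shell unless ``include_hetero_partners`` is set.
    """
    lig = np.asarray(ligand_selection.indices)
    if lig.size == 0:
        raise ValueError("ligand selection is empty")
    heavy = structure.heavy_mask
    lig = lig[heavy[lig]]
    lig_set = set(int(i) for i in lig)
    rows = []
    for r in range(structure.n_residues):
        idx = [i for i in structure.residue_atom_indices(r)
               if heavy[i] and int(i) not in lig_set]
        if not idx:
            continue
        if not include_hetero_partners and any(structure.atoms[i].is_hetero for i in idx):
            continue
        d = cdist(structure.coordinates[idx], structure.coordinates[lig])
        pos = np.unravel_index(np.argmin(d), d.shape)
        dmin = float(d[pos])
        if dmin <= cutoff:
            chain, resid, resname = structure.residue_keys[r]
            rows.append({
                "chain": chain, "resid": resid, "resname": resname,
                "min_distance": dmin,
                "atom_a": structure.atoms[idx[pos[0]]].name,
                "atom_b": structure.atoms[int(lig[pos[1]])].name,
            })
    df = pd.DataFrame(rows, columns=["chain", "resid", "resname", "min_distance", "atom_a", "atom_b"])
    df = df.sort_values("min_distance", kind="stable").reset_index(drop=True)
    return ContactTable(rows=df, cutoff=cutoff)


def min_distance(
    structure: Structure,
    sel_a: AtomIndexSet,
    sel_b: AtomIndexSet,
) -> tuple[float, tuple[int, int]]:
    """Minimum heavy-atom distance between two disjoint selections.

    Returns the distance and the realizing (atom_index_a, atom_index_b)
    pair; exact ties resolve to the lowest index pair.
    """
    ia, ib = np.asarray(sel_a.indices), np.asarray(sel_b.indices)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both selections must be non-empty")
    if set(map(int, ia)) & set(map(int, ib)):
        raise ValueError("selections overlap")
    heavy = structure.heavy_mask
    ia, ib = ia[heavy[ia]], ib[heavy[ib]]
    if ia.size == 0 or ib.size == 0:
        raise ValueError("a selection contains no heavy atoms")
    d = cdist(structure.coordinates[ia], structure.coordinates[ib])
    pos = np.unravel_index(np.argmin(d), d.shape)  # row-major argmin = lowest index pair on ties
    return float(d[pos]), (int(ia[pos[0]]), int(ib[pos[1]]))
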