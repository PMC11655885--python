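"""Distance-criterion contact detection and persistence networks.

Contacts use deliberately soft, distance-only definitions, the common
choice for trajectory-scale interaction statistics:

* polar (H-bond / salt-bridge): minimum distance between sidechain donor
  or acceptor atoms of the two partners strictly below δ_AD = 3.0 Å;
* nonpolar (hydrophobic / dispersion): minimum distance between sidechain
  carbon atoms strictly below δ_CC = 4.8 Å.

No angular term is applied anywhere — a donor–acceptor pair at 2.9 Å with
poor geometry still counts.  Ligand halogens (F, Cl, Br, I) are included
among polar partners by default, folding potential halogen bonds into the
general polar class without modeling σ-hole geometry.

The persistence of an edge is the fraction of analyzed frames in which at
least one qualifying atom pair exists; the number and persistence of the
contacts between two residues over a trajectory serve as a proxy for the
strength of their interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .maps import params_digest
from .model_io import BACKBONE_NAMES, AtomIndexSet, Ensemble, Structure

__all__ = [
    "InteractionParams",
    "InteractionEdge",
    "InteractionNetwork",
    "frame_contacts",
    "persistence_network",
    "salt_bridge_report",
]

logger = logging.getLogger(__name__)

#: Sidechain H-bond donor/acceptor atom names of the 20 standard residues.
#: Hydrophobic residues have none; Cys SG is excluded by default (weak and
#: frequently disulfide-bonded).
DONOR_ACCEPTOR_TABLE: dict[str, tuple[str, ...]] = {
    "ALA": (), "GLY": (), "VAL": (), "LEU": (), "ILE": (), "PRO": (),
    "PHE": (), "MET": (), "CYS": (),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1", "ND2"), "GLN": ("OE1", "NE2"),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"), "TRP": ("NE1",),
}

HALOGENS = ("F", "CL", "BR", "I")
WATER_NAMES = ("HOH", "WAT", "TIP3", "SOL")


@dataclass(frozen=True)
class InteractionParams:
    polar_cutoff: float = 3.0
    nonpolar_cutoff: float = 4.8
    donor_acceptor_table: tuple = tuple(sorted(DONOR_ACCEPTOR_TABLE.items()))
    treat_halogens_as_polar: bool = True
    scope: str = "sidechain-only"  # or "include-backbone"

    def __post_init__(self) -> None:
        if self.polar_cutoff <= 0 or self.nonpolar_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.scope not in ("sidechain-only", "include-backbone"):
            raise ValueError(f"unknown scope {self.scope!r}")
        table = dict(self.donor_acceptor_table) if not isinstance(self.donor_acceptor_table, dict) \
            else self.donor_acceptor_table
        object.__setattr__(self, "donor_acceptor_table",
                           tuple(sorted((k, tuple(v)) for k, v in table.items())))

    @property
    def table(self) -> dict[str, tuple[str, ...]]:
        return dict(self.donor_acceptor_table)

    @property
    def digest(self) -> str:
        return params_digest(self)


@dataclass(frozen=True)
class InteractionEdge:
    partner_a: tuple[str, int, str]
    partner_b: tuple[str, int, str]
    interaction_class: str  # "polar" | "nonpolar"
    persistence: float
    mean_min_distance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")
        if self.partner_a == self.partner_b:
            raise ValueError("an edge needs two distinct partners")


@dataclass
class InteractionNetwork:
    edges: list[InteractionEdge]
    n_frames_analyzed: int
    params_digest: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            key = (frozenset((e.partner_a, e.partner_b)), e.interaction_class)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "class": e.interaction_class,
                "chain_a": e.partner_a[0], "resid_a": e.partner_a[1], "resname_a": e.partner_a[2],
                "chain_b": e.partner_b[0], "resid_b": e.partner_b[1], "resname_b": e.partner_b[2],
                "persistence": e.persistence,
                "mean_min_distance": e.mean_min_distance,
            }
            for e in self.edges
        ]
        return pd.DataFrame(rows, columns=["class", "chain_a", "resid_a", "resname_a",
                                           "chain_b", "resid_b", "resname_b",
                                           "persistence", "mean_min_distance"])

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        for e in self.edges:
            g.add_edge(e.partner_a, e.partner_b, interaction_class=e.interaction_class,
                       persistence=e.persistence, mean_min_distance=e.mean_min_distance)
        return g


def _polar_atoms(structure: Structure, residue_index: int, params: InteractionParams) -> list[int]:
    """Donor/acceptor atom indices of one residue (or ligand/water group)."""
    idx = structure.residue_atom_indices(residue_index)
    key = structure.residue_keys[residue_index]
    resname = key[2]
    atoms = structure.atoms
    if any(atoms[i].is_hetero for i in idx):
        # ligand / water / ion group: polar partners are N and O atoms,
        # plus halogens when the flag is set
        polar_elements = ("N", "O") + (HALOGENS if params.treat_halogens_as_polar else ())
        return [i for i in idx if atoms[i].element.upper() in polar_elements]
    table = params.table
    if resname not in table:
        logger.warning("interactions: no donor/acceptor template for residue %s; skipped", key)
        return []
    names = set(table[resname])
    out = [i for i in idx if atoms[i].name in names]
    if params.scope == "include-backbone":
        out += [i for i in idx if atoms[i].name in ("N", "O")]
    return out


def _carbon_atoms(structure: Structure, residue_index: int, params: InteractionParams) -> list[int]:
    """Nonpolar-contact carbons: sidechain carbons for protein residues (the
    scope flag widens only the polar donor/acceptor set), all carbons for
    ligand/water groups."""
    idx = structure.residue_atom_indices(residue_index)
    atoms = structure.atoms
    hetero = any(atoms[i].is_hetero for i in idx)
    out = []
    for i in idx:
        if atoms[i].element.upper() != "C":
            continue
        if not hetero and atoms[i].name in BACKBONE_NAMES:
            continue
        out.append(i)
    return out


def _residue_pairs(structure: Structure, group_a: AtomIndexSet, group_b: AtomIndexSet):
    ra = np.unique(structure.atom_residue_index[np.asarray(group_a.indices)])
    rb = np.unique(structure.atom_residue_index[np.asarray(group_b.indices)])
    pairs = set()
    for a in ra:
        for b in rb:
            if a != b:
                pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


def _pair_min_distances(coords_frames: np.ndarray, ia: list[int], ib: list[int]) -> np.ndarray:
    """Per-frame minimum distance between two atom groups; +inf if either empty."""
    if not ia or not ib:
        return np.full(coords_frames.shape[0], np.inf)
    a = coords_frames[:, ia]
    b = coords_frames[:, ib]
    diff = a[:, :, None, :] - b[:, None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1)).min(axis=(1, 2))


def frame_contacts(
    ensemble: Ensemble,
    t: int,
    group_a: AtomIndexSet,
    group_b: AtomIndexSet,
    params: InteractionParams | None = None,
) -> list[tuple]:
    """Contacts present in one frame.

    Returns ``(key_a, key_b, interaction_class, min_distance)`` tuples, one
    per residue pair and class whose criterion is met (strict inequality at
    the cutoff).
    """
    params = params or InteractionParams()
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("contact groups must be non-empty")
    st = ensemble.topology
    frame = ensemble.frames[t][None]
    out = []
    for a, b in _residue_pairs(st, group_a, group_b):
        ka, kb = st.residue_keys[a], st.residue_keys[b]
        d_pol = _pair_min_distances(frame, _polar_atoms(st, a, params), _polar_atoms(st, b, params))[0]
        if d_pol < params.polar_cutoff:
            out.append((ka, kb, "polar", float(d_pol)))
        d_np = _pair_min_distances(frame, _carbon_atoms(st, a, params), _carbon_atoms(st, b, params))[0]
        if d_np < params.nonpolar_cutoff:
            out.append((ka, kb, "nonpolar", float(d_np)))
    return out


def persistence_network(
    ensemble: Ensemble,
    group_pairs: list[tuple[AtomIndexSet, AtomIndexSet]],
    params: InteractionParams | None = None,
) -> InteractionNetwork:
    """Aggregate per-frame contacts into a persistence-weighted network.

    Covers receptor–receptor, receptor–ligand, and ligand–water pairs alike:
    a group is any atom selection, partitioned into residues/het groups.
    Persistence is computed over the analyzed (post-burn-in) frames;
    ``mean_min_distance`` averages the per-frame minimum distance over the
    frames in which the edge is present.
    """
    params = params or InteractionParams()
    frames = ensemble.analyzed_frames
    if frames.shape[0] == 0:
        raise ValueError("no analyzed frames")
    st = ensemble.topology
    edges: dict[tuple, tuple[int, float]] = {}
    seen_pairs = set()
    for group_a, group_b in group_pairs:
        if len(group_a) == 0 or len(group_b) == 0:
            raise ValueError("contact groups must be non-empty")
        for a, b in _residue_pairs(st, group_a, group_b):
            if (a, b) in seen_pairs:
                continue
            seen_pairs.add((a, b))
            ka, kb = st.residue_keys[a], st.residue_keys[b]
            for cls, atoms_fn, cutoff in (
                ("polar", _polar_atoms, params.polar_cutoff),
                ("nonpolar", _carbon_atoms, params.nonpolar_cutoff),
            ):
                dmin = _pair_min_distances(frames, atoms_fn(st, a, params), atoms_fn(st, b, params))
                hit = dmin < cutoff
                n_hit = int(hit.sum())
                if n_hit:
                    edges[(ka, kb, cls)] = (n_hit, float(dmin[hit].mean()))
    n = frames.shape[0]
    edge_list = [
        InteractionEdge(ka, kb, cls, persistence=n_hit / n, mean_min_distance=mmd)
        for (ka, kb, cls), (n_hit, mmd) in edges.items()
    ]
    return InteractionNetwork(edge_list, n_frames_analyzed=n, params_digest=params.digest)


ACIDIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}


def salt_bridge_report(
    ensemble: Ensemble,
    pairs: list[tuple[tuple[str, int], tuple[str, int]]],
    params: InteractionParams | None = None,
) -> pd.DataFrame:
    """Persistence of named salt bridges (Asp/Glu carboxylate O vs
    Arg/Lys/His sidechain N, same δ_AD criterion).

    ``pairs`` is a list of ((chain, resnum), (chain, resnum)); each pair
    must consist of one acidic and one basic residue.  Pairs that never
    qualify are still reported with persistence 0.
    """
    params = params or InteractionParams()
    st = ensemble.topology
    frames = ensemble.analyzed_frames
    missing = []
    resolved = []
    for pa, pb in pairs:
        try:
            resolved.append((st.residue_index(*pa), st.residue_index(*pb)))
        except KeyError:
            missing.append((pa, pb))
    if missing:
        raise ValueError(f"salt-bridge residues not found: {missing}")
    rows = []
    for ra, rb in resolved:
        ka, kb = st.residue_keys[ra], st.residue_keys[rb]
        if ka[2] in ACIDIC and kb[2] in BASIC:
            acid, base = (ra, ka), (rb, kb)
        elif kb[2] in ACIDIC and ka[2] in BASIC:
            acid, base = (rb, kb), (ra, ka)
        else:
            raise ValueError(f"pair {ka}–{kb} is not an acidic/basic combination")
        o_atoms = [i for i in st.residue_atom_indices(acid[0])
                   if st.atoms[i].name in ACIDIC[acid[1][2]]]
        n_atoms = [i for i in st.residue_atom_indices(base[0])
                   if st.atoms[i].name in BASIC[base[1][2]]]
        dmin = _pair_min_distances(frames, o_atoms, n_atoms)
        hit = dmin < params.polar_cutoff
        rows.append({
            "chain_a": ka[0], "resid_a": ka[1], "resname_a": ka[2],
            "chain_b": kb[0], "resid_b": kb[1], "resname_b": kb[2],
            "persistence": float(hit.mean()),
            "mean_min_distance": float(dmin[hit].mean()) if hit.any() else float(dmin.mean()),
        })
    return pd.DataFrame(rows)
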