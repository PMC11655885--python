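"""Structures, ensembles, and atom selections.

Coordinates are in Å throughout. Residues are addressed by author numbering
(chain id + residue number + 3-letter name), never renumbered, because the
literature on these receptors cites residues that way (e.g. S123, W356).

Parsing of PDB/mmCIF files is delegated to :mod:`gemmi`; the containers here
are deliberately small and NumPy-backed so every downstream metric can
vectorize over frames.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "AtomIndexSet",
    "SelectionError",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "read_ensemble",
    "write_ensemble",
    "select",
]

#: Backbone heavy-atom names of an amino-acid residue.
BACKBONE_NAMES = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class SelectionError(ValueError):
    """Raised when a selection expression does not follow the grammar."""


@dataclass(frozen=True)
class Atom:
    """One atom of one conformation.

    ``coordinates`` is a length-3 float array in Å.  ``is_hetero`` marks
    HETATM records (ligands, waters, ions); they are retained on reading and
    flagged rather than dropped.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coordinates: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coordinates", coords)
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)


class Structure:
    """An ordered list of atoms grouped into residues.

    Residues are derived from the atom list by (chain_id, residue_number,
    residue_name); atoms of one residue need not be contiguous in the file,
    but residue order follows first appearance.
    """

    def __init__(self, atoms: Sequence[Atom]):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a Structure must contain at least one atom")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")
        self.atoms: list[Atom] = atoms
        self._coords = np.array([a.coordinates for a in atoms], dtype=float)
        # residue bookkeeping
        keys: list[tuple[str, int, str]] = []
        key_to_index: dict[tuple[str, int, str], int] = {}
        atom_residue = np.empty(len(atoms), dtype=int)
        for i, a in enumerate(atoms):
            k = a.residue_key
            if k not in key_to_index:
                key_to_index[k] = len(keys)
                keys.append(k)
            atom_residue[i] = key_to_index[k]
        self.residue_keys: list[tuple[str, int, str]] = keys
        self.atom_residue_index: np.ndarray = atom_residue
        self._residue_atoms: list[np.ndarray] = [
            np.flatnonzero(atom_residue == r) for r in range(len(keys))
        ]

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    @property
    def coordinates(self) -> np.ndarray:
        """(M, 3) array of coordinates in Å."""
        return self._coords

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def residue_atom_indices(self, residue_index: int) -> np.ndarray:
        return self._residue_atoms[residue_index]

    def residue_index(self, chain_id: str, residue_number: int) -> int:
        """Index of the residue with the given author chain + number."""
        for r, (c, n, _) in enumerate(self.residue_keys):
            if c == chain_id and n == residue_number:
                return r
        raise KeyError(f"no residue {residue_number} in chain {chain_id!r}")

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        """A copy of this structure carrying new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coordinates of shape ({len(self.atoms)}, 3), got {coords.shape}")
        atoms = [replace(a, coordinates=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms)


class Ensemble:
    """Ordered frames sharing one topology.

    ``burn_in_fraction`` reflects the common practice of discarding the
    initial, still-equilibrating part of a trajectory; analysis functions
    operate on :attr:`analyzed_frames` only.  The default of 0.5 analyzes
    the last half of the frames.
    """

    def __init__(
        self,
        topology: Structure,
        frames: np.ndarray | Sequence[np.ndarray],
        frame_times: Sequence[float] | None = None,
        burn_in_fraction: float = 0.5,
    ):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (topology.n_atoms, 3):
            raise ValueError(
                f"frames must have shape (n_frames, {topology.n_atoms}, 3); got {frames.shape}"
            )
        if frames.shape[0] == 0:
            raise ValueError("an Ensemble needs at least one frame")
        if not 0.0 <= burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        self.topology = topology
        self.frames = frames
        self.frame_times = None if frame_times is None else np.asarray(frame_times, dtype=float)
        self.burn_in_fraction = float(burn_in_fraction)
        if len(self.analyzed_frame_indices) == 0:
            raise ValueError("burn-in leaves no frames to analyze")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def analyzed_frame_indices(self) -> np.ndarray:
        start = int(self.n_frames * self.burn_in_fraction)
        return np.arange(start, self.n_frames)

    @property
    def analyzed_frames(self) -> np.ndarray:
        """(n_analyzed, M, 3) coordinates after burn-in."""
        return self.frames[self.analyzed_frame_indices]

    def frame_structure(self, t: int) -> Structure:
        return self.topology.with_coordinates(self.frames[t])

    def concatenate(self, other: "Ensemble") -> "Ensemble":
        """Pool two ensembles over the same topology, keeping zero burn-in.

        Burn-in is assumed to have been applied already when pooling runs
        into a single ensemble for analysis.
        """
        if other.topology.n_atoms != self.topology.n_atoms:
            raise ValueError("cannot concatenate ensembles with different atom counts")
        frames = np.concatenate([self.analyzed_frames, other.analyzed_frames], axis=0)
        return Ensemble(self.topology, frames, burn_in_fraction=0.0)


@dataclass(frozen=True)
class AtomIndexSet:
    """Sorted unique indices into ``Structure.atoms`` plus the expression
    that produced them (for provenance)."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: str) -> None:
    """Cheap structural check of ATOM/HETATM records so parse failures name
    the offending line (gemmi is more forgiving than we want)."""
    n_coord = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            n_coord += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}:{lineno}: truncated {rec} record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(f"{path}:{lineno}: malformed {rec} record: {exc}") from exc
    if n_coord == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")


def _atoms_from_gemmi_model(model, keep_altloc: bool = True) -> list[Atom]:
    import gemmi

    raw: list[Atom] = []
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for atom in residue:
                raw.append(
                    Atom(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name or atom.name[:1],
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        coordinates=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(float(atom.occ), 0.0), 1.0),
                        altloc=atom.altloc.strip("\x00") if atom.altloc else "",
                        bfactor=float(atom.b_iso),
                        is_hetero=het,
                    )
                )
    if not keep_altloc:
        return raw
    # keep the highest-occupancy altloc per (residue, atom name); ties broken
    # alphabetically by altloc id
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in raw:
        key = (a.chain_id, a.residue_number, a.residue_name, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                best[key] = a
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> int:
    # higher rank wins on occupancy ties; '' > 'A' > 'B' ...
    return 0 if not altloc else -ord(altloc[0])


def read_structure(path: str | os.PathLike) -> Structure:
    """Read a structure from a PDB (or mmCIF) file.

    The highest-occupancy alternate location is retained per atom name;
    waters and other heteroatoms are kept and flagged via ``Atom.is_hetero``.
    """
    import gemmi

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith((".pdb", ".ent")):
        _validate_pdb_lines(path)
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: file contains no model")
    atoms = _atoms_from_gemmi_model(st[0])
    if not atoms:
        raise PDBParseError(f"{path}: model contains no atoms")
    return Structure(atoms)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3}"
    return f"{name:<4}"


def _pdb_atom_line(a: Atom, serial: int, coords: np.ndarray) -> str:
    record = "HETATM" if a.is_hetero else "ATOM  "
    name = _format_atom_name(a.name, a.element)
    return (
        f"{record}{serial:>5} {name}{a.altloc[:1] or ' '}{a.residue_name:>3} "
        f"{a.chain_id[:1] or 'A'}{a.residue_number:>4}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element[:2]:>2}"
    )


def write_structure(structure: Structure, path: str | os.PathLike, bfactors: np.ndarray | None = None) -> None:
    """Write a structure as a PDB file.

    ``bfactors`` optionally overrides the B-factor column (one value per
    atom) — used to export per-residue metrics for surface heatmaps.
    """
    path = os.fspath(path)
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms):
            b = a.bfactor if bfactors is None else float(bfactors[i])
            fh.write(_pdb_atom_line(replace(a, bfactor=b), i + 1, a.coordinates) + "\n")
        fh.write("END\n")


def write_ensemble(ensemble: Ensemble, path: str | os.PathLike) -> None:
    """Write an ensemble as a multi-model PDB file."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        for t in range(ensemble.n_frames):
            fh.write(f"MODEL     {t + 1:>4}\n")
            for i, a in enumerate(ensemble.topology.atoms):
                fh.write(_pdb_atom_line(a, i + 1, ensemble.frames[t, i]) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_ensemble(
    topology_path: str | os.PathLike,
    frames_path: str | os.PathLike | None = None,
    burn_in_fraction: float = 0.5,
) -> Ensemble:
    """Read an ensemble: a topology plus frames.

    The mandatory frame format is multi-model PDB.  If ``frames_path`` is
    omitted, the topology file itself must be multi-model.  Binary
    trajectory formats (DCD/XTC) are accepted as an optional adapter via
    MDAnalysis when it is installed.
    """
    import gemmi

    topology = read_structure(topology_path)
    frames_path = os.fspath(frames_path if frames_path is not None else topology_path)

    if frames_path.endswith((".pdb", ".ent", ".cif")):
        if frames_path.endswith((".pdb", ".ent")):
            _validate_pdb_lines(frames_path)
        st = gemmi.read_structure(frames_path)
        frames = []
        for model in st:
            atoms = _atoms_from_gemmi_model(model)
            if len(atoms) != topology.n_atoms:
                raise ValueError(
                    f"frame atom count {len(atoms)} does not match topology atom count {topology.n_atoms}"
                )
            frames.append(np.array([a.coordinates for a in atoms]))
        if not frames:
            raise PDBParseError(f"{frames_path}: no models found")
        return Ensemble(topology, np.stack(frames), burn_in_fraction=burn_in_fraction)

    # optional binary-trajectory adapter
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ValueError(
            f"cannot read {frames_path}: binary trajectories need MDAnalysis"
        ) from exc
    u = mda.Universe(os.fspath(topology_path), frames_path)
    if len(u.atoms) != topology.n_atoms:
        raise ValueError(
            f"frame atom count {len(u.atoms)} does not match topology atom count {topology.n_atoms}"
        )
    frames = np.stack([u.atoms.positions.astype(float).copy() for _ in u.trajectory])
    return Ensemble(topology, frames, burn_in_fraction=burn_in_fraction)


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------
#
# Grammar (case-insensitive keywords):
#   expr     := or_expr
#   or_expr  := and_expr ( "or" and_expr )*
#   and_expr := not_expr ( "and" not_expr )*
#   not_expr := "not" not_expr | primary
#   primary  := "(" expr ")" | clause
#   clause   := "chain" ID+ | "resid" RANGE+ | "name" NAME+ | "element" SYM+
#             | "backbone" | "sidechain" | "calpha" | "all" | "hetero"
#   RANGE    := INT | INT "-" INT
#
# "backbone" matches N, CA, C, O of non-hetero residues; "sidechain" matches
# the non-backbone heavy atoms of a residue, with Cα standing in for glycine
# (which has no sidechain heavy atom); "calpha" matches carbon atoms named CA.

_KEYWORDS = {"chain", "resid", "name", "element", "backbone", "sidechain",
             "calpha", "all", "hetero", "and", "or", "not", "(", ")"}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expression):
        c = expression[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expression) and not expression[j].isspace() and expression[j] not in "()":
            j += 1
        tokens.append((expression[i:j], i))
        i = j
    return tokens


class _Parser:
    def __init__(self, structure: Structure, expression: str):
        self.structure = structure
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0
        self._n = structure.n_atoms

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression")
        mask = self._or_expr()
        if self.pos < len(self.tokens):
            tok, at = self.tokens[self.pos]
            raise SelectionError(f"unexpected token {tok!r} at position {at}")
        return mask

    # -- recursive descent -------------------------------------------
    def _peek(self) -> str | None:
        return self.tokens[self.pos][0].lower() if self.pos < len(self.tokens) else None

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek() == "or":
            self.pos += 1
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._not_expr()
        while self._peek() == "and":
            self.pos += 1
            mask = mask & self._not_expr()
        return mask

    def _not_expr(self) -> np.ndarray:
        if self._peek() == "not":
            self.pos += 1
            return ~self._not_expr()
        return self._primary()

    def _primary(self) -> np.ndarray:
        tok = self._peek()
        if tok is None:
            raise SelectionError(f"unexpected end of expression: {self.expression!r}")
        if tok == "(":
            self.pos += 1
            mask = self._or_expr()
            if self._peek() != ")":
                at = self.tokens[self.pos - 1][1]
                raise SelectionError(f"missing ')' after position {at}")
            self.pos += 1
            return mask
        return self._clause()

    def _values(self) -> list[str]:
        vals = []
        while self.pos < len(self.tokens):
            tok = self.tokens[self.pos][0]
            if tok.lower() in _KEYWORDS:
                break
            vals.append(tok)
            self.pos += 1
        if not vals:
            tok, at = self.tokens[self.pos - 1]
            raise SelectionError(f"keyword {tok!r} at position {at} expects at least one value")
        return vals

    def _clause(self) -> np.ndarray:
        tok, at = self.tokens[self.pos]
        kw = tok.lower()
        atoms = self.structure.atoms
        if kw == "all":
            self.pos += 1
            return np.ones(self._n, dtype=bool)
        if kw == "hetero":
            self.pos += 1
            return np.array([a.is_hetero for a in atoms], dtype=bool)
        if kw == "backbone":
            self.pos += 1
            return np.array(
                [a.name in BACKBONE_NAMES and not a.is_hetero for a in atoms], dtype=bool
            )
        if kw == "calpha":
            self.pos += 1
            return np.array(
                [a.name == "CA" and a.element.upper() == "C" for a in atoms], dtype=bool
            )
        if kw == "sidechain":
            self.pos += 1
            return self._sidechain_mask()
        if kw == "chain":
            self.pos += 1
            ids = set(self._values())
            return np.array([a.chain_id in ids for a in atoms], dtype=bool)
        if kw == "name":
            self.pos += 1
            names = {v.upper() for v in self._values()}
            return np.array([a.name.upper() in names for a in atoms], dtype=bool)
        if kw == "element":
            self.pos += 1
            syms = {v.upper() for v in self._values()}
            return np.array([a.element.upper() in syms for a in atoms], dtype=bool)
        if kw == "resid":
            self.pos += 1
            wanted: set[int] = set()
            for v in self._values():
                try:
                    if "-" in v[1:]:
                        sep = v.index("-", 1)
                        lo_i, hi_i = int(v[:sep]), int(v[sep + 1:])
                        if hi_i < lo_i:
                            raise ValueError("descending range")
                        wanted.update(range(lo_i, hi_i + 1))
                    else:
                        wanted.add(int(v))
                except ValueError as exc:
                    raise SelectionError(f"bad resid value {v!r} at position {at}: {exc}") from exc
            return np.array([a.residue_number in wanted for a in atoms], dtype=bool)
        raise SelectionError(f"unknown keyword {tok!r} at position {at}")

    def _sidechain_mask(self) -> np.ndarray:
        st = self.structure
        mask = np.zeros(self._n, dtype=bool)
        heavy = st.heavy_mask
        for r in range(st.n_residues):
            idx = st.residue_atom_indices(r)
            if any(st.atoms[i].is_hetero for i in idx):
                continue
            side = [i for i in idx if heavy[i] and st.atoms[i].name not in BACKBONE_NAMES
                    and st.atoms[i].name != "OXT"]
            if side:
                mask[side] = True
            else:
                # glycine: Cα stands in for the missing sidechain
                ca = [i for i in idx if st.atoms[i].name == "CA"]
                if ca:
                    mask[ca] = True
        return mask


def select(structure: Structure, expression: str) -> AtomIndexSet:
    """Resolve a selection expression to an :class:`AtomIndexSet`.

    Pure and deterministic: the same structure and expression always yield
    the same index set.  An expression that matches nothing returns an empty
    set; only grammar violations raise :class:`SelectionError`.
    """
    mask = _Parser(structure, expression).parse()
    return AtomIndexSet(np.flatnonzero(mask), expression)
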