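"""Per-residue scalar maps (topography, flexibility) and their exports."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import Structure, write_structure

__all__ = ["ResidueScalarMap", "params_digest"]


def params_digest(obj) -> str:
    """Stable short digest of a parameter object, for output provenance."""
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]


@dataclass
class ResidueScalarMap:
    """Finite scalar values keyed by (chain_id, residue_number, residue_name)."""

    entries: dict[tuple[str, int, str], float]
    metric_name: str
    params_digest: str = ""

    def __post_init__(self) -> None:
        for key, v in self.entries.items():
            if not np.isfinite(v):
                raise ValueError(f"{self.metric_name}: non-finite value for residue {key}")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key: tuple[str, int, str]) -> float:
        return self.entries[key]

    def value(self, chain_id: str, residue_number: int) -> float:
        for (c, n, _), v in self.entries.items():
            if c == chain_id and n == residue_number:
                return v
        raise KeyError(f"no value for residue {residue_number} in chain {chain_id!r}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"chain": c, "resid": n, "resname": rn, "value": v}
            for (c, n, rn), v in self.entries.items()
        ]
        df = pd.DataFrame(rows, columns=["chain", "resid", "resname", "value"])
        df.attrs["metric_name"] = self.metric_name
        df.attrs["params_digest"] = self.params_digest
        return df

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# metric={self.metric_name} params_digest={self.params_digest}\n")
            self.to_dataframe().to_csv(fh, index=False)

    def atom_values(self, structure: Structure, missing: float = 0.0) -> np.ndarray:
        """Broadcast residue values onto atoms (for B-factor export)."""
        out = np.full(structure.n_atoms, missing, dtype=float)
        for r, key in enumerate(structure.residue_keys):
            if key in self.entries:
                out[structure.residue_atom_indices(r)] = self.entries[key]
        return out

    def write_bfactor_pdb(self, structure: Structure, path: str) -> None:
        """Write the structure with the metric in the B-factor column, so
        molecular viewers can render it as a surface heatmap."""
        write_structure(structure, path, bfactors=self.atom_values(structure))

    def difference(self, other: "ResidueScalarMap") -> pd.DataFrame:
        """Per-residue difference self − other, aligned by (chain, resid).

        Residues present on one side only get NaN differences and a
        ``missing_in`` marker instead of a fabricated zero.
        """
        keys = list(dict.fromkeys(list(self.entries) + list(other.entries)))
        if not set(self.entries) & set(other.entries):
            raise ValueError("residue sets are disjoint; nothing to compare")
        rows = []
        for key in keys:
            a = self.entries.get(key)
            b = other.entries.get(key)
            rows.append({
                "chain": key[0], "resid": key[1], "resname": key[2],
                "value_a": np.nan if a is None else a,
                "value_b": np.nan if b is None else b,
                "difference": np.nan if (a is None or b is None) else a - b,
                "missing_in": "a" if a is None else ("b" if b is None else ""),
            })
        return pd.DataFrame(rows)
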