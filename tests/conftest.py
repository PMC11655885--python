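import numpy as np
import pytest

from trajscape.model_io import Atom, Ensemble, Structure


def build_structure(spec, chain="A"):
    """Build a Structure from (name, element, resname, resnum, xyz[, hetero]) tuples."""
    atoms = []
    for i, row in enumerate(spec):
        name, element, resname, resnum, xyz = row[:5]
        hetero = row[5] if len(row) > 5 else False
        atoms.append(Atom(serial=i + 1, name=name, element=element,
                          residue_name=resname, residue_number=resnum,
                          chain_id=chain, coordinates=np.asarray(xyz, dtype=float),
                          is_hetero=hetero))
    return Structure(atoms)


def static_ensemble(structure, n_frames=1):
    """All frames identical to the structure, no burn-in."""
    frames = np.repeat(structure.coordinates[None], n_frames, axis=0)
    return Ensemble(structure, frames, burn_in_fraction=0.0)


@pytest.fixture(scope="session")
def bundle():
    from trajscape.synthetic import make_bundle

    return make_bundle(4, 10, seed=1)


@pytest.fixture(scope="session")
def bundle_7tm():
    from trajscape.synthetic import make_bundle

    return make_bundle(7, 12, seed=0)
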