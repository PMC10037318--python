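import numpy as np
import pytest

from pepsurf import Atom, Frame, Trajectory


def make_slab_atoms(n_per_layer: int = 4, n_layers: int = 3) -> list[Atom]:
    return [
        Atom(index=i, name="AU", element="Au", residue_index=0,
             residue_name="AUS", is_slab=True)
        for i in range(n_per_layer * n_layers)
    ]


def slab_coordinates(n_per_layer: int = 4, n_layers: int = 3,
                     spacing: float = 2.35) -> np.ndarray:
    """n_layers flat layers of n_per_layer atoms at z = 0, spacing, ..."""
    coords = []
    for k in range(n_layers):
        for i in range(n_per_layer):
            coords.append([float(i), 0.0, k * spacing])
    return np.array(coords)


@pytest.fixture
def simple_system():
    """12 Au atoms in 3 layers (top at z = 4.70 A) + 1 MET residue (CA + SD)."""
    atoms = make_slab_atoms()
    n = len(atoms)
    atoms.append(Atom(index=n, name="CA", element="C",
                      residue_index=1, residue_name="MET"))
    atoms.append(Atom(index=n + 1, name="SD", element="S",
                      residue_index=1, residue_name="MET"))

    def build(sd_z: float, time: float = 0.0) -> Frame:
        coords = np.vstack([
            slab_coordinates(),
            [[1.0, 0.0, sd_z + 1.5]],  # CA
            [[1.0, 0.0, sd_z]],        # SD
        ])
        return Frame(coordinates=coords, box=(20.0, 20.0, 60.0), time=time)

    def make(sd_zs):
        return Trajectory(atoms=list(atoms),
                          frames=[build(z, t) for t, z in enumerate(sd_zs)])

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
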