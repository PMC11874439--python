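import numpy as np
import pytest

from minidock.molio import (
    build_torsion_tree,
    generate_toy_complex,
    ligand_from_template,
)


@pytest.fixture(scope="session")
def toy_complex():
    """Seed-0 imprinted pocket around a butane ground-truth pose."""
    return generate_toy_complex(0, 50, "butane")


@pytest.fixture(scope="session")
def butane():
    return ligand_from_template("butane", seed=0)


@pytest.fixture(scope="session")
def butane_tree(butane):
    return build_torsion_tree(butane)


@pytest.fixture(scope="session")
def separable_dataset():
    """200 separable labeled grids (session-cached: building is the cost)."""
    from minidock.cnn_models import make_synthetic_pose_dataset

    return make_synthetic_pose_dataset(200, seed=0, mode="separable")


def ideal_hexagon():
    """Planar regular hexagon of carbons (bond length 1.4 A), single bonds."""
    from minidock.molio import AtomRecord, TypedMolecule, assign_atom_types

    r = 1.4
    atoms = []
    for k in range(6):
        ang = np.pi / 3 * k
        atoms.append(
            AtomRecord(
                index=k,
                element="C",
                position=np.array([r * np.cos(ang), r * np.sin(ang), 0.0]),
                is_ligand=True,
            )
        )
    bonds = [(k, (k + 1) % 6, 1) for k in range(6)]
    return assign_atom_types(TypedMolecule(atoms=atoms, bonds=bonds, name="hex"))
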