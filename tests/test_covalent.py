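import numpy as np
import pytest

from minidock.covalent import (
    CovalentSpec,
    covalent_dock,
    find_ligand_covalent_atoms,
    generate_toy_covalent_complex,
    locate_receptor_atom,
    make_covalent_construct,
    new_bond_vector,
    place_ligand,
)
from minidock.errors import InputError
from minidock.metrics import symmetry_rmsd
from minidock.molio import (
    AtomRecord,
    TypedMolecule,
    assign_atom_types,
    build_torsion_tree,
    generate_toy_complex,
    ligand_from_template,
)
from minidock.sampler import SamplerConfig, mutate_pose
from minidock.molio import Pose


@pytest.fixture(scope="module")
def pocket():
    receptor, _, _ = generate_toy_complex(1, 50, "butane")
    return receptor


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_smarts_matches_both_disulfide_sulfurs():
    lig = ligand_from_template("dimethyl_disulfide", seed=0)
    assert len(find_ligand_covalent_atoms(lig, "[SX2H0]")) == 2


def test_smarts_single_and_no_match():
    methane = ligand_from_template("methane", seed=0)
    assert len(find_ligand_covalent_atoms(methane, "[C]")) == 1
    with pytest.raises(InputError):
        find_ligand_covalent_atoms(methane, "[Au]")
    with pytest.raises(InputError):
        find_ligand_covalent_atoms(methane, "[not-smarts")


def test_locate_receptor_atom(pocket):
    idx = locate_receptor_atom(pocket, ("A", "145", "SG"))
    assert pocket.atoms[idx].atom_name == "SG"
    with pytest.raises(InputError):
        locate_receptor_atom(pocket, ("B", "145", "SG"))


def test_locate_receptor_atom_ambiguous():
    atoms = [
        AtomRecord(index=k, element="C", position=np.array([float(k), 0, 0]),
                   chain_id="A", residue_number="1", residue_name="ALA",
                   atom_name="CA")
        for k in range(2)
    ]
    corrupt = assign_atom_types(TypedMolecule(atoms=atoms, bonds=[]))
    with pytest.raises(InputError, match="ambiguous"):
        locate_receptor_atom(corrupt, ("A", "1", "CA"))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def test_new_bond_vector_three_orthogonal_neighbors():
    atoms = [
        AtomRecord(index=0, element="C", position=np.zeros(3)),
        AtomRecord(index=1, element="C", position=np.array([1.5, 0, 0])),
        AtomRecord(index=2, element="C", position=np.array([0, 1.5, 0])),
        AtomRecord(index=3, element="C", position=np.array([0, 0, 1.5])),
    ]
    mol = assign_atom_types(
        TypedMolecule(atoms=atoms, bonds=[(0, 1, 1), (0, 2, 1), (0, 3, 1)])
    )
    direction, _ = new_bond_vector(mol, 0)
    assert np.allclose(direction, -np.ones(3) / np.sqrt(3), atol=1e-12)


def test_new_bond_vector_single_neighbor_and_isolated():
    atoms = [
        AtomRecord(index=0, element="C", position=np.zeros(3)),
        AtomRecord(index=1, element="C", position=np.array([1.5, 0, 0])),
    ]
    mol = assign_atom_types(TypedMolecule(atoms=atoms, bonds=[(0, 1, 1)]))
    direction, pos = new_bond_vector(mol, 0, partner_covalent_radius=0.76)
    assert np.allclose(direction, [-1.0, 0, 0])
    assert np.allclose(pos, [-(0.76 + 0.76), 0, 0])

    lone = assign_atom_types(
        TypedMolecule(atoms=[AtomRecord(index=0, element="C", position=np.zeros(3))])
    )
    direction, _ = new_bond_vector(lone, 0)
    assert np.allclose(direction, [1.0, 0, 0])


def test_new_bond_vector_reduces_one_hydrogen():
    atoms = [
        AtomRecord(index=0, element="S", position=np.zeros(3)),
        AtomRecord(index=1, element="C", position=np.array([0, 0, -1.8])),
        AtomRecord(index=2, element="H", position=np.array([1.3, 0, 0.3])),
    ]
    mol = assign_atom_types(
        TypedMolecule(atoms=atoms, bonds=[(0, 1, 1), (0, 2, 1)])
    )
    direction, _ = new_bond_vector(mol, 0)
    # with the hydrogen removed only the carbon remains: direction = +z
    assert np.allclose(direction, [0, 0, 1.0], atol=1e-12)


def test_place_ligand_geometry():
    lig = ligand_from_template("methanethiol", seed=0)
    s_idx = find_ligand_covalent_atoms(lig, "[SX2]")[0]
    target = np.array([1.0, 2.0, 3.0])
    pose = place_ligand(lig, s_idx, target, np.array([0.0, 0.0, 1.0]))
    assert np.linalg.norm(pose.coordinates[s_idx] - target) < 1e-6
    # rigidity: pairwise distances preserved
    def pdist(c):
        return np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
    assert np.allclose(pdist(pose.coordinates), pdist(lig.coords), atol=1e-9)
    # the C-S vector (from carbon to sulfur) anti-aligns with the bond direction
    c_idx = next(a.index for a in lig.atoms if a.element == "C")
    cs = pose.coordinates[s_idx] - pose.coordinates[c_idx]
    cs /= np.linalg.norm(cs)
    angle = np.degrees(np.arccos(np.clip(np.dot(cs, [0, 0, -1.0]), -1, 1)))
    assert angle < 15.0


# ---------------------------------------------------------------------------
# construct
# ---------------------------------------------------------------------------

def _placed_thiol(pocket):
    lig = ligand_from_template("ethanethiol", seed=3)
    s_idx = find_ligand_covalent_atoms(lig, "[SX2]")[0]
    rec_idx = locate_receptor_atom(pocket, ("A", "145", "SG"))
    direction, target = new_bond_vector(
        pocket, rec_idx, lig.atoms[s_idx].covalent_radius
    )
    pose = place_ligand(lig, s_idx, target, direction, pocket)
    return lig, s_idx, rec_idx, pose


def test_construct_bond_count_and_flags(pocket):
    lig, s_idx, rec_idx, pose = _placed_thiol(pocket)
    construct, tree = make_covalent_construct(pocket, lig, pose, s_idx, rec_idx)
    n_residue_bonds = 3  # N-CA, CA-CB, CB-SG
    assert len(construct.bonds) == n_residue_bonds + len(lig.bonds) + 1
    offset = construct.n_atoms - lig.n_atoms
    assert all(not a.is_ligand for a in construct.atoms[:offset])
    assert all(a.is_ligand for a in construct.atoms[offset:])


def test_construct_anchor_immobile_under_mutations(pocket):
    lig, s_idx, rec_idx, pose = _placed_thiol(pocket)
    construct, tree = make_covalent_construct(pocket, lig, pose, s_idx, rec_idx)
    assert tree.n_rotatable >= 1
    sg_local = next(
        k for k in range(construct.n_atoms)
        if construct.atoms[k].atom_name == "SG" and not construct.atoms[k].is_ligand
    )
    anchor_pos = construct.coords[sg_local].copy()
    backbone = [
        k for k in range(construct.n_atoms)
        if construct.atoms[k].atom_name in ("N", "CA") and not construct.atoms[k].is_ligand
    ]
    backbone_pos = construct.coords[backbone].copy()
    cfg = SamplerConfig(covalent_mode=True)
    rng = np.random.default_rng(0)
    current = Pose(coordinates=construct.coords)
    for _ in range(100):
        current = mutate_pose(current, tree, cfg, rng)
    assert np.array_equal(current.coordinates[sg_local], anchor_pos)
    assert np.array_equal(current.coordinates[backbone], backbone_pos)


def test_construct_requires_proximity(pocket):
    lig = ligand_from_template("ethanethiol", seed=3)
    s_idx = find_ligand_covalent_atoms(lig, "[SX2]")[0]
    rec_idx = locate_receptor_atom(pocket, ("A", "145", "SG"))
    far = Pose(coordinates=lig.coords + 50.0)
    with pytest.raises(InputError):
        make_covalent_construct(pocket, lig, far, s_idx, rec_idx)


# ---------------------------------------------------------------------------
# full covalent docking
# ---------------------------------------------------------------------------

def test_pairing_expansion_and_bond_invariant(pocket):
    lig = ligand_from_template("dimethyl_disulfide", seed=2)
    matches = find_ligand_covalent_atoms(lig, "[SX2H0]")
    rec_idx = locate_receptor_atom(pocket, ("A", "145", "SG"))
    anchor = pocket.atoms[rec_idx]
    spec = CovalentSpec(ligand_smarts="[SX2H0]", receptor_atom=("A", "145", "SG"))
    cfg = SamplerConfig(exhaustiveness=1, steps=8, seed=1, num_modes=3)
    poses = covalent_dock(pocket, lig, spec, cfg)
    groups = {p.provenance["covalent_pairing"] for p in poses}
    assert groups == set(range(len(matches)))
    assert len(poses) <= len(matches) * cfg.num_modes
    for p in poses:
        lig_atom = p.provenance["covalent_lig_atom"]
        blen = np.linalg.norm(p.coordinates[lig_atom] - anchor.position)
        target = anchor.covalent_radius + lig.atoms[lig_atom].covalent_radius
        assert abs(blen - target) <= 0.2


def test_explicit_position_honored(pocket):
    lig = ligand_from_template("ethanethiol", seed=3)
    rec_idx = locate_receptor_atom(pocket, ("A", "145", "SG"))
    ep = tuple(pocket.atoms[rec_idx].position + np.array([0.0, 0.0, 2.1]))
    spec = CovalentSpec(
        ligand_smarts="[SX2]",
        receptor_atom=("A", "145", "SG"),
        explicit_position=ep,
        fix_lig_atom=True,
    )
    poses = covalent_dock(
        pocket, lig, spec, SamplerConfig(exhaustiveness=1, steps=8, seed=2, num_modes=3)
    )
    for p in poses:
        drift = np.linalg.norm(
            p.coordinates[p.provenance["covalent_lig_atom"]] - np.asarray(ep)
        )
        assert drift <= 1e-6


def test_covalent_redock_recovers_reference():
    receptor, ligand, reference = generate_toy_covalent_complex(2)
    tree = build_torsion_tree(ligand)
    rng = np.random.default_rng(77)
    coords = ligand.coords
    for k in range(tree.n_rotatable):
        coords = tree.rotate(coords, k, float(rng.uniform(-np.pi, np.pi)))
    ligand.set_coords(coords)
    spec = CovalentSpec(ligand_smarts="[SX2]", receptor_atom=("A", "145", "SG"))
    poses = covalent_dock(
        receptor, ligand, spec,
        SamplerConfig(exhaustiveness=4, steps=30, seed=2, num_modes=9),
    )
    assert symmetry_rmsd(poses[0], reference, ligand) <= 2.0


def test_invalid_covalent_spec():
    with pytest.raises(InputError):
        CovalentSpec(ligand_smarts="[SX2]", receptor_atom=("A", "145", "SG"),
                     bond_order=4)
    with pytest.raises(InputError):
        CovalentSpec(ligand_smarts="[[[", receptor_atom=("A", "145", "SG"))
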