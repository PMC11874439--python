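"""Covalent docking.

The bound, covalent form of the ligand is the input (no reaction modeling).
A ligand atom is selected by SMARTS (all matches are evaluated, expanding the
output pose list per pairing) and a receptor atom by chain / residue number /
atom name. The ligand is rigidly placed so the covalent atom sits at a
chemically sensible position (a new-bond-vector heuristic on the receptor
atom, after removing one hydrogen if present, or an explicit user position),
the bond is created, and the residue-ligand construct is sampled as one
flexible residue: torsion moves only, no rigid-body transformations. Ligand
atoms keep their ligand identity for CNN channel assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem

from .errors import InputError
from .metrics import heavy_automorphisms
from .molio import (
    AtomRecord,
    Pose,
    TorsionTree,
    TypedMolecule,
    _rodrigues,
    assign_atom_types,
    build_torsion_tree,
)
from .sampler import SamplerConfig, diversity_filter, run_chain
from .scoring import DEFAULT_WEIGHTS, InteractionContext, TermWeights


@dataclass
class CovalentSpec:
    ligand_smarts: str
    receptor_atom: tuple[str, str | int, str]  # (chain, residue number, atom name)
    bond_order: int = 1
    explicit_position: tuple[float, float, float] | None = None
    optimize_construct: bool = False
    fix_lig_atom: bool = False

    def __post_init__(self):
        if self.bond_order not in (1, 2, 3):
            raise InputError("bond_order must be 1, 2 or 3")
        if Chem.MolFromSmarts(self.ligand_smarts) is None:
            raise InputError(f"invalid SMARTS {self.ligand_smarts!r}")


def find_ligand_covalent_atoms(ligand: TypedMolecule, smarts: str) -> list[int]:
    """First-atom index of every SMARTS match, deduplicated, stable order."""
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise InputError(f"invalid SMARTS {smarts!r}")
    mol = ligand.to_rdkit()
    matches = mol.GetSubstructMatches(patt, uniquify=True)
    out: list[int] = []
    for m in matches:
        if m[0] not in out:
            out.append(int(m[0]))
    if not out:
        raise InputError(f"SMARTS {smarts!r} matches no ligand atom")
    return out


def locate_receptor_atom(
    receptor: TypedMolecule, address: tuple[str, str | int, str]
) -> int:
    """Unique atom index at (chain, residue number, atom name)."""
    chain, resnum, atom_name = address
    resnum = str(resnum)
    hits = [
        a.index
        for a in receptor.atoms
        if a.chain_id == chain
        and a.residue_number == resnum
        and a.atom_name == atom_name
    ]
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        raise InputError(f"ambiguous receptor address {address}: atoms {hits}")
    near = sorted(
        {
            f"{a.chain_id}:{a.residue_number}:{a.atom_name}"
            for a in receptor.atoms
            if a.residue_number == resnum or a.atom_name == atom_name
        }
    )[:8]
    raise InputError(
        f"receptor atom {chain}:{resnum}:{atom_name} not found; near misses: {near}"
    )


def new_bond_vector(
    mol: TypedMolecule, atom_index: int, partner_covalent_radius: float = 0.76
) -> tuple[np.ndarray, np.ndarray]:
    """Direction and suggested position for a new bond at ``atom_index``.

    Direction is the normalized negative sum of unit vectors to the bonded
    neighbors that remain after removing one hydrogen (if present); an isolated
    atom falls back to +x. The suggested position extends along the direction
    by the sum of covalent radii.
    """
    atom = mol.atoms[atom_index]
    adj = mol.adjacency()
    neighbors = sorted(adj[atom_index])
    h_neighbors = [v for v in neighbors if mol.atoms[v].element == "H"]
    if h_neighbors:
        neighbors = [v for v in neighbors if v != h_neighbors[0]]
    vec = np.zeros(3)
    for v in neighbors:
        u = mol.atoms[v].position - atom.position
        nrm = np.linalg.norm(u)
        if nrm > 1e-9:
            vec -= u / nrm
    nrm = np.linalg.norm(vec)
    direction = vec / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    bond_length = atom.covalent_radius + partner_covalent_radius
    return direction, atom.position + direction * bond_length


def _mean_neighbor_direction(ligand: TypedMolecule, lig_atom: int) -> np.ndarray | None:
    adj = ligand.adjacency()
    neigh = [v for v in sorted(adj[lig_atom]) if ligand.atoms[v].element != "H"]
    if not neigh:
        neigh = sorted(adj[lig_atom])
    if not neigh:
        return None
    pos = ligand.atoms[lig_atom].position
    vec = np.zeros(3)
    for v in neigh:
        u = ligand.atoms[v].position - pos
        nrm = np.linalg.norm(u)
        if nrm > 1e-9:
            vec += u / nrm
    nrm = np.linalg.norm(vec)
    return vec / nrm if nrm > 1e-9 else None


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 rotation taking unit vector a onto unit vector b."""
    c = float(np.dot(a, b))
    axis = np.cross(a, b)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate pi about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        K = np.array(
            [[0, -perp[2], perp[1]], [perp[2], 0, -perp[0]], [-perp[1], perp[0], 0]]
        )
        return np.eye(3) + 2.0 * (K @ K)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + K + K @ K * ((1 - c) / (s * s))


def place_ligand(
    ligand: TypedMolecule,
    lig_atom: int,
    target_position: np.ndarray,
    target_direction: np.ndarray,
    receptor: TypedMolecule | None = None,
) -> Pose:
    """Rigidly place the ligand so the covalent atom lands on
    ``target_position`` with its bonds pointing away from the receptor (the
    mean heavy-neighbor direction at the covalent atom is rotated onto
    ``target_direction``). When a receptor is given, the free rotation about
    the new bond axis is chosen over a 12-point scan to maximize the minimum
    ligand-receptor heavy-atom distance (ties: first)."""
    target_position = np.asarray(target_position, dtype=float)
    target_direction = np.asarray(target_direction, dtype=float)
    target_direction = target_direction / np.linalg.norm(target_direction)

    coords = ligand.coords
    pivot = coords[lig_atom].copy()
    u = _mean_neighbor_direction(ligand, lig_atom)
    if u is None:
        rot = np.eye(3)
    else:
        rot = _rotation_between(u, target_direction)
    placed = (coords - pivot) @ rot.T + target_position

    if receptor is not None and ligand.n_atoms > 1:
        rec_heavy = receptor.coords[receptor.heavy_indices()]
        lig_heavy_idx = ligand.heavy_indices()
        best = None
        best_angle = 0.0
        for k in range(12):
            angle = 2.0 * np.pi * k / 12.0
            cand = (
                _rodrigues(placed - target_position, target_direction, angle)
                + target_position
            )
            dmin = float(
                np.linalg.norm(
                    cand[lig_heavy_idx][:, None, :] - rec_heavy[None, :, :], axis=2
                ).min()
            )
            if best is None or dmin > best + 1e-12:
                best = dmin
                best_angle = angle
        placed = (
            _rodrigues(placed - target_position, target_direction, best_angle)
            + target_position
        )

    return Pose(coordinates=placed, provenance={"covalent_lig_atom": int(lig_atom)})


def make_covalent_construct(
    receptor: TypedMolecule,
    ligand: TypedMolecule,
    ligand_pose: Pose,
    lig_atom: int,
    rec_atom: int,
    bond_order: int = 1,
) -> tuple[TypedMolecule, TorsionTree]:
    """Bond the placed ligand to the receptor atom and return the
    residue-ligand construct plus its torsion tree rooted at the residue
    backbone (so only side-chain and ligand torsions move).

    Construct atom order: the anchor residue's atoms in receptor order, then
    the ligand atoms in ligand order. Former ligand atoms keep is_ligand=True.
    """
    anchor = receptor.atoms[rec_atom]
    lig_coords = ligand_pose.coordinates
    target_len = anchor.covalent_radius + ligand.atoms[lig_atom].covalent_radius
    actual = float(np.linalg.norm(lig_coords[lig_atom] - anchor.position))
    if actual > 1.5 * target_len:
        raise InputError(
            f"covalent atoms are {actual:.2f} A apart (bond target "
            f"{target_len:.2f} A); place the ligand first"
        )

    residue_idx = [
        a.index
        for a in receptor.atoms
        if a.chain_id == anchor.chain_id
        and a.residue_number == anchor.residue_number
        and a.residue_name == anchor.residue_name
    ]
    # hydrogen reduction: drop one hydrogen bonded to the anchor, if present
    adj = receptor.adjacency()
    h_drop = next(
        (
            v
            for v in sorted(adj[rec_atom])
            if receptor.atoms[v].element == "H" and v in residue_idx
        ),
        None,
    )
    residue_idx = [i for i in residue_idx if i != h_drop]

    local = {orig: k for k, orig in enumerate(residue_idx)}
    atoms: list[AtomRecord] = []
    for orig in residue_idx:
        a = receptor.atoms[orig]
        atoms.append(replace(a, index=len(atoms), position=a.position.copy(),
                             is_ligand=False))
    offset = len(atoms)
    for a in ligand.atoms:
        atoms.append(
            replace(
                a,
                index=len(atoms),
                position=lig_coords[a.index].copy(),
                is_ligand=True,
            )
        )
    bonds = [
        (local[i], local[j], order)
        for i, j, order in receptor.bonds
        if i in local and j in local
    ]
    bonds += [(i + offset, j + offset, order) for i, j, order in ligand.bonds]
    bonds.append((local[rec_atom], lig_atom + offset, bond_order))

    construct = assign_atom_types(
        TypedMolecule(atoms=atoms, bonds=bonds, name="covalent_construct")
    )
    # root at the backbone: CA if present, else N, else the anchor atom itself
    names = {construct.atoms[k].atom_name: k for k in range(offset)}
    root = names.get("CA", names.get("N", local[rec_atom]))
    tree = build_torsion_tree(construct, root_atom=root)
    # the anchor atom itself must stay put (its coordinates are receptor
    # coordinates): drop torsions that would sweep it, keeping rotations about
    # bonds at or beyond the anchor
    rec_local = local[rec_atom]
    kept = tuple(t for t in tree.torsions if rec_local not in t.moving)
    tree = TorsionTree(root_atoms=tree.root_atoms, torsions=kept)
    return construct, tree


def _strip_residue(receptor: TypedMolecule, rec_atom: int) -> TypedMolecule:
    """Receptor without the anchor residue (whose atoms join the construct)."""
    anchor = receptor.atoms[rec_atom]
    keep = [
        a
        for a in receptor.atoms
        if not (
            a.chain_id == anchor.chain_id
            and a.residue_number == anchor.residue_number
            and a.residue_name == anchor.residue_name
        )
    ]
    remap = {a.index: k for k, a in enumerate(keep)}
    atoms = [replace(a, index=k, position=a.position.copy()) for k, a in enumerate(keep)]
    bonds = [
        (remap[i], remap[j], o)
        for i, j, o in receptor.bonds
        if i in remap and j in remap
    ]
    return TypedMolecule(atoms=atoms, bonds=bonds, name=receptor.name)


def relax_junction(
    construct: TypedMolecule, rec_local: int, lig_local: int, use_uff: bool = False
) -> None:
    """Bonded-geometry relaxation at the junction: restore the covalent bond
    length by translating the ligand-origin atoms along the bond axis. With
    ``use_uff`` an RDKit UFF optimization of the construct is attempted first
    (junction held by the force field); on failure it falls back silently to
    the bond-length adjustment."""
    if use_uff:
        try:
            from rdkit.Chem import AllChem

            mol = Chem.RWMol(construct.to_rdkit())
            mol.UpdatePropertyCache(strict=False)
            ff = AllChem.UFFGetMoleculeForceField(mol)
            for k in range(construct.n_atoms):
                if not construct.atoms[k].is_ligand:
                    ff.AddFixedPoint(k)
            ff.Minimize(maxIts=200)
            conf = mol.GetConformer()
            construct.set_coords(
                np.array(
                    [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
                )
            )
            construct._rdkit = None
        except Exception:
            warnings.warn("UFF refinement unavailable; using bond-length relaxation",
                          stacklevel=2)
    a = construct.atoms[rec_local]
    b = construct.atoms[lig_local]
    target = a.covalent_radius + b.covalent_radius
    axis = b.position - a.position
    nrm = float(np.linalg.norm(axis))
    if nrm < 1e-9:
        return
    shift = (target - nrm) * (axis / nrm)
    if abs(target - nrm) > 1e-9:
        coords = construct.coords
        lig_idx = [k for k in range(construct.n_atoms) if construct.atoms[k].is_ligand]
        coords[lig_idx] += shift
        construct.set_coords(coords)


def covalent_dock(
    receptor: TypedMolecule,
    ligand: TypedMolecule,
    spec: CovalentSpec,
    config: SamplerConfig | None = None,
    weights: TermWeights = DEFAULT_WEIGHTS,
) -> list[Pose]:
    """Dock covalently for every SMARTS-matched ligand atom; each pairing
    contributes up to num_modes poses, labeled via provenance
    ``covalent_pairing``. Returned pose coordinates cover the ligand atoms in
    input order; empirical scores are construct scores against the remaining
    receptor."""
    config = config or SamplerConfig()
    config = replace_config_covalent(config)
    lig_atoms = find_ligand_covalent_atoms(ligand, spec.ligand_smarts)
    rec_atom = locate_receptor_atom(receptor, spec.receptor_atom)
    rec_rest = _strip_residue(receptor, rec_atom)
    anchor = receptor.atoms[rec_atom]
    lig_maps = heavy_automorphisms(ligand)

    all_poses: list[Pose] = []
    for pairing_idx, lig_atom in enumerate(lig_atoms):
        if spec.explicit_position is not None:
            target_pos = np.asarray(spec.explicit_position, dtype=float)
            d = target_pos - anchor.position
            nrm = np.linalg.norm(d)
            direction = d / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        else:
            direction, target_pos = new_bond_vector(
                receptor, rec_atom, ligand.atoms[lig_atom].covalent_radius
            )
        placed = place_ligand(ligand, lig_atom, target_pos, direction, receptor)
        construct, tree = make_covalent_construct(
            receptor, ligand, placed, lig_atom, rec_atom, spec.bond_order
        )
        offset = construct.n_atoms - ligand.n_atoms
        rec_local = next(
            k
            for k in range(offset)
            if construct.atoms[k].atom_name == anchor.atom_name
            and not construct.atoms[k].is_ligand
        )
        lig_local = lig_atom + offset
        if spec.optimize_construct:
            relax_junction(construct, rec_local, lig_local, use_uff=True)

        if spec.fix_lig_atom:
            # rotations about bonds through the covalent atom keep it fixed;
            # only torsions that would sweep it are dropped
            kept = tuple(t for t in tree.torsions if lig_local not in t.moving)
            tree = TorsionTree(root_atoms=tree.root_atoms, torsions=kept)

        start = Pose(
            coordinates=construct.coords,
            provenance={
                "covalent_pairing": pairing_idx,
                "covalent_lig_atom": int(lig_atom),
            },
        )
        ctx = InteractionContext(rec_rest, construct, tree, weights)
        pool: list[Pose] = []
        for i in range(config.exhaustiveness):
            pool.extend(
                run_chain(
                    rec_rest,
                    construct,
                    start,
                    tree,
                    weights,
                    config,
                    (config.seed, pairing_idx * 1000 + i),
                    box=None,
                    context=ctx,
                )
            )
        pool.sort(key=lambda p: p.empirical_score)
        # diversity on the extracted ligand coordinates
        lig_poses = []
        for p in pool:
            lig_poses.append(
                Pose(
                    coordinates=p.coordinates[offset:],
                    empirical_score=p.empirical_score,
                    provenance=dict(p.provenance)
                    | {
                        "covalent_pairing": pairing_idx,
                        "covalent_lig_atom": int(lig_atom),
                        "rec_atom_position": tuple(
                            float(x) for x in anchor.position
                        ),
                    },
                )
            )
        kept = diversity_filter(
            lig_poses, ligand, config.min_pose_rmsd, config.num_modes, lig_maps
        )
        all_poses.extend(kept)
    return all_poses


def generate_toy_covalent_complex(
    seed: int,
    n_pocket_atoms: int = 40,
    ligand_spec: str = "butanethiol",
    smarts: str = "[SX2]",
) -> tuple[TypedMolecule, TypedMolecule, Pose]:
    """Deterministic covalent redocking fixture: the ligand is bound to the
    cysteine-like anchor (first SMARTS match, new-bond-vector placement) and a
    shape-complementary pocket is imprinted around that bound conformation, so
    the bound pose is the empirical-score optimum. Returns (receptor, ligand,
    reference); the returned ligand carries the reference coordinates (tests
    typically scramble its torsions before redocking)."""
    from .molio import (
        anchor_residue_atoms,
        build_torsion_tree as _btt,
        imprint_pocket_atoms,
        ligand_from_template,
    )

    rng = np.random.default_rng(seed)
    ligand = ligand_from_template(ligand_spec, seed=seed)
    lig_atom = find_ligand_covalent_atoms(ligand, smarts)[0]

    # randomize the bound conformer's torsions so each seed differs
    ltree = _btt(ligand)
    coords = ligand.coords
    for k in range(ltree.n_rotatable):
        coords = ltree.rotate(coords, k, float(rng.uniform(-np.pi, np.pi)))
    ligand.set_coords(coords)

    anchor_dir = rng.normal(size=3)
    anchor_dir /= np.linalg.norm(anchor_dir)
    atoms, bonds = anchor_residue_atoms(np.zeros(3), anchor_dir, 0)
    residue = assign_atom_types(
        TypedMolecule(atoms=atoms, bonds=bonds, name="anchor")
    )
    sg_idx = next(a.index for a in residue.atoms if a.atom_name == "SG")
    direction, target = new_bond_vector(
        residue, sg_idx, ligand.atoms[lig_atom].covalent_radius
    )
    bound = place_ligand(ligand, lig_atom, target, direction, residue)
    ligand.set_coords(bound.coordinates)

    n_shell = n_pocket_atoms - 4
    exclude = np.array([a.position for a in residue.atoms])
    placed = imprint_pocket_atoms(ligand, n_shell, rng, exclude_positions=exclude)

    rec_atoms: list[AtomRecord] = []
    for k, (element, pos) in enumerate(placed):
        rec_atoms.append(
            AtomRecord(
                index=len(rec_atoms),
                element=element,
                position=pos,
                chain_id="A",
                residue_number=str(k + 1),
                residue_name="SHL",
                atom_name=element,
            )
        )
    anchor_atoms, anchor_bonds = anchor_residue_atoms(
        np.zeros(3), anchor_dir, len(rec_atoms)
    )
    rec_atoms.extend(anchor_atoms)
    receptor = assign_atom_types(
        TypedMolecule(atoms=rec_atoms, bonds=anchor_bonds, name="toy_cov_pocket")
    )
    reference = Pose(
        coordinates=ligand.coords,
        provenance={
            "fixture_seed": int(seed),
            "ligand_spec": ligand_spec,
            "covalent_lig_atom": int(lig_atom),
        },
    )
    return receptor, ligand, reference


def replace_config_covalent(config: SamplerConfig) -> SamplerConfig:
    cfg = SamplerConfig(
        exhaustiveness=config.exhaustiveness,
        steps=config.steps,
        amplitude_translation=config.amplitude_translation,
        amplitude_rotation=config.amplitude_rotation,
        temperature=config.temperature,
        seed=config.seed,
        num_modes=config.num_modes,
        min_pose_rmsd=config.min_pose_rmsd,
        covalent_mode=True,
    )
    cfg.minimize.maxiter = config.minimize.maxiter
    cfg.minimize.gtol = config.minimize.gtol
    return cfg
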