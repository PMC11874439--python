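"""Molecular I/O, atom typing, torsion trees, and synthetic fixtures.

Coordinates are Angstrom; atom indices are 0-based internally; residue numbers
keep the author (1-based) numbering printed in the PDB, with insertion codes
appended, for user-facing addressing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial import cKDTree

from .elements import (
    HALOGENS,
    INTERACTION_TYPES,
    covalent_radius,
    vdw_radius,
)
from .errors import EmptyInputError, InputError, MolFormatError

WATER_RESNAMES = {"HOH", "WAT", "DOD", "TIP", "TIP3", "SOL"}


@dataclass
class AtomRecord:
    """One atom: element, position, interaction type, radii, provenance flags."""

    index: int
    element: str
    position: np.ndarray  # (3,) Angstrom
    interaction_type: str | None = None
    vdw_radius: float = 0.0
    covalent_radius: float = 0.0
    is_ligand: bool = False
    # residue metadata (receptors; optional for ligands)
    chain_id: str | None = None
    residue_number: str | None = None  # author numbering, insertion code appended
    residue_name: str | None = None
    atom_name: str | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.vdw_radius == 0.0:
            self.vdw_radius = vdw_radius(self.element)
        if self.covalent_radius == 0.0:
            self.covalent_radius = covalent_radius(self.element)


@dataclass
class TypedMolecule:
    """Atoms + bonds + coordinates, with optional cached RDKit mol."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    name: str = ""
    _rdkit: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise InputError(f"bond ({i},{j}) has invalid endpoints")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise InputError(f"duplicate bond {key}")
            seen.add(key)

    # -- basic views ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        for a, p in zip(self.atoms, coords):
            a.position = p.copy()

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [a.index for a in self.atoms if a.element != "H"], dtype=int
        )

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.atoms]
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def copy(self) -> "TypedMolecule":
        return TypedMolecule(
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            bonds=list(self.bonds),
            name=self.name,
            _rdkit=self._rdkit,
        )

    # -- RDKit bridge -----------------------------------------------------
    def to_rdkit(self) -> Chem.Mol:
        """RDKit mol for SMARTS matching and automorphism enumeration.

        Returns the cached source mol when the molecule came from RDKit and
        still has the same atom count; otherwise rebuilds from atoms/bonds with
        lenient sanitization.
        """
        if self._rdkit is not None and self._rdkit.GetNumAtoms() == self.n_atoms:
            return self._rdkit
        em = Chem.RWMol()
        for a in self.atoms:
            at = Chem.Atom(a.element)
            at.SetNoImplicit(True)
            em.AddAtom(at)
        order_map = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
        }
        for i, j, order in self.bonds:
            em.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
        mol = em.GetMol()
        conf = Chem.Conformer(self.n_atoms)
        for k, a in enumerate(self.atoms):
            conf.SetAtomPosition(k, tuple(float(x) for x in a.position))
        mol.AddConformer(conf)
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            mol.UpdatePropertyCache(strict=False)
            Chem.FastFindRings(mol)
        self._rdkit = mol
        return mol


@dataclass
class Pose:
    """One ligand conformation with provenance and scores (lower empirical
    score is better; cnn_pose_score is a probability; cnn_affinity is pK)."""

    coordinates: np.ndarray
    empirical_score: float | None = None
    cnn_pose_score: float | None = None
    cnn_affinity: float | None = None
    rmsd_to_reference: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("pose coordinates must be finite")
        if self.cnn_pose_score is not None and not (
            0.0 <= self.cnn_pose_score <= 1.0
        ):
            raise ValueError("cnn_pose_score must lie in [0, 1]")

    def copy(self) -> "Pose":
        return Pose(
            coordinates=self.coordinates.copy(),
            empirical_score=self.empirical_score,
            cnn_pose_score=self.cnn_pose_score,
            cnn_affinity=self.cnn_affinity,
            rmsd_to_reference=self.rmsd_to_reference,
            provenance=dict(self.provenance),
        )


@dataclass(frozen=True)
class Torsion:
    axis: tuple[int, int]  # (a, b): a on the root side
    moving: tuple[int, ...]  # atoms whose coordinates change (b's side)


@dataclass(frozen=True)
class TorsionTree:
    """Rigid root fragment plus rotatable bonds with disjoint moving sets."""

    root_atoms: tuple[int, ...]
    torsions: tuple[Torsion, ...]

    @property
    def n_rotatable(self) -> int:
        return len(self.torsions)

    def rotate(self, coords: np.ndarray, k: int, angle: float) -> np.ndarray:
        """Rotate torsion ``k`` by ``angle`` (radians); returns new coords."""
        t = self.torsions[k]
        a, b = t.axis
        out = coords.copy()
        axis = coords[b] - coords[a]
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            return out
        axis = axis / norm
        moving = np.asarray(t.moving, dtype=int)
        rel = coords[moving] - coords[a]
        out[moving] = coords[a] + _rodrigues(rel, axis, angle)
        return out

    def apply_angles(self, coords: np.ndarray, angles: np.ndarray) -> np.ndarray:
        out = coords
        for k, ang in enumerate(angles):
            if ang != 0.0:
                out = self.rotate(out, k, float(ang))
        return out


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    cross = np.cross(axis, v)
    dot = v @ axis
    return v * c + cross * s + np.outer(dot, axis) * (1 - c)


# ---------------------------------------------------------------------------
# atom typing
# ---------------------------------------------------------------------------

def assign_atom_types(mol: TypedMolecule) -> TypedMolecule:
    """Assign the reduced 13-type interaction vocabulary from elements+bonds.

    Carbon bonded only to carbon/hydrogen is HydrophobicC; N/O donor/acceptor
    status comes from bonded hydrogens (a structure without explicit hydrogens
    types its N/O as plain acceptors). Idempotent.
    """
    adj = mol.adjacency()
    for a in mol.atoms:
        el = a.element
        neigh_elems = [mol.atoms[j].element for j in adj[a.index]]
        n_h = sum(1 for e in neigh_elems if e == "H")
        n_heavy = len(neigh_elems) - n_h
        if el == "H":
            a.interaction_type = "H"
        elif el == "C":
            a.interaction_type = (
                "HydrophobicC"
                if all(e in ("C", "H") for e in neigh_elems)
                else "NonHydrophobicC"
            )
        elif el == "N":
            if n_h >= 1:
                a.interaction_type = "DonorN" if n_heavy >= 2 else "DonorAcceptorN"
            else:
                a.interaction_type = "AcceptorN"
        elif el == "O":
            a.interaction_type = "DonorAcceptorO" if n_h >= 1 else "AcceptorO"
        elif el == "S":
            a.interaction_type = "S"
        elif el == "P":
            a.interaction_type = "P"
        elif el in HALOGENS:
            a.interaction_type = "Halogen"
        else:
            if el not in ("Na", "Mg", "K", "Ca", "Mn", "Fe", "Co", "Ni", "Cu", "Zn"):
                warnings.warn(
                    f"unknown element {el!r}: typed as Metal", stacklevel=2
                )
            a.interaction_type = "Metal"
        assert a.interaction_type in INTERACTION_TYPES
    return mol


# ---------------------------------------------------------------------------
# torsion tree construction
# ---------------------------------------------------------------------------

def _bridge_bonds(n: int, bonds: list[tuple[int, int, int]]) -> set[tuple[int, int]]:
    """Bonds not in any ring (bridges), via iterative Tarjan DFS."""
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for eid, (i, j, _) in enumerate(bonds):
        adj[i].append((j, eid))
        adj[j].append((i, eid))
    disc = [-1] * n
    low = [0] * n
    bridges: set[tuple[int, int]] = set()
    timer = 0
    for start in range(n):
        if disc[start] != -1:
            continue
        stack = [(start, -1, iter(adj[start]))]
        disc[start] = low[start] = timer
        timer += 1
        while stack:
            u, pe, it = stack[-1]
            advanced = False
            for v, eid in it:
                if eid == pe:
                    continue
                if disc[v] == -1:
                    disc[v] = low[v] = timer
                    timer += 1
                    stack.append((v, eid, iter(adj[v])))
                    advanced = True
                    break
                low[u] = min(low[u], disc[v])
            if not advanced:
                stack.pop()
                if stack:
                    pu = stack[-1][0]
                    low[pu] = min(low[pu], low[u])
                    if low[u] > disc[pu]:
                        i, j = bonds[pe][0], bonds[pe][1]
                        bridges.add((min(i, j), max(i, j)))
    return bridges


def build_torsion_tree(
    mol: TypedMolecule, root_atom: int | None = None
) -> TorsionTree:
    """Rotatable bonds = acyclic single bonds with a heavy substituent beyond
    the axis on both sides. Root = largest rigid fragment unless ``root_atom``
    forces the fragment containing it (covalent mode roots at the anchor)."""
    n = mol.n_atoms
    adj = mol.adjacency()
    # connectivity check over the full graph
    if n == 0:
        raise EmptyInputError("molecule has no atoms")
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if len(seen) != n:
        raise InputError("disconnected molecular graph")

    is_heavy = [a.element != "H" for a in mol.atoms]
    bridges = _bridge_bonds(n, mol.bonds)

    def heavy_substituent(axis_atom: int, other: int) -> bool:
        return any(
            is_heavy[v] for v in adj[axis_atom] if v != other
        )

    rotatable: list[tuple[int, int]] = []
    for i, j, order in mol.bonds:
        key = (min(i, j), max(i, j))
        if order != 1 or key not in bridges:
            continue
        if not (is_heavy[i] and is_heavy[j]):
            continue
        if heavy_substituent(i, j) and heavy_substituent(j, i):
            rotatable.append(key)

    rot_set = set(rotatable)
    # fragments: components after cutting rotatable bonds
    frag_id = [-1] * n
    nfrag = 0
    for s in range(n):
        if frag_id[s] != -1:
            continue
        frag_id[s] = nfrag
        stack = [s]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if (min(u, v), max(u, v)) in rot_set:
                    continue
                if frag_id[v] == -1:
                    frag_id[v] = nfrag
                    stack.append(v)
        nfrag += 1

    frag_atoms: list[list[int]] = [[] for _ in range(nfrag)]
    for a in range(n):
        frag_atoms[frag_id[a]].append(a)

    if root_atom is not None:
        root_frag = frag_id[root_atom]
    else:
        root_frag = max(
            range(nfrag),
            key=lambda f: (sum(1 for a in frag_atoms[f] if is_heavy[a]),
                           -min(frag_atoms[f])),
        )

    def side_component(src: int, cut: tuple[int, int]) -> set[int]:
        comp = {src}
        stack = [src]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if {u, v} == set(cut):
                    continue
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        return comp

    root_rep = frag_atoms[root_frag][0]
    torsions: list[Torsion] = []
    for (i, j) in rotatable:
        comp_j = side_component(j, (i, j))
        if root_rep in comp_j:
            a, b = j, i
            comp = side_component(i, (i, j))
        else:
            a, b = i, j
            comp = comp_j
        # axis atom b stays fixed under rotation about (a, b)
        torsions.append(Torsion(axis=(a, b), moving=tuple(sorted(comp - {a, b}))))

    torsions.sort(key=lambda t: t.axis)
    return TorsionTree(
        root_atoms=tuple(sorted(frag_atoms[root_frag])),
        torsions=tuple(torsions),
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_bonds(atoms: list[AtomRecord]) -> list[tuple[int, int, int]]:
    """Distance-based single bonds: d < r_cov(i) + r_cov(j) + 0.45 A."""
    if not atoms:
        return []
    pos = np.array([a.position for a in atoms])
    rcov = np.array([a.covalent_radius for a in atoms])
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=float(2 * rcov.max() + 0.45))
    bonds = []
    for i, j in sorted(pairs):
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if 0.4 < d < rcov[i] + rcov[j] + 0.45:
            bonds.append((i, j, 1))
    return bonds


def read_receptor(path: str, exclude_waters: bool = True) -> TypedMolecule:
    """Read a PDB receptor; altLocs resolved to highest occupancy (ties: first
    seen); waters excluded by default; bonds inferred from covalent radii."""
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("receptor", path)
    except Exception as exc:  # pragma: no cover - parser detail
        raise MolFormatError(f"cannot parse PDB {path}: {exc}") from exc

    atoms: list[AtomRecord] = []
    model = next(structure.get_models(), None)
    if model is None:
        raise EmptyInputError(f"no models in PDB {path}")
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            if exclude_waters and resname in WATER_RESNAMES:
                continue
            het, resseq, icode = residue.get_id()
            resnum = f"{resseq}{icode.strip()}"
            for atom in residue:
                if atom.is_disordered():
                    alts = atom.disordered_get_list()
                    best = max(
                        range(len(alts)),
                        key=lambda k: (alts[k].get_occupancy() or 0.0, -k),
                    )
                    atom = alts[best]
                element = (atom.element or "").strip().capitalize() or "C"
                atoms.append(
                    AtomRecord(
                        index=len(atoms),
                        element=element,
                        position=np.asarray(atom.get_coord(), dtype=float),
                        chain_id=chain.id,
                        residue_number=resnum,
                        residue_name=resname,
                        atom_name=atom.get_name(),
                    )
                )
    if not atoms:
        raise EmptyInputError(f"no ATOM/HETATM records read from {path}")
    mol = TypedMolecule(atoms=atoms, bonds=_infer_bonds(atoms), name="receptor")
    return assign_atom_types(mol)


def typed_from_rdkit(
    mol: Chem.Mol, is_ligand: bool = True, name: str = ""
) -> TypedMolecule:
    """Convert an RDKit mol (with a 3D conformer) to a TypedMolecule."""
    if mol.GetNumConformers() == 0:
        raise MolFormatError("molecule has no conformer")
    conf = mol.GetConformer()
    atoms = []
    for i, at in enumerate(mol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        atoms.append(
            AtomRecord(
                index=i,
                element=at.GetSymbol(),
                position=np.array([p.x, p.y, p.z]),
                is_ligand=is_ligand,
            )
        )
    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            max(1, int(round(b.GetBondTypeAsDouble()))),
        )
        for b in mol.GetBonds()
    ]
    out = TypedMolecule(
        atoms=atoms, bonds=bonds, name=name or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
        _rdkit=mol,
    )
    return assign_atom_types(out)


def read_ligands(path: str) -> list[TypedMolecule]:
    """Read an SDF (or MOL2) ligand file; corrupt records are skipped with a
    warning; 2D-only records warn but are returned."""
    mols: list[TypedMolecule] = []
    if path.lower().endswith(".mol2"):
        m = Chem.MolFromMol2File(path, removeHs=False)
        records = [m] if m is not None else [None]
    else:
        try:
            supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=True)
        except OSError as exc:
            import os

            if os.path.exists(path) and os.path.getsize(path) == 0:
                return []
            raise MolFormatError(str(exc)) from exc
        records = list(supplier)
    for k, m in enumerate(records):
        if m is None:
            warnings.warn(f"skipping unparseable record {k} in {path}", stacklevel=2)
            continue
        if m.GetNumConformers() == 0:
            warnings.warn(f"record {k} has no coordinates; skipped", stacklevel=2)
            continue
        if not m.GetConformer().Is3D():
            warnings.warn(f"record {k} has 2D-only coordinates", stacklevel=2)
        mols.append(typed_from_rdkit(m, is_ligand=True))
    return mols


SDF_TAG_SCORE = "minimizedAffinity"
SDF_TAG_CNNSCORE = "CNNscore"
SDF_TAG_CNNAFFINITY = "CNNaffinity"
SDF_TAG_PAIRING = "covalent_pairing"


def write_poses_sdf(ligand: TypedMolecule, poses: list[Pose], path: str) -> None:
    """Write one SDF record per pose, tagged with minimizedAffinity / CNNscore /
    CNNaffinity (gnina-compatible tag names) and covalent_pairing when set."""
    template = Chem.Mol(ligand.to_rdkit())
    writer = Chem.SDWriter(path)
    writer.SetKekulize(False)
    try:
        for pose in poses:
            m = Chem.Mol(template)
            conf = m.GetConformer()
            for i in range(m.GetNumAtoms()):
                x, y, z = (float(v) for v in pose.coordinates[i])
                conf.SetAtomPosition(i, (x, y, z))
            if pose.empirical_score is not None:
                m.SetProp(SDF_TAG_SCORE, f"{pose.empirical_score:.6f}")
            if pose.cnn_pose_score is not None:
                m.SetProp(SDF_TAG_CNNSCORE, f"{pose.cnn_pose_score:.6f}")
            if pose.cnn_affinity is not None:
                m.SetProp(SDF_TAG_CNNAFFINITY, f"{pose.cnn_affinity:.6f}")
            pairing = pose.provenance.get("covalent_pairing")
            if pairing is not None:
                m.SetProp(SDF_TAG_PAIRING, str(pairing))
            writer.write(m)
    finally:
        writer.close()


def write_receptor_pdb(receptor: TypedMolecule, path: str) -> None:
    """Write receptor atoms as PDB ATOM records (fixture/debug output)."""
    with open(path, "w") as fh:
        for a in receptor.atoms:
            resnum = a.residue_number or "1"
            icode = " "
            if resnum and not resnum[-1].isdigit():
                resnum, icode = resnum[:-1], resnum[-1]
            name = (a.atom_name or a.element)[:4]
            fh.write(
                f"ATOM  {a.index + 1:>5d} {name:<4s} {(a.residue_name or 'UNK'):<3s} "
                f"{(a.chain_id or 'A')[:1]}{int(resnum):>4d}{icode}   "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")


def write_molecules_sdf(mols: list[TypedMolecule], path: str) -> None:
    writer = Chem.SDWriter(path)
    writer.SetKekulize(False)
    try:
        for tm in mols:
            m = Chem.Mol(tm.to_rdkit())
            conf = m.GetConformer()
            for i in range(m.GetNumAtoms()):
                x, y, z = (float(v) for v in tm.atoms[i].position)
                conf.SetAtomPosition(i, (x, y, z))
            writer.write(m)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

LIGAND_TEMPLATES = {
    "methane": "C",
    "ethane": "CC",
    "butane": "CCCC",
    "benzene": "c1ccccc1",
    "biphenyl": "c1ccc(-c2ccccc2)cc1",
    "ethanol": "CCO",
    "propanol": "CCCO",
    "methanethiol": "CS",
    "ethanethiol": "CCS",
    "butanethiol": "CCCCS",
    "dimethyl_disulfide": "CSSC",
    "acetamide": "CC(N)=O",
    "toluene": "Cc1ccccc1",
}


def ligand_from_template(ligand_spec: str, seed: int = 0) -> TypedMolecule:
    """Embed a named small-molecule template into 3D, centered at the origin."""
    if ligand_spec not in LIGAND_TEMPLATES:
        raise InputError(
            f"unknown ligand template {ligand_spec!r}; "
            f"choose from {sorted(LIGAND_TEMPLATES)}"
        )
    mol = Chem.MolFromSmiles(LIGAND_TEMPLATES[ligand_spec])
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1) or 1
    AllChem.EmbedMolecule(mol, params)
    AllChem.MMFFOptimizeMolecule(mol)
    tm = typed_from_rdkit(mol, is_ligand=True, name=ligand_spec)
    heavy = tm.heavy_indices()
    centroid = tm.coords[heavy].mean(axis=0)
    tm.set_coords(tm.coords - centroid)
    return tm


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    y = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - y * y))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), y, r * np.sin(theta)])


def imprint_pocket_atoms(
    ligand: TypedMolecule,
    n_shell: int,
    rng: np.random.Generator,
    exclude_positions: np.ndarray | None = None,
) -> list[tuple[str, np.ndarray]]:
    """Place ``n_shell`` receptor atoms complementary to the ligand's current
    pose: a contact layer at zero surface distance (carbon against apolar
    atoms, oxygen against polar ones), then outer layers at +3/+6 A once the
    surface saturates. Positions clashing with the ligand, with
    ``exclude_positions`` or with already placed atoms are rejected."""
    heavy = ligand.heavy_indices()
    lpos = ligand.coords[heavy]
    lvdw = np.array([ligand.atoms[int(k)].vdw_radius for k in heavy])
    lelem = [ligand.atoms[int(k)].element for k in heavy]
    placed: list[tuple[str, np.ndarray]] = []
    for layer_offset in (0.0, 3.0, 6.0):
        attempts = 0
        while len(placed) < n_shell and attempts < 200 * n_shell:
            attempts += 1
            j = int(rng.integers(len(heavy)))
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            element = "O" if lelem[j] in ("N", "O") else "C"
            r_el = vdw_radius(element)
            pos = lpos[j] + d * (lvdw[j] + r_el + layer_offset)
            d_surf = np.linalg.norm(lpos - pos, axis=1) - (lvdw + r_el)
            if d_surf.min() < -0.05 + layer_offset * 0.9:
                continue
            if exclude_positions is not None and np.linalg.norm(
                exclude_positions - pos, axis=1
            ).min() < 3.0:
                continue
            if placed and min(
                float(np.linalg.norm(pos - q)) for _, q in placed
            ) < 2.4:
                continue
            placed.append((element, pos))
        if len(placed) >= n_shell:
            break
    if len(placed) < n_shell:
        warnings.warn(
            f"placed only {len(placed)} of {n_shell} pocket atoms", stacklevel=2
        )
    return placed


def anchor_residue_atoms(
    sg: np.ndarray, anchor_dir: np.ndarray, start_index: int
) -> tuple[list[AtomRecord], list[tuple[int, int, int]]]:
    """Cysteine-like anchor residue (chain A, residue 145, atoms N/CA/CB/SG)
    with SG at ``sg`` and the backbone receding along ``anchor_dir``."""
    ortho = np.cross(anchor_dir, [0.0, 0.0, 1.0])
    if np.linalg.norm(ortho) < 1e-6:
        ortho = np.cross(anchor_dir, [0.0, 1.0, 0.0])
    ortho = ortho / np.linalg.norm(ortho)
    cb = sg + 1.81 * anchor_dir
    ca = cb + 1.53 * (0.77 * anchor_dir + 0.64 * ortho)
    nn = ca + 1.46 * (0.6 * anchor_dir - 0.8 * ortho)
    specs = [("N", "N", nn), ("CA", "C", ca), ("CB", "C", cb), ("SG", "S", sg)]
    atoms = [
        AtomRecord(
            index=start_index + k,
            element=element,
            position=np.asarray(pos, dtype=float),
            chain_id="A",
            residue_number="145",
            residue_name="CYS",
            atom_name=atom_name,
        )
        for k, (atom_name, element, pos) in enumerate(specs)
    ]
    bonds = [
        (start_index, start_index + 1, 1),      # N-CA
        (start_index + 1, start_index + 2, 1),  # CA-CB
        (start_index + 2, start_index + 3, 1),  # CB-SG
    ]
    return atoms, bonds


def generate_toy_complex(
    seed: int,
    n_pocket_atoms: int = 50,
    ligand_spec: str = "butane",
) -> tuple[TypedMolecule, TypedMolecule, Pose]:
    """Deterministic toy complex: a shape-complementary pocket imprinted
    around a ground-truth ligand pose.

    Each pocket atom is placed at zero surface distance from a randomly chosen
    ligand heavy atom (carbon against apolar ligand atoms, oxygen against
    polar ones), rejecting positions that would clash with the rest of the
    ligand or crowd other pocket atoms. The reference pose therefore sits in a
    deep, sharp minimum of the empirical score, and displaced poses clash. One
    cysteine-like residue (chain A, residue 145, atoms N/CA/CB/SG) is added
    with its SG on the pocket rim as a covalent anchor. ``n_pocket_atoms``
    counts receptor heavy atoms including the 4-atom anchor residue.
    """
    if n_pocket_atoms < 12:
        warnings.warn("n_pocket_atoms clamped to 12", stacklevel=2)
        n_pocket_atoms = 12
    rng = np.random.default_rng(seed)
    ligand = ligand_from_template(ligand_spec, seed=seed)

    # random rigid jiggle so each seed's ground truth is distinct
    angle = float(rng.uniform(0, 2 * math.pi))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    coords = _rodrigues(ligand.coords, axis, angle)
    coords += rng.normal(scale=0.05, size=3)
    ligand.set_coords(coords)

    heavy = ligand.heavy_indices()
    lpos = ligand.coords[heavy]

    # cysteine-like anchor on the pocket rim, SG pointing at the cavity
    centroid = lpos.mean(axis=0)
    lig_extent = float(np.linalg.norm(lpos - centroid, axis=1).max())
    anchor_dir = rng.normal(size=3)
    anchor_dir /= np.linalg.norm(anchor_dir)
    sg = centroid + (lig_extent + 3.5) * anchor_dir

    n_shell = n_pocket_atoms - 4
    anchor_atoms, _ = anchor_residue_atoms(sg, anchor_dir, 0)
    exclude = np.array([a.position for a in anchor_atoms])
    placed = imprint_pocket_atoms(ligand, n_shell, rng, exclude_positions=exclude)

    atoms: list[AtomRecord] = []
    for k, (element, pos) in enumerate(placed):
        atoms.append(
            AtomRecord(
                index=len(atoms),
                element=element,
                position=pos,
                chain_id="A",
                residue_number=str(k + 1),
                residue_name="SHL",
                atom_name=element,
            )
        )
    anchor_atoms, anchor_bonds = anchor_residue_atoms(sg, anchor_dir, len(atoms))
    atoms.extend(anchor_atoms)
    receptor = assign_atom_types(
        TypedMolecule(atoms=atoms, bonds=anchor_bonds, name="toy_pocket")
    )

    reference = Pose(
        coordinates=ligand.coords,
        provenance={"fixture_seed": int(seed), "ligand_spec": ligand_spec},
    )
    return receptor, ligand, reference
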