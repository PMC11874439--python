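"""Monte Carlo pose sampling.

Each chain repeats mutate -> local minimize -> Metropolis accept. A mutation
is one move drawn uniformly from {translation, rigid rotation, single torsion
change}; in covalent mode only torsion moves are drawn (the construct is a
flexible residue, so no rigid-body transformations). Multiple independent
chains ("exhaustiveness") are pooled, sorted by score, and greedily filtered
for mutual diversity before the top num_modes poses are returned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import SamplingError
from .metrics import heavy_automorphisms, symmetry_rmsd
from .molio import Pose, TorsionTree, TypedMolecule, _rodrigues
from .scoring import (
    DEFAULT_WEIGHTS,
    InteractionContext,
    MinimizeConfig,
    TermWeights,
    local_minimize,
)


@dataclass(frozen=True)
class Box:
    """Axis-aligned search box (center and edge lengths, Angstrom)."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def contains(self, point: np.ndarray) -> bool:
        c = np.asarray(self.center)
        s = np.asarray(self.size) / 2.0
        return bool(np.all(np.abs(np.asarray(point) - c) <= s + 1e-9))

    @classmethod
    def around_ligand(cls, coords: np.ndarray, margin: float = 4.0) -> "Box":
        """Reference-ligand extents plus ``margin`` per side."""
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        center = (lo + hi) / 2.0
        size = (hi - lo) + 2.0 * margin
        return cls(center=tuple(map(float, center)), size=tuple(map(float, size)))


@dataclass
class SamplerConfig:
    exhaustiveness: int = 8
    steps: int = 200
    amplitude_translation: float = 2.0  # Angstrom
    amplitude_rotation: float = math.pi  # radians
    temperature: float = 1.2  # score units (Vina lineage)
    seed: int = 0
    num_modes: int = 9
    min_pose_rmsd: float = 1.0
    covalent_mode: bool = False
    minimize: MinimizeConfig = field(default_factory=MinimizeConfig)

    def __post_init__(self):
        if self.exhaustiveness < 1 or self.steps < 0 or self.temperature <= 0:
            raise SamplingError("invalid sampler configuration")
        self.minimize.covalent_mode = self.covalent_mode


def mutate_pose(
    pose: Pose,
    torsion_tree: TorsionTree | None,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> Pose:
    """Apply exactly one random move to a copy of the pose."""
    n_rot = torsion_tree.n_rotatable if torsion_tree else 0
    if config.covalent_mode:
        moves = ["torsion"] if n_rot > 0 else []
        if not moves:
            warnings.warn(
                "covalent mode with no rotatable bonds: pose unchanged",
                stacklevel=2,
            )
            return pose.copy()
    else:
        moves = ["translation", "rotation"] + (["torsion"] if n_rot > 0 else [])
    move = moves[int(rng.integers(len(moves)))]
    coords = pose.coordinates.copy()
    if move == "translation":
        direction = rng.normal(size=3)
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        step = config.amplitude_translation * rng.random() ** (1.0 / 3.0)
        coords = coords + direction * step
    elif move == "rotation":
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = float(rng.uniform(-config.amplitude_rotation, config.amplitude_rotation))
        centroid = coords.mean(axis=0)
        coords = _rodrigues(coords - centroid, axis, angle) + centroid
    else:
        k = int(rng.integers(n_rot))
        angle = float(rng.uniform(-math.pi, math.pi))
        coords = torsion_tree.rotate(coords, k, angle)
    return Pose(coordinates=coords, provenance=dict(pose.provenance))


def metropolis_accept(
    delta_score: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Accept with probability min(1, exp(-delta/T))."""
    if temperature <= 0:
        raise SamplingError("temperature must be positive")
    if delta_score <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_score / temperature))


def _chain_rng(seed: int, chain_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(chain_index),))
    )


def run_chain(
    receptor: TypedMolecule,
    ligand: TypedMolecule,
    start_pose: Pose,
    torsion_tree: TorsionTree | None,
    weights: TermWeights,
    config: SamplerConfig,
    chain_seed: tuple[int, int],
    box: Box | None = None,
    context: InteractionContext | None = None,
    rng: np.random.Generator | None = None,
) -> list[Pose]:
    """One MCMC chain: mutate -> minimize -> Metropolis; records accepted
    in-box minimized poses. Deterministic for a fixed chain seed (an already
    advanced generator may be passed to continue a stream)."""
    ctx = context or InteractionContext(receptor, ligand, torsion_tree, weights)
    rng = rng or _chain_rng(*chain_seed)
    if box is not None and not box.contains(start_pose.coordinates.mean(axis=0)):
        raise SamplingError("start pose outside the search box")

    current = local_minimize(
        receptor, ligand, start_pose, torsion_tree, weights, config.minimize, ctx
    )
    label = f"chain{chain_seed[1]}"
    current.provenance.setdefault("chain", label)
    recorded: list[Pose] = [current]

    for _ in range(config.steps):
        candidate = mutate_pose(current, torsion_tree, config, rng)
        candidate = local_minimize(
            receptor, ligand, candidate, torsion_tree, weights, config.minimize, ctx
        )
        in_box = box is None or box.contains(candidate.coordinates.mean(axis=0))
        delta = candidate.empirical_score - current.empirical_score
        if in_box and metropolis_accept(delta, config.temperature, rng):
            current = candidate
            current.provenance["chain"] = label
            recorded.append(current)

    recorded.sort(key=lambda p: p.empirical_score)
    return recorded[: max(config.num_modes * 4, 8)]


def diversity_filter(
    poses: list[Pose],
    ligand: TypedMolecule,
    min_rmsd: float,
    num_modes: int,
    maps: np.ndarray | None = None,
) -> list[Pose]:
    """Greedy: walk poses best-first, keep those > min_rmsd (symmetry-corrected
    heavy-atom RMSD) from everything already kept; truncate to num_modes."""
    if maps is None:
        maps = heavy_automorphisms(ligand)
    kept: list[Pose] = []
    for pose in poses:
        if all(
            symmetry_rmsd(pose, k, ligand, maps) > min_rmsd for k in kept
        ):
            kept.append(pose)
        if len(kept) >= num_modes:
            break
    return kept


def random_start_pose(
    ligand: TypedMolecule, box: Box, rng: np.random.Generator
) -> Pose:
    """Random rigid placement of the ligand inside the box."""
    coords = ligand.coords
    centroid = coords.mean(axis=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = float(rng.uniform(0, 2 * math.pi))
    coords = _rodrigues(coords - centroid, axis, angle)
    c = np.asarray(box.center)
    half = np.asarray(box.size) / 2.0
    target = c + rng.uniform(-1.0, 1.0, size=3) * half * 0.5
    return Pose(coordinates=coords + target)


def run_docking(
    receptor: TypedMolecule,
    ligand: TypedMolecule,
    box: Box,
    weights: TermWeights = DEFAULT_WEIGHTS,
    config: SamplerConfig | None = None,
    torsion_tree: TorsionTree | None = None,
) -> list[Pose]:
    """Pool exhaustiveness-many chains, sort by empirical score, apply the
    diversity filter, truncate to num_modes. Returns [] (with a warning) if no
    in-box pose was found."""
    config = config or SamplerConfig()
    ctx = InteractionContext(receptor, ligand, torsion_tree, weights)
    maps = heavy_automorphisms(ligand)
    pool: list[Pose] = []
    for i in range(config.exhaustiveness):
        rng = _chain_rng(config.seed, i)
        start = random_start_pose(ligand, box, rng)
        try:
            pool.extend(
                run_chain(
                    receptor,
                    ligand,
                    start,
                    torsion_tree,
                    weights,
                    config,
                    (config.seed, i),
                    box,
                    ctx,
                    rng,
                )
            )
        except SamplingError:
            continue
    pool = [p for p in pool if box.contains(p.coordinates.mean(axis=0))]
    if not pool:
        warnings.warn("no in-box pose found", stacklevel=2)
        return []
    pool.sort(key=lambda p: p.empirical_score)
    return diversity_filter(pool, ligand, config.min_pose_rmsd, config.num_modes, maps)
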