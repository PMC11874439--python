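"""End-to-end docking orchestration.

Workflow: Monte Carlo sampling under the empirical score, local minimization,
optional CNN rescoring (pose ranking by CNNscore; coordinates are never
altered by rescoring), output as tagged SDF plus a JSON summary. Covalent
jobs route through the covalent module. Screening docks a multi-record
library and reports each compound's best pose score.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd

from .cnn_models import GridScorer, ensemble_score, load_checkpoint
from .covalent import CovalentSpec, covalent_dock
from .errors import InputError, MinidockError
from .gridder import GridSpec, compact_channel_map, default_channel_map, voxelize
from .molio import (
    Pose,
    TypedMolecule,
    build_torsion_tree,
    read_ligands,
    read_receptor,
    write_poses_sdf,
)
from .sampler import Box, SamplerConfig, run_docking
from .scoring import DEFAULT_WEIGHTS

CNN_MODES = ("ensemble", "fast", "none")
CNN_SCORING_MODES = ("rescore", "none", "refinement")


@dataclass
class JobConfig:
    receptor_path: str = ""
    ligand_path: str = ""
    box: Box | None = None
    autobox_ligand: str | None = None
    autobox_margin: float = 4.0
    cnn: str = "none"
    cnn_scoring: str = "rescore"
    cnn_checkpoints: list[str] = field(default_factory=list)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    covalent: CovalentSpec | None = None
    out_sdf: str = "poses.sdf"
    out_json: str | None = None
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if self.cnn not in CNN_MODES:
            raise InputError(f"cnn mode must be one of {CNN_MODES}")
        if self.cnn_scoring not in CNN_SCORING_MODES:
            raise InputError(
                f"cnn_scoring must be one of {CNN_SCORING_MODES}"
            )
        self.sampler.seed = self.seed


def _resolve_box(config: JobConfig, ligand: TypedMolecule) -> Box:
    if config.box is not None and config.autobox_ligand:
        raise InputError("specify either an explicit box or --autobox_ligand")
    if config.box is not None:
        return config.box
    if config.autobox_ligand:
        ref = read_ligands(config.autobox_ligand)
        if not ref:
            raise InputError(f"no reference ligand in {config.autobox_ligand}")
        return Box.around_ligand(ref[0].coords, margin=config.autobox_margin)
    raise InputError("no search box: give --center/--size or --autobox_ligand")


def load_cnn_models(config: JobConfig) -> list[GridScorer]:
    if config.cnn == "none":
        return []
    if not config.cnn_checkpoints:
        raise InputError(
            f"cnn={config.cnn} needs trained checkpoints (--cnn_weights); "
            "train with minidock-train / minidock-distill"
        )
    models = [load_checkpoint(p) for p in config.cnn_checkpoints]
    if config.cnn == "fast" and len(models) != 1:
        raise InputError("cnn=fast uses exactly one (distilled) checkpoint")
    return models


def grid_spec_for_model(model: GridScorer) -> GridSpec:
    """Grid geometry matching a checkpoint: the compact 8-channel map at 1 A
    is the desk-scale training layout; 26 channels means the full 0.5 A map."""
    if model.spec.n_channels == 8:
        return GridSpec(
            resolution=1.0,
            points_per_side=model.spec.grid_points,
            channel_map=compact_channel_map(),
        )
    return GridSpec(
        resolution=0.5,
        points_per_side=model.spec.grid_points,
        channel_map=default_channel_map(),
    )


def cnn_rescore(
    receptor: TypedMolecule,
    ligand: TypedMolecule,
    poses: list[Pose],
    models: list[GridScorer],
    center: tuple[float, float, float],
) -> list[Pose]:
    """Attach CNNscore/CNNaffinity to each pose and re-rank by descending
    CNNscore. Coordinates are untouched."""
    spec = grid_spec_for_model(models[0])
    rescored = []
    for pose in poses:
        grid = voxelize(receptor, pose, spec, center, ligand=ligand)
        out = ensemble_score(models, grid)
        p = pose.copy()
        p.cnn_pose_score = out.pose_score
        p.cnn_affinity = out.affinity
        rescored.append(p)
    rescored.sort(key=lambda p: -p.cnn_pose_score)
    return rescored


def run_job(config: JobConfig) -> tuple[list[Pose], dict]:
    """Dock, optionally rescore, write SDF + JSON summary. Deterministic for a
    fixed seed; partial output is removed on failure."""
    import warnings

    receptor = read_receptor(config.receptor_path)
    ligands = read_ligands(config.ligand_path)
    if not ligands:
        raise InputError(f"no ligand parsed from {config.ligand_path}")
    ligand = ligands[0]
    models = load_cnn_models(config)
    if config.cnn_scoring == "refinement":
        warnings.warn(
            "cnn_scoring=refinement is not implemented; using rescore",
            stacklevel=2,
        )
        config.cnn_scoring = "rescore"

    if config.covalent is not None:
        poses = covalent_dock(
            receptor, ligand, config.covalent, config.sampler
        )
        center = tuple(
            float(x) for x in receptor.atoms[0].position
        ) if poses == [] else tuple(
            float(x) for x in poses[0].coordinates.mean(axis=0)
        )
    else:
        tree = build_torsion_tree(ligand)
        box = _resolve_box(config, ligand)
        poses = run_docking(
            receptor, ligand, box, DEFAULT_WEIGHTS, config.sampler, tree
        )
        center = box.center

    if models and config.cnn_scoring == "rescore" and poses:
        poses = cnn_rescore(receptor, ligand, poses, models, center)

    summary = {
        "receptor": config.receptor_path,
        "ligand": config.ligand_path,
        "seed": config.seed,
        "cnn": config.cnn,
        "cnn_scoring": config.cnn_scoring,
        "n_poses": len(poses),
        "sampler": {
            "exhaustiveness": config.sampler.exhaustiveness,
            "steps": config.sampler.steps,
            "num_modes": config.sampler.num_modes,
            "temperature": config.sampler.temperature,
            "seed": config.sampler.seed,
        },
        "poses": [
            {
                "rank": k + 1,
                "minimizedAffinity": p.empirical_score,
                "CNNscore": p.cnn_pose_score,
                "CNNaffinity": p.cnn_affinity,
                "covalent_pairing": p.provenance.get("covalent_pairing"),
            }
            for k, p in enumerate(poses)
        ],
    }
    try:
        write_poses_sdf(ligand, poses, config.out_sdf)
        if config.out_json:
            with open(config.out_json, "w") as fh:
                json.dump(summary, fh, indent=1)
    except Exception:
        for path in (config.out_sdf, config.out_json):
            if path and os.path.exists(path):
                os.remove(path)
        raise
    return poses, summary


def run_screen(
    config: JobConfig, library_path: str, out_csv: str | None = None
) -> pd.DataFrame:
    """Dock every record of a library; one row per compound with its best
    pose's CNNscore (or negated empirical score when cnn=none). Per-record
    failures are logged and skipped."""
    import warnings

    receptor = read_receptor(config.receptor_path)
    library = read_ligands(library_path)
    if not library:
        warnings.warn("empty ligand library", stacklevel=2)
        return pd.DataFrame(columns=["id", "score"])
    models = load_cnn_models(config)

    rows = []
    for k, ligand in enumerate(library):
        name = ligand.name or f"compound_{k}"
        try:
            tree = build_torsion_tree(ligand)
            box = _resolve_box(config, ligand)
            poses = run_docking(
                receptor, ligand, box, DEFAULT_WEIGHTS, config.sampler, tree
            )
            if not poses:
                warnings.warn(f"{name}: no pose found", stacklevel=2)
                continue
            if models:
                poses = cnn_rescore(receptor, ligand, poses, models, box.center)
                score = poses[0].cnn_pose_score
            else:
                score = -poses[0].empirical_score
            rows.append({"id": name, "score": float(score)})
        except MinidockError as exc:
            warnings.warn(f"{name}: {exc}", stacklevel=2)
            continue
    df = pd.DataFrame(rows, columns=["id", "score"])
    if out_csv:
        df.to_csv(out_csv, index=False)
    return df
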