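"""Pose and screening evaluation.

Pose quality: heavy-atom RMSD in a common frame (no superposition), minimized
over molecular-graph automorphisms so that e.g. a flipped para-substituted
ring scores 0. Screening: rank-based ROC AUC, enrichment factor at a fraction
of the library (EF1% by default), and the normalized enrichment factor nEF
(EF divided by the best EF achievable for the same label multiset, so it lies
in [0, 1] and is comparable across targets).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import InputError
from .molio import Pose, TypedMolecule

MAX_AUTOMORPHISMS = 10_000


@dataclass(frozen=True)
class ScreenRecord:
    compound_id: str
    score: float  # higher = more likely active
    active: bool


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def heavy_automorphisms(mol: TypedMolecule) -> np.ndarray:
    """Element- and bond-preserving self-mappings, restricted to heavy atoms.

    Returns an (n_maps, n_heavy) index array mapping heavy-atom slot k of one
    pose onto the matched atom's heavy-atom slot. Falls back to the identity
    (with a warning) if the automorphism count exceeds the cap.
    """
    rd = mol.to_rdkit()
    matches = rd.GetSubstructMatches(
        rd, uniquify=False, useChirality=False, maxMatches=MAX_AUTOMORPHISMS + 1
    )
    heavy = list(mol.heavy_indices())
    slot = {int(a): k for k, a in enumerate(heavy)}
    if not matches or len(matches) > MAX_AUTOMORPHISMS:
        if len(matches) > MAX_AUTOMORPHISMS:
            warnings.warn(
                "automorphism count exceeds cap; falling back to identity",
                stacklevel=2,
            )
        return np.arange(len(heavy), dtype=int)[None, :]
    maps = []
    for m in matches:
        row = [slot[m[a]] for a in heavy]
        maps.append(row)
    return np.unique(np.array(maps, dtype=int), axis=0)


def _as_coords(pose) -> np.ndarray:
    if isinstance(pose, Pose):
        return pose.coordinates
    return np.asarray(pose, dtype=float)


def symmetry_rmsd(
    pose_a, pose_b, mol: TypedMolecule, maps: np.ndarray | None = None
) -> float:
    """Minimum heavy-atom RMSD over graph automorphisms; both poses must be in
    the same coordinate frame (no superposition is performed)."""
    heavy = mol.heavy_indices()
    ca, cb = _as_coords(pose_a), _as_coords(pose_b)
    if ca.shape[0] < mol.n_atoms or cb.shape[0] < mol.n_atoms:
        raise InputError("poses do not match the molecular graph")
    a = ca[heavy]
    b = cb[heavy]
    if maps is None:
        maps = heavy_automorphisms(mol)
    diffs = a[maps] - b[None, :, :]  # n_maps x n_heavy x 3
    rms = np.sqrt((diffs**2).sum(axis=2).mean(axis=1))
    return float(rms.min())


def naive_rmsd(pose_a, pose_b, mol: TypedMolecule) -> float:
    """Identity-mapping heavy-atom RMSD (no symmetry correction)."""
    heavy = mol.heavy_indices()
    a = _as_coords(pose_a)[heavy]
    b = _as_coords(pose_b)[heavy]
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# pose-ranking metrics
# ---------------------------------------------------------------------------

def topn(per_target_ranked_rmsds: list[list[float]], n: int) -> float:
    """Percentage of targets whose best RMSD among the first ``n`` ranked poses
    is <= 2.0 A."""
    if n < 1:
        raise InputError("n must be >= 1")
    if not per_target_ranked_rmsds:
        raise InputError("no targets")
    hits = 0
    for rmsds in per_target_ranked_rmsds:
        if not rmsds:
            raise InputError("each target needs at least one ranked pose")
        if min(rmsds[:n]) <= 2.0:
            hits += 1
    return 100.0 * hits / len(per_target_ranked_rmsds)


# ---------------------------------------------------------------------------
# screening metrics
# ---------------------------------------------------------------------------

def _split(records: list[ScreenRecord]):
    scores = np.array([r.score for r in records], dtype=float)
    labels = np.array([bool(r.active) for r in records])
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    return scores, labels


def roc_auc(records: list[ScreenRecord]) -> float:
    """Rank-based AUC (Mann-Whitney), ties counted half."""
    scores, labels = _split(records)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("need at least one active and one inactive")
    ranks = rankdata(scores)  # average ranks handle ties as half
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def enrichment_factor(records: list[ScreenRecord], fraction: float = 0.01) -> float:
    """(actives in top k / k) / (total actives / N), k = ceil(fraction * N).

    Ties at the k-th score are broken by stable input order.
    """
    if not (0.0 < fraction <= 1.0):
        raise InputError("fraction must lie in (0, 1]")
    scores, labels = _split(records)
    n = len(records)
    n_act = int(labels.sum())
    if n_act == 0:
        raise InputError("no active compounds")
    k = max(1, math.ceil(fraction * n))
    order = np.argsort(-scores, kind="stable")
    top_act = int(labels[order[:k]].sum())
    return (top_act / k) / (n_act / n)


def normalized_enrichment_factor(
    records: list[ScreenRecord], fraction: float = 0.01
) -> float:
    """EF divided by the EF of a perfect ranking of the same labels; in [0,1]."""
    scores, labels = _split(records)
    n = len(records)
    n_act = int(labels.sum())
    if n_act == 0:
        raise InputError("no active compounds")
    k = max(1, math.ceil(fraction * n))
    ef = enrichment_factor(records, fraction)
    best_ef = (min(k, n_act) / k) / (n_act / n)
    return float(ef / best_ef)
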