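"""Empirical pose scoring with the AutoDock Vina functional form.

Five inter-molecular terms evaluated on the surface distance
d = |r_i - r_j| - (vdw_i + vdw_j):

    gauss1      exp(-(d/0.5)^2)
    gauss2      exp(-((d-3)/2)^2)
    repulsion   d^2 for d < 0, else 0
    hydrophobic 1 for d <= 0.5, 0 for d >= 1.5, linear between
                (HydrophobicC-HydrophobicC pairs only)
    hbond       1 for d <= -0.7, 0 for d >= 0, linear between
                (donor-acceptor pairs only)

The final score divides the weighted inter-molecular sum by
(1 + w_rot * N_rot). Hydrogens never enter pair lists. Default weights are the
published Vina values. Local minimization is BFGS over 6 rigid-body variables
(or, in covalent mode, torsion angles only) with analytic gradients;
sub-gradient 0 is used at the piecewise-linear kinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .elements import HBOND_ACCEPTOR_TYPES, HBOND_DONOR_TYPES
from .errors import EmptyInputError, ScoringError
from .molio import Pose, TorsionTree, TypedMolecule

PAIR_CUTOFF = 8.0  # Angstrom, center-to-center

TERM_NAMES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond")


@dataclass(frozen=True)
class TermWeights:
    """Published AutoDock Vina weights (the docking lineage this package
    follows defers to the Vina scoring function; the weights are its own)."""

    w_gauss1: float = -0.035579
    w_gauss2: float = -0.005156
    w_repulsion: float = 0.840245
    w_hydrophobic: float = -0.035069
    w_hbond: float = -0.587439
    w_rot: float = 0.05846

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.w_gauss1,
                self.w_gauss2,
                self.w_repulsion,
                self.w_hydrophobic,
                self.w_hbond,
            ]
        )


DEFAULT_WEIGHTS = TermWeights()


@dataclass
class ScoringReport:
    term_sums: dict[str, float]
    weighted_total: float
    final_score: float
    pair_count: int
    n_rot: int


def surface_distance(i, j) -> float:
    """|pos_i - pos_j| - (vdw_i + vdw_j); negative means overlapping."""
    return float(
        np.linalg.norm(np.asarray(i.position) - np.asarray(j.position))
        - (i.vdw_radius + j.vdw_radius)
    )


def _is_hydrophobic_pair(t1: str, t2: str) -> bool:
    return t1 == "HydrophobicC" and t2 == "HydrophobicC"


def _is_hbond_pair(t1: str, t2: str) -> bool:
    return (t1 in HBOND_DONOR_TYPES and t2 in HBOND_ACCEPTOR_TYPES) or (
        t2 in HBOND_DONOR_TYPES and t1 in HBOND_ACCEPTOR_TYPES
    )


def evaluate_pair_terms(d_surf: float, types: tuple[str, str]) -> tuple[float, ...]:
    """The five Vina terms for one atom pair at surface distance ``d_surf``."""
    d = float(d_surf)
    g1 = math.exp(-((d / 0.5) ** 2))
    g2 = math.exp(-(((d - 3.0) / 2.0) ** 2))
    rep = d * d if d < 0.0 else 0.0
    if _is_hydrophobic_pair(*types):
        if d <= 0.5:
            hyd = 1.0
        elif d >= 1.5:
            hyd = 0.0
        else:
            hyd = 1.5 - d
    else:
        hyd = 0.0
    if _is_hbond_pair(*types):
        if d <= -0.7:
            hb = 1.0
        elif d >= 0.0:
            hb = 0.0
        else:
            hb = -d / 0.7
    else:
        hb = 0.0
    return (g1, g2, rep, hyd, hb)


# ---------------------------------------------------------------------------
# vectorized interaction context
# ---------------------------------------------------------------------------


class InteractionContext:
    """Precomputed arrays for fast repeated scoring of one receptor/ligand
    pair. Hydrogens are dropped here once; intra-molecular ligand pairs are
    those whose shortest bond path crosses a rotatable bond and spans >= 3
    bonds (the 1-4 relationship and beyond)."""

    def __init__(
        self,
        receptor: TypedMolecule,
        ligand: TypedMolecule,
        torsion_tree: TorsionTree | None = None,
        weights: TermWeights = DEFAULT_WEIGHTS,
    ):
        if ligand.n_atoms == 0:
            raise EmptyInputError("empty ligand")
        self.weights = weights
        self.wvec = weights.as_array()
        self.torsion_tree = torsion_tree
        self.n_rot = torsion_tree.n_rotatable if torsion_tree else 0

        self.rec_heavy = receptor.heavy_indices()
        self.lig_heavy = ligand.heavy_indices()
        if self.lig_heavy.size == 0:
            raise EmptyInputError("ligand has no heavy atoms")
        self.rec_pos = receptor.coords[self.rec_heavy]
        self.rec_vdw = np.array(
            [receptor.atoms[k].vdw_radius for k in self.rec_heavy]
        )
        rec_types = [receptor.atoms[k].interaction_type for k in self.rec_heavy]
        lig_types = [ligand.atoms[k].interaction_type for k in self.lig_heavy]
        self.lig_vdw = np.array(
            [ligand.atoms[k].vdw_radius for k in self.lig_heavy]
        )
        # pair masks (R x L)
        self.hyd_mask = np.array(
            [[_is_hydrophobic_pair(rt, lt) for lt in lig_types] for rt in rec_types]
        )
        self.hb_mask = np.array(
            [[_is_hbond_pair(rt, lt) for lt in lig_types] for rt in rec_types]
        )
        self.vdw_sum = self.rec_vdw[:, None] + self.lig_vdw[None, :]

        self.n_lig_atoms = ligand.n_atoms
        self._intra = self._intra_pairs(ligand, torsion_tree)

    def _intra_pairs(self, ligand, tree):
        if tree is None or tree.n_rotatable == 0:
            return None
        adj = ligand.adjacency()
        heavy = set(int(k) for k in self.lig_heavy)
        rot = {tuple(sorted(t.axis)) for t in tree.torsions}
        n = ligand.n_atoms
        pairs = []
        for s in sorted(heavy):
            # BFS shortest paths tracking bond count and rotatable crossing
            dist = {s: 0}
            crossed = {s: False}
            frontier = [s]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            crossed[v] = crossed[u] or (
                                tuple(sorted((u, v))) in rot
                            )
                            nxt.append(v)
                frontier = nxt
            for t in sorted(heavy):
                if t > s and dist.get(t, 10**9) >= 3 and crossed.get(t, False):
                    pairs.append((s, t))
        if not pairs:
            return None
        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
        vdw_i = np.array([ligand.atoms[int(k)].vdw_radius for k in ii])
        vdw_j = np.array([ligand.atoms[int(k)].vdw_radius for k in jj])
        types = [ligand.atoms[k].interaction_type for k in range(n)]
        hyd = np.array(
            [_is_hydrophobic_pair(types[int(a)], types[int(b)]) for a, b in zip(ii, jj)]
        )
        hb = np.array(
            [_is_hbond_pair(types[int(a)], types[int(b)]) for a, b in zip(ii, jj)]
        )
        return {"i": ii, "j": jj, "vdw": vdw_i + vdw_j, "hyd": hyd, "hb": hb}

    # -- term kernels (vectorized) -----------------------------------------
    @staticmethod
    def _terms_and_derivs(d, hyd_mask, hb_mask):
        g1 = np.exp(-((d / 0.5) ** 2))
        g2 = np.exp(-(((d - 3.0) / 2.0) ** 2))
        dg1 = -8.0 * d * g1
        dg2 = -0.5 * (d - 3.0) * g2
        neg = d < 0.0
        rep = np.where(neg, d * d, 0.0)
        drep = np.where(neg, 2.0 * d, 0.0)
        hyd = np.where(
            hyd_mask, np.clip(1.5 - d, 0.0, 1.0), 0.0
        )
        dhyd = np.where(hyd_mask & (d > 0.5) & (d < 1.5), -1.0, 0.0)
        hb = np.where(hb_mask, np.clip(-d / 0.7, 0.0, 1.0), 0.0)
        dhb = np.where(hb_mask & (d > -0.7) & (d < 0.0), -1.0 / 0.7, 0.0)
        return (g1, g2, rep, hyd, hb), (dg1, dg2, drep, dhyd, dhb)

    def inter_terms(self, lig_coords: np.ndarray):
        """Per-term sums and weighted inter-molecular energy with its gradient
        w.r.t. all ligand atom coordinates (hydrogens get zero gradient)."""
        lp = lig_coords[self.lig_heavy]
        diff = lp[None, :, :] - self.rec_pos[:, None, :]  # R x L x 3
        center_d = np.sqrt((diff**2).sum(axis=2))
        within = center_d <= PAIR_CUTOFF
        d = center_d - self.vdw_sum
        terms, derivs = self._terms_and_derivs(d, self.hyd_mask, self.hb_mask)
        term_sums = np.array([(t * within).sum() for t in terms])
        energy = float(self.wvec @ term_sums)
        # dE/dd summed with weights, then chain rule through d -> ligand coords
        dEdd = sum(w * dv for w, dv in zip(self.wvec, derivs)) * within
        safe = np.where(center_d > 1e-9, center_d, 1.0)
        unit = diff / safe[:, :, None]
        grad_heavy = (dEdd[:, :, None] * unit).sum(axis=0)  # L x 3
        grad = np.zeros((self.n_lig_atoms, 3))
        grad[self.lig_heavy] = grad_heavy
        return term_sums, energy, grad, int(within.sum())

    def intra_energy(self, lig_coords: np.ndarray):
        """Conformation-dependent internal ligand energy (and gradient)."""
        p = self._intra
        grad = np.zeros((self.n_lig_atoms, 3))
        if p is None:
            return 0.0, grad
        diff = lig_coords[p["i"]] - lig_coords[p["j"]]
        center_d = np.linalg.norm(diff, axis=1)
        within = center_d <= PAIR_CUTOFF
        d = center_d - p["vdw"]
        terms, derivs = self._terms_and_derivs(d, p["hyd"], p["hb"])
        energy = float(
            self.wvec @ np.array([(t * within).sum() for t in terms])
        )
        dEdd = sum(w * dv for w, dv in zip(self.wvec, derivs)) * within
        safe = np.where(center_d > 1e-9, center_d, 1.0)
        unit = diff / safe[:, None]
        contrib = dEdd[:, None] * unit
        np.add.at(grad, p["i"], contrib)
        np.add.at(grad, p["j"], -contrib)
        return energy, grad

    def report(self, lig_coords: np.ndarray) -> ScoringReport:
        term_sums, energy, _, pair_count = self.inter_terms(lig_coords)
        final = energy / (1.0 + self.weights.w_rot * self.n_rot)
        return ScoringReport(
            term_sums=dict(zip(TERM_NAMES, (float(t) for t in term_sums))),
            weighted_total=energy,
            final_score=final,
            pair_count=pair_count,
            n_rot=self.n_rot,
        )


def score_pose(
    receptor: TypedMolecule,
    ligand: TypedMolecule,
    pose: Pose | np.ndarray | None = None,
    weights: TermWeights = DEFAULT_WEIGHTS,
    torsion_tree: TorsionTree | None = None,
) -> ScoringReport:
    """Score one pose: weighted inter-molecular sum over all heavy-atom pairs
    within the 8 A cutoff, divided by (1 + w_rot * N_rot)."""
    ctx = InteractionContext(receptor, ligand, torsion_tree, weights)
    if pose is None:
        coords = ligand.coords
    elif isinstance(pose, Pose):
        coords = pose.coordinates
    else:
        coords = np.asarray(pose, dtype=float)
    return ctx.report(coords)


# ---------------------------------------------------------------------------
# local minimization
# ---------------------------------------------------------------------------


@dataclass
class MinimizeConfig:
    gtol: float = 1e-4       # gradient infinity-norm stopping tolerance
    maxiter: int = 200
    covalent_mode: bool = False  # torsion-only variables


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float
    )


def _rotvec_matrix(v: np.ndarray) -> np.ndarray:
    theta = float(np.linalg.norm(v))
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    K = _skew(k)
    return np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)


def _apply_rotvec(v: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return pts @ _rotvec_matrix(v).T


def local_minimize(
    receptor: TypedMolecule,
    ligand: TypedMolecule,
    pose: Pose,
    torsion_tree: TorsionTree | None = None,
    weights: TermWeights = DEFAULT_WEIGHTS,
    config: MinimizeConfig | None = None,
    context: InteractionContext | None = None,
) -> Pose:
    """BFGS local minimization of the empirical score.

    Default mode optimizes the 6 rigid-body variables (translation + rotation
    about the ligand centroid). Covalent mode optimizes torsion angles only
    (no rigid-body motion) and includes the conformation-dependent internal
    energy in the objective. The returned pose never scores worse than the
    input.
    """
    config = config or MinimizeConfig()
    ctx = context or InteractionContext(receptor, ligand, torsion_tree, weights)
    x0 = np.asarray(pose.coordinates, dtype=float)

    if config.covalent_mode:
        if torsion_tree is None or torsion_tree.n_rotatable == 0:
            report = ctx.report(x0)
            return Pose(
                coordinates=x0.copy(),
                empirical_score=report.final_score,
                provenance=dict(pose.provenance),
            )

        def objective(phi):
            coords = torsion_tree.apply_angles(x0, phi)
            _, e_inter, g_inter, _ = ctx.inter_terms(coords)
            e_intra, g_intra = ctx.intra_energy(coords)
            g = g_inter + g_intra
            if not np.all(np.isfinite(g)):
                raise ScoringError("non-finite gradient during minimization")
            gphi = np.zeros(len(phi))
            for k, t in enumerate(torsion_tree.torsions):
                a, b = t.axis
                axis = coords[b] - coords[a]
                nrm = np.linalg.norm(axis)
                if nrm < 1e-12:
                    continue
                axis = axis / nrm
                moving = np.asarray(t.moving, dtype=int)
                dxdphi = np.cross(axis, coords[moving] - coords[a])
                gphi[k] = float((dxdphi * g[moving]).sum())
            return e_inter + e_intra, gphi

        phi0 = np.zeros(torsion_tree.n_rotatable)
        f0, _ = objective(phi0)
        res = _scipy_minimize(
            objective,
            phi0,
            jac=True,
            method="BFGS",
            options={"gtol": config.gtol, "maxiter": config.maxiter},
        )
        phi = res.x if res.fun <= f0 else phi0
        coords = torsion_tree.apply_angles(x0, phi)
    else:
        centroid = x0.mean(axis=0)
        rel0 = x0 - centroid

        def objective(params):
            v, t = params[:3], params[3:]
            coords = _apply_rotvec(v, rel0) + centroid + t
            _, e, g, _ = ctx.inter_terms(coords)
            if not np.all(np.isfinite(g)):
                raise ScoringError("non-finite gradient during minimization")
            gt = g.sum(axis=0)
            gv = _rotvec_grad(v, rel0, g)
            return e, np.concatenate([gv, gt])

        p0 = np.zeros(6)
        f0, _ = objective(p0)
        res = _scipy_minimize(
            objective,
            p0,
            jac=True,
            method="BFGS",
            options={"gtol": config.gtol, "maxiter": config.maxiter},
        )
        params = res.x if res.fun <= f0 else p0
        coords = _apply_rotvec(params[:3], rel0) + centroid + params[3:]

    report = ctx.report(coords)
    return Pose(
        coordinates=coords,
        empirical_score=report.final_score,
        provenance=dict(pose.provenance),
    )


def _rotvec_grad(v: np.ndarray, pts: np.ndarray, grad_coords: np.ndarray) -> np.ndarray:
    """dE/dv for coords = R(v) pts (+const), given dE/dcoords."""
    theta = float(np.linalg.norm(v))
    if theta < 1e-8:
        # limit: d(Rp)/dv_i . g = (e_i x p) . g = e_i . (p x g)
        return np.cross(pts, grad_coords).sum(axis=0)
    eye = np.eye(3)
    R = _rotvec_matrix(v)
    rotated = pts @ R.T
    out = np.zeros(3)
    for i in range(3):
        wi = (v[i] * _skew(v) + _skew(np.cross(v, (eye[:, i] - R[:, i])))) / (
            theta**2
        )
        dRp = rotated @ wi.T
        out[i] = float((dRp * grad_coords).sum())
    return out
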