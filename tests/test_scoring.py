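import math

import numpy as np
import pytest

from minidock.elements import INTERACTION_TYPES
from minidock.molio import AtomRecord, Pose, TypedMolecule, assign_atom_types, build_torsion_tree, generate_toy_complex
from minidock.scoring import (
    DEFAULT_WEIGHTS,
    InteractionContext,
    MinimizeConfig,
    evaluate_pair_terms,
    local_minimize,
    score_pose,
    surface_distance,
)

DONORS = {"DonorN", "DonorAcceptorN", "DonorO", "DonorAcceptorO"}
ACCEPTORS = {"AcceptorN", "DonorAcceptorN", "AcceptorO", "DonorAcceptorO"}


def oracle_terms(d, t1, t2):
    """Independent straight-line transcription of the five empirical terms."""
    g1 = math.exp(-((d / 0.5) ** 2))
    g2 = math.exp(-(((d - 3.0) / 2.0) ** 2))
    rep = d * d if d < 0 else 0.0
    if t1 == "HydrophobicC" and t2 == "HydrophobicC":
        hyd = 1.0 if d <= 0.5 else (0.0 if d >= 1.5 else 1.5 - d)
    else:
        hyd = 0.0
    pair_ok = (t1 in DONORS and t2 in ACCEPTORS) or (t2 in DONORS and t1 in ACCEPTORS)
    if pair_ok:
        hb = 1.0 if d <= -0.7 else (0.0 if d >= 0 else -d / 0.7)
    else:
        hb = 0.0
    return (g1, g2, rep, hyd, hb)


def carbon(index, pos, is_ligand=False):
    return AtomRecord(index=index, element="C", position=np.asarray(pos, float),
                      interaction_type="HydrophobicC", is_ligand=is_ligand)


def test_surface_distance_arithmetic():
    a = carbon(0, [0, 0, 0])
    assert surface_distance(a, carbon(1, [3.8, 0, 0])) == pytest.approx(0.0)
    assert surface_distance(a, carbon(1, [5.8, 0, 0])) == pytest.approx(2.0)
    assert surface_distance(a, carbon(1, [2.8, 0, 0])) == pytest.approx(-1.0)
    assert surface_distance(a, carbon(1, [0, 0, 0])) == pytest.approx(-3.8)


def test_pair_term_closed_forms():
    g1, g2, rep, hyd, hb = evaluate_pair_terms(0.0, ("HydrophobicC", "HydrophobicC"))
    assert (g1, rep, hyd) == (1.0, 0.0, 1.0)
    assert evaluate_pair_terms(0.5, ("S", "S"))[0] == pytest.approx(math.exp(-1.0))
    hb = evaluate_pair_terms(-0.35, ("DonorN", "AcceptorO"))[4]
    assert hb == pytest.approx(0.5)


def test_pair_terms_match_oracle_on_random_pairs():
    rng = np.random.default_rng(42)
    types = [t for t in INTERACTION_TYPES if t != "H"]
    for _ in range(1000):
        d = float(rng.uniform(-2.5, 9.0))
        t1, t2 = rng.choice(types), rng.choice(types)
        ours = evaluate_pair_terms(d, (t1, t2))
        ref = oracle_terms(d, t1, t2)
        assert max(abs(a - b) for a, b in zip(ours, ref)) <= 1e-12


def test_score_pose_matches_brute_force(toy_complex):
    receptor, ligand, reference = toy_complex
    tree = build_torsion_tree(ligand)
    report = score_pose(receptor, ligand, reference, torsion_tree=tree)
    w = DEFAULT_WEIGHTS
    total = 0.0
    for i in receptor.heavy_indices():
        for j in ligand.heavy_indices():
            ra, la = receptor.atoms[int(i)], ligand.atoms[int(j)]
            center = float(np.linalg.norm(ra.position - reference.coordinates[int(j)]))
            if center > 8.0:
                continue
            d = center - (ra.vdw_radius + la.vdw_radius)
            g1, g2, rep, hyd, hb = oracle_terms(
                d, ra.interaction_type, la.interaction_type
            )
            total += (
                w.w_gauss1 * g1 + w.w_gauss2 * g2 + w.w_repulsion * rep
                + w.w_hydrophobic * hyd + w.w_hbond * hb
            )
    expected = total / (1.0 + w.w_rot * tree.n_rotatable)
    assert report.final_score == pytest.approx(expected, abs=1e-9)


def test_score_zero_beyond_cutoff(toy_complex):
    receptor, ligand, reference = toy_complex
    far = reference.coordinates + np.array([100.0, 0.0, 0.0])
    report = score_pose(receptor, ligand, far)
    assert report.weighted_total == 0.0
    assert all(v == 0.0 for v in report.term_sums.values())


def test_no_rotatable_bonds_means_no_torsion_penalty(toy_complex):
    receptor, ligand, reference = toy_complex
    report = score_pose(receptor, ligand, reference, torsion_tree=None)
    assert report.final_score == pytest.approx(report.weighted_total)


def test_score_invariant_under_joint_rigid_transform(toy_complex):
    from minidock.molio import _rodrigues

    receptor, ligand, reference = toy_complex
    base = score_pose(receptor, ligand, reference).final_score
    axis = np.array([1.0, 2.0, -0.5])
    axis /= np.linalg.norm(axis)
    shift = np.array([3.0, -7.0, 11.0])
    rec2 = receptor.copy()
    rec2.set_coords(_rodrigues(receptor.coords, axis, 1.1) + shift)
    lig2_coords = _rodrigues(reference.coordinates, axis, 1.1) + shift
    moved = score_pose(rec2, ligand, lig2_coords).final_score
    assert moved == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def _symmetric_pocket(radius=3.8, n=80):
    """Spherical carbon shell centered at the origin."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    y = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - y * y))
    theta = phi * k
    pos = radius * np.column_stack([r * np.cos(theta), y, r * np.sin(theta)])
    atoms = [
        AtomRecord(index=i, element="C", position=p, chain_id="A",
                   residue_number=str(i + 1), residue_name="SHL", atom_name="C")
        for i, p in enumerate(pos)
    ]
    return assign_atom_types(TypedMolecule(atoms=atoms, bonds=[]))


def _one_carbon_ligand():
    return assign_atom_types(
        TypedMolecule(
            atoms=[AtomRecord(index=0, element="C", position=np.zeros(3),
                              is_ligand=True)],
            bonds=[],
        )
    )


def test_minimize_never_increases_score(toy_complex):
    receptor, ligand, reference = toy_complex
    tree = build_torsion_tree(ligand)
    rng = np.random.default_rng(0)
    for _ in range(25):
        start_coords = reference.coordinates + rng.normal(scale=1.0, size=3)
        start = Pose(coordinates=start_coords)
        s0 = score_pose(receptor, ligand, start, torsion_tree=tree).final_score
        out = local_minimize(receptor, ligand, start, tree)
        assert out.empirical_score <= s0 + 1e-12
        assert np.all(np.isfinite(out.coordinates))


def test_one_atom_ligand_finds_pocket_center():
    receptor = _symmetric_pocket()
    ligand = _one_carbon_ligand()
    ctx = InteractionContext(receptor, ligand)

    # grid-search oracle over positions
    grid = np.linspace(-1.5, 1.5, 13)
    best, best_e = None, np.inf
    for x in grid:
        for y in grid:
            for z in grid:
                e = ctx.report(np.array([[x, y, z]])).final_score
                if e < best_e:
                    best_e, best = e, np.array([x, y, z])
    assert np.linalg.norm(best) < 0.2  # oracle confirms the center

    start = Pose(coordinates=np.array([[0.6, -0.4, 0.5]]))
    out = local_minimize(receptor, ligand, start)
    assert np.linalg.norm(out.coordinates[0] - best) <= 0.1


def test_minimize_fixed_point(toy_complex):
    receptor, ligand, reference = toy_complex
    tree = build_torsion_tree(ligand)
    once = local_minimize(receptor, ligand, reference, tree)
    twice = local_minimize(receptor, ligand, once, tree)
    assert np.allclose(once.coordinates, twice.coordinates, atol=5e-2)
    assert twice.empirical_score <= once.empirical_score + 1e-12


def test_rigid_gradient_matches_finite_differences(toy_complex):
    from minidock.scoring import _apply_rotvec, _rotvec_grad

    receptor, ligand, reference = toy_complex
    ctx = InteractionContext(receptor, ligand)
    x0 = reference.coordinates
    centroid = x0.mean(axis=0)
    rel0 = x0 - centroid

    def f(p):
        coords = _apply_rotvec(p[:3], rel0) + centroid + p[3:]
        _, e, g, _ = ctx.inter_terms(coords)
        return e, np.concatenate([_rotvec_grad(p[:3], rel0, g), g.sum(axis=0)])

    rng = np.random.default_rng(1)
    p = rng.normal(scale=0.4, size=6)
    _, grad = f(p)
    h = 1e-6
    for i in range(6):
        pp, pm = p.copy(), p.copy()
        pp[i] += h
        pm[i] -= h
        num = (f(pp)[0] - f(pm)[0]) / (2 * h)
        assert grad[i] == pytest.approx(num, abs=1e-6)
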