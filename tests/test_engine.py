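import numpy as np
import pytest

from nmr2dock.engine import (
    AssignmentMap,
    EngineConfig,
    EngineError,
    Pose,
    enumerate_assignments,
    feasibility_prune,
    optimize_pose,
    run_nmr2,
    score_pose,
)
from nmr2dock.restraints import (
    AnonymousLabel,
    Restraint,
    RestraintNetwork,
    apply_tolerance,
    extract_restraints,
)
from nmr2dock.structures import LigandConformer, MethylSite, ProtonSite
from nmr2dock.synthetic import make_case, STANDARD_SPEC
from nmr2dock.validation import pose_rmsd

from helpers import grid_best_tf


def _site(i, xyz, rtype="ALA", atom="CB"):
    return MethylSite(f"{rtype}{i}-{atom}", i, rtype, atom, np.asarray(xyz, float))


def _labels(n):
    return [AnonymousLabel(f"M_{i+1}") for i in range(n)]


# ---------------------------------------------------------------------------
# enumeration

def test_enumeration_unconstrained_count():
    sites = [_site(10 * (i + 1), [i * 3.0, 0, 0]) for i in range(4)]
    maps = list(enumerate_assignments(_labels(3), sites))
    assert len(maps) == 24  # 4 * 3 * 2
    assert maps == sorted(maps, key=lambda m: tuple(m[f"M_{k+1}"] for k in range(3)))


def test_enumeration_type_constraint_count():
    sites = [
        _site(10, [0, 0, 0], "MET", "CE"),
        _site(20, [3, 0, 0]),
        _site(30, [6, 0, 0]),
        _site(40, [9, 0, 0], "THR", "CG2"),
    ]
    labels = [AnonymousLabel("M_1", frozenset({"MET"}))] + _labels(3)[1:]
    maps = list(enumerate_assignments(labels, sites))
    assert len(maps) == 6  # 1 * 3 * 2
    assert all(m["M_1"] == 0 for m in maps)


def test_enumeration_same_residue_group():
    sites = [
        _site(10, [0, 0, 0], "VAL", "CG1"),
        _site(10, [2, 0, 0], "VAL", "CG2"),
        _site(20, [6, 0, 0], "MET", "CE"),
    ]
    labels = [
        AnonymousLabel("M_1"),
        AnonymousLabel("M_2", None, "g1"),
        AnonymousLabel("M_3", None, "g1"),
    ]
    maps = list(enumerate_assignments(labels, sites))
    # M_2/M_3 must share the VAL: M_1 takes the MET, pair fills CG1/CG2 both ways
    assert len(maps) == 2
    for m in maps:
        assert {m["M_2"], m["M_3"]} == {0, 1}
        assert m["M_1"] == 2


def test_enumeration_errors():
    sites = [_site(10, [0, 0, 0])]
    with pytest.raises(EngineError, match="over-determined"):
        list(enumerate_assignments(_labels(2), sites))
    labels = [AnonymousLabel("M_1", frozenset({"MET"}))]
    with pytest.raises(EngineError, match="M_1"):
        list(enumerate_assignments(labels, sites))


# ---------------------------------------------------------------------------
# pruning

def _pair_network(upper=5.0, lower=None):
    lower = upper if lower is None else lower
    protons = [ProtonSite("H1", "", np.zeros(3))]
    restraints = [
        Restraint("M_1", "H1", (lower + upper) / 2, lower, upper),
        Restraint("M_2", "H1", (lower + upper) / 2, lower, upper),
    ]
    return RestraintNetwork(restraints, _labels(2), protons)


def test_prune_triangle_inequality():
    net = _pair_network(upper=5.0, lower=4.0)
    far = [_site(10, [0, 0, 0]), _site(20, [20.0, 0, 0])]
    near = [_site(10, [0, 0, 0]), _site(20, [6.0, 0, 0])]
    assert not feasibility_prune({"M_1": 0}, "M_2", 1, net, far)   # 20 > 5 + 5
    assert feasibility_prune({"M_1": 0}, "M_2", 1, net, near)      # 6 <= 10


def test_prune_preserves_best_solution():
    """Pruning only removes provably infeasible branches: same winner."""
    case = make_case(STANDARD_SPEC["site"], STANDARD_SPEC["ligand"],
                     max_distance=STANDARD_SPEC["max_distance"], seed=5, case_id="p")
    config = EngineConfig(seed=3, n_restarts=3, sa_steps=60)
    with_prune = run_nmr2(case.network, case.sites, case.ligand,
                          case.receptor_heavy_xyz, config, prune=True)
    without = run_nmr2(case.network, case.sites, case.ligand,
                       case.receptor_heavy_xyz, config, prune=False)
    assert with_prune[0].assignment.key() == without[0].assignment.key()
    assert with_prune[0].tf == pytest.approx(without[0].tf, abs=1e-9)
    # pruned run's solutions are a subset of the unpruned run's assignments
    keys_with = {s.assignment.key() for s in with_prune}
    keys_without = {s.assignment.key() for s in without}
    assert keys_with <= keys_without


# ---------------------------------------------------------------------------
# scoring

def _one_restraint_problem(lower, upper, site_xyz):
    protons = [ProtonSite("H1", "", np.zeros(3))]
    net = RestraintNetwork(
        [Restraint("M_1", "H1", (lower + upper) / 2, lower, upper)],
        _labels(1), protons,
    )
    ligand = LigandConformer(("H1",), np.zeros((1, 3)), ("C0",), np.zeros((1, 3)))
    sites = [_site(10, site_xyz)]
    return net, ligand, sites


def test_score_pose_violation_squared():
    # bounds (4.5, 5.5), realized distance 6.0 -> (6.0 - 5.5)^2 = 0.25
    net, ligand, sites = _one_restraint_problem(4.5, 5.5, [6.0, 0, 0])
    amap = AssignmentMap({"M_1": sites[0]})
    assert score_pose(Pose.identity(), amap, net, ligand) == pytest.approx(0.25)
    # realized distance 5.2 lies inside the bounds -> no contribution
    net2, ligand2, sites2 = _one_restraint_problem(4.5, 5.5, [5.2, 0, 0])
    amap2 = AssignmentMap({"M_1": sites2[0]})
    assert score_pose(Pose.identity(), amap2, net2, ligand2) == 0.0


def test_score_pose_zero_at_exact_distances():
    case = make_case(STANDARD_SPEC["site"], STANDARD_SPEC["ligand"],
                     max_distance=STANDARD_SPEC["max_distance"], seed=9, case_id="z")
    tf = score_pose(case.truth_pose, case.truth_assignment, case.exact_network,
                    case.ligand, case.receptor_heavy_xyz)
    assert tf == pytest.approx(0.0, abs=1e-9)


def test_tf_invariant_under_joint_rigid_transform():
    from scipy.spatial.transform import Rotation

    case = make_case(STANDARD_SPEC["site"], STANDARD_SPEC["ligand"],
                     max_distance=STANDARD_SPEC["max_distance"], seed=13, case_id="t")
    rng = np.random.default_rng(0)
    R = Rotation.random(random_state=np.random.RandomState(4)).as_matrix()
    t = rng.uniform(-8, 8, 3)
    pose = Pose(case.truth_pose.rotation @ np.eye(3), case.truth_pose.translation + 0.7)
    tf0 = score_pose(pose, case.truth_assignment, case.exact_network, case.ligand,
                     case.receptor_heavy_xyz)
    moved_sites = {
        l: MethylSite(s.site_id, s.residue_number, s.residue_type,
                      s.methyl_atom_name, s.carbon_xyz @ R.T + t)
        for l, s in case.truth_assignment.mapping.items()
    }
    moved_pose = Pose(R @ pose.rotation, pose.translation @ R.T + t)
    moved_net = case.exact_network  # bounds are frame-free
    tf1 = score_pose(moved_pose, AssignmentMap(moved_sites), moved_net, case.ligand,
                     case.receptor_heavy_xyz @ R.T + t)
    assert tf0 == pytest.approx(tf1, rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# optimization

def test_optimize_pose_recovers_truth_and_is_deterministic(fast_config):
    case = make_case(STANDARD_SPEC["site"], STANDARD_SPEC["ligand"],
                     max_distance=STANDARD_SPEC["max_distance"], seed=21, case_id="o")
    config = fast_config(seed=11)
    sol1 = optimize_pose(case.truth_assignment, case.exact_network, case.ligand,
                         case.receptor_heavy_xyz, config)
    assert sol1.tf == pytest.approx(0.0, abs=1e-3)
    assert pose_rmsd(sol1.pose, case.truth_pose, case.ligand.heavy_xyz) < 0.5
    sol2 = optimize_pose(case.truth_assignment, case.exact_network, case.ligand,
                         case.receptor_heavy_xyz, config)
    assert sol1.tf == sol2.tf  # bit-identical under the same seed
    assert np.array_equal(sol1.pose.rotation, sol2.pose.rotation)
    assert np.array_equal(sol1.pose.translation, sol2.pose.translation)


def test_widening_tolerance_never_raises_optimal_tf(fast_config):
    case = make_case(STANDARD_SPEC["site"], STANDARD_SPEC["ligand"],
                     max_distance=STANDARD_SPEC["max_distance"], seed=33, case_id="w")
    config = fast_config(seed=5)
    tfs = []
    for frac in (0.0, 0.1, 0.2):
        net = apply_tolerance(case.exact_network, frac)
        sol = optimize_pose(case.truth_assignment, net, case.ligand,
                            case.receptor_heavy_xyz, config)
        tfs.append(sol.tf)
    assert tfs[0] >= tfs[1] - 1e-9
    assert tfs[1] >= tfs[2] - 1e-9


def test_run_nmr2_ranks_truth_first(fast_config):
    case = make_case(STANDARD_SPEC["site"], STANDARD_SPEC["ligand"],
                     max_distance=STANDARD_SPEC["max_distance"], seed=55, case_id="r")
    ranked = run_nmr2(case.network, case.sites, case.ligand,
                      case.receptor_heavy_xyz, fast_config(seed=2))
    truth_key = tuple(sorted(
        (l, s.site_id) for l, s in case.truth_assignment.mapping.items()
    ))
    assert ranked[0].assignment.key() == truth_key
    assert ranked[0].tf == pytest.approx(0.0, abs=1e-3)
    assert pose_rmsd(ranked[0].pose, case.truth_pose, case.ligand.heavy_xyz) < 1.0
    assert [s.tf for s in ranked] == sorted(s.tf for s in ranked)


def test_run_nmr2_deterministic_full_list(fast_config):
    case = make_case(STANDARD_SPEC["site"], STANDARD_SPEC["ligand"],
                     max_distance=STANDARD_SPEC["max_distance"], seed=77, case_id="d")
    a = run_nmr2(case.network, case.sites, case.ligand,
                 case.receptor_heavy_xyz, fast_config(seed=9))
    b = run_nmr2(case.network, case.sites, case.ligand,
                 case.receptor_heavy_xyz, fast_config(seed=9))
    assert len(a) == len(b)
    for sa, sb in zip(a, b):
        assert sa.tf == sb.tf
        assert sa.assignment.key() == sb.assignment.key()


def test_engine_matches_grid_oracle_small_instance(fast_config):
    """Best engine tf agrees with exhaustive assignments x dense grid search."""
    rng = np.random.default_rng(3)
    sites = [
        _site(10, [5.5, 0.5, -0.3], "MET", "CE"),
        _site(20, [-2.5, 4.8, 0.7]),
        _site(30, [-1.8, -4.6, 2.2], "THR", "CG2"),
    ]
    proton_xyz = np.array([[0, 0, 0], [2.8, 0, 0], [1.2, 1.9, 0.4], [0.9, -1.5, -0.6]])
    protons = [ProtonSite(f"H{i+1}", "", x) for i, x in enumerate(proton_xyz)]
    net, truth = extract_restraints(protons, sites, max_distance=12.0, seed=1)
    net = apply_tolerance(net, 0.10)
    ligand = LigandConformer(
        tuple(p.proton_id for p in protons), proton_xyz,
        ("C1",), np.array([[1.2, 0.1, 0.0]]),
    )
    config = fast_config(seed=4, n_restarts=4, sa_steps=120)
    ranked = run_nmr2(net, sites, ligand, None, config)
    oracle, grid_only = grid_best_tf(net, sites, ligand, None,
                                     n_rotations=400, seed=8)
    assert ranked[0].tf <= grid_only + 1e-9
    assert ranked[0].tf == pytest.approx(oracle, abs=0.05)
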