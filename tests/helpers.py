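"""Independent oracles for engine checks.

Everything here is deliberately written against the public data model only
(no reuse of the engine's internal scoring/search machinery): a plain
violation target function, an exhaustive assignment enumeration, and a dense
rigid-body grid search with Nelder-Mead refinement.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

CLASH_RMIN = 2.8


def naive_tf(rotvec, trans, network, site_of_label, ligand, receptor_xyz=None,
             slack=0.0, clash_weight=1.0):
    """Straight-line implementation of the violation target function."""
    R = Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix()
    t = np.asarray(trans, float)
    pidx = {p: i for i, p in enumerate(ligand.proton_ids)}
    protons = ligand.proton_xyz @ R.T + t
    tf = 0.0
    for r in network.restraints:
        d = float(np.linalg.norm(protons[pidx[r.proton_id]] - site_of_label[r.label]))
        v = max(0.0, d - r.upper - slack, r.lower - slack - d)
        tf += v * v
    if receptor_xyz is not None and len(receptor_xyz) and len(ligand.heavy_xyz):
        heavy = ligand.heavy_xyz @ R.T + t
        dist = np.linalg.norm(heavy[:, None] - np.asarray(receptor_xyz)[None], axis=2)
        pen = np.maximum(0.0, CLASH_RMIN - dist)
        tf += clash_weight * float((pen ** 2).sum())
    return tf


def all_injective_assignments(labels, sites):
    """Every injective label -> site map honoring type constraints and groups."""
    names = sorted((l for l in labels), key=lambda l: l.label)
    out = []
    for perm in itertools.permutations(range(len(sites)), len(names)):
        ok = True
        placed = {}
        for lab, si in zip(names, perm):
            site = sites[si]
            if lab.type_constraint is not None and site.residue_type not in lab.type_constraint:
                ok = False
                break
            if lab.same_residue_group is not None:
                for other, oi in placed.items():
                    if (other.same_residue_group == lab.same_residue_group
                            and sites[oi].residue_number != site.residue_number):
                        ok = False
                        break
                if not ok:
                    break
            placed[lab] = si
        if ok:
            out.append({lab.label: si for lab, si in zip(names, perm)})
    return out


def grid_best_tf(network, sites, ligand, receptor_xyz=None, slack=0.0,
                 n_rotations=500, trans_radius=3.0, trans_step=1.0,
                 refine_top=5, seed=0):
    """min tf over all assignments x (rotation sample x translation grid).

    The best few grid points per assignment are refined with Nelder-Mead.
    Returns (best_tf, grid_only_best_tf).
    """
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_rotations, random_state=np.random.RandomState(seed))
    rotvecs = rots.as_rotvec()
    center = np.mean([s.carbon_xyz for s in sites], axis=0)
    axes = np.arange(-trans_radius, trans_radius + 1e-9, trans_step)
    grid = np.array([
        [x, y, z] for x in axes for y in axes for z in axes
        if x * x + y * y + z * z <= trans_radius ** 2 + 1e-9
    ]) + center

    pidx = {p: i for i, p in enumerate(ligand.proton_ids)}
    r_proton = np.array([pidx[r.proton_id] for r in network.restraints])
    lower = np.array([r.lower for r in network.restraints]) - slack
    upper = np.array([r.upper for r in network.restraints]) + slack

    best = np.inf
    grid_best = np.inf
    for assign in all_injective_assignments(network.labels, sites):
        site_of_label = {l: sites[i].carbon_xyz for l, i in assign.items()}
        spr = np.array([site_of_label[r.label] for r in network.restraints])
        local_best = []
        for rv, rot in zip(rotvecs, rots):
            pp = rot.apply(ligand.proton_xyz)
            # (n_restraints, n_trans)
            d = np.linalg.norm(
                pp[r_proton][:, None, :] + grid[None, :, :] - spr[:, None, :], axis=2
            )
            viol = np.maximum(0.0, np.maximum(d - upper[:, None], lower[:, None] - d))
            tf_grid = (viol ** 2).sum(axis=0)
            if receptor_xyz is not None and len(receptor_xyz) and len(ligand.heavy_xyz):
                hh = rot.apply(ligand.heavy_xyz)
                dist = np.linalg.norm(
                    hh[:, None, None, :] + grid[None, :, None, :]
                    - np.asarray(receptor_xyz)[None, None, :, :], axis=3,
                )
                pen = np.maximum(0.0, CLASH_RMIN - dist)
                tf_grid = tf_grid + (pen ** 2).sum(axis=(0, 2))
            k = int(np.argmin(tf_grid))
            local_best.append((float(tf_grid[k]), rv, grid[k]))
        local_best.sort(key=lambda x: x[0])
        grid_best = min(grid_best, local_best[0][0])
        for tf0, rv, t0 in local_best[:refine_top]:
            res = minimize(
                lambda x: naive_tf(x[:3], x[3:], network, site_of_label, ligand,
                                   receptor_xyz, slack),
                np.concatenate([rv, t0]),
                method="Nelder-Mead",
                options=dict(maxiter=400, xatol=1e-6, fatol=1e-10),
            )
            best = min(best, float(res.fun))
        best = min(best, grid_best)
    return best, grid_best
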