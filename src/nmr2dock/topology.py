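"""Ligand topology parameters and binding-site suitability diagnostics.

The topology parameters normalize the ligand's characteristic proton-cloud
dimensions by the mean restraint distance:

    r_l = L_length / <d>        r_w = L_width / <d>

where L_length is the maximal proton-proton distance among *active* protons
(those carrying at least one restraint), L_width the longest proton-pair
component orthogonal to the length vector, and <d> the mean central restraint
distance.  Empirically, pose calculations from semi-ambiguous methyl
restraints mostly fail when r_l + r_w drops below ~2: short ligands probed
through long distances leave too much positional freedom.

Site suitability encodes the trilateration picture: at least three
methyl-bearing residues, not all on one side of the pocket.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .restraints import RestraintNetwork
from .structures import MethylSite, ProtonSite


@dataclass(frozen=True)
class TopologyParams:
    L_length: float
    L_width: float
    mean_d: float
    r_l: float
    r_w: float


@dataclass(frozen=True)
class SiteDiagnostics:
    n_methyl_residues: int
    n_methyl_sites: int
    one_sided: bool
    spread_score: float
    suitable: bool


def active_protons(network: RestraintNetwork) -> list[ProtonSite]:
    """Protons involved in at least one restraint, in network proton order."""
    used = {r.proton_id for r in network.restraints}
    return [p for p in network.protons if p.proton_id in used]


def length_width(protons: Sequence[ProtonSite]) -> tuple[float, float]:
    """Brute-force (L_length, L_width) over all proton pairs.

    L_length is the largest pairwise distance; with u the unit vector of a
    maximizing pair, L_width is the largest pair-vector component orthogonal
    to u.  When several pairs tie for L_length, the lexicographically
    smallest proton-id pair defines u.  Two collinear protons give width 0.
    """
    if len(protons) < 2:
        raise ValueError("need at least two protons for length/width")
    xyz = np.asarray([p.xyz for p in protons], dtype=float)
    ids = [p.proton_id for p in protons]
    n = len(protons)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    L_length = float(dist.max())
    best_pair: tuple[str, str] | None = None
    best_vec = None
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] >= L_length - 1e-9:
                pair = tuple(sorted((ids[i], ids[j])))
                if best_pair is None or pair < best_pair:
                    best_pair = pair
                    best_vec = diff[j, i]
    assert best_vec is not None
    if L_length == 0.0:
        return 0.0, 0.0
    u = best_vec / np.linalg.norm(best_vec)
    ortho = diff - np.tensordot(diff @ u, u, axes=0)
    L_width = float(np.linalg.norm(ortho, axis=2).max())
    return L_length, L_width


def topology_parameters(
    network: RestraintNetwork, protons: Sequence[ProtonSite] | None = None
) -> TopologyParams:
    """Topology parameters of a network, computed over its active protons.

    Dropping restraints changes the apparent topology: a proton that loses
    its last restraint no longer counts toward the ligand dimensions, and
    <d> shifts with the surviving distances.
    """
    if not network.restraints:
        raise ValueError("empty network")
    pool = list(protons) if protons is not None else network.protons
    used = {r.proton_id for r in network.restraints}
    act = [p for p in pool if p.proton_id in used]
    mean_d = network.mean_d
    if len(act) < 2:
        L_len, L_wid = 0.0, 0.0
    else:
        L_len, L_wid = length_width(act)
    return TopologyParams(
        L_length=L_len,
        L_width=L_wid,
        mean_d=mean_d,
        r_l=L_len / mean_d,
        r_w=L_wid / mean_d,
    )


def _origin_in_hull(directions: np.ndarray, tol: float = 1e-9) -> bool:
    """Is the origin a convex combination of the given direction vectors?"""
    n = directions.shape[0]
    # feasibility LP: sum_i lam_i * d_i = 0, sum lam = 1, lam >= 0
    A_eq = np.vstack([directions.T, np.ones(n)])
    b_eq = np.array([0.0, 0.0, 0.0, 1.0])
    res = linprog(c=np.zeros(n), A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * n,
                  method="highs")
    return bool(res.success)


def site_diagnostics(
    methyls: Sequence[MethylSite], ligand_centroid: np.ndarray
) -> SiteDiagnostics:
    """Judge whether a methyl constellation can trilaterate a ligand pose.

    ``one_sided`` is true when all methyl carbons fit in one closed
    half-space through the ligand centroid (no direction set surrounds the
    ligand).  ``spread_score`` is the ratio of smallest to largest singular
    value of the centered carbon coordinates: 0 for collinear/planar-
    degenerate constellations, toward 1 for isotropic ones.  A site is
    suitable when it has >= 3 methyl-bearing residues and is not one-sided.
    """
    methyls = list(methyls)
    n_sites = len(methyls)
    residues = {(m.residue_number, m.residue_type) for m in methyls}
    if n_sites == 0:
        return SiteDiagnostics(0, 0, True, 0.0, False)
    xyz = np.asarray([m.carbon_xyz for m in methyls], dtype=float)
    centroid = np.asarray(ligand_centroid, dtype=float)
    dirs = xyz - centroid
    norms = np.linalg.norm(dirs, axis=1)
    norms[norms == 0] = 1.0
    dirs = dirs / norms[:, None]
    one_sided = not _origin_in_hull(dirs)
    centered = xyz - xyz.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    spread = float(sv[-1] / sv[0]) if sv[0] > 0 else 0.0
    suitable = (len(residues) >= 3) and not one_sided
    return SiteDiagnostics(
        n_methyl_residues=len(residues),
        n_methyl_sites=n_sites,
        one_sided=one_sided,
        spread_score=spread,
        suitable=suitable,
    )
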