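"""Pose-calculation engine: assignment enumeration, rigid-body optimization, ranking.

The combinatorial unknown is the injective map from anonymous methyl labels
``M_n`` to candidate methyl sites.  For each assignment consistent with the
partial-assignment constraints (and not provably infeasible by a
triangle-inequality prune), a rigid ligand pose is optimized against the
distance bounds with multi-start simulated annealing plus a deterministic
least-squares polish, and scored with a violation target function:

    tf = sum_r max(0, dist_r - upper_r - slack, lower_r - slack - dist_r)^2
         + w_clash * sum_pairs max(0, r_min - dist)^2          [A^2]

``slack`` (methyl_slack) absorbs receptor side-chain librations as a small
per-restraint distance allowance instead of explicit torsion sampling.
Structures from all assignments are ranked by tf; distinct local minima of
one assignment (poses differing by > 2 A) are retained as separate solutions
so that downstream validation can see genuinely ambiguous landscapes.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .restraints import AnonymousLabel, RestraintNetwork
from .structures import LigandConformer, MethylSite

logger = logging.getLogger(__name__)

#: Heavy-atom contact distance for the soft clash penalty (A).
CLASH_RMIN = 2.8


class EngineError(ValueError):
    """Raised for unusable engine inputs."""


@dataclass(frozen=True)
class Pose:
    """Rigid transform applied to the ligand conformer (receptor frame)."""

    rotation: np.ndarray     # (3, 3) proper orthonormal
    translation: np.ndarray  # (3,)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class AssignmentMap:
    """Injective mapping from anonymous labels to methyl sites."""

    mapping: Mapping[str, MethylSite]

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.mapping.values()]
        if len(set(ids)) != len(ids):
            raise EngineError("assignment map is not injective")

    def key(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted((l, s.site_id) for l, s in self.mapping.items()))


@dataclass(frozen=True)
class Solution:
    """One optimized structure: pose + assignment + target-function value."""

    pose: Pose
    assignment: AssignmentMap
    tf: float

    def __post_init__(self) -> None:
        if self.tf < 0:
            raise EngineError("target function cannot be negative")


@dataclass
class EngineConfig:
    """Engine parameters.  ``seed`` drives every stochastic component.

    The per-assignment random stream is derived from (seed, assignment), so a
    given assignment is optimized identically regardless of which other
    assignments are enumerated alongside it.
    """

    seed: int
    search_center: np.ndarray | None = None
    search_radius: float | None = None
    n_restarts: int = 6
    sa_steps: int = 400
    cooling: float = 0.985
    clash_weight: float = 1.0
    methyl_slack: float = 0.0
    prune_margin: float = 1.0
    early_tf: float = 3.0
    cluster_rmsd: float = 2.0
    max_cluster_reps: int = 4

    def __post_init__(self) -> None:
        if self.seed is None:
            raise EngineError("seed is mandatory")
        if not 0 < self.cooling < 1:
            raise EngineError("cooling must be in (0, 1)")
        for name in ("n_restarts", "sa_steps"):
            if getattr(self, name) < 1:
                raise EngineError(f"{name} must be positive")


def _stable_seed(seed: int, payload: object) -> int:
    return zlib.crc32(repr((seed, payload)).encode()) & 0x7FFFFFFF


def _rotvec_matrix(v: np.ndarray) -> np.ndarray:
    """Rodrigues rotation-vector to matrix (hot path; avoids scipy overhead)."""
    angle = float(np.sqrt(v @ v))
    if angle < 1e-12:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])
        return np.eye(3) + K  # first-order approximation
    axis = v / angle
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _row_norms(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", a, a))


# ---------------------------------------------------------------------------
# Assignment enumeration

def _sorted_labels(labels: Sequence[AnonymousLabel]) -> list[AnonymousLabel]:
    return sorted(labels, key=lambda l: (l.index, l.label))


def _candidate_sites(label: AnonymousLabel, sites: Sequence[MethylSite]) -> list[int]:
    if label.type_constraint is None:
        return list(range(len(sites)))
    return [i for i, s in enumerate(sites) if s.residue_type in label.type_constraint]


def enumerate_assignments(
    labels: Sequence[AnonymousLabel],
    sites: Sequence[MethylSite],
    prune: "callable | None" = None,
) -> Iterator[dict[str, int]]:
    """Yield every constraint-consistent injective label -> site-index map.

    Deterministic lexicographic order over (label order, site index).  A
    ``prune(partial_map, label, site_index) -> bool`` callback may reject a
    partial assignment early (return False to prune the branch).
    """
    labels = _sorted_labels(labels)
    if len(labels) > len(sites):
        raise EngineError(
            f"over-determined labels: {len(labels)} labels but only {len(sites)} sites"
        )
    cand = {}
    for l in labels:
        c = _candidate_sites(l, sites)
        if not c:
            raise EngineError(f"unsatisfiable type constraint on label {l.label}")
        cand[l.label] = c

    groups: dict[str, list[str]] = {}
    for l in labels:
        if l.same_residue_group is not None:
            groups.setdefault(l.same_residue_group, []).append(l.label)

    def ok_groups(partial: dict[str, int], label: AnonymousLabel, si: int) -> bool:
        if label.same_residue_group is None:
            return True
        for other in groups[label.same_residue_group]:
            if other == label.label or other not in partial:
                continue
            if sites[partial[other]].residue_number != sites[si].residue_number:
                return False
        return True

    def rec(k: int, partial: dict[str, int], used: set[int]) -> Iterator[dict[str, int]]:
        if k == len(labels):
            yield dict(partial)
            return
        label = labels[k]
        for si in cand[label.label]:
            if si in used:
                continue
            if not ok_groups(partial, label, si):
                continue
            if prune is not None and not prune(partial, label.label, si):
                continue
            partial[label.label] = si
            used.add(si)
            yield from rec(k + 1, partial, used)
            del partial[label.label]
            used.discard(si)

    yield from rec(0, {}, set())


# ---------------------------------------------------------------------------
# Geometric feasibility pruning

class _PairBounds:
    """Per-label-pair separation bounds implied by shared protons.

    If labels l1 and l2 both restrain proton p, any pose places p within
    [lower, upper] of both assigned sites, so the sites must satisfy
    ||s1 - s2|| <= upper1 + upper2 and ||s1 - s2|| >= lower_i - upper_j.
    """

    def __init__(self, network: RestraintNetwork, labels: Sequence[AnonymousLabel]):
        idx = {l.label: i for i, l in enumerate(labels)}
        n = len(labels)
        self.index = idx
        self.maxsep = np.full((n, n), np.inf)
        self.minsep = np.zeros((n, n))
        per_label: dict[str, dict[str, tuple[float, float]]] = {}
        for r in network.restraints:
            per_label.setdefault(r.label, {})[r.proton_id] = (r.lower, r.upper)
        for l1, l2 in itertools.combinations(per_label, 2):
            if l1 not in idx or l2 not in idx:
                continue
            shared = per_label[l1].keys() & per_label[l2].keys()
            if not shared:
                continue
            hi = min(per_label[l1][p][1] + per_label[l2][p][1] for p in shared)
            lo = max(
                max(per_label[l1][p][0] - per_label[l2][p][1],
                    per_label[l2][p][0] - per_label[l1][p][1])
                for p in shared
            )
            i, j = idx[l1], idx[l2]
            self.maxsep[i, j] = self.maxsep[j, i] = hi
            self.minsep[i, j] = self.minsep[j, i] = max(0.0, lo)

    def compatible(
        self,
        partial: Mapping[str, int],
        label: str,
        site_index: int,
        site_dist: np.ndarray,
        slack: float,
        margin: float,
    ) -> bool:
        i = self.index[label]
        pad = 2.0 * slack + margin
        for other, sj in partial.items():
            j = self.index[other]
            d = site_dist[site_index, sj]
            if d > self.maxsep[i, j] + pad:
                return False
            if d < self.minsep[i, j] - pad:
                return False
        return True


def feasibility_prune(
    partial: Mapping[str, int],
    label: str,
    site_index: int,
    network: RestraintNetwork,
    sites: Sequence[MethylSite],
    methyl_slack: float = 0.0,
    margin: float = 0.0,
) -> bool:
    """True when extending ``partial`` with label -> site is geometrically feasible.

    Returns False (prune) when the inter-site distance violates the bounds
    implied by a shared proton: two sites cannot both be within their upper
    limits of one proton if they are farther apart than the limits' sum.
    """
    bounds = _PairBounds(network, _sorted_labels(network.labels))
    xyz = np.asarray([s.carbon_xyz for s in sites])
    site_dist = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
    return bounds.compatible(partial, label, site_index, site_dist, methyl_slack, margin)


# ---------------------------------------------------------------------------
# Scoring and optimization

class _Problem:
    """Vectorized scoring state shared across assignments."""

    def __init__(
        self,
        network: RestraintNetwork,
        sites: Sequence[MethylSite],
        ligand: LigandConformer,
        receptor_heavy_xyz: np.ndarray | None,
        config: EngineConfig,
    ):
        self.config = config
        self.labels = _sorted_labels(network.labels)
        self.label_index = {l.label: i for i, l in enumerate(self.labels)}
        self.sites = list(sites)
        self.site_xyz = np.asarray([s.carbon_xyz for s in sites], dtype=float)
        pidx = ligand.proton_index()
        missing = [r.proton_id for r in network.restraints if r.proton_id not in pidx]
        if missing:
            raise EngineError(f"restraint protons missing from ligand conformer: {missing[:3]}")
        self.centroid = ligand.heavy_xyz.mean(axis=0) if len(ligand.heavy_xyz) else \
            ligand.proton_xyz.mean(axis=0)
        self.proton_local = ligand.proton_xyz - self.centroid
        self.heavy_local = ligand.heavy_xyz - self.centroid if len(ligand.heavy_xyz) else \
            np.zeros((0, 3))
        order = sorted(
            network.restraints, key=lambda r: (self.label_index[r.label], r.proton_id)
        )
        self.r_proton = np.asarray([pidx[r.proton_id] for r in order])
        self.r_label = np.asarray([self.label_index[r.label] for r in order])
        self.lower = np.asarray([r.lower for r in order])
        self.upper = np.asarray([r.upper for r in order])
        self.central = 0.5 * (self.lower + self.upper)
        self.receptor = (
            np.asarray(receptor_heavy_xyz, dtype=float).reshape(-1, 3)
            if receptor_heavy_xyz is not None and len(receptor_heavy_xyz)
            else np.zeros((0, 3))
        )
        if config.search_center is None:
            center = self.site_xyz.mean(axis=0)
        else:
            center = np.asarray(config.search_center, dtype=float)
        self.center = center
        if config.search_radius is None:
            site_r = float(np.linalg.norm(self.site_xyz - center, axis=1).max())
            if len(self.proton_local) >= 2:
                span = float(
                    np.linalg.norm(
                        self.proton_local[:, None] - self.proton_local[None, :], axis=2
                    ).max()
                )
            else:
                span = 0.0
            self.radius = site_r + span / 2.0 + 2.0
        else:
            self.radius = float(config.search_radius)
        self.site_dist = np.linalg.norm(
            self.site_xyz[:, None] - self.site_xyz[None, :], axis=2
        )
        self.pair_bounds = _PairBounds(network, self.labels)

    # -- scoring ----------------------------------------------------------

    def violations(self, R: np.ndarray, t: np.ndarray, site_per_restraint: np.ndarray
                   ) -> np.ndarray:
        pp = self.proton_local @ R.T + t
        d = _row_norms(pp[self.r_proton] - site_per_restraint)
        slack = self.config.methyl_slack
        over = d - self.upper - slack
        under = self.lower - slack - d
        return np.maximum(0.0, np.maximum(over, under))

    def clash(self, R: np.ndarray, t: np.ndarray) -> np.ndarray:
        if self.receptor.shape[0] == 0 or self.heavy_local.shape[0] == 0:
            return np.zeros(0)
        lh = self.heavy_local @ R.T + t
        diff = lh[:, None, :] - self.receptor[None, :, :]
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        return np.maximum(0.0, CLASH_RMIN - d).ravel()

    def tf(self, R: np.ndarray, t: np.ndarray, site_per_restraint: np.ndarray) -> float:
        v = self.violations(R, t, site_per_restraint)
        out = float(v @ v)
        c = self.clash(R, t)
        if c.size:
            out += self.config.clash_weight * float(c @ c)
        return out

    def assignment_sites(self, assign: Mapping[str, int]) -> np.ndarray:
        per_label = np.asarray([assign[l.label] for l in self.labels])
        return self.site_xyz[per_label[self.r_label]]

    # -- optimization -----------------------------------------------------

    def _residuals(self, x: np.ndarray, spr: np.ndarray) -> np.ndarray:
        R = _rotvec_matrix(x[:3])
        t = x[3:]
        v = self.violations(R, t, spr)
        c = self.clash(R, t)
        if c.size:
            return np.concatenate([v, np.sqrt(self.config.clash_weight) * c])
        return v

    def _active_clash_pairs(self, R: np.ndarray, t: np.ndarray, pad: float = 0.5
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Ligand-heavy/receptor pairs within contact range (+pad) at a pose."""
        if self.receptor.shape[0] == 0 or self.heavy_local.shape[0] == 0:
            return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        lh = self.heavy_local @ R.T + t
        d = np.linalg.norm(lh[:, None, :] - self.receptor[None, :, :], axis=2)
        hi, ri = np.nonzero(d < CLASH_RMIN + pad)
        return hi, ri

    def _residuals_active(self, x: np.ndarray, spr: np.ndarray,
                          hi: np.ndarray, ri: np.ndarray) -> np.ndarray:
        R = _rotvec_matrix(x[:3])
        t = x[3:]
        v = self.violations(R, t, spr)
        if hi.size == 0:
            return v
        lh = self.heavy_local[hi] @ R.T + t
        d = _row_norms(lh - self.receptor[ri])
        c = np.maximum(0.0, CLASH_RMIN - d)
        return np.concatenate([v, np.sqrt(self.config.clash_weight) * c])

    def _analytic_seed(self, assign: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray] | None:
        """Trilateration-based starting pose for one assignment.

        Each proton restrained by >= 3 beacons has its position estimated by
        linearized multilateration against the assigned methyl carbons (using
        central distances); the rigid pose is then the proper Kabsch fit of
        the conformer protons onto those estimates.  For a geometrically
        consistent assignment this lands in the global basin directly; for an
        inconsistent one it still provides a sensible least-violation start.
        """
        per_label = np.asarray([assign[l.label] for l in self.labels])
        site_per_restraint = self.site_xyz[per_label[self.r_label]]
        est_world = []
        est_local = []
        for p in np.unique(self.r_proton):
            mask = self.r_proton == p
            if mask.sum() < 3:
                continue
            s = site_per_restraint[mask]
            d = self.central[mask]
            s0, d0 = s[0], d[0]
            A = 2.0 * (s[1:] - s0)
            b = (d0 ** 2 - d[1:] ** 2) + np.sum(s[1:] ** 2, axis=1) - np.sum(s0 ** 2)
            x, *_ = np.linalg.lstsq(A, b, rcond=None)
            est_world.append(x)
            est_local.append(self.proton_local[p])
        if len(est_world) < 3:
            return None
        W = np.asarray(est_world)
        L = np.asarray(est_local)
        wm, lm = W.mean(axis=0), L.mean(axis=0)
        rot, _ = Rotation.align_vectors(W - wm, L - lm)
        R = rot.as_matrix()
        t = wm - lm @ R.T
        return R, t

    def optimize_assignment(
        self, assign: Mapping[str, int], best_known: float = np.inf
    ) -> list[tuple[float, Pose]]:
        """Analytic seed + multi-start SA, each least-squares polished.

        Deterministic for a given (config.seed, assignment).  Random restarts
        after the first are skipped when the best polished tf so far exceeds
        ``early_tf`` above ``best_known`` (such an assignment can influence
        neither the top rank nor a near-threshold contrast).
        """
        cfg = self.config
        spr = self.assignment_sites(assign)
        akey = tuple(sorted(assign.items()))
        rng = np.random.Generator(np.random.PCG64(_stable_seed(cfg.seed, akey)))

        # Temperature scale from the tf spread of random poses.
        probes = [self.tf(*self._random_pose(rng), spr) for _ in range(4)]
        T0 = max(float(np.median(probes)), 1e-2)

        results: list[tuple[float, Pose]] = []
        seed_pose = self._analytic_seed(assign)
        if seed_pose is not None:
            results.append(self._polish(seed_pose[0], seed_pose[1], spr))
        for restart in range(cfg.n_restarts):
            R, t = self._random_pose(rng)
            cur = self.tf(R, t, spr)
            best_R, best_t, best_tf = R, t, cur
            T = T0
            for _ in range(cfg.sa_steps):
                T *= cfg.cooling
                s = max(T / T0, 1e-6) ** 0.5
                dR = _rotvec_matrix(rng.normal(0.0, 0.5 * s, 3))
                Rn = dR @ R
                tn = t + rng.normal(0.0, 0.35 * self.radius * s, 3)
                off = tn - self.center
                r = np.linalg.norm(off)
                if r > self.radius:
                    tn = self.center + off * (self.radius / r)
                new = self.tf(Rn, tn, spr)
                if new < cur or rng.random() < np.exp(-(new - cur) / max(T, 1e-12)):
                    R, t, cur = Rn, tn, new
                    if cur < best_tf:
                        best_R, best_t, best_tf = R, t, cur
            tf_val, pose = self._polish(best_R, best_t, spr)
            if tf_val > best_tf:  # polish can only be accepted if it helps
                tf_val, pose = best_tf, Pose(best_R, best_t + self.centroid_shift(best_R))
            results.append((tf_val, pose))
            if restart == 0 and min(r[0] for r in results) > best_known + cfg.early_tf:
                break
        return results

    def centroid_shift(self, R: np.ndarray) -> np.ndarray:
        # poses act on original (uncentered) conformer coordinates
        return -(self.centroid @ R.T)

    def _random_pose(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        R = Rotation.from_quat(q).as_matrix()
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        t = self.center + u * self.radius * rng.random() ** (1.0 / 3.0)
        return R, t

    def _polish(self, R: np.ndarray, t: np.ndarray, spr: np.ndarray) -> tuple[float, Pose]:
        """Least-squares refinement with an active-set clash term.

        Only near-contact ligand/receptor pairs enter the residual vector;
        after convergence the set is re-checked once and the fit repeated if
        new contacts appeared.  The returned tf is always recomputed with the
        full clash sum.
        """
        x = np.concatenate([Rotation.from_matrix(R).as_rotvec(), t])
        hi, ri = self._active_clash_pairs(R, t)
        for _ in range(2):
            res = least_squares(
                self._residuals_active, x, args=(spr, hi, ri), method="trf",
                max_nfev=60, xtol=1e-8, ftol=1e-10, gtol=1e-9,
            )
            x = res.x
            Rf = _rotvec_matrix(x[:3])
            hi2, ri2 = self._active_clash_pairs(Rf, x[3:], pad=0.0)
            known = set(zip(hi.tolist(), ri.tolist()))
            if all(p in known for p in zip(hi2.tolist(), ri2.tolist())):
                break
            hi, ri = self._active_clash_pairs(Rf, x[3:])
        Rf = _rotvec_matrix(x[:3])
        tf_val = self.tf(Rf, x[3:], spr)
        pose = Pose(Rf, x[3:] + self.centroid_shift(Rf))
        return tf_val, pose

    def pose_tf(self, pose: Pose, assign: Mapping[str, int]) -> float:
        """tf of a pose given in original-conformer convention."""
        spr = self.assignment_sites(assign)
        t_centered = pose.translation + self.centroid @ pose.rotation.T
        return self.tf(pose.rotation, t_centered, spr)


def score_pose(
    pose: Pose,
    assignment: AssignmentMap,
    network: RestraintNetwork,
    ligand: LigandConformer,
    receptor_heavy_xyz: np.ndarray | None = None,
    config: EngineConfig | None = None,
) -> float:
    """Target function of one pose under one assignment (deterministic)."""
    cfg = config or EngineConfig(seed=0, methyl_slack=0.0)
    site_ids = {l: s for l, s in assignment.mapping.items()}
    sites = [site_ids[l.label] for l in _sorted_labels(network.labels)]
    prob = _Problem(network, sites, ligand, receptor_heavy_xyz, cfg)
    assign = {l.label: i for i, l in enumerate(_sorted_labels(network.labels))}
    return prob.pose_tf(pose, assign)


def optimize_pose(
    assignment: AssignmentMap,
    network: RestraintNetwork,
    ligand: LigandConformer,
    receptor_heavy_xyz: np.ndarray | None = None,
    config: EngineConfig | None = None,
) -> Solution:
    """Best pose found for a single fixed assignment."""
    cfg = config or EngineConfig(seed=0)
    labels = _sorted_labels(network.labels)
    site_list = [assignment.mapping[l.label] for l in labels]
    prob = _Problem(network, site_list, ligand, receptor_heavy_xyz, cfg)
    assign = {l.label: i for i, l in enumerate(labels)}
    results = prob.optimize_assignment(assign)
    tf_val, pose = min(results, key=lambda r: r[0])
    return Solution(pose=pose, assignment=assignment, tf=tf_val)


def run_nmr2(
    network: RestraintNetwork,
    sites: Sequence[MethylSite],
    ligand: LigandConformer,
    receptor_heavy_xyz: np.ndarray | None = None,
    config: EngineConfig | None = None,
    prune: bool = True,
) -> list[Solution]:
    """Enumerate assignments, optimize each, and rank all structures by tf.

    Per assignment, the restart results are clustered by pose rmsd
    (> ``config.cluster_rmsd`` apart = distinct) and each cluster's best
    becomes a Solution, so intrinsically ambiguous landscapes surface as
    near-equal-tf solutions.  The list is sorted by (tf, enumeration order).
    """
    cfg = config or EngineConfig(seed=0)
    prob = _Problem(network, sites, ligand, receptor_heavy_xyz, cfg)

    prune_cb = None
    if prune:
        def prune_cb(partial, label, si):  # noqa: ANN001 - internal callback
            return prob.pair_bounds.compatible(
                partial, label, si, prob.site_dist, cfg.methyl_slack, cfg.prune_margin
            )

    solutions: list[tuple[float, int, Solution]] = []
    best_tf = np.inf
    n_assign = 0
    heavy = ligand.heavy_xyz if len(ligand.heavy_xyz) else ligand.proton_xyz
    for assign in enumerate_assignments(network.labels, sites, prune=prune_cb):
        n_assign += 1
        amap = AssignmentMap({l: sites[i] for l, i in assign.items()})
        results = sorted(prob.optimize_assignment(assign, best_known=best_tf),
                         key=lambda r: r[0])
        reps: list[tuple[float, Pose]] = []
        for tf_val, pose in results:
            coords = pose.apply(heavy)
            distinct = all(
                float(np.sqrt(np.mean(np.sum((coords - p.apply(heavy)) ** 2, axis=1))))
                > cfg.cluster_rmsd
                for _, p in reps
            )
            if distinct:
                reps.append((tf_val, pose))
            if len(reps) >= cfg.max_cluster_reps:
                break
        for tf_val, pose in reps:
            solutions.append((tf_val, len(solutions), Solution(pose, amap, tf_val)))
            best_tf = min(best_tf, tf_val)
    if n_assign == 0:
        raise EngineError("no assignment satisfies the constraints (empty stream)")
    solutions.sort(key=lambda s: (s[0], s[1]))
    logger.debug("ranked %d structures from %d assignments", len(solutions), n_assign)
    return [s for _, _, s in solutions]
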