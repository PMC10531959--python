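"""Seeded generator of ground-truth benchmark cases.

Each case is a desk-scale stand-in for one protein-fragment complex: a
sparse receptor shell with methyl beacons on a pocket sphere, a rigid
proton/heavy-atom ligand with controllable length/width, a known truth pose,
and the exact semi-ambiguous restraint network re-derivable from them.  The
generator controls the two knobs the method is sensitive to -- binding-site
geometry (spread / one-sided / collinear / too-few-residues) and ligand
topology (r_l + r_w above or below the empirical ~2 boundary) -- so every
downstream property is testable without external structures.

Receptor shells are minimal point clouds (methyl carbons plus wall atoms for
the clash term), not full proteins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .engine import AssignmentMap, Pose
from .restraints import (
    RestraintNetwork,
    apply_tolerance,
    attach_partial_assignment,
    extract_restraints,
    write_restraints_tsv,
)
from .topology import site_diagnostics
from .structures import (
    Atom,
    LigandConformer,
    MethylSite,
    ProtonSite,
    METHYL_CARBONS,
    TWO_METHYL_RESIDUES,
    methyl_sites_to_json,
    write_pdb,
)

#: Restraint floor below which fragment pose calculations are unreliable.
MIN_RESTRAINTS = 12

#: Geminal methyl carbon separation (A).
_GEMINAL_SEP = 2.5

_SINGLE_METHYL = ("ALA", "THR", "MET")
_ALL_TYPES = ("ALA", "VAL", "LEU", "ILE", "THR", "MET")

# Canonical well-spread unit directions for small n (jittered + rotated later).
_SPREAD_DIRS = {
    1: [(1, 0, 0)],
    2: [(1, 0, 0), (-1, 0, 0)],
    3: [(1, 0, 0), (-0.5, math.sqrt(3) / 2, 0), (-0.5, -math.sqrt(3) / 2, 0)],
    4: [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)],
    5: [(1, 0, 0), (-0.5, math.sqrt(3) / 2, 0), (-0.5, -math.sqrt(3) / 2, 0),
        (0, 0, 1), (0, 0, -1)],
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
}


class SyntheticError(RuntimeError):
    """Raised when a requested case cannot be generated."""


@dataclass
class SyntheticCase:
    """One ground-truth benchmark case."""

    case_id: str
    sites: list[MethylSite]
    receptor_shell_xyz: np.ndarray
    ligand: LigandConformer
    truth_pose: Pose
    truth_assignment: AssignmentMap
    network: RestraintNetwork          # tolerance/PA applied per request
    exact_network: RestraintNetwork    # 0% tolerance, no PA
    pa_types: dict[str, frozenset[str]]
    pa_pairs: list[tuple[str, str]]
    intended: dict
    seed: int
    network_seed: int = 0

    @property
    def receptor_heavy_xyz(self) -> np.ndarray:
        carbons = np.asarray([s.carbon_xyz for s in self.sites])
        if self.receptor_shell_xyz.size:
            return np.vstack([carbons, self.receptor_shell_xyz])
        return carbons

    def truth_protons(self) -> list[ProtonSite]:
        world = self.truth_pose.apply(self.ligand.proton_xyz)
        return [
            ProtonSite(pid, "", xyz)
            for pid, xyz in zip(self.ligand.proton_ids, world)
        ]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _jitter_dir(d: np.ndarray, sigma_rad: float, rng: np.random.Generator) -> np.ndarray:
    return _unit(d + rng.normal(0.0, sigma_rad, 3))


def _cap_dir(axis: np.ndarray, half_angle: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform direction within a spherical cap around *axis*."""
    cos_min = math.cos(half_angle)
    c = rng.uniform(cos_min, 1.0)
    s = math.sqrt(1.0 - c * c)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    # orthonormal frame around axis
    a = _unit(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(a, ref))
    e2 = np.cross(a, e1)
    return c * a + s * (math.cos(phi) * e1 + math.sin(phi) * e2)


def make_site(
    n_methyl_residues: int,
    geometry: str = "spread",
    radius: float = 6.0,
    seed: int = 0,
    max_sites: int = 5,
    cap_half_angle_deg: float = 40.0,
) -> tuple[list[MethylSite], np.ndarray]:
    """Place methyl-bearing residues on a pocket sphere around the origin.

    ``geometry`` is one of ``spread`` (evenly distributed beacons),
    ``one_sided`` (all carbons within one spherical cap -- the degenerate
    constellation that leaves the opposite half-space unprobed), or
    ``collinear`` (carbons on one line through the pocket).  Residue types
    are drawn from the six methyl types; type draws are repeated if the
    geminal methyls would push the carbon count past ``max_sites`` (keeps
    the assignment combinatorics desk-scale).

    Returns the methyl sites plus a sparse receptor wall (heavy-atom point
    cloud behind the beacons) for the clash term.
    """
    if n_methyl_residues < 1:
        raise ValueError("need at least one methyl residue")
    rng = np.random.default_rng(seed)

    # residue types, capped total carbon count
    for _ in range(200):
        types = [str(t) for t in rng.choice(_ALL_TYPES, size=n_methyl_residues)]
        n_carbons = sum(2 if t in TWO_METHYL_RESIDUES or t == "ILE" else 1 for t in types)
        if n_carbons <= max_sites:
            break
    else:
        types = [str(t) for t in rng.choice(_SINGLE_METHYL, size=n_methyl_residues)]

    n = n_methyl_residues
    if geometry == "spread":
        base = _SPREAD_DIRS.get(n)
        if base is None:
            # Fibonacci lattice for larger constellations
            i = np.arange(n) + 0.5
            phi = np.arccos(1 - 2 * i / n)
            theta = np.pi * (1 + 5 ** 0.5) * i
            base = np.c_[np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        R = _random_rotation(rng)
        # Strong jitter: real pockets are irregular, and a symmetric beacon
        # constellation is itself a degenerate (rotation-ambiguous) site.
        dirs = [_jitter_dir(np.asarray(_unit(np.asarray(d, float))) @ R.T, 0.30, rng)
                for d in base]
    elif geometry == "one_sided":
        axis = _unit(rng.normal(size=3))
        half = math.radians(cap_half_angle_deg)
        dirs = [_cap_dir(axis, half, rng) for _ in range(n)]
    elif geometry == "collinear":
        axis = _unit(rng.normal(size=3))
        ts = np.linspace(-1.0, 1.0, n) if n > 1 else np.array([1.0])
        dirs = [axis * (t if abs(t) > 0.2 else math.copysign(0.3, t if t else 1.0))
                for t in ts]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    sites: list[MethylSite] = []
    shell: list[np.ndarray] = []
    for i, (rtype, d) in enumerate(zip(types, dirs)):
        resnum = 10 * (i + 1)
        scale = radius * float(rng.uniform(0.85, 1.15))
        if geometry == "collinear":
            pos = np.asarray(d, float) * scale
            outward = _unit(pos) if np.linalg.norm(pos) > 0 else np.array([1.0, 0, 0])
        else:
            pos = np.asarray(d, float) * scale
            outward = np.asarray(d, float)
        carbons = METHYL_CARBONS[rtype]
        positions = [pos]
        if len(carbons) == 2:
            if geometry == "collinear":
                second = pos + _GEMINAL_SEP * _unit(pos)
            else:
                cap_axis = _unit(np.mean(np.asarray(dirs, float), axis=0))
                for _ in range(50):
                    g = _unit(rng.normal(size=3))
                    second = pos + _GEMINAL_SEP * g
                    if geometry == "one_sided":
                        ok = float(np.dot(_unit(second), cap_axis)) > 0.3
                    else:
                        ok = float(np.dot(g, outward)) > -0.3
                    if ok and np.linalg.norm(second) > 0.85 * radius:
                        break
            positions.append(second)
        for atom_name, cpos in zip(carbons, positions):
            sites.append(
                MethylSite(
                    site_id=f"{rtype}{resnum}-{atom_name}",
                    residue_number=resnum,
                    residue_type=rtype,
                    methyl_atom_name=atom_name,
                    carbon_xyz=np.asarray(cpos, dtype=float),
                )
            )
        # wall atoms behind this residue
        for extra in (1.8, 3.2):
            shell.append(pos + outward * extra + rng.normal(0, 0.4, 3))
    # sparse global wall behind the beacon hemisphere(s)
    mean_dir = _unit(np.mean([s.carbon_xyz for s in sites], axis=0)) \
        if geometry == "one_sided" else None
    for _ in range(10):
        if mean_dir is not None:
            d = _cap_dir(mean_dir, math.radians(70.0), rng)
        else:
            d = _unit(rng.normal(size=3))
        shell.append(d * (radius + 3.0) + rng.normal(0, 0.5, 3))
    sites.sort(key=lambda s: (s.residue_number, s.methyl_atom_name))
    return sites, np.asarray(shell, dtype=float)


def make_ligand(
    n_protons: int, length: float, width: float, seed: int = 0
) -> LigandConformer:
    """Rigid proton cloud with prescribed length and width, plus a heavy scaffold.

    Two protons at +/- length/2 on the long axis realize L_length exactly;
    for width > 0 a cross pair at +/- width/2 realizes L_width exactly; the
    remaining protons fall inside the enclosing lens so neither extreme is
    exceeded.  A carbon sits ~1.1 A under each proton (toward the centroid)
    and one at the center -- enough scaffold for rmsd and clash scoring.
    """
    if n_protons < 2:
        raise ValueError("need at least two protons")
    if width > length:
        raise ValueError("infeasible: width exceeds length")
    if width < 0:
        raise ValueError("negative width")
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = [
        np.array([-length / 2.0, 0.0, 0.0]),
        np.array([length / 2.0, 0.0, 0.0]),
    ]
    # Off-center cross pair: breaks the centro-symmetry that would make the
    # proton cloud (and hence the restraint network) rotation-ambiguous.
    x0 = float(rng.uniform(0.10, 0.25) * length * rng.choice([-1.0, 1.0]))
    if width > 0 and n_protons >= 4:
        pts.append(np.array([x0, width / 2.0, 0.0]))
        pts.append(np.array([x0, -width / 2.0, 0.0]))
    elif width > 0 and n_protons == 3:
        pts.append(np.array([x0, width, 0.0]))
    while len(pts) < n_protons:
        x = rng.uniform(-0.3 * length, 0.3 * length)
        # inside the (y, z) disc of diameter `width`: a genuinely 3-D proton
        # cloud, so the distance network carries no spurious mirror symmetry
        r = (width / 2.0) * math.sqrt(rng.uniform(0, 1)) if width > 0 else 0.0
        phi = rng.uniform(0, 2 * math.pi)
        pts.append(np.array([x, r * math.cos(phi), r * math.sin(phi)]))
    proton_xyz = np.asarray(pts[:n_protons], dtype=float)
    heavy = [np.zeros(3)]
    for p in proton_xyz:
        r = float(np.linalg.norm(p))
        # carbon ~1 A inside each proton, but never collapsing to the center:
        # the heavy skeleton must span most of the proton cloud (as in a real
        # ring system) or heavy-atom rmsd becomes blind to orientation.
        heavy.append(p * (max(r - 1.05, 0.58 * r) / r) if r > 1e-9 else np.array([0.3, 0, 0]))
    return LigandConformer(
        proton_ids=tuple(f"H{i+1}" for i in range(n_protons)),
        proton_xyz=proton_xyz,
        heavy_names=tuple(f"C{i}" for i in range(len(heavy))),
        heavy_xyz=np.asarray(heavy, dtype=float),
    )


def realistic_partial_assignment(
    truth: Mapping[str, MethylSite]
) -> tuple[dict[str, frozenset[str]], list[tuple[str, str]]]:
    """Partial assignment as auxiliary experiments would give it.

    MET methyls are identified as methionine (ctHSQC), ALA and THR by their
    TOCSY pattern; VAL/LEU/ILE methyls are only known to belong to that
    group.  Two labels whose methyls share a residue are paired.  Only true
    information is produced -- never a misleading constraint.
    """
    types: dict[str, frozenset[str]] = {}
    by_residue: dict[int, list[str]] = {}
    for label, site in truth.items():
        if site.residue_type in ("MET", "ALA", "THR"):
            types[label] = frozenset({site.residue_type})
        else:
            types[label] = frozenset({"VAL", "LEU", "ILE"})
        by_residue.setdefault(site.residue_number, []).append(label)
    pairs = [
        (labs[0], labs[1])
        for labs in by_residue.values()
        if len(labs) == 2
    ]
    return types, pairs


def _cavity_wall(
    heavy_world: np.ndarray,
    site_radius: float,
    carbons: np.ndarray,
    rng: np.random.Generator,
    n_points: int = 64,
    clearance: float = 4.0,
    mouth_half_angle_deg: float = 45.0,
) -> np.ndarray:
    """Heavy-atom pocket wall complementary to the bound ligand.

    Along each direction the wall sits at the ligand's support function plus
    ``clearance``: 2.8 A of van-der-Waals contact plus ~1.2 A of free room,
    the linear margin implied by a typical pocket/ligand volume ratio around
    2.4.  The wall never dips inside the methyl-beacon sphere
    (pockets are at least as large as the residue shell that lines them).
    A ligand that fills the pocket is therefore sterically confined, while a
    small fragment keeps positional freedom inside the same beacon shell.
    A cap around a random axis stays open (the solvent mouth); wall points
    too close to a methyl carbon are dropped so the beacons stay exposed.
    """
    i = np.arange(n_points) + 0.5
    phi = np.arccos(1 - 2 * i / n_points)
    theta = np.pi * (1 + 5 ** 0.5) * i
    dirs = np.c_[np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    mouth = _unit(rng.normal(size=3))
    dirs = dirs[dirs @ mouth < math.cos(math.radians(mouth_half_angle_deg))]
    support = (dirs @ heavy_world.T).max(axis=1)  # signed extent along each dir
    radii = np.maximum(support + clearance, site_radius - 1.5)
    pts = dirs * radii[:, None] + rng.normal(0, 0.25, (len(dirs), 3))
    if len(carbons):
        d = np.linalg.norm(pts[:, None] - carbons[None], axis=2).min(axis=1)
        pts = pts[d > 2.0]
    return pts


def make_case(
    site_spec: Mapping,
    ligand_spec: Mapping,
    placement: float = 0.8,
    tolerance_fraction: float = 0.0,
    pa_fraction: float = 0.0,
    seed: int = 0,
    max_distance: float = 7.5,
    min_restraints: int = MIN_RESTRAINTS,
    case_id: str | None = None,
    retries: int = 40,
) -> SyntheticCase:
    """Generate one ground-truth case (site + ligand + truth pose + network).

    The ligand is dropped at a random orientation within ``placement`` A of
    the pocket center; the exact network is extracted from the truth
    geometry, then tolerance and (optionally) a ``pa_fraction`` share of the
    realistic partial assignment are applied.  Attempts that yield fewer
    than ``min_restraints`` restraints, steric clashes at the truth pose, or
    proton-carbon contacts below van-der-Waals range are regenerated.
    """
    last_reason = ""
    n_residues_wanted = int(site_spec.get("n_methyl_residues", 0))
    for attempt in range(retries):
        ss = np.random.SeedSequence(entropy=(int(seed), attempt))
        s_site, s_lig, s_pose, s_net, s_pa = (
            int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(5)
        )
        sites, shell = make_site(seed=s_site, **site_spec)
        ligand = make_ligand(seed=s_lig, **ligand_spec)
        rng = np.random.default_rng(s_pose)
        R = _random_rotation(rng)
        t = rng.normal(size=3)
        t = t / np.linalg.norm(t) * placement * rng.random()
        pose = Pose(R, t)

        proton_world = pose.apply(ligand.proton_xyz)
        heavy_world = pose.apply(ligand.heavy_xyz)
        carbons = np.asarray([s.carbon_xyz for s in sites])
        receptor = np.vstack([carbons, shell])
        d_pc = np.linalg.norm(proton_world[:, None] - carbons[None], axis=2)
        d_hh = np.linalg.norm(heavy_world[:, None] - receptor[None], axis=2)
        if d_pc.min() < 2.0:
            last_reason = "proton-methyl contact below vdW range"
            continue
        if d_hh.min() < 2.85:
            last_reason = "steric clash at truth pose"
            continue
        if site_spec.get("geometry", "spread") == "spread" and n_residues_wanted >= 3:
            diag = site_diagnostics(sites, heavy_world.mean(axis=0))
            if not diag.suitable:
                last_reason = "spread site came out unsuitable"
                continue
        # Pocket wall just behind the beacon sphere: real pockets confine the
        # fragment sterically, which is part of what keeps tolerant
        # restraints resolvable for ligands that fill the pocket.
        wall = _cavity_wall(heavy_world, float(site_spec.get("radius", 6.0)),
                            carbons, rng)
        shell_full = np.vstack([shell, wall]) if len(wall) else shell
        d_hh_wall = np.linalg.norm(heavy_world[:, None] - shell_full[None], axis=2)
        if d_hh_wall.min() < 2.85:
            last_reason = "wall construction clashed with truth pose"
            continue
        protons = [
            ProtonSite(pid, "", xyz)
            for pid, xyz in zip(ligand.proton_ids, proton_world)
        ]
        try:
            exact, truth = extract_restraints(protons, sites, max_distance, seed=s_net)
        except Exception:
            last_reason = "no restraints in range"
            continue
        if len(exact) < min_restraints:
            last_reason = f"only {len(exact)} restraints (< {min_restraints})"
            continue

        pa_types, pa_pairs = realistic_partial_assignment(truth)
        network = apply_tolerance(exact, tolerance_fraction) \
            if tolerance_fraction > 0 else exact
        applied_types: dict[str, frozenset[str]] = {}
        applied_pairs: list[tuple[str, str]] = []
        if pa_fraction > 0:
            pa_rng = np.random.default_rng(s_pa)
            labels = sorted(pa_types, key=lambda l: int(l.split("_")[1]))
            k = int(math.ceil(pa_fraction * len(labels)))
            chosen = set(
                labels[i] for i in pa_rng.choice(len(labels), size=k, replace=False)
            )
            applied_types = {l: pa_types[l] for l in chosen}
            applied_pairs = [p for p in pa_pairs if p[0] in chosen and p[1] in chosen]
            network = attach_partial_assignment(network, applied_types, applied_pairs)

        return SyntheticCase(
            case_id=case_id or f"case-{seed}",
            sites=sites,
            receptor_shell_xyz=shell_full,
            ligand=ligand,
            truth_pose=pose,
            truth_assignment=AssignmentMap(dict(truth)),
            network=network,
            exact_network=exact,
            pa_types=pa_types,
            pa_pairs=pa_pairs,
            intended=dict(
                site=dict(site_spec),
                ligand=dict(ligand_spec),
                tolerance_fraction=tolerance_fraction,
                pa_fraction=pa_fraction,
                max_distance=max_distance,
                min_restraints=min_restraints,
            ),
            seed=seed,
            network_seed=s_net,
        )
    raise SyntheticError(
        f"could not generate a case after {retries} attempts (last: {last_reason})"
    )


# -- canned study conditions ------------------------------------------------

#: Mid-size fragment in a four-residue pocket (the default benchmark case).
STANDARD_SPEC = dict(
    site=dict(n_methyl_residues=4, geometry="spread", radius=6.0),
    ligand=dict(n_protons=7, length=6.5, width=3.2),
    max_distance=14.0,
)

#: Elongated pocket-filling fragment probed through short distances:
#: r_l + r_w well above 2.
HIGH_TOPOLOGY_SPEC = dict(
    site=dict(n_methyl_residues=5, geometry="spread", radius=6.0),
    ligand=dict(n_protons=8, length=10.0, width=4.8),
    max_distance=14.0,
)

#: Modest fragment probed through long distances: r_l + r_w well below 2.
LOW_TOPOLOGY_SPEC = dict(
    site=dict(n_methyl_residues=4, geometry="spread", radius=7.0),
    ligand=dict(n_protons=6, length=5.0, width=2.2),
    max_distance=14.0,
)

#: All methyl residues in one spherical cap (degenerate trilateration).
ONE_SIDED_SPEC = dict(
    site=dict(n_methyl_residues=3, geometry="one_sided", radius=6.0),
    ligand=dict(n_protons=7, length=6.5, width=3.2),
    max_distance=14.0,
)

#: Only two methyl-bearing residues (insufficient beacons).
TWO_RESIDUE_SPEC = dict(
    site=dict(n_methyl_residues=2, geometry="spread", radius=6.0),
    ligand=dict(n_protons=7, length=6.5, width=3.2),
    max_distance=14.0,
)

SPECS = {
    "standard": STANDARD_SPEC,
    "high_topology": HIGH_TOPOLOGY_SPEC,
    "low_topology": LOW_TOPOLOGY_SPEC,
    "one_sided": ONE_SIDED_SPEC,
    "two_residue": TWO_RESIDUE_SPEC,
}


def case_seeds(master_seed: int, n: int) -> list[int]:
    """Fan a master seed out to per-case seeds (re-generable in isolation)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n)]


def make_library(
    n_cases: int,
    design: Sequence[str] | None = None,
    master_seed: int = 0,
    tolerance_fraction: float = 0.0,
    pa_fraction: float = 0.0,
) -> list[SyntheticCase]:
    """Deterministic library of cases cycling through named design specs.

    ``design`` is a list of spec names from :data:`SPECS` (default: all
    ``standard``).  Case i uses spec ``design[i % len(design)]`` and a seed
    split off the master seed, so any case regenerates in isolation.
    """
    if n_cases < 1:
        raise ValueError("need at least one case")
    design = list(design) if design else ["standard"]
    seeds = case_seeds(master_seed, n_cases)
    cases = []
    for i in range(n_cases):
        name = design[i % len(design)]
        spec = SPECS[name]
        cases.append(
            make_case(
                site_spec=spec["site"],
                ligand_spec=spec["ligand"],
                max_distance=spec["max_distance"],
                tolerance_fraction=tolerance_fraction,
                pa_fraction=pa_fraction,
                seed=seeds[i],
                case_id=f"case{i:03d}-{name}",
            )
        )
    return cases


def library_manifest(cases: Sequence[SyntheticCase]) -> list[dict]:
    return [
        {
            "case_id": c.case_id,
            "seed": c.seed,
            "n_sites": len(c.sites),
            "n_restraints": len(c.exact_network),
            "intended": c.intended,
            "truth_assignment": {l: s.site_id for l, s in c.truth_assignment.mapping.items()},
        }
        for c in cases
    ]


# -- on-disk case bundle ----------------------------------------------------

def write_case_bundle(case: SyntheticCase, directory: str | Path) -> None:
    """Write a case as plain-text files: complex PDB, ligand PDB, TSV, truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    receptor_atoms = [
        Atom(s.residue_number, s.residue_type, s.methyl_atom_name, "C", s.carbon_xyz)
        for s in case.sites
    ]
    receptor_atoms += [
        Atom(900 + i, "SHL", "C1", "C", xyz)
        for i, xyz in enumerate(case.receptor_shell_xyz)
    ]
    lig_world = [
        Atom(1, "LIG", name, "C", xyz, hetero=True)
        for name, xyz in zip(case.ligand.heavy_names,
                             case.truth_pose.apply(case.ligand.heavy_xyz))
    ] + [
        Atom(1, "LIG", pid, "H", xyz, hetero=True)
        for pid, xyz in zip(case.ligand.proton_ids,
                            case.truth_pose.apply(case.ligand.proton_xyz))
    ]
    write_pdb(directory / "complex.pdb", receptor_atoms, [lig_world])
    write_pdb(directory / "receptor.pdb", receptor_atoms, [])
    lig_local = [
        Atom(1, "LIG", name, "C", xyz, hetero=True)
        for name, xyz in zip(case.ligand.heavy_names, case.ligand.heavy_xyz)
    ] + [
        Atom(1, "LIG", pid, "H", xyz, hetero=True)
        for pid, xyz in zip(case.ligand.proton_ids, case.ligand.proton_xyz)
    ]
    write_pdb(directory / "ligand.pdb", (), [lig_local])
    write_restraints_tsv(case.network, directory / "restraints.tsv")
    methyl_sites_to_json(case.sites, directory / "methyls.json")
    truth = {
        "rotation": case.truth_pose.rotation.tolist(),
        "translation": case.truth_pose.translation.tolist(),
        "assignment": {l: s.site_id for l, s in case.truth_assignment.mapping.items()},
        "seed": case.seed,
        "intended": case.intended,
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=2))
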