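"""The semi-ambiguous distance-restraint network.

Each restraint connects an assigned ligand proton to an *anonymous* receptor
methyl label ``M_n``: the ligand side of the NOE is assigned, the protein side
is not.  Distances run from the ligand proton to the methyl *carbon* (methyl
carbons, not methyl protons, are the beacons -- which is why in-silico
distances carry no pseudo-atom corrections).

Tolerance semantics: a fractional tolerance f turns a central distance d into
the bound pair (d*(1-f), d*(1+f)).  Partial assignment attaches amino-acid
type sets and same-residue pairings to labels; the assignment enumeration in
the engine honors them.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structures import (
    ComplexStructure,
    MethylSite,
    ProtonSite,
    METHYL_RESIDUES,
    ligand_protons,
)

logger = logging.getLogger(__name__)


class RestraintError(ValueError):
    """Raised for malformed restraint networks or files."""


@dataclass(frozen=True)
class AnonymousLabel:
    """An anonymized methyl resonance ``M_n``.

    ``type_constraint`` restricts the amino-acid types the label may be
    assigned to (partial assignment); ``same_residue_group`` links labels
    known to belong to one residue (e.g. the two methyls of a valine seen in
    an HCCH-TOCSY).
    """

    label: str
    type_constraint: frozenset[str] | None = None
    same_residue_group: str | None = None

    def __post_init__(self) -> None:
        if self.type_constraint is not None:
            if not self.type_constraint:
                raise RestraintError(f"empty type constraint on {self.label}")
            bad = set(self.type_constraint) - METHYL_RESIDUES
            if bad:
                raise RestraintError(f"non-methyl residue types in constraint: {sorted(bad)}")

    @property
    def index(self) -> int:
        """Numeric part of an ``M_n`` label (used for deterministic ordering)."""
        try:
            return int(self.label.split("_", 1)[1])
        except (IndexError, ValueError):
            return 0


@dataclass(frozen=True)
class Restraint:
    """One proton -> anonymous-methyl distance bound."""

    label: str
    proton_id: str
    d: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.d <= self.upper):
            raise RestraintError(
                f"invalid bounds for ({self.label}, {self.proton_id}): "
                f"need 0 < lower <= d <= upper, got ({self.lower}, {self.d}, {self.upper})"
            )


@dataclass
class RestraintNetwork:
    """The full semi-ambiguous network: restraints, labels, and ligand protons."""

    restraints: list[Restraint]
    labels: list[AnonymousLabel]
    protons: list[ProtonSite]
    tolerance_fraction: float = 0.0

    def __post_init__(self) -> None:
        known_labels = {l.label for l in self.labels}
        known_protons = {p.proton_id for p in self.protons}
        if len(known_labels) != len(self.labels):
            raise RestraintError("duplicate anonymous labels")
        for r in self.restraints:
            if r.label not in known_labels:
                raise RestraintError(f"restraint references undeclared label {r.label}")
            if r.proton_id not in known_protons:
                raise RestraintError(f"restraint references undeclared proton {r.proton_id}")

    def __len__(self) -> int:
        return len(self.restraints)

    @property
    def mean_d(self) -> float:
        """<d>: arithmetic mean of the central restraint distances."""
        if not self.restraints:
            raise RestraintError("empty network has no mean distance")
        return float(np.mean([r.d for r in self.restraints]))

    def label_by_name(self, name: str) -> AnonymousLabel:
        for l in self.labels:
            if l.label == name:
                return l
        raise KeyError(name)

    def restraints_of(self, label: str) -> list[Restraint]:
        return [r for r in self.restraints if r.label == label]


def extract_restraints(
    source: ComplexStructure | Sequence[ProtonSite],
    methyls: Sequence[MethylSite],
    max_distance: float = 6.0,
    seed: int = 0,
) -> tuple[RestraintNetwork, dict[str, MethylSite]]:
    """Measure in-silico proton-methyl distances and anonymize the methyls.

    Every (ligand proton, methyl carbon) pair within ``max_distance`` becomes
    one exact restraint (d = lower = upper = geometric distance).  Methyls are
    relabeled ``M_n`` in a seed-shuffled order, and the ground-truth
    label -> site map is returned separately -- it is benchmark metadata and
    must never be fed to the engine.

    Labels whose methyl has no proton within range are dropped: a restraint-
    free label would only inflate the assignment combinatorics.
    """
    if isinstance(source, ComplexStructure):
        protons = ligand_protons(source)
    else:
        protons = list(source)
    if not protons or not methyls:
        raise RestraintError("need at least one proton and one methyl")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(methyls))

    restraints: list[Restraint] = []
    labels: list[AnonymousLabel] = []
    truth: dict[str, MethylSite] = {}
    n = 0
    for site_idx in order:
        site = methyls[site_idx]
        hits = []
        for p in protons:
            d = float(np.linalg.norm(p.xyz - site.carbon_xyz))
            if d <= max_distance:
                hits.append((p.proton_id, d))
        if not hits:
            continue
        n += 1
        name = f"M_{n}"
        labels.append(AnonymousLabel(name))
        truth[name] = site
        restraints.extend(
            Restraint(label=name, proton_id=pid, d=d, lower=d, upper=d) for pid, d in hits
        )
    if not restraints:
        raise RestraintError(
            f"empty network: no proton-methyl pair within {max_distance} A"
        )
    return RestraintNetwork(restraints, labels, protons), truth


def apply_tolerance(network: RestraintNetwork, fraction: float) -> RestraintNetwork:
    """Symmetric multiplicative tolerance: bounds become d*(1 -/+ fraction)."""
    if not 0 <= fraction < 1:
        raise RestraintError("tolerance fraction must be in [0, 1)")
    restraints = [
        replace(r, lower=r.d * (1.0 - fraction), upper=r.d * (1.0 + fraction))
        for r in network.restraints
    ]
    return RestraintNetwork(restraints, list(network.labels), list(network.protons), fraction)


def attach_partial_assignment(
    network: RestraintNetwork,
    type_constraints: Mapping[str, Iterable[str]] | None = None,
    same_residue_pairs: Sequence[tuple[str, str]] = (),
) -> RestraintNetwork:
    """Attach partial-assignment knowledge to anonymous labels.

    ``type_constraints`` maps label -> allowed residue-type set (e.g. a
    methionine identified by a 13C-ctHSQC -> {"MET"}; a VAL/LEU/ILE methyl
    -> that three-type group).  ``same_residue_pairs`` links labels whose
    methyls share one residue (HCCH-TOCSY pattern).
    """
    type_constraints = dict(type_constraints or {})
    known = {l.label for l in network.labels}
    for name in type_constraints:
        if name not in known:
            raise RestraintError(f"constraint on unknown label {name}")
    for a, b in same_residue_pairs:
        for name in (a, b):
            if name not in known:
                raise RestraintError(f"same-residue pairing on unknown label {name}")

    group_of: dict[str, str] = {}
    for i, (a, b) in enumerate(same_residue_pairs, start=1):
        gid = group_of.get(a) or group_of.get(b) or f"g{i}"
        group_of[a] = gid
        group_of[b] = gid

    labels = []
    for l in network.labels:
        tc = l.type_constraint
        if l.label in type_constraints:
            tc = frozenset(type_constraints[l.label])
        labels.append(
            AnonymousLabel(l.label, tc, group_of.get(l.label, l.same_residue_group))
        )
    return RestraintNetwork(
        list(network.restraints), labels, list(network.protons), network.tolerance_fraction
    )


def noe_to_distances(
    buildups: Mapping[str, Sequence[tuple[float, float]]],
    reference: tuple[str, float],
) -> dict[str, float]:
    """Convert NOE build-up curves to distances by the isolated-spin-pair rule.

    Each entry of ``buildups`` is a cross-peak's (mixing time, normalized
    intensity) series.  The initial build-up slope is fit by least squares
    through the origin, and distances follow the r^-6 scaling against the
    reference pair of known distance:  d = d_ref * (slope_ref / slope)^(1/6).

    Pairs with a non-positive slope are dropped with a warning.
    """
    ref_key, d_ref = reference
    if ref_key not in buildups:
        raise RestraintError(f"reference pair {ref_key!r} not in build-up table")
    if d_ref <= 0:
        raise RestraintError("reference distance must be positive")

    def slope(series: Sequence[tuple[float, float]]) -> float:
        t = np.asarray([s[0] for s in series], dtype=float)
        i = np.asarray([s[1] for s in series], dtype=float)
        if len(t) < 2:
            raise RestraintError("need at least two mixing times per pair")
        denom = float(t @ t)
        if denom == 0:
            raise RestraintError("degenerate mixing-time series")
        return float(t @ i) / denom

    s_ref = slope(buildups[ref_key])
    if s_ref <= 0:
        raise RestraintError("reference pair has non-positive build-up slope")
    out: dict[str, float] = {}
    for key, series in buildups.items():
        s = slope(series)
        if s <= 0:
            logger.warning("dropping pair %s: non-positive NOE build-up slope", key)
            continue
        out[key] = d_ref * (s_ref / s) ** (1.0 / 6.0)
    return out


# ---------------------------------------------------------------------------
# File formats

_TSV_COLUMNS = ["label", "proton_id", "d", "lower", "upper", "type_constraint", "group",
                "px", "py", "pz"]


def write_restraints_tsv(network: RestraintNetwork, path: str | Path) -> None:
    """Write the native TSV dialect (lossless round-trip with read_restraints_tsv)."""
    by_label = {l.label: l for l in network.labels}
    by_proton = {p.proton_id: p for p in network.protons}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TSV_COLUMNS)
        for r in network.restraints:
            lab = by_label[r.label]
            p = by_proton[r.proton_id]
            w.writerow(
                [
                    r.label,
                    r.proton_id,
                    f"{r.d:.6f}",
                    f"{r.lower:.6f}",
                    f"{r.upper:.6f}",
                    ",".join(sorted(lab.type_constraint)) if lab.type_constraint else "",
                    lab.same_residue_group or "",
                    f"{p.xyz[0]:.6f}",
                    f"{p.xyz[1]:.6f}",
                    f"{p.xyz[2]:.6f}",
                ]
            )


def read_restraints_tsv(path: str | Path, tolerance_fraction: float = 0.0) -> RestraintNetwork:
    """Read the native TSV dialect back into a network."""
    restraints: list[Restraint] = []
    labels: dict[str, AnonymousLabel] = {}
    protons: dict[str, ProtonSite] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:7] != _TSV_COLUMNS[:7]:
            raise RestraintError(f"{path}: not a restraint TSV (bad header)")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            if len(row) < len(_TSV_COLUMNS):
                raise RestraintError(f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} columns")
            label, pid, d, lo, up, tc, group, px, py, pz = row[: len(_TSV_COLUMNS)]
            try:
                d, lo, up = float(d), float(lo), float(up)
                xyz = np.array([float(px), float(py), float(pz)])
            except ValueError as exc:
                raise RestraintError(f"{path}:{lineno}: {exc}") from None
            if lo > up:
                raise RestraintError(f"{path}:{lineno}: lower bound {lo} exceeds upper {up}")
            try:
                restraints.append(Restraint(label, pid, d, lo, up))
            except RestraintError as exc:
                raise RestraintError(f"{path}:{lineno}: {exc}") from None
            if label not in labels:
                labels[label] = AnonymousLabel(
                    label,
                    frozenset(tc.split(",")) if tc else None,
                    group or None,
                )
            if pid not in protons:
                protons[pid] = ProtonSite(pid, "", xyz)
    if not restraints:
        raise RestraintError(f"{path}: no restraints")
    return RestraintNetwork(
        restraints, list(labels.values()), list(protons.values()), tolerance_fraction
    )


def write_limit_file(network: RestraintNetwork, path: str | Path, kind: str) -> None:
    """Write CYANA-style .upl (upper) or .lol (lower) limit lines.

    One line per restraint: ligand pseudo-residue 1/LIG with the proton name,
    anonymous methyl as pseudo-residue n/MTH with atom CM, bound to 2 decimals.
    """
    if kind not in ("upl", "lol"):
        raise ValueError("kind must be 'upl' or 'lol'")
    lines = []
    for r in sorted(network.restraints, key=lambda r: (r.label, r.proton_id)):
        n = int(r.label.split("_", 1)[1])
        bound = r.upper if kind == "upl" else r.lower
        lines.append(f"{1:>4d} LIG  {r.proton_id:<5s}{n:>4d} MTH  CM   {bound:8.2f}")
    Path(path).write_text("\n".join(lines) + "\n")
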