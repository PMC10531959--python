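"""Structure input: protein-ligand complexes, binding-site methyls, ligand protons.

Coordinates are Cartesian angstroms in a fixed receptor frame.  The frame is
never re-fit: pose rmsd values downstream rely on all poses living in the
same frame.  Input files must already be protonated -- hydrogen placement is
left to external tools.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Canonical methyl carbons per methyl-bearing residue type.
METHYL_CARBONS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "VAL": ("CG1", "CG2"),
    "LEU": ("CD1", "CD2"),
    "ILE": ("CG2", "CD1"),
    "THR": ("CG2",),
    "MET": ("CE",),
}

METHYL_RESIDUES = frozenset(METHYL_CARBONS)

#: Residue types whose two methyls are geminal (same-residue pairing in
#: partial assignments applies to these plus ILE's CG2/CD1 pair).
TWO_METHYL_RESIDUES = frozenset({"VAL", "LEU", "ILE"})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class StructureError(ValueError):
    """Raised for malformed or ambiguous complex structures."""


@dataclass(frozen=True)
class Atom:
    """One atom record of a complex structure."""

    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    xyz: np.ndarray
    hetero: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass(frozen=True)
class ProtonSite:
    """An assigned ligand proton (the ligand side of every restraint)."""

    proton_id: str
    parent_heavy_atom: str
    xyz: np.ndarray


@dataclass(frozen=True)
class MethylSite:
    """A candidate receptor methyl carbon -- one trilateration beacon."""

    site_id: str
    residue_number: int
    residue_type: str
    methyl_atom_name: str
    carbon_xyz: np.ndarray

    def __post_init__(self) -> None:
        allowed = METHYL_CARBONS.get(self.residue_type)
        if allowed is None:
            raise StructureError(f"not a methyl-bearing residue type: {self.residue_type}")
        if self.methyl_atom_name not in allowed:
            raise StructureError(
                f"{self.methyl_atom_name} is not a methyl carbon of {self.residue_type}"
            )


@dataclass
class ComplexStructure:
    """A protonated protein-ligand complex in a fixed receptor frame."""

    receptor_atoms: list[Atom]
    ligand_atoms: list[Atom]
    ligand_residue_name: str = "LIG"

    def __post_init__(self) -> None:
        coords = [a.xyz for a in self.receptor_atoms] + [a.xyz for a in self.ligand_atoms]
        if coords and not np.all(np.isfinite(np.asarray(coords))):
            raise StructureError("non-finite coordinates in structure")
        if not any(a.is_hydrogen for a in self.ligand_atoms):
            raise StructureError(
                "ligand has no hydrogen atoms; protonate the structure first "
                "(e.g. with reduce or openbabel) -- restraints attach to ligand protons"
            )

    @property
    def receptor_heavy_xyz(self) -> np.ndarray:
        """(N, 3) coordinates of all non-hydrogen receptor atoms."""
        pts = [a.xyz for a in self.receptor_atoms if not a.is_hydrogen]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    @property
    def ligand_heavy_xyz(self) -> np.ndarray:
        pts = [a.xyz for a in self.ligand_atoms if not a.is_hydrogen]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def ligand_centroid(self) -> np.ndarray:
        return self.ligand_heavy_xyz.mean(axis=0)


@dataclass(frozen=True)
class LigandConformer:
    """A rigid ligand conformer: proton and heavy-atom coordinates.

    The frame is arbitrary (a pose maps it into the receptor frame); the
    internal geometry is what matters.
    """

    proton_ids: tuple[str, ...]
    proton_xyz: np.ndarray      # (P, 3)
    heavy_names: tuple[str, ...]
    heavy_xyz: np.ndarray       # (H, 3)

    def __post_init__(self) -> None:
        if len(self.proton_ids) != len(self.proton_xyz):
            raise StructureError("proton id/coordinate length mismatch")
        if len(self.proton_ids) < 1:
            raise StructureError("conformer needs at least one proton")

    @classmethod
    def from_complex(cls, complex_: ComplexStructure) -> "LigandConformer":
        """Use the ligand as found in the complex (identity pose = crystal pose)."""
        protons = ligand_protons(complex_)
        heavy = [a for a in complex_.ligand_atoms if not a.is_hydrogen]
        return cls(
            proton_ids=tuple(p.proton_id for p in protons),
            proton_xyz=np.asarray([p.xyz for p in protons], dtype=float),
            heavy_names=tuple(a.atom_name for a in heavy),
            heavy_xyz=np.asarray([a.xyz for a in heavy], dtype=float).reshape(-1, 3),
        )

    def proton_index(self) -> dict[str, int]:
        return {pid: i for i, pid in enumerate(self.proton_ids)}


def _atom_from_gemmi(res: gemmi.Residue, at: gemmi.Atom, hetero: bool) -> Atom:
    return Atom(
        residue_number=res.seqid.num,
        residue_name=res.name.strip(),
        atom_name=at.name.strip(),
        element=at.element.name,
        xyz=np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
        hetero=hetero,
    )


def read_complex(path: str | Path, ligand_residue_name: str) -> ComplexStructure:
    """Read a protonated protein-ligand complex from a PDB file.

    Parameters
    ----------
    path:
        PDB file with exactly one copy of the ligand (as a HETATM residue).
    ligand_residue_name:
        Residue name of the ligand, e.g. ``"LIG"``.

    Raises
    ------
    StructureError
        If the ligand residue is missing, present more than once, or carries
        no hydrogen atoms.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    ligand_residues = []
    receptor_atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            name = res.name.strip()
            if name == ligand_residue_name:
                ligand_residues.append(res)
            elif name in _WATER_NAMES:
                continue
            else:
                receptor_atoms.extend(_atom_from_gemmi(res, at, hetero=False) for at in res)
    if not ligand_residues:
        raise StructureError(f"ligand residue {ligand_residue_name!r} not found in {path}")
    if len(ligand_residues) > 1:
        raise StructureError(
            f"ambiguous ligand: {len(ligand_residues)} copies of {ligand_residue_name!r} "
            f"in {path}; extract the copy of interest first"
        )
    lig = ligand_residues[0]
    ligand_atoms = [_atom_from_gemmi(lig, at, hetero=True) for at in lig]
    return ComplexStructure(receptor_atoms, ligand_atoms, ligand_residue_name)


def ligand_protons(complex_: ComplexStructure) -> list[ProtonSite]:
    """All ligand hydrogens as individual proton sites, ordered by atom name.

    Methyl-rotor protons stay separate (no pseudo-atom collapsing): the
    protein side of each restraint is a methyl *carbon*, so ligand protons
    are the only per-proton entities.
    """
    heavy = [(a.atom_name, a.xyz) for a in complex_.ligand_atoms if not a.is_hydrogen]
    out = []
    for a in sorted(complex_.ligand_atoms, key=lambda a: a.atom_name):
        if not a.is_hydrogen:
            continue
        if heavy:
            parent = min(heavy, key=lambda h: float(np.linalg.norm(h[1] - a.xyz)))[0]
        else:
            parent = ""
        out.append(ProtonSite(proton_id=a.atom_name, parent_heavy_atom=parent, xyz=a.xyz))
    return out


def find_binding_site_methyls(
    complex_: ComplexStructure, cutoff: float = 7.0
) -> list[MethylSite]:
    """Methyl carbons of ALA/VAL/LEU/ILE/THR/MET within *cutoff* of any ligand proton.

    Only the six standard methyl-bearing residue types are recognized; the
    result is ordered by (residue number, atom name).  Default cutoff 7 A
    comfortably covers NOE-detectable proton-carbon distances.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    proton_xyz = np.asarray(
        [a.xyz for a in complex_.ligand_atoms if a.is_hydrogen], dtype=float
    )
    sites: list[MethylSite] = []
    for atom in complex_.receptor_atoms:
        if atom.residue_name not in METHYL_CARBONS:
            continue
        if atom.atom_name not in METHYL_CARBONS[atom.residue_name]:
            continue
        d = np.linalg.norm(proton_xyz - atom.xyz, axis=1).min()
        if d <= cutoff:
            sites.append(
                MethylSite(
                    site_id=f"{atom.residue_name}{atom.residue_number}-{atom.atom_name}",
                    residue_number=atom.residue_number,
                    residue_type=atom.residue_name,
                    methyl_atom_name=atom.atom_name,
                    carbon_xyz=atom.xyz,
                )
            )
    sites.sort(key=lambda s: (s.residue_number, s.methyl_atom_name))
    return sites


def methyl_sites_to_json(sites: Sequence[MethylSite], path: str | Path) -> None:
    payload = [
        {
            "site_id": s.site_id,
            "residue_number": s.residue_number,
            "residue_type": s.residue_type,
            "methyl_atom_name": s.methyl_atom_name,
            "xyz": [float(x) for x in s.carbon_xyz],
        }
        for s in sites
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def methyl_sites_from_json(path: str | Path) -> list[MethylSite]:
    payload = json.loads(Path(path).read_text())
    return [
        MethylSite(
            site_id=d["site_id"],
            residue_number=int(d["residue_number"]),
            residue_type=d["residue_type"],
            methyl_atom_name=d["methyl_atom_name"],
            carbon_xyz=np.asarray(d["xyz"], dtype=float),
        )
        for d in payload
    ]


def write_pdb(
    path: str | Path,
    receptor_atoms: Iterable[Atom] = (),
    ligand_models: Sequence[Sequence[Atom]] = (),
    ligand_chain: str = "L",
) -> None:
    """Write a PDB file with an optional receptor chain and ligand model(s).

    Multiple ligand coordinate sets become successive MODEL records (used for
    rank-ordered pose output); the receptor chain is repeated in each model.
    """
    receptor_atoms = list(receptor_atoms)
    ligand_models = [list(m) for m in ligand_models] or [[]]
    st = gemmi.Structure()
    st.name = "nmr2dock"
    for i, lig_atoms in enumerate(ligand_models, start=1):
        model = gemmi.Model(i)
        if receptor_atoms:
            model.add_chain(_gemmi_chain("A", receptor_atoms, hetero=False))
        if lig_atoms:
            model.add_chain(_gemmi_chain(ligand_chain, lig_atoms, hetero=True))
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _gemmi_chain(name: str, atoms: Sequence[Atom], hetero: bool) -> gemmi.Chain:
    # group into residues first: gemmi copies residues on add_residue, so
    # they must be fully built before insertion
    grouped: dict[tuple[int, str], list[Atom]] = {}
    for a in atoms:
        grouped.setdefault((a.residue_number, a.residue_name), []).append(a)
    chain = gemmi.Chain(name)
    for (num, resname), members in grouped.items():
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(num, " ")
        res.het_flag = "H" if hetero else "A"
        for a in members:
            at = gemmi.Atom()
            at.name = a.atom_name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*map(float, a.xyz))
            res.add_atom(at)
        chain.add_residue(res)
    return chain
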