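"""Protein structure handling: PDB input, atom classification, geometry.

Structures are reduced to a lightweight heavy-atom representation
sufficient for contact counting, solvent accessibility and CA-based
geometry.  Hydrogens are dropped on input: crystallographic models
rarely carry them and excluding them keeps wild-type/mutant feature
parity.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.SVDSuperimposer import SVDSuperimposer

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SiteSelection",
    "PDBParseError",
    "read_pdb",
    "classify_atom",
    "sphere_residues",
    "ca_rmsd",
    "to_pdb",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: elements that count as polar in the contact scheme
_POLAR_ELEMENTS = frozenset({"N", "O"})
_NONPOLAR_ELEMENTS = frozenset({"C", "S"})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

STANDARD_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL"
).split()

AA3_TO_1 = dict(
    zip(
        STANDARD_AA3,
        "A R N D C Q E G H I L K M F P S T W Y V".split(),
    )
)
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


class PDBParseError(ValueError):
    """Raised when a PDB stream cannot be turned into a model."""


@dataclass(frozen=True)
class Atom:
    """A single heavy atom with its contact-scheme classification."""

    name: str
    element: str
    coords: np.ndarray  # (3,) float, Angstrom
    residue_key: tuple
    is_backbone: bool
    polarity: str  # "polar" | "nonpolar" | "excluded"

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)


@dataclass
class Residue:
    key: tuple  # (chain id, residue number)
    aa_code: str  # 3-letter code
    atoms: list = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class Structure:
    id: str
    residues: list = field(default_factory=list)

    def __post_init__(self):
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue keys in structure")

    def residue(self, key: tuple) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(f"residue {key} not in structure {self.id}")

    def residue_keys(self) -> list:
        return [r.key for r in self.residues]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass(frozen=True)
class SiteSelection:
    """The residue to be mutated (chain id, residue number)."""

    residue_key: tuple

    def validate(self, s: Structure) -> None:
        if self.residue_key not in set(s.residue_keys()):
            raise KeyError(f"site {self.residue_key} not present in structure {s.id}")


def classify_atom(atom_name: str, element: str, aa_code: str) -> tuple:
    """Classify an atom for contact counting.

    Returns ``(is_backbone, polarity)``.  Backbone membership is by atom
    name (N, CA, C, O, OXT); polarity follows the element: N/O polar,
    C/S nonpolar, H excluded.  Unrecognised elements are treated as
    nonpolar with a warning so the function stays total.
    """
    is_backbone = atom_name.strip() in BACKBONE_ATOMS
    el = element.strip().upper()
    if el in _POLAR_ELEMENTS:
        polarity = "polar"
    elif el in _NONPOLAR_ELEMENTS:
        polarity = "nonpolar"
    elif el == "H" or el == "D":
        polarity = "excluded"
    else:
        warnings.warn(
            f"element {element!r} ({aa_code}/{atom_name}) not in polarity table; "
            "treating as nonpolar"
        )
        polarity = "nonpolar"
    return is_backbone, polarity


def _guess_element(atom) -> str:
    el = (atom.element or "").strip()
    if el:
        return el.upper()
    name = atom.get_name().strip()
    # PDB convention: columns 13-14 hold the element for standard names
    return "".join(c for c in name if c.isalpha())[:1].upper()


def read_pdb(stream, keep_hetero: bool = False, structure_id: str = "model") -> Structure:
    """Parse PDB ATOM/HETATM records into a heavy-atom :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties resolved to the first in the file).  Waters are always
    excluded; non-amino-acid heteroatom residues are excluded unless
    ``keep_hetero``.  Hydrogens are dropped.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = parser.get_structure(structure_id, stream)
    except PDBConstructionException as exc:
        raise PDBParseError(f"malformed PDB record: {exc}") from exc
    models = list(model.get_models())
    if not models:
        raise PDBParseError("empty model: no ATOM/HETATM records parsed")

    residues: list[Residue] = []
    for chain in models[0]:
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            resname = res.get_resname().strip()
            if resname in _WATER_NAMES or hetflag == "W":
                continue
            is_aa = resname in AA3_TO_1
            if hetflag.strip() and not is_aa and not keep_hetero:
                continue
            key = (chain.get_id(), resseq if not icode.strip() else f"{resseq}{icode.strip()}")
            atoms = []
            seen = set()
            for atom in res.get_atoms():
                # Biopython's disordered handling already selects the
                # highest-occupancy altloc (first in file on ties).
                name = atom.get_name().strip()
                if name in seen:
                    continue
                el = _guess_element(atom)
                is_bb, polarity = classify_atom(name, el, resname)
                if polarity == "excluded":
                    continue
                seen.add(name)
                atoms.append(
                    Atom(
                        name=name,
                        element=el,
                        coords=np.array(atom.get_coord(), dtype=float),
                        residue_key=key,
                        is_backbone=is_bb,
                        polarity=polarity,
                    )
                )
            if atoms:
                residues.append(Residue(key=key, aa_code=resname, atoms=atoms))
    if not residues:
        raise PDBParseError("empty model: no residues after filtering")
    return Structure(id=structure_id, residues=residues)


def sphere_residues(s: Structure, site: SiteSelection, radius: float = 8.0) -> list:
    """Residue keys whose CA lies within ``radius`` (CA-CA, <=) of the site CA.

    The site itself is excluded.  Keys are returned in structure order,
    so membership is independent of any input shuffling of equal
    structures.  Residues without a CA atom are skipped with a warning.
    """
    site.validate(s)
    site_res = s.residue(site.residue_key)
    if site_res.ca is None:
        raise ValueError(f"site residue {site.residue_key} has no CA atom")
    center = site_res.ca.coords
    out = []
    for r in s.residues:
        if r.key == site.residue_key:
            continue
        if r.ca is None:
            warnings.warn(f"residue {r.key} has no CA atom; skipped from sphere")
            continue
        if np.linalg.norm(r.ca.coords - center) <= radius:
            out.append(r.key)
    return out


def _ca_matrix(s: Structure) -> np.ndarray:
    coords = []
    for r in s.residues:
        if r.ca is None:
            raise ValueError(f"residue {r.key} in {s.id} has no CA atom")
        coords.append(r.ca.coords)
    return np.array(coords)


def ca_rmsd(a: Structure, b: Structure, superpose: bool = True) -> float:
    """Alpha-carbon RMSD between two structures sharing residue keys.

    With ``superpose`` the optimal least-squares rigid-body
    superposition (Kabsch) is applied first; otherwise the deviation is
    measured in the shared input frame (appropriate when both models
    come from refinement of a common starting structure).
    """
    keys_a, keys_b = a.residue_keys(), b.residue_keys()
    if set(keys_a) != set(keys_b):
        only_a = sorted(set(keys_a) - set(keys_b), key=str)
        only_b = sorted(set(keys_b) - set(keys_a), key=str)
        raise ValueError(
            f"residue sets differ: only in {a.id}: {only_a}; only in {b.id}: {only_b}"
        )
    xa = _ca_matrix(a)
    order = {k: i for i, k in enumerate(keys_b)}
    xb = _ca_matrix(b)[[order[k] for k in keys_a]]
    if superpose:
        sup = SVDSuperimposer()
        sup.set(xa, xb)
        sup.run()
        return float(sup.get_rms())
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def to_pdb(s: Structure) -> str:
    """Serialize a structure to minimal PDB ATOM records (3-decimal coords)."""
    lines = []
    serial = 1
    for r in s.residues:
        chain, resnum = r.key
        for a in r.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.coords
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s} {r.aa_code:<3.3s} {str(chain):1.1s}"
                f"{int(resnum):4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element:>2.2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
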