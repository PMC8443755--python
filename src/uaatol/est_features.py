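"""Empirical score terms: contact counts, accessibility, and their deltas.

The empirical feature set characterises a mutation site by categorised
heavy-atom contact counts (polar/nonpolar x backbone/sidechain pairing
x intra/inter-residue) within a strict 4 Angstrom distance cutoff, the
site's absolute and relative solvent accessibility on the wild-type
structure, and the mutant-minus-wild-type change in each contact
category.

Covalently bonded geometry is not a "contact": atom pairs separated by
one or two covalent bonds (1-2 and 1-3 neighbours) are excluded, both
within the site residue and across its peptide junctions.  Bond graphs
come from standard residue templates; unknown residue codes fall back
to distance-based bond inference (<= 1.8 Angstrom).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structures import SiteSelection, Structure

__all__ = [
    "ContactCounts",
    "EstVector",
    "enumerate_contacts",
    "shrake_rupley_sasa",
    "relative_sasa",
    "est_delta_vector",
    "CONTACT_CATEGORIES",
]

# ---------------------------------------------------------------------------
# residue bond templates (heavy atoms only)

_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT"), ("CA", "CB")]

_SIDECHAIN_BONDS = {
    "ALA": [],
    "ARG": [("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CB", "SG")],
    "GLN": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CB", "OG")],
    "THR": [("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"),
            ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "VAL": [("CB", "CG1"), ("CB", "CG2")],
}

_BOND_INFER_CUTOFF = 1.8  # Angstrom, heavy-atom covalent bond inference


def _residue_bonds(residue) -> set:
    """Set of bonded atom-name pairs (frozensets) within one residue."""
    names = {a.name for a in residue.atoms}
    if residue.aa_code in _SIDECHAIN_BONDS:
        template = _BACKBONE_BONDS + _SIDECHAIN_BONDS[residue.aa_code]
        bonds = {frozenset(b) for b in template if b[0] in names and b[1] in names}
    else:
        bonds = set()
        for a, b in itertools.combinations(residue.atoms, 2):
            if np.linalg.norm(a.coords - b.coords) <= _BOND_INFER_CUTOFF:
                bonds.add(frozenset((a.name, b.name)))
    return bonds


def _near_bonded_pairs(residue) -> set:
    """Atom-name pairs within the residue separated by <= 2 covalent bonds."""
    bonds = _residue_bonds(residue)
    adj: dict[str, set] = {}
    for b in bonds:
        x, y = tuple(b)
        adj.setdefault(x, set()).add(y)
        adj.setdefault(y, set()).add(x)
    near = set(bonds)
    for center, nbrs in adj.items():
        for x, y in itertools.combinations(sorted(nbrs), 2):
            near.add(frozenset((x, y)))
    return near


# peptide-junction exclusions: (site atom, neighbour atom) pairs that are
# 1-2 or 1-3 across the backbone link, for the following (+1) and the
# preceding (-1) residue in the chain.
_JUNCTION_NEXT = {("C", "N"), ("C", "CA"), ("O", "N"), ("CA", "N")}
_JUNCTION_PREV = {("N", "C"), ("N", "CA"), ("N", "O"), ("CA", "C")}


CONTACT_CATEGORIES = tuple(
    f"{pol}_{pair}_{loc}"
    for pol in ("np", "p")
    for pair in ("bb_bb", "bb_sc", "sc_sc")
    for loc in ("intra", "inter")
)


@dataclass
class ContactCounts:
    """Categorised heavy-atom contact tallies around a mutation site."""

    np_bb_bb_intra: int = 0
    np_bb_bb_inter: int = 0
    np_bb_sc_intra: int = 0
    np_bb_sc_inter: int = 0
    np_sc_sc_intra: int = 0
    np_sc_sc_inter: int = 0
    p_bb_bb_intra: int = 0
    p_bb_bb_inter: int = 0
    p_bb_sc_intra: int = 0
    p_bb_sc_inter: int = 0
    p_sc_sc_intra: int = 0
    p_sc_sc_inter: int = 0

    @property
    def total_np_contacts(self) -> int:
        return sum(getattr(self, c) for c in CONTACT_CATEGORIES if c.startswith("np_"))

    @property
    def total_p_contacts(self) -> int:
        return sum(getattr(self, c) for c in CONTACT_CATEGORIES if c.startswith("p_"))

    @property
    def total_contacts(self) -> int:
        return self.total_np_contacts + self.total_p_contacts

    def as_dict(self) -> dict:
        d = {c: getattr(self, c) for c in CONTACT_CATEGORIES}
        d["total_np_contacts"] = self.total_np_contacts
        d["total_p_contacts"] = self.total_p_contacts
        d["total_contacts"] = self.total_contacts
        return d


def _adjacent_key(key, offset):
    chain, num = key
    if isinstance(num, int):
        return (chain, num + offset)
    return None


def enumerate_contacts(
    s: Structure,
    site: SiteSelection,
    cutoff: float = 4.0,
    mixed_polarity: str = "polar",
    exclude_bonded: bool = True,
) -> ContactCounts:
    """Count heavy-atom contacts (< ``cutoff``) involving the site residue.

    A contact is an unordered atom pair at strictly less than ``cutoff``
    Angstrom.  *Intra* contacts have both atoms in the site residue;
    *inter* contacts exactly one.  Pairing class follows the atoms'
    backbone flags; a pair is nonpolar only when both atoms are
    nonpolar (``mixed_polarity='polar'``, the default) unless
    ``mixed_polarity='nonpolar'`` assigns mixed pairs to the nonpolar
    class.  With ``exclude_bonded`` (default) 1-2 and 1-3 covalent
    neighbours are not counted, within the residue and across its
    peptide junctions.
    """
    site.validate(s)
    if mixed_polarity not in ("polar", "nonpolar"):
        raise ValueError("mixed_polarity must be 'polar' or 'nonpolar'")
    site_res = s.residue(site.residue_key)
    counts = ContactCounts()

    def classify_pair(a, b):
        if a.is_backbone and b.is_backbone:
            pair = "bb_bb"
        elif a.is_backbone or b.is_backbone:
            pair = "bb_sc"
        else:
            pair = "sc_sc"
        if a.polarity == "nonpolar" and b.polarity == "nonpolar":
            pol = "np"
        elif a.polarity == "polar" and b.polarity == "polar":
            pol = "p"
        else:
            pol = "np" if mixed_polarity == "nonpolar" else "p"
        return pol, pair

    # intra-residue
    near = _near_bonded_pairs(site_res) if exclude_bonded else set()
    for a, b in itertools.combinations(site_res.atoms, 2):
        if frozenset((a.name, b.name)) in near:
            continue
        if np.linalg.norm(a.coords - b.coords) < cutoff:
            pol, pair = classify_pair(a, b)
            name = f"{pol}_{pair}_intra"
            setattr(counts, name, getattr(counts, name) + 1)

    # inter-residue: site atoms vs all other atoms, via a KD-tree
    other_atoms = [a for r in s.residues if r.key != site.residue_key for a in r.atoms]
    if other_atoms:
        tree = cKDTree(np.array([a.coords for a in other_atoms]))
        next_key = _adjacent_key(site.residue_key, +1)
        prev_key = _adjacent_key(site.residue_key, -1)
        for a in site_res.atoms:
            for j in tree.query_ball_point(a.coords, cutoff):
                b = other_atoms[j]
                if np.linalg.norm(a.coords - b.coords) >= cutoff:
                    continue
                if exclude_bonded:
                    if b.residue_key == next_key and (a.name, b.name) in _JUNCTION_NEXT:
                        continue
                    if b.residue_key == prev_key and (a.name, b.name) in _JUNCTION_PREV:
                        continue
                pol, pair = classify_pair(a, b)
                name = f"{pol}_{pair}_inter"
                setattr(counts, name, getattr(counts, name) + 1)
    return counts


# ---------------------------------------------------------------------------
# solvent accessible surface area


def _load_table(name: str, key_col: int = 0) -> dict:
    text = resources.files("uaatol.data").joinpath(name).read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        out[parts[key_col]] = [float(v) for v in parts[key_col + 1:]]
    return out


_VDW_RADII = {k: v[0] for k, v in _load_table("vdw_radii.tsv").items()}
_MAX_ASA = {k: v[0] for k, v in _load_table("max_asa.tsv").items()}

DEFAULT_VDW_RADIUS = 1.70


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley_sasa(
    s: Structure, probe: float = 1.4, n_sphere_points: int = 960
) -> dict:
    """Per-residue solvent accessible surface area (Angstrom^2).

    Shrake-Rupley rolling-probe approximation on heavy atoms: each
    atom's solvent-extended sphere is sampled at ``n_sphere_points``
    deterministic quasi-uniform points, and the accessible fraction is
    the fraction of points outside every neighbouring extended sphere.
    Per-atom areas are summed per residue.
    """
    atoms = [a for r in s.residues for a in r.atoms]
    if not atoms:
        return {}
    coords = np.array([a.coords for a in atoms])
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        r = _VDW_RADII.get(a.element.upper())
        if r is None:
            warnings.warn(
                f"no van der Waals radius for element {a.element!r}; "
                f"using default {DEFAULT_VDW_RADIUS}"
            )
            r = DEFAULT_VDW_RADIUS
        radii[i] = r
    ext = radii + probe
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_ext = ext.max()
    asa_per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + ext[i] * unit
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], ext[i] + max_ext):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        asa_per_atom[i] = (
            4.0 * np.pi * ext[i] ** 2 * accessible.sum() / n_sphere_points
        )
    out: dict = {}
    for a, area in zip(atoms, asa_per_atom):
        out[a.residue_key] = out.get(a.residue_key, 0.0) + float(area)
    return out


def relative_sasa(asa: float, aa_code: str) -> float:
    """ASA normalised by the residue's theoretical maximum (RSA).

    Values can exceed 1 for extended conformations.  ``aa_code`` is a
    3-letter code present in the bundled maximum-ASA table.
    """
    code = aa_code.strip().upper()
    if code not in _MAX_ASA:
        raise KeyError(f"no maximum-ASA entry for residue code {aa_code!r}")
    return float(asa) / _MAX_ASA[code]


# ---------------------------------------------------------------------------
# delta vector


@dataclass
class EstVector:
    """Mutant-minus-WT contact deltas plus WT-site accessibility."""

    deltas: dict  # category / total name -> int
    asa: float  # WT site ASA, Angstrom^2
    rsa: float  # WT site relative ASA

    def as_dict(self) -> dict:
        d = dict(self.deltas)
        d["ASA"] = self.asa
        d["RSA"] = self.rsa
        return d


def est_delta_vector(
    wt: Structure,
    mut: Structure,
    site: SiteSelection,
    contact_cutoff: float = 4.0,
    sasa_probe: float = 1.4,
    n_sphere_points: int = 960,
) -> EstVector:
    """Empirical feature vector for a WT/mutant structure pair.

    Contact deltas are ``enumerate_contacts(mut) - enumerate_contacts(wt)``
    per category; ASA and RSA come from the WT structure at the site
    (accessibility of the residue that is to be mutated).  The two
    structures must be identical away from the site.
    """
    site.validate(wt)
    site.validate(mut)
    differing = []
    wt_map = {r.key: r for r in wt.residues}
    mut_map = {r.key: r for r in mut.residues}
    if set(wt_map) != set(mut_map):
        raise ValueError("WT and mutant structures have different residue sets")
    for key, rw in wt_map.items():
        if key == site.residue_key:
            continue
        rm = mut_map[key]
        same = (
            rw.aa_code == rm.aa_code
            and [a.name for a in rw.atoms] == [a.name for a in rm.atoms]
            and all(
                np.allclose(aw.coords, am.coords, atol=1e-6)
                for aw, am in zip(rw.atoms, rm.atoms)
            )
        )
        if not same:
            differing.append(key)
    if differing:
        raise ValueError(f"structures differ away from the site at residues {differing}")

    cw = enumerate_contacts(wt, site, cutoff=contact_cutoff).as_dict()
    cm = enumerate_contacts(mut, site, cutoff=contact_cutoff).as_dict()
    deltas = {k: cm[k] - cw[k] for k in cw}
    asa_map = shrake_rupley_sasa(wt, probe=sasa_probe, n_sphere_points=n_sphere_points)
    asa = asa_map.get(site.residue_key, 0.0)
    try:
        rsa = relative_sasa(asa, wt_map[site.residue_key].aa_code)
    except KeyError:
        warnings.warn(
            f"no maximum-ASA entry for {wt_map[site.residue_key].aa_code}; RSA set to NaN"
        )
        rsa = float("nan")
    return EstVector(deltas=deltas, asa=asa, rsa=rsa)
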