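"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the three kinds of input the pipeline consumes:

* an ideal alpha-helix backbone with small template sidechains, plus a
  "bulky mutant" whose site sidechain is replaced by a planar
  fused-ring dummy of nonpolar pseudo-atoms (mimicking a tricyclic
  acridone sidechain) — exercises the contact/accessibility features;
* replicate per-residue score tables with a planted energy shift at the
  site and a smaller shift across its contact sphere, plus Gaussian
  noise — exercises replicate averaging and delta recovery;
* labeled feature matrices with a known sparse linear signal in a
  51-sample, two-pseudo-protein (32:19) shape — exercises feature
  selection, tuning and holdout evaluation.

All generators are pure functions of their :class:`SynthConfig` (seed
included), so every test input is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .energy_features import ScoreTable, residue_token
from .structures import (
    Atom,
    Residue,
    SiteSelection,
    Structure,
    classify_atom,
    sphere_residues,
)

__all__ = [
    "SynthConfig",
    "make_helix_structure",
    "make_bulky_mutant",
    "make_score_tables",
    "make_labeled_dataset",
    "latent_noise_sd_for_bayes",
]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for all synthetic generators (defaults mirror the study shape)."""

    seed: int = 0
    # structures
    n_residues: int = 30
    site: int | None = None  # residue number (1-based); default mid-chain
    wt_sidechain_size: int = 1  # pseudo-atoms per template sidechain (1-4)
    sidechain_size: int = 12  # mutant fused-ring atom count
    # score tables
    terms: tuple = ("fa_atr", "fa_rep", "fa_sol", "rama_prepro", "residue_total_score")
    replicates: int = 5
    site_shift: float = 2.0  # REU, planted delta at the site
    sphere_shift: float = 0.5  # REU, planted delta across the sphere
    noise_sd: float = 0.3  # REU, per-cell Gaussian noise
    # labeled datasets
    n_samples: int = 51
    n_features: int = 30
    informative: tuple = (0, 1, 2)
    coefficients: tuple = (3.0, 2.0, 1.0)
    bayes_accuracy: float = 0.95  # sets the latent noise level
    protein_ratio: tuple = (32, 19)

    def __post_init__(self):
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues")
        if self.site is None:
            object.__setattr__(self, "site", self.n_residues // 2)
        if not (1 <= self.site <= self.n_residues):
            raise ValueError("site outside the chain")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(i >= self.n_features for i in self.informative):
            raise ValueError("informative indices must be < n_features")
        if len(self.informative) != len(self.coefficients):
            raise ValueError("informative indices and coefficients differ in length")


# ---------------------------------------------------------------------------
# geometry helpers (internal-coordinate chain building)

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_BOND_CA_CB = 1.530
_ANGLE_N_CA_C = math.radians(111.2)
_ANGLE_CA_C_N = math.radians(116.2)
_ANGLE_C_N_CA = math.radians(121.7)
_ANGLE_CA_C_O = math.radians(120.8)
_PHI = math.radians(-57.0)
_PSI = math.radians(-47.0)
_OMEGA = math.radians(180.0)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
           angle: float, torsion: float) -> np.ndarray:
    """Place atom D given chain A-B-C, |CD|, angle BCD and torsion ABCD."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


_SIDECHAIN_NAMES = ("CB", "CG", "CD", "CE")


def make_helix_structure(cfg: SynthConfig) -> Structure:
    """Ideal alpha-helix (phi -57, psi -47) with small template sidechains.

    Residue keys are ``("A", i)`` for i = 1..n.  Template sidechains of
    ``wt_sidechain_size`` carbon pseudo-atoms (CB, CG, ...) extend away
    from the helix axis; size 1 gives alanine-like residues.
    """
    n = cfg.n_residues
    # seed backbone for residue 1
    coords = {}
    coords[(1, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(1, "CA")] = np.array([_BOND_N_CA, 0.0, 0.0])
    coords[(1, "C")] = _place(
        np.array([0.0, 1.0, 0.0]),
        coords[(1, "N")],
        coords[(1, "CA")],
        _BOND_CA_C,
        _ANGLE_N_CA_C,
        _PHI,
    )
    for i in range(1, n):
        coords[(i + 1, "N")] = _place(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            _BOND_C_N, _ANGLE_CA_C_N, _PSI,
        )
        coords[(i + 1, "CA")] = _place(
            coords[(i, "CA")], coords[(i, "C")], coords[(i + 1, "N")],
            _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA,
        )
        coords[(i + 1, "C")] = _place(
            coords[(i, "C")], coords[(i + 1, "N")], coords[(i + 1, "CA")],
            _BOND_CA_C, _ANGLE_N_CA_C, _PHI,
        )
    # carbonyl O: torsion psi + pi about N-CA-C
    for i in range(1, n + 1):
        coords[(i, "O")] = _place(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            _BOND_C_O, _ANGLE_CA_C_O, _PSI + math.pi,
        )

    size = max(1, min(cfg.wt_sidechain_size, 4))
    aa_code = "ALA" if size == 1 else "UNK"
    residues = []
    for i in range(1, n + 1):
        key = ("A", i)
        atoms = []
        for name in ("N", "CA", "C", "O"):
            el = name[0]
            is_bb, pol = classify_atom(name, el, aa_code)
            atoms.append(Atom(name, el, coords[(i, name)], key, is_bb, pol))
        # CB direction: tetrahedral off N-CA-C
        cb = _place(
            coords[(i, "C")], coords[(i, "N")], coords[(i, "CA")],
            _BOND_CA_CB, math.radians(110.5), math.radians(122.5),
        )
        sc_positions = [cb]
        direction = cb - coords[(i, "CA")]
        direction /= np.linalg.norm(direction)
        for j in range(1, size):
            sc_positions.append(cb + 1.53 * j * direction)
        for name, pos in zip(_SIDECHAIN_NAMES[:size], sc_positions):
            is_bb, pol = classify_atom(name, "C", aa_code)
            atoms.append(Atom(name, "C", pos, key, is_bb, pol))
        residues.append(Residue(key=key, aa_code=aa_code, atoms=atoms))
    return Structure(id=f"helix{n}", residues=residues)


def make_bulky_mutant(
    s: Structure, site: SiteSelection, sidechain_size: int
) -> Structure:
    """Replace the site sidechain with a planar fused-ring nonpolar dummy.

    ``sidechain_size`` pseudo-carbon atoms are laid out on a planar
    hexagonal lattice (1.4 Angstrom spacing) in the plane through the
    CA-CB direction, emulating a large flat aromatic sidechain.  All
    other residues are untouched.  A clash with the residue's own
    backbone is warned about but atoms are placed anyway.
    """
    import warnings as _w

    site.validate(s)
    residues = []
    for r in s.residues:
        if r.key != site.residue_key:
            residues.append(Residue(key=r.key, aa_code=r.aa_code, atoms=list(r.atoms)))
            continue
        backbone = [a for a in r.atoms if a.is_backbone]
        ca = r.atom("CA")
        cb = r.atom("CB")
        if ca is None:
            raise ValueError("site residue lacks CA")
        if cb is not None:
            u = cb.coords - ca.coords
        else:
            u = np.array([1.0, 0.0, 0.0])
        u = u / np.linalg.norm(u)
        # second in-plane axis: any direction orthogonal to u
        helper = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(helper, u)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, helper)
        v /= np.linalg.norm(v)
        origin = ca.coords + _BOND_CA_CB * u
        # hexagonal lattice points in the (u, v) plane, nearest-first
        spacing = 1.4
        lattice = []
        for p in range(-4, 7):
            for q in range(-4, 5):
                pos = origin + spacing * (p * u + q * (0.5 * u + (3**0.5 / 2) * v))
                lattice.append(pos)
        lattice.sort(key=lambda pos: (np.linalg.norm(pos - origin), tuple(pos)))
        atoms = list(backbone)
        names = ["CB"] + [f"C{j}" for j in range(1, sidechain_size)]
        placed = lattice[:sidechain_size]
        for name, pos in zip(names, placed):
            for b in backbone:
                if np.linalg.norm(pos - b.coords) < 1.5 and b.name != "CA":
                    _w.warn(
                        f"bulky sidechain atom {name} clashes with backbone {b.name}"
                    )
            is_bb, pol = classify_atom(name, "C", "ACD")
            atoms.append(Atom(name, "C", pos, r.key, is_bb, pol))
        residues.append(Residue(key=r.key, aa_code="ACD", atoms=atoms))
    return Structure(id=f"{s.id}_mut", residues=residues)


# ---------------------------------------------------------------------------
# score tables


def make_score_tables(cfg: SynthConfig):
    """WT and mutant replicate score tables with planted site/sphere shifts.

    WT cells are i.i.d. N(0, sd^2) about a zero mean; mutant cells add
    the site shift (at the site row) or the sphere shift (at
    contact-sphere rows) to the zero mean plus fresh noise.  Returns
    ``(wt_tables, mut_tables, site_key, sphere_keys)``.
    """
    if cfg.replicates < 1:
        raise ValueError("need at least one replicate")
    helix = make_helix_structure(cfg)
    site_key = ("A", cfg.site)
    sphere = sphere_residues(helix, SiteSelection(site_key), radius=8.0)
    rng = np.random.default_rng(cfg.seed)
    tokens = [residue_token(k) for k in helix.residue_keys()]
    offsets = np.zeros((len(tokens), len(cfg.terms)))
    site_i = tokens.index(residue_token(site_key))
    offsets[site_i, :] = cfg.site_shift
    for k in sphere:
        offsets[tokens.index(residue_token(k)), :] = cfg.sphere_shift

    def tables(variant: str, shifted: bool):
        out = []
        for rep in range(1, cfg.replicates + 1):
            values = rng.normal(0.0, cfg.noise_sd, size=offsets.shape)
            if shifted:
                values = values + offsets
            out.append(
                ScoreTable(
                    protein="synthetic",
                    variant=variant,
                    replicate=rep,
                    scores=pd.DataFrame(values, index=tokens, columns=list(cfg.terms)),
                )
            )
        return out

    wt_tables = tables("WT", shifted=False)
    mut_tables = tables(f"site{cfg.site}", shifted=True)
    return wt_tables, mut_tables, site_key, sphere


# ---------------------------------------------------------------------------
# labeled feature matrices


def latent_noise_sd_for_bayes(coefficients, target_accuracy: float) -> float:
    """Noise level giving a target Bayes accuracy for a linear latent signal.

    With latent response s + eps (s = beta.x, x standard normal,
    eps ~ N(0, sigma^2)) and labels split at the latent median, the
    optimal classifier predicts sign(s) and its accuracy is
    1/2 + arcsin(rho)/pi with rho = |beta| / sqrt(|beta|^2 + sigma^2)
    (Sheppard's orthant probability).  Inverting gives sigma.
    """
    if not (0.5 < target_accuracy < 1.0):
        raise ValueError("target accuracy must be in (0.5, 1)")
    s = float(np.linalg.norm(coefficients))
    rho = math.sin(math.pi * (target_accuracy - 0.5))
    return s * math.sqrt(1.0 / rho**2 - 1.0)


_AA1 = "ARNDCQEGHILKMFPSTWYV"


def make_labeled_dataset(cfg: SynthConfig) -> LabeledDataset:
    """Feature matrix with a known sparse linear signal, study-shaped.

    Features are i.i.d. standard normal; the latent response is a
    sparse linear combination plus Gaussian noise scaled to the target
    Bayes accuracy; binary labels cut at the latent median (balanced).
    Rows are tagged to two pseudo-proteins at ``protein_ratio``
    (seeded assignment) and carry phenotype columns that increase
    monotonically with the latent response.
    """
    if cfg.n_samples < 20:
        raise ValueError("need at least 20 samples")
    rng = np.random.default_rng(cfg.seed)
    X = rng.standard_normal((cfg.n_samples, cfg.n_features))
    beta = np.zeros(cfg.n_features)
    for i, c in zip(cfg.informative, cfg.coefficients):
        beta[i] = c
    sigma = (
        latent_noise_sd_for_bayes(cfg.coefficients, cfg.bayes_accuracy)
        if any(cfg.coefficients)
        else 1.0
    )
    latent = X @ beta + rng.normal(0.0, sigma, size=cfg.n_samples)
    labels = latent > np.median(latent)

    n_a, n_b = cfg.protein_ratio
    if n_a + n_b != cfg.n_samples:
        # scale the ratio to the sample count
        n_a = int(round(cfg.n_samples * n_a / (n_a + n_b)))
        n_b = cfg.n_samples - n_a
    tags = np.array(["ProtA"] * n_a + ["ProtB"] * n_b)
    rng.shuffle(tags)

    # phenotypes monotone in the latent response; soluble fraction is the
    # percentile of the latent, yields are consistent with the fraction
    order = np.argsort(np.argsort(latent))
    soluble_fraction = 100.0 * (order + 0.5) / cfg.n_samples
    total_yield = 1600.0 * np.exp(rng.normal(0.0, 0.4, cfg.n_samples))
    soluble_yield = soluble_fraction / 100.0 * total_yield
    site_counter: dict = {}
    sites, wt_aas = [], []
    for t in tags:
        site_counter[t] = site_counter.get(t, 0) + 1
        sites.append(site_counter[t])
        wt_aas.append(_AA1[rng.integers(0, 20)])
    records = pd.DataFrame(
        {
            "protein": tags,
            "site": sites,
            "wt_aa": wt_aas,
            "soluble_yield_nM": soluble_yield,
            "total_yield_nM": total_yield,
            "soluble_fraction_pct": soluble_fraction,
        }
    )
    features = pd.DataFrame(
        X, columns=[f"feat_{j}" for j in range(cfg.n_features)]
    )
    ds = LabeledDataset(features=features, records=records)
    ds.labels["latent"] = labels
    return ds
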