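"""Structure-independent bioinformatics features of a mutation site.

These features depend only on the identity of the wild-type residue to
be replaced: its BLOSUM62 substitution-score row, three side-chain
transfer free-energy (hydrophobicity) scales, and a melting-temperature
change measure relative to glycine.  All are pure table lookups; the
tables are bundled as tab-separated files under ``uaatol/data`` and are
swappable (see the file headers for provenance).

Evolutionary-conservation and secondary-structure/domain features are
accepted downstream as optional user-supplied columns and are not
computed here (they would require multiple sequence alignments or a
DSSP run).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from Bio.Align import substitution_matrices

from .structures import AA1_TO_3, AA3_TO_1

__all__ = [
    "blosum_features",
    "hydrophobicity_features",
    "delta_tm_feature",
    "bioinfo_vector",
    "HYDROPHOBICITY_SCALES",
]

HYDROPHOBICITY_SCALES = (
    "kD_cyclohexane_water",
    "kD_vapor_to_water",
    "kD_octanol_to_water",
)

_AA1_ORDER = "ARNDCQEGHILKMFPSTWYV"


def _check_aa(wt_aa: str) -> str:
    aa = wt_aa.strip().upper()
    if len(aa) == 3:
        if aa not in AA3_TO_1:
            raise KeyError(f"nonstandard residue code {wt_aa!r}")
        aa = AA3_TO_1[aa]
    if aa not in _AA1_ORDER:
        raise KeyError(f"nonstandard residue code {wt_aa!r}")
    return aa


@lru_cache(maxsize=1)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=1)
def _scale_table() -> dict:
    text = resources.files("uaatol.data").joinpath("hydrophobicity_scales.tsv").read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, *vals = line.split("\t")
        table[aa] = dict(zip(HYDROPHOBICITY_SCALES, map(float, vals)))
    return table


@lru_cache(maxsize=1)
def _delta_tm_table() -> dict:
    text = (
        resources.files("uaatol.data").joinpath("delta_tm_vs_gly.synthetic.tsv").read_text()
    )
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, val = line.split("\t")
        table[aa] = float(val)
    return table


def blosum_features(wt_aa: str) -> dict:
    """BLOSUM62 substitution scores for replacing ``wt_aa`` by each residue.

    Returns exactly 20 integer-valued entries keyed
    ``blosum62_<aa3 lowercase>`` (e.g. ``blosum62_his``).
    """
    aa = _check_aa(wt_aa)
    mat = _blosum62()
    return {
        f"blosum62_{AA1_TO_3[b].lower()}": int(mat[aa, b]) for b in _AA1_ORDER
    }


def hydrophobicity_features(wt_aa: str) -> dict:
    """The three bundled transfer free-energy scale values for ``wt_aa``."""
    aa = _check_aa(wt_aa)
    return dict(_scale_table()[aa])


def delta_tm_feature(wt_aa: str) -> float:
    """Melting-temperature change measure vs glycine for ``wt_aa`` (deg C)."""
    aa = _check_aa(wt_aa)
    return _delta_tm_table()[aa]


def bioinfo_vector(wt_aa: str) -> dict:
    """All bioinformatics features for a site, merged into one mapping."""
    out = blosum_features(wt_aa)
    out.update(hydrophobicity_features(wt_aa))
    out["delta_t_d_m"] = delta_tm_feature(wt_aa)
    return out
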