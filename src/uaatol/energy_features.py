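"""Per-residue energy-term ingestion and site/sphere delta features.

Score tables carry pre-weighted per-residue energies (Rosetta energy
units, REU), one column per score term, typically five independent
refinement replicates per variant.  Replicates are averaged per residue
and per term; the feature vector then holds, for every term *t*, the
mutant-minus-WT delta at the mutation site (``t_Site``) and the mean
delta over the surrounding contact-sphere residues (``t_8A``).

Table dialect (plain text, whitespace-delimited)::

    #meta protein=<id> variant=<label> replicate=<int>
    residue <term1> <term2> ...
    A:1 -1.2 0.4 ...

Residue identifiers are ``<chain>:<number>`` tokens.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScoreTable",
    "parse_score_table",
    "write_score_table",
    "average_replicates",
    "energy_delta_vector",
    "residue_token",
    "parse_residue_token",
]


def residue_token(key: tuple) -> str:
    return f"{key[0]}:{key[1]}"


def parse_residue_token(token: str) -> tuple:
    chain, _, num = token.partition(":")
    if not _:
        raise ValueError(f"malformed residue token {token!r}")
    try:
        return (chain, int(num))
    except ValueError:
        return (chain, num)


@dataclass
class ScoreTable:
    """Per-residue, per-term weighted scores for one replicate."""

    protein: str
    variant: str  # "WT" or a site identifier
    replicate: int
    scores: pd.DataFrame  # index: residue token, columns: term names (ordered)

    @property
    def terms(self) -> list:
        return list(self.scores.columns)

    @property
    def residues(self) -> list:
        return list(self.scores.index)


def parse_score_table(stream) -> ScoreTable:
    """Parse the score-table dialect; errors name the offending line."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    if not lines or not lines[0].startswith("#meta"):
        raise ValueError("line 1: missing '#meta protein=... variant=... replicate=...'")
    meta = {}
    for tok in lines[0].split()[1:]:
        k, _, v = tok.partition("=")
        meta[k] = v
    for req in ("protein", "variant", "replicate"):
        if req not in meta:
            raise ValueError(f"line 1: meta field {req!r} missing")
    if len(lines) < 2:
        raise ValueError("line 2: missing header row")
    header = lines[1].split()
    if not header or header[0] != "residue":
        raise ValueError("line 2: header must start with 'residue'")
    terms = header[1:]
    if len(set(terms)) != len(terms):
        raise ValueError("line 2: duplicate term names")
    rows, index = [], []
    for ln, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != len(terms) + 1:
            raise ValueError(
                f"line {ln}: expected {len(terms) + 1} fields, got {len(parts)}"
            )
        if parts[0] in index:
            raise ValueError(f"line {ln}: duplicate residue {parts[0]!r}")
        index.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"line {ln}: non-numeric score field ({exc})") from None
    if not rows:
        raise ValueError("no residue rows in score table")
    df = pd.DataFrame(rows, index=index, columns=terms)
    return ScoreTable(
        protein=meta["protein"],
        variant=meta["variant"],
        replicate=int(meta["replicate"]),
        scores=df,
    )


def write_score_table(table: ScoreTable) -> str:
    out = [
        f"#meta protein={table.protein} variant={table.variant} "
        f"replicate={table.replicate}",
        " ".join(["residue"] + table.terms),
    ]
    for res, row in table.scores.iterrows():
        out.append(" ".join([res] + [repr(float(v)) for v in row]))
    return "\n".join(out) + "\n"


def average_replicates(tables: list) -> pd.DataFrame:
    """Arithmetic per-residue, per-term mean over replicate score tables."""
    if not tables:
        raise ValueError("no score tables to average")
    first = tables[0]
    reps = set()
    for t in tables:
        if t.protein != first.protein or t.variant != first.variant:
            raise ValueError(
                f"mixed protein/variant: {(t.protein, t.variant)} vs "
                f"{(first.protein, first.variant)}"
            )
        if t.terms != first.terms:
            raise ValueError("replicates disagree on term names/order")
        if set(t.residues) != set(first.residues):
            raise ValueError("replicates disagree on residue sets")
        if t.replicate in reps:
            raise ValueError(f"duplicate replicate id {t.replicate}")
        reps.add(t.replicate)
    stack = np.stack([t.scores.loc[first.residues].to_numpy() for t in tables])
    return pd.DataFrame(
        stack.mean(axis=0), index=first.residues, columns=first.terms
    )


def energy_delta_vector(
    wt: pd.DataFrame, mut: pd.DataFrame, site, sphere
) -> dict:
    """Site and sphere-averaged score deltas for every term.

    ``wt`` and ``mut`` are replicate-averaged tables (as from
    :func:`average_replicates`).  For each term *t* the vector holds
    ``t_Site``, the delta at the mutation site, and ``t_8A``, the mean
    delta over the contact-sphere residues.  ``site`` and the members
    of ``sphere`` may be residue keys or tokens.
    """
    if list(wt.columns) != list(mut.columns):
        raise ValueError("WT and mutant tables disagree on terms")
    if set(wt.index) != set(mut.index):
        raise ValueError("WT and mutant tables disagree on residues")

    def tok(x):
        return x if isinstance(x, str) else residue_token(x)

    site_t = tok(site)
    if site_t not in wt.index:
        raise KeyError(f"site {site_t!r} missing from score tables")
    sphere_t = [tok(r) for r in sphere]
    missing = [r for r in sphere_t if r not in wt.index]
    if missing:
        raise KeyError(f"sphere residues missing from score tables: {missing}")

    delta = mut.loc[wt.index] - wt
    out = {}
    site_row = delta.loc[site_t]
    if sphere_t:
        sphere_mean = delta.loc[sphere_t].mean(axis=0)
    else:
        warnings.warn("empty contact sphere; *_8A deltas set to 0")
        sphere_mean = pd.Series(0.0, index=delta.columns)
    for term in wt.columns:
        out[f"{term}_Site"] = float(site_row[term])
        out[f"{term}_8A"] = float(sphere_mean[term])
    return out
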