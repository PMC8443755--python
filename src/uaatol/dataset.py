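"""Mutant phenotype table, response binarization and holdout construction.

The experimental readouts per mutant are soluble yield (nM), total
yield (nM) and soluble fraction (%).  Each is turned into a binary
active/inactive class at a cutoff chosen to balance the classes
(defaults 520 nM, 1600 nM and 39% respectively); a value strictly above
the cutoff is active, ties are inactive.

The holdout is 20% of the samples, split equally between the proteins,
with a representative distribution of the response: within each
protein, records are binned by the global response quartiles and
sampled proportionally (largest-remainder allocation, seeded sampling
within bins).  An explicit-membership mode accepts a user-provided
holdout index list instead.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RESPONSES",
    "DEFAULT_CUTOFFS",
    "LabeledDataset",
    "SplitSpec",
    "load_phenotypes",
    "binarize_response",
    "make_holdout",
    "round_half_away",
]

RESPONSES = ("soluble_yield_nM", "total_yield_nM", "soluble_fraction_pct")

#: class-balancing cutoffs per response
DEFAULT_CUTOFFS = {
    "soluble_yield_nM": 520.0,
    "total_yield_nM": 1600.0,
    "soluble_fraction_pct": 39.0,
}

_PHENOTYPE_COLUMNS = ["protein", "site", "wt_aa"] + list(RESPONSES)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (school rounding, not banker's)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def load_phenotypes(path_or_buffer) -> pd.DataFrame:
    """Read the mutant phenotype CSV and validate its shape."""
    df = pd.read_csv(path_or_buffer)
    missing = [c for c in _PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if (df[["soluble_yield_nM", "total_yield_nM"]] < 0).any().any():
        raise ValueError("yields must be non-negative")
    frac = df["soluble_fraction_pct"]
    if ((frac < 0) | (frac > 100)).any():
        raise ValueError("soluble_fraction_pct must lie in [0, 100]")
    return df


def binarize_response(values, cutoff: float) -> np.ndarray:
    """Active (True) iff value > cutoff; ties and lower are inactive."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    arr = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(arr)):
        bad = list(np.nonzero(~np.isfinite(arr))[0])
        raise ValueError(f"missing/non-finite response values at rows {bad}")
    return arr > cutoff


@dataclass
class LabeledDataset:
    """Named feature matrix aligned with phenotype records and labels."""

    features: pd.DataFrame
    records: pd.DataFrame  # phenotype table, one row per feature row
    labels: dict = field(default_factory=dict)  # response -> bool array

    def __post_init__(self):
        if len(self.features) != len(self.records):
            raise ValueError("feature matrix and records are not aligned")
        for resp, lab in self.labels.items():
            if len(lab) != len(self.records):
                raise ValueError(f"labels for {resp!r} are not aligned")

    @property
    def n(self) -> int:
        return len(self.records)

    def label_from_cutoff(self, response: str, cutoff: float | None = None) -> np.ndarray:
        if cutoff is None:
            cutoff = DEFAULT_CUTOFFS[response]
        lab = binarize_response(self.records[response].to_numpy(), cutoff)
        self.labels[response] = lab
        return lab


@dataclass
class SplitSpec:
    """A train/holdout partition with its provenance."""

    train: list
    holdout: list
    seed: int | None
    per_protein_holdout: dict

    def __post_init__(self):
        if set(self.train) & set(self.holdout):
            raise ValueError("train and holdout overlap")

    def to_json(self) -> str:
        return json.dumps(
            {
                "train": [int(i) for i in self.train],
                "holdout": [int(i) for i in self.holdout],
                "seed": self.seed,
                "per_protein_holdout": {
                    str(k): int(v) for k, v in self.per_protein_holdout.items()
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        d = json.loads(text)
        return cls(
            train=d["train"],
            holdout=d["holdout"],
            seed=d["seed"],
            per_protein_holdout=d["per_protein_holdout"],
        )


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    if weights.sum() == 0:
        return np.zeros_like(weights, dtype=int)
    quota = weights / weights.sum() * total
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    # ties in remainder resolved toward earlier bins
    order = np.argsort(-remainder, kind="stable")
    for idx in order[: total - alloc.sum()]:
        alloc[idx] += 1
    return alloc


def make_holdout(
    records: pd.DataFrame,
    frac: float = 0.2,
    response: str = "soluble_fraction_pct",
    seed: int = 0,
    explicit_holdout=None,
) -> SplitSpec:
    """Construct the protein-balanced, response-representative holdout.

    The holdout has ``round(frac * n)`` rows (half away from zero),
    divided as equally as possible between the proteins.  Within each
    protein, rows are binned by the global quartiles of ``response``
    and drawn proportionally from the bins, so the holdout carries a
    representative distribution of the response.  Deterministic given
    ``seed``.  ``explicit_holdout`` bypasses sampling with a fixed list
    of row positions (mirroring an externally published membership).
    """
    n = len(records)
    if explicit_holdout is not None:
        holdout = sorted(int(i) for i in explicit_holdout)
        if any(i < 0 or i >= n for i in holdout):
            raise ValueError("explicit holdout indices out of range")
        train = [i for i in range(n) if i not in set(holdout)]
        counts = records.iloc[holdout]["protein"].value_counts().to_dict()
        return SplitSpec(train=train, holdout=holdout, seed=None,
                         per_protein_holdout=counts)

    if not (0.0 < frac <= 0.5):
        raise ValueError(f"holdout fraction must be in (0, 0.5], got {frac}")
    proteins = sorted(records["protein"].unique())
    if len(proteins) < 2:
        raise ValueError("need at least two proteins for a balanced holdout")
    sizes = records["protein"].value_counts()
    if (sizes < 5).any():
        raise ValueError("need at least 5 records per protein")

    h = int(round_half_away(frac * n))
    base, extra = divmod(h, len(proteins))
    # equal per-protein counts; any remainder goes to the larger proteins
    by_size = sorted(proteins, key=lambda p: (-sizes[p], p))
    quota = {p: base for p in proteins}
    for p in by_size[:extra]:
        quota[p] += 1

    y = records[response].to_numpy(dtype=float)
    edges = np.quantile(y, [0.25, 0.5, 0.75])
    bins = np.searchsorted(edges, y, side="left")  # 0..3 global quartile bins

    rng = np.random.default_rng(seed)
    holdout: list[int] = []
    for p in proteins:
        rows = np.nonzero((records["protein"] == p).to_numpy())[0]
        bin_ids = bins[rows]
        weights = np.array([(bin_ids == b).sum() for b in range(4)], dtype=float)
        alloc = _largest_remainder(weights, quota[p])
        for b in range(4):
            members = rows[bin_ids == b]
            take = min(alloc[b], len(members))
            if take:
                holdout.extend(rng.choice(members, size=take, replace=False))
        short = quota[p] - sum(1 for i in holdout if i in rows)
        if short > 0:
            # top up from any remaining rows of this protein
            pool = np.array([i for i in rows if i not in holdout])
            holdout.extend(rng.choice(pool, size=short, replace=False))
    # reconciliation: per-protein rounding can compound, so nudge the
    # holdout's above/below-median split to within one sample of the
    # global proportion by swapping rows within a protein
    target_upper = h * float(np.sum(bins >= 2)) / n
    holdout_set = set(int(i) for i in holdout)

    def _swap(direction: int) -> bool:
        # direction +1: move one holdout row from lower to upper bins
        want_in, want_out = (2, 0) if direction > 0 else (0, 2)
        for p in proteins:
            rows = np.nonzero((records["protein"] == p).to_numpy())[0]
            outs = [i for i in rows if i in holdout_set and (bins[i] >= 2) == (want_out == 2)]
            ins = [i for i in rows if i not in holdout_set and (bins[i] >= 2) == (want_in == 2)]
            if outs and ins:
                holdout_set.remove(int(rng.choice(outs)))
                holdout_set.add(int(rng.choice(ins)))
                return True
        return False

    for _ in range(h):
        upper = sum(1 for i in holdout_set if bins[i] >= 2)
        if upper > target_upper + 1 and _swap(-1):
            continue
        if upper < target_upper - 1 and _swap(+1):
            continue
        break

    holdout = sorted(holdout_set)
    train = [i for i in range(n) if i not in holdout_set]
    if len(holdout) != h:
        warnings.warn(f"holdout size {len(holdout)} differs from target {h}")
    return SplitSpec(
        train=train,
        holdout=holdout,
        seed=seed,
        per_protein_holdout={p: quota[p] for p in proteins},
    )
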