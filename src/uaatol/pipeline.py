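"""End-to-end orchestration: featurize -> label -> split -> tune -> report.

A single :class:`PipelineConfig` drives the whole run.  Feature
matrices come either precomputed (CSV aligned to the phenotype table by
protein and site) or from raw inputs via the ``featurize_*`` helpers.
For every response variable the pipeline binarizes at its cutoff,
reuses one protein-balanced holdout (stratified on soluble fraction),
screens correlations, fits a backward-selected linear model, tunes and
evaluates every configured classifier, and writes all reports plus a
manifest with checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bioinfo_features, est_features
from .dataset import (
    DEFAULT_CUTOFFS,
    RESPONSES,
    load_phenotypes,
    make_holdout,
)
from .energy_features import average_replicates, energy_delta_vector, parse_score_table
from .learning import (
    default_model_specs,
    dummy_stratified,
    evaluate,
    tune_and_evaluate,
)
from .mlr_stats import backward_select, rank_features
from .structures import SiteSelection, read_pdb, sphere_residues

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "featurize_energy_dir",
    "featurize_est_pairs",
]

log = logging.getLogger("uaatol")


def setup_logging(run_log: Path | None = None, seed: int | None = None) -> None:
    handlers = [logging.StreamHandler()]
    if run_log is not None:
        handlers.append(logging.FileHandler(run_log))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
    if seed is not None:
        log.info("seed=%d", seed)


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs; serializable to YAML/JSON."""

    phenotypes: str
    output_dir: str
    feature_csv: str | None = None
    score_dir: str | None = None
    structures_dir: str | None = None
    feature_set: str = "BOTH"  # EST | ENERGY | BOTH
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    holdout_frac: float = 0.2
    contact_cutoff: float = 4.0
    sphere_radius: float = 8.0
    k_max: int = 10
    folds: int = 5
    seed: int = 0
    algorithms: list = field(default_factory=lambda: ["LOG", "KRR", "SVC", "KNN", "GNB"])
    responses: list = field(default_factory=lambda: list(RESPONSES))

    def validate(self) -> None:
        if not (0.0 < self.holdout_frac <= 0.5):
            raise ValueError(f"holdout fraction must be in (0, 0.5], got {self.holdout_frac}")
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")
        if any(c <= 0 for c in self.cutoffs.values()):
            raise ValueError("cutoffs must be positive")
        if self.feature_set not in ("EST", "ENERGY", "BOTH"):
            raise ValueError("feature_set must be EST, ENERGY or BOTH")
        if self.feature_csv is None and self.score_dir is None and self.structures_dir is None:
            raise ValueError("no feature source configured")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# featurization helpers

_SCORE_FILE_RE = re.compile(r".*\.(sc|scores|txt)$")


def featurize_energy_dir(
    score_dir, phenotypes: pd.DataFrame, sphere_map: dict | None = None,
    structures_dir=None, sphere_radius: float = 8.0,
) -> pd.DataFrame:
    """Energy delta features for every phenotype row from a score-table dir.

    Score tables are grouped by their ``#meta`` protein/variant; the WT
    variant is labelled ``WT`` and mutant variants by site number.  The
    contact sphere per site comes from ``sphere_map`` (``"protein:site"``
    -> residue tokens) or is computed from ``<protein>_WT.pdb`` in
    ``structures_dir``.
    """
    score_dir = Path(score_dir)
    groups: dict = {}
    for f in sorted(score_dir.iterdir()):
        if not f.is_file() or not _SCORE_FILE_RE.match(f.name):
            continue
        table = parse_score_table(f.read_text())
        variant = table.variant
        if variant.lower().startswith("site"):
            variant = variant[4:]
        groups.setdefault((table.protein, variant), []).append(table)
    averaged = {key: average_replicates(tabs) for key, tabs in groups.items()}

    rows = []
    for _, rec in phenotypes.iterrows():
        protein, site = rec["protein"], int(rec["site"])
        wt_key, mut_key = (protein, "WT"), (protein, str(site))
        if wt_key not in averaged or mut_key not in averaged:
            raise KeyError(f"missing score tables for {protein} site {site}")
        wt_avg, mut_avg = averaged[wt_key], averaged[mut_key]
        site_token = next(
            (tok for tok in wt_avg.index if tok.split(":")[1] == str(site)), None
        )
        if site_token is None:
            raise KeyError(f"site {site} not found in score table for {protein}")
        if sphere_map is not None:
            sphere = sphere_map[f"{protein}:{site}"]
        else:
            if structures_dir is None:
                raise ValueError("need sphere_map or structures_dir for *_8A features")
            pdb = Path(structures_dir) / f"{protein}_WT.pdb"
            s = read_pdb(pdb.read_text(), structure_id=protein)
            chain = site_token.split(":")[0]
            sphere = [
                f"{k[0]}:{k[1]}"
                for k in sphere_residues(s, SiteSelection((chain, site)), sphere_radius)
            ]
        vec = energy_delta_vector(wt_avg, mut_avg, site_token, sphere)
        vec.update({"protein": protein, "site": site})
        rows.append(vec)
    df = pd.DataFrame(rows)
    return df[["protein", "site"] + [c for c in df.columns if c not in ("protein", "site")]]


def featurize_est_pairs(
    pairs: dict, phenotypes: pd.DataFrame, contact_cutoff: float = 4.0
) -> pd.DataFrame:
    """EST + bioinformatics features for every phenotype row.

    ``pairs`` maps ``"protein:site"`` to ``(wt Structure, mut Structure,
    SiteSelection)``.
    """
    rows = []
    for _, rec in phenotypes.iterrows():
        protein, site, wt_aa = rec["protein"], int(rec["site"]), rec["wt_aa"]
        wt, mut, sel = pairs[f"{protein}:{site}"]
        vec = est_features.est_delta_vector(wt, mut, sel, contact_cutoff=contact_cutoff)
        row = vec.as_dict()
        row.update(bioinfo_features.bioinfo_vector(wt_aa))
        row.update({"protein": protein, "site": site})
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["protein", "site"] + [c for c in df.columns if c not in ("protein", "site")]]


# ---------------------------------------------------------------------------
# the run


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(path: Path, text: str, manifest: dict) -> None:
    path.write_text(text)
    manifest["artifacts"][str(path)] = _sha256(path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out / "run.log", cfg.seed)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "artifacts": {},
        "completed_stages": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["completed_stages"].append(name)

    try:
        stage("load")
        phen = load_phenotypes(cfg.phenotypes)
        if cfg.feature_csv is not None:
            features = pd.read_csv(cfg.feature_csv)
        elif cfg.score_dir is not None:
            features = featurize_energy_dir(
                cfg.score_dir, phen, structures_dir=cfg.structures_dir,
                sphere_radius=cfg.sphere_radius,
            )
        else:
            raise ValueError("structure-only featurization requires featurize_est_pairs")
        merged = phen.merge(features, on=["protein", "site"], how="inner", validate="1:1")
        if len(merged) != len(phen):
            raise ValueError("feature matrix does not cover every phenotype row")
        feat_cols = [c for c in features.columns if c not in ("protein", "site")]
        X_df = merged[feat_cols]
        _write(out / "features.csv", merged.to_csv(index=False), manifest)

        stage("split")
        split = make_holdout(
            merged, cfg.holdout_frac, "soluble_fraction_pct", seed=cfg.seed
        )
        _write(out / "split.json", split.to_json(), manifest)

        summary_rows = []
        for response in cfg.responses:
            stage(f"label:{response}")
            cutoff = cfg.cutoffs[response]
            y = merged[response].to_numpy() > cutoff
            y_cont = merged[response].to_numpy(dtype=float)

            stage(f"correlations:{response}")
            corr = rank_features(X_df, y_cont, method="pearson")
            _write(
                out / f"correlations_{response}.csv",
                corr.as_frame().to_csv(index=False),
                manifest,
            )

            stage(f"mlr:{response}")
            mlr = backward_select(X_df, y_cont, max_features=cfg.k_max)
            _write(
                out / f"mlr_{response}.json", json.dumps(mlr.as_dict(), indent=2), manifest
            )

            tr, ho = split.train, split.holdout
            X = X_df.to_numpy(dtype=float)
            dummy_pred = dummy_stratified(y[tr], len(ho), seed=cfg.seed)
            dummy_rep = evaluate(dummy_pred, y[ho])
            summary_rows.append(
                {"response": response, "algorithm": "DUMMY", "split": "holdout",
                 **dummy_rep.as_dict()}
            )
            for spec in default_model_specs(cfg.algorithms):
                stage(f"train:{response}:{spec.algorithm}")
                report = tune_and_evaluate(
                    spec, X[tr], y[tr], X[ho], y[ho],
                    k_max=cfg.k_max, folds=cfg.folds, seed=cfg.seed,
                    feature_names=feat_cols,
                )
                _write(
                    out / f"model_{response}_{spec.algorithm}.json",
                    json.dumps(report, indent=2),
                    manifest,
                )
                for split_name in ("cv", "holdout"):
                    summary_rows.append(
                        {"response": response, "algorithm": spec.algorithm,
                         "split": split_name, **report[split_name]}
                    )
                if "importance" in report:
                    imp = pd.DataFrame(
                        sorted(report["importance"].items(), key=lambda t: -t[1]),
                        columns=["feature", "importance"],
                    )
                    _write(
                        out / f"importance_{response}_{spec.algorithm}.csv",
                        imp.to_csv(index=False),
                        manifest,
                    )

        stage("summary")
        summary = pd.DataFrame(summary_rows)
        _write(out / "metric_summary.csv", summary.to_csv(index=False), manifest)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed at stage {manifest['completed_stages'][-1]}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
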