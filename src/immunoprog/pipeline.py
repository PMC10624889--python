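"""End-to-end orchestration and the ``immunoprog`` command line.

A single YAML config drives the full analysis: clone tables -> diversity
metrics -> feature assembly -> prognostic score (published or freshly
fitted by forward stepwise AIC) -> risk groups -> survival evaluation. Each
stage writes a TSV/JSON artifact and the run ends with a manifest recording
the seed, config hash and per-stage row accounting, so that a rerun with
the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import encode_clinical_frame, fit_transform_spec, apply_transform
from .prognostic_model import (
    ScoreModel,
    ScoreTerm,
    assign_groups,
    derive_tertile_cutoffs,
    forward_stepwise_aic,
    load_model,
    published_her2event,
    save_model,
    score_frame,
)
from .repertoire import compute_all_scopes, metrics_long_frame, metrics_wide_frame, process_clone_table
from .survival_eval import harrell_c, kaplan_meier, log_rank, survival_at
from .synthetic_data import (
    CohortSimConfig,
    RepertoireSimConfig,
    simulate_cohort,
    simulate_repertoire,
    write_clone_tsv,
)

logger = logging.getLogger("immunoprog")

__all__ = ["PipelineConfig", "run_pipeline", "main"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    clinical_file: str
    out_dir: str
    seed: int = 0
    clones_dir: str | None = None
    totals_file: str | None = None
    column_map: Mapping[str, str] | None = None
    model: str = "published"  # "published", "fit", or a path to a saved model
    candidate_pool: list[str] = field(default_factory=list)
    transform_variables: list[str] = field(default_factory=list)
    evaluation_horizon: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "clinical_file": self.clinical_file,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "clones_dir": self.clones_dir,
            "totals_file": self.totals_file,
            "column_map": dict(self.column_map) if self.column_map else None,
            "model": self.model,
            "candidate_pool": list(self.candidate_pool),
            "transform_variables": list(self.transform_variables),
            "evaluation_horizon": self.evaluation_horizon,
        }


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _repertoire_stage(cfg: PipelineConfig, out: Path) -> pd.DataFrame | None:
    if cfg.clones_dir is None:
        return None
    totals = pd.read_csv(cfg.totals_file, sep="\t").set_index("sample_id")[
        "total_mapped_reads"
    ]
    results = {}
    for path in sorted(Path(cfg.clones_dir).glob("*.tsv")):
        sample_id = path.stem
        if sample_id not in totals.index:
            raise ValueError(f"no total mapped reads for sample {sample_id}")
        table = process_clone_table(
            path, int(totals[sample_id]), sample_id=sample_id, columns=cfg.column_map
        )
        results[sample_id] = compute_all_scopes(table)
    long = metrics_long_frame(results)
    wide = metrics_wide_frame(results)
    long.to_csv(out / "metrics_long.tsv", sep="\t", index=False)
    wide.to_csv(out / "metrics_wide.tsv", sep="\t")
    return wide


def _resolve_model(cfg: PipelineConfig, features: pd.DataFrame,
                   time, event, out: Path) -> ScoreModel:
    if cfg.model == "published":
        return published_her2event()
    if cfg.model != "fit":
        return load_model(cfg.model)
    pool = list(cfg.candidate_pool)
    feats = features.copy()
    transform_log = {}
    for var in cfg.transform_variables:
        values = feats[var].to_numpy(dtype=float)
        spec = fit_transform_spec(values, var, fitted_on="pipeline")
        feats[var] = apply_transform(values, spec)
        transform_log[var] = spec.to_dict()
    trace = forward_stepwise_aic(pool, feats, time, event)
    if not trace.final_variables:
        raise RuntimeError("stepwise selected no variables; cannot build a score")
    coefs = trace.final_fit.coefficients
    terms = tuple(ScoreTerm(v, float(coefs[v])) for v in trace.final_variables)
    scores = pd.Series(0.0, index=feats.index)
    for term in terms:
        scores = scores + term.coefficient * feats[term.variable].astype(float)
    lo, hi = derive_tertile_cutoffs(scores.dropna())
    ev_center = ev_scale = None
    if "bcr_evenness" in features.columns:
        raw = features["bcr_evenness"].dropna()
        ev_center, ev_scale = float(raw.mean()), float(raw.std(ddof=1))
    model = ScoreModel(
        terms=terms, cutoff_good=lo, cutoff_mid=hi,
        evenness_center=ev_center, evenness_scale=ev_scale, provenance="fitted",
    )
    save_model(model, out / "fitted_model.yaml")
    with open(out / "stepwise_trace.json", "w") as fh:
        json.dump(
            {
                "steps": trace.steps,
                "final_variables": list(trace.final_variables),
                "final_aic": trace.final_aic,
                "null_aic": trace.null_aic,
                "transforms": transform_log,
            },
            fh,
            indent=2,
        )
    return model


def _evaluate(scored: pd.DataFrame, horizon: float) -> dict:
    report: dict = {"groups": {}}
    for name, sub in scored.groupby("group"):
        curve = kaplan_meier(sub["efs_time"], sub["efs_event"])
        rate, ci = survival_at(curve, horizon)
        report["groups"][name] = {
            "n": int(len(sub)),
            "events": int(sub["efs_event"].sum()),
            f"efs_rate_{horizon:g}y": rate,
            "ci_95": list(ci) if ci else None,
        }
    if scored["group"].nunique() >= 2:
        stat, p = log_rank(scored["group"], scored["efs_time"], scored["efs_event"])
        report["log_rank"] = {"statistic": stat, "p_value": p}
    conc = harrell_c(scored["score"], scored["efs_time"], scored["efs_event"])
    report["c_index"] = conc.c_index
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    metrics = _repertoire_stage(cfg, out)

    clinical = pd.read_csv(cfg.clinical_file)
    n_input = len(clinical)
    features = encode_clinical_frame(clinical)
    if metrics is not None and "BCR_evenness" in metrics.columns:
        # computed repertoire metrics take precedence over any evenness
        # column already present in the clinical table
        features = features.drop(columns=["bcr_evenness"], errors="ignore").join(
            metrics["BCR_evenness"].rename("bcr_evenness")
        )

    model = _resolve_model(
        cfg, features, features["efs_time"], features["efs_event"], out
    )

    scores = score_frame(features, model)
    groups = assign_groups(scores, model)
    scored = groups.join(features[["efs_time", "efs_event"]])

    # complete-case accounting: n(scored) + n(excluded by reason) = n(input)
    exclusions: dict[str, int] = {}
    unresolved = scores.isna()
    feat_std = features.copy()
    if "bcr_evenness_std" in model.variables and "bcr_evenness_std" not in feat_std:
        feat_std["bcr_evenness_std"] = feat_std.get("bcr_evenness")
    for var in model.variables:
        mask = unresolved & feat_std[var].isna()
        if mask.any():
            exclusions[f"missing_{var}"] = int(mask.sum())
            unresolved = unresolved & ~mask
    n_scored = int(scores.notna().sum())

    scored_out = scored.copy()
    scored_out.index.name = "patient_id"
    scored_out.to_csv(out / "scores.tsv", sep="\t")

    report = _evaluate(scored.dropna(subset=["score"]), cfg.evaluation_horizon)
    with open(out / "evaluation.json", "w") as fh:
        json.dump(report, fh, indent=2)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "model_provenance": model.provenance,
        "counts": {
            "n_input": n_input,
            "n_scored": n_scored,
            "n_excluded": exclusions,
        },
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Command line


@click.group()
@click.version_option(__version__)
def main() -> None:
    """Immune-repertoire diversity metrics and the HER2-EveNT score."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")


@main.command("repertoire")
@click.option("--clones", required=True, type=click.Path(exists=True))
@click.option("--totals", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def cli_repertoire(clones, totals, out):
    """Compute per-sample diversity metrics from a directory of clone TSVs."""
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(clinical_file="", out_dir=str(out_dir),
                         clones_dir=clones, totals_file=totals)
    _repertoire_stage(cfg, out_dir)
    click.echo(f"wrote {out_dir}/metrics_long.tsv and metrics_wide.tsv")


@main.command("score")
@click.option("--model", "model_src", default="published", show_default=True)
@click.option("--clinical", required=True, type=click.Path(exists=True))
@click.option("--metrics", type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def cli_score(model_src, clinical, metrics, out):
    """Score patients and assign prognostic groups."""
    model = published_her2event() if model_src == "published" else load_model(model_src)
    features = encode_clinical_frame(pd.read_csv(clinical))
    if metrics:
        wide = pd.read_csv(metrics, sep="\t", index_col=0)
        features = features.join(wide["BCR_evenness"].rename("bcr_evenness"))
    groups = assign_groups(score_frame(features, model), model)
    groups.index.name = "patient_id"
    groups.to_csv(out, sep="\t")
    click.echo(f"wrote {out} ({int(groups['score'].notna().sum())} patients scored)")


@main.command("evaluate")
@click.option("--assignments", required=True, type=click.Path(exists=True))
@click.option("--clinical", required=True, type=click.Path(exists=True))
@click.option("--horizon", default=5.0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_evaluate(assignments, clinical, horizon, out):
    """Kaplan-Meier report, log-rank test and C-index for scored patients."""
    groups = pd.read_csv(assignments, sep="\t", index_col="patient_id")
    clin = pd.read_csv(clinical).set_index("patient_id")
    scored = groups.join(clin[["efs_time", "efs_event"]]).dropna(subset=["score"])
    report = _evaluate(scored, horizon)
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2)
    click.echo(f"wrote {out}")


@main.command("simulate")
@click.argument("kind", type=click.Choice(["repertoire", "cohort"]))
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--n", default=250, show_default=True, type=int)
@click.option("--out", required=True, type=click.Path())
def cli_simulate(kind, seed, n, out):
    """Generate a synthetic clone table or clinical cohort."""
    out_path = Path(out)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if kind == "repertoire":
        table = simulate_repertoire(RepertoireSimConfig(seed=seed))
        write_clone_tsv(table, out_path, seed=seed)
    else:
        clinical, _ = simulate_cohort(CohortSimConfig(seed=seed, n_patients=n))
        clinical.to_csv(out_path, index=False)
    click.echo(f"wrote {out_path}")


@main.command("run")
@click.option("--config", required=True, type=click.Path(exists=True))
def cli_run(config):
    """Run the full pipeline from a YAML config."""
    manifest = run_pipeline(PipelineConfig.from_yaml(config))
    click.echo(json.dumps(manifest["counts"], indent=2))


if __name__ == "__main__":
    main()
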