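"""End-to-end pipeline: read/simulate -> filter -> fit -> score -> infer.

A single configuration mapping drives every stage; all randomness flows
from one top-level seed split per stage, so identical config + input +
seed yields byte-identical outputs and a reproducible run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .allometry import fit_robust_allometry
from .inference import fit_robust_linear, pairwise_wilcoxon
from .records import (
    filter_analysis_set,
    measurement_subsets,
    read_records,
    records_to_frame,
    write_records,
)
from .scoring import score_population
from .simulate import config_from_dict, default_config, generate_population
from .tables import summary_tables

__all__ = ["PipelineError", "RunManifest", "run_pipeline"]

#: Per-stage seed offsets (top-level seed + offset, kept below 2**31).
SEED_OFFSETS = {"simulate": 0, "linear_fit": 1}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config_hash: str
    input_hash: str
    seed: int
    stage_seeds: dict[str, int]
    version: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    output_paths: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "input_hash": self.input_hash,
            "seed": self.seed,
            "stage_seeds": dict(self.stage_seeds),
            "version": self.version,
            "stage_counts": dict(self.stage_counts),
            "output_paths": sorted(self.output_paths),
        }


def _sha256_of(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _canonical_json(obj: Any) -> bytes:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"),
                      default=str).encode()


def validate_config(config: Mapping) -> dict:
    """Check the run configuration before any compute."""
    cfg = dict(config)
    has_input = "input" in cfg and cfg["input"].get("path")
    has_sim = "simulate" in cfg
    if has_input == has_sim:
        raise ValueError("config needs exactly one of input.path or simulate")
    if has_input and not Path(cfg["input"]["path"]).exists():
        raise ValueError(f"input file not found: {cfg['input']['path']}")
    cfg.setdefault("seed", 0)
    if not (0 <= int(cfg["seed"]) < 2 ** 31 - max(SEED_OFFSETS.values())):
        raise ValueError("seed must be a small nonnegative integer")
    cfg.setdefault("filter", {})
    cfg.setdefault("fit", {})
    cfg.setdefault("linear_terms", ["habitat", "sex"])
    cfg.setdefault("compare", {"group_by": "location", "adjust": "bonferroni",
                               "index": "bci1"})
    return cfg


def run_pipeline(config: Mapping, out_dir) -> tuple[dict, RunManifest]:
    """Run every stage; returns the report bundle and the manifest.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stage_seeds = {k: seed + off for k, off in SEED_OFFSETS.items()}
    manifest = RunManifest(
        config_hash=_sha256_of(_canonical_json(cfg)),
        input_hash="", seed=seed, stage_seeds=stage_seeds,
        version=__version__,
    )
    bundle: dict[str, Any] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return deco

    @stage("load")
    def records_and_issues():
        if "simulate" in cfg:
            sim_cfg = config_from_dict(cfg["simulate"]) if cfg["simulate"] else default_config()
            from dataclasses import replace
            sim_cfg = replace(sim_cfg, seed=stage_seeds["simulate"])
            recs = generate_population(sim_cfg)
            manifest.input_hash = _sha256_of(
                records_to_frame(recs).to_csv(index=False).encode())
            return recs, []
        res = read_records(cfg["input"]["path"],
                           units=cfg["input"].get("units", "m_kg"))
        manifest.input_hash = _sha256_of(Path(cfg["input"]["path"]).read_bytes())
        return res.records, res.rejected

    records, issues = records_and_issues
    manifest.stage_counts["input"] = len(records) + len(issues)

    @stage("filter")
    def filtered():
        retained, report = filter_analysis_set(
            records,
            include_condition_groups=bool(
                cfg["filter"].get("include_condition_groups", False)),
            exclude_ids=cfg["filter"].get("exclude_ids", ()),
            read_issues=issues,
        )
        if not retained:
            raise ValueError("no records retained after filtering")
        return retained, report

    retained, filter_report = filtered
    manifest.stage_counts["retained"] = len(retained)
    bundle["filter_report"] = filter_report

    @stage("fit")
    def fits():
        subsets = measurement_subsets(retained)
        fit_cfg = dict(cfg["fit"])
        factors = tuple(fit_cfg.pop("factors", ("habitat", "sex")))
        out_fits = {}
        for model in ("bci1", "bci2", "bci3"):
            out_fits[model] = fit_robust_allometry(
                subsets[model], model=model, factors=factors, **fit_cfg)
            manifest.stage_counts[f"n_{model}"] = out_fits[model].nobs
        return out_fits

    model_fits = fits
    bundle["fits"] = model_fits

    @stage("score")
    def scored():
        return score_population(retained, model_fits)

    scores = scored
    manifest.stage_counts["scores"] = len(scores)
    bundle["scores"] = scores

    @stage("linear_models")
    def linear():
        out_lin = {}
        for model in ("bci1", "bci2", "bci3"):
            out_lin[model] = fit_robust_linear(
                scores, terms=cfg["linear_terms"], index=model,
                seed=stage_seeds["linear_fit"])
        return out_lin

    bundle["linear_fits"] = linear

    @stage("pairwise")
    def pairwise():
        c = cfg["compare"]
        return pairwise_wilcoxon(scores, group_by=c.get("group_by", "location"),
                                 adjust=c.get("adjust", "bonferroni"),
                                 index=c.get("index", "bci1"))

    bundle["pairwise"] = pairwise

    @stage("tables")
    def tables():
        return summary_tables(scores, model_fits, records=retained)

    bundle["tables"] = tables

    @stage("write")
    def write():
        paths = []  # kept relative to out_dir so manifests are portable

        def save_csv(frame: pd.DataFrame, name: str):
            frame.to_csv(out / name, index=False)
            paths.append(name)

        write_records(retained, out / "filtered_records.csv")
        paths.append("filtered_records.csv")
        (out / "filter_report.json").write_text(
            json.dumps(filter_report.to_dict(), indent=2))
        paths.append("filter_report.json")
        (out / "fits.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in model_fits.items()}, indent=2,
            sort_keys=True))
        paths.append("fits.json")
        (out / "linear_fits.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in bundle["linear_fits"].items()},
            indent=2, sort_keys=True))
        paths.append("linear_fits.json")
        save_csv(scores.rounded(), "scores.csv")
        for name, frame in bundle["tables"].items():
            save_csv(frame.round(6), f"table_{name}.csv")
        pw = bundle["pairwise"]
        save_csv(pw.adjusted_p.round(6).reset_index(names="group"),
                 "pairwise_adjusted_p.csv")
        save_csv(pw.lower_triangle().reset_index(names="group"),
                 "pairwise_lower_triangle.csv")
        return paths

    manifest.output_paths = write
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    return bundle, manifest
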