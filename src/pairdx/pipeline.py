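"""End-to-end orchestration: data → pairs → screen → train → prognosis → enrich.

A single seeded configuration drives the whole run; every stage's
randomness comes from a named substream of that seed, all stage outputs
are plain text under ``<out>/<stage>/``, and a JSON manifest records
parameters, per-stage summaries and the SHA-256 of every output file, so
two runs with the same configuration produce byte-identical trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import diagnostic, prognostic
from .enrich import enrich as run_enrichment, results_to_frame as enrichment_frame
from .screen import results_to_frame as screen_frame, screen_pairs
from .io import read_expression, read_gmt, read_labels, read_survival, write_model
from .pairs import candidate_pairs, concat_cohorts
from .presets import small_synthetic_config
from .simulate import (
    PlantedPair,
    SurvivalConfig,
    SyntheticConfig,
    generate_study,
    write_fixtures,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("data", "pairs", "screen", "train", "prognosis", "enrich")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    cohort_paths: tuple[tuple[str, str, str], ...] = ()  # (cohort_id, expr, labels)
    gmt_path: str | None = None
    survival_path: str | None = None
    alpha_threshold: float = 1e-20
    n_repeats: int = 100
    occurrence_threshold: int | str = "auto"  # int or "auto"
    occurrence_grid: tuple[int, ...] = tuple(range(10, 101, 10))
    cv_folds: int = 10
    horizons: tuple[float, ...] = (1.0, 3.0, 5.0)
    fraction_train: float = 0.8
    auc_gate: float = 0.8

    def __post_init__(self) -> None:
        if self.synthetic is None and not self.cohort_paths:
            raise ValueError("config needs either a synthetic study or cohort input paths")
        if self.synthetic is None and self.gmt_path is None:
            raise ValueError("file-based configs must name a gene-set GMT file")
        if isinstance(self.occurrence_threshold, str) and self.occurrence_threshold != "auto":
            raise ValueError("occurrence_threshold must be an integer or 'auto'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        syn = None
        if "synthetic" in raw:
            s = raw["synthetic"]
            if isinstance(s, str) or (isinstance(s, dict) and "preset" in s):
                name = s if isinstance(s, str) else s["preset"]
                if name != "small":
                    raise ValueError(f"unknown synthetic preset {name!r}")
                syn = small_synthetic_config(seed=int(raw.get("seed", 0)))
            else:
                planted = tuple(PlantedPair(*p) for p in s.pop("planted_pairs", []))
                surv = s.pop("survival", None)
                if surv is not None:
                    surv = SurvivalConfig(
                        baseline_rate=float(surv.get("baseline_rate", 0.25)),
                        betas=tuple((a, b, float(v)) for a, b, v in surv.get("betas", [])),
                        censor_time_max=surv.get("censor_time_max", 12.0),
                    )
                syn = SyntheticConfig(planted_pairs=planted, survival=surv,
                                      seed=int(raw.get("seed", 0)), **s)
        cohorts = tuple(
            (c["id"], c["expression"], c["labels"]) for c in raw.get("cohorts", [])
        )
        params = raw.get("params", {})
        kwargs: dict[str, Any] = {}
        for key in ("alpha_threshold", "n_repeats", "occurrence_threshold", "cv_folds",
                    "fraction_train", "auc_gate"):
            if key in params:
                kwargs[key] = params[key]
        if "occurrence_grid" in params:
            kwargs["occurrence_grid"] = tuple(int(v) for v in params["occurrence_grid"])
        if "horizons" in params:
            kwargs["horizons"] = tuple(float(h) for h in params["horizons"])
        return cls(
            seed=int(raw.get("seed", 0)),
            synthetic=syn,
            cohort_paths=cohorts,
            gmt_path=raw.get("gene_sets"),
            survival_path=raw.get("survival"),
            **kwargs,
        )

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    k = _STAGES.index(stage)
    return int(np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages, write outputs and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": config.to_jsonable(), "seed": config.seed, "stages": []}

    def record(stage: str, status: str, outputs: Mapping[str, Path] = {}, **summary: Any) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "status": status,
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs.values()},
                "summary": json.loads(json.dumps(summary, default=float)),
            }
        )
        logger.info("stage %s: %s %s", stage, status, summary)

    # ---- data -------------------------------------------------------
    stage = "data"
    try:
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        if config.synthetic is not None:
            study = generate_study(config.synthetic)
            files = write_fixtures(study, sdir)
            cohorts = study.cohorts
            gene_sets = study.gene_sets
            survival = study.survival
        else:
            cohorts = []
            for cid, expr_path, lab_path in config.cohort_paths:
                cohorts.append((read_expression(expr_path, cid), read_labels(lab_path)))
            gene_sets = read_gmt(config.gmt_path)
            survival = read_survival(config.survival_path) if config.survival_path else None
            files = {}
        record(stage, "ok", files, n_cohorts=len(cohorts),
               n_samples=sum(len(lab) for _, lab in cohorts),
               has_survival=survival is not None)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- pairs ------------------------------------------------------
    stage = "pairs"
    try:
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        common: set[str] = set(cohorts[0][0].gene_ids)
        for expr, _ in cohorts[1:]:
            common &= set(expr.gene_ids)
        pairs = candidate_pairs(gene_sets, common)
        p_pairs = sdir / "pairs.tsv"
        _write_tsv(
            pd.DataFrame({"gene_a": [p.gene_a for p in pairs], "gene_b": [p.gene_b for p in pairs]}),
            p_pairs,
        )
        record(stage, "ok", {"pairs": p_pairs}, n_common_genes=len(common), n_pairs=len(pairs))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- screen -----------------------------------------------------
    stage = "screen"
    try:
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        features, labels = concat_cohorts(cohorts, pairs)
        results = screen_pairs(features, labels, config.alpha_threshold)
        p_screen = sdir / "screen.tsv"
        _write_tsv(screen_frame(results), p_screen)
        significant = [r.pair for r in results if r.significant]
        if not significant:
            raise ValueError(
                f"no pair is significant at adjusted p < {config.alpha_threshold}"
            )
        record(stage, "ok", {"screen": p_screen},
               n_tested=len(results), n_significant=len(significant))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- train ------------------------------------------------------
    stage = "train"
    try:
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        seed = _stage_seed(config.seed, stage)
        feats_sig = features.subset(significant)
        disc_ids, eval_ids = diagnostic.split_discovery(labels, config.fraction_train, seed)
        f_disc, l_disc = feats_sig.select_samples(disc_ids), labels.loc[disc_ids]
        f_eval, l_eval = feats_sig.select_samples(eval_ids), labels.loc[eval_ids]
        stab = diagnostic.stability_select(
            f_disc, l_disc, config.n_repeats, config.fraction_train, seed,
            auc_gate=config.auc_gate,
        )
        if config.occurrence_threshold == "auto":
            occ = diagnostic.tune_occurrence_threshold(
                stab, f_disc, l_disc, f_eval, l_eval,
                grid=config.occurrence_grid, cv_folds=config.cv_folds, seed=seed,
            )
        else:
            occ = int(config.occurrence_threshold)
        candidates = diagnostic.select_candidates(stab, occ)
        model = diagnostic.fit_final_model(f_disc, l_disc, candidates, config.cv_folds, seed)
        comparators = diagnostic.fit_comparators(f_disc, l_disc, candidates, seed)
        report = diagnostic.comparison_report(
            model, comparators, {"eval": (f_eval, l_eval)}, comparator_pairs=candidates
        )
        p_model, p_report = sdir / "model.txt", sdir / "report.tsv"
        write_model(model, p_model)
        _write_tsv(report, p_report)
        eval_auc = float(report.loc[report["method"] == "lasso_logistic", "auc"].iloc[0])
        record(stage, "ok", {"model": p_model, "report": p_report},
               occurrence_threshold=occ, n_candidates=len(candidates),
               n_model_pairs=len(model.pairs), eval_auc=eval_auc)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- prognosis --------------------------------------------------
    stage = "prognosis"
    try:
        if survival is None:
            record(stage, "skipped", {}, reason="no survival data in config")
        else:
            sdir = out / stage
            sdir.mkdir(exist_ok=True)
            seed = _stage_seed(config.seed, stage)
            surv_ids = [s for s in features.sample_ids if s in survival.index]
            feats_surv = features.select_samples(surv_ids)
            kept = prognostic.filter_univariate(model.pairs, feats_surv, survival)
            prog = prognostic.lasso_cox(feats_surv, survival, kept, config.cv_folds, seed)
            scores = prognostic.risk_score(prog, feats_surv)
            strata = prognostic.median_split(scores)
            curves, logrank_p = prognostic.km_logrank(strata, survival)
            aucs: dict[str, float | None] = {}
            for h in config.horizons:
                try:
                    aucs[str(h)] = prognostic.time_dependent_auc(scores, survival, h)
                except ValueError as exc:
                    logger.warning("horizon %s: %s", h, exc)
                    aucs[str(h)] = None
            p_model = sdir / "prog_model.txt"
            write_model(prog, p_model)
            km_frames = [df.assign(group=g) for g, df in sorted(curves.items())]
            p_km = sdir / "km.tsv"
            _write_tsv(pd.concat(km_frames, ignore_index=True), p_km)
            record(stage, "ok", {"model": p_model, "km": p_km},
                   n_univariate=len(kept), n_model_pairs=len(prog.pairs),
                   logrank_p=logrank_p, time_dependent_auc=aucs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- enrich -----------------------------------------------------
    stage = "enrich"
    try:
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        genes = sorted({g for p in model.pairs for g in p})
        results = run_enrichment(genes, gene_sets, common)
        p_enrich = sdir / "enrich.tsv"
        _write_tsv(enrichment_frame(results), p_enrich)
        record(stage, "ok", {"enrich": p_enrich},
               n_genes=len(genes), n_sets_tested=len(results))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    p_manifest = out / "manifest.json"
    p_manifest.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest
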