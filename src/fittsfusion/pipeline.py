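"""End-to-end workflow: simulate -> extract -> screen -> fit -> report.

Each stage writes plain delimited-text artifacts into the run directory so
diffs stay reviewable: the dataset manifest and per-trial channel files, the
feature table, the correlation-screen report (mirroring the r / p /
category / inclusion / set-assignment layout), the model-comparison table
with the six criteria per model plus percent RMSE improvements, and a run
manifest echoing the configuration, seeds, package version, and per-stage
row counts and checksums.  Identical configuration (including the master
seed) reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .features import build_feature_table
from .io import write_dataset
from .plsr import CRITERIA, ModelComparison, compare_models
from .screening import (
    ALL_METRICS,
    CorrelationScreen,
    FeatureSets,
    one_way_anova,
    screen_features,
    select_features,
)
from .synthetic import SynthConfig, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "screen_report_frame",
           "comparison_frame"]

log = logging.getLogger("fittsfusion")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration: generator settings plus analysis knobs."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    screening_threshold: float = 0.20
    cv_folds: int = 10
    cv_inner_folds: int = 5
    cv_seed: int = 0
    n_components: int | None = None
    standardization: str = "fold"  # "fold" (leakage-safe) or "global"
    outdir: str = "fittsfusion_run"
    write_trial_files: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.screening_threshold < 1.0:
            raise ValueError("screening threshold must be in [0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = self.synth.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = SynthConfig.from_dict(d["synth"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def make_fixtures(seed: int = 0) -> list:
    """Miniature dataset for fast tests: 2 subjects x 2 conditions x 2
    repetitions = 8 trials with every channel populated."""
    config = SynthConfig(
        n_subjects=2, repetitions=2, distances=(10.0, 320.0), seed=seed
    )
    return generate_dataset(config)


def screen_report_frame(
    screen: CorrelationScreen, sets: FeatureSets, anova: dict | None = None
) -> pd.DataFrame:
    """Tabular screen report: metric, r, p, category, inclusion, set flags."""
    rows = []
    for m in ALL_METRICS:
        row = screen.rows[m]
        entry = {
            "metric": m,
            "r": row.r,
            "p": row.p,
            "category": row.category,
            "included": row.included,
            "set_I": m in sets.set_i.metrics,
            "set_II": m in sets.set_ii.metrics,
            "set_III": m in sets.set_iii.metrics,
            "set_IV": m in sets.set_iv.metrics,
        }
        if anova and m in anova:
            entry["anova_F"], entry["anova_p"] = anova[m]
        rows.append(entry)
    return pd.DataFrame(rows)


def comparison_frame(comparison: ModelComparison) -> pd.DataFrame:
    """Model-comparison table: one row per model, six criteria plus the
    percent RMSE improvement over the movement-time model."""
    rows = []
    for sid in ("I", "II", "III", "IV"):
        rep = comparison.reports[sid]
        rows.append(
            {
                "model": sid,
                **{c: getattr(rep, c) for c in CRITERIA},
                "rmse_improvement_vs_I_pct": comparison.improvement_vs_mt.get(sid),
                "metrics": ";".join(comparison.metric_sets[sid]),
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the run artifacts; returns paths and the
    in-memory results.  A stage failure raises with the stage named and
    leaves a failure marker next to any partial outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"outdir": str(outdir)}
    stage = "simulate"
    t_all = time.perf_counter()
    try:
        # --- simulate ---------------------------------------------------
        t0 = time.perf_counter()
        records = generate_dataset(config.synth)
        if config.write_trial_files:
            write_dataset(records, outdir)
        log.info("simulate: %d trials in %.1fs", len(records), time.perf_counter() - t0)

        # --- extract ----------------------------------------------------
        stage = "extract"
        t0 = time.perf_counter()
        table = build_feature_table(records)
        features_path = outdir / "features.csv"
        table.to_csv(features_path, index=False)
        artifacts["features_csv"] = str(features_path)
        log.info(
            "extract: %d rows x %d metric columns in %.1fs",
            len(table), len(ALL_METRICS), time.perf_counter() - t0,
        )

        # --- screen -----------------------------------------------------
        stage = "screen"
        t0 = time.perf_counter()
        screen = screen_features(table, table["ID"], threshold=config.screening_threshold)
        sets = select_features(screen)
        anova = {
            m: one_way_anova(*(g[m].to_numpy() for _, g in table.groupby("ID")))
            for m in ALL_METRICS
        }
        screen_df = screen_report_frame(screen, sets, anova)
        screen_path = outdir / "screen.csv"
        screen_df.to_csv(screen_path, index=False)
        artifacts["screen_csv"] = str(screen_path)
        log.info(
            "screen: %d/%d metrics included in %.1fs",
            len(sets.set_ii.metrics) + 1, len(ALL_METRICS), time.perf_counter() - t0,
        )

        # --- fit + report -----------------------------------------------
        stage = "fit"
        t0 = time.perf_counter()
        comparison = compare_models(
            table,
            table["ID"],
            sets,
            k=config.cv_folds,
            seed=config.cv_seed,
            n_components=config.n_components,
            standardization=config.standardization,
        )
        models_df = comparison_frame(comparison)
        models_path = outdir / "models.csv"
        models_df.to_csv(models_path, index=False)
        artifacts["models_csv"] = str(models_path)
        log.info("fit: 4 models x %d folds in %.1fs", config.cv_folds,
                 time.perf_counter() - t0)

        stage = "report"
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "n_trials": len(records),
            "rows": {"features": len(table), "screen": len(screen_df),
                     "models": len(models_df)},
            "checksums": {
                p.name: _sha256(p) for p in (features_path, screen_path, models_path)
            },
        }
        with open(outdir / "run_manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        artifacts["run_manifest"] = str(outdir / "run_manifest.yaml")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    artifacts.update(
        records=records, features=table, screen=screen, feature_sets=sets,
        comparison=comparison,
    )
    log.info("pipeline complete in %.1fs", time.perf_counter() - t_all)
    return artifacts
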