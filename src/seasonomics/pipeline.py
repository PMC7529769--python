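"""End-to-end orchestration: simulate -> seasonality -> clustering ->
interval differential -> diversity, with one seed, TSV outputs and a
run manifest.

Every stage reads/writes plain TSV so any stage can also be run in
isolation (see :mod:`seasonomics.cli`). A run writes ``manifest.json``
with the config snapshot, package version, per-stage row counts,
runtimes and output checksums; rerunning with the same config and seed
reproduces the checksums. Day coordinates are 1-based inclusive in
[1, 365]; intervals [t, t+1] span grid days t to t+1.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as sio
from .clustering import (EmptySelection, fuzzy_cmeans, hard_labels,
                         project_membership, select_k, standardize_curve,
                         standardize_curves)
from .cohort import (CohortDesign, default_feature_panel, generate_features,
                     generate_taxon_counts, generate_visits)
from .diversity import aggregate_taxa, chao1_table, diversity_seasonality
from .intervals import run_interval_test
from .seasonal import ModelSpec, fit_table

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "seasonomics_run"
    seed: int = 0
    # simulation (used when no input long table is given)
    simulate: bool = True
    n_subjects: int = 40
    n_years: int = 3
    visits_per_year: int = 4
    n_features: int = 200
    n_taxa: int = 120
    winter_richness_boost: float = 1.5
    # external inputs (override simulation)
    long_path: str | None = None
    counts_path: str | None = None
    taxonomy_path: str | None = None
    project_curves_path: str | None = None
    # stages
    run_seasonality: bool = True
    run_clustering: bool = True
    run_differential: bool = True
    run_diversity: bool = True
    # model / clustering / differential / diversity parameters
    n_basis: int = 10
    p_threshold: float = 0.05
    k_min: int = 2
    k_max: int = 10
    fuzzifier: float = 2.0
    n_restarts: int = 10
    B: int = 200
    T: int = 52
    alpha: float = 0.05
    permutation_unit: str = "subject"
    differential_max_features: int | None = None
    diversity_level: str = "genus"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.B < 1 or self.T < 2:
            raise ConfigError("B must be >= 1 and T >= 2")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ConfigError("k range must satisfy 2 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = sio.read_config(path)
        unknown = set(cfg) - {f.name for f in __import__("dataclasses").fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**cfg)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def model_spec(self, covariates=("group", "bmi")) -> ModelSpec:
        return ModelSpec(n_basis=self.n_basis, covariates=tuple(covariates))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def write(self, outdir: Path) -> Path:
        path = outdir / "manifest.json"
        path.write_text(json.dumps(
            {"config": self.config, "version": self.version, "seed": self.seed,
             "stages": self.stages, "outputs": self.outputs}, indent=2))
        return path


def run_all(config: PipelineConfig) -> RunManifest:
    """Run the configured stages, writing TSV outputs and a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__,
                           seed=config.seed)
    written: list[Path] = []

    def _finish_stage(stage: str, t0: float, tables: dict[str, pd.DataFrame],
                      index: dict[str, bool] | None = None) -> None:
        for name, df in tables.items():
            p = sio.write_tsv(df, outdir / name, index=(index or {}).get(name, False))
            written.append(p)
            log.info("[%s] wrote %s (%d rows)", stage, name, len(df))
        manifest.stages[stage] = {
            "runtime_s": round(time.time() - t0, 3),
            "rows": {name: int(len(df)) for name, df in tables.items()}}

    def _fail(stage: str, exc: Exception) -> StageError:
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        for p in written:
            manifest.outputs[p.name] = _sha256(p)
        manifest.write(outdir)
        return StageError(stage, exc)

    # ------------------------------------------------------------- simulate
    long = counts = taxonomy = None
    if config.long_path:
        long = sio.read_long(config.long_path)
    if config.counts_path:
        counts = sio.read_counts(config.counts_path)
        if config.taxonomy_path:
            taxonomy = pd.read_csv(config.taxonomy_path, sep="\t")
    if long is None and config.simulate:
        t0 = time.time()
        try:
            design = CohortDesign(n_subjects=config.n_subjects,
                                  n_years=config.n_years,
                                  visits_per_year=config.visits_per_year,
                                  seed=config.seed)
            visits = generate_visits(design)
            specs = default_feature_panel(config.n_features)
            long, truth = generate_features(design, specs, visits)
            counts, taxonomy = generate_taxon_counts(
                design, visits, n_taxa=config.n_taxa,
                winter_richness_boost=config.winter_richness_boost)
            _finish_stage("simulate", t0, {
                "visits.tsv": visits, "long.tsv": long, "ground_truth.tsv": truth,
                "taxon_counts.tsv": counts.reset_index(), "taxonomy.tsv": taxonomy})
        except Exception as exc:
            raise _fail("simulate", exc)
    if long is None:
        raise _fail("input", ConfigError("no input long table and simulate=False"))

    visits = long.drop_duplicates("sample_id")[sio.VISIT_COLUMNS].reset_index(drop=True)

    # ---------------------------------------------------------- seasonality
    fits = {}
    if config.run_seasonality:
        t0 = time.time()
        try:
            table, fits = fit_table(long, config.model_spec())
            n_sig = int((table.loc[table["fitted"], "p_value"] <= config.p_threshold).sum())
            log.info("[seasonality] %d/%d features with p <= %g",
                     n_sig, len(table), config.p_threshold)
            curves = pd.concat([
                pd.DataFrame({"feature_id": fid, "day": np.arange(1, 366),
                              "fit": f.fitted_curve,
                              "lower": f.fitted_curve - 1.96 * f.curve_sd,
                              "upper": f.fitted_curve + 1.96 * f.curve_sd})
                for fid, f in fits.items()], ignore_index=True)
            _finish_stage("seasonality", t0,
                          {"seasonality.tsv": table, "curves.tsv": curves})
        except Exception as exc:
            raise _fail("seasonality", exc)

    # ----------------------------------------------------------- clustering
    if config.run_clustering and fits:
        t0 = time.time()
        try:
            cm = standardize_curves(fits, p_threshold=config.p_threshold)
            kmax = min(config.k_max, len(cm) - 1)
            report = select_k(cm, range(config.k_min, kmax + 1),
                              m=config.fuzzifier, seed=config.seed,
                              n_restarts=config.n_restarts)
            model = report.models[report.chosen_k]
            ksel = pd.DataFrame({"k": report.ks, "silhouette": report.silhouette,
                                 "dispersion": report.dispersion,
                                 "chosen": [k == report.chosen_k for k in report.ks]})
            memb = pd.DataFrame(model.membership,
                                columns=[f"cluster_{j + 1}" for j in range(model.k)])
            memb.insert(0, "feature_id", cm.feature_ids)
            memb["hard_label"] = hard_labels(model) + 1
            cents = pd.concat([
                pd.DataFrame({"cluster": j + 1, "day": np.arange(1, 366),
                              "value": model.centroids[j]})
                for j in range(model.k)], ignore_index=True)
            tables = {"k_selection.tsv": ksel, "membership.tsv": memb,
                      "centroids.tsv": cents}
            if config.project_curves_path:
                proj_rows = []
                ext = sio.read_curves(config.project_curves_path)
                for sid, sub in ext.groupby("feature_id"):
                    curve = standardize_curve(
                        sub.sort_values("day")["fit"].to_numpy())
                    u = project_membership(curve, model)
                    proj_rows.append({"feature_id": sid,
                                      **{f"cluster_{j + 1}": u[j] for j in range(model.k)}})
                tables["projection.tsv"] = pd.DataFrame(proj_rows)
            _finish_stage("clustering", t0, tables)
        except EmptySelection as exc:
            log.warning("[clustering] skipped: %s", exc)
            manifest.stages["clustering"] = {"skipped": str(exc)}
        except Exception as exc:
            raise _fail("clustering", exc)

    # --------------------------------------------------------- differential
    if config.run_differential:
        t0 = time.time()
        try:
            rows, summaries = [], []
            feature_ids = sorted(long["feature_id"].unique())
            if config.differential_max_features:
                feature_ids = feature_ids[:config.differential_max_features]
            for fid in feature_ids:
                sub = long[long["feature_id"] == fid]
                res = run_interval_test(
                    sub["value"].to_numpy(), sub, B=config.B, T=config.T,
                    alpha=config.alpha, unit=config.permutation_unit,
                    seed=config.seed, feature_id=fid)
                g = res.grid_days
                rows.append(pd.DataFrame({
                    "feature_id": fid, "interval_start_day": g[:-1],
                    "interval_end_day": g[1:], "statistic": res.statistics,
                    "p": res.pvalues, "adj_p": res.adjusted,
                    "significant": res.significant}))
                summaries.append({
                    "feature_id": fid, "classification": res.classification,
                    "significant_ranges": ";".join(
                        f"{a:.0f}-{b:.0f}" for a, b in res.significant_ranges)})
            _finish_stage("differential", t0, {
                "intervals.tsv": pd.concat(rows, ignore_index=True),
                "intervals_summary.tsv": pd.DataFrame(summaries)})
        except Exception as exc:
            raise _fail("differential", exc)

    # ------------------------------------------------------------ diversity
    if config.run_diversity and counts is not None and taxonomy is not None:
        t0 = time.time()
        try:
            level_counts = aggregate_taxa(counts, taxonomy, config.diversity_level)
            est = chao1_table(level_counts, level=config.diversity_level)
            ds = diversity_seasonality(est, visits)
            est["seasonality_p"] = ds.pvalue
            est["winter_summer_contrast"] = ds.winter_summer_contrast
            _finish_stage("diversity", t0, {"diversity.tsv": est})
        except Exception as exc:
            raise _fail("diversity", exc)

    for p in written:
        manifest.outputs[p.name] = _sha256(p)
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    manifest.write(outdir)
    return manifest
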