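"""Pipeline configuration and the end-to-end orchestration.

One prediction model is fit per organ × stage × intensity scale: the
organ–stage subset is filtered for missingness, KNN-imputed, optionally
log2-transformed, pushed through the resampling stability engine, and the
DR-thresholded metabolites are refit on all rows and on the WS and HY rows
separately. Results land in the output directory as TSV tables and JSON,
with a manifest recording every derived seed — the whole run is
reproducible byte-for-byte from the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .containers import MetabolomeMatrix, derive_seed
from .preprocess import DEFAULT_K, DEFAULT_MAX_MISSING_FRAC, filter_by_missingness, knn_impute, log2_transform
from .refit import DEFAULT_DR_THRESHOLD, refit_all_subsets, shares_table
from .stability import DEFAULT_N_RUNS, DEFAULT_TRAIN_FRACTION, LassoConfig, make_splits, run_stability
from .synthetic import simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs: either file paths or a simulation request
    matrix_path: str | None = None
    design_path: str | None = None
    traits_path: str | None = None
    simulate: bool = True
    n_metabolites: int = 80

    # preprocessing
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC
    knn_k: int = DEFAULT_K
    scales: list[str] = field(default_factory=lambda: ["raw", "log2"])
    pooled_imputation: bool = False  # impute per organ–stage cell by default

    # resampling
    n_runs: int = DEFAULT_N_RUNS
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    stratify: str | None = None
    seed: int = 0

    # lasso
    n_grid: int = 100
    eps: float = 1e-3
    inner_folds: int = 5
    rule: str = "min"
    tol: float = 1e-8

    # refit
    dr_threshold: float = DEFAULT_DR_THRESHOLD
    variance_method: str = "sequential_dr"

    # scope
    organs: list[str] = field(default_factory=lambda: ["flag_leaf", "glume", "lemma"])
    stages: list[str] = field(default_factory=lambda: ["anthesis", "grain_filling"])
    trait: str = "GY"

    def validate(self) -> None:
        if not (0.0 < self.dr_threshold <= 1.0):
            raise ValueError(f"dr_threshold must lie in (0, 1], got {self.dr_threshold}")
        if not (0.0 <= self.max_missing_frac < 1.0):
            raise ValueError("max_missing_frac must lie in [0, 1)")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if any(s not in ("raw", "log2") for s in self.scales):
            raise ValueError(f"scales must be among raw/log2, got {self.scales}")
        if self.rule not in ("min", "1se"):
            raise ValueError("rule must be 'min' or '1se'")
        if self.variance_method not in ("sequential_dr", "lmg"):
            raise ValueError("variance_method must be 'sequential_dr' or 'lmg'")
        if not self.simulate and not (self.matrix_path and self.design_path and self.traits_path):
            raise ValueError("without simulation, matrix/design/traits paths are required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(d or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def preprocess_cell(
    matrix: MetabolomeMatrix, config: PipelineConfig, scale: str
) -> tuple[MetabolomeMatrix, dict]:
    """Filter → impute → (optionally) log2 for one organ–stage subset."""
    filtered, filter_report = filter_by_missingness(matrix, config.max_missing_frac)
    imputed, impute_report = knn_impute(filtered, k=config.knn_k)
    if scale == "log2":
        imputed = log2_transform(imputed)
    report = filter_report.to_dict()
    report.update(
        imputed_cell_count=impute_report.imputed_cell_count,
        k_used=impute_report.k_used,
        scale_out=scale,
        warnings=filter_report.warnings + impute_report.warnings,
    )
    return imputed, report


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every organ × stage × scale model and write the result bundle.

    Returns the manifest (also written to ``manifest.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lasso_cfg = LassoConfig(
        n_grid=config.n_grid, eps=config.eps, inner_folds=config.inner_folds,
        rule=config.rule, tol=config.tol,
    )

    if config.simulate:
        matrix, truth, traits = simulate_study(config.seed, n_metabolites=config.n_metabolites)
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        _io.write_matrix(matrix, inputs / "matrix.tsv")
        _io.write_design(matrix.design, inputs / "design.tsv")
        _io.write_traits(traits, inputs / "traits.tsv")
        _io.write_ground_truth(truth, inputs / "ground_truth.json")
    else:
        design = _io.read_design(config.design_path)
        matrix = _io.read_matrix(config.matrix_path, design)
        traits = _io.read_traits(config.traits_path)

    trait_by_sample = traits.set_index("sample_id")[config.trait]
    manifest: dict = {"config": config.to_dict(), "models": {}, "seeds": {"root": config.seed}}
    effects_frames = []
    shares_frames = []

    for organ in config.organs:
        for stage in config.stages:
            cell_raw = matrix.select_cell(organ, stage)
            y = trait_by_sample.loc[cell_raw.sample_ids].to_numpy(dtype=float)
            for scale in config.scales:
                name = f"{organ}.{stage}.{scale}"
                logger.info("fitting model %s (n=%d)", name, cell_raw.n_samples)
                prepped, report = preprocess_cell(cell_raw, config, scale)
                split_seed = derive_seed(config.seed, f"splits.{name}")
                plan = make_splits(
                    prepped.n_samples,
                    n_runs=config.n_runs,
                    train_fraction=config.train_fraction,
                    seed=split_seed,
                    stratify_by=prepped.design[config.stratify] if config.stratify else None,
                )
                stab = run_stability(prepped, y, plan, lasso_cfg)
                models = refit_all_subsets(
                    prepped, y, stab,
                    dr_threshold=config.dr_threshold,
                    variance_method=config.variance_method,
                )

                cell_dir = out / name
                cell_dir.mkdir(exist_ok=True)
                _io.write_json(report, cell_dir / "preprocess_report.json")
                _io.write_json(stab.to_dict(), cell_dir / "stability.json")
                _io.write_json({s: m.to_dict() for s, m in models.items()}, cell_dir / "refit.json")

                eff = stab.effects_table()
                eff.insert(0, "organ", organ)
                eff.insert(1, "stage", stage)
                eff.insert(2, "scale", scale)
                effects_frames.append(eff)
                sh = shares_table(models)
                sh.insert(0, "organ", organ)
                sh.insert(1, "stage", stage)
                sh.insert(2, "scale", scale)
                shares_frames.append(sh)

                manifest["models"][name] = {
                    "n_samples": prepped.n_samples,
                    "n_metabolites": prepped.n_metabolites,
                    "removed_metabolites": report["removed_metabolites"],
                    "split_seed": split_seed,
                    "summary": stab.summary,
                    "dr_selected": models["all"].features,
                    "refit_adj_r2": {s: m.adj_r2 for s, m in models.items()},
                    "refit_overall_p": {s: m.overall_p for s, m in models.items()},
                }

    pd.concat(effects_frames, ignore_index=True).to_csv(out / "effects.tsv", sep="\t", index=False)
    pd.concat(shares_frames, ignore_index=True).to_csv(out / "variance_shares.tsv", sep="\t", index=False)
    import metabyield

    manifest["version"] = metabyield.__version__
    _io.write_json(manifest, out / "manifest.json")
    return manifest
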