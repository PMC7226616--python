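"""Repeated train/validation resampling around the LASSO: the stability engine.

100 random 75/25 train–validation splits by default. Per run: standardize
within the training rows only, pick the penalty by inner 5-fold CV, fit,
record training R², Adj-R² and RMSE, the validation predictive ability
(squared Pearson correlation between predicted and observed yield), and
which metabolites carry a nonzero coefficient. Across runs, each
metabolite's *detection rate* — the fraction of runs in which it was
selected — is the importance statistic, and its effect is averaged both
over all runs (zero-inclusive) and over selecting runs only.

A literal 20×5-fold mode (80/20 splits) is available behind
``make_splits(..., mode="kfold")`` for comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lasso as _lasso
from .containers import MetabolomeMatrix, rng_for
from .preprocess import log2_transform

logger = logging.getLogger(__name__)

DEFAULT_N_RUNS = 100
DEFAULT_TRAIN_FRACTION = 0.75


@dataclass
class LassoConfig:
    """Knobs of the per-run penalized fit and its inner CV selection."""

    n_grid: int = 100
    eps: float = 1e-3
    inner_folds: int = 5
    rule: str = "min"
    tol: float = 1e-8
    cv_tol: float | None = None  # looser tolerance for CV-scoring path fits
    max_iter: int = 100_000
    fixed_lambda: float | None = None  # skip inner CV and fit at this penalty


@dataclass
class SplitPlan:
    n_runs: int
    train_fraction: float
    seed: int
    assignments: list[np.ndarray]  # per run, training row indices
    n_samples: int

    def validation(self, run: int) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_samples), self.assignments[run], assume_unique=True)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "n_samples": self.n_samples,
            "assignments": [a.tolist() for a in self.assignments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitPlan":
        return cls(
            n_runs=d["n_runs"],
            train_fraction=d["train_fraction"],
            seed=d["seed"],
            n_samples=d["n_samples"],
            assignments=[np.asarray(a, int) for a in d["assignments"]],
        )


def make_splits(
    n_samples: int,
    n_runs: int = DEFAULT_N_RUNS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    stratify_by: np.ndarray | pd.Series | None = None,
    mode: str = "subsample",
) -> SplitPlan:
    """Draw the training row sets for every resampling run.

    ``mode="subsample"`` (default): independent uniform random subsets of
    round(train_fraction*n) rows per run. ``mode="kfold"``: ceil(n_runs/k)
    repetitions of k-fold partitions with k = round(1/(1-train_fraction)),
    each run training on all-but-one fold. Optional stratification keeps the
    per-level proportions of a design column in every training set.
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples to resample")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = rng_for(seed, "splits")
    n_train = int(round(train_fraction * n_samples))
    assignments: list[np.ndarray] = []

    if mode == "kfold":
        k = int(round(1.0 / (1.0 - train_fraction)))
        reps = math.ceil(n_runs / k)
        for _ in range(reps):
            perm = rng.permutation(n_samples)
            folds = np.array_split(perm, k)
            for f in folds:
                assignments.append(np.sort(np.setdiff1d(perm, f, assume_unique=True)))
        assignments = assignments[:n_runs]
    elif mode == "subsample":
        if stratify_by is None:
            for _ in range(n_runs):
                assignments.append(np.sort(rng.choice(n_samples, size=n_train, replace=False)))
        else:
            strata = np.asarray(stratify_by)
            levels = pd.unique(strata)
            level_idx = [np.flatnonzero(strata == lv) for lv in levels]
            targets = np.array([train_fraction * len(ix) for ix in level_idx])
            base = np.floor(targets).astype(int)
            for _ in range(n_runs):
                counts = base.copy()
                short = n_train - counts.sum()
                if short > 0:
                    # distribute the remainder by largest fractional part, rng-tiebroken
                    frac = targets - base
                    order = np.lexsort((rng.random(len(levels)), -frac))
                    counts[order[:short]] += 1
                take = [rng.choice(ix, size=c, replace=False) for ix, c in zip(level_idx, counts)]
                assignments.append(np.sort(np.concatenate(take)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SplitPlan(
        n_runs=len(assignments),
        train_fraction=train_fraction,
        seed=seed,
        assignments=assignments,
        n_samples=n_samples,
    )


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 − (1 − R²)(n − 1)/(n − p − 1); NaN when n ≤ p + 1 (undefined)."""
    if n <= p + 1:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class RunMetrics:
    r2_train: float
    adj_r2_train: float
    rmse_train: float
    predictive_ability: float
    n_selected: int
    lam: float
    converged: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class StabilityResult:
    metabolite_ids: list[str]
    per_run: list[RunMetrics]
    detection_rate: np.ndarray
    mean_effect: np.ndarray  # zero-inclusive average coefficient
    mean_effect_selected: np.ndarray  # average over selecting runs only (NaN if never)
    summary: dict[str, float]
    scale: str = "raw"

    def effects_table(self) -> pd.DataFrame:
        """Per-metabolite effect/DR table, sorted by descending detection rate."""
        df = pd.DataFrame(
            {
                "metabolite": self.metabolite_ids,
                "detection_rate": self.detection_rate,
                "mean_effect": self.mean_effect,
                "mean_effect_selected": self.mean_effect_selected,
            }
        )
        return df.sort_values(
            ["detection_rate", "mean_effect"], ascending=[False, False], key=lambda s: s.abs() if s.name == "mean_effect" else s
        ).reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "metabolite_ids": self.metabolite_ids,
            "scale": self.scale,
            "detection_rate": self.detection_rate.tolist(),
            "mean_effect": self.mean_effect.tolist(),
            "mean_effect_selected": [None if np.isnan(v) else v for v in self.mean_effect_selected],
            "summary": self.summary,
            "per_run": [m.to_dict() for m in self.per_run],
        }


def predictive_ability(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation between predicted and observed values;
    0 when either side is constant (no usable prediction)."""
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        return 0.0
    r = np.corrcoef(y_obs, y_pred)[0, 1]
    return float(r * r)


def run_stability(
    matrix: MetabolomeMatrix,
    y: np.ndarray | pd.Series,
    split_plan: SplitPlan,
    lasso_config: LassoConfig | None = None,
) -> StabilityResult:
    """Run the full resampling loop and aggregate detection rates and effects.

    The matrix must be complete (post filter + imputation). Standardization
    happens inside :func:`metabyield.lasso.fit_lasso` on the training rows of
    each run only; validation rows are scored with the de-standardized
    coefficients, so no information leaks from validation into training.
    Columns with zero variance inside a training set are dropped for that run
    (they count as not selected).
    """
    if lasso_config is None:
        lasso_config = LassoConfig()
    if not matrix.is_complete():
        raise ValueError("run_stability requires a complete (imputed) matrix")
    x_all = matrix.values.to_numpy(dtype=float)
    y = np.asarray(y, float)
    if len(y) != matrix.n_samples:
        raise ValueError("y length does not match matrix rows")
    if split_plan.n_samples != matrix.n_samples:
        raise ValueError("split plan was built for a different sample count")
    p = matrix.n_metabolites
    n_runs = split_plan.n_runs

    selected = np.zeros((n_runs, p), dtype=bool)
    effects = np.zeros((n_runs, p))
    per_run: list[RunMetrics] = []

    for run in range(n_runs):
        tr = split_plan.assignments[run]
        va = split_plan.validation(run)
        x_tr, y_tr = x_all[tr], y[tr]
        live = x_tr.std(axis=0) > 0
        if not live.all():
            logger.warning("run %d: dropping %d zero-variance columns", run, int((~live).sum()))
        if not live.any():
            # degenerate: nothing to fit; intercept-only null model
            ybar = float(y_tr.mean())
            resid = y_tr - ybar
            per_run.append(
                RunMetrics(
                    r2_train=0.0,
                    adj_r2_train=0.0,
                    rmse_train=float(np.sqrt(resid @ resid / len(tr))),
                    predictive_ability=0.0,
                    n_selected=0,
                    lam=float("nan"),
                    converged=True,
                )
            )
            continue
        if lasso_config.fixed_lambda is not None:
            lam = lasso_config.fixed_lambda
            fit = _lasso.fit_lasso(
                x_tr[:, live], y_tr, lam, tol=lasso_config.tol, max_iter=lasso_config.max_iter
            )
        else:
            lam, fit = _lasso.select_lambda_cv(
                x_tr[:, live],
                y_tr,
                n_grid=lasso_config.n_grid,
                eps=lasso_config.eps,
                inner_folds=lasso_config.inner_folds,
                rule=lasso_config.rule,
                seed=rng_for(split_plan.seed, "run", run).integers(2**31),
                tol=lasso_config.tol,
                cv_tol=lasso_config.cv_tol,
                max_iter=lasso_config.max_iter,
            )
        beta_full = np.zeros(p)
        beta_full[live] = fit.beta
        sel = beta_full != 0.0
        selected[run] = sel
        effects[run] = beta_full

        pred_tr = fit.intercept + x_tr[:, live] @ fit.beta
        resid = y_tr - pred_tr
        sst = float(((y_tr - y_tr.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
        n_sel = int(sel.sum())
        metrics = RunMetrics(
            r2_train=r2,
            adj_r2_train=adjusted_r2(r2, len(tr), n_sel),
            rmse_train=float(np.sqrt(resid @ resid / len(tr))),
            predictive_ability=predictive_ability(y[va], fit.intercept + x_all[np.ix_(va, np.flatnonzero(live))] @ fit.beta),
            n_selected=n_sel,
            lam=lam,
            converged=fit.converged,
        )
        per_run.append(metrics)

    detection_rate = selected.mean(axis=0)
    mean_effect = effects.mean(axis=0)
    with np.errstate(invalid="ignore"):
        counts = selected.sum(axis=0)
        mean_sel = np.where(counts > 0, effects.sum(axis=0) / np.maximum(counts, 1), np.nan)
    summary = {
        k: float(np.nanmean([getattr(m, k) for m in per_run]))
        for k in ("r2_train", "adj_r2_train", "rmse_train", "predictive_ability", "n_selected")
    }
    return StabilityResult(
        metabolite_ids=matrix.metabolite_ids,
        per_run=per_run,
        detection_rate=detection_rate,
        mean_effect=mean_effect,
        mean_effect_selected=mean_sel,
        summary=summary,
        scale=matrix.scale,
    )


def compare_scales(
    matrix_raw: MetabolomeMatrix,
    y: np.ndarray | pd.Series,
    split_plan: SplitPlan,
    lasso_config: LassoConfig | None = None,
) -> tuple[str, dict[str, StabilityResult]]:
    """Run the stability engine on raw and log2 intensities with the same
    split plan; recommend the scale with higher mean predictive ability
    (ties broken toward raw, with a warning)."""
    if matrix_raw.scale != "raw":
        raise ValueError("compare_scales expects a raw-scale matrix")
    res_raw = run_stability(matrix_raw, y, split_plan, lasso_config)
    res_log2 = run_stability(log2_transform(matrix_raw), y, split_plan, lasso_config)
    pa_raw = res_raw.summary["predictive_ability"]
    pa_log2 = res_log2.summary["predictive_ability"]
    if pa_log2 > pa_raw:
        recommended = "log2"
    else:
        if pa_log2 == pa_raw:
            logger.warning("raw and log2 scales tie on predictive ability; recommending raw")
        recommended = "raw"
    return recommended, {"raw": res_raw, "log2": res_log2}
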