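"""Data preparation: missingness filter, KNN imputation, log2, standardization.

The chain mirrors common GC-MS practice: metabolites with more than 10% of
cells missing over all samples are removed (strictly greater — exactly 10%
is kept); the remaining gaps are filled by a Troyanskaya-style K-nearest-
neighbour imputation; models may then run on raw or log2 intensities.

KNN distance is Euclidean over the metabolites observed in *both* samples,
with each metabolite standardized to unit variance on its observed values
and the squared distance rescaled by the number of shared observed columns
(so samples with different missingness patterns are comparable). Imputed
values are inverse-distance-weighted means of the neighbours' observed raw
values; observed cells are never touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MetabolomeMatrix

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISSING_FRAC = 0.10
DEFAULT_K = 10  # DMwR's documented knnImputation default
_DIST_EPS = 1e-9  # keeps inverse-distance weights finite for duplicate samples


@dataclass
class PreprocessReport:
    removed_metabolites: list[str] = field(default_factory=list)
    retained_metabolites: list[str] = field(default_factory=list)
    imputed_cell_count: int = 0
    k_used: int | None = None
    scale_out: str = "raw"
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed_metabolites": self.removed_metabolites,
            "retained_metabolites": self.retained_metabolites,
            "imputed_cell_count": self.imputed_cell_count,
            "k_used": self.k_used,
            "scale_out": self.scale_out,
            "warnings": self.warnings,
        }


def filter_by_missingness(
    matrix: MetabolomeMatrix, max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC
) -> tuple[MetabolomeMatrix, PreprocessReport]:
    """Drop metabolites whose missing fraction exceeds ``max_missing_frac``.

    The comparison is strict: a column at exactly the threshold is retained.
    """
    if not (0.0 <= max_missing_frac < 1.0):
        raise ValueError("max_missing_frac must lie in [0, 1)")
    if matrix.n_samples == 0 or matrix.n_metabolites == 0:
        raise ValueError("cannot filter an empty matrix")
    frac = matrix.missing_fraction()
    keep = frac <= max_missing_frac
    removed = [m for m, k in keep.items() if not k]
    report = PreprocessReport(
        removed_metabolites=removed,
        retained_metabolites=[m for m, k in keep.items() if k],
        scale_out=matrix.scale,
    )
    if removed:
        logger.info("missingness filter removed %d/%d metabolites", len(removed), len(frac))
    return matrix.subset_columns(report.retained_metabolites), report


def knn_impute(matrix: MetabolomeMatrix, k: int = DEFAULT_K) -> tuple[MetabolomeMatrix, PreprocessReport]:
    """Fill masked cells from the k nearest samples (see module docstring).

    Falls back, with a logged warning, to all available neighbours when fewer
    than k candidates observe a cell's metabolite, and to the column median
    when no sample observes it alongside the target.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = matrix.values.to_numpy(dtype=float).copy()
    mask = matrix.mask.to_numpy()
    n, p = vals.shape
    report = PreprocessReport(
        retained_metabolites=matrix.metabolite_ids, k_used=k, scale_out=matrix.scale
    )
    if not mask.any():
        out = matrix.copy()
        return out, report
    if (mask.all(axis=1)).any():
        bad = int(np.where(mask.all(axis=1))[0][0])
        raise ValueError(f"sample {matrix.sample_ids[bad]!r} has no observed values")

    obs = ~mask
    # unit-variance standardization on observed values, for distances only
    col_mean = np.array([vals[obs[:, j], j].mean() for j in range(p)])
    col_sd = np.array([vals[obs[:, j], j].std(ddof=1) if obs[:, j].sum() > 1 else 0.0 for j in range(p)])
    col_sd_safe = np.where(col_sd > 0, col_sd, 1.0)
    z = (vals - col_mean) / col_sd_safe
    z[mask] = 0.0

    # pairwise shared-column-rescaled squared distances
    zsq = z**2
    obs_f = obs.astype(float)
    shared = obs_f @ obs_f.T  # counts of mutually observed metabolites
    # sum over shared j of (z_i - z_l)^2, using masked-zero z
    cross = z @ z.T
    sq_i = zsq @ obs_f.T
    sq_l = obs_f @ zsq.T
    d2 = sq_i + sq_l - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(d2, 0.0) / shared)
    d[shared == 0] = np.inf
    np.fill_diagonal(d, np.inf)

    filled = vals.copy()
    imputed = 0
    fell_back_all = False
    for i in range(n):
        missing_j = np.where(mask[i])[0]
        if missing_j.size == 0:
            continue
        order = np.argsort(d[i], kind="stable")
        for j in missing_j:
            candidates = order[obs[order, j] & np.isfinite(d[i, order])]
            if candidates.size == 0:
                med = np.median(vals[obs[:, j], j])
                filled[i, j] = med
                msg = (
                    f"no neighbour observes metabolite {matrix.metabolite_ids[j]!r} for "
                    f"sample {matrix.sample_ids[i]!r}; column-median fallback"
                )
                logger.warning(msg)
                report.warnings.append(msg)
            else:
                if candidates.size < k and not fell_back_all:
                    fell_back_all = True
                    msg = f"fewer than k={k} candidate neighbours available; using all"
                    logger.warning(msg)
                    report.warnings.append(msg)
                nb = candidates[:k]
                w = 1.0 / (d[i, nb] + _DIST_EPS)
                filled[i, j] = float(np.dot(w, vals[nb, j]) / w.sum())
            imputed += 1
    report.imputed_cell_count = imputed
    values = pd.DataFrame(filled, index=matrix.values.index, columns=matrix.values.columns)
    empty_mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return (
        MetabolomeMatrix(design=matrix.design, values=values, mask=empty_mask, scale=matrix.scale),
        report,
    )


def mean_impute(matrix: MetabolomeMatrix) -> MetabolomeMatrix:
    """Column-mean imputation baseline (used as the comparison oracle)."""
    vals = matrix.values.to_numpy(dtype=float).copy()
    mask = matrix.mask.to_numpy()
    for j in range(vals.shape[1]):
        if mask[:, j].any():
            vals[mask[:, j], j] = vals[~mask[:, j], j].mean()
    values = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    empty = pd.DataFrame(False, index=values.index, columns=values.columns)
    return MetabolomeMatrix(design=matrix.design, values=values, mask=empty, scale=matrix.scale)


def log2_transform(matrix: MetabolomeMatrix) -> MetabolomeMatrix:
    """Elementwise log2; requires a complete raw-scale matrix of positives."""
    if matrix.scale != "raw":
        raise ValueError(f"log2_transform expects raw scale, got {matrix.scale!r}")
    vals = matrix.values.to_numpy(dtype=float)
    bad = np.argwhere(vals <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"nonpositive intensity at sample {matrix.sample_ids[i]!r}, "
            f"metabolite {matrix.metabolite_ids[j]!r}: {vals[i, j]!r}"
        )
    return matrix.with_scale(
        pd.DataFrame(np.log2(vals), index=matrix.values.index, columns=matrix.values.columns),
        scale="log2",
    )


@dataclass
class Scaler:
    """Per-column (center, scale) record; sd uses the n−1 denominator."""

    center: np.ndarray
    scale: np.ndarray
    columns: list[str]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.center) / self.scale

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, float) * self.scale + self.center

    def destandardize_coef(self, beta_std: np.ndarray, intercept_std: float) -> tuple[np.ndarray, float]:
        """Map coefficients fit on standardized columns back to the original
        columns: beta = beta_std/scale, b0 = b0_std − center·beta."""
        beta = np.asarray(beta_std, float) / self.scale
        return beta, float(intercept_std - self.center @ beta)


def standardize(matrix: MetabolomeMatrix) -> tuple[MetabolomeMatrix, Scaler]:
    """Center and scale each metabolite to mean 0, sd 1 (ddof=1)."""
    if not matrix.is_complete():
        raise ValueError("standardize requires a complete matrix")
    vals = matrix.values.to_numpy(dtype=float)
    center = vals.mean(axis=0)
    scale = vals.std(axis=0, ddof=1)
    zero = np.where(scale == 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance column {matrix.metabolite_ids[int(zero[0])]!r}")
    scaler = Scaler(center=center, scale=scale, columns=matrix.metabolite_ids)
    z = pd.DataFrame((vals - center) / scale, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_scale(z, scale=matrix.scale), scaler
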