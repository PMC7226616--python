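"""Agronomic and isotope formulas, spectral indices, and per-metabolite
association statistics.

Small exact formulas: δ13C per-mil notation, grain nitrogen yield
(GY × grain %N), harvest index (GY/biomass), thousand-kernel weight, and
generic normalized-difference reflectance indices (NDWI/NWI/NDMI wrappers
with configurable band pairs — the band choice is a configuration of the
instrument, not a constant of the method).

Association statistics: Pearson (or Spearman) metabolite–trait correlations
with Benjamini–Hochberg q-values, and per-metabolite fixed-effects factorial
ANOVA (main effects + two-way interactions, Type-II sums of squares) across
the design factors, BH-adjusted across metabolites within each term.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .containers import MetabolomeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# exact formulas


def delta_notation(ratio_sample: float, ratio_standard: float):
    """Stable-isotope composition in per-mil: (R_sample/R_standard − 1)·1000."""
    ratio_sample = np.asarray(ratio_sample, float)
    ratio_standard = np.asarray(ratio_standard, float)
    if np.any(ratio_sample <= 0) or np.any(ratio_standard <= 0):
        raise ValueError("isotope ratios must be > 0")
    return (ratio_sample / ratio_standard - 1.0) * 1000.0


def derived_traits(plot_records: pd.DataFrame) -> pd.DataFrame:
    """Append GNY, HI and TKW to a per-plot trait table.

    GNY = GY · (%N/100) (same area units as GY); HI = GY/biomass;
    TKW = 1000 · grain mass / grain count (grams per thousand kernels).
    Zero denominators yield NaN (flagged missing), not exceptions.
    """
    required = {"GY", "biomass", "grain_pctN", "grain_count", "grain_mass_g"}
    missing = required - set(plot_records.columns)
    if missing:
        raise ValueError(f"trait table lacks columns: {sorted(missing)}")
    out = plot_records.copy()
    out["GNY"] = out["GY"] * out["grain_pctN"] / 100.0
    biomass = out["biomass"].to_numpy(dtype=float)
    count = out["grain_count"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["HI"] = np.where(biomass != 0, out["GY"].to_numpy(float) / biomass, np.nan)
        out["TKW"] = np.where(count != 0, 1000.0 * out["grain_mass_g"].to_numpy(float) / count, np.nan)
    return out


def normalized_difference(reflectance_a, reflectance_b):
    """(a − b)/(a + b) ∈ [−1, 1]; NaN when a + b = 0."""
    a = np.asarray(reflectance_a, float)
    b = np.asarray(reflectance_b, float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("reflectances must be >= 0")
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (a - b) / np.where(denom != 0, denom, 1.0), np.nan)
    return out if out.shape else float(out)


# band-pair defaults follow the common literature conventions for each index;
# override per instrument as needed
SPECTRAL_INDEX_BANDS: dict[str, tuple[int, int]] = {
    "NDWI": (860, 1240),
    "NWI": (970, 900),
    "NDMI": (860, 1640),
}


def spectral_index(name: str, reflectance: dict[int, np.ndarray], bands: tuple[int, int] | None = None):
    """Named normalized-difference index over a {wavelength_nm: reflectance}
    mapping; the band pair is configurable."""
    if bands is None:
        try:
            bands = SPECTRAL_INDEX_BANDS[name]
        except KeyError:
            raise ValueError(f"unknown index {name!r}; provide bands explicitly") from None
    a, b = bands
    if a not in reflectance or b not in reflectance:
        raise ValueError(f"reflectance table lacks band {a if a not in reflectance else b} nm")
    return normalized_difference(reflectance[a], reflectance[b])


# ---------------------------------------------------------------------------
# association statistics


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up q-values (NaN-safe: NaN p-values get NaN q-values)."""
    p = np.asarray(pvalues, float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def metabolite_trait_correlations(
    matrix: MetabolomeMatrix,
    trait_table: pd.DataFrame,
    traits: list[str] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per metabolite × trait: correlation r, two-sided p (t approximation),
    and BH q across all pairs. Constant columns give NaN r (flagged missing).
    """
    if not matrix.is_complete():
        raise ValueError("correlations require a complete matrix")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    tt = trait_table.set_index("sample_id") if "sample_id" in trait_table.columns else trait_table
    tt = tt.loc[matrix.sample_ids]
    if traits is None:
        traits = [c for c in tt.columns if pd.api.types.is_numeric_dtype(tt[c])]
    n = matrix.n_samples
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    x = matrix.values.to_numpy(dtype=float)
    if method == "spearman":
        x = scipy.stats.rankdata(x, axis=0)
    rows = []
    for trait in traits:
        t = tt[trait].to_numpy(dtype=float)
        tv = scipy.stats.rankdata(t) if method == "spearman" else t
        t_sd = tv.std(ddof=0)
        x_sd = x.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = ((x - x.mean(axis=0)) * (tv - tv.mean())[:, None]).mean(axis=0) / (x_sd * t_sd)
        r[x_sd == 0] = np.nan
        if t_sd == 0:
            r[:] = np.nan
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
        pvals = 2.0 * scipy.stats.t.sf(np.abs(tstat), df=n - 2)
        pvals[np.isnan(r)] = np.nan
        for j, m in enumerate(matrix.metabolite_ids):
            rows.append({"metabolite": m, "trait": trait, "r": r[j], "p": pvals[j]})
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def factorial_anova(
    matrix: MetabolomeMatrix,
    design: pd.DataFrame | None = None,
    factors: list[str] = ("organ", "condition", "genotype", "stage"),
) -> pd.DataFrame:
    """Per-metabolite fixed-effects ANOVA over the design factors.

    Model: intensity ~ all main effects + all two-way interactions among the
    usable factors (a factor with a single level is dropped with a warning).
    Type-II sums of squares; F and p per term; BH q across metabolites
    within each term.
    """
    if not matrix.is_complete():
        raise ValueError("ANOVA requires a complete matrix")
    design = matrix.design if design is None else design
    usable = []
    for f in factors:
        if f not in design.columns:
            raise ValueError(f"unknown design factor {f!r}")
        if design[f].nunique() < 2:
            logger.warning("factor %r has a single level; term dropped", f)
        else:
            usable.append(f)
    if not usable:
        raise ValueError("no factor has >= 2 levels")
    terms = [f"C({f})" for f in usable] + [f"C({a}):C({b})" for a, b in combinations(usable, 2)]
    formula_rhs = " + ".join(terms)
    df = design[usable].copy().reset_index(drop=True)
    rows = []
    for m in matrix.metabolite_ids:
        df["_y"] = matrix.values[m].to_numpy(dtype=float)
        fit = smf.ols(f"_y ~ {formula_rhs}", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        for term in table.index:
            if term == "Residual":
                continue
            rows.append(
                {
                    "metabolite": m,
                    "term": term.replace("C(", "").replace(")", ""),
                    "F": float(table.loc[term, "F"]),
                    "p": float(table.loc[term, "PR(>F)"]),
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for term in out["term"].unique():
        sel = out["term"] == term
        out.loc[sel, "q"] = benjamini_hochberg(out.loc[sel, "p"].to_numpy())
    return out
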