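"""Synthetic factorial metabolome + trait generator with known ground truth.

The study design this emulates: durum wheat grown under two contrasting
water regimes (water stress, WS, and high-yielding, HY), 5 genotypes ×
4 trials × 3 replicates = 60 plots, sampled in three organs (flag leaf,
glume, lemma) at two stages (anthesis, grain filling) — 360 organ samples
in all — and profiled by GC-MS as relative ion intensities.

Intensities are simulated on the log2 scale as

    x_ij = baseline_j + organ/stage/condition/genotype effects + sigma * e_ij

where e has block-exchangeable correlation ``block_rho`` within metabolite
"pathway" blocks, then exponentiated (raw = 2**x), so all raw intensities
are strictly positive and biological effects are multiplicative on the raw
scale. Grain yield is generated as a sparse linear function of the log2
intensities plus an optional additive WS penalty and Gaussian noise; the
generator records the hidden coefficients, so recovery by the downstream
LASSO stability pipeline can be scored exactly.

Missing values are injected MCAR by default (each cell of metabolite j
masked independently with probability rates[j]); an intensity-dependent
left-censoring mode is available because GC-MS missingness is often
abundance-related.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CONDITIONS,
    DESIGN_COLUMNS,
    ORGANS,
    STAGES,
    GroundTruth,
    MetabolomeMatrix,
    rng_for,
)

logger = logging.getLogger(__name__)

# Defaults chosen to mirror the study's factorial layout and a typical
# annotated GC-MS panel: ~80 metabolites in ~10 pathway blocks with moderate
# within-block correlation, WS baseline yields ~2.4 t/ha below HY (a ~37%
# reduction from a ~6.5 t/ha intercept).
DEFAULT_N_METABOLITES = 80
DEFAULT_N_BLOCKS = 10
DEFAULT_BLOCK_RHO = 0.5
DEFAULT_INTENSITY_SD = 1.0
DEFAULT_YIELD_INTERCEPT = 6.5
DEFAULT_CONDITION_SHIFT = -2.4


def build_design(
    n_genotypes: int = 5,
    n_trials: int = 4,
    n_replicates: int = 3,
    organs=ORGANS,
    stages=STAGES,
) -> pd.DataFrame:
    """Full-factorial sample design in deterministic (organ, stage, trial,
    genotype, replicate) order.

    Condition is a trial attribute: the first half of the trials are WS,
    the rest HY (two of each under the default four trials).
    """
    if min(n_genotypes, n_trials, n_replicates) < 1 or not organs or not stages:
        raise ValueError("all design counts must be >= 1 and factor lists non-empty")
    for o in organs:
        if o not in ORGANS:
            raise ValueError(f"unknown organ {o!r}; expected one of {ORGANS}")
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; expected one of {STAGES}")
    n_ws = n_trials // 2 if n_trials > 1 else 1
    rows = []
    for organ in organs:
        for stage in stages:
            for t in range(n_trials):
                condition = "WS" if t < n_ws else "HY"
                trial = f"T{t + 1}"
                for g in range(n_genotypes):
                    genotype = f"G{g + 1}"
                    for r in range(1, n_replicates + 1):
                        rows.append(
                            {
                                "sample_id": f"{organ}.{stage}.{trial}.{genotype}.R{r}",
                                "organ": organ,
                                "stage": stage,
                                "condition": condition,
                                "genotype": genotype,
                                "trial": trial,
                                "replicate": r,
                            }
                        )
    return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))


@dataclass
class EffectTemplates:
    """Additive log2-scale effects per design factor.

    Each mapping sends a factor level to a length-p vector of log2 shifts;
    absent levels contribute zero. Dimensions are validated against the
    requested metabolite count at simulation time.
    """

    organ: dict[str, np.ndarray] = field(default_factory=dict)
    stage: dict[str, np.ndarray] = field(default_factory=dict)
    condition: dict[str, np.ndarray] = field(default_factory=dict)
    genotype: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self, p: int) -> None:
        for factor in ("organ", "stage", "condition", "genotype"):
            for level, vec in getattr(self, factor).items():
                if np.asarray(vec).shape != (p,):
                    raise ValueError(
                        f"effect template {factor}={level!r} has shape "
                        f"{np.asarray(vec).shape}, expected ({p},)"
                    )


def default_effect_templates(design: pd.DataFrame, p: int, seed: int) -> EffectTemplates:
    """Realistic factor shifts: organs differ most, then condition and stage,
    genotypes least; only a subset of metabolites responds to each factor."""
    rng = rng_for(seed, "effect_templates")

    def draw(levels, sd, frac_responsive):
        out = {}
        for lv in levels:
            responsive = rng.random(p) < frac_responsive
            out[lv] = np.where(responsive, rng.normal(0.0, sd, p), 0.0)
        return out

    return EffectTemplates(
        organ=draw(sorted(design["organ"].unique()), sd=1.0, frac_responsive=0.6),
        stage=draw(sorted(design["stage"].unique()), sd=0.6, frac_responsive=0.5),
        condition=draw(sorted(design["condition"].unique()), sd=0.7, frac_responsive=0.4),
        genotype=draw(sorted(design["genotype"].unique()), sd=0.3, frac_responsive=0.3),
    )


def _make_ground_truth(
    p: int,
    n_blocks: int,
    n_true_effects: int,
    rng: np.random.Generator,
    base_missing_rate: float,
    high_missing_frac: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block assignment, sparse beta (unscaled), per-metabolite missing rates.

    Nonzero effects are spread across blocks (evenly spaced indices) so the
    true predictors are not mutually redundant within one correlated block.
    """
    block_assignment = np.arange(p) % n_blocks
    true_beta = np.zeros(p)
    if n_true_effects > 0:
        if n_true_effects <= n_blocks:
            # spread over distinct blocks: block of index i is i % n_blocks
            step = p / n_true_effects
            idx = np.array(
                [min(int(k * step) - int(k * step) % n_blocks + k, p - 1) for k in range(n_true_effects)]
            )
        else:
            idx = np.linspace(0, p - 1, n_true_effects).round().astype(int)
        signs = rng.choice([-1.0, 1.0], size=n_true_effects)
        # equal magnitudes: the sparsity level and target R² define the per-
        # effect strength; unequal magnitudes would make "s effects" ambiguous
        true_beta[idx] = signs * 1.0
    missing_rates = rng.uniform(0.0, base_missing_rate, size=p)
    n_high = int(round(high_missing_frac * p))
    if n_high > 0:
        high_idx = rng.choice(p, size=n_high, replace=False)
        missing_rates[high_idx] = rng.uniform(0.12, 0.30, size=n_high)
    return block_assignment, true_beta, missing_rates


def simulate_metabolome(
    design: pd.DataFrame,
    n_metabolites: int = DEFAULT_N_METABOLITES,
    n_blocks: int = DEFAULT_N_BLOCKS,
    block_rho: float = DEFAULT_BLOCK_RHO,
    effect_templates: EffectTemplates | None = None,
    seed: int = 0,
    *,
    n_true_effects: int = 10,
    target_r2: float | None = 0.7,
    noise_sd: float = 1.0,
    condition_shift: float = DEFAULT_CONDITION_SHIFT,
    intercept: float = DEFAULT_YIELD_INTERCEPT,
    intensity_sd: float = DEFAULT_INTENSITY_SD,
    base_missing_rate: float = 0.08,
    high_missing_frac: float = 0.05,
) -> tuple[MetabolomeMatrix, GroundTruth]:
    """Simulate a complete raw-scale intensity matrix plus its ground truth.

    Parameters
    ----------
    block_rho
        Exchangeable correlation of the log2 residuals within each pathway
        block (0 <= rho < 1).
    n_true_effects, target_r2, noise_sd
        Sparsity of the hidden metabolite→yield coefficient vector and the
        signal fraction it should carry. When ``target_r2`` is given, the
        yield noise SD is solved from the realized signal variance so that
        var(signal)/var(GY) ≈ target_r2; otherwise ``noise_sd`` is used
        as-is (the only option under a pure null, where signal variance is 0).
    intensity_sd
        Within-plot residual SD of log2 intensities (the replicate-level
        variation; exposed rather than fixed because it is design-specific).
    """
    if not (n_metabolites >= n_blocks >= 1):
        raise ValueError("need n_metabolites >= n_blocks >= 1")
    if not (0.0 <= block_rho < 1.0):
        raise ValueError("block_rho must lie in [0, 1)")
    p = n_metabolites
    n = len(design)
    if effect_templates is None:
        effect_templates = EffectTemplates()  # pure block-correlation structure
    effect_templates.validate(p)

    rng = rng_for(seed, "metabolome")
    block_assignment, true_beta_shape, missing_rates = _make_ground_truth(
        p, n_blocks, n_true_effects, rng, base_missing_rate, high_missing_frac
    )

    baseline = rng.uniform(8.0, 18.0, size=p)  # typical log2 relative-intensity range

    # block-exchangeable residuals: e_j = sqrt(rho)*u_block(j) + sqrt(1-rho)*z_j
    u = rng.standard_normal((n, n_blocks))
    z = rng.standard_normal((n, p))
    resid = np.sqrt(block_rho) * u[:, block_assignment] + np.sqrt(1.0 - block_rho) * z

    log2 = np.tile(baseline, (n, 1)) + intensity_sd * resid
    for factor in ("organ", "stage", "condition", "genotype"):
        templates = getattr(effect_templates, factor)
        for level, vec in templates.items():
            rows = (design[factor] == level).to_numpy()
            log2[rows] += np.asarray(vec, float)

    # scale the yield noise so the sparse linear signal carries target_r2
    ws = (design["condition"] == "WS").to_numpy().astype(float)
    signal = log2 @ true_beta_shape + condition_shift * ws
    var_signal = float(np.var(signal))
    if target_r2 is not None and var_signal > 0:
        if not (0.0 < target_r2 < 1.0):
            raise ValueError("target_r2 must lie in (0, 1)")
        noise_sd = float(np.sqrt(var_signal * (1.0 - target_r2) / target_r2))

    values = pd.DataFrame(
        np.exp2(log2),
        index=pd.Index(design["sample_id"], name="sample_id"),
        columns=[f"M{j + 1:03d}" for j in range(p)],
    )
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    matrix = MetabolomeMatrix(design=design, values=values, mask=mask, scale="raw")
    truth = GroundTruth(
        metabolite_ids=list(values.columns),
        true_beta=true_beta_shape,
        intercept=intercept,
        noise_sd=noise_sd,
        condition_shift=condition_shift,
        missing_rates=missing_rates,
        block_assignment=block_assignment,
    )
    return matrix, truth


def simulate_traits(matrix: MetabolomeMatrix, truth: GroundTruth, seed: int = 0) -> pd.DataFrame:
    """Per-sample agronomic traits generated from the (complete) metabolome.

    GY = intercept + log2(intensities)·beta + condition_shift·1[WS] + N(0, sd),
    on a t/ha-like scale. Biomass, grain %N, grain counts and masses are
    generated consistently so the derived-trait formulas (HI, TKW, GNY) have
    realistic inputs. The achieved signal fraction R²_true = var(signal)/var(GY)
    is stored on ``truth.r2_true``.
    """
    if not matrix.is_complete():
        raise ValueError("simulate_traits requires a complete matrix (no masked cells)")
    if len(truth.true_beta) != matrix.n_metabolites:
        raise ValueError("truth.true_beta length does not match matrix columns")
    rng = rng_for(seed, "traits")
    x = matrix.values.to_numpy(dtype=float)
    log2x = x if matrix.scale == "log2" else np.log2(x)
    ws = (matrix.design["condition"] == "WS").to_numpy().astype(float)
    signal = log2x @ truth.true_beta + truth.condition_shift * ws
    noise = rng.normal(0.0, truth.noise_sd, size=len(signal))
    gy = truth.intercept + signal + noise
    var_gy = float(np.var(gy))
    truth.r2_true = float(np.var(signal) / var_gy) if var_gy > 0 else 0.0

    hi = np.clip(rng.normal(0.45, 0.03, len(gy)) - 0.05 * ws, 0.2, 0.7)
    biomass = gy / hi
    pct_n = np.clip(rng.normal(2.0, 0.15, len(gy)) + 0.25 * ws, 1.0, 4.0)
    grain_count = np.clip(rng.normal(500, 50, len(gy)), 200, None).round()
    tkw_true = np.clip(rng.normal(42.0, 4.0, len(gy)) - 6.0 * ws, 15.0, None)
    grain_mass = grain_count * tkw_true / 1000.0  # grams for the counted subsample
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "GY": gy,
            "biomass": biomass,
            "grain_pctN": pct_n,
            "grain_count": grain_count,
            "grain_mass_g": grain_mass,
            "condition": matrix.design["condition"].to_numpy(),
        }
    )


def inject_missing(
    matrix: MetabolomeMatrix,
    missing_rates: np.ndarray,
    seed: int = 0,
    mechanism: str = "mcar",
) -> MetabolomeMatrix:
    """Mask cells per metabolite: MCAR with probability rates[j], or
    left-censored (``mechanism="censored"``: the lowest-rate[j] quantile of
    each metabolite is masked, emulating abundance-dependent GC-MS dropouts).

    The generating values stay in ``values`` under the mask so imputation
    accuracy can be scored; file round-trips drop them.
    """
    rates = np.asarray(missing_rates, dtype=float)
    if rates.shape != (matrix.n_metabolites,):
        raise ValueError("missing_rates must have one entry per metabolite")
    if np.any((rates < 0) | (rates >= 1)):
        raise ValueError("missing_rates must lie in [0, 1)")
    rng = rng_for(seed, "missing")
    vals = matrix.values.to_numpy()
    if mechanism == "mcar":
        mask = rng.random(vals.shape) < rates[None, :]
    elif mechanism == "censored":
        mask = np.zeros(vals.shape, dtype=bool)
        for j, r in enumerate(rates):
            if r > 0:
                cutoff = np.quantile(vals[:, j], r)
                mask[:, j] = vals[:, j] <= cutoff
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    new_mask = pd.DataFrame(mask, index=matrix.values.index, columns=matrix.values.columns)
    return MetabolomeMatrix(design=matrix.design, values=matrix.values, mask=new_mask, scale=matrix.scale)


# ---------------------------------------------------------------------------
# scenario helpers


def simulate_cell(
    seed: int,
    n_genotypes: int = 5,
    n_trials: int = 4,
    n_replicates: int = 3,
    organ: str = "flag_leaf",
    stage: str = "anthesis",
    n_metabolites: int = DEFAULT_N_METABOLITES,
    n_true_effects: int = 10,
    target_r2: float | None = 0.7,
    noise_sd: float = 1.0,
    condition_shift: float = 0.0,
    block_rho: float = DEFAULT_BLOCK_RHO,
    with_missing: bool = False,
    **kwargs,
) -> tuple[MetabolomeMatrix, GroundTruth, pd.DataFrame]:
    """One organ–stage cell (default 60 plots) with traits: the unit entering
    each prediction model. Condition/genotype shifts on the metabolome are on
    by default (the study's structure); the WS yield *penalty* defaults to 0
    so the stated R²_true is carried by metabolite effects alone.
    """
    design = build_design(n_genotypes, n_trials, n_replicates, organs=[organ], stages=[stage])
    if "effect_templates" not in kwargs:
        kwargs["effect_templates"] = default_effect_templates(design, n_metabolites, seed)
    matrix, truth = simulate_metabolome(
        design,
        n_metabolites=n_metabolites,
        seed=seed,
        n_true_effects=n_true_effects,
        target_r2=target_r2,
        noise_sd=noise_sd,
        condition_shift=condition_shift,
        block_rho=block_rho,
        **kwargs,
    )
    traits = simulate_traits(matrix, truth, seed=seed)
    if with_missing:
        matrix = inject_missing(matrix, truth.missing_rates, seed=seed)
    return matrix, truth, traits


def simulate_study(
    seed: int,
    n_metabolites: int = DEFAULT_N_METABOLITES,
    with_missing: bool = True,
    **kwargs,
) -> tuple[MetabolomeMatrix, GroundTruth, pd.DataFrame]:
    """The full 360-sample study: 3 organs × 2 stages × 60 plots, one trait
    row per plot sample, organ/stage/condition/genotype metabolome shifts,
    default WS yield penalty and 10 hidden metabolite yield effects."""
    design = build_design()
    if "effect_templates" not in kwargs:
        kwargs["effect_templates"] = default_effect_templates(design, n_metabolites, seed)
    matrix, truth = simulate_metabolome(design, n_metabolites=n_metabolites, seed=seed, **kwargs)
    traits = simulate_traits(matrix, truth, seed=seed)
    if with_missing:
        matrix = inject_missing(matrix, truth.missing_rates, seed=seed)
    return matrix, truth, traits
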