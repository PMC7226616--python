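"""Core in-memory containers for the yield-prediction pipeline.

The central object is :class:`MetabolomeMatrix`: a plot-level samples ×
metabolites table of relative GC-MS ion intensities with an explicit
missing-value mask and the factorial design annotations (organ, stage,
growing condition, genotype, trial, replicate) attached row-wise.

Intensities live on one of two declared scales, ``raw`` (strictly positive
relative intensities) or ``log2``; the scale is carried as metadata and is
never changed silently.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

ORGANS = ("flag_leaf", "glume", "lemma")
STAGES = ("anthesis", "grain_filling")
CONDITIONS = ("WS", "HY")

#: design-table columns, in canonical order (sample_id is the row identifier)
DESIGN_COLUMNS = ("sample_id", "organ", "stage", "condition", "genotype", "trial", "replicate")


def derive_seed(root_seed: int, name: str, counter: int = 0) -> int:
    """Derive a sub-stream seed < 2**31 from a root seed by stable hashing.

    One root seed governs the whole pipeline; every stochastic stage draws
    its own generator from ``derive_seed(root, stage_name, counter)`` so a
    stage can be re-run in isolation and still reproduce exactly.
    """
    digest = hashlib.sha256(f"{root_seed}:{name}:{counter}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(root_seed: int, name: str, counter: int = 0) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root_seed, name, counter))


@dataclass
class MetabolomeMatrix:
    """Samples × metabolites intensity table with mask and design annotations.

    Parameters
    ----------
    design
        One row per sample, columns :data:`DESIGN_COLUMNS`; ``sample_id``
        must be unique and match ``values.index``.
    values
        Float DataFrame, rows indexed by sample_id, columns by metabolite id.
        Cells under the mask may hold the (hidden) generating value — useful
        for scoring imputation accuracy — or NaN for data read from disk.
    mask
        Boolean DataFrame of the same shape; True marks a missing cell.
    scale
        ``"raw"`` or ``"log2"``.
    """

    design: pd.DataFrame
    values: pd.DataFrame
    mask: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if list(self.values.columns) != list(self.mask.columns) or not self.values.index.equals(
            self.mask.index
        ):
            raise ValueError("values and mask must share index and columns")
        ids = self.design["sample_id"].tolist()
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r} in design")
        if ids != list(self.values.index):
            raise ValueError("design sample_id order must match values index")
        observed = self.values.to_numpy()[~self.mask.to_numpy()]
        if not np.all(np.isfinite(observed)):
            raise ValueError("non-finite value in an observed (unmasked) cell")

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def is_complete(self) -> bool:
        return not bool(self.mask.to_numpy().any())

    def missing_fraction(self) -> pd.Series:
        """Per-metabolite fraction of masked cells."""
        return self.mask.mean(axis=0)

    # -- derived views -------------------------------------------------------
    def observed(self) -> pd.DataFrame:
        """Values with masked cells replaced by NaN (what an analyst sees)."""
        return self.values.mask(self.mask)

    def subset_rows(self, row_mask: np.ndarray | pd.Series) -> "MetabolomeMatrix":
        row_mask = np.asarray(row_mask)
        return MetabolomeMatrix(
            design=self.design.loc[row_mask].reset_index(drop=True),
            values=self.values.loc[row_mask],
            mask=self.mask.loc[row_mask],
            scale=self.scale,
        )

    def select_cell(self, organ: str, stage: str) -> "MetabolomeMatrix":
        """Restrict to one organ × stage cell of the factorial design."""
        keep = ((self.design["organ"] == organ) & (self.design["stage"] == stage)).to_numpy()
        if not keep.any():
            raise ValueError(f"no samples for organ={organ!r}, stage={stage!r}")
        return self.subset_rows(keep)

    def subset_columns(self, metabolites: Sequence[str]) -> "MetabolomeMatrix":
        return replace(self, values=self.values[list(metabolites)], mask=self.mask[list(metabolites)])

    def with_scale(self, values: pd.DataFrame, scale: str) -> "MetabolomeMatrix":
        return MetabolomeMatrix(design=self.design, values=values, mask=self.mask, scale=scale)

    def copy(self) -> "MetabolomeMatrix":
        return MetabolomeMatrix(
            design=self.design.copy(), values=self.values.copy(), mask=self.mask.copy(), scale=self.scale
        )


@dataclass
class GroundTruth:
    """The synthetic generator's hidden parameters, for scoring recovery.

    ``true_beta`` are yield effects per log2-unit (per doubling) of each
    metabolite; most entries are zero. ``condition_shift`` is the additive
    water-stress yield penalty in the same units as yield.
    """

    metabolite_ids: list[str]
    true_beta: np.ndarray
    intercept: float
    noise_sd: float
    condition_shift: float
    missing_rates: np.ndarray
    block_assignment: np.ndarray
    r2_true: float | None = None  # achieved signal fraction, set by simulate_traits

    def __post_init__(self) -> None:
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        self.missing_rates = np.asarray(self.missing_rates, dtype=float)
        self.block_assignment = np.asarray(self.block_assignment, dtype=int)
        p = len(self.metabolite_ids)
        if not (len(self.true_beta) == len(self.missing_rates) == len(self.block_assignment) == p):
            raise ValueError("GroundTruth field lengths disagree with metabolite_ids")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if np.any((self.missing_rates < 0) | (self.missing_rates >= 1)):
            raise ValueError("missing_rates must lie in [0, 1)")

    @property
    def true_support(self) -> list[str]:
        return [m for m, b in zip(self.metabolite_ids, self.true_beta) if b != 0.0]

    def to_dict(self) -> dict:
        return {
            "metabolite_ids": self.metabolite_ids,
            "true_beta": self.true_beta.tolist(),
            "intercept": self.intercept,
            "noise_sd": self.noise_sd,
            "condition_shift": self.condition_shift,
            "missing_rates": self.missing_rates.tolist(),
            "block_assignment": self.block_assignment.tolist(),
            "r2_true": self.r2_true,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            metabolite_ids=list(d["metabolite_ids"]),
            true_beta=np.asarray(d["true_beta"], float),
            intercept=float(d["intercept"]),
            noise_sd=float(d["noise_sd"]),
            condition_shift=float(d["condition_shift"]),
            missing_rates=np.asarray(d["missing_rates"], float),
            block_assignment=np.asarray(d["block_assignment"], int),
            r2_true=d.get("r2_true"),
        )
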