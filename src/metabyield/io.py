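"""Reading and writing the pipeline's on-disk formats.

The matrix dialect: TSV (or CSV, chosen by extension) with a header row,
``sample_id`` as the first column, one column per metabolite, and empty
cells marking missing values. Design and trait tables use the same dialect;
ground truth, reports and fitted models serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DESIGN_COLUMNS, GroundTruth, MetabolomeMatrix


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path, design: pd.DataFrame, scale: str = "raw") -> MetabolomeMatrix:
    """Parse an intensity table; empty cells become masked entries.

    Raises a parse error naming the offending row/column on ragged rows,
    duplicate sample ids, or non-numeric non-empty cells.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if raw.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got {raw.columns[0]!r}")
    ids = raw["sample_id"].tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    cells = raw.iloc[:, 1:]
    values = np.full(cells.shape, np.nan)
    mask = np.zeros(cells.shape, dtype=bool)
    for j, col in enumerate(cells.columns):
        for i, cell in enumerate(cells[col]):
            if cell == "":
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at sample {ids[i]!r}, column {col!r}"
                    ) from None
    vdf = pd.DataFrame(values, index=pd.Index(ids, name="sample_id"), columns=cells.columns)
    mdf = pd.DataFrame(mask, index=vdf.index, columns=vdf.columns)
    design = design.loc[design["sample_id"].isin(ids)].reset_index(drop=True)
    order = {s: i for i, s in enumerate(ids)}
    design = design.sort_values("sample_id", key=lambda s: s.map(order)).reset_index(drop=True)
    return MetabolomeMatrix(design=design, values=vdf, mask=mdf, scale=scale)


def write_matrix(matrix: MetabolomeMatrix, path: str | Path) -> None:
    path = Path(path)
    out = matrix.observed()
    out.insert(0, "sample_id", matrix.sample_ids)
    out.to_csv(path, sep=_sep_for(path), index=False, na_rep="")


def read_design(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design table lacks columns {sorted(missing)}")
    return df[list(DESIGN_COLUMNS)]


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    design.to_csv(path, sep=_sep_for(path), index=False)


def read_traits(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: trait table lacks 'sample_id'")
    return df


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    traits.to_csv(path, sep=_sep_for(path), index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    write_json(truth.to_dict(), path)


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(read_json(path))
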