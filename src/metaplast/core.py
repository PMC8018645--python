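"""Panel data model: reading, block-mean aggregation, scaling, and the
environmental coefficient of variation.

A *panel* is a long-format table of replicated metabolite measurements with
columns (variety, location, year, block, compound, value).  The combined
``environment`` label is location-year; downstream statistics only ever see
that combined label.  Per compound, block-averaging yields a variety ×
environment *means matrix*, the unit of every stability computation.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import PANEL_COLUMNS

__all__ = [
    "read_panel",
    "add_environment",
    "block_means",
    "stack_means",
    "sample_matrix",
    "scale_compounds",
    "environmental_cv",
]

KEY_COLUMNS = ("variety", "location", "year", "block", "compound")


class PanelSchemaError(ValueError):
    pass


class PanelValidationError(ValueError):
    pass


def add_environment(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the combined location-year ``environment`` label."""
    out = table.copy()
    out["environment"] = out["location"].astype(str) + "-" + out["year"].astype(str)
    return out


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a long CSV/TSV panel, validating schema and key uniqueness.

    Raises
    ------
    PanelSchemaError
        if a required column is absent.
    PanelValidationError
        if any (variety, location, year, block, compound) key is duplicated;
        the message lists the offending keys.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={c: str for c in KEY_COLUMNS})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"{path}: missing required column(s) {missing}")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        offenders = (
            df.loc[dup, list(KEY_COLUMNS)].drop_duplicates().head(10).to_dict("records")
        )
        raise PanelValidationError(f"{path}: duplicated measurement keys, e.g. {offenders}")
    return add_environment(df[list(PANEL_COLUMNS)])


def _with_environment(table: pd.DataFrame) -> pd.DataFrame:
    return table if "environment" in table.columns else add_environment(table)


def block_means(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Average over blocks: one variety × environment matrix per compound.

    Missing (variety, environment) cells stay NaN; they are represented,
    never imputed.
    """
    t = _with_environment(table)
    means = t.groupby(["compound", "variety", "environment"], sort=True)["value"].mean()
    out: dict[str, pd.DataFrame] = {}
    for compound, sub in means.groupby(level="compound"):
        out[str(compound)] = sub.droplevel("compound").unstack("environment")
    return out


def stack_means(means: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-compound means matrices into one sample × compound frame.

    Samples are (variety, environment) pairs (MultiIndex); used for PCA and
    distance construction on block-averaged data.
    """
    cols = {c: m.stack(future_stack=True) for c, m in means.items()}
    stacked = pd.DataFrame(cols)
    stacked.index.names = ["variety", "environment"]
    return stacked.sort_index()


def sample_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot the long panel to a replicate-level sample × compound matrix.

    Returns (values, factors): one row per (variety, environment, block)
    sample, plus the aligned factor frame used as a PERMANOVA design.
    """
    t = _with_environment(table)
    wide = t.pivot_table(
        index=["variety", "environment", "block"],
        columns="compound",
        values="value",
        aggfunc="first",
    ).sort_index()
    factors = wide.index.to_frame(index=False)
    factors.index = wide.index
    return wide, factors


def scale_compounds(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Centre and scale each compound column to mean 0, sample sd 1.

    Zero-variance (or all-NaN) compounds cannot be scaled and are dropped
    with a warning, mirroring how constant metabolites are excluded before
    multivariate analysis.
    """
    sd = matrix.std(axis=0, ddof=ddof)
    bad = sd.index[(sd == 0) | sd.isna()]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} zero-variance compound(s): {list(map(str, bad[:5]))}",
            stacklevel=2,
        )
        matrix = matrix.drop(columns=bad)
        sd = sd.drop(bad)
    return (matrix - matrix.mean(axis=0)) / sd


def environmental_cv(means: pd.DataFrame, compound: str | None = None) -> pd.DataFrame:
    """Environmental coefficient of variation per variety, CV% = 100·sd/mean.

    Operates on one raw-scale variety × environment means matrix (CV on
    centred data would be meaningless).  sd uses the n−1 denominator across
    environments; varieties with mean 0 are flagged undefined (NaN CV).
    """
    vals = means.to_numpy(dtype=float)
    n_env = np.sum(~np.isnan(vals), axis=1)
    if (n_env < 2).any():
        bad = means.index[n_env < 2].tolist()
        raise ValueError(f"need >= 2 environments per variety, offenders: {bad}")
    sd = means.std(axis=1, ddof=1)
    mean = means.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    cv[mean == 0] = np.nan
    out = pd.DataFrame(
        {
            "sd": sd,
            "mean": mean,
            "cv_percent": cv,
            "defined": mean != 0,
        }
    )
    out.index.name = "variety"
    if compound is not None:
        out.insert(0, "compound", compound)
    return out
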