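"""Amplitude-based phenotypic-plasticity screen.

For each variety and compound, the *amplitude* is the range (max − min) of
its block-mean content across environments.  Treating the variety ×
compound amplitude table like a contingency table gives a margin-product
expectation E = Sci·Srj/St (row sum × column sum / grand total) and a
standardized Pearson residual r = (A − E)/√E per cell.  Compounds whose
summed |r| across varieties is large show a strong *differential* of
plasticity between varieties; the screen keeps compounds whose |r| sum
exceeds the median (strictly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "amplitudes",
    "AmplitudeTable",
    "expected_amplitudes",
    "screen_compounds",
    "summarize_residuals",
]


def _zscale_cells(m: pd.DataFrame) -> pd.DataFrame:
    vals = m.to_numpy(dtype=float)
    mu = np.nanmean(vals)
    sd = np.nanstd(vals, ddof=1)
    if sd == 0:
        raise ValueError("cannot z-scale a constant means matrix")
    return (m - mu) / sd


def amplitudes(
    means: dict[str, pd.DataFrame],
    scale_mode: str = "zscore",
    presence_threshold: float = 0.0,
) -> pd.DataFrame:
    """Observed plasticity amplitudes A(v, c) = max_e − min_e per variety.

    Only compounds accumulated by all varieties enter the screen: a
    compound is kept when every variety × environment block mean exceeds
    ``presence_threshold`` (a detection-limit convention).  With
    ``scale_mode='zscore'`` (default) each compound's means matrix is
    z-scaled over all its cells first, so amplitudes of compounds measured
    in heterogeneous units are comparable; ``'raw'`` skips that.

    Returns a variety × compound amplitude frame.
    """
    if scale_mode not in ("zscore", "raw"):
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    cols = {}
    for compound in sorted(means):
        m = means[compound]
        if m.shape[1] < 2:
            raise ValueError(f"{compound}: need >= 2 environments for an amplitude")
        vals = m.to_numpy(dtype=float)
        if np.isnan(vals).all(axis=1).any():
            raise ValueError(f"{compound}: a variety has no environment data")
        if not (np.nanmin(vals) > presence_threshold):
            continue  # not accumulated by all varieties
        scaled = _zscale_cells(m) if scale_mode == "zscore" else m
        cols[compound] = scaled.max(axis=1, skipna=True) - scaled.min(axis=1, skipna=True)
    if not cols:
        raise ValueError("no compound is accumulated by all varieties")
    out = pd.DataFrame(cols)
    out.index.name = "variety"
    out.columns.name = "compound"
    return out


@dataclass
class AmplitudeTable:
    """Observed amplitudes with margin-based expectations and residuals."""

    observed: pd.DataFrame   # variety x compound
    expected: pd.DataFrame
    residuals: pd.DataFrame  # (A − E)/√E, NaN where undefined
    row_sums: pd.Series      # Sci per variety
    col_sums: pd.Series      # Srj per compound
    total: float             # St


def expected_amplitudes(observed: pd.DataFrame, standardized: bool = False) -> AmplitudeTable:
    """Margin-product expected amplitudes and Pearson residuals.

    E(v,c) = Sci·Srj/St and r = (A − E)/√E.  With ``standardized=True``
    the fully standardized (adjusted) residual divides additionally by
    √((1 − Sci/St)(1 − Srj/St)).  Cells in a zero row or column margin get
    NaN residuals.
    """
    a = observed.astype(float)
    if (a.to_numpy() < 0).any():
        raise ValueError("amplitudes must be non-negative")
    sci = a.sum(axis=1)
    srj = a.sum(axis=0)
    st = float(a.to_numpy().sum())
    if st <= 0:
        raise ValueError("total amplitude must be positive")
    e = pd.DataFrame(np.outer(sci, srj) / st, index=a.index, columns=a.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a - e) / np.sqrt(e)
        if standardized:
            adj = np.sqrt(np.outer(1.0 - sci / st, 1.0 - srj / st))
            r = r / adj
    r[e == 0] = np.nan
    return AmplitudeTable(
        observed=a, expected=e, residuals=r, row_sums=sci, col_sums=srj, total=st
    )


def summarize_residuals(residuals: pd.DataFrame) -> pd.DataFrame:
    """Per-compound sum, mean and sd of |Pearson residuals| over varieties."""
    ab = residuals.abs()
    out = pd.DataFrame(
        {"sum": ab.sum(axis=0), "mean": ab.mean(axis=0), "sd": ab.std(axis=0, ddof=1)}
    ).sort_values("sum", ascending=False)
    out.index.name = "compound"
    return out


def screen_compounds(
    residuals: pd.DataFrame, rule: str = "median", threshold: float | None = None
) -> pd.DataFrame:
    """Select compounds with a strong plasticity differential.

    The per-compound statistic is S_c = Σ_v |r(v,c)|.  Under the default
    ``median`` rule a compound is selected when S_c is strictly above the
    median of all S (the median compound itself is excluded); the
    ``threshold`` rule selects S_c > threshold.
    """
    if residuals.isna().any().any():
        bad = list(residuals.columns[residuals.isna().any(axis=0)])
        raise ValueError(f"residuals undefined for compound(s): {bad}")
    summary = summarize_residuals(residuals)
    if rule == "median":
        cutoff = float(summary["sum"].median())
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("rule='threshold' needs a threshold")
        cutoff = float(threshold)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    summary["cutoff"] = cutoff
    summary["selected"] = summary["sum"] > cutoff
    return summary
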