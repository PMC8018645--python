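"""Distance construction and permutational multivariate ANOVA.

Partitions a dissimilarity matrix over a crossed two-factor design
(factor A, factor B, their interaction, residual) with sequential
(Type I) sums of squares computed from the Gower-centred inner-product
matrix G = −½·J·D²·J, and permutation-based pseudo-F inference under
unrestricted permutation of sample rows.  One-factor designs are a
special case.

Bray–Curtis requires non-negative profiles, which conflicts with
centre-and-scale preprocessing; a ``shift_policy`` makes the chosen
reconciliation explicit rather than silent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["bray_curtis", "permanova", "complete_partition", "DistanceMatrix"]


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    data: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != d.shape[0]:
            raise ValueError("ids length must match matrix size")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.data = d

    def __len__(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def bray_curtis(matrix: pd.DataFrame, shift_policy: str = "minshift") -> DistanceMatrix:
    """Bray–Curtis dissimilarities between sample rows.

    d(i,j) = Σ_c |x_ic − x_jc| / Σ_c (x_ic + x_jc), defined for
    non-negative profiles.  Because centred-and-scaled data contain
    negatives, a policy states how to restore non-negativity first:

    - ``minshift`` (default): shift each compound column so its minimum is 0;
    - ``range01``: min-max rescale each column to [0, 1];
    - ``raise``: require the input to already be non-negative.
    """
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("bray_curtis requires complete data (no NaNs)")
    if shift_policy == "minshift":
        x = x - x.min(axis=0, keepdims=True)
    elif shift_policy == "range01":
        rng = x.max(axis=0, keepdims=True) - x.min(axis=0, keepdims=True)
        rng[rng == 0] = 1.0
        x = (x - x.min(axis=0, keepdims=True)) / rng
    elif shift_policy == "raise":
        if (x < 0).any():
            raise ValueError("negative values; choose shift_policy='minshift' or 'range01'")
    else:
        raise ValueError(f"unknown shift_policy {shift_policy!r}")

    row_sums = x.sum(axis=1)
    if (row_sums == 0).any():
        bad = [str(matrix.index[i]) for i in np.flatnonzero(row_sums == 0)]
        raise ValueError(f"all-zero sample profile(s) make Bray-Curtis undefined: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    ids = ["|".join(map(str, i)) if isinstance(i, tuple) else str(i) for i in matrix.index]
    return DistanceMatrix(d, ids)


def euclidean_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    """Euclidean pairwise distances (used for oracle checks and clustering)."""
    d = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))
    ids = ["|".join(map(str, i)) if isinstance(i, tuple) else str(i) for i in matrix.index]
    return DistanceMatrix(d, ids)


# --------------------------------------------------------------------------
# PERMANOVA


def _projector(x: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of x (rank via SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
    u = u[:, s > tol]
    return u @ u.T


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels.astype(str)).to_numpy(dtype=float)


def complete_partition(table: pd.DataFrame) -> pd.DataFrame:
    """Fill in MeanSqs, R² and pseudo-F from a DF/SS partition.

    Input needs columns ``DF`` and ``SumsOfSqs`` with one row per model
    term plus a ``Residuals`` row; a ``Total`` row is appended (or
    recomputed) from term additivity.  This is the summary arithmetic used
    both for this package's own PERMANOVA output and to audit an already
    printed partition table.
    """
    t = table.loc[table.index != "Total", ["DF", "SumsOfSqs"]].astype(float).copy()
    if "Residuals" not in t.index:
        raise ValueError("partition needs a 'Residuals' row")
    total_ss = t["SumsOfSqs"].sum()
    total_df = t["DF"].sum()
    t["MeanSqs"] = t["SumsOfSqs"] / t["DF"]
    t["R2"] = t["SumsOfSqs"] / total_ss
    ms_res = t.loc["Residuals", "MeanSqs"]
    t["F.Model"] = t["MeanSqs"] / ms_res
    t.loc["Residuals", "F.Model"] = np.nan
    t.loc["Total"] = [total_df, total_ss, np.nan, 1.0, np.nan]
    return t


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    factors: list[str] | None = None,
    interaction: bool = True,
    n_perm: int = 9999,
    seed: int = 0,
    chunk: int = 512,
) -> pd.DataFrame:
    """Sequential-SS PERMANOVA of a distance matrix over 1–2 crossed factors.

    Parameters
    ----------
    dm
        Pairwise dissimilarities for n samples.
    design
        One row per sample, aligned with ``dm.ids`` order, holding the
        factor label columns.
    factors
        Factor column names, in the sequential fitting order (defaults to
        all columns of ``design``, max 2).
    interaction
        Include the A×B interaction term (two-factor designs only).
    n_perm
        Number of unrestricted row permutations; p-values carry the +1
        correction: p = (1 + #{F* ≥ F}) / (1 + n_perm).

    Returns
    -------
    DataFrame with rows per term (factor(s), interaction, Residuals, Total)
    and columns DF, SumsOfSqs, MeanSqs, R2, F.Model, Pr(>F).
    """
    n = len(dm)
    if len(design) != n:
        raise ValueError("design must have one row per sample")
    factors = list(factors) if factors is not None else list(design.columns)
    if not 1 <= len(factors) <= 2:
        raise ValueError("permanova supports 1 or 2 crossed factors")
    for f in factors:
        if f not in design.columns:
            raise ValueError(f"design has no column {f!r}")

    # Gower-centred inner product matrix
    d2 = dm.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j

    ones = np.ones((n, 1))
    p0 = _projector(ones)
    hats: list[tuple[str, np.ndarray]] = []
    prev = p0
    xs = [ones]
    term_names: list[str] = []
    for f in factors:
        xs.append(_dummies(design[f]))
        p = _projector(np.hstack(xs))
        hats.append((f, p - prev))
        prev = p
        term_names.append(f)
    if len(factors) == 2 and interaction:
        cell = _dummies(design[factors[0]].astype(str) + "\x1f" + design[factors[1]].astype(str))
        p = _projector(cell)
        name = f"{factors[0]}:{factors[1]}"
        hats.append((name, p - prev))
        prev = p
        term_names.append(name)
    h_res = np.eye(n) - prev

    df_terms = np.array([round(np.trace(h)) for _, h in hats], dtype=int)
    df_res = round(np.trace(h_res))
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    if (df_terms <= 0).any():
        bad = [t for t, d in zip(term_names, df_terms) if d <= 0]
        raise ValueError(f"term(s) with zero degrees of freedom: {bad}")

    h_stack = np.stack([h for _, h in hats] + [h_res])  # (T+1, n, n)
    ss = np.einsum("tij,ij->t", h_stack, g)
    ss_terms, ss_res = ss[:-1], ss[-1]
    ms_terms = ss_terms / df_terms
    ms_res = ss_res / df_res
    f_obs = ms_terms / ms_res

    # batched permutations of sample rows (equivalently of G rows/cols)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(hats), dtype=int)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(n) for _ in range(m)])
        gp = g[perms[:, :, None], perms[:, None, :]]  # (m, n, n)
        ss_p = np.einsum("tij,mij->mt", h_stack, gp)
        f_p = (ss_p[:, :-1] / df_terms) / (ss_p[:, -1:] / df_res)
        exceed += (f_p >= f_obs - 1e-12).sum(axis=0)
        done += m
    p_vals = (1.0 + exceed) / (1.0 + n_perm)

    total_ss = float(np.trace(g))
    rows = {
        name: [df, s, s / df, s / total_ss, f, p]
        for name, df, s, f, p in zip(term_names, df_terms, ss_terms, f_obs, p_vals)
    }
    rows["Residuals"] = [df_res, ss_res, ms_res, ss_res / total_ss, np.nan, np.nan]
    rows["Total"] = [n - 1, total_ss, np.nan, 1.0, np.nan, np.nan]
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["DF", "SumsOfSqs", "MeanSqs", "R2", "F.Model", "Pr(>F)"]
    )
    out.attrs["n_permutations"] = n_perm
    out.attrs["seed"] = seed
    return out
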