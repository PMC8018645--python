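"""Classical stability models on a variety × environment means matrix.

Three complementary views of genotype-by-environment interaction:

* **Joint regression** (Finlay–Wilkinson): regress each variety's content
  on the environmental index I_e (the per-environment mean over all
  varieties); the slope b_v is the variety's environmental sensitivity
  (b ≈ 1 average response, b > 1 hypersensitive, b < 1 buffered).
* **Ecovalence** (Wricke): W_v = Σ_e (y_ve − ȳ_v· − ȳ·e + ȳ··)², a
  variety's contribution to the interaction sum of squares.
* **AMMI**: additive main effects plus a multiplicative (SVD)
  decomposition of the doubly-centred interaction; singular vectors give
  biplot coordinates and λ_k² partitions the interaction SS.

All three operate on one complete raw-scale means matrix per compound;
incomplete matrices are rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "environmental_index",
    "FwFit",
    "fw_regression",
    "EcovalenceResult",
    "ecovalence",
    "AmmiModel",
    "ammi",
    "best_environments",
]


def _check_complete(matrix: pd.DataFrame, op: str) -> np.ndarray:
    y = matrix.to_numpy(dtype=float)
    if np.isnan(y).any():
        vi, ei = np.argwhere(np.isnan(y))[0]
        raise ValueError(
            f"{op} requires a complete means matrix; first missing cell: "
            f"({matrix.index[vi]}, {matrix.columns[ei]})"
        )
    return y


def environmental_index(matrix: pd.DataFrame) -> pd.Series:
    """Environmental index I_e: mean content over varieties per environment."""
    _check_complete(matrix, "environmental_index")
    idx = matrix.mean(axis=0)
    idx.name = "environmental_index"
    return idx


@dataclass
class FwFit:
    """Per-variety joint-regression fit for one compound."""

    table: pd.DataFrame       # variety: intercept, slope, slope_se, resid_sd
    index: pd.Series          # I_e per environment
    compound: str | None = None

    @property
    def slopes(self) -> pd.Series:
        return self.table["slope"]


def fw_regression(matrix: pd.DataFrame, compound: str | None = None) -> FwFit:
    """Finlay–Wilkinson joint regression of each variety on the index.

    OLS per variety: b_v = cov(y_v·, I)/var(I), a_v = ȳ_v· − b_v·Ī, with
    the slope standard error and residual sd from the per-variety fit.
    Because the index is the variety mean, slopes average exactly 1 over
    varieties on complete data.
    """
    y = _check_complete(matrix, "fw_regression")
    n_e = y.shape[1]
    if n_e < 3:
        raise ValueError("fw_regression needs >= 3 environments")
    i = y.mean(axis=0)
    ic = i - i.mean()
    sxx = float(ic @ ic)
    if sxx <= 0:
        raise ValueError("degenerate environmental index (zero variance)")
    slopes = (y @ ic) / sxx
    intercepts = y.mean(axis=1) - slopes * i.mean()
    fitted = intercepts[:, None] + np.outer(slopes, i)
    rss = ((y - fitted) ** 2).sum(axis=1)
    dof = n_e - 2
    sigma2 = rss / dof
    table = pd.DataFrame(
        {
            "intercept": intercepts,
            "slope": slopes,
            "slope_se": np.sqrt(sigma2 / sxx),
            "resid_sd": np.sqrt(sigma2),
        },
        index=matrix.index,
    )
    table.index.name = "variety"
    return FwFit(table=table, index=environmental_index(matrix), compound=compound)


@dataclass
class EcovalenceResult:
    table: pd.DataFrame       # variety: ecovalence, share
    interaction_ss: float
    compound: str | None = None


def _double_centre(y: np.ndarray) -> np.ndarray:
    return y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()


def ecovalence(matrix: pd.DataFrame, compound: str | None = None) -> EcovalenceResult:
    """Wricke ecovalence W_v and each variety's share of the interaction SS."""
    y = _check_complete(matrix, "ecovalence")
    if y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("ecovalence needs >= 2 varieties and >= 2 environments")
    z = _double_centre(y)
    w = (z**2).sum(axis=1)
    total = float(w.sum())
    table = pd.DataFrame(
        {"ecovalence": w, "share": w / total if total > 0 else np.zeros_like(w)},
        index=matrix.index,
    )
    table.index.name = "variety"
    return EcovalenceResult(table=table, interaction_ss=total, compound=compound)


@dataclass
class AmmiModel:
    """Additive main effects + multiplicative interaction decomposition."""

    grand_mean: float
    genotype_effects: pd.Series      # g_v, sums to 0
    environment_effects: pd.Series   # h_e, sums to 0
    singular_values: np.ndarray      # λ_k, all of them
    variety_scores: pd.DataFrame     # α_vk, orthonormal columns
    environment_scores: pd.DataFrame # γ_ek, orthonormal columns
    k: int                           # retained components
    compound: str | None = None
    scaling: str = "symmetric"
    _matrix: pd.DataFrame = field(repr=False, default=None)

    @property
    def interaction_ss(self) -> float:
        return float((self.singular_values**2).sum())

    def biplot_coordinates(self, scaling: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Variety and environment coordinates on the retained axes.

        symmetric: both sides × √λ; genotype: varieties × λ, environments
        unscaled; environment: the reverse.
        """
        scaling = scaling or self.scaling
        lam = self.singular_values[: self.k]
        a = self.variety_scores.iloc[:, : self.k]
        g = self.environment_scores.iloc[:, : self.k]
        if scaling == "symmetric":
            return a * np.sqrt(lam), g * np.sqrt(lam)
        if scaling == "genotype":
            return a * lam, g.copy()
        if scaling == "environment":
            return a.copy(), g * lam
        raise ValueError(f"unknown scaling {scaling!r}")

    def fitted(self, k: int | None = None) -> pd.DataFrame:
        """Modelled means μ + g_v + h_e + Σ_{j<=k} λ_j α_vj γ_ej."""
        k = self.k if k is None else k
        lam = self.singular_values[:k]
        inter = (self.variety_scores.iloc[:, :k] * lam) @ self.environment_scores.iloc[:, :k].T
        base = (
            self.grand_mean
            + np.add.outer(self.genotype_effects.to_numpy(), self.environment_effects.to_numpy())
        )
        return pd.DataFrame(
            base, index=self.genotype_effects.index, columns=self.environment_effects.index
        ) + inter


def ammi(matrix: pd.DataFrame, k: int = 2, compound: str | None = None) -> AmmiModel:
    """Fit the AMMI model to a complete variety × environment means matrix.

    The means table is double-centred and its residual SVD'd; all singular
    values are reported, ``k`` only sets how many axes biplots and fitted
    values retain.  Axis signs are fixed deterministically: the
    largest-|score| environment on each axis is positive.
    """
    y = _check_complete(matrix, "ammi")
    n_v, n_e = y.shape
    max_k = min(n_v, n_e) - 1
    if not 0 < k <= max_k:
        raise ValueError(f"k must be in 1..{max_k} for a {n_v}x{n_e} matrix, got {k}")
    mu = float(y.mean())
    g = y.mean(axis=1) - mu
    h = y.mean(axis=0) - mu
    z = _double_centre(y)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    u, s, vt = u[:, :max_k], s[:max_k], vt[:max_k]
    flips = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    flips[flips == 0] = 1.0
    u, vt = u * flips, vt * flips[:, None]
    axes = [f"IPC{i + 1}" for i in range(len(s))]
    return AmmiModel(
        grand_mean=mu,
        genotype_effects=pd.Series(g, index=matrix.index, name="g"),
        environment_effects=pd.Series(h, index=matrix.columns, name="h"),
        singular_values=s,
        variety_scores=pd.DataFrame(u, index=matrix.index, columns=axes),
        environment_scores=pd.DataFrame(vt.T, index=matrix.columns, columns=axes),
        k=k,
        compound=compound,
        _matrix=matrix.copy(),
    )


def best_environments(model: AmmiModel, variety: str, k: int | None = None) -> pd.Series:
    """Environments ranked by a variety's modelled content, best first."""
    if variety not in model.genotype_effects.index:
        raise KeyError(f"unknown variety {variety!r}")
    fitted = model.fitted(k)
    return fitted.loc[variety].sort_values(ascending=False)
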