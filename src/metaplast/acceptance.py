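"""Reusable experiment drivers shared by the acceptance checks.

These run the package end to end at stated problem sizes: joint-regression
slope recovery, screen power on panels with one planted high-interaction
compound, and permutation-test type-I calibration on null data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import block_means
from .permanova import euclidean_distance, permanova
from .plasticity import amplitudes, expected_amplitudes, screen_compounds
from .simulate import CompoundSpec, SimSpec, simulate_panel
from .stability import fw_regression

__all__ = ["fw_recovery", "screen_power", "permanova_type1"]


def fw_recovery(
    seed: int = 0, slopes=(0.5, 1.0, 1.5), n_env: int = 20, n_reps: int = 20
) -> pd.DataFrame:
    """Refit known sensitivity slopes over replicate simulated panels.

    Each panel has ``n_env`` environments (half as many locations over two
    years), two blocks, and one compound whose per-variety slopes are
    ``slopes``.  Returns one row per (replicate, variety) with the
    generating slope, the OLS estimate, its standard error, and whether
    the estimate lies within two standard errors of the truth.  Because a
    2-SE band is a ~95% interval, recovery is judged by the coverage rate
    over replicates rather than any single draw.
    """
    rng = np.random.default_rng(seed)
    truth = np.asarray(slopes, dtype=float)
    rows = []
    for rep in range(n_reps):
        spec = SimSpec(
            n_varieties=len(truth),
            n_locations=n_env // 2,
            n_years=2,
            n_blocks=2,
            compounds=[CompoundSpec("c1", mu=20.0, sigma_g=0.5, sigma_e=2.0,
                                    sigma_resid=0.3)],
            fw_slopes={"c1": list(truth)},
            seed=int(rng.integers(2**31 - 1)),
        )
        table, _ = simulate_panel(spec)
        fit = fw_regression(block_means(table)["c1"])
        for v, beta in zip(fit.table.index, truth):
            est = fit.table.loc[v, "slope"]
            se = fit.table.loc[v, "slope_se"]
            rows.append(
                {"rep": rep, "variety": v, "truth": beta, "estimate": est,
                 "se": se, "within_2se": abs(est - beta) <= 2.0 * se}
            )
    return pd.DataFrame(rows)


def _power_spec(seed: int, snr: float, n_null: int = 9) -> SimSpec:
    sigma_resid = 0.25
    comps = [
        CompoundSpec(f"null{i}", mu=10.0, sigma_g=0.5, sigma_e=1.0,
                     sigma_gxe=0.0, sigma_resid=sigma_resid)
        for i in range(n_null)
    ]
    comps.append(
        CompoundSpec("hot", mu=10.0, sigma_g=0.5, sigma_e=1.0,
                     sigma_gxe=snr * sigma_resid, sigma_resid=sigma_resid)
    )
    return SimSpec(n_varieties=5, n_locations=10, n_years=2, n_blocks=2,
                   compounds=comps, seed=seed)


def screen_power(seed: int = 0, snr: float = 4.0, n_reps: int = 200) -> float:
    """Fraction of replicate panels where the planted high-interaction
    compound passes the median |Pearson residual| screen.

    Panels: 5 varieties x 20 environments x 2 blocks, nine interaction-free
    compounds plus one whose interaction RMS is ``snr`` times the residual
    sd.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        spec = _power_spec(int(rng.integers(2**31 - 1)), snr)
        table, _ = simulate_panel(spec)
        amp = amplitudes(block_means(table), scale_mode="zscore")
        out = screen_compounds(expected_amplitudes(amp).residuals)
        hits += bool(out.loc["hot", "selected"])
    return hits / n_reps


def permanova_type1(
    seed: int = 0, n_sims: int = 1000, n_perm: int = 999, alpha: float = 0.05
) -> float:
    """Empirical rejection rate of PERMANOVA on effect-free data.

    Each simulation: 12 samples in 3 nominal groups of 4, 4 uncorrelated
    standard-normal compounds, Euclidean distances, one-factor test with
    ``n_perm`` unrestricted permutations.
    """
    rng = np.random.default_rng(seed)
    design = pd.DataFrame({"g": np.repeat(["a", "b", "c"], 4)})
    rejections = 0
    for _ in range(n_sims):
        x = pd.DataFrame(rng.normal(size=(12, 4)))
        dm = euclidean_distance(x)
        res = permanova(dm, design, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        rejections += bool(res.loc["g", "Pr(>F)"] <= alpha)
    return rejections / n_sims
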