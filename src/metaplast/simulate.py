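"""Synthetic multi-environment metabolite panels with known ground truth.

Emulates replicated variety × environment trials of quantified metabolites:
additive variety and environment effects, a structured (optionally low-rank
or slope-parameterized) interaction, field-block effects shared across
compounds, and per-compound residual noise on a gaussian or lognormal scale.

The generator exists so every downstream estimator in this package —
variance partitioning, plasticity screens, joint-regression slopes,
ecovalence, AMMI scores — can be checked against the effects that actually
produced the data.  The returned :class:`SimTruth` sidecar stores every
realized effect.

Two conventions matter when reading parameter values:

* All main effects are drawn sum-to-zero (centred after sampling), and the
  interaction matrix of each compound is doubly centred, so the classical
  two-way decomposition of the noise-free cell means is exact.
* ``sigma_gxe`` is realized as the exact root-mean-square of the centred
  interaction matrix (the draw is rescaled), which makes signal-to-noise
  ratios in recovery experiments exact rather than approximate.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["CompoundSpec", "SimSpec", "SimTruth", "simulate_panel", "write_panel"]

#: canonical long-table column order
PANEL_COLUMNS = ("variety", "location", "year", "block", "compound", "value")


class InvalidSpecError(ValueError):
    """Raised when a simulation spec violates its invariants."""


@dataclass(frozen=True)
class CompoundSpec:
    """Per-compound generating parameters.

    mu is the base level in the compound family's own units; the sd
    parameters are on the same scale (log scale when the panel is
    lognormal).
    """

    name: str
    family: str = "generic"
    mu: float = 10.0
    sigma_g: float = 1.0
    sigma_e: float = 1.0
    sigma_gxe: float = 0.0
    sigma_resid: float = 0.5

    def validate(self) -> None:
        for attr in ("sigma_g", "sigma_e", "sigma_gxe", "sigma_resid"):
            if getattr(self, attr) < 0:
                raise InvalidSpecError(f"{self.name}: {attr} must be >= 0")
        if self.mu < 0:
            raise InvalidSpecError(f"{self.name}: mu must be >= 0")


@dataclass
class SimSpec:
    """Design and effect-size description of a simulated panel.

    fw_slopes maps a compound name to one environmental-sensitivity slope
    per variety; for those compounds the interaction is (beta_v - 1) * h_e,
    so the generating joint-regression slope is exactly beta_v.
    interaction_rank > 0 constrains each remaining compound's interaction
    matrix to that rank.  marker_offsets plant constitutive (variety,
    compound) shifts for marker-screen experiments.
    """

    n_varieties: int
    n_locations: int
    n_years: int = 1
    n_blocks: int = 2
    compounds: Sequence[CompoundSpec] = field(default_factory=list)
    fw_slopes: Mapping[str, Sequence[float]] | None = None
    interaction_rank: int = 0
    block_sd: float = 0.0
    marker_offsets: Sequence[tuple[str, str, float]] = ()
    noise_model: str = "gaussian"
    seed: int = 0

    # -- label helpers -------------------------------------------------
    @property
    def varieties(self) -> list[str]:
        return [f"V{i + 1:02d}" for i in range(self.n_varieties)]

    @property
    def locations(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_locations)]

    @property
    def years(self) -> list[str]:
        return [f"Y{i + 1}" for i in range(self.n_years)]

    @property
    def blocks(self) -> list[str]:
        return [f"B{i + 1}" for i in range(self.n_blocks)]

    @property
    def environments(self) -> list[str]:
        # environment = location x year combination; downstream analyses
        # only ever see this combined label
        return [f"{loc}-{yr}" for loc in self.locations for yr in self.years]

    def validate(self) -> None:
        for name, n in (
            ("n_varieties", self.n_varieties),
            ("n_locations", self.n_locations),
            ("n_years", self.n_years),
            ("n_blocks", self.n_blocks),
        ):
            if n <= 0:
                raise InvalidSpecError(f"{name} must be a positive count, got {n}")
        if self.n_blocks < 2:
            raise InvalidSpecError("n_blocks must be >= 2 (replication is required downstream)")
        if not self.compounds:
            raise InvalidSpecError("at least one compound is required")
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise InvalidSpecError("compound names must be unique")
        for c in self.compounds:
            c.validate()
        if self.interaction_rank < 0:
            raise InvalidSpecError("interaction_rank must be >= 0")
        if self.block_sd < 0:
            raise InvalidSpecError("block_sd must be >= 0")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise InvalidSpecError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_model == "lognormal":
            for c in self.compounds:
                if c.mu <= 0:
                    raise InvalidSpecError(
                        f"{c.name}: lognormal panels need mu > 0 (value = mu * exp(effects))"
                    )
        if self.fw_slopes:
            for cname, slopes in self.fw_slopes.items():
                if cname not in names:
                    raise InvalidSpecError(f"fw_slopes references unknown compound {cname!r}")
                if len(slopes) != self.n_varieties:
                    raise InvalidSpecError(
                        f"fw_slopes[{cname!r}] must give one slope per variety"
                    )
        known_v, known_c = set(self.varieties), set(names)
        for v, cname, _ in self.marker_offsets:
            if v not in known_v or cname not in known_c:
                raise InvalidSpecError(f"marker_offsets references unknown ({v}, {cname})")

    # -- config I/O ----------------------------------------------------
    @classmethod
    def from_dict(cls, d: Mapping) -> "SimSpec":
        d = dict(d)
        comps = [
            c if isinstance(c, CompoundSpec) else CompoundSpec(**c)
            for c in d.pop("compounds", [])
        ]
        offsets = [tuple(t) for t in d.pop("marker_offsets", [])]
        return cls(compounds=comps, marker_offsets=offsets, **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimSpec":
        path = Path(path)
        with open(path) as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(data)


@dataclass
class SimTruth:
    """Realized effects behind a simulated panel.

    All frames are indexed by the generator's labels; ``interaction`` maps
    compound name to its doubly-centred variety × environment matrix and
    ``fw_slopes`` holds the exact generating joint-regression slope
    b_vc = 1 + cov(interaction_v, h) / var(h) per (variety, compound).
    """

    seed: int
    grand_means: pd.Series                 # mu_c per compound
    genotype: pd.DataFrame                 # variety x compound
    environment: pd.DataFrame              # environment x compound
    interaction: dict[str, pd.DataFrame]   # compound -> variety x environment
    block_effects: pd.DataFrame            # environment x block
    fw_slopes: pd.DataFrame                # variety x compound
    variance_shares: pd.DataFrame          # compound x component

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "grand_means": self.grand_means.to_dict(),
            "genotype": self.genotype.to_dict(),
            "environment": self.environment.to_dict(),
            "interaction": {k: v.to_dict() for k, v in self.interaction.items()},
            "block_effects": self.block_effects.to_dict(),
            "fw_slopes": self.fw_slopes.to_dict(),
            "variance_shares": self.variance_shares.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _compound_rng(seed: int, name: str) -> np.random.Generator:
    # deterministic per-compound substream: adding a compound never
    # perturbs the draws of any other compound
    return np.random.default_rng(np.random.SeedSequence([seed, 1, zlib.crc32(name.encode())]))


def _centred_normal(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    x = rng.normal(0.0, 1.0, n)
    x -= x.mean()
    return sd * x


def _interaction_matrix(
    rng: np.random.Generator, n_v: int, n_e: int, sd: float, rank: int
) -> np.ndarray:
    """Doubly-centred interaction with exact element RMS equal to sd."""
    if sd == 0.0:
        return np.zeros((n_v, n_e))
    if rank > 0:
        k = min(rank, n_v - 1, n_e - 1)
        a = rng.normal(size=(n_v, k))
        b = rng.normal(size=(n_e, k))
        a -= a.mean(axis=0)
        b -= b.mean(axis=0)
        m = a @ b.T
    else:
        m = rng.normal(size=(n_v, n_e))
        m -= m.mean(axis=1, keepdims=True)
        m -= m.mean(axis=0, keepdims=True)
    rms = np.sqrt(np.mean(m**2))
    if rms == 0.0:  # pathological draw; keep zeros rather than divide
        return np.zeros((n_v, n_e))
    return m * (sd / rms)


def simulate_panel(spec: SimSpec) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a replicated long-format panel and its ground truth.

    Cell model per compound c:
        value(v, e, b) = mu_c + g_vc + h_ce + gh_vce + block_be + eps
    (or mu_c * exp(g + h + gh + block + eps) under the lognormal model).

    Returns
    -------
    (table, truth)
        ``table`` is a long DataFrame with columns
        variety, location, year, block, compound, value and exactly
        n_varieties * n_locations * n_years * n_blocks * n_compounds rows;
        ``truth`` stores every realized effect (see :class:`SimTruth`).
    """
    spec.validate()
    varieties, envs, blocks = spec.varieties, spec.environments, spec.blocks
    n_v, n_e, n_b = len(varieties), len(envs), len(blocks)

    block_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    block_eff = block_rng.normal(0.0, 1.0, (n_e, n_b)) * spec.block_sd

    offsets: dict[tuple[str, str], float] = {}
    for v, cname, off in spec.marker_offsets:
        offsets[(v, cname)] = offsets.get((v, cname), 0.0) + float(off)

    g_frame = pd.DataFrame(index=varieties)
    h_frame = pd.DataFrame(index=envs)
    slope_frame = pd.DataFrame(index=varieties)
    inter: dict[str, pd.DataFrame] = {}
    shares: dict[str, dict[str, float]] = {}
    mu_map: dict[str, float] = {}
    values = np.empty((len(spec.compounds), n_v, n_e, n_b))

    for ci, comp in enumerate(spec.compounds):
        rng = _compound_rng(spec.seed, comp.name)
        g = _centred_normal(rng, n_v, comp.sigma_g)
        h = _centred_normal(rng, n_e, comp.sigma_e)
        if spec.fw_slopes and comp.name in spec.fw_slopes:
            beta = np.asarray(spec.fw_slopes[comp.name], dtype=float)
            gh = np.outer(beta - 1.0, h)
        else:
            gh = _interaction_matrix(rng, n_v, n_e, comp.sigma_gxe, spec.interaction_rank)
        for vi, v in enumerate(varieties):
            g[vi] += offsets.get((v, comp.name), 0.0)

        eps = rng.normal(0.0, comp.sigma_resid, (n_v, n_e, n_b)) if comp.sigma_resid > 0 else np.zeros((n_v, n_e, n_b))
        lin = (
            g[:, None, None]
            + h[None, :, None]
            + gh[:, :, None]
            + block_eff[None, :, :]
            + eps
        )
        if spec.noise_model == "lognormal":
            values[ci] = comp.mu * np.exp(lin)
        else:
            values[ci] = comp.mu + lin

        var_h = float(np.var(h)) if n_e > 1 else 0.0
        fw = np.ones(n_v) if var_h == 0.0 else 1.0 + (gh @ (h - h.mean())) / np.sum((h - h.mean()) ** 2)

        g_frame[comp.name] = g
        h_frame[comp.name] = h
        slope_frame[comp.name] = fw
        inter[comp.name] = pd.DataFrame(gh, index=varieties, columns=envs)
        mu_map[comp.name] = comp.mu
        comp_vars = {
            "genotype": float(np.var(g)),
            "environment": var_h,
            "interaction": float(np.mean(gh**2)),
            "block": float(spec.block_sd**2),
            "residual": float(comp.sigma_resid**2),
        }
        total = sum(comp_vars.values()) or 1.0
        shares[comp.name] = {k: v / total for k, v in comp_vars.items()}

    # assemble the long table; index order matches the value tensor layout
    idx = pd.MultiIndex.from_product(
        [[c.name for c in spec.compounds], varieties, spec.locations, spec.years, blocks],
        names=["compound", "variety", "location", "year", "block"],
    )
    table = idx.to_frame(index=False)
    table["value"] = values.reshape(-1)
    table = table[list(PANEL_COLUMNS)]

    truth = SimTruth(
        seed=spec.seed,
        grand_means=pd.Series(mu_map, name="mu"),
        genotype=g_frame,
        environment=h_frame,
        interaction=inter,
        block_effects=pd.DataFrame(block_eff, index=envs, columns=blocks),
        fw_slopes=slope_frame,
        variance_shares=pd.DataFrame(shares).T,
    )
    return table, truth


def write_panel(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long panel as CSV (or TSV when the suffix is .tsv/.txt)."""
    if table.empty:
        raise ValueError("refusing to write an empty panel")
    missing = [c for c in PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"panel is missing columns: {missing}")
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    table[list(PANEL_COLUMNS)].to_csv(path, sep=sep, index=False)
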