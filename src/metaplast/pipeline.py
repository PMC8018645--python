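"""End-to-end pipeline: long panel file in, report bundle out.

Stages run in analysis order — ingest, block means, scaling, variance
partition, structure (PCA / areas / clustering / CV), plasticity screen,
stability models on the screened compounds — and every stage writes its
result as CSV/JSON into the output directory, together with a manifest
(config, seed, package version, config hash) from which the whole bundle
is re-derivable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, core, permanova as vp, plasticity, stability, structure

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

STAGES = ("permanova", "structure", "screen", "stability")


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline parameters; unknown keys are rejected on load."""

    input: str
    out_dir: str
    seed: int = 0
    n_perm: int = 999
    scale_mode: str = "zscore"          # amplitude scaling
    shift_policy: str = "minshift"      # Bray-Curtis non-negativity policy
    screen_rule: str = "median"
    screen_threshold: float | None = None
    presence_threshold: float = 0.0
    ammi_k: int = 2
    cluster_k: int = 5
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggle(s): {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        if any(self.stages.values()) and self.seed is None:
            raise ValueError("a seed is required when stochastic stages are enabled")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_csv(df: pd.DataFrame, path: Path, outputs: list[str]) -> None:
    df.to_csv(path, float_format="%.12g")
    outputs.append(path.name)


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages and write the report bundle.

    Returns the manifest dict (also written as manifest.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    with stage("ingest"):
        table = core.read_panel(config.input)

    with stage("block_means"):
        means = core.block_means(table)
        stacked = core.stack_means(means)
        _write_csv(stacked, out / "block_means.csv", outputs)

    with stage("scaling"):
        scaled_means = core.scale_compounds(stacked.dropna(axis=1))
        _write_csv(scaled_means, out / "block_means_scaled.csv", outputs)

    results: dict = {}

    if config.stages["permanova"]:
        with stage("permanova"):
            samples, factors = core.sample_matrix(table)
            scaled_samples = core.scale_compounds(samples.dropna(axis=1))
            dm = vp.bray_curtis(scaled_samples, shift_policy=config.shift_policy)
            part = vp.permanova(
                dm,
                factors,
                factors=["environment", "variety"],
                n_perm=config.n_perm,
                seed=config.seed,
            )
            _write_csv(part, out / "permanova.csv", outputs)
            results["permanova"] = part

    if config.stages["structure"]:
        with stage("structure"):
            model = structure.pca(scaled_means)
            _write_csv(model.scores, out / "pca_scores.csv", outputs)
            _write_csv(model.loadings, out / "pca_loadings.csv", outputs)
            (out / "pca_inertia.json").write_text(
                json.dumps({"inertia_fractions": model.inertia.tolist()})
            )
            outputs.append("pca_inertia.json")
            n_env = stacked.index.get_level_values("environment").nunique()
            if n_env == 3 and model.n_components >= 3:
                areas = structure.variety_areas(model)
                _write_csv(areas, out / "pca_areas.csv", outputs)
                results["areas"] = areas
            variety_means = scaled_means.groupby(level="variety").mean()
            clust = structure.ward_clustering(variety_means)
            (out / "dendrogram.nwk").write_text(clust.to_newick() + "\n")
            outputs.append("dendrogram.nwk")
            k = min(config.cluster_k, variety_means.shape[0])
            _write_csv(clust.cut(k).to_frame(), out / "clusters.csv", outputs)
            cv = pd.concat(
                [core.environmental_cv(m, compound=c) for c, m in means.items()]
            )
            _write_csv(cv, out / "environmental_cv.csv", outputs)
            results["pca"] = model
            results["cv"] = cv

    selected: list[str] | None = None
    if config.stages["screen"]:
        with stage("screen"):
            amp = plasticity.amplitudes(
                means,
                scale_mode=config.scale_mode,
                presence_threshold=config.presence_threshold,
            )
            tab = plasticity.expected_amplitudes(amp)
            _write_csv(tab.observed, out / "amplitudes_observed.csv", outputs)
            _write_csv(tab.expected, out / "amplitudes_expected.csv", outputs)
            _write_csv(tab.residuals, out / "amplitude_residuals.csv", outputs)
            summary = plasticity.screen_compounds(
                tab.residuals, rule=config.screen_rule, threshold=config.screen_threshold
            )
            _write_csv(summary, out / "plasticity_screen.csv", outputs)
            selected = list(summary.index[summary["selected"]])
            results["screen"] = summary

    if config.stages["stability"]:
        with stage("stability"):
            compounds = selected if selected is not None else sorted(means)
            fw_rows, eco_rows, ammi_json = [], [], {}
            for c in compounds:
                m = means[c]
                fit = stability.fw_regression(m, compound=c)
                t = fit.table.copy()
                t.insert(0, "compound", c)
                fw_rows.append(t)
                eco = stability.ecovalence(m, compound=c)
                te = eco.table.copy()
                te.insert(0, "compound", c)
                eco_rows.append(te)
                model = stability.ammi(m, k=config.ammi_k, compound=c)
                av, ae = model.biplot_coordinates()
                ammi_json[c] = {
                    "grand_mean": model.grand_mean,
                    "singular_values": model.singular_values.tolist(),
                    "genotype_effects": model.genotype_effects.to_dict(),
                    "environment_effects": model.environment_effects.to_dict(),
                    "variety_biplot": av.to_dict(),
                    "environment_biplot": ae.to_dict(),
                    "k": model.k,
                    "scaling": model.scaling,
                }
            if fw_rows:
                _write_csv(pd.concat(fw_rows), out / "fw_regression.csv", outputs)
                _write_csv(pd.concat(eco_rows), out / "ecovalence.csv", outputs)
                (out / "ammi.json").write_text(json.dumps(ammi_json, indent=1))
                outputs.append("ammi.json")
            results["stability_compounds"] = compounds

    cfg = config.to_dict()
    manifest = {
        "package": "metaplast",
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
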