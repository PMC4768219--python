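"""Pipeline orchestration: validated YAML configuration, staged execution,
run manifest.  A run is deterministic given an identical config + seed."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError, CrosstalkError, InputError
from .model import CrosstalkModel, FitOptions
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "scan", "bind", "classify", "enrich")


@dataclass
class PipelineConfig:
    """Everything a run needs: input paths (or a simulation block), thresholds
    and the RNG seed."""

    outdir: str = "crosstalk_out"
    seed: int = 0
    simulate: bool = True
    n_genes: int = 2000
    # input paths, used when simulate is false
    expression: str | None = None
    sample_map: str | None = None
    annotation: str | None = None
    promoters: str | None = None
    pwms: str | None = None
    peaks: dict = field(default_factory=dict)
    terms: str | None = None
    # thresholds
    ratio_up: float = 1.2
    ratio_down: float = 0.8
    fdr: float = 0.05
    fdr_method: str = "storey"
    motif_rel_threshold: float = 0.8
    window_upstream: int = 7500
    window_downstream: int = 2500
    binding_fdr: float = 0.05
    binding_score_ratio: float = 2.0
    enrichment_alpha: float = 0.05
    stages: list = field(default_factory=lambda: list(STAGES))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def fit_options(self) -> FitOptions:
        return FitOptions(
            thresholds=(self.ratio_up, self.ratio_down, self.fdr),
            fdr_method=self.fdr_method,
            motif_rel_threshold=self.motif_rel_threshold,
            window_upstream=self.window_upstream,
            window_downstream=self.window_downstream,
            binding_fdr=self.binding_fdr,
            binding_score_ratio=self.binding_score_ratio,
            enrichment_alpha=self.enrichment_alpha,
        )

    def validate(self) -> None:
        self.fit_options().validate()
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ConfigurationError(f"unknown stages: {sorted(bad)}")
        if not self.simulate:
            for name in ("expression", "sample_map"):
                path = getattr(self, name)
                if not path:
                    raise ConfigurationError(f"non-simulated run needs {name}")
                if not Path(path).exists():
                    raise InputError(f"{name} file not found: {path}")


def run_all(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the output path map.

    Any stage failure raises with the stage name logged; outputs plus a
    manifest (inputs, version, seed, thresholds, stages) land in ``outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    stage = "setup"
    try:
        if config.simulate and "simulate" in config.stages:
            stage = "simulate"
            logger.info("stage simulate: %d genes, seed %d", config.n_genes, config.seed)
            cfg = SimulationConfig(n_genes=config.n_genes, rng_seed=config.seed)
            study = simulate_study(cfg)
            sim_dir = outdir / "simulated_inputs"
            paths.update({f"sim_{k}": str(v) for k, v in study.write(sim_dir).items()})
            model = CrosstalkModel(
                study.expression,
                annotation=study.annotation,
                promoters=study.promoters,
                pwms=study.pwms,
                peaks=study.peaks,
                terms=study.terms,
            )
        else:
            stage = "load"
            model = CrosstalkModel.from_files(
                config.expression,
                config.sample_map,
                annotation_path=config.annotation,
                promoters_path=config.promoters,
                pwm_path=config.pwms,
                peak_paths=config.peaks or None,
                terms_path=config.terms,
            )
        if "scan" not in config.stages:
            model.promoters = None
        if "bind" not in config.stages:
            model.peaks = None
        if "enrich" not in config.stages:
            model.terms = None
        stage = "fit"
        results = model.fit(config.fit_options())
        stage = "save"
        paths.update({k: str(v) for k, v in results.save(outdir).items()})
    except CrosstalkError:
        logger.error("pipeline failed in stage %r", stage)
        raise
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": [s for s in STAGES if s in config.stages],
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = str(outdir / "manifest.json")
    return paths
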