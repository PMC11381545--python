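"""End-to-end orchestration: simulate or load, then run every stage.

``run_pipeline`` wires the stages together and writes each stage's table
plus a JSON run manifest (seed, thresholds, versions) sufficient to
reproduce the bundle byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import AbundanceMatrix
from .detection import GammaDetectionModel, call_presence, fit_detection_model
from .flux import MarkovFluxEstimator
from .retention import build_retention_events, km_curve
from .scores import (
    compare_similarity,
    compute_scores,
    consecutive_dynamics,
    jaccard_consecutive,
    richness_dynamics,
    stratify_individuals,
)
from .synthetic import SimulationConfig, simulate_abundances, simulate_presence_paths
from . import io as mio

logger = logging.getLogger("microflux")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML."""

    abundance_path: str | None = None
    metadata_path: str | None = None
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection_percentile: float = 0.01
    t_in: float = 0.3
    t_out: float = 0.3
    stratify_hi: float = 2.0
    stratify_lo: float = -2.0
    similarity_test: str = "wilcoxon_one_sided"
    downsize_target: int = 10_000_000
    seed: int = 0
    output_dir: str = "microflux_out"

    def to_dict(self) -> dict:
        d = vars(self).copy()
        sim = d.pop("simulation")
        d["simulation"] = {
            "n_subjects": sim.n_subjects,
            "n_visits": sim.n_visits,
            "n_species": sim.n_species,
            "read_depth": sim.read_depth,
            "n_markers_per_species": sim.n_markers_per_species,
            "seed": sim.seed,
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the report."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write the result bundle, return it in memory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("input")
        if config.simulate:
            sim = config.simulation
            presence_true, truth = simulate_presence_paths(sim, seed=config.seed)
            abundance, _ = simulate_abundances(presence_true, sim, seed=config.seed)
            truth_table = pd.DataFrame(
                {
                    "inflow": truth.inflow,
                    "outflow": truth.outflow,
                    "label": truth.labels,
                }
            )
            truth_table.to_csv(out / "truth.tsv", sep="\t")
        else:
            if not (config.abundance_path and config.metadata_path):
                raise ValueError("abundance_path and metadata_path required when simulate=False")
            abundance = mio.read_abundance_table(config.abundance_path, config.metadata_path)
        mio.write_abundance_table(abundance, out / "abundance.tsv")
        mio.write_metadata(abundance.metadata, out / "metadata.tsv")
    except Exception as e:  # noqa: BLE001 — stage name is the contract
        raise StageError("input", e) from e

    try:
        stage("detect")
        model = fit_detection_model(abundance, percentile=config.detection_percentile)
        model.to_json(out / "detection_model.json")
        presence = call_presence(abundance, model)
        mio.write_presence_table(presence, out / "presence.tsv")
        results["detection_model"] = model
        results["presence"] = presence
    except Exception as e:
        raise StageError("detect", e) from e

    try:
        stage("flux")
        est = MarkovFluxEstimator(t_in=config.t_in, t_out=config.t_out).fit(presence)
        flux = est.summary_
        flux.to_csv(out / "flux.tsv", sep="\t")
        results["flux"] = flux
    except Exception as e:
        raise StageError("flux", e) from e

    try:
        stage("retention")
        events = build_retention_events(presence)
        events.to_csv(out / "retention_events.tsv", sep="\t", index=False)
        curve = km_curve(events)
        curve.to_csv(out / "retention_curve.tsv", sep="\t")
        results["retention_events"] = events
        results["retention_curve"] = curve
    except Exception as e:
        raise StageError("retention", e) from e

    try:
        stage("scores")
        scores = compute_scores(abundance, flux["label"], presence)
        scores.to_csv(out / "scores.tsv", sep="\t")
        pair_table = consecutive_dynamics(scores[["Z_PCS", "Z_TCS"]], abundance.metadata)
        pair_table["jaccard"] = jaccard_consecutive(presence)
        strata = stratify_individuals(
            pair_table, hi=config.stratify_hi, lo=config.stratify_lo
        )
        pair_table["tcs_stratum"] = strata
        pair_table.to_csv(out / "pairs.tsv", sep="\t", index=False)
        results["scores"] = scores
        results["pairs"] = pair_table
        try:
            results["similarity_test"] = compare_similarity(
                pair_table["jaccard"], strata, test=config.similarity_test
            )
        except ValueError as err:
            logger.warning("similarity comparison skipped: %s", err)
        results["richness_dynamics"] = richness_dynamics(scores["richness"], pair_table)
    except Exception as e:
        raise StageError("scores", e) from e

    manifest = {
        "microflux_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "detection_percentile": config.detection_percentile,
        "t_in": config.t_in,
        "t_out": config.t_out,
        "stratify_hi": config.stratify_hi,
        "stratify_lo": config.stratify_lo,
        "config": config.to_dict(),
        "n_species": int(len(abundance.species)),
        "n_samples": int(len(abundance.samples)),
        "detection_threshold": results["detection_model"].threshold_,
        "n_pcs": int((flux["label"] == "PCS").sum()),
        "n_tcs": int((flux["label"] == "TCS").sum()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
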