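"""End-to-end orchestration: models -> data -> GLM -> features -> thresholds.

The pipeline strings the stages together in the analysis order: build phone
model dRDMs from likelihood streams; optionally validate the feature set
against the second-order model structure; build searchlight data dRDMs;
fit the phone GLM per vertex and window; epoch-average the coefficients;
aggregate into feature fits; simulate the permutation null and threshold
the maps.  Every artefact is persisted together with the full config, its
hash, the seed and the package version, so a rerun with an identical
config reproduces every numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

import ssrsa
from ssrsa.brain_states import SearchlightConfig, build_data_drdms
from ssrsa.feature_space import (
    FeatureMatrix,
    default_feature_matrix,
    load_feature_matrix,
)
from ssrsa.glm_fitting import epoch_average_betas, fit_drdms
from ssrsa.io import (
    feature_maps_to_frame,
    load_likelihood_streams,
    load_mesh_and_epochs,
    save_data_drdms,
    save_model_set,
    save_null_distributions,
)
from ssrsa.machine_states import build_model_set
from ssrsa.model_validation import feature_cluster_diagnostics
from ssrsa.permutation_stats import (
    build_null,
    most_conservative_quantiles,
    observed_feature_fits,
    threshold_feature_maps,
)
from ssrsa.synthetic_data import (
    SyntheticSpec,
    gen_likelihood_streams,
    gen_source_epochs,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full pipeline run.

    Inputs are either file paths (likelihood-stream container, mesh TSV,
    epoch container) or a synthetic spec; the searchlight geometry, the
    permutation count, the significance quantiles and the seed complete
    the run definition.
    """

    output_dir: str = "ssrsa_out"
    streams_path: str | None = None
    mesh_path: str | None = None
    epochs_path: str | None = None
    feature_matrix_path: str | None = None
    synthetic: SyntheticSpec | None = None
    searchlight: SearchlightConfig = field(default_factory=SearchlightConfig)
    n_perm: int = 100
    quantiles: tuple[float, ...] = (0.95, 0.99, 0.999)
    seed: int = 0
    run_validation: bool = True
    model_only: bool = False

    def __post_init__(self) -> None:
        if self.synthetic is None and self.streams_path is None:
            raise ValueError(
                "config must provide streams_path or a synthetic spec"
            )
        if not all(0 < q < 1 for q in self.quantiles):
            raise ValueError("quantiles must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        object.__setattr__(self, "quantiles", tuple(self.quantiles))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def config_from_yaml(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "searchlight" in raw and isinstance(raw["searchlight"], dict):
        raw["searchlight"] = SearchlightConfig(**raw["searchlight"])
    if "synthetic" in raw and isinstance(raw["synthetic"], dict):
        syn = dict(raw["synthetic"])
        if "implants" in syn:
            from ssrsa.synthetic_data import Implant

            syn["implants"] = tuple(
                Implant(**i) for i in syn["implants"]
            )
        raw["synthetic"] = SyntheticSpec(**syn)
    if "quantiles" in raw:
        raw["quantiles"] = tuple(raw["quantiles"])
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    config: PipelineConfig
    model_set: Any = None
    validation_report: pd.DataFrame | None = None
    data_drdms: dict | None = None
    glm_results: dict | None = None
    epoch_betas: dict | None = None
    observed_fits: dict | None = None
    nulls: dict | None = None
    thresholded: dict | None = None
    conservative_quantiles: dict | None = None
    counts: dict = field(default_factory=dict)


def _provenance(cfg: PipelineConfig) -> dict[str, Any]:
    return {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "package_version": ssrsa.__version__,
    }


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; persist artefacts under cfg.output_dir."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=cfg)
    t0 = time.time()

    fm: FeatureMatrix = (
        load_feature_matrix(cfg.feature_matrix_path)
        if cfg.feature_matrix_path
        else default_feature_matrix()
    )
    sl = cfg.searchlight
    onsets = sl.window_onsets

    stage = "build-models"
    try:
        if cfg.synthetic is not None:
            streams, _ = gen_likelihood_streams(cfg.synthetic)
            inventory = cfg.synthetic.inventory
        else:
            streams = load_likelihood_streams(cfg.streams_path)
            inventory = tuple(
                sorted({t.centre for t in streams.triphones})
            )
        model_set = build_model_set(
            streams, inventory, onsets, window_ms=sl.window_ms
        )
        result.model_set = model_set
        result.counts["phones_modelled"] = len(model_set.phones)
        result.counts["model_rdm_frames"] = model_set.total_frames
        save_model_set(model_set, out / "model_drdms.h5")
        logger.info(
            "%s: %d phones x %d windows = %d model RDM frames",
            stage,
            len(model_set.phones),
            model_set.n_windows,
            model_set.total_frames,
        )

        if cfg.run_validation:
            stage = "validate-features"
            report = feature_cluster_diagnostics(model_set, fm)
            result.validation_report = report
            report.to_csv(out / "feature_validation.csv", index=False)

        if cfg.model_only:
            _finish(out, cfg, result, t0)
            return result

        stage = "build-data-rdms"
        if cfg.synthetic is not None:
            epochs, mesh, _ = gen_source_epochs(cfg.synthetic, model_set)
        else:
            mesh, epochs = load_mesh_and_epochs(
                cfg.mesh_path, cfg.epochs_path
            )
        data_drdms = build_data_drdms(epochs, mesh, sl)
        result.data_drdms = data_drdms
        result.counts["masked_vertices"] = len(data_drdms)
        result.counts["data_rdms"] = len(data_drdms) * sl.n_windows
        save_data_drdms(data_drdms, out / "data_drdms.h5")

        stage = "fit"
        glm = fit_drdms(data_drdms, model_set)
        result.glm_results = glm
        epoch_betas = {v: epoch_average_betas(rs) for v, rs in glm.items()}
        result.epoch_betas = epoch_betas
        rows = [
            {"vertex_id": v, "window": "epoch", "phone": p, "beta": b,
             "residual_ss": r.residual_ss,
             "condition_number": r.condition_number}
            for v, r in epoch_betas.items()
            for p, b in r.betas.items()
        ]
        pd.DataFrame(rows).to_csv(out / "epoch_betas.csv", index=False)

        stage = "permtest"
        fits = observed_feature_fits(data_drdms, model_set, fm)
        result.observed_fits = fits
        nulls = build_null(
            data_drdms, model_set, fm, cfg.n_perm, cfg.seed
        )
        result.nulls = nulls
        result.counts["permutations"] = cfg.n_perm
        result.counts["null_pool_per_feature"] = cfg.n_perm * len(data_drdms)
        save_null_distributions(nulls, out / "null_distributions.h5")
        thresholded = {
            q: threshold_feature_maps(fits, nulls, q)
            for q in cfg.quantiles
        }
        result.thresholded = thresholded
        result.conservative_quantiles = most_conservative_quantiles(
            fits, nulls, cfg.quantiles
        )
        for q, maps in thresholded.items():
            feature_maps_to_frame(maps).to_csv(
                out / f"feature_maps_q{q}.tsv", sep="\t", index=False
            )
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    _finish(out, cfg, result, t0)
    return result


def _finish(
    out: Path, cfg: PipelineConfig, result: PipelineResult, t0: float
) -> None:
    report = _provenance(cfg)
    report["counts"] = result.counts
    report["elapsed_s"] = round(time.time() - t0, 2)
    if result.conservative_quantiles is not None:
        report["most_conservative_quantiles"] = {
            k: v for k, v in result.conservative_quantiles.items()
        }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    logger.info("pipeline finished in %.1fs", report["elapsed_s"])
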