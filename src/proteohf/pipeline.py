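"""End-to-end pipeline: simulate -> filter -> associate -> stability ->
interaction -> correlation, with deterministic text artifacts.

Every stage writes plain CSV plus a JSON manifest capturing the config
and seed, so a run can be reproduced bit-identically from the manifest
alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import associate_all, spearman_matrix
from .cohort import GeneratorConfig, generate_study, write_study
from .interaction import DEFAULT_INTERACTION_ALPHA, interaction_screen
from .stability import StabilityConfig, bootstrap_selection
from .studyio import filter_by_lod, load_study

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``generator`` is set (simulate mode) or all three input paths
    point at existing study tables.
    """

    outdir: str = "results/run"
    seed: int = 20260924
    generator: GeneratorConfig | None = None
    subject_path: str | None = None
    matrix_path: str | None = None
    meta_path: str | None = None
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    interaction_alpha: float = DEFAULT_INTERACTION_ALPHA
    max_below_lod_fraction: float = 0.80
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.generator is None and not (
            self.subject_path and self.matrix_path and self.meta_path
        ):
            # default to simulate mode with the study-sized generator
            self.generator = GeneratorConfig(seed=self.seed)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: dict[str, dict] = {}

    def record(name: str, path: Path, n_rows: int) -> None:
        # paths are stored relative to outdir so identically-configured
        # runs produce identical manifests wherever they land
        artifacts[name] = {
            "path": os.path.relpath(path, outdir),
            "rows": int(n_rows),
        }

    stage = "simulate"
    try:
        if config.generator is not None:
            cohort, matrix, meta, truth = generate_study(config.generator)
            paths = write_study(outdir / "study", cohort, matrix, meta, truth,
                                config.generator)
            subject_path = paths["subjects"]
            matrix_path = paths["matrix"]
            meta_path = paths["assay_meta"]
            record("truth", Path(paths["truth"]), len(truth))
        else:
            subject_path = config.subject_path
            matrix_path = config.matrix_path
            meta_path = config.meta_path

        stage = "ingest"
        study = load_study(subject_path, matrix_path, meta_path)
        record("subjects", Path(subject_path), len(study.subjects))

        stage = "lod_filter"
        filtered, exclusions = filter_by_lod(
            study.matrix, study.assay_meta, config.max_below_lod_fraction
        )
        _write_csv(exclusions, outdir / "lod_exclusions.csv")
        record("lod_exclusions", outdir / "lod_exclusions.csv", len(exclusions))
        logger.info("LOD filter: %d of %d assays excluded",
                    len(exclusions), study.matrix.shape[1])

        stage = "association"
        assoc = associate_all(study.subjects, filtered, study.assay_meta)
        _write_csv(assoc, outdir / "association.csv")
        record("association", outdir / "association.csv", len(assoc))

        stage = "stability"
        stab = bootstrap_selection(study.subjects, filtered, config.stability)
        _write_csv(stab, outdir / "stability.csv")
        record("stability", outdir / "stability.csv", len(stab))

        stage = "interaction"
        screened = stab.loc[stab["tier"] != "none", "assay"].tolist()
        if screened:
            inter = interaction_screen(
                study.subjects, filtered, screened, config.interaction_alpha
            )
        else:
            inter = pd.DataFrame(
                columns=["assay", "or_no_surgery", "p_no_surgery", "or_surgery",
                         "p_surgery", "p_interaction", "flagged", "estimable"]
            )
        _write_csv(inter, outdir / "interaction.csv")
        record("interaction", outdir / "interaction.csv", len(inter))

        stage = "correlation"
        major = stab.loc[stab["tier"] == "major", "assay"].tolist()
        if len(major) >= 2:
            rho = spearman_matrix(filtered[major])
        else:
            rho = pd.DataFrame(index=pd.Index(major, name="assay"), columns=major)
        rho.index.name = "assay"
        _write_csv(rho, outdir / "correlation_major.csv", index=True)
        record("correlation_major", outdir / "correlation_major.csv", len(rho))
    except Exception as exc:
        manifest = {
            "status": "failed",
            "stage": stage,
            "error": str(exc),
            "artifacts": artifacts,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    logger.info("pipeline complete in %.1f s", time.time() - t0)
    manifest = {
        "status": "complete",
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("log_level", None)
    d.pop("outdir", None)
    gen = d.get("generator")
    if gen is not None:
        for key in ("true_log_or", "interaction_log_or"):
            if gen.get(key) is not None:
                gen[key] = [float(v) for v in gen[key]]
        gen["correlation_block_spec"] = [list(b) for b in gen["correlation_block_spec"]]
    return d
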