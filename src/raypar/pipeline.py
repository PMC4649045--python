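"""End-to-end orchestration: simulate -> section -> quantify -> accuracy
-> stats, with every intermediate artifact written to disk and a manifest
of content hashes for reproducibility checks.

All randomness derives from one global seed through named substreams
(generation, per-section windows, bootstrap), so identical configurations
produce byte-identical artifacts and manifest hashes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as rio
from ._rng import child_seed
from .accuracy import PerparAccuracy, pool_windows, sample_windows
from .config import WoodModelConfig
from .metrics import assemble_time_series, compute_perpar, extract_outlines, ring_metrics
from .microtome import SectionSpec, cut_section
from .stats import coefficient_of_variation, mean_sensitivity, pearson_matrix
from .wood import generate_wood

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("raypar")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``sections`` are section specifications (dicts with SectionSpec
    fields); window/bootstrap settings drive the accuracy stage on the
    tangential sections.
    """

    wood: WoodModelConfig = field(default_factory=WoodModelConfig)
    sections: Sequence[dict] = field(
        default_factory=lambda: [{"plane": "cross"}, {"plane": "tangential"}, {"plane": "radial"}]
    )
    window_size: float = 1.0
    window_count: int = 1000
    bootstrap_sizes: Sequence[int] = tuple(range(1, 16))
    bootstrap_reps: int = 1000
    seed: int = 0
    out_dir: str = "raypar_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wood"] = self.wood.to_dict()
        d["bootstrap_sizes"] = list(self.bootstrap_sizes)
        d["sections"] = [dict(s) for s in self.sections]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "wood" in d:
            d["wood"] = WoodModelConfig.from_dict(d["wood"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _stage(name: str, path, fn):
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(f"stage {name!r} failed on {path}: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return a manifest (stage -> file -> sha256).

    Partial outputs are retained on failure; the raised error names the
    failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "files": {}}

    def record(stage: str, paths) -> None:
        for p in paths:
            p = Path(p)
            manifest["files"][str(p.relative_to(out))] = rio.file_sha256(p)
            log.info("%s: wrote %s (%s)", stage, p, manifest["files"][str(p.relative_to(out))][:12])

    # simulate ----------------------------------------------------------
    wood_cfg = config.wood.replace(rng_seed=child_seed(config.seed, "generate"))
    model = _stage("simulate", "config", lambda: generate_wood(wood_cfg))
    record("simulate", _stage("simulate", out / "model", lambda: rio.write_model(model, out / "model")))

    # section + quantify -------------------------------------------------
    images = []
    summaries = []
    for i, sdict in enumerate(config.sections):
        spec = SectionSpec(**dict(sdict))
        name = f"section_{i:02d}_{spec.plane}"
        image = _stage("section", name, lambda: cut_section(model, spec))
        images.append((name, spec, image))
        record("section", _stage("section", name, lambda: rio.write_section(image, out / "sections", name)))

        outlines = _stage("quantify", name, lambda: extract_outlines(image))
        if spec.plane == "cross":
            rings = _stage("quantify", name, lambda: ring_metrics(image, outlines))
            record("quantify", [rio.write_ring_metrics(rings, out / "metrics" / f"{name}_rings.csv")])
            series = assemble_time_series(rings, "perpar")
            summaries.append(
                {
                    "section": name,
                    "plane": spec.plane,
                    "perpar": compute_perpar(image),
                    "interannual_cv": coefficient_of_variation(series),
                    "mean_sensitivity_pct": mean_sensitivity(series) if np.all(series.values > 0) else np.nan,
                }
            )
        else:
            dims = outlines.loc[~outlines["touches_edge"]] if len(outlines) else outlines
            summaries.append(
                {
                    "section": name,
                    "plane": spec.plane,
                    "perpar": compute_perpar(image),
                    "mean_ray_area_um2": dims["area_um2"].mean() if len(dims) else np.nan,
                    "mean_ray_height_um": dims["height_um"].mean() if len(dims) else np.nan,
                    "mean_ray_width_um": dims["width_um"].mean() if len(dims) else np.nan,
                }
            )
        record("quantify", [rio.write_outlines(outlines, out / "metrics" / f"{name}_outlines.csv", name, spec.plane)])

    # accuracy ------------------------------------------------------------
    tangential = [(n, im) for n, sp, im in images if sp.plane == "tangential"]
    if tangential:
        pools = [
            sample_windows(im, config.window_size, config.window_count, seed=child_seed(config.seed, f"windows-{n}"))
            for n, im in tangential
        ]
        pool = pool_windows(pools)
        results = _stage(
            "accuracy",
            "windows",
            lambda: PerparAccuracy(pool, config.bootstrap_sizes, config.bootstrap_reps).fit(
                seed=child_seed(config.seed, "bootstrap")
            ),
        )
        record("accuracy", [rio.write_accuracy(results.summary(), out / "accuracy" / "accuracy_curve.csv")])
        pd.DataFrame({"perpar": pool.values}).to_csv(out / "accuracy" / "window_pool.csv", index=False)
        record("accuracy", [out / "accuracy" / "window_pool.csv"])

    # stats ----------------------------------------------------------------
    summary = pd.DataFrame(summaries)
    stats_path = out / "stats" / "section_summary.csv"
    stats_path.parent.mkdir(parents=True, exist_ok=True)
    summary.round(6).to_csv(stats_path, index=False)
    record("stats", [stats_path])
    numeric = summary.select_dtypes("number").dropna(axis=1, how="any")
    if len(numeric.dropna()) >= 3 and numeric.shape[1] >= 2:
        r, _p = pearson_matrix(numeric)
        corr_path = out / "stats" / "correlation_r.csv"
        r.round(6).to_csv(corr_path)
        record("stats", [corr_path])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
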