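"""End-to-end run: table in, optimized layout + images + metrics out.

Stages: optional top-variance selection / zero-padding to the grid size,
rank-matrix construction, layout optimization, rendering, export, and an
LH summary against random layouts.  Every run writes a JSON manifest
with the full configuration echo, the input checksum and the package
version, so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import TabularDataset
from .imaging import FeatureOrdering, export_images, normalize_features, render_images
from .metrics import layout_lh_summary
from .optimizer import IGTDConfig, igtd_optimize
from .ranking import (
    DistanceSpec,
    ImageGrid,
    feature_distance_rank_matrix,
    pad_or_trim_to_grid,
    pixel_distance_rank_matrix,
    select_top_variance_features,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised with the failing stage name when any stage errors out."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the reference run for 50x50 layouts."""

    input_path: str
    output_dir: str
    n_rows: int = 50
    n_cols: int = 50
    feature_metric: str = "euclidean"
    pixel_metric: str = "euclidean"
    ties: str = "average"
    diff_fn: str = "absolute"
    s_max: int = 30_000
    s_con: int = 500
    t_con: float = 1e-6
    t_swap: float = 0.0
    select_k: int | None = None
    allow_trim: bool = True
    ranking_normalization: str = "none"
    render_normalization: str = "minmax"
    export_format: str = "png8"
    lh_neighborhoods: tuple = (3,)
    n_random_layouts: int = 20
    random_layout_seed: int = 0
    invert_gray: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full transform; returns (and writes) the run manifest."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = ImageGrid(cfg.n_rows, cfg.n_cols)
    spec = DistanceSpec(cfg.feature_metric, cfg.pixel_metric, cfg.ties)

    try:
        data = TabularDataset.read_csv(cfg.input_path)
    except Exception as exc:
        raise PipelineError("read_input", exc) from exc

    try:
        if cfg.select_k is not None:
            data = select_top_variance_features(data, cfg.select_k)
        data = pad_or_trim_to_grid(data, grid, allow_trim=cfg.allow_trim)
    except Exception as exc:
        raise PipelineError("feature_selection", exc) from exc

    try:
        ranking_data = normalize_features(data, cfg.ranking_normalization) \
            if cfg.ranking_normalization != "none" else data
        R = feature_distance_rank_matrix(ranking_data, spec)
        Q = pixel_distance_rank_matrix(grid, spec)
    except Exception as exc:
        raise PipelineError("ranking", exc) from exc

    try:
        opt_cfg = IGTDConfig(cfg.s_max, cfg.s_con, cfg.t_con, cfg.t_swap, cfg.diff_fn)
        result = igtd_optimize(R, Q, opt_cfg)
    except Exception as exc:
        raise PipelineError("optimize", exc) from exc

    try:
        ordering = FeatureOrdering(result.ordering, grid)
        rendered_data = normalize_features(data, cfg.render_normalization)
        if cfg.invert_gray:
            rendered_data = TabularDataset(
                1.0 - rendered_data.values,
                sample_ids=list(rendered_data.sample_ids),
                feature_names=list(rendered_data.feature_names),
            )
        images = render_images(rendered_data, ordering)
    except Exception as exc:
        raise PipelineError("render", exc) from exc

    try:
        manifest_csv = export_images(images, outdir / "images", cfg.export_format)
        ordering_path = outdir / "ordering.csv"
        ordering.to_frame(data.feature_names).to_csv(ordering_path, index=False)
        trace_path = outdir / "error_trace.csv"
        pd.DataFrame({
            "iteration": np.arange(len(result.error_trace)),
            "error": result.error_trace,
        }).to_csv(trace_path, index=False)
    except Exception as exc:
        raise PipelineError("export", exc) from exc

    try:
        rng = np.random.default_rng(cfg.random_layout_seed)
        # only neighborhood sizes that fit the grid are summarized
        usable_ps = tuple(p for p in cfg.lh_neighborhoods
                          if p % 2 == 1 and p <= min(cfg.n_rows, cfg.n_cols))
        random_images = None
        if cfg.n_random_layouts > 0 and usable_ps:
            # mean LH over random layouts as a null reference for the optimized one
            lh_rows = []
            for _ in range(cfg.n_random_layouts):
                rand_ord = FeatureOrdering(rng.permutation(grid.size), grid)
                rand_imgs = render_images(rendered_data, rand_ord)
                lh_rows.append(layout_lh_summary(rand_imgs, usable_ps)
                               .assign(layout="random"))
            random_images = pd.concat(lh_rows)
        summary = layout_lh_summary(images, usable_ps).assign(layout="optimized")
        if random_images is not None:
            null = (random_images.groupby("p", as_index=False)["lh_mean"].mean()
                    .rename(columns={"lh_mean": "lh_mean_random"}))
            summary = summary.merge(null, on="p")
        lh_path = outdir / "lh_summary.csv"
        summary.to_csv(lh_path, index=False)
    except Exception as exc:
        raise PipelineError("metrics", exc) from exc

    manifest = {
        "config": asdict(cfg),
        "package_version": __version__,
        "input_sha256": _sha256(Path(cfg.input_path)),
        "n_samples": data.n_samples,
        "n_features": data.n_features,
        "initial_error": float(result.error_trace[0]),
        "final_error": float(result.error),
        "best_iteration": int(result.best_iteration),
        "n_iterations": int(result.n_iterations),
        "converged": bool(result.converged),
        "outputs": {
            "ordering": str(ordering_path),
            "error_trace": str(trace_path),
            "image_manifest": str(manifest_csv),
            "lh_summary": str(lh_path),
        },
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
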