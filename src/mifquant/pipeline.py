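"""Configuration and end-to-end pipeline orchestration.

A YAML run configuration is validated into a :class:`RunConfig`;
:func:`run_pipeline` then chains the stages

    simulate-images -> unmix -> segment -> score -> quantify -> cohort-stats

writing every intermediate artifact under the output directory and a JSON
manifest with per-stage runtimes, output checksums and cell counts.  One
global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed).generate_state(n_stages)`` (stage i uses
child state i, reduced mod 2**31), so any stage can be re-run in isolation
reproducibly and re-running an identical config reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import run_longitudinal_report
from .exceptions import ConfigError, StageError
from .images import (
    read_component_tiff,
    read_multispectral_tiff,
    write_component_tiff,
    write_multispectral_tiff,
)
from .panel import MarkerPanel, default_panel
from .scoring import (
    fit_panel_bounds,
    pooled_fractions,
    quantify,
    quantify_many,
    rescale,
    score_cells,
    suggest_threshold,
)
from .segment import LabelImage, compute_cell_stats, expand_cytoplasm, segment_nuclei
from .spectra import make_default_library
from .synth_cohort import CohortSimParams, simulate_cohort
from .synth_images import place_random_cells, render_tissue_image
from .unmix import unmix_pixelwise

STAGES = ("simulate_images", "unmix", "segment", "score", "quantify", "cohort_stats")


@dataclass
class ImageSimConfig:
    n_rois: int = 3
    roi_shape: tuple[int, int] = (256, 256)
    n_cells_min: int = 30
    n_cells_max: int = 60
    noise_sd: float = 0.02
    autofluorescence_level: float = 0.1
    calibrate_thresholds: bool = True


@dataclass
class StatsConfig:
    pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("crp", "weight"), ("il6", "weight"), ("cd8", "weight")]
    )
    n_boot: int = 500
    adjust: str = "sidak"
    alpha: float = 0.05


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    pixel_size: float = 0.496
    expansion_um: float = 2.0
    n_channels: int = 10
    roi_n_max: int = 10
    panel: MarkerPanel = field(default_factory=default_panel)
    images: ImageSimConfig = field(default_factory=ImageSimConfig)
    cohort: CohortSimParams = field(default_factory=CohortSimParams)
    stats: StatsConfig = field(default_factory=StatsConfig)


_TOP_KEYS = {"out_dir", "seed", "pixel_size", "expansion_um", "n_channels",
             "roi_n_max", "panel", "images", "stats", "cohort"}
_IMAGE_KEYS = {"n_rois", "roi_shape", "n_cells_min", "n_cells_max", "noise_sd",
               "autofluorescence_level", "calibrate_thresholds"}
_STATS_KEYS = {"pairs", "n_boot", "adjust", "alpha"}


def validate_config(config_file: str | Path) -> RunConfig:
    """Parse and range-check a YAML run configuration.

    Defaults follow the acquisition described for the panel: 0.496 um/pixel,
    2 um cytoplasm expansion, up to 10 ROIs, alpha 0.05.  All violations are
    collected and reported together in one :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(config_file).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    problems: list[str] = []

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    if "out_dir" not in raw:
        problems.append("out_dir is required")

    cfg = RunConfig(out_dir=Path(raw.get("out_dir", ".")))
    for key in ("seed", "pixel_size", "expansion_um", "n_channels", "roi_n_max"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if cfg.pixel_size <= 0:
        problems.append(f"pixel_size must be > 0, got {cfg.pixel_size}")
    if cfg.expansion_um <= 0:
        problems.append(f"expansion_um must be > 0, got {cfg.expansion_um}")
    if cfg.n_channels < 8:
        problems.append(f"n_channels must be >= 8, got {cfg.n_channels}")
    if cfg.roi_n_max < 1:
        problems.append(f"roi_n_max must be >= 1, got {cfg.roi_n_max}")

    if "panel" in raw and raw["panel"] is not None:
        try:
            cfg.panel = MarkerPanel.from_yaml(raw["panel"])
        except Exception as exc:
            problems.append(f"panel file invalid: {exc}")

    img_raw = raw.get("images", {}) or {}
    unknown = set(img_raw) - _IMAGE_KEYS
    if unknown:
        problems.append(f"unknown images keys: {sorted(unknown)}")
    for key, val in img_raw.items():
        if key in _IMAGE_KEYS:
            setattr(cfg.images, key, tuple(val) if key == "roi_shape" else val)
    if cfg.images.n_rois < 1:
        problems.append("images.n_rois must be >= 1")
    if cfg.images.n_cells_min > cfg.images.n_cells_max or cfg.images.n_cells_min < 0:
        problems.append("images.n_cells_min must be in [0, n_cells_max]")
    if cfg.images.noise_sd < 0:
        problems.append("images.noise_sd must be >= 0")

    stats_raw = raw.get("stats", {}) or {}
    unknown = set(stats_raw) - _STATS_KEYS
    if unknown:
        problems.append(f"unknown stats keys: {sorted(unknown)}")
    if "pairs" in stats_raw:
        try:
            cfg.stats.pairs = [tuple(p.split(":")) if isinstance(p, str) else tuple(p)
                               for p in stats_raw["pairs"]]
            if any(len(p) != 2 for p in cfg.stats.pairs):
                problems.append("each stats.pairs entry must be 'x:y'")
        except Exception:
            problems.append("stats.pairs must be a list of 'x:y' strings")
    for key in ("n_boot", "adjust", "alpha"):
        if key in stats_raw:
            setattr(cfg.stats, key, stats_raw[key])
    if cfg.stats.adjust not in ("sidak", "bh"):
        problems.append(f"stats.adjust must be 'sidak' or 'bh', got {cfg.stats.adjust!r}")
    if not 0 < cfg.stats.alpha < 1:
        problems.append("stats.alpha must lie in (0, 1)")
    if cfg.stats.n_boot < 0:
        problems.append("stats.n_boot must be >= 0")

    if "cohort" in raw and raw["cohort"]:
        try:
            cfg.cohort = CohortSimParams(**raw["cohort"])
        except TypeError as exc:
            problems.append(f"unknown cohort keys: {exc}")
        except Exception as exc:
            problems.append(f"cohort parameters invalid: {exc}")

    if problems:
        raise ConfigError("configuration invalid: " + "; ".join(problems))
    return cfg


def stage_seeds(seed: int, n: int = len(STAGES)) -> list[int]:
    """Fan one global seed out to per-stage child seeds (< 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) % (2**31) for s in state]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all six stages and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, stage_seeds(config.seed)))
    manifest: dict = {
        "package": "mifquant",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": [],
    }
    state: dict = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            info = _STAGE_FUNCS[stage](config, seeds[stage], out, state)
        except Exception as exc:
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(stage, str(exc)) from exc
        entry = {
            "name": stage,
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {
                str(p.relative_to(out)): _sha256(p) for p in sorted(info.get("outputs", []))
            },
        }
        entry.update({k: v for k, v in info.items() if k != "outputs"})
        manifest["stages"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# --- stage implementations --------------------------------------------------


def _stage_simulate_images(cfg: RunConfig, seed: int, out: Path, state: dict) -> dict:
    library = make_default_library(cfg.n_channels, seed=seed)
    lib_path = out / "library.csv"
    library.to_csv(lib_path)
    rng = np.random.default_rng(seed)
    outputs = [lib_path]
    rois = []
    for i in range(cfg.images.n_rois):
        n_cells = int(rng.integers(cfg.images.n_cells_min, cfg.images.n_cells_max + 1))
        roi_seed = int(rng.integers(0, 2**31))
        cells = place_random_cells(
            n_cells, cfg.images.roi_shape, cfg.pixel_size,
            expansion_um=cfg.expansion_um, panel=cfg.panel, seed=roi_seed,
        )
        image, truth = render_tissue_image(
            cells, library, cfg.images.roi_shape, cfg.pixel_size,
            autofluorescence_level=cfg.images.autofluorescence_level,
            noise_sd=cfg.images.noise_sd, expansion_um=cfg.expansion_um,
            panel=cfg.panel, seed=roi_seed + 1,
        )
        img_path = out / f"roi_{i:02d}.tif"
        truth_path = out / f"roi_{i:02d}_truth.csv"
        write_multispectral_tiff(img_path, image)
        truth.to_csv(truth_path, index=False)
        outputs += [img_path, truth_path, img_path.with_suffix(".tif.json")]
        rois.append(f"roi_{i:02d}")
    state["library"], state["rois"] = library, rois
    return {"outputs": outputs, "n_rois": len(rois)}


def _stage_unmix(cfg: RunConfig, seed: int, out: Path, state: dict) -> dict:
    outputs = []
    residuals = {}
    for roi in state["rois"]:
        image = read_multispectral_tiff(out / f"{roi}.tif")
        stack = unmix_pixelwise(image, state["library"])
        path = out / f"{roi}_components.tif"
        write_component_tiff(path, stack)
        outputs += [path, path.with_suffix(".tif.json")]
        residuals[roi] = stack.residual_norm
    state["residuals"] = residuals
    return {"outputs": outputs, "mean_residual_norm": float(np.mean(list(residuals.values())))}


def _stage_segment(cfg: RunConfig, seed: int, out: Path, state: dict) -> dict:
    outputs = []
    counts = {}
    state["cells"], state["nuclei"] = {}, {}
    for roi in state["rois"]:
        stack = read_component_tiff(out / f"{roi}_components.tif")
        nuclei = segment_nuclei(stack.plane("DAPI"), cfg.pixel_size)
        rings = expand_cytoplasm(nuclei, cfg.expansion_um)
        cells = compute_cell_stats(stack, nuclei, rings)
        path = out / f"{roi}_cells.csv"
        cells.to_csv(path, index=False)
        outputs.append(path)
        counts[roi] = nuclei.n_cells
        state["cells"][roi], state["nuclei"][roi] = cells, nuclei
    return {"outputs": outputs, "cell_counts": counts}


def _stage_score(cfg: RunConfig, seed: int, out: Path, state: dict) -> dict:
    pooled = pd.concat(state["cells"].values(), ignore_index=True)
    panel = fit_panel_bounds(cfg.panel, pooled)
    if cfg.images.calibrate_thresholds:
        for m in panel:
            col = f"{m.fluorophore}_{m.primary_compartment}_mean"
            norm = rescale(pooled[col].dropna().to_numpy(), m.p1, m.p99)
            m.threshold = suggest_threshold(norm, method="otsu").value
    panel_path = out / "panel_fitted.yaml"
    panel.to_yaml(panel_path)
    outputs = [panel_path]
    state["calls"] = {}
    for roi in state["rois"]:
        calls = score_cells(state["cells"][roi], panel)
        path = out / f"{roi}_calls.csv"
        calls.to_csv(path, index=False)
        outputs.append(path)
        state["calls"][roi] = calls
    return {"outputs": outputs}


def _stage_quantify(cfg: RunConfig, seed: int, out: Path, state: dict) -> dict:
    quants = [
        quantify(state["calls"][roi], state["nuclei"][roi], cfg.pixel_size, roi_id=roi)
        for roi in state["rois"]
    ]
    per_roi = quantify_many(quants)
    path = out / "quantification.csv"
    per_roi.to_csv(path, index=False)
    pooled_path = out / "pooled_fractions.json"
    pooled_path.write_text(json.dumps(pooled_fractions(quants), indent=2))
    return {"outputs": [path, pooled_path],
            "total_cells": int(per_roi["total_cells"].sum())}


def _stage_cohort_stats(cfg: RunConfig, seed: int, out: Path, state: dict) -> dict:
    table, truth = simulate_cohort(cfg.cohort, seed=seed)
    table_path = out / "cohort.csv"
    table.to_csv(table_path, index=False)
    truth_path = out / "cohort_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    report = run_longitudinal_report(
        table, pairs=cfg.stats.pairs, alpha=cfg.stats.alpha,
        adjust=cfg.stats.adjust, n_boot=cfg.stats.n_boot, seed=seed,
    )
    report_dir = out / "report"
    report.to_csv(report_dir)
    outputs = [table_path, truth_path] + sorted(report_dir.glob("*.csv"))
    return {"outputs": outputs, "n_subjects": int(table["subject_id"].nunique())}


_STAGE_FUNCS = {
    "simulate_images": _stage_simulate_images,
    "unmix": _stage_unmix,
    "segment": _stage_segment,
    "score": _stage_score,
    "quantify": _stage_quantify,
    "cohort_stats": _stage_cohort_stats,
}
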