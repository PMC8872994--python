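"""Percentile rescaling, threshold positivity scoring and density quantification.

Every marker's intensity is rescaled onto [0, 1] using the 1st and 99th
percentiles of that marker's intensities pooled over the *full dataset*, so
the same raw intensity maps to the same rescaled value in every image.  A
cell is positive for a marker when the rescaled mean intensity in the
marker's primary compartment reaches that marker's single dataset-wide
threshold.  Positive cells are then quantified per region of interest as a
count, a density in cells/mm^2, and a fraction of all segmented cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .exceptions import (
    DegenerateMarkerError,
    InvalidParameterError,
    SchemaError,
)
from .panel import MarkerPanel
from .segment import LabelImage

MIN_VALUES_FOR_BOUNDS = 100


def fit_rescale_bounds(values: np.ndarray) -> tuple[float, float]:
    """Empirical 1st and 99th percentiles (linear interpolation) of pooled values.

    Computed once over the entire dataset and stored in the panel so that the
    same intensity is represented with equal brightness in all images.
    """
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < MIN_VALUES_FOR_BOUNDS:
        raise InvalidParameterError(
            f"need >= {MIN_VALUES_FOR_BOUNDS} values to fit rescale bounds, got {vals.size}"
        )
    p1, p99 = np.percentile(vals, [1.0, 99.0])
    if not p1 < p99:
        raise DegenerateMarkerError("marker is constant: p1 == p99")
    return float(p1), float(p99)


def fit_panel_bounds(panel: MarkerPanel, cells: pd.DataFrame) -> MarkerPanel:
    """Fit p1/p99 for every marker from pooled per-cell compartment means.

    ``cells`` is the concatenation of cell-statistics tables over the whole
    dataset (all ROIs); bounds for each marker are fitted on the mean
    intensity in its primary compartment.
    """
    for m in panel:
        col = f"{m.fluorophore}_{m.primary_compartment}_mean"
        if col not in cells.columns:
            raise SchemaError(f"cell table lacks column {col!r} for marker {m.name}")
        m.p1, m.p99 = fit_rescale_bounds(cells[col].to_numpy())
    return panel


def rescale(intensity, p1: float, p99: float):
    """Map raw intensity to [0, 1]: ``(x - p1) / (p99 - p1)``, clipped."""
    if not p1 < p99:
        raise InvalidParameterError("p1 must be < p99")
    x = np.asarray(intensity, dtype=float)
    out = np.clip((x - p1) / (p99 - p1), 0.0, 1.0)
    return float(out) if np.isscalar(intensity) else out


@dataclass
class ThresholdSuggestion:
    """Advisory threshold from a calibration set; the panel value is authoritative."""

    value: float
    method: str
    fallback: bool = False  # True when the requested method degenerated to Otsu


def suggest_threshold(normalized_intensities: np.ndarray, method: str = "otsu") -> ThresholdSuggestion:
    """Suggest a positivity threshold from rescaled calibration intensities.

    ``otsu`` maximizes between-class variance of the empirical distribution;
    ``gmm2`` fits a two-component Gaussian mixture and returns the density
    crossing point between the component means.  Degenerate input (a
    single-mode mixture or a failed fit) falls back to Otsu with
    ``fallback=True``.
    """
    vals = np.asarray(normalized_intensities, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if np.unique(vals).size < 2:
        raise DegenerateMarkerError("calibration set has < 2 distinct values")
    if method not in ("otsu", "gmm2"):
        raise InvalidParameterError(f"unknown threshold method {method!r}")

    otsu_val = float(threshold_otsu(vals))
    if method == "otsu":
        return ThresholdSuggestion(_clip_open(otsu_val), "otsu")

    try:
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
        gm.fit(vals.reshape(-1, 1))
        mu = np.sort(gm.means_.ravel())
        if mu[1] - mu[0] < 1e-6:
            return ThresholdSuggestion(_clip_open(otsu_val), "otsu", fallback=True)
        # crossing point: where the two weighted component densities are equal
        from scipy.optimize import brentq
        from scipy.stats import norm

        order = np.argsort(gm.means_.ravel())
        w = gm.weights_.ravel()[order]
        s = np.sqrt(gm.covariances_.ravel()[order])

        def diff(x):
            return w[0] * norm.pdf(x, mu[0], s[0]) - w[1] * norm.pdf(x, mu[1], s[1])

        if np.sign(diff(mu[0])) == np.sign(diff(mu[1])):
            return ThresholdSuggestion(_clip_open(otsu_val), "otsu", fallback=True)
        t = brentq(diff, mu[0], mu[1])
        return ThresholdSuggestion(_clip_open(float(t)), "gmm2")
    except Exception:
        return ThresholdSuggestion(_clip_open(otsu_val), "otsu", fallback=True)


def _clip_open(t: float, eps: float = 1e-6) -> float:
    """Clamp a threshold into the open interval (0, 1)."""
    return float(min(max(t, eps), 1.0 - eps))


def score_cells(cells: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Call per-cell positivity for every panel marker.

    A cell is positive for marker ``m`` iff the rescaled mean intensity in
    ``m``'s primary compartment is >= the panel threshold.  Cells missing the
    primary compartment (fully clipped ring) are negative-by-missing and
    flagged in ``<marker>_missing``.
    """
    out = pd.DataFrame({"cell_id": cells["cell_id"].to_numpy()})
    for m in panel:
        if not m.fitted:
            raise InvalidParameterError(f"marker {m.name} has no fitted rescale bounds")
        col = f"{m.fluorophore}_{m.primary_compartment}_mean"
        if col not in cells.columns:
            raise SchemaError(f"cell table lacks column {col!r} required by marker {m.name}")
        raw = cells[col].to_numpy(dtype=float)
        missing = ~np.isfinite(raw)
        norm = rescale(np.where(missing, 0.0, raw), m.p1, m.p99)
        out[m.name] = (norm >= m.threshold) & ~missing
        out[f"{m.name}_missing"] = missing
    return out


@dataclass
class ROIQuantification:
    """Positive-cell counts, densities and fractions for one ROI."""

    roi_id: str
    area_mm2: float
    total_cells: int
    positive_cells: dict[str, int] = field(default_factory=dict)
    density_mm2: dict[str, float] = field(default_factory=dict)
    fraction_positive: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"roi_id": self.roi_id, "area_mm2": self.area_mm2, "total_cells": self.total_cells}
        for m in self.positive_cells:
            row[f"{m}_count"] = self.positive_cells[m]
            row[f"{m}_density_mm2"] = self.density_mm2[m]
            row[f"{m}_fraction"] = self.fraction_positive[m]
        return row


def quantify(
    calls: pd.DataFrame,
    labels: LabelImage,
    pixel_size: float | None = None,
    roi_id: str = "roi",
) -> ROIQuantification:
    """Quantify positive cells per unit area for one ROI.

    The ROI area is the full label-map extent (pixel count x pixel_size^2),
    reported in mm^2.  With zero segmented cells all counts and densities are
    zero and fractions are undefined (NaN).
    """
    px = labels.pixel_size if pixel_size is None else pixel_size
    h, w = labels.labels.shape
    area_mm2 = h * w * px**2 / 1e6
    total = int(len(calls))
    if total != labels.n_cells:
        raise InvalidParameterError(
            f"calls cover {total} cells but label map has {labels.n_cells}"
        )
    markers = [c for c in calls.columns if c != "cell_id" and not c.endswith("_missing")]
    q = ROIQuantification(roi_id=roi_id, area_mm2=area_mm2, total_cells=total)
    for m in markers:
        pos = int(calls[m].sum())
        q.positive_cells[m] = pos
        q.density_mm2[m] = pos / area_mm2
        q.fraction_positive[m] = pos / total if total > 0 else float("nan")
    return q


def quantify_many(quantifications: list[ROIQuantification]) -> pd.DataFrame:
    """Stack per-ROI quantifications into one table (one row per ROI)."""
    return pd.DataFrame([q.to_row() for q in quantifications])


def pooled_fractions(quantifications: list[ROIQuantification]) -> dict[str, float]:
    """Sample-level fractions: positive cells over all ROIs pooled.

    Complements the per-ROI fractions — the denominator is every segmented
    cell in the sample rather than in a single ROI.
    """
    total = sum(q.total_cells for q in quantifications)
    markers: dict[str, int] = {}
    for q in quantifications:
        for m, c in q.positive_cells.items():
            markers[m] = markers.get(m, 0) + c
    return {m: (c / total if total else float("nan")) for m, c in markers.items()}
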