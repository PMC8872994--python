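"""Linear spectral unmixing, tile stitching and ROI sampling.

Unmixing solves, for every pixel, the non-negative least-squares problem

    min_a || y - M a ||^2   subject to  a >= 0

where ``y`` is the observed C-channel spectrum and ``M`` the spectral
library (C channels x F components, autofluorescence included as an
ordinary column).  Non-negativity reflects that component abundances are
physical fluorophore quantities.  An unconstrained least-squares mode is
available for oracle comparisons.

The solver takes a fast path: the unconstrained solution is computed for all
pixels in one matrix product, and the exact active-set NNLS is run only for
pixels whose unconstrained optimum is infeasible (has a negative abundance).
Both paths yield the same optimum.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .exceptions import InvalidLibraryError, InvalidParameterError
from .images import ComponentStack, MultispectralImage
from .spectra import SpectralLibrary

_FEAS_TOL = 1e-10


def unmix_pixelwise(
    image: MultispectralImage,
    library: SpectralLibrary,
    method: str = "nnls",
) -> ComponentStack:
    """Unmix a multispectral image into per-component abundance planes.

    Parameters
    ----------
    image : MultispectralImage
        ``H x W x C`` non-negative intensities.
    library : SpectralLibrary
        The unmixing design matrix; channel count must match the image.
    method : {"nnls", "ols"}
        ``"nnls"`` (default) constrains abundances to be non-negative;
        ``"ols"`` solves the unconstrained problem (may go negative) and is
        intended only for oracle comparisons.
    """
    if method not in ("nnls", "ols"):
        raise InvalidParameterError(f"unknown unmixing method {method!r}")
    A = library.matrix
    c, f = A.shape
    if image.n_channels != c:
        raise ValueError(
            f"image has {image.n_channels} channels but library expects {c}"
        )
    if np.linalg.matrix_rank(A) < f:
        raise InvalidLibraryError("library matrix is rank-deficient")

    h, w = image.shape
    Y = image.pixels.reshape(-1, c)
    pinv = np.linalg.pinv(A)
    X = Y @ pinv.T  # unconstrained solution for every pixel

    if method == "nnls":
        scale = max(float(np.abs(Y).max()), 1.0)
        tol = _FEAS_TOL * scale
        infeasible = np.flatnonzero(X.min(axis=1) < -tol)
        for i in infeasible:
            X[i], _ = _scipy_nnls(A, Y[i])
        np.clip(X, 0.0, None, out=X)

    residual = Y - X @ A.T
    res_norm = float(np.sqrt((residual**2).sum(axis=1)).mean())
    planes = X.T.reshape(f, h, w)
    return ComponentStack(planes, image.pixel_size, list(library.component_names), res_norm)


def stitch_tiles(
    tiles: list[list[MultispectralImage]],
    layout: tuple[int, int] | None = None,
) -> MultispectralImage:
    """Abutting row-major concatenation of a fully populated tile grid.

    No blending and no overlap model: tiles are assumed to partition the
    stitched field, as for export from a multispectral scanner that acquires
    a region as a grid (typically 3 x 3 = nine tiles per region).
    """
    if not tiles or not all(row for row in tiles):
        raise InvalidParameterError("tile grid must be non-empty and fully populated")
    n_rows, n_cols = len(tiles), len(tiles[0])
    if layout is not None and layout != (n_rows, n_cols):
        raise InvalidParameterError(f"layout {layout} does not match grid {(n_rows, n_cols)}")
    if any(len(row) != n_cols for row in tiles):
        raise ValueError("ragged tile grid: rows have differing lengths")

    first = tiles[0][0]
    for row in tiles:
        for t in row:
            if t.n_channels != first.n_channels:
                raise ValueError("all tiles must share the channel count")
            if t.pixel_size != first.pixel_size:
                raise ValueError("all tiles must share the pixel size")
    # shape consistency: heights match within a row, widths within a column
    for r, row in enumerate(tiles):
        heights = {t.pixels.shape[0] for t in row}
        if len(heights) > 1:
            raise ValueError(f"tiles in row {r} have mismatched heights {sorted(heights)}")
    for j in range(n_cols):
        widths = {tiles[r][j].pixels.shape[1] for r in range(n_rows)}
        if len(widths) > 1:
            raise ValueError(f"tiles in column {j} have mismatched widths {sorted(widths)}")

    stitched = np.concatenate(
        [np.concatenate([t.pixels for t in row], axis=1) for row in tiles], axis=0
    )
    return MultispectralImage(stitched, first.pixel_size, first.channel_names)


def sample_rois(
    overview_shape: tuple[int, int],
    roi_shape: tuple[int, int],
    n_max: int = 10,
    mask: np.ndarray | None = None,
    seed: int = 0,
) -> list[tuple[int, int, int, int]]:
    """Randomly sample up to ``n_max`` non-overlapping ROI rectangles.

    Emulates random region-of-interest sampling from a low-resolution slide
    overview: axis-aligned ``roi_shape`` rectangles are drawn uniformly among
    positions whose area is at least 50% inside the foreground mask (when a
    mask is given) and that do not overlap previously accepted ROIs.

    Returns a list of ``(row0, col0, height, width)`` tuples; fewer than
    ``n_max`` are returned when no more non-overlapping positions can be
    found.  Deterministic for a fixed seed.
    """
    H, W = overview_shape
    h, w = roi_shape
    if n_max < 1:
        raise InvalidParameterError("n_max must be >= 1")
    if h > H or w > W or h < 1 or w < 1:
        raise InvalidParameterError(
            f"roi shape {roi_shape} does not fit inside overview {overview_shape}"
        )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (H, W):
            raise InvalidParameterError("mask shape must equal overview_shape")
        # 50%-inside criterion via an integral image over the mask
        integral = np.pad(mask.astype(np.int64).cumsum(0).cumsum(1), ((1, 0), (1, 0)))

    rng = np.random.default_rng(seed)
    accepted: list[tuple[int, int, int, int]] = []
    attempts = 0
    max_attempts = 2000 * n_max
    while len(accepted) < n_max and attempts < max_attempts:
        attempts += 1
        r0 = int(rng.integers(0, H - h + 1))
        c0 = int(rng.integers(0, W - w + 1))
        if mask is not None:
            inside = (
                integral[r0 + h, c0 + w]
                - integral[r0, c0 + w]
                - integral[r0 + h, c0]
                + integral[r0, c0]
            )
            if inside < 0.5 * h * w:
                continue
        if any(r0 < ar + ah and ar < r0 + h and c0 < ac + aw and ac < c0 + w
               for ar, ac, ah, aw in accepted):
            continue
        accepted.append((r0, c0, h, w))
    return accepted
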