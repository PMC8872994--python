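"""Spectral libraries for linear unmixing.

A spectral library is the design matrix of the unmixing problem: one column
per fluorescent component (six marker fluorophores, the DAPI counterstain and
tissue autofluorescence), one row per acquisition channel.  Columns are
unit-normalized (they sum to 1) so abundances carry the brightness.

Libraries are built either synthetically (:func:`make_default_library`) or
from single-stain reference slides (:func:`extract_spectrum`), mirroring how
a library is assembled on a real multispectral imaging system: one
single-stained slide per fluorophore, a DAPI-only slide, and an unstained
slide for the autofluorescence signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateSpectrumError, InvalidLibraryError, InvalidParameterError
from .images import MultispectralImage

#: Canonical component order: DAPI first, marker fluorophores, autofluorescence last.
DEFAULT_COMPONENT_NAMES = [
    "DAPI",
    "Opal520",
    "Opal540",
    "Opal570",
    "Opal620",
    "Opal650",
    "Opal690",
    "AF",
]

_COND_LIMIT = 1e8  # beyond this the design matrix is numerically rank-deficient


@dataclass
class FluorophoreSpectrum:
    """A single emission signature over C acquisition channels, summing to 1."""

    name: str
    emission: np.ndarray

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=float)
        if self.emission.ndim != 1:
            raise InvalidParameterError("emission must be a 1-D vector")
        if np.any(self.emission < 0):
            raise InvalidParameterError("emission weights must be non-negative")
        total = self.emission.sum()
        if total <= 0:
            raise DegenerateSpectrumError(f"spectrum {self.name!r} has zero total emission")
        self.emission = self.emission / total


@dataclass
class SpectralLibrary:
    """Unmixing design matrix: ``C channels x F components``, unit columns."""

    matrix: np.ndarray
    component_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise InvalidLibraryError("library matrix must be 2-D (channels x components)")
        c, f = self.matrix.shape
        if len(self.component_names) != f:
            raise InvalidLibraryError("one name per component column required")
        if np.any(self.matrix < 0):
            raise InvalidLibraryError("library entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if np.any(sums <= 0):
            raise InvalidLibraryError("every component column needs positive total emission")
        self.matrix = self.matrix / sums  # enforce unit normalization
        if c < f or self.condition_number > _COND_LIMIT:
            raise InvalidLibraryError(
                f"library is rank-deficient: {f} components in {c} channels "
                f"(condition number {self.condition_number:.3g})"
            )

    @classmethod
    def from_spectra(cls, spectra: list[FluorophoreSpectrum]) -> "SpectralLibrary":
        return cls(np.column_stack([s.emission for s in spectra]), [s.name for s in spectra])

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_components(self) -> int:
        return self.matrix.shape[1]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.component_names.index(name)]

    def to_csv(self, path: str | Path) -> None:
        """Serialize as CSV: rows = channels, columns = components."""
        df = pd.DataFrame(
            self.matrix,
            index=[f"channel_{i}" for i in range(self.n_channels)],
            columns=self.component_names,
        )
        df.to_csv(path, index_label="channel")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralLibrary":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns))


def make_default_library(
    n_channels: int = 10,
    seed: int = 0,
    component_names: list[str] | None = None,
) -> SpectralLibrary:
    """Build a synthetic 8-component spectral library.

    Seven dye signatures (DAPI plus six marker fluorophores) are modelled as
    Gaussian emission peaks at staggered channel positions with seeded jitter;
    tissue autofluorescence is a broad, slowly decaying signature spanning all
    channels.  Columns are unit-normalized and pairwise linearly independent.

    Parameters
    ----------
    n_channels : int
        Number of acquisition channels; must be >= 8 so that all eight
        components can be linearly independent.
    seed : int
        Seed for the peak-position/width jitter; identical seeds give
        bit-identical libraries.
    """
    names = list(component_names) if component_names is not None else list(DEFAULT_COMPONENT_NAMES)
    n_dyes = len(names) - 1  # all but the trailing autofluorescence entry
    if n_channels < len(names):
        raise InvalidParameterError(
            f"{len(names)} components cannot be linearly independent in "
            f"{n_channels} channels; need n_channels >= {len(names)}"
        )
    rng = np.random.default_rng(seed)
    idx = np.arange(n_channels, dtype=float)
    centers = np.linspace(0.3, n_channels - 1.3, n_dyes) + rng.uniform(-0.15, 0.15, n_dyes)
    widths = 0.75 + rng.uniform(0.0, 0.25, n_dyes)
    cols = [np.exp(-0.5 * ((idx - c) / w) ** 2) for c, w in zip(centers, widths)]
    # autofluorescence: broad exponential decay across the channel range
    af = np.exp(-idx / (0.8 * n_channels)) + 0.15
    cols.append(af)
    return SpectralLibrary(np.column_stack(cols), names)


def extract_spectrum(
    reference_image: MultispectralImage,
    background_image: MultispectralImage | None = None,
    top_fraction: float = 0.05,
    name: str = "extracted",
) -> FluorophoreSpectrum:
    """Estimate a fluorophore signature from a single-stain reference slide.

    The spectrum is the mean over the brightest ``top_fraction`` of pixels
    ranked by total channel sum, optionally background-corrected by
    subtracting the per-channel mean of ``background_image`` (an unstained
    slide), floored at zero, and unit-normalized.
    """
    if not 0 < top_fraction <= 1:
        raise InvalidParameterError("top_fraction must be in (0, 1]")
    pixels = reference_image.pixels.reshape(-1, reference_image.n_channels)
    totals = pixels.sum(axis=1)
    if totals.sum() <= 0:
        raise DegenerateSpectrumError("reference image has no signal")
    cutoff = np.quantile(totals, 1.0 - top_fraction)
    bright = pixels[totals >= cutoff]
    spectrum = bright.mean(axis=0)
    if background_image is not None:
        bg = background_image.pixels.reshape(-1, background_image.n_channels).mean(axis=0)
        spectrum = spectrum - bg
    spectrum = np.clip(spectrum, 0.0, None)
    if spectrum.sum() <= 0:
        raise DegenerateSpectrumError("background subtraction removed all signal")
    return FluorophoreSpectrum(name, spectrum)
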