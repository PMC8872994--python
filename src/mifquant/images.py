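"""In-memory containers and text-friendly I/O for multispectral image data.

A :class:`MultispectralImage` holds raw acquisition data as an ``H x W x C``
array of non-negative intensities together with the physical pixel size in
micrometres.  A :class:`ComponentStack` holds the result of spectral
unmixing: one abundance plane per library component (``F x H x W``).

Images are written as multichannel TIFF with a JSON sidecar recording the
channel/component names and pixel size, so that round-tripping through disk
loses no metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class MultispectralImage:
    """Raw multispectral pixels, ``H x W x C``, with pixel size in um/pixel."""

    pixels: np.ndarray
    pixel_size: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError(f"expected H x W x C array, got shape {self.pixels.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class ComponentStack:
    """Per-component abundance planes (``F x H x W``) from spectral unmixing.

    ``residual_norm`` is the mean per-pixel Euclidean norm of the unmixing
    residual over the tile, reported for QC.
    """

    planes: np.ndarray
    pixel_size: float
    component_names: list[str]
    residual_norm: float | None = None

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3:
            raise ValueError(f"expected F x H x W array, got shape {self.planes.shape}")
        if len(self.component_names) != self.planes.shape[0]:
            raise ValueError("one name per plane required")

    def plane(self, name: str) -> np.ndarray:
        """Return the abundance plane for a named component."""
        try:
            idx = self.component_names.index(name)
        except ValueError:
            raise KeyError(f"no component named {name!r}; have {self.component_names}")
        return self.planes[idx]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_multispectral_tiff(path: str | Path, image: MultispectralImage) -> None:
    """Write an image as a multichannel TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    # channel-first layout on disk (C x H x W), conventional for component TIFFs
    tifffile.imwrite(path, np.moveaxis(image.pixels, -1, 0).astype(np.float32))
    meta = {
        "kind": "multispectral",
        "pixel_size_um": image.pixel_size,
        "channel_names": image.channel_names,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_multispectral_tiff(path: str | Path) -> MultispectralImage:
    path = Path(path)
    arr = np.moveaxis(tifffile.imread(path), 0, -1).astype(float)
    meta = json.loads(_sidecar_path(path).read_text())
    return MultispectralImage(arr, meta["pixel_size_um"], meta.get("channel_names"))


def write_component_tiff(path: str | Path, stack: ComponentStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.planes.astype(np.float32))
    meta = {
        "kind": "components",
        "pixel_size_um": stack.pixel_size,
        "component_names": stack.component_names,
        "residual_norm": stack.residual_norm,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_component_tiff(path: str | Path) -> ComponentStack:
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar_path(path).read_text())
    return ComponentStack(
        arr, meta["pixel_size_um"], meta["component_names"], meta.get("residual_norm")
    )
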