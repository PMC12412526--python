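"""Shared containers, coordinate conventions, and map file I/O.

Coordinate conventions used package-wide
----------------------------------------
* Images are row-major :class:`numpy.ndarray` indexed ``[row, col]``,
  0-based.
* En-face maps: ``row`` is the slow scan axis (y, anterior→posterior of the
  larva mounted sideways maps onto columns in our phantoms; see
  :mod:`vesselquant.synthvasc`), ``col`` is the fast scan axis (x).
* B-scans are indexed ``[z (depth), x (fast axis)]``.
* Regions of interest are half-open rectangles: rows ``r0 <= r < r1``,
  columns ``c0 <= c < c1``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ROI", "EnFaceMap", "write_map_tiff", "read_map_tiff"]

#: allowed channel tags for en-face maps
CHANNELS = ("flow", "structure", "merged")


@dataclass(frozen=True)
class ROI:
    """Half-open rectangular region of interest (rows [r0, r1), cols [c0, c1))."""

    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 and self.c0 < self.c1):
            raise ValueError(f"empty or inverted ROI: {self}")
        if min(self.r0, self.c0) < 0:
            raise ValueError(f"negative ROI bounds: {self}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r1), slice(self.c0, self.c1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.r1 - self.r0, self.c1 - self.c0)

    @property
    def area_px(self) -> int:
        return (self.r1 - self.r0) * (self.c1 - self.c0)

    def fits(self, shape: tuple[int, int]) -> bool:
        return self.r1 <= shape[0] and self.c1 <= shape[1]

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (N, 2) array of (row, col) points."""
        p = np.asarray(points, dtype=float)
        return (
            (p[:, 0] >= self.r0)
            & (p[:, 0] < self.r1)
            & (p[:, 1] >= self.c0)
            & (p[:, 1] < self.c1)
        )


@dataclass
class EnFaceMap:
    """2-D non-negative grayscale en-face map with physical pixel pitch.

    ``channel`` is one of ``"flow"`` (OCTA), ``"structure"`` (GFP) or
    ``"merged"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "flow"
    roi: ROI | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("EnFaceMap.pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("EnFaceMap.pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("EnFaceMap.pixels must be non-negative")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.roi is not None and not self.roi.fits(self.pixels.shape):
            raise ValueError("ROI exceeds image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def full_roi(self) -> ROI:
        return ROI(0, self.pixels.shape[0], 0, self.pixels.shape[1])

    def view_roi(self) -> np.ndarray:
        roi = self.roi or self.full_roi()
        return self.pixels[roi.slices]

    def normalized(self) -> "EnFaceMap":
        """Copy scaled to [0, 1] (identity for an all-zero map)."""
        mx = float(self.pixels.max())
        px = self.pixels / mx if mx > 0 else self.pixels.copy()
        return EnFaceMap(px, self.pixel_size_um, self.channel, self.roi)


def write_map_tiff(m: EnFaceMap, path: str | Path, sidecar: dict | None = None) -> None:
    """Write a map as 16-bit grayscale TIFF plus a JSON sidecar.

    Pixel values are scaled so the map maximum hits 65535; the scale factor
    and pixel pitch are stored in ``<path>.json`` for lossless-enough
    round-tripping of normalized maps.
    """
    path = Path(path)
    mx = float(m.pixels.max())
    scale = 65535.0 / mx if mx > 0 else 1.0
    data = np.round(m.pixels * scale).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "scale": scale,
        "pixel_size_um": m.pixel_size_um,
        "channel": m.channel,
        "roi": dataclasses.asdict(m.roi) if m.roi else None,
    }
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_map_tiff(
    path: str | Path,
    pixel_size_um: float | None = None,
    channel: str | None = None,
) -> EnFaceMap:
    """Read a TIFF/PNG map; uses the JSON sidecar when present."""
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta_path = Path(str(path) + ".json")
    scale, roi = 1.0, None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        scale = meta.get("scale", 1.0)
        pixel_size_um = pixel_size_um or meta.get("pixel_size_um")
        channel = channel or meta.get("channel")
        if meta.get("roi"):
            roi = ROI(**meta["roi"])
    return EnFaceMap(data / scale, pixel_size_um or 1.0, channel or "flow", roi)
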