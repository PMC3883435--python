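"""Plate-image reading and per-well total RGB quantification.

This re-implements the scanned-plate color quantification step: for every
mapped well, sum each of the red, green, and blue channel values over all
pixels in a fixed region of interest centered on the well.  The sums are
exact integer totals — no background subtraction or white-balance is
applied, because the downstream control-vs-analyte differencing is itself
the normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, GeometryError
from .plate import PlateLayout, RoiSpec, WellAddress

log = logging.getLogger(__name__)


@dataclass
class PlateImage:
    """RGB raster of a scanned plate at native bit depth (8 or 16)."""

    pixels: np.ndarray  # H x W x 3, uint8 or uint16, channel order R,G,B
    bit_depth: int

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(f"pixels must be HxWx3, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit depth must be 8 or 16, got {self.bit_depth}")

    @property
    def channel_max(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def rescaled_to_8bit(self) -> "PlateImage":
        """Right-shift 16-bit data to the 8-bit scale the default threshold assumes."""
        if self.bit_depth == 8:
            return self
        return PlateImage((self.pixels >> 8).astype(np.uint8), 8)


@dataclass(frozen=True)
class WellColorValue:
    """Exact per-well channel totals over the ROI, plus the pixel count."""

    addr: WellAddress
    red_total: int
    green_total: int
    blue_total: int
    pixel_count: int

    def total(self, channel: str) -> int:
        return {"R": self.red_total, "G": self.green_total, "B": self.blue_total}[channel]


def read_image(path, rescale_8bit: bool = False) -> PlateImage:
    """Read a PNG or TIFF plate scan as an RGB :class:`PlateImage`.

    RGBA input has its alpha channel dropped (with a log warning); 16-bit
    data is kept at native depth unless ``rescale_8bit`` is set.  Grayscale
    images are rejected: channel totals are meaningless without color.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"image file not found: {p}")
    arr = iio.imread(p)
    if arr.ndim == 2:
        raise FormatError(f"grayscale image not supported (mode L): {p}")
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise FormatError(f"unsupported image layout with shape {arr.shape}: {p}")
    if arr.shape[2] == 4:
        log.warning("dropping alpha channel of %s", p)
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"unsupported pixel dtype {arr.dtype} (mode must be 8- or 16-bit RGB)")
    img = PlateImage(arr, depth)
    return img.rescaled_to_8bit() if rescale_8bit else img


def write_image(path, img: PlateImage) -> None:
    iio.imwrite(Path(path), img.pixels)


def roi_offsets(roi: RoiSpec) -> np.ndarray:
    """Integer (dy, dx) offsets of all pixels in the ROI around a grid-aligned center.

    Disk rule: pixel center within Euclidean distance <= radius.
    Square rule: both |dx| and |dy| <= half-width.
    """
    r = int(np.floor(roi.size))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    if roi.shape == "disk":
        mask = dx * dx + dy * dy <= roi.size * roi.size
    else:
        mask = (np.abs(dx) <= roi.size) & (np.abs(dy) <= roi.size)
    return np.stack([dy[mask], dx[mask]], axis=1)


def roi_pixel_count(roi: RoiSpec) -> int:
    """Number of pixels in the ROI (317 for the default radius-10 disk)."""
    return len(roi_offsets(roi))


def roi_mask_indices(roi: RoiSpec, center_x: float, center_y: float) -> tuple:
    """(rows, cols) integer pixel indices of the ROI at an arbitrary center.

    Pixel (i, j) has its center at x = j, y = i; membership follows the
    same distance rule as :func:`roi_offsets`.
    """
    r = roi.size
    j0, j1 = int(np.floor(center_x - r)), int(np.ceil(center_x + r))
    i0, i1 = int(np.floor(center_y - r)), int(np.ceil(center_y + r))
    ii, jj = np.mgrid[i0 : i1 + 1, j0 : j1 + 1]
    if roi.shape == "disk":
        mask = (jj - center_x) ** 2 + (ii - center_y) ** 2 <= r * r
    else:
        mask = (np.abs(jj - center_x) <= r) & (np.abs(ii - center_y) <= r)
    return ii[mask], jj[mask]


def extract_well_totals(img: PlateImage, layout: PlateLayout) -> list:
    """Exact integer R/G/B sums over each mapped well's ROI.

    Deterministic; raises :class:`GeometryError` naming the first well whose
    ROI extends past the image edge.
    """
    h, w, _ = img.pixels.shape
    out = []
    for addr in sorted(layout.well_map):
        cx, cy = layout.well_center(addr)
        rows, cols = roi_mask_indices(layout.roi, cx, cy)
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
            raise GeometryError(
                f"ROI of well {addr} (center {cx},{cy}, size {layout.roi.size}) "
                f"exceeds image bounds {w}x{h}"
            )
        px = img.pixels[rows, cols].astype(np.int64)
        sums = px.sum(axis=0)
        out.append(
            WellColorValue(
                addr=addr,
                red_total=int(sums[0]),
                green_total=int(sums[1]),
                blue_total=int(sums[2]),
                pixel_count=len(rows),
            )
        )
    return out


def totals_to_frame(totals, layout: PlateLayout):
    """Well totals as a DataFrame with the documented well_totals.csv columns."""
    import pandas as pd

    rows = []
    for t in totals:
        a = layout.well_map[t.addr]
        rows.append(
            {
                "well": str(t.addr),
                "row": t.addr.row,
                "col": t.addr.col,
                "sensor": a.sensor,
                "condition": a.condition,
                "role": a.role,
                "pair": a.pair,
                "red_total": t.red_total,
                "green_total": t.green_total,
                "blue_total": t.blue_total,
                "pixel_count": t.pixel_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "well", "row", "col", "sensor", "condition", "role", "pair",
            "red_total", "green_total", "blue_total", "pixel_count",
        ],
    )


def totals_from_frame(df, layout: PlateLayout) -> list:
    """Inverse of :func:`totals_to_frame` (layout supplies the semantics)."""
    return [
        WellColorValue(
            addr=WellAddress.parse(r["well"]),
            red_total=int(r["red_total"]),
            green_total=int(r["green_total"]),
            blue_total=int(r["blue_total"]),
            pixel_count=int(r["pixel_count"]),
        )
        for _, r in df.iterrows()
    ]
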