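"""Single-ion images from pixel-indexed spectra and ROI statistics.

Pixel coordinates are 0-based, row-major, origin at the top-left.  A
single-ion image sums, per pixel, the intensities of peaks within a ppm
window around a target m/z; region-of-interest statistics are arithmetic
means over rectangular pixel blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DataError

__all__ = [
    "IonImage",
    "RoiSpec",
    "build_ion_image",
    "roi_mean",
    "roi_pixels",
    "overlay_channels",
    "write_image_csv",
    "read_image_csv",
    "read_pixel_grid",
]


@dataclass
class IonImage:
    """A single-ion intensity grid; ``intensities`` has shape (height, width)."""

    width: int
    height: int
    pixel_size_um: float
    center_mz: float
    tolerance_ppm: float
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.width < 1 or self.height < 1:
            raise DataError("image dimensions must be positive")
        if self.intensities.shape != (self.height, self.width):
            raise DataError(
                f"intensity grid {self.intensities.shape} does not match "
                f"(height, width) = ({self.height}, {self.width})"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise DataError("image intensities must be finite")


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest: origin (x, y), size (w, h), in pixels."""

    origin: tuple[int, int]
    size: tuple[int, int]
    label: str = ""

    def bounds_check(self, image: IonImage) -> None:
        x, y = self.origin
        w, h = self.size
        if w < 1 or h < 1:
            raise DataError(f"ROI {self.label!r} has non-positive size {self.size}")
        if x < 0 or y < 0 or x + w > image.width or y + h > image.height:
            raise DataError(
                f"ROI {self.label!r} at {self.origin} size {self.size} exceeds "
                f"image bounds {image.width}x{image.height}"
            )


def build_ion_image(
    pixel_spectra: list[list[tuple[np.ndarray, np.ndarray]]],
    center_mz: float,
    tolerance_ppm: float,
    pixel_size_um: float = 3.0,
) -> IonImage:
    """Sum in-window peak intensities per pixel into a single-ion image.

    ``pixel_spectra`` is a row-major grid: ``pixel_spectra[y][x]`` is a
    (mz, intensity) pair of arrays for the pixel at (x, y).
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    if not pixel_spectra or not pixel_spectra[0]:
        raise DataError("empty pixel grid")
    height = len(pixel_spectra)
    width = len(pixel_spectra[0])
    if any(len(row) != width for row in pixel_spectra):
        raise DataError("ragged pixel grid")
    half_window = center_mz * tolerance_ppm * 1e-6
    grid = np.zeros((height, width))
    for y, row in enumerate(pixel_spectra):
        for x, (mz, inten) in enumerate(row):
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            in_window = np.abs(mz - center_mz) <= half_window
            grid[y, x] = inten[in_window].sum()
    return IonImage(width, height, pixel_size_um, center_mz, tolerance_ppm, grid)


def roi_pixels(image: IonImage, roi: RoiSpec) -> np.ndarray:
    """The ROI's pixel values as a (h, w) block."""
    roi.bounds_check(image)
    x, y = roi.origin
    w, h = roi.size
    return image.intensities[y : y + h, x : x + w]


def roi_mean(image: IonImage, roi: RoiSpec) -> float:
    """Arithmetic mean intensity over the ROI pixels."""
    return float(roi_pixels(image, roi).mean())


def overlay_channels(*images: IonImage) -> np.ndarray:
    """Per-channel max-normalized grids stacked along the last axis.

    The overlay composite for plotting: each channel is divided by its own
    maximum (all-zero channels stay zero).
    """
    if not images:
        raise DataError("no channels given")
    shape = images[0].intensities.shape
    channels = []
    for img in images:
        if img.intensities.shape != shape:
            raise DataError("overlay channels must share dimensions")
        peak = img.intensities.max()
        channels.append(img.intensities / peak if peak > 0 else img.intensities)
    return np.stack(channels, axis=-1)


def write_image_csv(image: IonImage, path: str | Path) -> None:
    header = (
        f"# width={image.width} height={image.height} "
        f"pixel_size_um={float(image.pixel_size_um)!r} "
        f"center_mz={float(image.center_mz)!r} "
        f"tolerance_ppm={float(image.tolerance_ppm)!r}"
    )
    with Path(path).open("w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, image.intensities, delimiter=",")


def read_image_csv(path: str | Path) -> IonImage:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise DataError(f"{path}: missing image header line")
        meta = dict(kv.split("=") for kv in header[1:].split())
        grid = np.loadtxt(fh, delimiter=",", ndmin=2)
    return IonImage(
        int(meta["width"]),
        int(meta["height"]),
        float(meta["pixel_size_um"]),
        float(meta["center_mz"]),
        float(meta["tolerance_ppm"]),
        grid,
    )


def read_pixel_grid(index_path: str | Path) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Read a directory of per-pixel peak lists via an (x, y, path) index TSV."""
    index_path = Path(index_path)
    index = pd.read_csv(index_path, sep="\t")
    required = {"x", "y", "path"}
    if not required.issubset(index.columns):
        raise DataError(f"{index_path}: pixel index needs columns {sorted(required)}")
    width = int(index["x"].max()) + 1
    height = int(index["y"].max()) + 1
    grid: list[list] = [[None] * width for _ in range(height)]
    for row in index.itertuples():
        table = pd.read_csv(index_path.parent / row.path, sep="\t")
        grid[int(row.y)][int(row.x)] = (
            table.iloc[:, 0].to_numpy(float),
            table.iloc[:, 1].to_numpy(float),
        )
    for y in range(height):
        for x in range(width):
            if grid[y][x] is None:
                raise DataError(f"pixel ({x}, {y}) missing from index")
    return grid
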