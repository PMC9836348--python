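"""Colony quantification from gridded plate images.

Recovers per-position colony sizes (foreground pixel counts) from a
grayscale image of a pinned colony array, the readout a flat-bed scanner
plus gridding software provides. The grid is fixed and regular: the image
is divided into rows x cols equal cells (half-open intervals, a pixel
belongs to the cell containing its center) and the count per cell is the
number of pixels above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class GeometryError(ValueError):
    """Image too small for the requested grid."""


class FormatError(ValueError):
    """Input image is not a single-channel grayscale array."""


@dataclass
class GridSpec:
    rows: int = 16
    cols: int = 24

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise GeometryError("grid dimensions must be positive")


def quantify_plate(
    image: np.ndarray,
    grid: GridSpec | None = None,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
) -> np.ndarray:
    """Count foreground pixels per grid cell.

    Parameters
    ----------
    image : 2-D array
        Grayscale plate image (any numeric dtype).
    grid : GridSpec
        Grid geometry; default 16x24 (384 format).
    threshold_method : {"otsu", "fixed"}
        Global Otsu threshold by default; ``fixed`` uses
        ``fixed_threshold`` (foreground = intensity strictly above it).

    Returns
    -------
    counts : (rows, cols) int array
    """
    if grid is None:
        grid = GridSpec()
    image = np.asarray(image)
    if image.ndim != 2:
        raise FormatError(f"expected 2-D grayscale image, got shape {image.shape}")
    h, w = image.shape
    if h < 8 * grid.rows or w < 8 * grid.cols:
        raise GeometryError(
            f"image {h}x{w} too small for {grid.rows}x{grid.cols} grid (cells must be >= 8x8 px)"
        )

    if threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        thr = float(fixed_threshold)
    elif threshold_method == "otsu":
        if image.min() == image.max():
            # constant image: foreground iff nonzero intensity
            thr = 0.0 if image.max() > 0 else float(image.max())
            fg = image > thr if image.max() > 0 else np.zeros_like(image, dtype=bool)
            return _bin_counts(fg, grid)
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(image))
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    return _bin_counts(image > thr, grid)


def _bin_counts(foreground: np.ndarray, grid: GridSpec) -> np.ndarray:
    h, w = foreground.shape
    # pixel center (i + 0.5) mapped to half-open cells of height h/rows
    row_idx = np.minimum(((np.arange(h) + 0.5) * grid.rows / h).astype(int), grid.rows - 1)
    col_idx = np.minimum(((np.arange(w) + 0.5) * grid.cols / w).astype(int), grid.cols - 1)
    cell = row_idx[:, None] * grid.cols + col_idx[None, :]
    counts = np.bincount(cell[foreground], minlength=grid.rows * grid.cols)
    return counts.reshape(grid.rows, grid.cols)


def counts_to_frame(counts: np.ndarray) -> pd.DataFrame:
    """Long-format (row, col, count) table, 1-based indices."""
    rows, cols = counts.shape
    r, c = np.meshgrid(np.arange(1, rows + 1), np.arange(1, cols + 1), indexing="ij")
    return pd.DataFrame({"row": r.ravel(), "col": c.ravel(), "count": counts.ravel()})


def quantify_image_file(path, rows: int = 16, cols: int = 24, **kwargs) -> pd.DataFrame:
    from skimage.io import imread

    img = imread(path)
    if img.ndim == 3:
        raise FormatError("expected 8-bit grayscale PNG, got multi-channel image")
    return counts_to_frame(quantify_plate(img, GridSpec(rows, cols), **kwargs))
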