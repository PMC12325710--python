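"""Tissue localization, grid segmentation and per-core labeling.

Works on a stitched mosaic: subtractive white balance against an
automatically sampled background block, grayscale threshold + smoothing +
border clearing to find the tissue bounding box, equal-cell grid
segmentation against the layout, and manifest-driven crop labeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
from skimage.color import rgb2gray
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import clear_border

from .errors import (CellTooSmallError, EmptyTissueError, LabelMismatchError,
                     NoBackgroundError)
from .stitch import Mosaic
from .synthslide import CoreLayout, GroundTruthManifest

#: gray level below which a (white-balanced) pixel counts as tissue
TISSUE_GRAY_THRESHOLD = 0.92


def _as_array(mosaic: Union[Mosaic, np.ndarray]) -> np.ndarray:
    return mosaic.raster if isinstance(mosaic, Mosaic) else np.asarray(mosaic)


def _wrap_like(template: Union[Mosaic, np.ndarray],
               raster: np.ndarray) -> Union[Mosaic, np.ndarray]:
    if isinstance(template, Mosaic):
        return Mosaic(raster=raster, pixel_size_um=template.pixel_size_um,
                      provenance=dict(template.provenance))
    return raster


def _find_background_block(img: np.ndarray, block: int,
                           std_tol: float) -> Optional[tuple[int, int]]:
    h, w = img.shape[:2]
    if h < block or w < block:
        return None
    stride = max(1, block // 2)
    best = None
    for y in range(0, h - block + 1, stride):
        for x in range(0, w - block + 1, stride):
            win = img[y:y + block, x:x + block]
            # spatial uniformity per channel; a global color cast must not
            # disqualify an otherwise empty block
            if win.reshape(-1, win.shape[-1]).std(axis=0).max() > std_tol:
                continue
            m = float(win.mean())
            if best is None or m > best[0]:
                best = (m, y, x)
    if best is None:
        return None
    return best[1], best[2]


def white_balance(mosaic: Union[Mosaic, np.ndarray], block: int = 64,
                  std_tol: float = 0.02) -> Union[Mosaic, np.ndarray]:
    """Shift each channel so the sampled background block maps to white.

    The background is the brightest low-variance block; the per-channel
    offset (1 - block mean) is added and values clipped to [0, 1], so the
    correction is purely subtractive.
    """
    img = _as_array(mosaic).astype(np.float32)
    loc = _find_background_block(img, block, std_tol)
    if loc is None:
        raise NoBackgroundError("no tissue-free background block found")
    y, x = loc
    bg = img[y:y + block, x:x + block].reshape(-1, img.shape[2]).mean(axis=0)
    offset = 1.0 - bg
    out = np.clip(img + offset[None, None, :], 0.0, 1.0)
    return _wrap_like(mosaic, out)


@dataclass(frozen=True)
class TissueBBox:
    """Half-open pixel bounding box of the tissue region."""

    min_x: int
    min_y: int
    max_x: int
    max_y: int

    def __post_init__(self) -> None:
        if self.max_x <= self.min_x or self.max_y <= self.min_y:
            raise ValueError("bounding box must be non-empty")

    @property
    def width(self) -> int:
        return self.max_x - self.min_x

    @property
    def height(self) -> int:
        return self.max_y - self.min_y

    def contains(self, x: float, y: float) -> bool:
        return self.min_x <= x < self.max_x and self.min_y <= y < self.max_y


def tissue_mask(mosaic: Union[Mosaic, np.ndarray],
                blur_sigma: float = 2.0,
                threshold_method: str = "otsu") -> np.ndarray:
    """Binary tissue mask: grayscale -> threshold -> smooth -> re-threshold."""
    img = _as_array(mosaic)
    gray = rgb2gray(img) if img.ndim == 3 else np.asarray(img, dtype=np.float64)
    if np.ptp(gray) < 1e-3:
        raise EmptyTissueError("image has no contrast; no tissue found")
    if threshold_method == "otsu":
        th = threshold_otsu(gray)
    elif threshold_method == "fixed":
        th = TISSUE_GRAY_THRESHOLD
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = gray < th
    if blur_sigma > 0:
        binary = gaussian(binary.astype(np.float64), sigma=blur_sigma) > 0.5
    return binary


def _drop_small_components(binary: np.ndarray, min_area_px: int) -> np.ndarray:
    labels = cc_label(binary)
    if labels.max() == 0:
        return binary
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area_px
    keep[0] = False
    return keep[labels]


def find_tissue_bbox(mosaic: Union[Mosaic, np.ndarray],
                     threshold_method: str = "otsu",
                     blur_sigma: float = 2.0,
                     border_margin_px: int = 2,
                     min_area_px: int = 16) -> TissueBBox:
    """Bounding box of all tissue components away from the mosaic border."""
    binary = tissue_mask(mosaic, blur_sigma=blur_sigma,
                         threshold_method=threshold_method)
    binary = clear_border(binary, buffer_size=border_margin_px)
    binary = _drop_small_components(binary, min_area_px)
    if not binary.any():
        raise EmptyTissueError("no tissue component after filtering")
    ys, xs = np.nonzero(binary)
    return TissueBBox(min_x=int(xs.min()), min_y=int(ys.min()),
                      max_x=int(xs.max()) + 1, max_y=int(ys.max()) + 1)


def count_tissue_components(mosaic: Union[Mosaic, np.ndarray],
                            blur_sigma: float = 2.0,
                            min_area_px: int = 16) -> int:
    """Number of connected tissue components (cores, if fully separated)."""
    binary = tissue_mask(mosaic, blur_sigma=blur_sigma)
    binary = _drop_small_components(binary, min_area_px)
    return int(cc_label(binary).max())


@dataclass(frozen=True)
class GridCell:
    grid_row: int
    grid_col: int
    x0: int
    y0: int
    x1: int
    y1: int


def segment_grid(bbox: TissueBBox, layout: CoreLayout,
                 min_cell_px: int = 8) -> list[GridCell]:
    """Divide the bbox into n_rows x n_cols equal cells in reading order."""
    xs = np.linspace(bbox.min_x, bbox.max_x, layout.n_cols + 1).round().astype(int)
    ys = np.linspace(bbox.min_y, bbox.max_y, layout.n_rows + 1).round().astype(int)
    if np.diff(xs).min() < min_cell_px or np.diff(ys).min() < min_cell_px:
        raise CellTooSmallError(f"grid cells fall below {min_cell_px} px")
    cells = []
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            cells.append(GridCell(grid_row=r, grid_col=c,
                                  x0=int(xs[c]), y0=int(ys[r]),
                                  x1=int(xs[c + 1]), y1=int(ys[r + 1])))
    return cells


@dataclass
class LabeledCoreImage:
    core_id: str
    rgb: np.ndarray
    her2_score: int
    grid_row: int
    grid_col: int
    repeat_index: int = 1

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"{self.core_id}_rep{self.repeat_index}.tiff"
        arr8 = np.round(np.clip(self.rgb, 0, 1) * 255.0).astype(np.uint8)
        tifffile.imwrite(path, arr8)
        return path


def crop_and_label(mosaic: Union[Mosaic, np.ndarray],
                   cells: Sequence[GridCell],
                   manifest: GroundTruthManifest,
                   repeat_index: int = 1,
                   min_tissue_fraction: float = 0.02,
                   tissue_gray_threshold: float = TISSUE_GRAY_THRESHOLD,
                   ) -> list[LabeledCoreImage]:
    """One labeled crop per occupied grid cell; empty cells are skipped."""
    img = _as_array(mosaic)
    n_rows = max(c.grid_row for c in cells) + 1
    n_cols = max(c.grid_col for c in cells) + 1
    m_rows, m_cols = manifest.grid_shape
    if m_rows > n_rows or m_cols > n_cols:
        raise LabelMismatchError(
            f"manifest grid {m_rows}x{m_cols} exceeds segmented grid "
            f"{n_rows}x{n_cols}")

    out = []
    for cell in cells:
        crop = img[cell.y0:cell.y1, cell.x0:cell.x1]
        gray = rgb2gray(crop) if crop.ndim == 3 else crop
        frac = float((gray < tissue_gray_threshold).mean())
        if frac < min_tissue_fraction:
            continue
        rec = manifest.core_at(cell.grid_row, cell.grid_col)
        if rec is None:
            raise LabelMismatchError(
                f"occupied cell ({cell.grid_row}, {cell.grid_col}) missing "
                f"from manifest")
        out.append(LabeledCoreImage(
            core_id=str(rec["core_id"]), rgb=np.asarray(crop, dtype=np.float32),
            her2_score=int(rec["her2_score"]), grid_row=cell.grid_row,
            grid_col=cell.grid_col, repeat_index=repeat_index))
    return out


def labels_to_csv(crops: Sequence[LabeledCoreImage], path: str | Path) -> None:
    pd.DataFrame([
        {"core_id": c.core_id, "repeat_index": c.repeat_index,
         "her2_score": c.her2_score, "grid_row": c.grid_row,
         "grid_col": c.grid_col}
        for c in crops
    ]).to_csv(path, index=False)


def brown_stain_statistic(rgb: np.ndarray,
                          tissue: Optional[np.ndarray] = None,
                          tissue_gray_threshold: float = TISSUE_GRAY_THRESHOLD,
                          eps: float = 1e-6) -> float:
    """Mean brown-staining readout over the tissue mask.

    Per pixel the blue/brown ratio B / ((R + G) / 2) is clipped to [0, 1]
    and inverted; neutral (gray/white) or bluish pixels contribute ~0 while
    brown membrane staining pushes the statistic toward 1. This is the
    quantitative readout the synthetic generator's score monotonicity is
    measured with.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    if tissue is None:
        tissue = rgb2gray(arr) < tissue_gray_threshold
    if not tissue.any():
        return 0.0
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    ratio = b / (0.5 * (r + g) + eps)
    stat = 1.0 - np.clip(ratio, 0.0, 1.0)
    return float(stat[tissue].mean())
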