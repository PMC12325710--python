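"""Synthetic tissue-microarray slide generator.

Renders stylized IHC-stained tissue cores -- bluish nuclei surrounded by
brown membrane rings whose darkness and arc completeness increase with the
score -- on a near-white background, and produces a ground-truth layout
manifest alongside each slide.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InvalidScoreError, SizeError

VALID_SCORES = (0, 1, 2, 3)

#: multiplicative stain colors (fraction of light transmitted per channel)
DAB_BROWN_RGB = (0.40, 0.22, 0.05)
HEMATOXYLIN_RGB = (0.30, 0.33, 0.62)


@dataclass(frozen=True)
class HER2AppearanceParams:
    """Per-score rendering parameters for the stylized staining model.

    Index ``s`` of each per-score tuple applies to score ``s``. Membrane
    darkening and arc completeness increase with score under the defaults;
    the tissue matrix itself carries a neutral (gray) attenuation so that
    the brown-stain readout stays near zero when no membrane is drawn.
    """

    membrane_stain_level: tuple[float, float, float, float] = (0.05, 0.35, 0.65, 0.95)
    membrane_completeness: tuple[float, float, float, float] = (0.10, 0.40, 0.70, 0.95)
    cell_density_per_mm2: tuple[float, float, float, float] = (2000.0,) * 4
    nucleus_stain_level: tuple[float, float, float, float] = (0.55,) * 4
    background_rgb: tuple[float, float, float] = (0.97, 0.97, 0.96)
    tissue_attenuation: float = 0.85
    nucleus_radius_um: float = 3.0
    membrane_radius_um: float = 6.0
    membrane_thickness_um: float = 1.8

    def __post_init__(self) -> None:
        for name in ("membrane_stain_level", "membrane_completeness",
                     "nucleus_stain_level"):
            vals = getattr(self, name)
            if len(vals) != 4 or any(not (0.0 <= v <= 1.0) for v in vals):
                raise ValueError(f"{name} must be four values in [0, 1]")
        if any(v < 0.9 for v in self.background_rgb):
            raise ValueError("background_rgb channels must be >= 0.9")
        if any(d <= 0 for d in self.cell_density_per_mm2):
            raise ValueError("cell densities must be positive")


@dataclass(frozen=True)
class CoreLayout:
    """Regular TMA core grid: ``n_rows x n_cols`` cores at ``pitch_um``."""

    n_rows: int
    n_cols: int
    pitch_um: float
    core_diameter_um: float
    origin_um: Optional[tuple[float, float]] = None  # (x, y) of top-left core center

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("layout must have at least one row and column")
        if self.pitch_um <= self.core_diameter_um:
            raise ValueError("pitch_um must exceed core_diameter_um "
                             "(cores must stay fully separated)")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch_um": float(self.pitch_um),
            "core_diameter_um": float(self.core_diameter_um),
        }
        if self.origin_um is not None:
            data["origin_um"] = [float(v) for v in self.origin_um]
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CoreLayout":
        data = yaml.safe_load(Path(path).read_text())
        origin = data.get("origin_um")
        return cls(
            n_rows=int(data["n_rows"]),
            n_cols=int(data["n_cols"]),
            pitch_um=float(data["pitch_um"]),
            core_diameter_um=float(data["core_diameter_um"]),
            origin_um=tuple(origin) if origin is not None else None,
        )


@dataclass
class SlideImage:
    """An RGB raster with an isotropic physical pixel size."""

    rgb: np.ndarray  # (H, W, 3) float in [0, 1]
    pixel_size_um: float = 1.0

    @property
    def height_um(self) -> float:
        return self.rgb.shape[0] * self.pixel_size_um

    @property
    def width_um(self) -> float:
        return self.rgb.shape[1] * self.pixel_size_um

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arr = np.clip(np.asarray(self.rgb, dtype=np.float64), 0.0, 1.0)
        arr8 = np.round(arr * 255.0).astype(np.uint8)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, arr8, metadata={"pixel_size_um": self.pixel_size_um})
        else:
            iio.imwrite(path, arr8)

    @classmethod
    def load(cls, path: str | Path, pixel_size_um: float = 1.0) -> "SlideImage":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
        rgb = np.asarray(arr, dtype=np.float32)
        if rgb.dtype != np.float32 or rgb.max() > 1.5:
            rgb = rgb / 255.0
        return cls(rgb=rgb.astype(np.float32), pixel_size_um=pixel_size_um)


class GroundTruthManifest:
    """Core records plus optional per-(core, repeat) scan records."""

    CORE_COLUMNS = ["core_id", "grid_row", "grid_col",
                    "center_x_um", "center_y_um", "her2_score", "split"]

    def __init__(self, cores: pd.DataFrame,
                 scans: Optional[pd.DataFrame] = None) -> None:
        cores = cores.reset_index(drop=True)
        missing = [c for c in self.CORE_COLUMNS if c not in cores.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if len(cores):
            if cores.duplicated(subset=["grid_row", "grid_col"]).any():
                raise ValueError("(grid_row, grid_col) must be unique per core")
            bad = ~cores["her2_score"].isin(VALID_SCORES)
            if bad.any():
                raise InvalidScoreError("her2_score must be in {0, 1, 2, 3}")
        self.cores = cores
        if scans is None:
            scans = pd.DataFrame(columns=["core_id", "repeat_index"])
        self.scans = scans.reset_index(drop=True)

    @property
    def n_cores(self) -> int:
        return len(self.cores)

    @property
    def n_scan_records(self) -> int:
        return len(self.scans)

    def add_scan_records(self, n_repeats: int) -> "GroundTruthManifest":
        if n_repeats < 0:
            raise ValueError("n_repeats must be >= 0")
        records = [
            {"core_id": cid, "repeat_index": rep}
            for cid in self.cores["core_id"]
            for rep in range(1, n_repeats + 1)
        ]
        self.scans = pd.DataFrame(records, columns=["core_id", "repeat_index"])
        return self

    def score_at(self, grid_row: int, grid_col: int) -> Optional[int]:
        sel = self.cores[(self.cores["grid_row"] == grid_row)
                         & (self.cores["grid_col"] == grid_col)]
        if sel.empty:
            return None
        return int(sel["her2_score"].iloc[0])

    def core_at(self, grid_row: int, grid_col: int) -> Optional[pd.Series]:
        sel = self.cores[(self.cores["grid_row"] == grid_row)
                         & (self.cores["grid_col"] == grid_col)]
        return None if sel.empty else sel.iloc[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        if self.cores.empty:
            return (0, 0)
        return (int(self.cores["grid_row"].max()) + 1,
                int(self.cores["grid_col"].max()) + 1)

    def to_csv(self, path: str | Path, include_scans: bool = False) -> None:
        if include_scans and len(self.scans):
            merged = self.scans.merge(self.cores, on="core_id", how="left")
            merged = merged[self.CORE_COLUMNS + ["repeat_index"]]
            merged.to_csv(path, index=False)
        else:
            self.cores[self.CORE_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruthManifest":
        df = pd.read_csv(path)
        if "repeat_index" in df.columns:
            cores = df[cls.CORE_COLUMNS].drop_duplicates("core_id")
            scans = df[["core_id", "repeat_index"]]
            return cls(cores, scans)
        return cls(df)


def _derive_seed(*parts) -> int:
    key = ":".join(str(p) for p in parts).encode()
    return zlib.crc32(key) & 0xFFFFFFFF


def _apply_stain(img: np.ndarray, level_map: np.ndarray,
                 stain_rgb: Sequence[float]) -> None:
    """Multiplicative attenuation: transmitted = 1 - L * (1 - stain_color)."""
    color = np.asarray(stain_rgb, dtype=np.float64)
    factor = 1.0 - level_map[..., None] * (1.0 - color[None, None, :])
    img *= factor


def render_core(params: HER2AppearanceParams, score: int, diameter_um: float,
                pixel_size_um: float = 1.0, seed: int = 0,
                canvas_px: Optional[int] = None) -> np.ndarray:
    """Render one circular tissue core as an (N, N, 3) float64 raster.

    Deterministic given ``seed``: cell positions, membrane arc phases and
    nucleus placement all come from a single seeded generator.
    """
    if score not in VALID_SCORES:
        raise InvalidScoreError(f"score must be one of {VALID_SCORES}, got {score!r}")
    if diameter_um <= 0:
        raise ValueError("diameter_um must be positive")

    r_px = 0.5 * diameter_um / pixel_size_um
    n = canvas_px if canvas_px is not None else int(np.ceil(diameter_um / pixel_size_um)) + 4
    rng = np.random.default_rng(seed)

    img = np.ones((n, n, 3), dtype=np.float64)
    img *= np.asarray(params.background_rgb)[None, None, :]

    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    tissue = (yy - c) ** 2 + (xx - c) ** 2 <= r_px ** 2
    img[tissue] *= params.tissue_attenuation

    area_mm2 = np.pi * (0.5 * diameter_um / 1000.0) ** 2
    n_cells = int(round(params.cell_density_per_mm2[score] * area_mm2))

    mem_level = params.membrane_stain_level[score]
    mem_completeness = params.membrane_completeness[score]
    nuc_level = params.nucleus_stain_level[score]
    nuc_r = params.nucleus_radius_um / pixel_size_um
    mem_r = params.membrane_radius_um / pixel_size_um
    mem_t = params.membrane_thickness_um / pixel_size_um

    mem_map = np.zeros((n, n), dtype=np.float64)
    nuc_map = np.zeros((n, n), dtype=np.float64)

    if n_cells > 0:
        # uniform positions inside the disk, keeping membranes within tissue
        r_place = max(r_px - mem_r - 1.0, 0.0)
        u = rng.random(n_cells)
        theta = rng.random(n_cells) * 2.0 * np.pi
        cx = c + np.sqrt(u) * r_place * np.cos(theta)
        cy = c + np.sqrt(u) * r_place * np.sin(theta)
        arc_start = rng.random(n_cells) * 2.0 * np.pi

        half = int(np.ceil(mem_r + mem_t)) + 1
        for k in range(n_cells):
            x0 = int(np.floor(cx[k])) - half
            y0 = int(np.floor(cy[k])) - half
            x1, y1 = x0 + 2 * half + 1, y0 + 2 * half + 1
            x0c, y0c = max(x0, 0), max(y0, 0)
            x1c, y1c = min(x1, n), min(y1, n)
            ly, lx = np.mgrid[y0c:y1c, x0c:x1c].astype(np.float64)
            dy, dx = ly - cy[k], lx - cx[k]
            d = np.hypot(dx, dy)

            if nuc_level > 0:
                nwin = nuc_map[y0c:y1c, x0c:x1c]
                np.maximum(nwin, np.where(d <= nuc_r, nuc_level, 0.0), out=nwin)

            if mem_level > 0 and mem_completeness > 0:
                ring = np.abs(d - mem_r) <= 0.5 * mem_t
                ang = np.mod(np.arctan2(dy, dx) - arc_start[k], 2.0 * np.pi)
                arc = ang <= mem_completeness * 2.0 * np.pi
                mwin = mem_map[y0c:y1c, x0c:x1c]
                np.maximum(mwin, np.where(ring & arc, mem_level, 0.0), out=mwin)

    mem_map[~tissue] = 0.0
    nuc_map[~tissue] = 0.0
    _apply_stain(img, nuc_map, HEMATOXYLIN_RGB)
    _apply_stain(img, mem_map, DAB_BROWN_RGB)
    return np.clip(img, 0.0, 1.0)


DEFAULT_MAX_RASTER_PX = 30_000


def generate_slide(layout: CoreLayout,
                   score_assignment: Sequence[Optional[int]],
                   params: Optional[HER2AppearanceParams] = None,
                   pixel_size_um: float = 1.0,
                   seed: int = 0,
                   margin_um: Optional[float] = None,
                   split: str = "test",
                   max_raster_px: int = DEFAULT_MAX_RASTER_PX,
                   ) -> tuple[SlideImage, GroundTruthManifest]:
    """Render a full TMA slide plus its ground-truth manifest.

    ``score_assignment`` is read in reading order (row-major); ``None``
    entries leave the corresponding grid position empty.
    """
    params = params or HER2AppearanceParams()
    scores = list(score_assignment)
    if len(scores) != layout.n_cells:
        raise ValueError(f"score_assignment must have {layout.n_cells} entries "
                         f"(got {len(scores)})")

    if margin_um is None:
        margin_um = layout.pitch_um / 2.0
    if layout.origin_um is not None:
        ox, oy = layout.origin_um
    else:
        ox = oy = margin_um + layout.core_diameter_um / 2.0

    width_um = ox + (layout.n_cols - 1) * layout.pitch_um \
        + layout.core_diameter_um / 2.0 + margin_um
    height_um = oy + (layout.n_rows - 1) * layout.pitch_um \
        + layout.core_diameter_um / 2.0 + margin_um
    w_px = int(round(width_um / pixel_size_um))
    h_px = int(round(height_um / pixel_size_um))
    if max(w_px, h_px) > max_raster_px:
        raise SizeError(f"slide raster {h_px}x{w_px} exceeds limit {max_raster_px}")

    rgb = np.ones((h_px, w_px, 3), dtype=np.float64)
    rgb *= np.asarray(params.background_rgb)[None, None, :]

    records = []
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            score = scores[r * layout.n_cols + c]
            if score is None:
                continue
            core_seed = _derive_seed(seed, r, c)
            patch = render_core(params, int(score), layout.core_diameter_um,
                                pixel_size_um, seed=core_seed)
            cx_um = ox + c * layout.pitch_um
            cy_um = oy + r * layout.pitch_um
            cx = int(round(cx_um / pixel_size_um))
            cy = int(round(cy_um / pixel_size_um))
            ph, pw = patch.shape[:2]
            y0, x0 = cy - ph // 2, cx - pw // 2
            region = rgb[y0:y0 + ph, x0:x0 + pw]
            # keep the darker (stained) value where the patch has tissue
            np.minimum(region, patch[:region.shape[0], :region.shape[1]], out=region)
            records.append({
                "core_id": f"core_r{r:02d}c{c:02d}",
                "grid_row": r, "grid_col": c,
                "center_x_um": cx_um, "center_y_um": cy_um,
                "her2_score": int(score), "split": split,
            })

    cores = pd.DataFrame(records, columns=GroundTruthManifest.CORE_COLUMNS)
    manifest = GroundTruthManifest(cores)
    slide = SlideImage(rgb=rgb.astype(np.float32), pixel_size_um=pixel_size_um)
    return slide, manifest


def generate_dataset_manifest(n_train: int, n_test: int, n_repeats: int = 3,
                              seed: int = 0, n_cols: int = 24,
                              pitch_um: float = 600.0) -> GroundTruthManifest:
    """Bookkeeping-only manifest: (n_train + n_test) cores x n_repeats scans."""
    if n_train < 0 or n_test < 0 or n_repeats < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    n_total = n_train + n_test
    records = []
    for i in range(n_total):
        r, c = divmod(i, n_cols)
        records.append({
            "core_id": f"core_{i:05d}",
            "grid_row": r, "grid_col": c,
            "center_x_um": (c + 0.5) * pitch_um,
            "center_y_um": (r + 0.5) * pitch_um,
            "her2_score": int(rng.integers(0, 4)),
            "split": "train" if i < n_train else "test",
        })
    cores = pd.DataFrame(records, columns=GroundTruthManifest.CORE_COLUMNS)
    return GroundTruthManifest(cores).add_scan_records(n_repeats)
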