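"""Continuous zigzag scan simulation.

Models the acquisition as a stage translating at constant speed while the
camera exposes for a fixed time, which makes every moving frame a window of
the slide convolved along the scan direction with a normalized rectangular
kernel whose physical width is the blur distance (stage speed x exposure).
Static frames captured during line-end pauses are unblurred windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import (CoverageGapError, InvalidConfigError, InvalidKernelError,
                     OutOfBoundsError)
from .synthslide import SlideImage

DIRECTION_SIGN = {"+x": 1, "-x": -1}
SIGN_DIRECTION = {1: "+x", -1: "-x"}


@dataclass(frozen=True)
class JitterSpec:
    """Sinusoidal stage jitter: amplitude (um) and frequency (Hz) per axis."""

    amp_x_um: float = 0.0
    freq_x_hz: float = 0.0
    amp_y_um: float = 0.0
    freq_y_hz: float = 0.0

    @property
    def is_zero(self) -> bool:
        return self.amp_x_um == 0.0 and self.amp_y_um == 0.0


@dataclass(frozen=True)
class ScanConfig:
    s_x_um_per_s: float = 5000.0
    acquisition_time_s: float = 0.0078
    fps: float = 30.0
    fov_px: tuple[int, int] = (640, 480)  # (width, height)
    pixel_size_um: float = 1.0
    pause_s: float = 0.5
    row_step_um: Optional[float] = None  # default 0.8 x frame height
    jitter: Optional[JitterSpec] = None

    def __post_init__(self) -> None:
        if self.s_x_um_per_s < 0:
            raise InvalidConfigError("stage speed must be >= 0")
        if self.acquisition_time_s <= 0:
            raise InvalidConfigError("acquisition time must be > 0")
        if self.fps <= 0:
            raise InvalidConfigError("frame rate must be > 0")
        if self.acquisition_time_s > 1.0 / self.fps + 1e-12:
            raise InvalidConfigError("acquisition time cannot exceed the frame period")
        if self.pixel_size_um <= 0:
            raise InvalidConfigError("pixel size must be > 0")
        if self.row_step_um is not None and self.row_step_um > self.fov_height_um:
            raise CoverageGapError("row_step_um larger than the frame height "
                                   "would leave vertical gaps")

    @property
    def fov_width_um(self) -> float:
        return self.fov_px[0] * self.pixel_size_um

    @property
    def fov_height_um(self) -> float:
        return self.fov_px[1] * self.pixel_size_um

    @property
    def effective_row_step_um(self) -> float:
        if self.row_step_um is not None:
            return self.row_step_um
        return 0.8 * self.fov_height_um

    @property
    def advance_um_per_frame(self) -> float:
        return self.s_x_um_per_s / self.fps

    @property
    def advance_px_per_frame(self) -> float:
        return self.advance_um_per_frame / self.pixel_size_um

    @property
    def n_pause_frames(self) -> int:
        return int(round(self.pause_s * self.fps))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "s_x_um_per_s": self.s_x_um_per_s,
            "acquisition_time_s": self.acquisition_time_s,
            "fps": self.fps,
            "fov_px": list(self.fov_px),
            "pixel_size_um": self.pixel_size_um,
            "pause_s": self.pause_s,
        }
        if self.row_step_um is not None:
            data["row_step_um"] = self.row_step_um
        if self.jitter is not None:
            data["jitter"] = {"amp_x_um": self.jitter.amp_x_um,
                              "freq_x_hz": self.jitter.freq_x_hz,
                              "amp_y_um": self.jitter.amp_y_um,
                              "freq_y_hz": self.jitter.freq_y_hz}
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScanConfig":
        data = yaml.safe_load(Path(path).read_text())
        jitter = data.pop("jitter", None)
        if jitter is not None:
            jitter = JitterSpec(**jitter)
        fov = data.pop("fov_px", (640, 480))
        return cls(fov_px=tuple(int(v) for v in fov), jitter=jitter, **data)


def blur_width(s_x_um_per_s: float, acquisition_time_s: float) -> float:
    """Physical blur distance in um: stage speed times exposure time."""
    if s_x_um_per_s < 0:
        raise InvalidConfigError("stage speed must be >= 0")
    if acquisition_time_s <= 0:
        raise InvalidConfigError("acquisition time must be > 0")
    return s_x_um_per_s * acquisition_time_s


@dataclass(frozen=True)
class BlurKernel:
    """1-D rectangular blur of physical width ``width_um`` along x."""

    width_um: float
    pixel_size_um: float = 1.0
    direction: str = "+x"

    def __post_init__(self) -> None:
        if self.width_um < 0:
            raise InvalidKernelError("blur width must be >= 0")
        if self.direction not in DIRECTION_SIGN:
            raise InvalidKernelError("direction must be '+x' or '-x'")

    @property
    def width_px(self) -> int:
        return max(1, int(round(self.width_um / self.pixel_size_um)))

    @property
    def weights(self) -> np.ndarray:
        w = self.width_px
        return np.full(w, 1.0 / w)

    @classmethod
    def from_config(cls, config: ScanConfig, direction: str = "+x") -> "BlurKernel":
        return cls(width_um=blur_width(config.s_x_um_per_s,
                                       config.acquisition_time_s),
                   pixel_size_um=config.pixel_size_um, direction=direction)


def motion_blur(image: np.ndarray, kernel: BlurKernel) -> np.ndarray:
    """Convolve each row with the normalized rect along the scan direction.

    The kernel is anchored at the exposure start, so output pixel x averages
    input pixels x .. x+w-1 for '+x' (and x-w+1 .. x for '-x'), with
    replicate-edge boundary handling. Implemented with a cumulative sum so it
    stays O(n) in the kernel width.
    """
    img = np.asarray(image)
    w = kernel.width_px
    if w > img.shape[1]:
        raise InvalidKernelError(f"kernel width {w} px exceeds image width "
                                 f"{img.shape[1]} px")
    if w == 1:
        return img.astype(np.float64, copy=True) if not np.issubdtype(
            img.dtype, np.floating) else img.copy()

    work = img.astype(np.float64, copy=False)
    sign = DIRECTION_SIGN[kernel.direction]
    pad = [(0, 0)] * work.ndim
    pad[1] = (0, w - 1) if sign > 0 else (w - 1, 0)
    padded = np.pad(work, pad, mode="edge")

    csum = np.cumsum(padded, axis=1, dtype=np.float64)
    zero = np.zeros_like(csum[:, :1])
    csum = np.concatenate([zero, csum], axis=1)
    width = img.shape[1]
    # window starting at column x (already offset by the left pad for '-x')
    out = (csum[:, w:w + width] - csum[:, 0:width]) / w
    if np.issubdtype(img.dtype, np.floating):
        out = out.astype(img.dtype, copy=False)
    return out


@dataclass
class MotionTrace:
    """Per-frame stage state realizing the zigzag schedule."""

    frame_index: np.ndarray
    time_s: np.ndarray
    stage_x_um: np.ndarray  # frame-center x
    stage_y_um: np.ndarray  # frame-center y
    moving: np.ndarray      # bool
    row_index: np.ndarray   # int
    direction: np.ndarray   # int, +1 / -1

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def n_rows(self) -> int:
        return int(self.row_index.max()) + 1 if len(self) else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_index": self.frame_index,
            "time_s": self.time_s,
            "stage_x_um": self.stage_x_um,
            "stage_y_um": self.stage_y_um,
            "moving": self.moving.astype(int),
            "row_index": self.row_index,
            "direction": [SIGN_DIRECTION[int(d)] for d in self.direction],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MotionTrace":
        df = pd.read_csv(path)
        return cls(
            frame_index=df["frame_index"].to_numpy(int),
            time_s=df["time_s"].to_numpy(float),
            stage_x_um=df["stage_x_um"].to_numpy(float),
            stage_y_um=df["stage_y_um"].to_numpy(float),
            moving=df["moving"].to_numpy(int).astype(bool),
            row_index=df["row_index"].to_numpy(int),
            direction=np.array([DIRECTION_SIGN[d] for d in df["direction"]]),
        )


def plan_zigzag(slide_extent_um: tuple[float, float], config: ScanConfig,
                first_direction: str = "+x") -> MotionTrace:
    """Plan the serpentine frame schedule covering ``(width, height)`` um.

    Each scan line is bracketed by ``pause_s`` of static frames at its start
    and end positions; rows alternate direction and advance by the row step.
    """
    width_um, height_um = slide_extent_um
    if width_um <= 0 or height_um <= 0:
        raise ValueError("slide extent must be positive")
    if first_direction not in DIRECTION_SIGN:
        raise ValueError("first_direction must be '+x' or '-x'")
    fw, fh = config.fov_width_um, config.fov_height_um
    step = config.effective_row_step_um
    if step > fh:
        raise CoverageGapError("row step larger than frame height")

    adv = config.advance_um_per_frame
    n_pause = config.n_pause_frames
    if width_um <= fw:
        n_move = 1
    else:
        n_move = int(math.ceil((width_um - fw) / adv)) + 1
    xs = fw / 2.0 + adv * np.arange(n_move)
    if height_um <= fh:
        n_rows = 1
    else:
        n_rows = int(math.ceil((height_um - fh) / step)) + 1
    ys = fh / 2.0 + step * np.arange(n_rows)

    first = DIRECTION_SIGN[first_direction]
    x_list, y_list, mov_list, row_list, dir_list = [], [], [], [], []
    for r in range(n_rows):
        sign = first * (1 if r % 2 == 0 else -1)
        row_xs = xs if sign > 0 else xs[::-1]
        # pause at one frame-advance short of the first moving position
        x_entry = row_xs[0] - sign * adv
        x_exit = row_xs[-1] + sign * adv
        seq_x = ([x_entry] * n_pause) + list(row_xs) + ([x_exit] * n_pause)
        seq_m = ([False] * n_pause) + ([True] * n_move) + ([False] * n_pause)
        x_list.extend(seq_x)
        y_list.extend([ys[r]] * len(seq_x))
        mov_list.extend(seq_m)
        row_list.extend([r] * len(seq_x))
        dir_list.extend([sign] * len(seq_x))

    n = len(x_list)
    idx = np.arange(n)
    return MotionTrace(
        frame_index=idx,
        time_s=idx / config.fps,
        stage_x_um=np.asarray(x_list, dtype=float),
        stage_y_um=np.asarray(y_list, dtype=float),
        moving=np.asarray(mov_list, dtype=bool),
        row_index=np.asarray(row_list, dtype=int),
        direction=np.asarray(dir_list, dtype=int),
    )


@dataclass
class FrameSequence:
    """Ordered camera frames plus the motion trace that produced them."""

    frames: np.ndarray  # (N, H, W, 3) float32
    trace: MotionTrace
    config: ScanConfig

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.trace):
            raise ValueError("frame count must equal trace length")

    def __len__(self) -> int:
        return len(self.frames)

    def save(self, out_dir: str | Path, fmt: str = "png") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(self.frames):
            arr8 = np.round(np.clip(frame, 0, 1) * 255.0).astype(np.uint8)
            if fmt == "tiff":
                tifffile.imwrite(out_dir / f"frame_{i:05d}.tiff", arr8)
            else:
                iio.imwrite(out_dir / f"frame_{i:05d}.png", arr8)
        self.trace.to_csv(out_dir / "trace.csv")
        self.config.to_yaml(out_dir / "scan_config.yaml")

    @classmethod
    def load(cls, in_dir: str | Path) -> "FrameSequence":
        in_dir = Path(in_dir)
        paths = sorted(list(in_dir.glob("frame_*.png"))
                       + list(in_dir.glob("frame_*.tif*")))
        frames = np.stack([
            np.asarray(tifffile.imread(p) if p.suffix.startswith(".tif")
                       else iio.imread(p), dtype=np.float32) / 255.0
            for p in paths])
        trace = MotionTrace.from_csv(in_dir / "trace.csv")
        config = ScanConfig.from_yaml(in_dir / "scan_config.yaml")
        return cls(frames=frames, trace=trace, config=config)


def load_frames(in_dir: str | Path) -> np.ndarray:
    """Load just the numbered frames from a directory (no trace needed)."""
    in_dir = Path(in_dir)
    paths = sorted(list(in_dir.glob("frame_*.png"))
                   + list(in_dir.glob("frame_*.tif*")))
    if not paths:
        raise FileNotFoundError(f"no frame_* images in {in_dir}")
    return np.stack([
        np.asarray(tifffile.imread(p) if p.suffix.startswith(".tif")
                   else iio.imread(p), dtype=np.float32) / 255.0
        for p in paths])


def simulate_scan(slide: SlideImage, trace: MotionTrace, config: ScanConfig,
                  seed: int = 0) -> FrameSequence:
    """Window + blur the slide at every trace position.

    The slide is pre-blurred once per scan direction and moving frames are
    cut from the pre-blurred raster, which is mathematically identical to
    blurring each frame individually with replicate-edge padding.
    """
    px = config.pixel_size_um
    if abs(px - slide.pixel_size_um) > 1e-9:
        raise InvalidConfigError("config and slide pixel sizes disagree")
    fw_px, fh_px = config.fov_px
    h, w = slide.rgb.shape[:2]

    jitter = config.jitter or JitterSpec()
    if jitter.is_zero:
        dx = np.zeros(len(trace))
        dy = np.zeros(len(trace))
    else:
        rng = np.random.default_rng(seed)
        phx, phy = rng.random(2) * 2.0 * np.pi
        t = trace.time_s
        dx = jitter.amp_x_um * np.sin(2 * np.pi * jitter.freq_x_hz * t + phx)
        dy = jitter.amp_y_um * np.sin(2 * np.pi * jitter.freq_y_hz * t + phy)

    cx_px = (trace.stage_x_um + dx) / px
    cy_px = (trace.stage_y_um + dy) / px
    x0 = np.round(cx_px - fw_px / 2.0).astype(int)
    y0 = np.round(cy_px - fh_px / 2.0).astype(int)

    if (cx_px < -fw_px).any() or (cx_px > w + fw_px).any() \
            or (cy_px < -fh_px).any() or (cy_px > h + fh_px).any():
        raise OutOfBoundsError("trace leaves the padded slide area")

    pad_l = max(0, -int(x0.min()))
    pad_r = max(0, int(x0.max()) + fw_px - w)
    pad_t = max(0, -int(y0.min()))
    pad_b = max(0, int(y0.max()) + fh_px - h)
    padded = np.pad(slide.rgb.astype(np.float32),
                    [(pad_t, pad_b), (pad_l, pad_r), (0, 0)], mode="edge")

    blurred = {}
    for d in (1, -1):
        if (trace.moving & (trace.direction == d)).any():
            kernel = BlurKernel.from_config(config, SIGN_DIRECTION[d])
            blurred[d] = motion_blur(padded, kernel).astype(np.float32)

    frames = np.empty((len(trace), fh_px, fw_px, 3), dtype=np.float32)
    for i in range(len(trace)):
        src = blurred[int(trace.direction[i])] if trace.moving[i] else padded
        yy, xx = y0[i] + pad_t, x0[i] + pad_l
        frames[i] = src[yy:yy + fh_px, xx:xx + fw_px]
    return FrameSequence(frames=frames, trace=trace, config=config)


def area_throughput(config: ScanConfig) -> float:
    """Scanned area per second in mm^2/s: (speed + FOV width) x FOV height."""
    um2_per_s = (config.s_x_um_per_s + config.fov_width_um) * config.fov_height_um
    return um2_per_s / 1e6


def frame_area_um2(config: ScanConfig) -> float:
    """Footprint of a single camera frame in um^2."""
    return config.fov_width_um * config.fov_height_um
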