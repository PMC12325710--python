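"""Whole-slide mosaic reconstruction from the frame stream.

The stitcher never looks at the stage trace: it classifies frames as moving
or static from consecutive-frame correlations, repairs the labels with a
square-wave motion-model fit, splits the stream into alternating scan-line
segments, and lays frames out at the uniform per-frame advance implied by
the scan configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import (InsufficientInputError, NoScanLinesError, SizeError)
from .scansim import DIRECTION_SIGN, SIGN_DIRECTION, ScanConfig


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        return frame.mean(axis=2)
    return frame


def frame_correlations(frames: Sequence[np.ndarray] | np.ndarray,
                       crop_fraction: float = 0.5) -> np.ndarray:
    """Normalized correlation of consecutive grayscale center crops.

    Pairs of featureless (constant) frames are defined to correlate at 1.0;
    a constant frame against a textured one correlates at 0.0. That mirrors
    the behaviour of real correlation trackers on blank slide regions, which
    is exactly the failure mode the square-wave fit corrects.
    """
    n = len(frames)
    if n < 2:
        raise InsufficientInputError("need at least 2 frames")

    def crop(i: int) -> np.ndarray:
        g = _to_gray(np.asarray(frames[i], dtype=np.float64))
        h, w = g.shape
        ch, cw = max(1, int(h * crop_fraction)), max(1, int(w * crop_fraction))
        y0, x0 = (h - ch) // 2, (w - cw) // 2
        return g[y0:y0 + ch, x0:x0 + cw].ravel()

    out = np.empty(n - 1)
    prev = crop(0)
    for i in range(1, n):
        cur = crop(i)
        a = prev - prev.mean()
        b = cur - cur.mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-12 and nb < 1e-12:
            out[i - 1] = 1.0
        elif na < 1e-12 or nb < 1e-12:
            out[i - 1] = 0.0
        else:
            out[i - 1] = float(np.dot(a, b) / (na * nb))
        prev = cur
    return out


def _two_means_threshold(values: np.ndarray) -> float:
    """Midpoint between the two cluster centers of a 1-D 2-means fit."""
    lo, hi = float(values.min()), float(values.max())
    for _ in range(100):
        thr = 0.5 * (lo + hi)
        low = values[values <= thr]
        high = values[values > thr]
        if len(low) == 0 or len(high) == 0:
            break
        new_lo, new_hi = float(low.mean()), float(high.mean())
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return 0.5 * (lo + hi)


@dataclass
class SquareWaveModel:
    """Fitted alternating moving/static motion model.

    ``line_period_frames``/``pause_frames``/``phase_frames`` describe the
    square wave in the correlation-series domain; ``frame_moving`` carries
    the per-frame labels derived from it.
    """

    line_period_frames: int
    pause_frames: int
    phase_frames: int
    series_static: np.ndarray  # bool, length n_frames - 1
    frame_moving: np.ndarray   # bool, length n_frames

    @property
    def n_frames(self) -> int:
        return len(self.frame_moving)

    @classmethod
    def from_frame_labels(cls, frame_moving: Sequence[bool]) -> "SquareWaveModel":
        fm = np.asarray(frame_moving, dtype=bool)
        static = ~fm[:-1] & ~fm[1:]
        return cls(0, 0, 0, series_static=static, frame_moving=fm)


def _fit_square_wave(raw_static: np.ndarray) -> tuple[int, int, int, np.ndarray]:
    """Grid-search the (period, pause, phase) minimizing label disagreement.

    Ties resolve to the smallest period, then the smallest phase, matching a
    deterministic reading of the fit. Cost evaluation is folded onto residue
    classes so the search is O(sum of period^2), not O(n * period^2).
    """
    n = len(raw_static)
    raw = raw_static.astype(np.int64)
    best = None  # lexicographic key (cost, period, phase, pause)
    for p in range(4, n // 2 + 1):
        res = np.arange(n) % p
        c = np.bincount(res, weights=raw, minlength=p)        # static raw per residue
        tot = np.bincount(res, minlength=p).astype(np.float64)
        t = tot - 2.0 * c  # adding residue r to the static window costs t[r]
        tt = np.concatenate([t, t])
        cs = np.concatenate([[0.0], np.cumsum(tt)])
        base = float(c.sum())
        for q in range(1, p):
            win = cs[q:q + p] - cs[0:p]  # window sum starting at each phase
            phase = int(np.argmin(win))
            cost = base + float(win[phase])
            cand = (cost, p, phase, q)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise NoScanLinesError("series too short to fit a square wave")
    _, p, phase, q = best
    fitted = ((np.arange(n) - phase) % p) < q
    return p, q, phase, fitted


def classify_motion(series: np.ndarray, fit: bool = True,
                    threshold: Optional[float] = None) -> SquareWaveModel:
    """Label frames moving/static from the correlation series.

    Raw labels come from thresholding the series (2-means midpoint by
    default); with ``fit`` enabled the best-fitting square wave replaces
    them, repairing misclassifications over featureless slide regions.
    """
    series = np.asarray(series, dtype=np.float64)
    n = len(series)
    if n < 2 or np.ptp(series) < 1e-9:
        raise NoScanLinesError("correlation series is constant; no "
                               "moving/static alternation detected")
    if threshold is None:
        threshold = _two_means_threshold(series)
    raw_static = series >= threshold
    if raw_static.all() or (~raw_static).all():
        raise NoScanLinesError("thresholding produced a single motion state")

    if fit:
        p, q, phase, fitted = _fit_square_wave(raw_static)
        static = fitted
    else:
        p = q = phase = 0
        static = raw_static

    # series element i covers the frame pair (i, i+1); a frame is static
    # when it participates in any static pair
    frame_static = np.zeros(n + 1, dtype=bool)
    frame_static[:-1] |= static
    frame_static[1:] |= static
    if frame_static.all() or (~frame_static).all():
        raise NoScanLinesError("motion model degenerated to a single state")
    return SquareWaveModel(line_period_frames=p, pause_frames=q,
                           phase_frames=phase, series_static=static,
                           frame_moving=~frame_static)


@dataclass(frozen=True)
class ScanLineSegment:
    """Contiguous run of moving frames forming one scan line."""

    start_frame: int  # inclusive
    end_frame: int    # exclusive
    row_index: int
    direction: str    # '+x' or '-x'

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def detect_scan_lines(model: SquareWaveModel,
                      first_direction: str = "+x") -> list[ScanLineSegment]:
    """One segment per moving run, directions alternating row to row."""
    if first_direction not in DIRECTION_SIGN:
        raise ValueError("first_direction must be '+x' or '-x'")
    fm = model.frame_moving
    segments: list[ScanLineSegment] = []
    first = DIRECTION_SIGN[first_direction]
    i = 0
    n = len(fm)
    while i < n:
        if fm[i]:
            j = i
            while j < n and fm[j]:
                j += 1
            r = len(segments)
            sign = first * (1 if r % 2 == 0 else -1)
            segments.append(ScanLineSegment(start_frame=i, end_frame=j,
                                            row_index=r,
                                            direction=SIGN_DIRECTION[sign]))
            i = j
        else:
            i += 1
    if not segments:
        raise NoScanLinesError("no moving run found")
    return segments


@dataclass
class Mosaic:
    """Stitched whole-slide raster with provenance metadata."""

    raster: np.ndarray  # (H, W, 3) float32
    pixel_size_um: float = 1.0
    provenance: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        arr8 = np.round(np.clip(self.raster, 0, 1) * 255.0).astype(np.uint8)
        tifffile.imwrite(Path(path), arr8)

    @classmethod
    def load(cls, path: str | Path, pixel_size_um: float = 1.0) -> "Mosaic":
        arr = np.asarray(tifffile.imread(Path(path)), dtype=np.float32) / 255.0
        return cls(raster=arr, pixel_size_um=pixel_size_um)


DEFAULT_MAX_MOSAIC_PX = 40_000


def assemble_mosaic(frames: np.ndarray | Sequence[np.ndarray],
                    segments: Sequence[ScanLineSegment],
                    per_frame_advance_px: float,
                    row_step_px: float,
                    pixel_size_um: float = 1.0,
                    blend: str = "last",
                    max_px: int = DEFAULT_MAX_MOSAIC_PX) -> Mosaic:
    """Place segment frames at uniform offsets and stack rows.

    '-x' segments run right-to-left in slide coordinates, so their frames
    are laid out from the far end back toward the origin. Overlaps resolve
    by the blend rule: 'last' (later frame wins) or 'average'.
    """
    if per_frame_advance_px <= 0 or row_step_px <= 0:
        raise ValueError("advance and row step must be positive")
    if blend not in ("last", "average"):
        raise ValueError("blend must be 'last' or 'average'")
    if not segments:
        raise ValueError("no segments to assemble")
    f0 = np.asarray(frames[segments[0].start_frame])
    fh, fw = f0.shape[:2]

    max_len = max(s.n_frames for s in segments)
    width = fw + int(round(per_frame_advance_px * (max_len - 1)))
    height = fh + int(round(row_step_px * (len(segments) - 1)))
    if max(width, height) > max_px:
        raise SizeError(f"mosaic {height}x{width} exceeds limit {max_px}")

    canvas = np.ones((height, width, 3), dtype=np.float32)
    if blend == "average":
        acc = np.zeros_like(canvas)
        cnt = np.zeros((height, width, 1), dtype=np.float32)

    for seg in segments:
        y0 = int(round(seg.row_index * row_step_px))
        k = seg.n_frames
        for j in range(k):
            frame = np.asarray(frames[seg.start_frame + j], dtype=np.float32)
            if frame.ndim == 2:
                frame = frame[..., None].repeat(3, axis=2)
            slot = j if seg.direction == "+x" else (k - 1 - j)
            x0 = int(round(slot * per_frame_advance_px))
            if blend == "last":
                canvas[y0:y0 + fh, x0:x0 + fw] = frame
            else:
                acc[y0:y0 + fh, x0:x0 + fw] += frame
                cnt[y0:y0 + fh, x0:x0 + fw] += 1.0
    if blend == "average":
        covered = cnt[..., 0] > 0
        canvas[covered] = (acc[covered] / cnt[covered])

    return Mosaic(raster=canvas, pixel_size_um=pixel_size_um,
                  provenance={"n_frames": int(len(frames)),
                              "n_segments": len(segments),
                              "advance_px": float(per_frame_advance_px),
                              "row_step_px": float(row_step_px),
                              "blend": blend})


def stitch_frames(frames: np.ndarray, config: ScanConfig,
                  first_direction: str = "+x", fit: bool = True,
                  blend: str = "last") -> tuple[Mosaic, list[ScanLineSegment],
                                                SquareWaveModel]:
    """Full chain: correlations -> motion model -> segments -> mosaic."""
    series = frame_correlations(frames)
    model = classify_motion(series, fit=fit)
    segments = detect_scan_lines(model, first_direction)
    mosaic = assemble_mosaic(
        frames, segments,
        per_frame_advance_px=config.advance_px_per_frame,
        row_step_px=config.effective_row_step_um / config.pixel_size_um,
        pixel_size_um=config.pixel_size_um,
        blend=blend)
    return mosaic, segments, model
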