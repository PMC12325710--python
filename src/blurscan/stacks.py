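"""Multi-scale input stacks: one global downsample plus random crops."""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile
from skimage.transform import resize

from .cores import LabeledCoreImage
from .errors import SizeError


@dataclass
class PatchStack:
    """(1 + n_crops) S x S RGB images: slot 0 is the downsampled full core,
    the remaining slots are random full-resolution crops."""

    images: np.ndarray  # (n_slots, S, S, 3) float32
    offsets: list[tuple[int, int]]  # (y, x) per crop slot
    size: int
    seed: int
    core_id: str = ""
    repeat_index: int = 1
    label: int = -1

    def __post_init__(self) -> None:
        n, s1, s2, ch = self.images.shape
        if s1 != self.size or s2 != self.size or ch != 3:
            raise ValueError("stack images must be (n_slots, S, S, 3)")
        if len(self.offsets) != n - 1:
            raise ValueError("one offset per crop slot expected")

    @property
    def n_slots(self) -> int:
        return self.images.shape[0]

    def as_channels(self) -> np.ndarray:
        """Channel-stacked layout for the classifier: (3 * n_slots, S, S)."""
        return np.transpose(self.images, (0, 3, 1, 2)).reshape(
            3 * self.n_slots, self.size, self.size)

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = f"{self.core_id or 'stack'}_rep{self.repeat_index}"
        arr8 = np.round(np.clip(self.images, 0, 1) * 255.0).astype(np.uint8)
        tifffile.imwrite(out_dir / f"{stem}.tiff", arr8)
        meta = {"core_id": self.core_id, "repeat_index": self.repeat_index,
                "label": self.label, "size": self.size, "seed": self.seed,
                "offsets": [list(o) for o in self.offsets]}
        (out_dir / f"{stem}.json").write_text(json.dumps(meta))
        return out_dir / f"{stem}.tiff"

    @classmethod
    def load(cls, tiff_path: str | Path) -> "PatchStack":
        tiff_path = Path(tiff_path)
        images = np.asarray(tifffile.imread(tiff_path), dtype=np.float32) / 255.0
        meta = json.loads(tiff_path.with_suffix(".json").read_text())
        return cls(images=images,
                   offsets=[tuple(o) for o in meta["offsets"]],
                   size=int(meta["size"]), seed=int(meta["seed"]),
                   core_id=meta["core_id"],
                   repeat_index=int(meta["repeat_index"]),
                   label=int(meta["label"]))


def derive_stack_seed(global_seed: int, core_id: str, repeat_index: int) -> int:
    key = f"{global_seed}:{core_id}:{repeat_index}".encode()
    return zlib.crc32(key) & 0xFFFFFFFF


def build_stack(core: Union[LabeledCoreImage, np.ndarray], size: int = 512,
                n_crops: int = 4, seed: int = 0) -> PatchStack:
    """Build the multi-scale stack for one core image.

    Sources smaller than ``size`` are reflect-padded before cropping; the
    downsample uses anti-aliased interpolation over the full source.
    Deterministic given ``seed``.
    """
    if size <= 0:
        raise SizeError("stack size must be positive")
    if n_crops < 0:
        raise ValueError("n_crops must be >= 0")

    if isinstance(core, LabeledCoreImage):
        src = core.rgb
        core_id, repeat_index, label = core.core_id, core.repeat_index, core.her2_score
    else:
        src = np.asarray(core)
        core_id, repeat_index, label = "", 1, -1
    src = np.asarray(src, dtype=np.float32)
    if src.ndim == 2:
        src = src[..., None].repeat(3, axis=2)

    h, w = src.shape[:2]
    pad_y, pad_x = max(0, size - h), max(0, size - w)
    if pad_y or pad_x:
        src = np.pad(src, [(0, pad_y), (0, pad_x), (0, 0)], mode="reflect")
        h, w = src.shape[:2]

    if (h, w) == (size, size):
        down = src.copy()
    else:
        down = resize(src, (size, size), order=1, anti_aliasing=True,
                      preserve_range=True).astype(np.float32)

    rng = np.random.default_rng(seed)
    slots = [down]
    offsets: list[tuple[int, int]] = []
    for _ in range(n_crops):
        y = int(rng.integers(0, h - size + 1))
        x = int(rng.integers(0, w - size + 1))
        slots.append(src[y:y + size, x:x + size].copy())
        offsets.append((y, x))

    return PatchStack(images=np.stack(slots).astype(np.float32),
                      offsets=offsets, size=size, seed=seed, core_id=core_id,
                      repeat_index=repeat_index, label=label)
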