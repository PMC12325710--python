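"""Convenience generators for classifier-ready synthetic datasets.

Glue between the slide generator, the blur model and the stack builder:
renders single cores per score class, applies the scan blur, and packs the
multi-scale stacks into arrays for training.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .scansim import BlurKernel, motion_blur
from .stacks import build_stack
from .synthslide import HER2AppearanceParams, _derive_seed, render_core


def make_stack_dataset(n_per_class: int, size: int = 128, n_crops: int = 4,
                       core_diameter_um: float = 160.0,
                       pixel_size_um: float = 1.0,
                       blur_width_um: float = 16.0,
                       params: Optional[HER2AppearanceParams] = None,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render blurred cores for every score and build their input stacks.

    Returns ``(stacks, labels)`` where ``stacks`` is
    (4 * n_per_class, 3 * (1 + n_crops), size, size) uint8 and rows
    alternate over classes so any prefix stays balanced. Blur direction
    alternates sample to sample, mimicking zigzag rows. Deterministic
    given ``seed``.
    """
    params = params or HER2AppearanceParams()
    n_slots = 1 + n_crops
    n_total = 4 * n_per_class
    stacks = np.empty((n_total, 3 * n_slots, size, size), dtype=np.uint8)
    labels = np.empty(n_total, dtype=np.int64)

    i = 0
    for k in range(n_per_class):
        for score in range(4):
            core_seed = _derive_seed(seed, "core", score, k)
            core = render_core(params, score, core_diameter_um,
                               pixel_size_um, seed=core_seed)
            if blur_width_um > 0:
                direction = "+x" if (i % 2 == 0) else "-x"
                kernel = BlurKernel(width_um=blur_width_um,
                                    pixel_size_um=pixel_size_um,
                                    direction=direction)
                core = motion_blur(core, kernel)
            stack = build_stack(core.astype(np.float32), size=size,
                                n_crops=n_crops,
                                seed=_derive_seed(seed, "stack", score, k))
            stacks[i] = np.round(
                np.clip(stack.as_channels(), 0, 1) * 255).astype(np.uint8)
            labels[i] = score
            i += 1
    return stacks, labels
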