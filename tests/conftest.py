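import numpy as np
import pytest

from blurscan.scansim import ScanConfig, plan_zigzag, simulate_scan
from blurscan.synthslide import CoreLayout, generate_slide


@pytest.fixture(scope="session")
def small_layout() -> CoreLayout:
    return CoreLayout(n_rows=2, n_cols=3, pitch_um=200.0,
                      core_diameter_um=120.0)


@pytest.fixture(scope="session")
def small_slide(small_layout):
    """2x3 synthetic TMA slide with one core per score plus repeats."""
    slide, manifest = generate_slide(small_layout, [0, 1, 2, 3, 2, 1],
                                     seed=1, margin_um=60.0)
    return slide, manifest


@pytest.fixture(scope="session")
def scan_config() -> ScanConfig:
    """Desk-scale scan: 160x120 px FOV, 80 px/frame advance, 16 px blur."""
    return ScanConfig(s_x_um_per_s=2000.0, acquisition_time_s=0.0078,
                      fps=25.0, fov_px=(160, 120), pixel_size_um=1.0,
                      pause_s=0.6, row_step_um=96.0)


@pytest.fixture(scope="session")
def small_scan(small_slide, scan_config):
    """Simulated zero-jitter scan of the small slide."""
    slide, _ = small_slide
    trace = plan_zigzag((slide.width_um, slide.height_um), scan_config)
    return simulate_scan(slide, trace, scan_config, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
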