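import numpy as np
import pytest

from mxsqueeze.core import DetectorGeometry, Frame, FrameStack, ScanMetadata
from mxsqueeze.synth import preset, render_stack


@pytest.fixture(scope="session")
def desk_small():
    """The standard desk-scale synthetic acquisition (512x512, 40 frames)."""
    stack, truth = render_stack(preset("desk-small", seed=7))
    return stack, truth


@pytest.fixture
def tiny_stack():
    """4-frame 16x16 stack with one gap stripe, deterministic counts."""
    rng = np.random.default_rng(42)
    geometry = DetectorGeometry(
        n_rows=16,
        n_cols=16,
        pixel_size=0.075,
        beam_center_row=8.0,
        beam_center_col=8.0,
        detector_distance=150.0,
        wavelength=1.0,
        gap_regions=((6, 8, 0, 16),),
    )
    scan = ScanMetadata(osc_start=0.0, osc_width=0.2, n_frames=4, count_time=0.1)
    valid = geometry.valid_plane()
    frames = []
    for i in range(4):
        counts = rng.integers(0, 1000, size=(16, 16)).astype(np.int32)
        counts[~valid] = 0
        frames.append(Frame(counts, valid.copy(), i))
    return FrameStack(frames, geometry, scan)
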