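import numpy as np
import pytest

from ivoct import (
    AcquisitionConfig,
    make_calibration,
    make_phantom_polar_pullback,
)
from ivoct import segment as sg
from ivoct import stent_region as rg

PHANTOM_SEED = 11


@pytest.fixture(scope="session")
def small_cfg():
    """Small fringe geometry: padded length 256, demod grid 512."""
    return AcquisitionConfig(n_samples=200, n_alines=8, n_channels=2, n_frames=2)


@pytest.fixture(scope="session")
def ideal_cal(small_cfg):
    """Identity k-map, zero dispersion."""
    return make_calibration(small_cfg, k_nonlinearity=0.0, dispersion_coeffs=(0.0,), seed=1)


@pytest.fixture(scope="session")
def warped_cal(small_cfg):
    """Nonlinear k-map plus quadratic dispersion."""
    return make_calibration(
        small_cfg, k_nonlinearity=0.15, dispersion_coeffs=(0.0, 0.0, 25.0), seed=1
    )


@pytest.fixture(scope="session")
def phantom_cfg():
    return AcquisitionConfig(n_frames=20, n_alines=256)


@pytest.fixture(scope="session")
def noisy_phantom(phantom_cfg):
    """20-frame default-noise phantom with struts in frames 4-15."""
    return make_phantom_polar_pullback(
        phantom_cfg, rows=400, stent_frames=(4, 15), noise_sd=6.0, seed=PHANTOM_SEED
    )


@pytest.fixture(scope="session")
def clean_phantom(phantom_cfg):
    """Zero-noise phantom whose strut distances keep a >= 3 px margin from the
    malapposition threshold (apposed <= 12, malapposed >= 19)."""
    return make_phantom_polar_pullback(
        phantom_cfg,
        rows=400,
        stent_frames=(4, 15),
        apposed_distance_px=(0, 12),
        malapposed_distance_px=(19, 28),
        noise_sd=0.0,
        seed=PHANTOM_SEED,
    )


def segment_phantom(stack, first, last):
    """Run the segmentation chain over a frame range; returns FrameSegmentations."""
    sub = stack[first : last + 1]
    candidates = sg.detect_guidewire_alines(rg.build_enface(sub))
    out = []
    for i, f in enumerate(range(first, last + 1)):
        out.append(
            sg.segment_frame(stack[f], frame_index=f, guidewire_candidate=candidates[i])
        )
    return out


@pytest.fixture(scope="session")
def noisy_phantom_segmentation(noisy_phantom):
    stack, truth = noisy_phantom
    s0, s1 = truth.stent_frame_range
    return segment_phantom(stack, s0, s1)


@pytest.fixture(scope="session")
def clean_phantom_segmentation(clean_phantom):
    stack, truth = clean_phantom
    s0, s1 = truth.stent_frame_range
    return segment_phantom(stack, s0, s1)
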