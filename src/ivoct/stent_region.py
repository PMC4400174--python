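"""Automatic selection of the pullback frames containing stent struts.

The pullback is collapsed into an *en face* image (depth-averaged intensity,
A-lines x frames). Struts perturb the depth-averaged intensity sharply, so an
8-neighbor Laplacian after contrast stretching responds strongly around them;
thresholding the response at 240 marks strut evidence, and a sliding window
sized from the nominal stent length picks the frame range with the most
evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "FrameRange",
    "build_enface",
    "enhance_struts",
    "estimate_window_length",
    "select_stent_region",
    "region_accuracy",
]

#: Laplacian response threshold marking strut evidence on the stretched en face
DEFAULT_STRUT_THRESHOLD = 240

LAPLACIAN_8 = np.array([[1, 1, 1], [1, -8, 1], [1, 1, 1]], dtype=float)


@dataclass(frozen=True)
class FrameRange:
    """Inclusive frame interval."""

    first: int
    last: int

    def __post_init__(self) -> None:
        if not 0 <= self.first <= self.last:
            raise ValueError(f"invalid frame range [{self.first}, {self.last}]")

    def __len__(self) -> int:
        return self.last - self.first + 1

    def frames(self) -> range:
        return range(self.first, self.last + 1)


def build_enface(stack: np.ndarray) -> np.ndarray:
    """Depth-averaged en face image: pixel (aline, frame) = mean over depth.

    ``stack`` is (n_frames, rows, n_alines); the result is
    (n_alines, n_frames).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("expected a non-empty (n_frames, rows, n_alines) stack")
    return stack.mean(axis=1, dtype=float).T


def enhance_struts(
    enface: np.ndarray,
    threshold: float = DEFAULT_STRUT_THRESHOLD,
    min_component_px: int = 0,
) -> np.ndarray:
    """Binary strut-evidence mask from an en face image.

    The en face is contrast-stretched so its brightest pixel maps to 255, the
    8-neighbor Laplacian magnitude is taken and clipped to [0, 255], and
    pixels with response above ``threshold`` are kept. ``min_component_px``
    optionally removes small connected components as noise (off by default).
    """
    ef = np.asarray(enface, float)
    lo, hi = ef.min(), ef.max()
    stretched = np.zeros_like(ef) if hi == lo else (ef - lo) * (255.0 / (hi - lo))
    response = np.abs(ndimage.convolve(stretched, LAPLACIAN_8, mode="nearest"))
    response = np.clip(response, 0, 255)
    mask = response > threshold
    if min_component_px > 1:
        mask = morphology.remove_small_objects(mask, min_size=min_component_px)
    return mask


def estimate_window_length(
    stent_length_mm: float, frame_pitch_mm: float, margin_frames: int = 0
) -> int:
    """Frames needed to cover a stent: ceil(length / pitch) + margin (28/0.2 -> 140)."""
    if stent_length_mm <= 0 or frame_pitch_mm <= 0:
        raise ValueError("stent length and frame pitch must be positive")
    if margin_frames < 0:
        raise ValueError("margin_frames must be >= 0")
    return math.ceil(stent_length_mm / frame_pitch_mm) + margin_frames


def select_stent_region(mask: np.ndarray, window_len: int) -> FrameRange:
    """Pick the window of frames with the most strut evidence, trimmed to content.

    A window of ``window_len`` frames slides over the mask columns; the window
    with the largest total count wins, ties going to the smallest first index.
    The returned range is trimmed to the first and last frame inside the
    window that contain at least one mask pixel.
    """
    mask = np.asarray(mask, bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D (n_alines, n_frames)")
    n_frames = mask.shape[1]
    per_frame = mask.sum(axis=0)
    if per_frame.sum() == 0:
        raise ValueError("no stent detected: strut-evidence mask is empty")
    window_len = min(max(int(window_len), 1), n_frames)
    counts = np.convolve(per_frame, np.ones(window_len, dtype=int), mode="valid")
    start = int(np.argmax(counts))  # argmax returns the first maximum: smallest index
    stop = start + window_len  # exclusive
    inside = np.nonzero(per_frame[start:stop])[0]
    return FrameRange(first=start + int(inside[0]), last=start + int(inside[-1]))


def region_accuracy(truth: FrameRange, predicted: FrameRange) -> tuple[int, int]:
    """(missed, extra): truth frames not predicted, predicted frames not in truth."""
    t = set(truth.frames())
    p = set(predicted.frames())
    return len(t - p), len(p - t)
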