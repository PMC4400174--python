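"""Label-encoded Cartesian volume construction and static projection renders.

The intensity encoding keeps the vessel wall in [0, 200] and reserves the
band above for features: guide-wire 210, apposed strut 230, malapposed strut
255. Wall pixels are interpolated bilinearly through every geometric
transform while label pixels use nearest-neighbour, so label values are never
blended into intermediate intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, restoration, transform

from .segment import FrameSegmentation

__all__ = [
    "LABEL_GUIDEWIRE",
    "LABEL_APPOSED",
    "LABEL_MALAPPOSED",
    "LabeledVolume",
    "remap_intensity",
    "denoise_and_remap",
    "encode_features",
    "polar_to_cartesian",
    "align_lumen_center",
    "build_volume",
    "render_projection",
]

WALL_MAX = 200
LABEL_GUIDEWIRE = 210
LABEL_APPOSED = 230
LABEL_MALAPPOSED = 255
LABELS = (LABEL_GUIDEWIRE, LABEL_APPOSED, LABEL_MALAPPOSED)

#: bilateral filter defaults: spatial sigma in pixels, range sigma in 8-bit levels
BILATERAL_SIGMA_SPATIAL = 3.0
BILATERAL_SIGMA_LEVELS = 25.0


@dataclass
class LabeledVolume:
    """Cartesian label-encoded stack (frame, y, x) with its intensity encoding."""

    voxels: np.ndarray
    aspect_ratio: float = 1.0  # longitudinal pitch / in-plane pitch
    encoding: dict = field(
        default_factory=lambda: {
            "wall": [0, WALL_MAX],
            "guidewire": LABEL_GUIDEWIRE,
            "apposed_strut": LABEL_APPOSED,
            "malapposed_strut": LABEL_MALAPPOSED,
        }
    )

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3-D (frame, y, x)")


def remap_intensity(values: np.ndarray) -> np.ndarray:
    """Noise-suppressing piecewise remap of an 8-bit image.

    Values below 128 become 0; values in [128, 255] map linearly onto
    [0, 200]: v -> round((v - 128) * 200 / 127).
    """
    v = np.asarray(values, float)
    out = np.where(v < 128, 0.0, np.round((v - 128.0) * 200.0 / 127.0))
    return out.astype(np.uint8)


def denoise_and_remap(frame: np.ndarray) -> np.ndarray:
    """Bilateral-filter, equalize, and remap a polar frame for rendering.

    The bilateral filter removes high-frequency noise while keeping the lumen
    edge; histogram equalization spreads intensities over [0, 255]; the
    piecewise remap zeroes the lower half (residual noise) and compresses the
    rest into the wall band [0, 200].
    """
    img = np.asarray(frame, float) / 255.0
    den = restoration.denoise_bilateral(
        img,
        sigma_color=BILATERAL_SIGMA_LEVELS / 255.0,
        sigma_spatial=BILATERAL_SIGMA_SPATIAL,
    )
    eq = np.round(exposure.equalize_hist(den) * 255.0)
    return remap_intensity(eq)


def encode_features(frame: np.ndarray, seg: FrameSegmentation, strut_radius: int = 3) -> np.ndarray:
    """Zero the lumen interior and stamp guide-wire / strut labels.

    ``frame`` must already be wall-remapped (values <= 200). Pixels shallower
    than the lumen contour are cleared; the guide-wire mask is set to 210 and
    each strut becomes a small disk of 230 (apposed) or 255 (malapposed).
    Without a lumen contour the frame passes through unchanged.
    """
    out = np.asarray(frame).copy()
    out = np.minimum(out, WALL_MAX).astype(np.uint8)
    if seg.lumen is None:
        return out
    rows = out.shape[0]
    depths = np.clip(np.round(seg.lumen.surface_depth_px).astype(int), 0, rows)
    mask_inside = np.arange(rows)[:, None] < depths[None, :]
    out[mask_inside] = 0
    if seg.guidewire.mask is not None:
        out[seg.guidewire.mask] = LABEL_GUIDEWIRE
    for s in seg.struts:
        label = LABEL_MALAPPOSED if s.malapposed else LABEL_APPOSED
        r0 = max(int(round(s.depth_px)) - strut_radius, 0)
        r1 = min(int(round(s.depth_px)) + strut_radius + 1, rows)
        c0 = max(s.aline - strut_radius, 0)
        c1 = min(s.aline + strut_radius + 1, out.shape[1])
        out[r0:r1, c0:c1] = label
    return out


def _polar_coords(out_size: int, rows: int, n_alines: int) -> tuple[np.ndarray, np.ndarray]:
    c = (out_size - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(out_size), np.arange(out_size), indexing="ij")
    dy, dx = yy - c, xx - c
    r = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    depth = r * rows / (out_size / 2.0)
    col = theta * n_alines / (2 * np.pi)
    return depth, col


def polar_to_cartesian(frame: np.ndarray, out_size: int = 1024) -> np.ndarray:
    """Inverse-map a polar frame onto a Cartesian disk.

    A-line 0 lies along +x and the angle grows counter-clockwise (toward +y
    rows). Wall intensities are sampled bilinearly from a label-free copy;
    label pixels (>= 201) are sampled nearest-neighbour and overlaid, so they
    stay exact. Pixels beyond the maximum depth are 0.
    """
    img = np.asarray(frame, float)
    rows, n_alines = img.shape
    depth, col = _polar_coords(out_size, rows, n_alines)
    # wrap the angular axis by appending the first column
    wall = np.where(img > WALL_MAX, 0.0, img)
    wall_w = np.concatenate([wall, wall[:, :1]], axis=1)
    img_w = np.concatenate([img, img[:, :1]], axis=1)
    coords = np.stack([depth.ravel(), col.ravel()])
    out = ndimage.map_coordinates(wall_w, coords, order=1, cval=0.0).reshape(depth.shape)
    labels = ndimage.map_coordinates(img_w, coords, order=0, cval=0.0).reshape(depth.shape)
    out[labels > WALL_MAX] = labels[labels > WALL_MAX]
    out[depth > rows - 1] = 0.0
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def lumen_center_cartesian(
    lumen_depths: np.ndarray, rows: int, out_size: int
) -> tuple[float, float]:
    """Area centroid (y, x) of the lumen contour polygon in Cartesian pixels.

    The area (shoelace) centroid is used rather than the vertex mean: A-lines
    sample the contour uniformly in angle as seen from the catheter, which
    over-represents the near wall, so the vertex mean recovers only half of
    the catheter eccentricity while the polygon centroid recovers it exactly
    for a circular lumen.
    """
    depths = np.asarray(lumen_depths, float)
    n_alines = depths.shape[0]
    theta = 2 * np.pi * np.arange(n_alines) / n_alines
    scale = (out_size / 2.0) / rows
    c = (out_size - 1) / 2.0
    x = c + depths * scale * np.cos(theta)
    y = c + depths * scale * np.sin(theta)
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-9:
        return float(y.mean()), float(x.mean())
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    return float(cy), float(cx)


def align_lumen_center(
    frame: np.ndarray, lumen_depths: np.ndarray | None, polar_rows: int
) -> tuple[np.ndarray, tuple[int, int]]:
    """Translate the frame so the lumen center sits at the image center.

    Returns the shifted frame and the integer (dy, dx) applied. Vacated
    pixels are zero; a missing contour yields the identity shift.
    """
    img = np.asarray(frame)
    if lumen_depths is None:
        return img.copy(), (0, 0)
    out_size = img.shape[0]
    cy, cx = lumen_center_cartesian(lumen_depths, polar_rows, out_size)
    c = (out_size - 1) / 2.0
    dy, dx = int(round(c - cy)), int(round(c - cx))
    out = np.zeros_like(img)
    src_y = slice(max(0, -dy), min(out_size, out_size - dy))
    src_x = slice(max(0, -dx), min(out_size, out_size - dx))
    dst_y = slice(max(0, dy), min(out_size, out_size + dy))
    dst_x = slice(max(0, dx), min(out_size, out_size + dx))
    out[dst_y, dst_x] = img[src_y, src_x]
    return out, (dy, dx)


def build_volume(
    frames: np.ndarray, out_size: int = 512, aspect_ratio: float = 1.0
) -> LabeledVolume:
    """Resize aligned Cartesian frames and stack them into a labeled volume.

    Wall intensities are resized with area-weighted (anti-aliased bilinear)
    interpolation; labels with nearest-neighbour so their values survive.
    """
    frames = np.asarray(frames)
    resized = []
    for img in frames:
        wall = np.where(img > WALL_MAX, 0, img).astype(float)
        wall_r = transform.resize(
            wall, (out_size, out_size), order=1, anti_aliasing=True, preserve_range=True
        )
        lab_r = transform.resize(
            img, (out_size, out_size), order=0, anti_aliasing=False, preserve_range=True
        )
        out = np.clip(np.round(wall_r), 0, WALL_MAX)
        out[lab_r > WALL_MAX] = lab_r[lab_r > WALL_MAX]
        resized.append(out.astype(np.uint8))
    return LabeledVolume(voxels=np.stack(resized, axis=0), aspect_ratio=aspect_ratio)


_COLOR_TABLE = {
    LABEL_GUIDEWIRE: (128, 128, 128),  # gray
    LABEL_APPOSED: (255, 220, 0),  # yellow
    LABEL_MALAPPOSED: (40, 90, 255),  # blue
}


def _colorize(values: np.ndarray) -> np.ndarray:
    """Wall -> red ramp, labels -> fixed colors."""
    rgb = np.zeros(values.shape + (3,), dtype=np.uint8)
    wall = values <= WALL_MAX
    rgb[..., 0][wall] = np.round(values[wall] * 255.0 / WALL_MAX)
    rgb[..., 1][wall] = np.round(values[wall] * 40.0 / WALL_MAX)
    rgb[..., 2][wall] = np.round(values[wall] * 40.0 / WALL_MAX)
    for label, color in _COLOR_TABLE.items():
        rgb[values == label] = color
    return rgb


def render_projection(volume: LabeledVolume, view: str = "cutaway-y") -> np.ndarray:
    """Orthographic maximum-value projection of the label-encoded volume.

    Because the encoding is ordered (wall < guide-wire < apposed <
    malapposed), a max projection surfaces the clinically most important
    voxel on each ray. Views: ``axial`` (along the pullback axis),
    ``cutaway-y`` / ``cutaway-x`` (remove the near half, project along y or
    x). Returns an RGB uint8 image.
    """
    vox = volume.voxels
    if view == "axial":
        proj = vox.max(axis=0) if vox.size else np.zeros((1, 1), np.uint8)
    elif view == "cutaway-y":
        half = vox[:, : vox.shape[1] // 2 or 1, :]
        proj = half.max(axis=1)
    elif view == "cutaway-x":
        half = vox[:, :, : vox.shape[2] // 2 or 1]
        proj = half.max(axis=2)
    else:
        raise ValueError(f"unknown view {view!r}")
    return _colorize(proj.astype(float))
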