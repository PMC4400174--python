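"""Raw pullback and calibration file I/O.

File layout (declared by this package; the acquisition hardware defines no
on-disk format):

* Raw pullback: flat little-endian signed int16, index order
  ``(frame, channel, aline, sample)`` with samples innermost, plus a YAML
  sidecar ``<stem>.yaml`` carrying the :class:`~ivoct.config.AcquisitionConfig`.
* Calibration: a directory with ``manifest.yaml`` referencing flat float64
  binaries for the background fringe (per channel), spectral window,
  k-linearization map and dispersion phase.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .config import AcquisitionConfig

__all__ = [
    "RawPullback",
    "CalibrationSet",
    "read_raw_pullback",
    "write_raw_pullback",
    "load_calibration",
    "save_calibration",
]


@dataclass
class RawPullback:
    """Integer fringe samples of a whole pullback, shape (frame, channel, aline, sample)."""

    samples: np.ndarray
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        c = self.config
        expected = (c.n_frames, c.n_channels, c.n_alines, c.n_samples)
        if self.samples.shape != expected:
            raise ValueError(
                f"sample array shape {self.samples.shape} does not match config {expected}"
            )
        if not np.issubdtype(self.samples.dtype, np.integer):
            raise ValueError("samples must be an integer array")
        lo, hi = int(self.samples.min(initial=0)), int(self.samples.max(initial=0))
        if lo < c.sample_min or hi > c.sample_max:
            raise ValueError(
                f"sample values [{lo}, {hi}] exceed signed {c.sample_bits}-bit range "
                f"[{c.sample_min}, {c.sample_max}]"
            )


@dataclass
class CalibrationSet:
    """Per-system reconstruction calibration.

    Attributes
    ----------
    background_fringe : (n_channels, n_samples) reference fringe recorded with
        the sample arm blocked; subtracted before windowing.
    window : (n_samples,) spectral shaping window in [0, 1].
    k_map : (demod_length,) strictly increasing fractional sample positions at
        which the demodulated complex fringe is resampled to become uniform in
        wavenumber.
    dispersion_phase : (demod_length,) phase correction in radians applied as
        exp(-i * phase) after k-linearization.
    """

    background_fringe: np.ndarray
    window: np.ndarray
    k_map: np.ndarray
    dispersion_phase: np.ndarray

    def __post_init__(self) -> None:
        self.background_fringe = np.atleast_2d(np.asarray(self.background_fringe, float))
        self.window = np.asarray(self.window, float)
        self.k_map = np.asarray(self.k_map, float)
        self.dispersion_phase = np.asarray(self.dispersion_phase, float)
        if self.window.min() < 0 or self.window.max() > 1:
            raise ValueError("window values must lie in [0, 1]")
        if self.background_fringe.shape[-1] != self.window.shape[0]:
            raise ValueError("background_fringe and window lengths differ")
        if np.any(np.diff(self.k_map) <= 0):
            raise ValueError("k_map must be strictly increasing")
        if self.k_map.shape != self.dispersion_phase.shape:
            raise ValueError("k_map and dispersion_phase lengths differ")

    @property
    def n_channels(self) -> int:
        return self.background_fringe.shape[0]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_raw_pullback(data: RawPullback, path: str | os.PathLike) -> None:
    """Write a pullback as flat little-endian int16 plus a YAML config sidecar."""
    path = Path(path)
    data.samples.astype("<i2").tofile(path)
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump({"acquisition": data.config.to_dict()}, fh)


def read_raw_pullback(
    path: str | os.PathLike, config: AcquisitionConfig | None = None
) -> RawPullback:
    """Read a pullback written by :func:`write_raw_pullback`.

    ``config`` overrides the sidecar when given; the file size must match the
    geometry exactly.
    """
    path = Path(path)
    if config is None:
        with open(_sidecar(path)) as fh:
            config = AcquisitionConfig.from_dict(yaml.safe_load(fh)["acquisition"])
    c = config
    expected = c.n_frames * c.n_channels * c.n_alines * c.n_samples * 2
    actual = path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"raw file size mismatch for {path}: expected {expected} bytes "
            f"({c.n_frames}x{c.n_channels}x{c.n_alines}x{c.n_samples} int16), got {actual}"
        )
    flat = np.fromfile(path, dtype="<i2")
    samples = flat.reshape(c.n_frames, c.n_channels, c.n_alines, c.n_samples)
    return RawPullback(samples=samples.astype(np.int16), config=c)


_CAL_ARRAYS = ("background_fringe", "window", "k_map", "dispersion_phase")


def save_calibration(cal: CalibrationSet, path: str | os.PathLike) -> None:
    """Save a calibration set as a directory of float64 binaries plus manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"arrays": {}}
    for name in _CAL_ARRAYS:
        arr = np.asarray(getattr(cal, name), "<f8")
        fname = f"{name}.bin"
        arr.tofile(path / fname)
        manifest["arrays"][name] = {"file": fname, "shape": list(arr.shape)}
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def load_calibration(path: str | os.PathLike) -> CalibrationSet:
    """Load a calibration directory; validates k_map monotonicity and window range."""
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    kwargs = {}
    for name in _CAL_ARRAYS:
        entry = manifest["arrays"][name]
        arr = np.fromfile(path / entry["file"], dtype="<f8").reshape(entry["shape"])
        kwargs[name] = arr
    return CalibrationSet(**kwargs)
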