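"""Acquisition geometry shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


@dataclass(frozen=True)
class AcquisitionConfig:
    """Geometry of one catheter pullback acquisition.

    Defaults describe a swept-source intracoronary system digitizing 1600
    samples per spectral sweep on two polarization channels, 1024 A-lines per
    rotation, with a 200 um longitudinal pitch and 6.5 um axial pixel pitch.

    Parameters
    ----------
    n_samples : samples digitized per A-line fringe.
    n_alines : A-lines per frame per polarization channel.
    n_channels : polarization channels.
    n_frames : frames in the pullback.
    frame_pitch_um : longitudinal spacing between frames (um).
    axial_pitch_um : depth pixel spacing in reconstructed images (um).
    sample_bits : digitizer resolution in bits (samples stored as int16).
    """

    n_samples: int = 1600
    n_alines: int = 1024
    n_channels: int = 2
    n_frames: int = 260
    frame_pitch_um: float = 200.0
    axial_pitch_um: float = 6.5
    sample_bits: int = 14

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_alines", "n_channels", "n_frames"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.frame_pitch_um <= 0 or self.axial_pitch_um <= 0:
            raise ValueError("pitches must be positive")
        if not 8 <= self.sample_bits <= 16:
            raise ValueError(f"sample_bits must be in [8, 16], got {self.sample_bits}")

    @property
    def padded_length(self) -> int:
        """Zero-padded fringe length: next power of two >= n_samples (1600 -> 2048)."""
        return _next_pow2(self.n_samples)

    @property
    def demod_length(self) -> int:
        """Length of the demodulated complex fringe (2x the padded length)."""
        return 2 * self.padded_length

    @property
    def sample_min(self) -> int:
        return -(1 << (self.sample_bits - 1))

    @property
    def sample_max(self) -> int:
        return (1 << (self.sample_bits - 1)) - 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown AcquisitionConfig keys: {sorted(unknown)}")
        return cls(**d)
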