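"""Synthetic fringes and phantom pullbacks with ground truth.

Two generators drive the hardware-free pipeline:

* :func:`simulate_pullback_fringes` builds raw interference fringes from point
  scatterers under a quarter-rate frequency-shift carrier, sampled on a
  nonlinear wavenumber grid with a polynomial dispersion phase — the inverse
  model of the reconstruction chain.
* :func:`make_phantom_polar_pullback` renders 8-bit polar frames of an
  eccentric vessel wall with catheter sheath, guide-wire (bright spot plus
  full-depth shadow) and apposed/malapposed stent struts, together with an
  exact ground-truth table for scoring segmentation.

Everything is deterministic given its seed.

Signal model
------------
For a scatterer at signed depth ``d`` pixels (padded record length L, carrier
at L/4 cycles per record) the fringe at digitizer sample n is::

    a * cos(2*pi*(L/4)*n/L + 2*pi*d*u(n)/L + phi(n))

where ``u`` is the nonlinear wavenumber sampling map and ``phi`` the
dispersion phase. The carrier rides the uniform digitizer clock (it is an
electro-optic frequency shift) while the depth-encoding term follows the
laser sweep, so k-linearization straightens depth chirp without touching the
carrier. Depths are limited to |d| < L/4, the band the quarter-rate carrier
can separate without folding at DC or Nyquist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AcquisitionConfig
from .io import CalibrationSet, RawPullback

__all__ = [
    "ScattererSpec",
    "StrutTruth",
    "PhantomTruth",
    "make_calibration",
    "simulate_pullback_fringes",
    "make_phantom_polar_pullback",
]


@dataclass(frozen=True)
class ScattererSpec:
    """A point reflector: signed depth in pixels, relative amplitude in counts,
    and the half-open A-line interval where it is present."""

    depth_px: float
    amplitude: float
    aline_range: tuple[int, int] | None = None  # None = all A-lines

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class StrutTruth:
    frame: int
    aline: int
    depth_px: int
    distance_px: int
    malapposed: bool


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom polar pullback."""

    stent_frame_range: tuple[int, int] | None
    lumen_contour: np.ndarray  # (n_frames, n_alines) int depths
    struts: list[StrutTruth]
    guidewire_alines: np.ndarray  # (n_frames, 2) inclusive intervals
    sheath_depth_px: np.ndarray  # (n_frames,)
    malapposition_threshold_px: int
    catheter_offset_px: tuple[float, float]


def make_calibration(
    config: AcquisitionConfig,
    k_nonlinearity: float = 0.0,
    dispersion_coeffs: tuple[float, ...] = (0.0,),
    seed: int = 0,
) -> CalibrationSet:
    """Build a self-consistent calibration set.

    The wavenumber sampling map is ``u(n) = n + k*(L/(2*pi))*sin(2*pi*n/L)``
    on the padded grid; it stays strictly monotone for |k| < 1. The stored
    k_map gives, for each demodulated-grid bin m, the fractional position
    ``2*u^-1(m/2)`` at which resampling linearizes the fringe. The dispersion
    phase is the polynomial ``dispersion_coeffs`` (ascending powers) in the
    centered, normalized sample coordinate, evaluated on the post-resampling
    grid so multiplication by exp(-i*phase) cancels the simulator's phase
    exactly. Background fringes are smooth positive integer-valued curves,
    slightly different per channel; the window is a Hanning window.
    """
    L = config.padded_length
    if abs(k_nonlinearity) >= 1.0:
        raise ValueError(
            f"|k_nonlinearity| must be < 1 to keep the sampling map monotone, "
            f"got {k_nonlinearity}"
        )
    rng = np.random.default_rng(seed)

    n_grid = np.arange(L + 1, dtype=float)
    u_vals = n_grid + k_nonlinearity * (L / (2 * np.pi)) * np.sin(2 * np.pi * n_grid / L)
    if np.any(np.diff(u_vals) <= 0):
        raise ValueError("sampling map is not strictly monotone")

    m = np.arange(2 * L, dtype=float)
    # u^-1 by interpolating the (u, n) relation
    k_map = 2.0 * np.interp(m / 2.0, u_vals, n_grid)
    # cap within the grid while staying strictly increasing: the min of two
    # strictly increasing sequences is strictly increasing; the affected bins
    # lie in the zero-padded tail of the record
    cap = (2 * L - 1.0) - 1e-6 * (2 * L - 1 - m)
    k_map = np.minimum(k_map, cap)

    half = config.n_samples / 2.0
    x = (k_map / 2.0 - half) / half
    dispersion_phase = np.polynomial.polynomial.polyval(x, np.asarray(dispersion_coeffs, float))

    n = np.arange(config.n_samples, dtype=float)
    bg = np.empty((config.n_channels, config.n_samples))
    for ch in range(config.n_channels):
        level = 250.0 + 40.0 * rng.random()
        ripple = 30.0 * np.sin(2 * np.pi * (2 + ch) * n / config.n_samples + rng.random())
        envelope = np.exp(-(((n - half) / (0.6 * config.n_samples)) ** 2))
        bg[ch] = np.round(level * envelope + ripple + 100.0)

    window = np.hanning(config.n_samples)
    return CalibrationSet(
        background_fringe=bg,
        window=window,
        k_map=np.ascontiguousarray(k_map),
        dispersion_phase=dispersion_phase,
    )


def _sampling_map(cal: CalibrationSet, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward nonlinear map u(n) and dispersion phase phi(n) at digitizer samples."""
    m = np.arange(cal.k_map.shape[0], dtype=float)
    n = np.arange(n_samples, dtype=float)
    u = np.interp(n, cal.k_map / 2.0, m / 2.0)
    phi = np.interp(n, cal.k_map / 2.0, cal.dispersion_phase)
    return u, phi


def simulate_pullback_fringes(
    scatterers: list[list[ScattererSpec]],
    cal: CalibrationSet,
    config: AcquisitionConfig,
    carrier_frequency: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RawPullback:
    """Synthesize raw integer fringes for a pullback.

    ``scatterers`` holds one list of :class:`ScattererSpec` per frame (the
    list is cycled if shorter than ``config.n_frames``). The default carrier
    is L/4 cycles per padded record, which the demodulation stage maps to
    depth zero. Both polarization channels receive the same scatterers (the
    phantom carries no birefringence contrast); noise is independent per
    channel. Samples are quantized to integer counts and clipped to the
    digitizer range.
    """
    L = config.padded_length
    fc = L / 4.0 if carrier_frequency is None else float(carrier_frequency)
    max_depth = L / 4.0
    rng = np.random.default_rng(seed)
    u, phi = _sampling_map(cal, config.n_samples)
    n = np.arange(config.n_samples, dtype=float)
    carrier_phase = 2 * np.pi * fc * n / L + phi

    out = np.zeros(
        (config.n_frames, config.n_channels, config.n_alines, config.n_samples), dtype=float
    )
    for f in range(config.n_frames):
        specs = scatterers[f % len(scatterers)] if scatterers else []
        frame = np.zeros((config.n_alines, config.n_samples))
        for sc in specs:
            if abs(sc.depth_px) >= max_depth:
                raise ValueError(
                    f"scatterer depth {sc.depth_px} outside full-range band "
                    f"(|d| < {max_depth})"
                )
            tone = sc.amplitude * np.cos(carrier_phase + 2 * np.pi * sc.depth_px * u / L)
            if sc.aline_range is None:
                frame += tone
            else:
                a0, a1 = sc.aline_range
                frame[a0:a1] += tone
        for ch in range(config.n_channels):
            sig = frame + cal.background_fringe[ch]
            if noise_sd > 0:
                sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
            out[f, ch] = sig
    quantized = np.clip(np.round(out), config.sample_min, config.sample_max).astype(np.int16)
    return RawPullback(samples=quantized, config=config)


def _gaussian_blob(img: np.ndarray, row: int, col: int, amplitude: float, sigma: float) -> None:
    """Add a small isotropic Gaussian spot in place (3-sigma support)."""
    r = int(np.ceil(3 * sigma))
    r0, r1 = max(row - r, 0), min(row + r + 1, img.shape[0])
    c0, c1 = max(col - r, 0), min(col + r + 1, img.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2)
    )


def _lumen_depths(
    n_alines: int, radius_px: float, offset: tuple[float, float]
) -> np.ndarray:
    """Depth of an eccentric circular lumen surface seen from the catheter.

    The catheter sits at ``offset`` (pixels) from the lumen center; the ray at
    angle theta meets the circle at range e*cos(theta-phi0) +
    sqrt(R^2 - e^2 sin^2(theta-phi0)).
    """
    theta = 2 * np.pi * np.arange(n_alines) / n_alines
    ox, oy = offset
    e = float(np.hypot(ox, oy))
    if e >= radius_px:
        raise ValueError("catheter offset must be inside the lumen")
    phi0 = np.arctan2(-oy, -ox)  # direction from catheter toward lumen center
    rel = theta - phi0
    depths = e * np.cos(rel) + np.sqrt(radius_px**2 - (e * np.sin(rel)) ** 2)
    return np.round(depths).astype(int)


def make_phantom_polar_pullback(
    config: AcquisitionConfig,
    rows: int = 400,
    sheath_depth_px: int = 30,
    lumen_radius_px: float = 160.0,
    wall_thickness_px: int = 110,
    catheter_offset_px: tuple[float, float] = (25.0, 12.0),
    stent_frames: tuple[int, int] | None = None,
    struts_per_frame: int = 6,
    apposed_distance_px: tuple[int, int] = (0, 8),
    malapposed_distance_px: tuple[int, int] = (19, 28),
    malapposed_fraction: float = 0.3,
    malapposition_threshold_px: int = 15,
    guidewire_width_alines: int = 36,
    guidewire_depth_px: int = 60,
    noise_sd: float = 6.0,
    seed: int = 0,
) -> tuple[np.ndarray, PhantomTruth]:
    """Render a phantom polar pullback and its ground truth.

    Returns an 8-bit stack ``(n_frames, rows, n_alines)`` and a
    :class:`PhantomTruth`. Frames contain a bright sheath line, an eccentric
    vessel wall, a guide-wire blob with a full-depth shadow, and — within
    ``stent_frames`` — bright strut blobs (sigma 2 px) casting rectangular
    shadows. Apposed strut distances are drawn from ``apposed_distance_px``
    and malapposed ones from ``malapposed_distance_px``; the latter must lie
    strictly above the threshold.
    """
    if malapposed_distance_px[0] <= malapposition_threshold_px:
        raise ValueError(
            f"malapposed distances must exceed the threshold "
            f"{malapposition_threshold_px}, got minimum {malapposed_distance_px[0]}"
        )
    if apposed_distance_px[1] > malapposition_threshold_px:
        raise ValueError("apposed distances must not exceed the threshold")
    n_frames, n_alines = config.n_frames, config.n_alines
    if stent_frames is not None:
        s0, s1 = stent_frames
        if not (0 <= s0 <= s1 < n_frames):
            raise ValueError(f"stent_frames {stent_frames} outside [0, {n_frames})")
    rng = np.random.default_rng(seed)

    lumen = np.empty((n_frames, n_alines), dtype=int)
    gw = np.empty((n_frames, 2), dtype=int)
    struts: list[StrutTruth] = []
    stack = np.zeros((n_frames, rows, n_alines), dtype=float)

    gw_center0 = int(0.55 * n_alines)
    for f in range(n_frames):
        img = stack[f]
        depths = _lumen_depths(n_alines, lumen_radius_px, catheter_offset_px)
        depths = np.clip(depths, sheath_depth_px + 20, rows - wall_thickness_px - 5)
        lumen[f] = depths

        # vessel wall: bright surface decaying into depth
        rr = np.arange(rows)[:, None]
        rel = rr - depths[None, :]
        in_wall = (rel >= 0) & (rel < wall_thickness_px)
        img[in_wall] = (185.0 * np.exp(-np.clip(rel, 0, None) / (0.9 * wall_thickness_px)))[in_wall]

        # catheter sheath: strong horizontal line
        img[sheath_depth_px - 1 : sheath_depth_px + 2, :] = 230.0

        # guide-wire: bright blob near the catheter with a full-depth shadow
        drift = int(round(3 * np.sin(2 * np.pi * f / max(n_frames, 1))))
        g0 = gw_center0 + drift
        g1 = g0 + guidewire_width_alines - 1
        gw[f] = (g0, g1)
        img[guidewire_depth_px : guidewire_depth_px + 12, g0 : g1 + 1] = 255.0
        img[guidewire_depth_px + 12 :, g0 : g1 + 1] *= 0.04

        # stent struts
        if stent_frames is not None and s0 <= f <= s1:
            margin = 8
            forbidden = set(range(g0 - margin - 40, g1 + margin + 41))
            placed: list[int] = []
            attempts = 0
            while len(placed) < struts_per_frame and attempts < 200:
                attempts += 1
                a = int(rng.integers(margin, n_alines - margin))
                if a in forbidden or any(abs(a - p) < 18 for p in placed):
                    continue
                placed.append(a)
            for a in sorted(placed):
                mal = bool(rng.random() < malapposed_fraction)
                lo, hi = malapposed_distance_px if mal else apposed_distance_px
                dist = int(rng.integers(lo, hi + 1))
                depth = int(depths[a]) - dist
                _gaussian_blob(img, depth, a, 255.0, 2.0)
                img[depth + 4 :, a - 2 : a + 3] *= 0.05
                struts.append(
                    StrutTruth(frame=f, aline=a, depth_px=depth, distance_px=dist, malapposed=mal)
                )

    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    stack8 = np.clip(np.round(stack), 0, 255).astype(np.uint8)

    truth = PhantomTruth(
        stent_frame_range=stent_frames,
        lumen_contour=lumen,
        struts=struts,
        guidewire_alines=gw,
        sheath_depth_px=np.full(n_frames, sheath_depth_px, dtype=int),
        malapposition_threshold_px=malapposition_threshold_px,
        catheter_offset_px=catheter_offset_px,
    )
    return stack8, truth
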