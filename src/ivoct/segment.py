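"""Feature segmentation: catheter sheath, guide-wire, lumen, stent struts.

Processing order per selected frame mirrors the imaging geometry: the sheath
(a bright constant-depth line near the top) is found and masked; guide-wire
A-lines are proposed from the en face shadow and refined per frame with
Otsu / erosion / top-hat / connected components; the luminal surface is
traced per A-line as the first persistent bright crossing, with shadowed
A-lines interpolated; struts are bright peaks just inside the lumen that cast
a distal shadow, clustered across adjacent A-lines; a strut is malapposed
when its radial distance to the lumen exceeds the strut-plus-polymer
thickness (100 um = 15 pixels at 6.5 um axial pitch, strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure

__all__ = [
    "SegmentationParams",
    "LumenContour",
    "StrutDetection",
    "GuidewireSegment",
    "FrameSegmentation",
    "detect_sheath",
    "mask_sheath",
    "detect_guidewire_alines",
    "refine_guidewire",
    "segment_lumen",
    "detect_struts",
    "cluster_struts",
    "classify_malapposition",
    "segment_frame",
    "evaluate_detection",
    "match_detections",
    "score_phantom",
]

#: malapposition threshold: floor(100 um / 6.5 um per pixel) = 15 pixels
MALAPPOSITION_THRESHOLD_PX = 15


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable constants of the segmentation chain (pixel units)."""

    sheath_band_frac: float = 0.2  # sheath searched in the top fraction of rows
    sheath_mask_halfwidth: int = 2
    guidewire_pad_alines: int = 40
    guidewire_pad_rows: int = 8  # zero rows prepended so erosion cannot clip the top
    lumen_persistence_rows: int = 25  # surface must stay bright this deep ...
    lumen_persistence_frac: float = 0.7  # ... in at least this fraction of rows
    lumen_median_width: int = 5
    lumen_outlier_px: int = 3  # contour deviation from the local median baseline ...
    lumen_outlier_median_width: int = 9  # ... computed over this many A-lines
    strut_search_above_px: int = 30
    strut_search_below_px: int = 5
    strut_intensity_min: float = 220.0
    strut_shadow_max: float = 40.0
    strut_shadow_gap_px: int = 6
    strut_shadow_depth_px: int = 40
    strut_contour_pad_alines: int = 4  # contour re-interpolated this far around struts
    cluster_max_gap_alines: int = 1
    cluster_max_depth_diff_px: int = 5
    cluster_min_alines: int = 2
    malapposition_threshold_px: int = MALAPPOSITION_THRESHOLD_PX


@dataclass
class LumenContour:
    """Per-A-line depth of the luminal surface; interpolated entries flagged."""

    surface_depth_px: np.ndarray
    interpolated: np.ndarray  # bool per A-line

    def __post_init__(self) -> None:
        self.surface_depth_px = np.asarray(self.surface_depth_px, float)
        self.interpolated = np.asarray(self.interpolated, bool)
        if self.surface_depth_px.shape != self.interpolated.shape:
            raise ValueError("contour and flag lengths differ")


@dataclass
class StrutDetection:
    frame: int
    aline: int
    depth_px: float
    distance_px: float = 0.0
    malapposed: bool = False


@dataclass
class GuidewireSegment:
    interval: tuple[int, int] | None  # inclusive A-line interval, None = absent
    mask: np.ndarray | None = None  # full-frame bool mask


@dataclass
class FrameSegmentation:
    frame: int
    sheath_depth_px: int
    guidewire: GuidewireSegment
    lumen: LumenContour | None
    struts: list[StrutDetection] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sheath


def detect_sheath(frame: np.ndarray, search_band: tuple[int, int] | None = None) -> int:
    """Row of the catheter sheath: the band row with the highest mean intensity.

    ``search_band`` is a half-open row interval; by default the top 20% of
    rows. Ties go to the smallest row.
    """
    img = np.asarray(frame, float)
    if search_band is None:
        search_band = (0, max(1, int(round(0.2 * img.shape[0]))))
    r0, r1 = search_band
    if not 0 <= r0 < r1 <= img.shape[0]:
        raise ValueError(f"search band {search_band} outside image rows [0, {img.shape[0]}]")
    means = img[r0:r1].mean(axis=1)
    return r0 + int(np.argmax(means))


def mask_sheath(frame: np.ndarray, sheath_row: int, halfwidth: int = 2) -> np.ndarray:
    """Copy of the frame with the sheath rows (and everything above) zeroed."""
    out = np.asarray(frame, float).copy()
    out[: sheath_row + halfwidth + 1] = 0.0
    return out


# ---------------------------------------------------------------------------
# guide-wire


def detect_guidewire_alines(enface: np.ndarray) -> list[tuple[int, int] | None]:
    """Candidate guide-wire A-line interval per frame from the en face shadow.

    The en face is Otsu-binarized with the dark class taken as shadow, cleaned
    by 3x3 morphological closing then opening, and the largest dark run of
    A-lines in each frame column becomes the candidate (None when no dark run
    survives).
    """
    ef = np.asarray(enface, float)
    if ef.max() == ef.min():
        return [None] * ef.shape[1]
    thr = filters.threshold_otsu(ef)
    dark = ef < thr
    footprint = np.ones((3, 3), bool)
    # edge-pad so shadows touching the first/last frame or A-line survive erosion
    padded = np.pad(dark, 2, mode="edge")
    padded = ndimage.binary_closing(padded, structure=footprint)
    padded = ndimage.binary_opening(padded, structure=footprint)
    dark = padded[2:-2, 2:-2]
    out: list[tuple[int, int] | None] = []
    for i in range(ef.shape[1]):
        col = dark[:, i]
        if not col.any():
            out.append(None)
            continue
        labels, n = ndimage.label(col)
        sizes = ndimage.sum(col, labels, index=np.arange(1, n + 1))
        best = 1 + int(np.argmax(sizes))
        idx = np.nonzero(labels == best)[0]
        out.append((int(idx[0]), int(idx[-1])))
    return out


def refine_guidewire(
    frame: np.ndarray,
    candidate: tuple[int, int],
    pad_alines: int = 40,
    params: SegmentationParams = SegmentationParams(),
) -> GuidewireSegment:
    """Pixel-precise guide-wire segmentation inside a padded ROI.

    The ROI spans the candidate interval padded by ``pad_alines`` columns on
    each side with zero rows prepended at the top. It is Otsu-binarized,
    eroded (3x3), and the top-hat of the erosion (5x5 opening residue) is
    subtracted to sever narrow bridges between the wire and nearby noise;
    connected-component labelling then keeps the largest component touching
    the candidate columns.
    """
    img = np.asarray(frame, float)
    n_alines = img.shape[1]
    a0 = max(candidate[0] - pad_alines, 0)
    a1 = min(candidate[1] + pad_alines, n_alines - 1)
    roi = img[:, a0 : a1 + 1]
    pad = np.zeros((params.guidewire_pad_rows, roi.shape[1]))
    roi = np.vstack([pad, roi])
    if roi.max() <= 0:
        return GuidewireSegment(interval=None)
    thr = filters.threshold_otsu(roi)
    binary = roi > thr
    if not binary.any():
        return GuidewireSegment(interval=None)
    ero = ndimage.binary_erosion(binary, structure=np.ones((3, 3), bool))
    opened = ndimage.binary_opening(ero, structure=np.ones((5, 5), bool))
    tophat = ero & ~opened
    severed = ero & ~tophat  # == opening; removes bridges narrower than 5 px
    labels = measure.label(severed, connectivity=2)
    if labels.max() == 0:
        return GuidewireSegment(interval=None)
    c_lo, c_hi = candidate[0] - a0, candidate[1] - a0
    best_label, best_area = 0, 0
    for region in measure.regionprops(labels):
        _, cmin, _, cmax = region.bbox
        if cmax - 1 < c_lo or cmin > c_hi:
            continue  # no overlap with the candidate columns
        if region.area > best_area:
            best_label, best_area = region.label, region.area
    if best_label == 0:
        return GuidewireSegment(interval=None)
    keep = labels == best_label
    keep = keep[params.guidewire_pad_rows :, :]  # drop the zero padding rows
    mask = np.zeros(img.shape, bool)
    mask[:, a0 : a1 + 1] = keep
    cols = np.nonzero(keep.any(axis=0))[0]
    interval = (a0 + int(cols[0]), a0 + int(cols[-1]))
    return GuidewireSegment(interval=interval, mask=mask)


# ---------------------------------------------------------------------------
# lumen


def _circular_interp(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid entries by linear interpolation around the circular A-line axis."""
    n = values.shape[0]
    if valid.all():
        return values
    if not valid.any():
        raise ValueError("no valid entries to interpolate from")
    idx = np.arange(n)
    good = np.nonzero(valid)[0]
    # unwrap by tiling the valid samples once on each side
    xp = np.concatenate([good - n, good, good + n])
    fp = np.tile(values[good], 3)
    out = values.copy()
    out[~valid] = np.interp(idx[~valid], xp, fp)
    return out


def segment_lumen(
    frame: np.ndarray,
    sheath_row: int,
    guidewire: tuple[int, int] | None,
    params: SegmentationParams = SegmentationParams(),
) -> LumenContour:
    """Trace the luminal surface per A-line.

    The sheath-masked frame is median-smoothed along depth; per A-line the
    surface is the first row below the sheath whose intensity exceeds an
    Otsu-derived tissue threshold and stays bright over the persistence
    window (so thin bright blobs followed by shadow — struts — do not count
    as wall). A-lines without a persistent surface (guide-wire and strut
    shadows) are filled by circular linear interpolation and flagged; the
    contour is median-filtered across A-lines.

    Raises when fewer than half of the A-lines yield a surface.
    """
    img = mask_sheath(frame, sheath_row, params.sheath_mask_halfwidth)
    rows, n_alines = img.shape
    smoothed = ndimage.median_filter(img, size=(3, 1))
    body = smoothed[smoothed > 0]
    if body.size == 0:
        raise ValueError("frame unsegmentable: no signal below the sheath")
    thr = filters.threshold_otsu(body)
    bright = smoothed > thr

    w = params.lumen_persistence_rows
    need = params.lumen_persistence_frac
    # fraction of bright rows in [r, r+w) for every r, via cumulative sums
    cs = np.cumsum(bright, axis=0)
    cs = np.vstack([np.zeros((1, n_alines), int), cs])
    upper = np.minimum(np.arange(rows)[:, None] + w, rows)
    frac = (cs[upper, np.arange(n_alines)[None, :]] - cs[:-1]) / np.maximum(
        upper - np.arange(rows)[:, None], 1
    )
    persistent = bright & (frac >= need)
    persistent[: sheath_row + params.sheath_mask_halfwidth + 1] = False

    depth = np.full(n_alines, np.nan)
    has = persistent.any(axis=0)
    depth[has] = np.argmax(persistent, axis=0)[has]
    valid = has.copy()
    if guidewire is not None:
        g0, g1 = guidewire
        valid[g0 : g1 + 1] = False
    if valid.sum() < 0.5 * n_alines:
        raise ValueError(
            f"frame unsegmentable: surface found on {int(valid.sum())}/{n_alines} A-lines"
        )
    # reject outliers against a local median baseline: bright tails of strut
    # blobs in A-lines just outside the cast shadow trigger early crossings.
    # The baseline runs over the sequence of valid samples only, so gaps
    # bridged by interpolation cannot drag it toward a corrupted endpoint.
    valid_idx = np.nonzero(valid)[0]
    vals = depth[valid_idx]
    baseline = ndimage.median_filter(vals, size=params.lumen_outlier_median_width, mode="wrap")
    outlier_idx = valid_idx[np.abs(vals - baseline) > params.lumen_outlier_px]
    valid[outlier_idx] = False
    filled = _circular_interp(np.where(valid, depth, 0.0), valid)
    filled = ndimage.median_filter(filled, size=params.lumen_median_width, mode="wrap")
    return LumenContour(surface_depth_px=filled, interpolated=~valid)


# ---------------------------------------------------------------------------
# struts


def detect_struts(
    frame: np.ndarray,
    lumen: LumenContour,
    guidewire: tuple[int, int] | None,
    params: SegmentationParams = SegmentationParams(),
) -> list[tuple[int, float]]:
    """Per-A-line strut candidates as (aline, peak_depth) pairs.

    A candidate needs a bright peak (>= ``strut_intensity_min``) within
    [lumen - 30, lumen + 5] rows and a dark distal shadow (mean intensity
    below ``strut_shadow_max`` over the rows behind the peak).
    """
    img = np.asarray(frame, float)
    rows, n_alines = img.shape
    smoothed = ndimage.median_filter(img, size=(3, 1))
    excluded = np.zeros(n_alines, bool)
    if guidewire is not None:
        excluded[guidewire[0] : guidewire[1] + 1] = True
    out: list[tuple[int, float]] = []
    lum = lumen.surface_depth_px
    for a in range(n_alines):
        if excluded[a]:
            continue
        lo = max(int(lum[a]) - params.strut_search_above_px, 0)
        hi = min(int(lum[a]) + params.strut_search_below_px + 1, rows)
        if hi <= lo:
            continue
        # peak on the raw frame: smoothing erodes the narrow strut spot, and
        # isolated noise peaks are rejected later by clustering
        band = img[lo:hi, a]
        peak = lo + int(np.argmax(band))
        if img[peak, a] < params.strut_intensity_min:
            continue
        s0 = min(peak + params.strut_shadow_gap_px, rows)
        s1 = min(s0 + params.strut_shadow_depth_px, rows)
        if s1 <= s0:
            continue
        if smoothed[s0:s1, a].mean() >= params.strut_shadow_max:
            continue
        out.append((a, float(peak)))
    return out


def cluster_struts(
    candidates: list[tuple[int, float]],
    frame: int = 0,
    params: SegmentationParams = SegmentationParams(),
) -> list[StrutDetection]:
    """Merge per-A-line candidates into struts.

    Candidates in adjacent A-lines (gap <= ``cluster_max_gap_alines``) at
    similar depths (|diff| <= ``cluster_max_depth_diff_px``) join one strut;
    groups smaller than ``cluster_min_alines`` are discarded as noise. The
    strut's A-line and depth are the member medians.
    """
    if not candidates:
        return []
    cands = sorted(candidates)
    n = len(cands)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            gap = cands[j][0] - cands[i][0] - 1
            if gap > params.cluster_max_gap_alines:
                break  # sorted by A-line; later candidates are farther
            if abs(cands[j][1] - cands[i][1]) <= params.cluster_max_depth_diff_px:
                parent[find(j)] = find(i)
    groups_map: dict[int, list[tuple[int, float]]] = {}
    for i, c in enumerate(cands):
        groups_map.setdefault(find(i), []).append(c)
    out = []
    for g in groups_map.values():
        if len(g) < params.cluster_min_alines:
            continue
        alines = np.array([a for a, _ in g])
        depths = np.array([d for _, d in g])
        out.append(
            StrutDetection(
                frame=frame,
                aline=int(np.median(alines)),
                depth_px=float(np.median(depths)),
            )
        )
    return out


def interpolate_contour_at(
    lumen: LumenContour, alines: np.ndarray
) -> LumenContour:
    """Re-interpolate the contour across the given A-lines (circularly).

    Used to bridge the wall surface across strut footprints: the first bright
    crossing there follows the strut body rather than the vessel wall.
    """
    flag = lumen.interpolated.copy()
    flag[np.asarray(alines, int)] = True
    valid = ~flag
    if not valid.any():
        return lumen
    filled = _circular_interp(np.where(valid, lumen.surface_depth_px, 0.0), valid)
    return LumenContour(surface_depth_px=filled, interpolated=flag)


def classify_malapposition(
    struts: list[StrutDetection],
    lumen: LumenContour,
    threshold_px: int = MALAPPOSITION_THRESHOLD_PX,
) -> list[StrutDetection]:
    """Label each strut by its radial lumen distance.

    distance = max(0, lumen surface depth - strut depth) along the strut's
    A-line; malapposed iff distance > threshold (strictly).
    """
    out = []
    for s in struts:
        dist = max(0.0, float(lumen.surface_depth_px[s.aline]) - s.depth_px)
        out.append(
            StrutDetection(
                frame=s.frame,
                aline=s.aline,
                depth_px=s.depth_px,
                distance_px=dist,
                malapposed=dist > threshold_px,
            )
        )
    return out


def segment_frame(
    frame: np.ndarray,
    frame_index: int = 0,
    guidewire_candidate: tuple[int, int] | None = None,
    params: SegmentationParams = SegmentationParams(),
) -> FrameSegmentation:
    """Run the full per-frame chain: sheath -> guide-wire -> lumen -> struts."""
    sheath = detect_sheath(frame)
    gw = GuidewireSegment(interval=None)
    if guidewire_candidate is not None:
        gw = refine_guidewire(
            mask_sheath(frame, sheath, params.sheath_mask_halfwidth),
            guidewire_candidate,
            pad_alines=params.guidewire_pad_alines,
            params=params,
        )
        if gw.interval is None:  # fall back to the en face candidate
            gw = GuidewireSegment(interval=guidewire_candidate)
    lumen = segment_lumen(frame, sheath, gw.interval, params)
    candidates = detect_struts(frame, lumen, gw.interval, params)
    struts = cluster_struts(candidates, frame=frame_index, params=params)
    if struts:
        pad = params.strut_contour_pad_alines
        n_alines = frame.shape[1]
        footprint = np.concatenate(
            [np.arange(s.aline - pad, s.aline + pad + 1) % n_alines for s in struts]
        )
        lumen = interpolate_contour_at(lumen, footprint)
    struts = classify_malapposition(struts, lumen, params.malapposition_threshold_px)
    return FrameSegmentation(
        frame=frame_index, sheath_depth_px=sheath, guidewire=gw, lumen=lumen, struts=struts
    )


# ---------------------------------------------------------------------------
# evaluation


def evaluate_detection(
    tp: int, fp: int, tn: int | None, fn: int
) -> tuple[float | None, float | None]:
    """(sensitivity %, specificity %), each rounded to one decimal.

    Specificity is None when true negatives are undefined (strut detection has
    no well-defined true negative); sensitivity is None when tp + fn == 0.
    """
    if min(tp, fp, fn) < 0 or (tn is not None and tn < 0):
        raise ValueError("counts must be non-negative")
    sens = None if tp + fn == 0 else round(100.0 * tp / (tp + fn), 1)
    spec = None if tn is None or tn + fp == 0 else round(100.0 * tn / (tn + fp), 1)
    return sens, spec


def match_detections(
    predicted: list[StrutDetection],
    truth: list,
    tol_alines: int = 5,
    tol_px: int = 5,
) -> tuple[int, int, int, list[tuple[StrutDetection, object]]]:
    """Greedy one-to-one matching of predicted struts to ground truth.

    Pairs within the same frame, |aline difference| <= ``tol_alines`` and
    |depth difference| <= ``tol_px`` are matched nearest-first. Returns
    (tp, fp, fn, matched_pairs); unmatched predictions are false positives,
    unmatched truth entries false negatives.
    """
    pairs = []
    for i, p in enumerate(predicted):
        for j, t in enumerate(truth):
            if p.frame != t.frame:
                continue
            da, dd = abs(p.aline - t.aline), abs(p.depth_px - t.depth_px)
            if da <= tol_alines and dd <= tol_px:
                pairs.append((da + dd, i, j))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matched.append((predicted[i], truth[j]))
    tp = len(matched)
    fp = len(predicted) - tp
    fn = len(truth) - tp
    return tp, fp, fn, matched


def score_phantom(
    predicted: list[StrutDetection],
    truth_struts: list,
    tol_alines: int = 5,
    tol_px: int = 5,
) -> dict:
    """Strut detection and malapposition counts against phantom ground truth.

    Malapposition is scored on matched struts: positives are malapposed truth
    struts; a matched pair counts toward TP/TN/FP/FN by the agreement of its
    labels.
    """
    tp, fp, fn, matched = match_detections(predicted, truth_struts, tol_alines, tol_px)
    m_tp = sum(1 for p, t in matched if t.malapposed and p.malapposed)
    m_fn = sum(1 for p, t in matched if t.malapposed and not p.malapposed)
    m_fp = sum(1 for p, t in matched if not t.malapposed and p.malapposed)
    m_tn = sum(1 for p, t in matched if not t.malapposed and not p.malapposed)
    strut_sens, _ = evaluate_detection(tp, fp, None, fn)
    mal_sens, mal_spec = evaluate_detection(m_tp, m_fp, m_tn, m_fn)
    return {
        "strut": {"tp": tp, "fp": fp, "fn": fn, "sensitivity_pct": strut_sens},
        "malapposition": {
            "tp": m_tp,
            "fp": m_fp,
            "tn": m_tn,
            "fn": m_fn,
            "sensitivity_pct": mal_sens,
            "specificity_pct": mal_spec,
        },
    }
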