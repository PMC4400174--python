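"""One-command pullback processing: reconstruct -> select region -> segment -> render.

Also provides the host/accelerator decision rule used when an accelerated
implementation of a submodule group exists: the group runs on the host when
its accelerator runtime plus accelerator auxiliary time exceeds the round
trip of transferring to the host, computing there, and transferring back.
The reference pipeline itself is host-only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import segment as seg_mod
from . import stent_region as region_mod
from . import visualize as vis_mod
from .config import AcquisitionConfig
from .io import load_calibration, read_raw_pullback
from .reconstruct import DEFAULT_CEIL_DB, DEFAULT_FLOOR_DB, reconstruct_pullback
from .segment import SegmentationParams

__all__ = [
    "TimingProfile",
    "PipelineConfig",
    "select_backend",
    "run_push_of_button",
]

log = logging.getLogger("ivoct")


@dataclass(frozen=True)
class TimingProfile:
    """Measured times (seconds) for one submodule group."""

    t_device: float  # group runtime on the accelerator
    t_device_aux: float  # accelerator auxiliary time (allocation etc.)
    t_d2h: float  # device-to-host transfer
    t_host: float  # group runtime on the host
    t_h2d: float  # host-to-device transfer
    t_host_aux: float  # host auxiliary time

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


def select_backend(profile: TimingProfile) -> str:
    """'host' iff t_device + t_device_aux > t_d2h + t_host + t_h2d + t_host_aux.

    Ties go to the accelerator (data already resides there).
    """
    device = profile.t_device + profile.t_device_aux
    host = profile.t_d2h + profile.t_host + profile.t_h2d + profile.t_host_aux
    return "host" if device > host else "accelerator"


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one document.

    Defaults follow the reference system: Laplacian threshold 240, selection
    window 150 frames (28 mm stent at 0.2 mm pitch plus 10 margin frames),
    guide-wire ROI pad +/-40 A-lines, malapposition threshold 15 px, remap
    knee 128 -> wall band [0, 200], Cartesian sizes 1024 and 512.
    """

    image_rows: int = 1024
    floor_db: float = DEFAULT_FLOOR_DB
    ceil_db: float = DEFAULT_CEIL_DB
    enface_threshold: int = 240
    stent_length_mm: float = 28.0
    margin_frames: int = 10
    cartesian_size: int = 1024
    volume_size: int = 512
    render_views: tuple[str, ...] = ("axial", "cutaway-y")
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["render_views"] = list(self.render_views)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        seg_keys = set(SegmentationParams.__dataclass_fields__)
        top_keys = set(cls.__dataclass_fields__)
        unknown = set(d) - top_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "segmentation" in d and d["segmentation"] is not None:
            sd = dict(d["segmentation"])
            unknown = set(sd) - seg_keys
            if unknown:
                raise ValueError(f"unknown segmentation keys: {sorted(unknown)}")
            d["segmentation"] = SegmentationParams(**sd)
        if "render_views" in d:
            d["render_views"] = tuple(d["render_views"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _segment_stack(
    stack: np.ndarray, frame_range: region_mod.FrameRange, params: SegmentationParams
) -> list[seg_mod.FrameSegmentation]:
    sub = stack[frame_range.first : frame_range.last + 1]
    enface = region_mod.build_enface(sub)
    candidates = seg_mod.detect_guidewire_alines(enface)
    out = []
    for i, f in enumerate(frame_range.frames()):
        out.append(
            seg_mod.segment_frame(
                stack[f], frame_index=f, guidewire_candidate=candidates[i], params=params
            )
        )
    return out


def _visualize(
    stack: np.ndarray,
    segs: list[seg_mod.FrameSegmentation],
    cfg: PipelineConfig,
    acq: AcquisitionConfig,
) -> vis_mod.LabeledVolume:
    frames = []
    rows = stack.shape[1]
    for s in segs:
        remapped = vis_mod.denoise_and_remap(stack[s.frame])
        encoded = vis_mod.encode_features(remapped, s)
        cart = vis_mod.polar_to_cartesian(encoded, out_size=cfg.cartesian_size)
        lum = None if s.lumen is None else s.lumen.surface_depth_px
        aligned, _ = vis_mod.align_lumen_center(cart, lum, polar_rows=rows)
        frames.append(aligned)
    inplane_um = acq.axial_pitch_um * rows / (cfg.volume_size / 2.0)
    aspect = acq.frame_pitch_um / inplane_um
    return vis_mod.build_volume(np.stack(frames), out_size=cfg.volume_size, aspect_ratio=aspect)


def run_push_of_button(
    raw_path, cal_path, out_dir, config: PipelineConfig | None = None
) -> dict:
    """Process a raw pullback end to end, writing every stage artifact.

    Writes the reconstructed polar stack, en face and strut-evidence images,
    the per-strut CSV table, the labeled Cartesian volume, projection renders,
    and ``summary.json``. Returns the summary dict. A pullback without
    detectable struts completes with segmentation skipped and the outcome
    recorded in the summary.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage=reconstruct raw=%s", raw_path)
    raw = read_raw_pullback(raw_path)
    cal = load_calibration(cal_path)
    try:
        stack = reconstruct_pullback(
            raw, cal, rows=cfg.image_rows, floor_db=cfg.floor_db, ceil_db=cfg.ceil_db
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'reconstruct' failed: {exc}") from exc
    tifffile.imwrite(out / "polar_stack.tif", stack, photometric="minisblack")

    return process_stack(stack, out, cfg, raw.config)


def process_stack(
    stack: np.ndarray,
    out_dir,
    cfg: PipelineConfig | None = None,
    acq: AcquisitionConfig | None = None,
) -> dict:
    """Select-region -> segment -> visualize on an existing polar stack."""
    cfg = cfg or PipelineConfig()
    acq = acq or AcquisitionConfig(n_frames=stack.shape[0], n_alines=stack.shape[2])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "n_frames": int(stack.shape[0]),
        "config": cfg.to_dict(),
    }

    log.info("stage=select-region")
    enface = region_mod.build_enface(stack)
    mask = region_mod.enhance_struts(enface, threshold=cfg.enface_threshold)
    tifffile.imwrite(out / "enface.tif", np.round(enface).astype(np.uint8))
    tifffile.imwrite(out / "strut_evidence.tif", mask.astype(np.uint8) * 255)
    window = region_mod.estimate_window_length(
        cfg.stent_length_mm, acq.frame_pitch_um / 1000.0, cfg.margin_frames
    )
    try:
        frame_range = region_mod.select_stent_region(mask, window)
    except ValueError:
        summary["stent_region"] = None
        summary["outcome"] = "no stent detected"
        _write_summary(out, summary)
        return summary
    summary["stent_region"] = {"first": frame_range.first, "last": frame_range.last}

    log.info("stage=segment frames=%d-%d", frame_range.first, frame_range.last)
    try:
        segs = _segment_stack(stack, frame_range, cfg.segmentation)
    except Exception as exc:
        raise RuntimeError(f"stage 'segment' failed: {exc}") from exc
    rows_csv = [
        {
            "frame": s.frame,
            "aline": d.aline,
            "depth_px": d.depth_px,
            "distance_px": d.distance_px,
            "malapposed": d.malapposed,
        }
        for s in segs
        for d in s.struts
    ]
    pd.DataFrame(
        rows_csv, columns=["frame", "aline", "depth_px", "distance_px", "malapposed"]
    ).to_csv(out / "struts.csv", index=False)
    n_struts = len(rows_csv)
    n_mal = sum(r["malapposed"] for r in rows_csv)
    summary["strut_count"] = n_struts
    summary["malapposed_count"] = int(n_mal)

    log.info("stage=render")
    try:
        volume = _visualize(stack, segs, cfg, acq)
    except Exception as exc:
        raise RuntimeError(f"stage 'render' failed: {exc}") from exc
    tifffile.imwrite(out / "volume.tif", volume.voxels, photometric="minisblack")
    with open(out / "volume_meta.json", "w") as fh:
        json.dump(
            {"encoding": volume.encoding, "aspect_ratio": volume.aspect_ratio},
            fh,
            indent=2,
            sort_keys=True,
        )
    for view in cfg.render_views:
        img = vis_mod.render_projection(volume, view=view)
        tifffile.imwrite(out / f"render_{view}.tif", img)

    summary["outcome"] = "ok"
    _write_summary(out, summary)
    return summary


def _write_summary(out: Path, summary: dict) -> None:
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
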