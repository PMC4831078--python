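"""Configuration, logging, and file I/O binding the pipeline together.

Run configuration is a schema-validated YAML document (unknown keys are
rejected, defaults reproduce the reference study geometry: SAD 1000 mm,
SID 1500 mm, IDD 500 mm, MV/kV rates 9.5/11 Hz, 1 rpm, 177 control
points).  Image interchange is multi-frame TIFF plus a CSV sidecar
(frame index, system, gantry angle, timestamp); traces are CSV and
summaries JSON, with a manifest recording hashes, seed and version for
reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from contextlib import contextmanager
from pathlib import Path
from typing import List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .geometry import (
    KV_PIXEL_PITCH_MM,
    MV_PIXEL_PITCH_MM,
    ImagingGeometry,
)
from .register import SearchConfig
from .sadts import SadtsConfig
from .simulate import (
    ArcPlan,
    FrameStream,
    MotionScenario,
    PhantomModel,
    ProjectionFrame,
    default_phantom,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "write_outputs",
    "write_frame_stack",
    "read_frame_stack",
    "setup_logging",
    "stage_timer",
]

log = logging.getLogger("mvkvtrack")


class ConfigError(ValueError):
    pass


class ChainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sad_mm: float = 1000.0
    sid_mm: float = 1500.0
    idd_mm: float = 500.0
    pixel_pitch_mm: float = MV_PIXEL_PITCH_MM
    detector_px: Tuple[int, int] = (256, 256)

    @model_validator(mode="after")
    def _check_distances(self):
        if abs(self.sid_mm - (self.sad_mm + self.idd_mm)) > 1e-6:
            raise ValueError(
                f"sid_mm ({self.sid_mm}) must equal sad_mm + idd_mm "
                f"({self.sad_mm + self.idd_mm})"
            )
        return self


class GeometryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mv: ChainConfig = Field(default_factory=ChainConfig)
    kv: ChainConfig = Field(default_factory=lambda: ChainConfig(pixel_pitch_mm=KV_PIXEL_PITCH_MM))
    kv_offset_deg: float = -90.0
    # Sign convention of gantry angles: degrees, clockwise viewed from the
    # foot of the couch (IEC-style).  Recorded here so it travels with runs.
    angle_convention: Literal["cw-from-foot"] = "cw-from-foot"


class PlanBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_control_points: int = 177
    arc_span_deg: float = 360.0
    start_angle_deg: float = 0.0
    gantry_speed_deg_s: float = 6.0
    mv_rate_hz: float = 9.5
    kv_rate_hz: float = 11.0


class ScenarioBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["static", "prostate", "respiratory"] = "static"
    duration_s: Optional[float] = None  # None = full arc
    prostate_max_mm: Tuple[float, float, float] = (1.9, 1.8, 4.9)
    resp_period_s: float = 4.0
    resp_p2p_mm: Tuple[float, float, float] = (5.0, 2.0, 10.0)
    dwell_exponent: int = 2
    setup_error_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 80.0
    fiducial_contrast: float = 400.0
    aperture_mode: Literal["rect", "open", "closed"] = "rect"
    aperture_margin_mm: float = 15.0


class SadtsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    arc_length_deg: float = 4.0
    plane_depth_mm: float = 0.0
    interpolation: Literal["nearest", "bilinear"] = "bilinear"


class SearchBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    initial_region_mm: float = 10.0
    subsequent_region_mm: float = 5.0
    grid_spacing_mm: float = 2.0
    n_starts: int = 5
    fom_threshold: float = 5.0
    simplex_xatol_mm: float = 0.01
    max_iter: int = 200
    drop_blocked_rois: bool = False


class OutputBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dir: str = "out"
    create_missing: bool = True
    write_frames: bool = False


class RunConfig(BaseModel):
    """Top-level run configuration; every run writes its resolved copy."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    mode: Literal["single", "sadts"] = "single"
    log_level: str = "INFO"
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    plan: PlanBlock = Field(default_factory=PlanBlock)
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    sadts: SadtsBlock = Field(default_factory=SadtsBlock)
    search: SearchBlock = Field(default_factory=SearchBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)

    # -- converters to the runtime dataclasses ------------------------------

    def mv_geometry(self, angle_deg: float = 0.0) -> ImagingGeometry:
        g = self.geometry.mv
        return ImagingGeometry(
            system_label="MV", gantry_angle_deg=angle_deg, sad_mm=g.sad_mm,
            sid_mm=g.sid_mm, idd_mm=g.idd_mm, pixel_pitch_mm=g.pixel_pitch_mm,
            detector_px=tuple(g.detector_px),
        )

    def kv_geometry(self, angle_deg: Optional[float] = None) -> ImagingGeometry:
        g = self.geometry.kv
        if angle_deg is None:
            angle_deg = self.geometry.kv_offset_deg
        return ImagingGeometry(
            system_label="kV", gantry_angle_deg=angle_deg, sad_mm=g.sad_mm,
            sid_mm=g.sid_mm, idd_mm=g.idd_mm, pixel_pitch_mm=g.pixel_pitch_mm,
            detector_px=tuple(g.detector_px),
        )

    def arc_plan(self) -> ArcPlan:
        p = self.plan
        return ArcPlan(
            n_control_points=p.n_control_points, arc_span_deg=p.arc_span_deg,
            start_angle_deg=p.start_angle_deg,
            gantry_speed_deg_s=p.gantry_speed_deg_s,
            mv_rate_hz=p.mv_rate_hz, kv_rate_hz=p.kv_rate_hz,
        )

    def motion_scenario(self) -> MotionScenario:
        s = self.scenario
        return MotionScenario(
            kind=s.kind, prostate_max_mm=tuple(s.prostate_max_mm),
            resp_period_s=s.resp_period_s, resp_p2p_mm=tuple(s.resp_p2p_mm),
            dwell_exponent=s.dwell_exponent,
            setup_error_mm=tuple(s.setup_error_mm), seed=self.seed,
        )

    def phantom(self) -> PhantomModel:
        return default_phantom(
            noise_sd=self.scenario.noise_sd,
            contrast=self.scenario.fiducial_contrast,
        )

    def search_config(self) -> SearchConfig:
        s = self.search
        return SearchConfig(
            initial_region_mm=s.initial_region_mm,
            subsequent_region_mm=s.subsequent_region_mm,
            grid_spacing_mm=s.grid_spacing_mm, n_starts=s.n_starts,
            fom_threshold=s.fom_threshold,
            simplex_xatol_mm=s.simplex_xatol_mm, max_iter=s.max_iter,
            drop_blocked_rois=s.drop_blocked_rois,
        )

    def sadts_config(self) -> SadtsConfig:
        s = self.sadts
        return SadtsConfig(
            arc_length_deg=s.arc_length_deg, plane_depth_mm=s.plane_depth_mm,
            interpolation=s.interpolation,
        )


def load_config(path: "str | Path | None" = None) -> RunConfig:
    """Load and validate a YAML run configuration (``None`` or an empty file
    yields all defaults).  Validation errors name the offending key path."""
    data = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        with open(p) as fh:
            data = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**data)
    except ValidationError as e:
        locs = "; ".join(
            ".".join(str(x) for x in err["loc"]) + ": " + err["msg"] for err in e.errors()
        )
        raise ConfigError(f"invalid configuration ({locs})") from e


def save_config(config: RunConfig, path: "str | Path") -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)


def setup_logging(level: str = "INFO") -> None:
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [h]
    log.setLevel(level.upper())


@contextmanager
def stage_timer(stage: str):
    t0 = time.perf_counter()
    yield
    log.info("%s finished in %.2f s", stage, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# Frame-stack I/O: multi-frame TIFF + CSV sidecar


def write_frame_stack(frames: List[ProjectionFrame], tiff_path: "str | Path",
                      sidecar_path: "str | Path") -> None:
    """Write frames as a multi-frame float32 TIFF with a CSV sidecar of
    (frame, system, angle_deg, time_s)."""
    if not frames:
        raise ValueError("no frames to write")
    stack = np.stack([np.asarray(f.pixels, dtype=np.float32) for f in frames])
    tifffile.imwrite(str(tiff_path), stack, photometric="minisblack")
    pd.DataFrame(
        {
            "frame": np.arange(len(frames)),
            "system": [f.system_label for f in frames],
            "angle_deg": [f.angle_deg for f in frames],
            "time_s": [f.time_s for f in frames],
        }
    ).to_csv(sidecar_path, index=False)


def read_frame_stack(tiff_path: "str | Path", sidecar_path: "str | Path") -> List[ProjectionFrame]:
    stack = tifffile.imread(str(tiff_path))
    if stack.ndim == 2:
        stack = stack[None]
    meta = pd.read_csv(sidecar_path)
    if len(meta) != len(stack):
        raise ValueError(
            f"sidecar rows ({len(meta)}) do not match TIFF frames ({len(stack)})"
        )
    return [
        ProjectionFrame(
            pixels=np.asarray(stack[j], dtype=float),
            system_label=str(meta["system"][j]),
            angle_deg=float(meta["angle_deg"][j]),
            time_s=float(meta["time_s"][j]),
        )
        for j in range(len(stack))
    ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    trace,
    out_dir: "str | Path",
    config: Optional[RunConfig] = None,
    frames: Optional[List[ProjectionFrame]] = None,
    create_missing: bool = True,
) -> dict:
    """Write trace CSV, summary JSON, optional frame TIFF, the resolved
    config, and a manifest (file hashes, seed, version).  Re-running with
    the same config and seed reproduces byte-identical CSVs."""
    out = Path(out_dir)
    if not out.exists():
        if create_missing:
            out.mkdir(parents=True)
        else:
            raise IOError(f"output directory does not exist: {out}")
    written = []
    trace.samples.to_csv(out / "trace.csv", index=False, float_format="%.9g")
    written.append("trace.csv")
    with open(out / "summary.json", "w") as fh:
        json.dump(trace.summary, fh, indent=2, sort_keys=True, default=float)
    written.append("summary.json")
    if frames:
        write_frame_stack(frames, out / "frames.tif", out / "frames_sidecar.csv")
        written += ["frames.tif", "frames_sidecar.csv"]
    if config is not None:
        save_config(config, out / "resolved_config.yaml")
        written.append("resolved_config.yaml")
    manifest = {
        "version": __version__,
        "seed": getattr(config, "seed", None),
        "files": {name: _sha256(out / name) for name in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
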