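"""MV-kV pairing, 3-D displacement recovery, trace assembly and statistics.

Each kV frame is paired with the MV frame whose gantry angle is closest to
kV orthogonality (90 degrees apart).  For every pair, the registered 2-D
fiducial center-of-mass positions on the two detectors are triangulated
into a single 3-D patient-frame point; subtracting the planned 3-D center
of mass yields the measured displacement, reported on anatomical axes
(left-right, anterior-posterior, superior-inferior).  If either chain's
registration fails its confidence gate the sample falls back to a 2-D
kV-only assessment and is excluded from the 3-D statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import (
    DetectorPoint,
    ImagingGeometry,
    PatientPoint,
    triangulate,
)
from .preprocess import NoApertureError, detect_irradiated, remove_bands
from .register import RegistrationResult, SearchConfig, register
from .sadts import SadtsConfig, frames_for_arc, reconstruct
from .simulate import (
    ArcPlan,
    FrameStream,
    MotionScenario,
    PhantomModel,
    ProjectionFrame,
    acquisition_schedule,
    default_phantom,
    render_projection,
    scenario_sampler,
    xyz_to_anatomical,
)
from .template import TemplateImage, TemplateSet, build_templates, nearest_template

__all__ = [
    "TrackingError",
    "MvKvPair",
    "MotionTrace",
    "pair_streams",
    "displacement_3d",
    "summarize",
    "simulate_streams",
    "run_pipeline",
    "patient_study_pair_count",
]

_AXES = ("lr", "ap", "si")  # patient (x, y, z)


class TrackingError(ValueError):
    pass


@dataclass(frozen=True)
class MvKvPair:
    """One kV frame matched with its most-orthogonal MV frame."""

    kv_index: int
    mv_index: int
    time_s: float                 # kV timestamp
    angular_offset_deg: float     # deviation of (theta_MV - theta_kV) from 90


def _circular_offset_from_90(mv_angle: float, kv_angle: float) -> float:
    return ((mv_angle - kv_angle - 90.0 + 180.0) % 360.0) - 180.0


def pair_streams(kv_stream: FrameStream, mv_stream: FrameStream) -> List[MvKvPair]:
    """One pair per kV frame, choosing the MV frame closest to orthogonality.

    With both chains rotating together the residual angular offset is
    bounded by half the MV inter-frame angular spacing.
    """
    if len(kv_stream) == 0 or len(mv_stream) == 0:
        raise TrackingError("both frame streams must be non-empty")
    pairs = []
    mv_angles = np.asarray(mv_stream.angles_deg)
    mv_times = np.asarray(mv_stream.times_s)
    for j in range(len(kv_stream)):
        off = ((mv_angles - kv_stream.angles_deg[j] - 90.0 + 180.0) % 360.0) - 180.0
        # exact ties (kV frame equidistant between two MV frames) break
        # toward the earlier MV frame, independent of storage order
        best = np.abs(off).min()
        tied = np.flatnonzero(np.abs(np.abs(off) - best) < 1e-9)
        i = int(tied[np.argmin(mv_times[tied])])
        pairs.append(
            MvKvPair(
                kv_index=j,
                mv_index=i,
                time_s=float(kv_stream.times_s[j]),
                angular_offset_deg=float(off[i]),
            )
        )
    pairs.sort(key=lambda p: p.time_s)
    return pairs


def displacement_3d(
    kv_result: RegistrationResult,
    mv_result: RegistrationResult,
    kv_template: TemplateImage,
    mv_template: TemplateImage,
    kv_geom: ImagingGeometry,
    mv_geom: ImagingGeometry,
    planned_com_3d: PatientPoint,
) -> Tuple[np.ndarray, float]:
    """3-D displacement (patient xyz, mm) from one registered MV-kV pair.

    The measured 2-D center of mass on each detector is the template's
    planned center of mass plus the registered shift; the two detector
    points are triangulated and the planned 3-D center of mass subtracted.
    Both registrations must have succeeded.
    """
    if not (kv_result.success and mv_result.success):
        raise TrackingError("both registrations must be successful for 3-D recovery")
    kv_obs = DetectorPoint(
        kv_template.planned_com.i_mm + kv_result.shift_mm[0],
        kv_template.planned_com.k_mm + kv_result.shift_mm[1],
    )
    mv_obs = DetectorPoint(
        mv_template.planned_com.i_mm + mv_result.shift_mm[0],
        mv_template.planned_com.k_mm + mv_result.shift_mm[1],
    )
    tri = triangulate(kv_obs, mv_obs, kv_geom, mv_geom)
    disp = tri.point.as_array() - planned_com_3d.as_array()
    return disp, tri.residual_mm


@dataclass
class MotionTrace:
    """Per-pair samples plus planned-vs-measured summary statistics."""

    samples: pd.DataFrame
    summary: Dict[str, object] = field(default_factory=dict)


def summarize(trace: "MotionTrace | pd.DataFrame") -> Dict[str, object]:
    """Per-axis mean/SD/max of (measured - planned), failure bookkeeping, and
    the all-axis mean SD used when accuracy is quoted as a single number."""
    df = trace.samples if isinstance(trace, MotionTrace) else trace
    ok = df[df["success_3d"]]
    n_fail = int((~df["success_3d"]).sum())
    out: Dict[str, object] = {
        "n_pairs": int(len(df)),
        "n_success_3d": int(len(ok)),
        "n_failures": n_fail,
        "failure_rate": (n_fail / len(df)) if len(df) else float("nan"),
    }
    if len(ok) < 2:
        raise TrackingError("need at least 2 successful samples for summary statistics")
    sds = []
    for ax, col in zip(_AXES, ("x", "y", "z")):
        err = ok[f"d{col}_mm"] - ok[f"planned_d{col}_mm"]
        out[f"mean_{ax}_mm"] = float(err.mean())
        out[f"sd_{ax}_mm"] = float(err.std(ddof=1))
        out[f"max_abs_{ax}_mm"] = float(err.abs().max())
        sds.append(out[f"sd_{ax}_mm"])
    out["sd_all_axes_mm"] = float(np.mean(sds))
    return out


# ---------------------------------------------------------------------------
# Simulation-driven pipeline


def simulate_streams(
    scenario: MotionScenario,
    plan: ArcPlan,
    phantom: PhantomModel,
    mv_geom_base: ImagingGeometry,
    kv_geom_base: ImagingGeometry,
    duration_s: Optional[float] = None,
    seed: int = 0,
    mv_aperture: str = "rect",
    aperture_margin_mm: float = 15.0,
    add_noise: bool = True,
) -> Tuple[List[ProjectionFrame], List[ProjectionFrame], Callable[[float], np.ndarray], Tuple[FrameStream, FrameStream]]:
    """Render the MV and kV acquisition streams for a motion scenario.

    Returns (mv_frames, kv_frames, displacement_sampler, (mv_stream, kv_stream)).
    All randomness derives from ``seed``.
    """
    from .simulate import aperture_mask  # local to avoid circular confusion

    mv_stream, kv_stream = acquisition_schedule(plan, duration_s)
    sampler = scenario_sampler(scenario, plan, duration_s)
    ss = np.random.SeedSequence(seed)
    rng_mv, rng_kv = (np.random.default_rng(s) for s in ss.spawn(2))

    mv_frames: List[ProjectionFrame] = []
    for t, ang in zip(mv_stream.times_s, mv_stream.angles_deg):
        geom = mv_geom_base.at_angle(float(ang))
        disp = sampler(float(t))
        ap = aperture_mask(geom, phantom, disp, mode=mv_aperture, margin_mm=aperture_margin_mm)
        mv_frames.append(
            render_projection(
                phantom, geom, disp, aperture=ap, rng=rng_mv, time_s=float(t),
                add_noise=add_noise,
            )
        )
    kv_frames: List[ProjectionFrame] = []
    for t, ang in zip(kv_stream.times_s, kv_stream.angles_deg):
        geom = kv_geom_base.at_angle(float(ang))
        disp = sampler(float(t))
        kv_frames.append(
            render_projection(
                phantom, geom, disp, aperture="open", rng=rng_kv, time_s=float(t),
                add_noise=add_noise, add_bands=False,
            )
        )
    return mv_frames, kv_frames, sampler, (mv_stream, kv_stream)


class _TemplateCache:
    """Lazily built reference templates at one-degree gantry increments."""

    def __init__(self, fiducials, geom_base: ImagingGeometry, margin_mm: float = 1.0,
                 blur_px: float = 0.8):
        self.fiducials = fiducials
        self.geom_base = geom_base
        self.margin_mm = margin_mm
        self.blur_px = blur_px
        self._cache: Dict[int, TemplateImage] = {}

    def for_angle(self, angle_deg: float) -> TemplateImage:
        key = int(round(angle_deg)) % 360
        if key not in self._cache:
            ts = build_templates(
                self.fiducials, self.geom_base, [float(key)],
                margin_mm=self.margin_mm, blur_px=self.blur_px,
            )
            self._cache[key] = ts.templates[0]
        return self._cache[key]


def _preprocess_mv(frame: ProjectionFrame) -> ProjectionFrame:
    """Band removal on one MV frame; a frame with no detectable aperture is
    passed through unchanged (it will fail registration downstream)."""
    try:
        mask = detect_irradiated(frame.pixels)
        cleaned = remove_bands(frame.pixels, mask)
    except NoApertureError:
        return frame
    return dataclasses.replace(frame, pixels=cleaned)


def run_pipeline(
    scenario: "MotionScenario | str",
    mode: str = "single",
    arc_deg: float = 4.0,
    seed: int = 0,
    duration_s: Optional[float] = None,
    plan: Optional[ArcPlan] = None,
    phantom: Optional[PhantomModel] = None,
    mv_geom: Optional[ImagingGeometry] = None,
    kv_geom: Optional[ImagingGeometry] = None,
    search: Optional[SearchConfig] = None,
    sadts_cfg: Optional[SadtsConfig] = None,
    mv_aperture: str = "rect",
    aperture_margin_mm: float = 15.0,
    add_noise: bool = True,
) -> MotionTrace:
    """End-to-end simulation study: render, clean, (optionally) reconstruct,
    register both chains, pair, triangulate, and summarise.

    ``mode`` is ``"single"`` (register raw MV frames) or ``"sadts"``
    (register short-arc reconstructions of ``arc_deg`` degrees).  Fully
    deterministic given ``seed``.
    """
    if isinstance(scenario, str):
        scenario = MotionScenario(kind=scenario, seed=seed)
    if mode not in ("single", "sadts"):
        raise TrackingError(f"mode must be 'single' or 'sadts', got {mode!r}")
    plan = plan or ArcPlan()
    phantom = phantom or default_phantom()
    mv_geom = mv_geom or ImagingGeometry.mv()
    kv_geom = kv_geom or ImagingGeometry.kv()
    search = search or SearchConfig()
    sadts_cfg = sadts_cfg or SadtsConfig(arc_length_deg=arc_deg)

    mv_frames, kv_frames, sampler, (mv_stream, kv_stream) = simulate_streams(
        scenario, plan, phantom, mv_geom, kv_geom,
        duration_s=duration_s, seed=seed,
        mv_aperture=mv_aperture, aperture_margin_mm=aperture_margin_mm,
        add_noise=add_noise,
    )
    mv_frames = [_preprocess_mv(f) for f in mv_frames]
    pairs = pair_streams(kv_stream, mv_stream)

    mv_templates = _TemplateCache(phantom.fiducials, mv_geom)
    kv_templates = _TemplateCache(phantom.fiducials, kv_geom)
    planned_com = phantom.fiducial_com()
    cp_spacing = plan.arc_span_deg / (plan.n_control_points - 1)

    n_sadts = frames_for_arc(arc_deg, plan.mv_rate_hz, plan.gantry_speed_deg_s)
    half = n_sadts // 2

    rows = []
    prev_mv = (0.0, 0.0)
    prev_kv = (0.0, 0.0)
    first = True
    for pair in pairs:
        mv_frame = mv_frames[pair.mv_index]
        kv_frame = kv_frames[pair.kv_index]
        if mode == "sadts":
            lo = max(pair.mv_index - half, 0)
            hi = min(pair.mv_index + half, len(mv_frames) - 1)
            window = mv_frames[lo : hi + 1]
            mv_image_frame = reconstruct(
                window, mv_geom, sadts_cfg, center_angle_deg=mv_frame.angle_deg
            )
        else:
            mv_image_frame = mv_frame
        mv_tmpl = mv_templates.for_angle(mv_frame.angle_deg)
        kv_tmpl = kv_templates.for_angle(kv_frame.angle_deg)

        region_mv = search.initial_region_mm if first else search.subsequent_region_mm
        region_kv = region_mv
        mv_res = register(
            mv_image_frame.pixels, mv_tmpl, prev_shift=prev_mv,
            planned_shift=(0.0, 0.0), config=search,
            pitch_mm=mv_geom.pixel_pitch_mm, region_mm=region_mv,
        )
        kv_res = register(
            kv_frame.pixels, kv_tmpl, prev_shift=prev_kv,
            planned_shift=(0.0, 0.0), config=search,
            pitch_mm=kv_geom.pixel_pitch_mm, region_mm=region_kv,
        )
        first = False
        if np.isfinite(mv_res.cost):
            prev_mv = mv_res.shift_mm
        if np.isfinite(kv_res.cost):
            prev_kv = kv_res.shift_mm

        planned_disp = sampler(pair.time_s)
        row = {
            "time_s": pair.time_s,
            "cp_index": int((mv_frame.time_s * plan.gantry_speed_deg_s) // cp_spacing),
            "mv_angle_deg": mv_frame.angle_deg,
            "kv_angle_deg": kv_frame.angle_deg,
            "angular_offset_deg": pair.angular_offset_deg,
            "planned_dx_mm": planned_disp[0],
            "planned_dy_mm": planned_disp[1],
            "planned_dz_mm": planned_disp[2],
            "kv_success": kv_res.success,
            "mv_success": mv_res.success,
            "fom_kv": kv_res.fom,
            "fom_mv": mv_res.fom,
            "mode": mode,
        }
        if kv_res.success and mv_res.success:
            disp, resid = displacement_3d(
                kv_res, mv_res, kv_tmpl, mv_tmpl,
                kv_geom.at_angle(kv_frame.angle_deg),
                mv_geom.at_angle(mv_frame.angle_deg),
                planned_com,
            )
            row.update(
                dx_mm=disp[0], dy_mm=disp[1], dz_mm=disp[2],
                residual_mm=resid, success_3d=True,
                kv_inplane_i_mm=np.nan, kv_inplane_k_mm=np.nan,
            )
        else:
            # 2-D kV-only fallback: in-plane displacement at isocenter scale.
            mag = kv_geom.magnification
            row.update(
                dx_mm=np.nan, dy_mm=np.nan, dz_mm=np.nan,
                residual_mm=np.nan, success_3d=False,
                kv_inplane_i_mm=(kv_res.shift_mm[0] / mag) if kv_res.success else np.nan,
                kv_inplane_k_mm=(kv_res.shift_mm[1] / mag) if kv_res.success else np.nan,
            )
        rows.append(row)

    samples = pd.DataFrame(rows)
    trace = MotionTrace(samples=samples)
    try:
        trace.summary = summarize(trace)
    except TrackingError:
        trace.summary = {
            "n_pairs": int(len(samples)),
            "n_failures": int((~samples["success_3d"]).sum()) if len(samples) else 0,
        }
    return trace


def patient_study_pair_count(
    pairs_per_arc: int = 19, arcs_per_session: int = 2, sessions: Sequence[int] = (4, 4, 5)
) -> int:
    """Total MV-kV image pairs across a multi-patient study: pairs per arc
    (kV triggered every 20 degrees over a full arc) x arcs per session x
    total sessions."""
    return pairs_per_arc * arcs_per_session * int(sum(sessions))
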