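"""Digital phantom, motion traces, acquisition timing, and projection rendering.

The simulator emulates a phantom accuracy study on a rotating-gantry linac:
three implanted cylindrical gold-seed fiducials near isocenter, a single
360-degree arc delivered at constant gantry speed (1 rpm) with 177 control
points, a kV imager acquiring continuously at ~11 Hz and the portal (MV)
imager at ~9.5 Hz, MLC-aperture occlusion of the treatment field, additive
detector noise and, on MV frames, multiplicative horizontal band artifacts
caused by readout/beam-pulse asynchrony.

Rendered images use a line-integral ("attenuation") convention: fiducials
and background clutter appear as positive excess intensity on top of the
open-field level, so the same renderer serves both simulated acquisitions
and fiducial reference templates.  Monte-Carlo transport, scatter and
detector lag are deliberately not modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .geometry import (
    DetectorPoint,
    ImagingGeometry,
    PatientPoint,
    detector_to_pixel,
    kv_angle_for,
    project,
    project_many,
    rotation_matrix,
)

__all__ = [
    "FiducialModel",
    "BackgroundStructure",
    "BandArtifactModel",
    "PhantomModel",
    "ArcPlan",
    "MotionScenario",
    "FrameStream",
    "ProjectionFrame",
    "make_prostate_trace",
    "make_respiratory_trace",
    "acquisition_schedule",
    "scenario_sampler",
    "render_fiducials",
    "fiducial_footprint_mask",
    "aperture_mask",
    "render_projection",
    "default_phantom",
    "default_fiducials",
]

# Anatomical reporting order used throughout: (vertical, lateral, longitudinal)
# = (anterior-posterior, left-right, superior-inferior) = patient (y, x, z).
_ANATOMICAL_TO_XYZ = (1, 0, 2)


def anatomical_to_xyz(v: Sequence[float]) -> np.ndarray:
    """(vertical, lateral, longitudinal) -> patient (x, y, z)."""
    v = np.asarray(v, dtype=float)
    out = np.empty(3)
    out[1], out[0], out[2] = v[0], v[1], v[2]
    return out


def xyz_to_anatomical(v: Sequence[float]) -> np.ndarray:
    """Patient (x, y, z) -> (vertical, lateral, longitudinal)."""
    v = np.asarray(v, dtype=float)
    return np.array([v[1], v[0], v[2]])


@dataclass(frozen=True)
class FiducialModel:
    """A cylindrical gold-seed fiducial (default 3 mm x 1.2 mm)."""

    center: PatientPoint
    orientation: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    length_mm: float = 3.0
    diameter_mm: float = 1.2
    contrast: float = 400.0  # excess intensity at the cylinder axis

    def __post_init__(self) -> None:
        n = float(np.linalg.norm(self.orientation))
        if not np.isclose(n, 1.0, atol=1e-6):
            object.__setattr__(self, "orientation", tuple(np.asarray(self.orientation) / n))
        if self.length_mm <= 0 or self.diameter_mm <= 0:
            raise ValueError("fiducial dimensions must be positive")

    def endpoints(self, displacement: Sequence[float] = (0, 0, 0)) -> np.ndarray:
        """(2, 3) array of the cylinder end points in the patient frame."""
        c = self.center.as_array() + np.asarray(displacement, dtype=float)
        a = np.asarray(self.orientation) * (self.length_mm / 2.0)
        return np.vstack([c - a, c + a])


@dataclass(frozen=True)
class BackgroundStructure:
    """Ellipsoidal clutter standing in for overlying anatomy (e.g. vertebral
    bodies).  Rendered as a projected anisotropic Gaussian blob."""

    center: PatientPoint
    semiaxes_mm: Tuple[float, float, float] = (10.0, 10.0, 10.0)
    contrast: float = 50.0

    def __post_init__(self) -> None:
        if self.contrast < 0:
            raise ValueError("background contrast must be >= 0")


@dataclass(frozen=True)
class BandArtifactModel:
    """Horizontal band artifacts on MV frames: a random subset of detector
    rows is scaled by a multiplicative factor drawn uniformly per frame."""

    row_period: int = 12         # mean spacing between banded row groups
    band_height_px: int = 4      # rows per band
    gain_range: Tuple[float, float] = (0.6, 1.0)

    def row_factors(self, n_rows: int, rng: np.random.Generator) -> np.ndarray:
        factors = np.ones(n_rows)
        row = int(rng.integers(0, max(self.row_period, 1)))
        while row < n_rows:
            g = float(rng.uniform(*self.gain_range))
            factors[row : row + self.band_height_px] = g
            row += int(rng.integers(self.row_period // 2 + 1, self.row_period * 2))
        return factors


@dataclass(frozen=True)
class PhantomModel:
    """Digital phantom: fiducials plus background clutter and noise model."""

    fiducials: Tuple[FiducialModel, ...]
    background: Tuple[BackgroundStructure, ...] = ()
    noise_sd: float = 80.0
    open_level: float = 1000.0
    blocked_level: float = 50.0
    detector_blur_px: float = 0.8
    band_artifact: Optional[BandArtifactModel] = field(default_factory=BandArtifactModel)

    def __post_init__(self) -> None:
        if len(self.fiducials) < 1:
            raise ValueError("phantom needs at least one fiducial")

    def fiducial_com(self) -> PatientPoint:
        centers = np.array([f.center.as_array() for f in self.fiducials])
        return PatientPoint.from_array(centers.mean(axis=0))


def default_fiducials(contrast: float = 400.0) -> Tuple[FiducialModel, ...]:
    """Three seeds with center of mass exactly at isocenter (offsets <= 10 mm),
    mimicking an arc planned 'centered on the fiducials'."""
    centers = [(8.0, -2.0, -6.0), (-6.0, 6.0, 2.0), (-2.0, -4.0, 4.0)]
    orientations = [(0.17, 0.1, 0.98), (-0.12, 0.2, 0.97), (0.05, -0.15, 0.99)]
    out = []
    for c, o in zip(centers, orientations):
        o = np.asarray(o) / np.linalg.norm(o)
        out.append(FiducialModel(center=PatientPoint(*c), orientation=tuple(o), contrast=contrast))
    return tuple(out)


def default_phantom(noise_sd: float = 80.0, contrast: float = 400.0) -> PhantomModel:
    """Anthropomorphic-like phantom: three fiducials near isocenter with
    vertebral-body-like clutter both in and out of the isocenter plane."""
    background = (
        BackgroundStructure(PatientPoint(0.0, 25.0, 0.0), (14.0, 10.0, 18.0), 60.0),
        BackgroundStructure(PatientPoint(-12.0, -30.0, 8.0), (10.0, 8.0, 12.0), 45.0),
        BackgroundStructure(PatientPoint(15.0, 5.0, -10.0), (8.0, 8.0, 8.0), 35.0),
    )
    return PhantomModel(
        fiducials=default_fiducials(contrast=contrast),
        background=background,
        noise_sd=noise_sd,
    )


@dataclass(frozen=True)
class ArcPlan:
    """A single full VMAT arc delivered at constant gantry speed."""

    n_control_points: int = 177
    arc_span_deg: float = 360.0
    start_angle_deg: float = 0.0
    gantry_speed_deg_s: float = 6.0  # 1 rpm
    mv_rate_hz: float = 9.5
    kv_rate_hz: float = 11.0

    def __post_init__(self) -> None:
        if self.mv_rate_hz <= 0 or self.kv_rate_hz <= 0 or self.gantry_speed_deg_s <= 0:
            raise ValueError("rates and gantry speed must be positive")
        if self.n_control_points < 2:
            raise ValueError("need at least 2 control points")

    @property
    def duration_s(self) -> float:
        return self.arc_span_deg / self.gantry_speed_deg_s

    def control_point_times(self) -> np.ndarray:
        """Times of the control points (evenly spaced in angle, hence time)."""
        return np.linspace(0.0, self.duration_s, self.n_control_points)


@dataclass(frozen=True)
class MotionScenario:
    """Phantom motion scenario.

    ``prostate_max_mm`` and ``resp_p2p_mm`` are in anatomical order
    (vertical, lateral, longitudinal).  The prostate trace reproduces the
    stated maximum excursions of a transponder-measured trace; the
    respiratory waveform is a periodic asymmetric function dwelling at
    end-exhale.
    """

    kind: str = "static"  # static | prostate | respiratory
    prostate_max_mm: Tuple[float, float, float] = (1.9, 1.8, 4.9)
    resp_period_s: float = 4.0
    resp_p2p_mm: Tuple[float, float, float] = (5.0, 2.0, 10.0)
    dwell_exponent: int = 2
    setup_error_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # constant offset, xyz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("static", "prostate", "respiratory"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.resp_period_s <= 0:
            raise ValueError("respiratory period must be positive")


def make_prostate_trace(
    max_mm: Sequence[float] = (1.9, 1.8, 4.9),
    n_points: int = 177,
    seed: int = 0,
    smooth_sigma: float = 10.0,
) -> np.ndarray:
    """Slow drifting target motion at the arc control points.

    A seeded band-limited random walk per axis, rescaled so the maximum
    absolute excursion on each axis equals the configured maximum exactly.
    Returns an (n_points, 3) array in anatomical order
    (vertical, lateral, longitudinal), starting at zero displacement.

    Stands in for a transponder-measured trace resampled to the control
    points; a measured trace can be supplied instead via the pipeline's
    CSV-trace option.
    """
    if n_points < 2:
        raise ValueError("need at least 2 control points")
    max_mm = np.asarray(max_mm, dtype=float)
    rng = np.random.default_rng(seed)
    trace = np.zeros((n_points, 3))
    for ax in range(3):
        w = np.cumsum(rng.standard_normal(n_points))
        w = gaussian_filter1d(w, sigma=smooth_sigma, mode="nearest")
        w -= w[0]
        peak = np.max(np.abs(w))
        if max_mm[ax] == 0 or peak == 0:
            continue
        trace[:, ax] = w * (max_mm[ax] / peak)
    return trace


def make_respiratory_trace(
    times: Sequence[float],
    period_s: float = 4.0,
    p2p_mm: Sequence[float] = (5.0, 2.0, 10.0),
    dwell_exponent: int = 2,
) -> np.ndarray:
    """Periodic asymmetric breathing displacement sampled at ``times``.

    Waveform ``A * sin(pi*t/T)**(2n)``: period exactly ``T``, peak-to-peak
    exactly ``A`` on each axis, with the flat troughs of the even sine
    power producing the extra dwell at the end-exhale (zero-displacement)
    extreme.  Delivery starts at end-exhale (zero displacement at t = 0),
    the position the phantom is set up and matched in.  Returns
    (len(times), 3) in anatomical order.
    """
    if period_s <= 0:
        raise ValueError("respiratory period must be positive")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (times.size > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError("times must be a strictly increasing 1-D sequence")
    s = np.sin(np.pi * times / period_s) ** (2 * int(dwell_exponent))
    return np.outer(s, np.asarray(p2p_mm, dtype=float))


@dataclass(frozen=True)
class FrameStream:
    """Acquisition schedule for one imaging chain: per-frame gantry angle of
    that chain and timestamp."""

    system_label: str
    times_s: np.ndarray
    angles_deg: np.ndarray

    def __len__(self) -> int:
        return len(self.times_s)


def acquisition_schedule(plan: ArcPlan, duration_s: Optional[float] = None) -> Tuple[FrameStream, FrameStream]:
    """Frame streams for both chains over ``duration_s`` of constant-speed
    arc delivery (defaults to the full arc).

    Frame counts are ``floor(rate * duration)``; frame ``j`` is stamped at
    ``j / rate`` with the chain's gantry angle at that instant.  The kV
    chain trails the MV chain by 90 degrees.
    """
    if duration_s is None:
        duration_s = plan.duration_s
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    streams = []
    for label, rate in (("MV", plan.mv_rate_hz), ("kV", plan.kv_rate_hz)):
        n = int(np.floor(rate * duration_s))
        t = np.arange(n) / rate
        gantry = plan.start_angle_deg + plan.gantry_speed_deg_s * t
        angles = gantry if label == "MV" else kv_angle_for(gantry)
        streams.append(FrameStream(label, t, angles % 360.0))
    return streams[0], streams[1]


def scenario_sampler(
    scenario: MotionScenario, plan: ArcPlan, duration_s: Optional[float] = None
) -> Callable[[float], np.ndarray]:
    """Displacement-vs-time function (patient xyz, mm) for a scenario.

    Prostate motion is defined at the control points and linearly
    interpolated in time, emulating continuous couch motion between
    programmed couch positions; respiratory motion is evaluated
    analytically; static returns the constant setup error.
    """
    setup = np.asarray(scenario.setup_error_mm, dtype=float)
    if scenario.kind == "static":
        return lambda t: setup.copy()
    if scenario.kind == "prostate":
        cp_times = plan.control_point_times()
        trace = make_prostate_trace(
            scenario.prostate_max_mm, plan.n_control_points, seed=scenario.seed
        )
        trace_xyz = np.column_stack([anatomical_to_xyz(row) for row in trace]).T

        def sample(t: float) -> np.ndarray:
            return setup + np.array(
                [np.interp(t, cp_times, trace_xyz[:, ax]) for ax in range(3)]
            )

        return sample
    # respiratory

    def sample_resp(t: float) -> np.ndarray:
        d = make_respiratory_trace(
            np.atleast_1d(float(t)),
            scenario.resp_period_s,
            scenario.resp_p2p_mm,
            scenario.dwell_exponent,
        )[0]
        return setup + anatomical_to_xyz(d)

    return sample_resp


@dataclass
class ProjectionFrame:
    """One acquired 2-D frame with its acquisition metadata."""

    pixels: np.ndarray
    system_label: str
    angle_deg: float
    time_s: float = 0.0
    aperture: Optional[np.ndarray] = None  # boolean irradiated mask, MV only


# ---------------------------------------------------------------------------
# Rendering


def _segment_distance_field(
    shape: Tuple[int, int], p1_px: Tuple[float, float], p2_px: Tuple[float, float],
    window_pad: float,
):
    """Distance (px) from each pixel in a local window to the segment p1-p2.

    Returns (row_slice, col_slice, distances) or None if the window misses
    the array entirely.
    """
    rows, cols = shape
    r1, c1 = p1_px
    r2, c2 = p2_px
    rmin = int(np.floor(min(r1, r2) - window_pad))
    rmax = int(np.ceil(max(r1, r2) + window_pad)) + 1
    cmin = int(np.floor(min(c1, c2) - window_pad))
    cmax = int(np.ceil(max(c1, c2) + window_pad)) + 1
    rmin, rmax = max(rmin, 0), min(rmax, rows)
    cmin, cmax = max(cmin, 0), min(cmax, cols)
    if rmin >= rmax or cmin >= cmax:
        return None
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    dr, dc = r2 - r1, c2 - c1
    seg_len2 = dr * dr + dc * dc
    if seg_len2 < 1e-12:
        d = np.hypot(rr - r1, cc - c1)
    else:
        t = np.clip(((rr - r1) * dr + (cc - c1) * dc) / seg_len2, 0.0, 1.0)
        d = np.hypot(rr - (r1 + t * dr), cc - (c1 + t * dc))
    return slice(rmin, rmax), slice(cmin, cmax), d


def _fiducial_segment_px(
    fid: FiducialModel, geom: ImagingGeometry, displacement: Sequence[float]
):
    """Projected cylinder axis as pixel endpoints plus the projected radius in px."""
    ends = fid.endpoints(displacement)
    ik = project_many(geom, ends)
    p_px = [
        detector_to_pixel(DetectorPoint(ik[j, 0], ik[j, 1]), geom, tol_px=1e9)
        for j in range(2)
    ]
    center = fid.center.as_array() + np.asarray(displacement, dtype=float)
    u = rotation_matrix(geom.gantry_angle_deg) @ center
    mag = geom.sid_mm / (geom.sad_mm - u[1])
    r_px = (fid.diameter_mm / 2.0) * mag / geom.pixel_pitch_mm
    return p_px[0], p_px[1], r_px


def render_fiducials(
    fiducials: Sequence[FiducialModel],
    geom: ImagingGeometry,
    displacement: Sequence[float] = (0.0, 0.0, 0.0),
    blur_px: float = 0.8,
    out: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Render cylinder fiducials onto the detector grid.

    Each fiducial is splatted as its analytic projected footprint: for a
    pixel at distance d from the projected cylinder axis, intensity is
    proportional to the chord length ``2*sqrt(r^2 - d^2)`` through the
    cylinder (peak = the fiducial's contrast on the axis).  A Gaussian blur
    models the detector response.  Shared by the acquisition simulator and
    the reference-template builder so both agree on sub-pixel positioning.
    """
    cols, rows = geom.detector_px
    img = out if out is not None else np.zeros((rows, cols))
    for fid in fiducials:
        p1, p2, r_px = _fiducial_segment_px(fid, geom, displacement)
        w = _segment_distance_field((rows, cols), p1, p2, window_pad=r_px + 4 * blur_px + 2)
        if w is None:
            continue
        rs, cs, d = w
        chord = np.sqrt(np.clip(r_px * r_px - d * d, 0.0, None)) / max(r_px, 1e-9)
        img[rs, cs] += fid.contrast * chord
    if blur_px > 0:
        img = gaussian_filter(img, sigma=blur_px)
    return img


def fiducial_footprint_mask(
    fid: FiducialModel,
    geom: ImagingGeometry,
    displacement: Sequence[float] = (0.0, 0.0, 0.0),
    margin_mm: float = 0.0,
) -> np.ndarray:
    """Boolean projected footprint of a fiducial, optionally grown by a 3-D
    margin (applied to the cylinder radius and length before projection)."""
    grown = dataclasses.replace(
        fid,
        length_mm=fid.length_mm + 2 * margin_mm,
        diameter_mm=fid.diameter_mm + 2 * margin_mm,
    )
    p1, p2, r_px = _fiducial_segment_px(grown, geom, displacement)
    cols, rows = geom.detector_px
    mask = np.zeros((rows, cols), dtype=bool)
    w = _segment_distance_field((rows, cols), p1, p2, window_pad=r_px + 2)
    if w is not None:
        rs, cs, d = w
        mask[rs, cs] = d <= r_px
    return mask


def _render_background(
    background: Sequence[BackgroundStructure],
    geom: ImagingGeometry,
    displacement: Sequence[float],
    img: np.ndarray,
) -> None:
    rows, cols = img.shape
    rot = rotation_matrix(geom.gantry_angle_deg)
    for bg in background:
        c = bg.center.as_array() + np.asarray(displacement, dtype=float)
        u = rot @ c
        depth = geom.sad_mm - u[1]
        if depth <= 1e-9:
            continue
        mag = geom.sid_mm / depth
        ik = project(geom, PatientPoint.from_array(c))
        r0, c0 = detector_to_pixel(ik, geom, tol_px=1e9)
        # In-plane semiaxes projected; sigma ~ semiaxis/2 gives a soft blob.
        ax = np.asarray(bg.semiaxes_mm)
        sig_c = max(ax[0] * mag / geom.pixel_pitch_mm / 2.0, 0.5)
        sig_r = max(ax[2] * mag / geom.pixel_pitch_mm / 2.0, 0.5)
        pad = 3.5 * max(sig_r, sig_c)
        rmin, rmax = max(int(r0 - pad), 0), min(int(r0 + pad) + 1, rows)
        cmin, cmax = max(int(c0 - pad), 0), min(int(c0 + pad) + 1, cols)
        if rmin >= rmax or cmin >= cmax:
            continue
        rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
        img[rmin:rmax, cmin:cmax] += bg.contrast * np.exp(
            -0.5 * (((rr - r0) / sig_r) ** 2 + ((cc - c0) / sig_c) ** 2)
        )


def aperture_mask(
    geom: ImagingGeometry,
    phantom: PhantomModel,
    displacement: Sequence[float] = (0.0, 0.0, 0.0),
    mode: str = "rect",
    margin_mm: float = 15.0,
) -> np.ndarray:
    """Boolean mask of irradiated detector pixels for the MLC aperture.

    ``rect``: fiducial-enclosing rectangle with a beam's-eye-view margin
    (mm at the detector plane) around the *planned* fiducial positions —
    the aperture tracks the plan, not the moving target.  ``open``: whole
    detector; ``closed``: nothing irradiated.
    """
    cols, rows = geom.detector_px
    if mode == "open":
        return np.ones((rows, cols), dtype=bool)
    if mode == "closed":
        return np.zeros((rows, cols), dtype=bool)
    if mode != "rect":
        raise ValueError(f"unknown aperture mode {mode!r}")
    pts = np.vstack([f.endpoints((0.0, 0.0, 0.0)) for f in phantom.fiducials])
    ik = project_many(geom, pts)
    pad = margin_mm
    i_lo, i_hi = ik[:, 0].min() - pad, ik[:, 0].max() + pad
    k_lo, k_hi = ik[:, 1].min() - pad, ik[:, 1].max() + pad
    rc, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    k_of_row = (rc - np.arange(rows)) * geom.pixel_pitch_mm
    i_of_col = (np.arange(cols) - cc) * geom.pixel_pitch_mm
    mask = (
        ((k_of_row >= k_lo) & (k_of_row <= k_hi))[:, None]
        & ((i_of_col >= i_lo) & (i_of_col <= i_hi))[None, :]
    )
    return mask


def render_projection(
    phantom: PhantomModel,
    geom: ImagingGeometry,
    displacement: Sequence[float] = (0.0, 0.0, 0.0),
    aperture: "np.ndarray | str" = "open",
    rng: Optional[np.random.Generator] = None,
    time_s: float = 0.0,
    add_noise: bool = True,
    add_bands: Optional[bool] = None,
) -> ProjectionFrame:
    """Forward-render one acquisition frame.

    ``aperture`` may be a boolean mask or one of {"open", "rect", "closed"}.
    Irradiated pixels carry the open-field level plus projected background
    clutter and fiducial signal; blocked pixels sit at the blocked level.
    MV frames optionally receive multiplicative row-band artifacts.
    Deterministic given an ``rng`` state.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    cols, rows = geom.detector_px
    if isinstance(aperture, str):
        aperture = aperture_mask(geom, phantom, displacement, mode=aperture)
    if aperture.shape != (rows, cols):
        raise ValueError("aperture mask shape does not match the detector")

    signal = np.zeros((rows, cols))
    _render_background(phantom.background, geom, displacement, signal)
    render_fiducials(
        phantom.fiducials, geom, displacement,
        blur_px=0.0, out=signal,
    )
    if phantom.detector_blur_px > 0:
        signal = gaussian_filter(signal, sigma=phantom.detector_blur_px)

    img = np.where(aperture, phantom.open_level + signal, phantom.blocked_level)

    if add_bands is None:
        add_bands = geom.system_label == "MV"
    if add_bands and phantom.band_artifact is not None:
        factors = phantom.band_artifact.row_factors(rows, rng)
        img = np.where(aperture, img * factors[:, None], img)

    if add_noise and phantom.noise_sd > 0:
        img = img + rng.normal(0.0, phantom.noise_sd, size=img.shape)

    return ProjectionFrame(
        pixels=img,
        system_label=geom.system_label,
        angle_deg=geom.gantry_angle_deg,
        time_s=time_s,
        aperture=aperture,
    )
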