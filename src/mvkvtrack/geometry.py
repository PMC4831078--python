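"""Cone-beam projection geometry and stereoscopic MV/kV triangulation.

Coordinate conventions
----------------------
The patient frame is right-handed with its origin at the machine isocenter:
``x`` = left-right (lateral), ``y`` = anterior-posterior (vertical, pointing
toward the gantry-zero source), ``z`` = superior-inferior (the gantry
rotation axis, longitudinal).  Gantry angles are in degrees and increase
clockwise when viewed from the foot of the couch; the on-board kV imaging
chain trails the treatment (MV) chain by 90 degrees.

Each imaging chain at gantry angle ``theta`` defines a *system frame*
obtained by applying :func:`rotation_matrix` to patient coordinates.  In
that frame the X-ray source sits at ``[0, SAD, 0]`` and the detector center
at ``[0, -IDD, 0]``, where SAD is the source-axis distance and IDD the
isocenter-detector distance (SID = SAD + IDD is the source-detector
distance).  A point on the detector is expressed as ``(i, k)`` in physical
millimetres at the detector plane, measured from the detector center:
``i`` lies in the rotation plane (+i along +x at gantry zero) and ``k``
along the rotation axis (+k superior).

Pixel convention: frame arrays are ``(rows, cols)`` with row 0 at the top;
``+col`` maps to ``+i`` and ``+row`` to ``-k`` (image rows run inferior-ward
down the array).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "GeometryError",
    "DegenerateProjectionError",
    "IllConditionedGeometryError",
    "DetectorBoundsError",
    "ImagingGeometry",
    "PatientPoint",
    "DetectorPoint",
    "TriangulationResult",
    "rotation_matrix",
    "project",
    "triangulate",
    "pixel_to_detector",
    "detector_to_pixel",
    "kv_angle_for",
    "MV_PIXEL_PITCH_MM",
    "KV_PIXEL_PITCH_MM",
    "KV_OFFSET_DEG",
]

#: Effective detector pixel pitch of the portal (MV) imager, mm.
MV_PIXEL_PITCH_MM = 0.392
#: Effective detector pixel pitch of the on-board kV imager, mm.
KV_PIXEL_PITCH_MM = 0.388
#: Angular offset of the kV chain relative to the MV chain, degrees.
KV_OFFSET_DEG = -90.0


class GeometryError(ValueError):
    """Invalid imaging geometry or geometric operation."""


class DegenerateProjectionError(GeometryError):
    """Point at or behind the X-ray source cannot be projected."""


class IllConditionedGeometryError(GeometryError):
    """Imaging chains too close to parallel for stable triangulation."""


class DetectorBoundsError(GeometryError):
    """Pixel or detector coordinate outside the physical detector."""


@dataclass(frozen=True)
class ImagingGeometry:
    """One imaging chain (MV or kV) of a rotating gantry.

    Parameters are all in millimetres / degrees.  The invariant
    ``sid_mm == sad_mm + idd_mm`` is enforced at construction.
    """

    system_label: str  # "MV" or "kV"
    gantry_angle_deg: float
    sad_mm: float = 1000.0
    sid_mm: float = 1500.0
    idd_mm: float = 500.0
    pixel_pitch_mm: float = MV_PIXEL_PITCH_MM
    detector_px: Tuple[int, int] = (256, 256)  # (cols, rows)

    def __post_init__(self) -> None:
        if self.system_label not in ("MV", "kV"):
            raise GeometryError(f"system_label must be 'MV' or 'kV', got {self.system_label!r}")
        for name in ("sad_mm", "sid_mm", "idd_mm"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0")
        if abs(self.sid_mm - (self.sad_mm + self.idd_mm)) > 1e-6:
            raise GeometryError(
                f"sid_mm ({self.sid_mm}) must equal sad_mm + idd_mm "
                f"({self.sad_mm} + {self.idd_mm})"
            )
        if not self.pixel_pitch_mm > 0:
            raise GeometryError("pixel_pitch_mm must be > 0")
        if not np.isfinite(self.gantry_angle_deg):
            raise GeometryError("gantry_angle_deg must be finite")

    @property
    def magnification(self) -> float:
        """Magnification of the isocenter plane onto the detector (SID/SAD)."""
        return self.sid_mm / self.sad_mm

    def at_angle(self, gantry_angle_deg: float) -> "ImagingGeometry":
        """Same chain rotated to a different gantry angle."""
        return dataclasses.replace(self, gantry_angle_deg=gantry_angle_deg)

    @classmethod
    def mv(cls, gantry_angle_deg: float = 0.0, **kw) -> "ImagingGeometry":
        kw.setdefault("pixel_pitch_mm", MV_PIXEL_PITCH_MM)
        return cls(system_label="MV", gantry_angle_deg=gantry_angle_deg, **kw)

    @classmethod
    def kv(cls, gantry_angle_deg: float = KV_OFFSET_DEG, **kw) -> "ImagingGeometry":
        kw.setdefault("pixel_pitch_mm", KV_PIXEL_PITCH_MM)
        return cls(system_label="kV", gantry_angle_deg=gantry_angle_deg, **kw)


def kv_angle_for(mv_angle_deg: float) -> float:
    """Gantry angle of the kV chain when the MV chain is at ``mv_angle_deg``."""
    return mv_angle_deg + KV_OFFSET_DEG


@dataclass(frozen=True)
class PatientPoint:
    """A point in the fixed patient frame, origin at isocenter, mm."""

    x_mm: float
    y_mm: float
    z_mm: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x_mm, self.y_mm, self.z_mm])):
            raise GeometryError("PatientPoint coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm, self.z_mm], dtype=float)

    @classmethod
    def from_array(cls, a) -> "PatientPoint":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class DetectorPoint:
    """A point on a detector plane: physical mm from the detector center."""

    i_mm: float  # in-rotation-plane coordinate
    k_mm: float  # along the rotation (longitudinal) axis

    def as_array(self) -> np.ndarray:
        return np.array([self.i_mm, self.k_mm], dtype=float)


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """Rotation taking patient-frame coordinates into the system frame of an
    imaging chain at gantry angle ``theta_deg`` (rotation about the patient
    longitudinal z axis)."""
    if not np.isfinite(theta_deg):
        raise GeometryError("rotation angle must be finite")
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def project(geom: ImagingGeometry, p: PatientPoint) -> DetectorPoint:
    """Cone projection of a patient-frame point onto the detector plane.

    The source, the point, and the returned detector point are collinear.
    Raises :class:`DegenerateProjectionError` if the point lies at or behind
    the source plane.
    """
    u = rotation_matrix(geom.gantry_angle_deg) @ p.as_array()
    depth = geom.sad_mm - u[1]  # distance from source plane along the beam axis
    if depth <= 1e-9:
        raise DegenerateProjectionError(
            f"point at/behind the source (system-frame y={u[1]:.3f} >= SAD={geom.sad_mm})"
        )
    scale = geom.sid_mm / depth
    return DetectorPoint(float(u[0] * scale), float(u[2] * scale))


def project_many(geom: ImagingGeometry, points_xyz: np.ndarray) -> np.ndarray:
    """Vectorised :func:`project` for an (N, 3) array; returns (N, 2) of (i, k) mm."""
    pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
    u = pts @ rotation_matrix(geom.gantry_angle_deg).T
    depth = geom.sad_mm - u[:, 1]
    if np.any(depth <= 1e-9):
        raise DegenerateProjectionError("one or more points at/behind the source")
    scale = geom.sid_mm / depth
    return np.column_stack([u[:, 0] * scale, u[:, 2] * scale])


@dataclass(frozen=True)
class TriangulationResult:
    """Least-squares 3D point and its reprojection residual."""

    point: PatientPoint
    residual_mm: float  # max reprojection distance over the two chains

    def __iter__(self):
        return iter((self.point, self.residual_mm))


def _angular_separation_deg(a: float, b: float) -> float:
    """Separation of two ray directions modulo 180 degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def triangulate(
    kv_obs: DetectorPoint,
    mv_obs: DetectorPoint,
    kv_geom: ImagingGeometry,
    mv_geom: ImagingGeometry,
    min_separation_deg: float = 5.0,
) -> TriangulationResult:
    """Recover the 3D patient-frame point from one kV and one MV observation.

    Each observation constrains the point to the ray from that chain's source
    through the observed detector position.  In the system frame of a chain,
    with ``u = r(theta) @ X_p``, a point on the ray through detector position
    (i, k) satisfies::

        SID * u_x + i * u_y = i * SAD
        SID * u_z + k * u_y = k * SAD

    Stacking both chains gives four linear equations in the three unknowns
    of ``X_p``; the overdetermined system is solved by ordinary least
    squares.  For consistent observations the solution is exact to numerical
    precision; for noisy observations it is the least-squares compromise.
    """
    sep = _angular_separation_deg(kv_geom.gantry_angle_deg, mv_geom.gantry_angle_deg)
    if sep < min_separation_deg:
        raise IllConditionedGeometryError(
            f"imaging chains separated by only {sep:.2f} deg (< {min_separation_deg} deg); "
            "rays too close to parallel"
        )

    rows = []
    rhs = []
    for obs, geom in ((kv_obs, kv_geom), (mv_obs, mv_geom)):
        r = rotation_matrix(geom.gantry_angle_deg)
        sid, sad = geom.sid_mm, geom.sad_mm
        rows.append(sid * r[0] + obs.i_mm * r[1])
        rhs.append(obs.i_mm * sad)
        rows.append(sid * r[2] + obs.k_mm * r[1])
        rhs.append(obs.k_mm * sad)
    a = np.asarray(rows)
    b = np.asarray(rhs)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    point = PatientPoint.from_array(sol)

    resid = 0.0
    for obs, geom in ((kv_obs, kv_geom), (mv_obs, mv_geom)):
        reproj = project(geom, point)
        resid = max(resid, float(np.hypot(reproj.i_mm - obs.i_mm, reproj.k_mm - obs.k_mm)))
    return TriangulationResult(point=point, residual_mm=resid)


def _detector_center_px(geom: ImagingGeometry) -> Tuple[float, float]:
    cols, rows = geom.detector_px
    return (rows - 1) / 2.0, (cols - 1) / 2.0  # (center_row, center_col)


def pixel_to_detector(
    frame_coords: Tuple[float, float], geom: ImagingGeometry, tol_px: float = 0.5
) -> DetectorPoint:
    """Map array (row, col) coordinates to physical detector (i, k) mm.

    The detector center pixel maps to (0, 0) mm; +col is +i, +row is -k.
    """
    row, col = frame_coords
    cols, rows = geom.detector_px
    if not (-tol_px <= row <= rows - 1 + tol_px and -tol_px <= col <= cols - 1 + tol_px):
        raise DetectorBoundsError(
            f"pixel ({row}, {col}) outside {rows}x{cols} detector"
        )
    rc, cc = _detector_center_px(geom)
    return DetectorPoint(
        i_mm=(col - cc) * geom.pixel_pitch_mm,
        k_mm=(rc - row) * geom.pixel_pitch_mm,
    )


def detector_to_pixel(
    point: DetectorPoint, geom: ImagingGeometry, tol_px: float = 0.5
) -> Tuple[float, float]:
    """Inverse of :func:`pixel_to_detector`: (i, k) mm to array (row, col)."""
    rc, cc = _detector_center_px(geom)
    row = rc - point.k_mm / geom.pixel_pitch_mm
    col = cc + point.i_mm / geom.pixel_pitch_mm
    cols, rows = geom.detector_px
    if not (-tol_px <= row <= rows - 1 + tol_px and -tol_px <= col <= cols - 1 + tol_px):
        raise DetectorBoundsError(
            f"detector point ({point.i_mm:.2f}, {point.k_mm:.2f}) mm outside detector"
        )
    return (row, col)
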