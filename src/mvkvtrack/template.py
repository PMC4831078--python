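"""Per-angle fiducial reference templates with registration ROIs.

Reference images are rendered analytically from the 3-D fiducial models
(center, orientation, cylinder dimensions) at each requested gantry angle,
using the same renderer as the acquisition simulator so template and image
agree on sub-pixel fiducial placement.  Each fiducial also contributes a
region of interest: its 3-D shape grown by a margin (default 1 mm) and then
projected — the cost function of the registration stage is evaluated over
these ROI pixels only.  Template backgrounds are zero: no anatomy is
rendered, which is what gives fiducial templates their advantage over
conventional DRRs for registration.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import DetectorPoint, ImagingGeometry, PatientPoint, project, project_many
from .simulate import FiducialModel, fiducial_footprint_mask, render_fiducials

__all__ = [
    "TemplateError",
    "TemplateImage",
    "TemplateSet",
    "build_templates",
    "nearest_template",
    "adjust_to_daily_positions",
]


class TemplateError(ValueError):
    pass


@dataclass
class TemplateImage:
    """Rendered fiducial-only reference image at one gantry angle."""

    pixels: np.ndarray
    rois: List[np.ndarray]          # per-fiducial boolean masks
    planned_com: DetectorPoint      # projection of the 3-D fiducial center of mass
    angle_deg: float
    out_of_view: bool = False       # any fiducial (partly) outside the detector

    @property
    def roi_union(self) -> np.ndarray:
        u = np.zeros_like(self.rois[0], dtype=bool)
        for r in self.rois:
            u |= r
        return u


@dataclass
class TemplateSet:
    """Templates over a set of angles plus the build inputs needed to
    re-render them (e.g. after a position-of-the-day adjustment)."""

    templates: List[TemplateImage]
    fiducials: Tuple[FiducialModel, ...]
    geom_base: ImagingGeometry
    margin_mm: float = 1.0
    blur_px: float = 0.8

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([t.angle_deg for t in self.templates])


def _fiducial_in_view(fid: FiducialModel, geom: ImagingGeometry) -> bool:
    ik = project_many(geom, fid.endpoints())
    cols, rows = geom.detector_px
    half_i = cols * geom.pixel_pitch_mm / 2.0
    half_k = rows * geom.pixel_pitch_mm / 2.0
    return bool(np.all(np.abs(ik[:, 0]) <= half_i) and np.all(np.abs(ik[:, 1]) <= half_k))


def build_templates(
    fiducials: Sequence[FiducialModel],
    geom_base: ImagingGeometry,
    angles_deg: Sequence[float],
    margin_mm: float = 1.0,
    blur_px: float = 0.8,
) -> TemplateSet:
    """Render one reference template per requested gantry angle.

    The per-fiducial ROI is the projection of the cylinder grown by
    ``margin_mm`` in 3-D (radius and half-length), guaranteeing the ROI
    fully contains the rendered footprint.  Fiducials falling outside the
    field of view raise a warning and flag the template rather than failing.
    """
    if len(fiducials) < 1:
        raise TemplateError("need at least one fiducial")
    angles = np.asarray(angles_deg, dtype=float)
    if np.any((angles < 0) | (angles >= 360)):
        raise TemplateError("template angles must lie in [0, 360)")
    com3d = PatientPoint.from_array(
        np.mean([f.center.as_array() for f in fiducials], axis=0)
    )
    templates: List[TemplateImage] = []
    for ang in angles:
        geom = geom_base.at_angle(float(ang))
        pixels = render_fiducials(fiducials, geom, blur_px=blur_px)
        rois = [fiducial_footprint_mask(f, geom, margin_mm=margin_mm) for f in fiducials]
        out_of_view = not all(_fiducial_in_view(f, geom) for f in fiducials)
        if out_of_view:
            warnings.warn(
                f"fiducial outside the field of view at gantry {ang:.1f} deg; "
                "template flagged",
                stacklevel=2,
            )
        if any(not r.any() for r in rois):
            warnings.warn(
                f"empty ROI at gantry {ang:.1f} deg (fiducial off-detector)",
                stacklevel=2,
            )
        templates.append(
            TemplateImage(
                pixels=pixels,
                rois=rois,
                planned_com=project(geom, com3d),
                angle_deg=float(ang),
                out_of_view=out_of_view,
            )
        )
    return TemplateSet(
        templates=templates,
        fiducials=tuple(fiducials),
        geom_base=geom_base,
        margin_mm=margin_mm,
        blur_px=blur_px,
    )


def nearest_template(template_set: "TemplateSet | Sequence[TemplateImage]", angle_deg: float) -> TemplateImage:
    """Template minimising circular angular distance to ``angle_deg``; ties
    are broken toward the smaller template angle."""
    templates = template_set.templates if isinstance(template_set, TemplateSet) else list(template_set)
    if not templates:
        raise TemplateError("empty template set")
    ang = angle_deg % 360.0
    best = None
    best_key = None
    for t in templates:
        d = abs(t.angle_deg - ang) % 360.0
        d = min(d, 360.0 - d)
        key = (round(d, 9), t.angle_deg)  # tie -> smaller angle
        if best_key is None or key < best_key:
            best, best_key = t, key
    return best


def adjust_to_daily_positions(
    template_set: TemplateSet, observed_positions: Sequence[PatientPoint]
) -> TemplateSet:
    """Re-render the template set with fiducial centers moved to their
    observed (setup-imaging) 3-D positions, preserving orientations.

    This captures inter-fraction fiducial migration or tissue deformation:
    the relative inter-fiducial geometry of the daily observation replaces
    the planned one in every template.
    """
    if len(observed_positions) != len(template_set.fiducials):
        raise TemplateError(
            f"{len(observed_positions)} observed positions for "
            f"{len(template_set.fiducials)} fiducials"
        )
    new_fids = tuple(
        dataclasses.replace(f, center=p)
        for f, p in zip(template_set.fiducials, observed_positions)
    )
    return build_templates(
        new_fids,
        template_set.geom_base,
        [t.angle_deg for t in template_set.templates],
        margin_mm=template_set.margin_mm,
        blur_px=template_set.blur_px,
    )
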