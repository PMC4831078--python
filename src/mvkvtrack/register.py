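"""2-D template registration: NCC cost, multi-start simplex, FOM gating.

The match position of the fiducial pattern in an acquired frame is found by
minimising ``1 - ZNCC`` (zero-normalised cross-correlation, evaluated over
the template's ROI pixels only) over a 2-D translation.  To avoid local
minima, the cost is first evaluated on a coarse grid of starting positions
inside the search region; Nelder-Mead simplex minimisation is launched
from the best grid points and, independently, from the planned position,
and the lowest-cost converged result wins.  A peak-to-sidelobe figure of
merit (correlation magnitude at the match divided by the standard deviation
of the correlation on a surrounding annulus) gates acceptance: matches with
FOM below threshold are flagged as failures (e.g. fiducials blocked by the
MLC), letting the caller fall back to a 2-D kV-only assessment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize

from .template import TemplateImage

__all__ = [
    "RegistrationError",
    "ZeroVariancePatchError",
    "SearchConfig",
    "RegistrationResult",
    "ncc_cost",
    "compute_fom",
    "register",
    "track_sequence",
]

_FAILED_COST = float("inf")
_PENALTY_COST = 3.0  # worse than the worst attainable NCC cost (2.0)


class RegistrationError(ValueError):
    pass


class ZeroVariancePatchError(RegistrationError):
    """Image patch under the ROI has no intensity variation (blocked fiducial)."""


@dataclass(frozen=True)
class SearchConfig:
    """Search-strategy and confidence-gate settings (all lengths in mm at
    the detector plane)."""

    initial_region_mm: float = 10.0
    subsequent_region_mm: float = 5.0
    grid_spacing_mm: float = 2.0
    n_starts: int = 5
    fom_threshold: float = 5.0
    simplex_xatol_mm: float = 0.01
    max_iter: int = 200
    drop_blocked_rois: bool = False
    fom_annulus_mm: Tuple[float, float] = (5.0, 8.0)
    fom_lattice_mm: float = 0.5
    fom_core_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.initial_region_mm < self.grid_spacing_mm:
            raise RegistrationError("search region must be >= grid spacing")
        if self.n_starts < 1:
            raise RegistrationError("n_starts must be >= 1")


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of one template-to-image registration."""

    shift_mm: Tuple[float, float]  # (i, k) displacement of the fiducial COM
    cost: float
    fom: float
    success: bool
    origin: str  # "tracked_start" | "planned_start"


class _CostEvaluator:
    """ZNCC cost of a template against an image as a function of 2-D shift.

    Template ROI pixel coordinates and intensities are precomputed; each
    evaluation bilinearly samples the image at the ROI coordinates offset
    by the candidate shift (detector mm -> pixels).
    """

    def __init__(
        self,
        image: np.ndarray,
        template: TemplateImage,
        pitch_mm: float,
        drop_blocked_rois: bool = False,
    ):
        self.image = np.asarray(image, dtype=float)
        self.pitch = float(pitch_mm)
        self.drop_blocked_rois = drop_blocked_rois
        self.roi_coords: List[np.ndarray] = []
        self.roi_tvals: List[np.ndarray] = []
        for roi in template.rois:
            rr, cc = np.nonzero(roi)
            if rr.size == 0:
                continue
            self.roi_coords.append(np.vstack([rr, cc]).astype(float))
            self.roi_tvals.append(np.asarray(template.pixels, dtype=float)[rr, cc])
        if not self.roi_coords:
            raise RegistrationError("template has no ROI pixels")

    def _samples(self, shift_mm: Sequence[float]) -> List[np.ndarray]:
        drow = -shift_mm[1] / self.pitch
        dcol = shift_mm[0] / self.pitch
        out = []
        for coords in self.roi_coords:
            out.append(
                map_coordinates(
                    self.image,
                    coords + np.array([[drow], [dcol]]),
                    order=1,
                    mode="nearest",
                )
            )
        return out

    def batch_costs(self, shifts_mm: np.ndarray) -> np.ndarray:
        """Costs for an (S, 2) array of shifts in one resampling pass.

        Entries are NaN where the image patch has (near-)zero variance.
        Blocked-ROI dropping is not applied in batch mode; batch evaluation
        serves surface probing (FOM sidelobes, exhaustive searches).
        """
        shifts = np.atleast_2d(np.asarray(shifts_mm, dtype=float))
        drow = -shifts[:, 1] / self.pitch
        dcol = shifts[:, 0] / self.pitch
        sample_blocks = []
        for coords in self.roi_coords:
            rows = coords[0][None, :] + drow[:, None]
            cols = coords[1][None, :] + dcol[:, None]
            vals = map_coordinates(
                self.image,
                np.stack([rows.ravel(), cols.ravel()]),
                order=1,
                mode="nearest",
            ).reshape(len(shifts), coords.shape[1])
            sample_blocks.append(vals)
        b = np.concatenate(sample_blocks, axis=1)
        a = np.concatenate(self.roi_tvals)
        a = a - a.mean()
        na = np.linalg.norm(a)
        b = b - b.mean(axis=1, keepdims=True)
        nb = np.linalg.norm(b, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            costs = 1.0 - (b @ a) / (na * nb)
        costs[nb < 1e-12] = np.nan
        return costs

    def __call__(self, shift_mm: Sequence[float]) -> float:
        samples = self._samples(shift_mm)
        tvals, ivals = [], []
        for t, s in zip(self.roi_tvals, samples):
            if self.drop_blocked_rois and np.std(s) < 1e-9:
                continue  # fully blocked fiducial: exclude from the cost
            tvals.append(t)
            ivals.append(s)
        if not tvals:
            raise ZeroVariancePatchError("all ROIs blocked (no image variation)")
        a = np.concatenate(tvals)
        b = np.concatenate(ivals)
        a = a - a.mean()
        b = b - b.mean()
        nb = np.linalg.norm(b)
        if nb < 1e-12:
            raise ZeroVariancePatchError("zero-variance image patch under the ROI")
        na = np.linalg.norm(a)
        if na < 1e-12:
            raise RegistrationError("zero-variance template (no fiducial signal)")
        return float(1.0 - np.dot(a, b) / (na * nb))


def ncc_cost(
    image: np.ndarray,
    template: TemplateImage,
    shift_mm: Sequence[float],
    pitch_mm: float,
    drop_blocked_rois: bool = False,
) -> float:
    """``1 - ZNCC`` of the template against the image at a trial shift.

    Evaluated over ROI pixels only; range [0, 2]; invariant to affine
    intensity rescaling of the image.  Raises
    :class:`ZeroVariancePatchError` on a flat image patch.
    """
    return _CostEvaluator(image, template, pitch_mm, drop_blocked_rois)(shift_mm)


def compute_fom(
    cost_sampler: Callable[[Sequence[float]], float],
    match_shift_mm: Sequence[float],
    config: SearchConfig = SearchConfig(),
) -> float:
    """Peak-to-sidelobe ratio of the correlation surface at a match point.

    The peak is the correlation magnitude ``|1 - cost|`` at the match; the
    sidelobe is the correlation sampled on a regular lattice over an
    annulus around the match (excluding a core region).  Higher means a
    more detectable fiducial pattern.  Deterministic given the lattice.
    """
    match = np.asarray(match_shift_mm, dtype=float)
    try:
        peak = abs(1.0 - cost_sampler(match))
    except ZeroVariancePatchError:
        return 0.0
    r_in, r_out = config.fom_annulus_mm
    step = config.fom_lattice_mm
    offs = np.arange(-r_out, r_out + step / 2, step)
    oi, ok = np.meshgrid(offs, offs, indexing="ij")
    r = np.hypot(oi, ok)
    keep = (r >= max(r_in, config.fom_core_mm)) & (r <= r_out)
    lattice = match + np.column_stack([oi[keep], ok[keep]])
    if hasattr(cost_sampler, "batch_costs"):
        costs = cost_sampler.batch_costs(lattice)
        vals = list(1.0 - costs[np.isfinite(costs)])
    else:
        vals = []
        for pt in lattice:
            try:
                vals.append(1.0 - cost_sampler(pt))
            except ZeroVariancePatchError:
                continue
    if len(vals) < 8:
        warnings.warn("too few sidelobe samples; FOM undefined", stacklevel=2)
        return 0.0
    sd = float(np.std(vals))
    if sd < 1e-12:
        warnings.warn("zero sidelobe variance; FOM set to +inf", stacklevel=2)
        return float("inf")
    return peak / sd


def _failure_result(prev_shift: Sequence[float]) -> RegistrationResult:
    return RegistrationResult(
        shift_mm=(float(prev_shift[0]), float(prev_shift[1])),
        cost=_FAILED_COST,
        fom=0.0,
        success=False,
        origin="tracked_start",
    )


def register(
    image: np.ndarray,
    template: TemplateImage,
    prev_shift: Sequence[float] = (0.0, 0.0),
    planned_shift: Sequence[float] = (0.0, 0.0),
    config: SearchConfig = SearchConfig(),
    pitch_mm: float = 1.0,
    region_mm: Optional[float] = None,
) -> RegistrationResult:
    """Find the template's match shift in the image.

    The cost is evaluated on a grid (``grid_spacing_mm`` spacing, edges
    inclusive, laid symmetrically about ``prev_shift``) covering the search
    region; simplex minimisation runs from the ``n_starts`` lowest-cost
    grid points and additionally from ``planned_shift``, and the lowest
    final cost wins (ties broken toward the smallest displacement from the
    start).  The result is FOM-gated: ``success`` requires the
    peak-to-sidelobe ratio to reach the configured threshold.
    """
    region = float(region_mm if region_mm is not None else config.initial_region_mm)
    center = np.asarray(prev_shift, dtype=float)
    try:
        evaluator = _CostEvaluator(image, template, pitch_mm, config.drop_blocked_rois)
    except RegistrationError:
        return _failure_result(prev_shift)

    half = region / 2.0
    bound_half = half + 1.0  # small slack so simplex can converge at the edge

    def make_objective(anchor: np.ndarray):
        # Each start arm is confined to the search region about its own
        # anchor (the tracked position for grid starts, the planned
        # position for the restart arm), so the planned restart can recover
        # a target that left the tracked region.
        def objective(s: np.ndarray) -> float:
            excess = np.abs(s - anchor) - bound_half
            if np.any(excess > 0):
                return _PENALTY_COST + float(np.sum(np.clip(excess, 0, None)))
            try:
                return evaluator(s)
            except ZeroVariancePatchError:
                return _PENALTY_COST

        return objective

    tracked_objective = make_objective(center)
    offs = np.arange(-half, half + 1e-9, config.grid_spacing_mm)
    grid = [center + np.array([oi, ok]) for oi in offs for ok in offs]
    grid_costs = np.array([tracked_objective(g) for g in grid])
    valid = grid_costs < _PENALTY_COST
    starts: List[Tuple[np.ndarray, str, object]] = []
    if valid.any():
        order = np.argsort(grid_costs)
        for idx in order[: config.n_starts]:
            if grid_costs[idx] < _PENALTY_COST:
                starts.append((grid[idx], "tracked_start", tracked_objective))
    planned = np.asarray(planned_shift, dtype=float)
    starts.append((planned, "planned_start", make_objective(planned)))

    best: Optional[Tuple[float, float, np.ndarray, str]] = None  # (cost, |d|, shift, origin)
    for s0, origin, objective in starts:
        res = minimize(
            objective,
            s0,
            method="Nelder-Mead",
            options={
                "xatol": config.simplex_xatol_mm,
                "fatol": 1e-9,
                "maxiter": config.max_iter,
            },
        )
        cost = float(res.fun)
        if cost >= _PENALTY_COST:
            continue
        key = (round(cost, 12), float(np.linalg.norm(res.x - s0)))
        if best is None or key < (round(best[0], 12), best[1]):
            best = (cost, key[1], res.x, origin)
    if best is None:
        return _failure_result(prev_shift)

    cost, _, shift, origin = best
    fom = compute_fom(evaluator, shift, config)
    return RegistrationResult(
        shift_mm=(float(shift[0]), float(shift[1])),
        cost=cost,
        fom=fom,
        success=bool(np.isfinite(cost) and fom >= config.fom_threshold),
        origin=origin,
    )


def track_sequence(
    images: Sequence[np.ndarray],
    templates: Sequence[TemplateImage],
    config: SearchConfig = SearchConfig(),
    pitch_mm: float = 1.0,
    planned_shift: Sequence[float] = (0.0, 0.0),
) -> List[RegistrationResult]:
    """Register a time-ordered image sequence, chaining match positions.

    The first frame searches the initial (wide) region about the planned
    position; subsequent frames search the smaller region about the
    previous match.  FOM failures are recorded as data and tracking
    continues uncorrected; the parallel planned-position restart lets the
    tracker recover when the target jumps outside the local search region.
    """
    if len(images) != len(templates):
        raise RegistrationError("one template per image required")
    results: List[RegistrationResult] = []
    prev = np.asarray(planned_shift, dtype=float)
    for n, (img, tmpl) in enumerate(zip(images, templates)):
        region = config.initial_region_mm if n == 0 else config.subsequent_region_mm
        res = register(
            img, tmpl, prev_shift=prev, planned_shift=planned_shift,
            config=config, pitch_mm=pitch_mm, region_mm=region,
        )
        if np.isfinite(res.cost):
            prev = np.asarray(res.shift_mm)
        results.append(res)
    return results
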