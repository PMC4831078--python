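"""MV frame cleanup: irradiated-region detection and band-artifact removal.

Portal frames acquired during arc delivery show horizontal intensity bands
caused by asynchrony between the detector readout and the accelerator beam
pulses.  Because each band scales a whole detector row uniformly within the
irradiated region, correction is a per-row gain: every irradiated pixel in
row r is multiplied by ``I_ave,max / I_ave,r``, where ``I_ave,r`` is the
mean of the irradiated pixels in that row and ``I_ave,max`` the maximum
such row mean in the frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["PreprocessError", "NoApertureError", "ApertureMask", "detect_irradiated", "remove_bands"]


class PreprocessError(ValueError):
    pass


class NoApertureError(PreprocessError):
    """Frame carries no detectable irradiated region."""


@dataclass(frozen=True)
class ApertureMask:
    """Boolean per-pixel mask of irradiated (MLC-exposed) pixels."""

    mask: np.ndarray
    provenance: str  # "thresholded" | "supplied"

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))
        if not self.mask.any():
            raise NoApertureError("aperture mask has no irradiated pixels")


def detect_irradiated(frame: np.ndarray, method: str = "otsu", percentile: float = 50.0) -> ApertureMask:
    """Identify irradiated pixels by thresholding the intensity histogram.

    Default rule is Otsu's criterion (the bright mode is the MLC-exposed
    region, the dark mode the blocked region); ``method="percentile"`` uses
    a fixed percentile cut instead.  A constant frame raises
    :class:`NoApertureError`.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) < 1e-12:
        raise NoApertureError("constant frame: no intensity spread to threshold")
    if method == "otsu":
        thr = threshold_otsu(frame)
    elif method == "percentile":
        thr = np.percentile(frame, percentile)
    else:
        raise PreprocessError(f"unknown threshold method {method!r}")
    mask = frame > thr
    if not mask.any():
        raise NoApertureError("thresholding yielded an empty irradiated region")
    return ApertureMask(mask=mask, provenance="thresholded")


def remove_bands(
    frame: np.ndarray,
    mask: "ApertureMask | np.ndarray",
    min_row_pixels: int = 5,
    max_gain: float = 5.0,
) -> np.ndarray:
    """Equalise row means over the irradiated region (band removal).

    Each row with at least ``min_row_pixels`` irradiated pixels is scaled so
    its irradiated-pixel mean equals the frame's maximum row mean; sparse
    rows and non-irradiated pixels are left untouched.  Gains are clamped to
    ``max_gain`` so a near-empty noisy row cannot be amplified into an
    artifact.  Idempotent on its own output.
    """
    frame = np.asarray(frame, dtype=float)
    m = mask.mask if isinstance(mask, ApertureMask) else np.asarray(mask, dtype=bool)
    if m.shape != frame.shape:
        raise PreprocessError("mask shape does not match frame")
    if not m.any():
        raise NoApertureError("empty aperture mask")

    counts = m.sum(axis=1)
    sums = np.where(m, frame, 0.0).sum(axis=1)
    valid = counts >= max(min_row_pixels, 1)
    if not valid.any():
        raise NoApertureError(f"no row has >= {min_row_pixels} irradiated pixels")
    row_means = np.full(frame.shape[0], np.nan)
    row_means[valid] = sums[valid] / counts[valid]
    i_max = np.nanmax(row_means)

    gains = np.ones(frame.shape[0])
    ok = valid & (row_means > 0)
    gains[ok] = np.minimum(i_max / row_means[ok], max_gain)

    out = frame.copy()
    scaled = frame * gains[:, None]
    out[m] = scaled[m]
    return out
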