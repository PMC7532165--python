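"""FFT focus measure and autofocus.

The sharpness score of a frame is computed from the log-magnitude of the
DFT of its central crop, ``log(1 + sqrt(Re^2 + Im^2))``, binned into a
polar (radius x angle) grid; the score is the sum over radial bins of
the angular mean of the log-magnitude, restricted to radii between 6 and
1600 of the centred spectrum.  Excluding the lowest radii makes the score
exactly invariant to overall intensity offsets (the image mean is removed
before the transform, so only the masked DC bin could differ), and
capping the high radii discards frequencies dominated by noise.

Autofocus is a coarse scan over the search range followed by
golden-section refinement around the best interior point; montage focus
averages accepted measurements at the ROI centroid plus satellite points,
which rides out local voids (blood vessels) and sample height gradients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AutofocusError, MontageFocusError
from .geometry import Rect, StageROI

log = logging.getLogger(__name__)

__all__ = [
    "FocusSpectrum",
    "FocusSearch",
    "FocusResult",
    "SatellitePoint",
    "focus_score",
    "autofocus",
    "multi_point_focus",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class FocusSpectrum:
    """Masked log-magnitude spectrum of a frame's centre crop."""

    log_magnitude: np.ndarray
    r_min: int
    r_max: int


def _center_crop_pow2(image: np.ndarray, max_px: int = 2048) -> np.ndarray:
    h, w = image.shape
    side = min(max_px, 2 ** int(math.floor(math.log2(min(h, w)))))
    if side < min(h, w) and side < max_px:
        log.debug("focus crop reduced to %d px (input %dx%d)", side, h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return image[r0 : r0 + side, c0 : c0 + side]


def compute_focus_spectrum(
    image: np.ndarray, r_min: int = 6, r_max: int = 1600
) -> FocusSpectrum:
    crop = _center_crop_pow2(np.asarray(image)).astype(np.float64)
    crop = crop - crop.mean()
    spec = np.fft.fftshift(np.fft.fft2(crop))
    return FocusSpectrum(log_magnitude=np.log1p(np.abs(spec)), r_min=r_min, r_max=r_max)


def focus_score(
    image: np.ndarray, r_min: int = 6, r_max: int = 1600, n_theta: int = 720
) -> float:
    """Scalar sharpness score of ``image`` (see module docstring).

    The polar transform bins Cartesian frequency samples into integer
    radii and ``n_theta`` angular cells by nearest assignment; empty
    cells are ignored in the angular mean.
    """
    fs = compute_focus_spectrum(image, r_min=r_min, r_max=r_max)
    lm = fs.log_magnitude
    n = lm.shape[0]
    center = n // 2  # fftshift places DC here
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.rint(np.hypot(yy - center, xx - center)).astype(np.int64)
    r_cap = min(r_max, int(r.max()))
    sel = (r >= r_min) & (r <= r_cap)
    theta = np.arctan2(yy - center, xx - center)
    tbin = np.minimum((theta[sel] + np.pi) / (2 * np.pi) * n_theta, n_theta - 1).astype(
        np.int64
    )
    idx = (r[sel] - r_min) * n_theta + tbin
    n_r = r_cap - r_min + 1
    sums = np.bincount(idx, weights=lm[sel], minlength=n_r * n_theta)
    counts = np.bincount(idx, minlength=n_r * n_theta)
    sums = sums.reshape(n_r, n_theta)
    counts = counts.reshape(n_r, n_theta)
    with np.errstate(invalid="ignore"):
        cell_mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    row_mean = np.nanmean(cell_mean, axis=1)
    return float(np.nansum(row_mean))


# ---------------------------------------------------------------------------
# Autofocus search
# ---------------------------------------------------------------------------


@dataclass
class FocusSearch:
    """Autofocus search parameters: scan range (lens units), coarse step
    (default range/12), golden-section tolerance as a fraction of the
    range, and the minimum relative score contrast below which the curve
    is declared peakless."""

    range: tuple[float, float] = (0.0, 24.0)
    coarse_step: float | None = None
    refine_frac: float = 0.01
    min_contrast: float = 0.05
    n_avg: int = 2  # frames averaged per score evaluation (shot-noise control)

    @property
    def span(self) -> float:
        return self.range[1] - self.range[0]

    @property
    def step(self) -> float:
        return self.coarse_step if self.coarse_step is not None else self.span / 12.0


def _score_at(scope, f: float, correction_set=None, n_avg: int = 1) -> float:
    acc = None
    for _ in range(max(1, n_avg)):
        raw = scope.render_frame(beam_on=True, focus_value=f)
        img = raw.pixels
        if correction_set is not None:
            from .calibration import correct_frame

            img = correct_frame(raw, correction_set)
        acc = img.astype(np.float64) if acc is None else acc + img
    return focus_score(acc / max(1, n_avg))


def autofocus(
    scope,
    position_um: tuple[float, float] | None = None,
    search: FocusSearch | None = None,
    correction_set=None,
) -> tuple[float, float]:
    """Find the focus value maximizing the FFT score at a stage position.

    Coarse scan over the range, then golden-section refinement around the
    best coarse point.  Raises :class:`AutofocusError` with reason
    ``"boundary"`` if the best coarse score sits on a range boundary and
    ``"no_peak"`` if the score curve is too flat to carry a maximum (as
    over a blood-vessel void)."""
    search = search or FocusSearch()
    if position_um is not None:
        scope.move_stage(position_um)
    lo, hi = search.range
    if hi <= lo:
        raise ValueError("search range must be increasing")
    n = max(3, int(math.ceil(search.span / search.step)) + 1)
    fs = np.linspace(lo, hi, n)
    scores = np.array([_score_at(scope, f, correction_set, search.n_avg) for f in fs])

    smax, smin = float(scores.max()), float(scores.min())
    if smax <= 0 or (smax - smin) < search.min_contrast * smax:
        raise AutofocusError("no_peak", "focus score curve has no usable peak")
    best = int(np.argmax(scores))
    if best == 0 or best == n - 1:
        raise AutofocusError("boundary", "best focus at search-range boundary")

    # golden-section maximization in the bracket around the best point
    a, b = fs[best - 1], fs[best + 1]
    tol = search.refine_frac * search.span
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = _score_at(scope, c, correction_set, search.n_avg)
    fd = _score_at(scope, d, correction_set, search.n_avg)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = _score_at(scope, c, correction_set, search.n_avg)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = _score_at(scope, d, correction_set, search.n_avg)
    f_best = (a + b) / 2.0
    return float(f_best), float(max(fc, fd))


# ---------------------------------------------------------------------------
# Multi-point (satellite) montage focus
# ---------------------------------------------------------------------------


@dataclass
class SatellitePoint:
    position_um: tuple[float, float]
    focus_value: float | None
    score: float | None
    accepted: bool
    reason: str = ""


@dataclass
class FocusResult:
    """Montage focus: mean of the accepted measurement points."""

    focus_value: float
    score: float
    satellite_scores: list[SatellitePoint] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return sum(1 for p in self.satellite_scores if p.accepted)


def _satellite_positions(roi, n_satellites: int) -> list[tuple[float, float]]:
    rect: Rect = roi.bounding_rect if isinstance(roi, StageROI) else roi
    cx, cy = rect.cx, rect.cy
    corners = [(rect.x, rect.y), (rect.x1, rect.y), (rect.x1, rect.y1), (rect.x, rect.y1)]
    mids = [((cx + px) / 2.0, (cy + py) / 2.0) for px, py in corners]
    return [(cx, cy)] + mids[: max(0, n_satellites)]


def multi_point_focus(
    scope,
    roi,
    n_satellites: int = 4,
    search: FocusSearch | None = None,
    correction_set=None,
) -> FocusResult:
    """Autofocus at the ROI centroid plus up to four satellite points at
    the midpoints of the centroid-to-corner segments; failed or boundary
    points are rejected and the montage focus is the mean of the accepted
    focus values."""
    search = search or FocusSearch()
    points = _satellite_positions(roi, n_satellites)
    records: list[SatellitePoint] = []
    for pos in points:
        try:
            f, s = autofocus(scope, position_um=pos, search=search, correction_set=correction_set)
            records.append(SatellitePoint(pos, f, s, accepted=True))
        except AutofocusError as exc:
            log.info("focus point %s rejected: %s", pos, exc.reason)
            records.append(SatellitePoint(pos, None, None, accepted=False, reason=exc.reason))
    accepted = [p for p in records if p.accepted]
    if not accepted:
        raise MontageFocusError("all focus measurement points were rejected")
    focus = float(np.mean([p.focus_value for p in accepted]))
    score = float(np.mean([p.score for p in accepted]))
    return FocusResult(focus_value=focus, score=score, satellite_scores=records)
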