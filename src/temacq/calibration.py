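"""Flat-field correction and camera calibration.

The per-montage correction is the classic flat-field ratio

    corrected = (image - darkfield) / (brightfield - darkfield)

computed in floating point and mapped to 8 bpp with a configurable gain.
The darkfield is the pixel-wise mean of 16 beam-off frames; the
brightfield is the mean of 16 frames integrated while the stage wanders
randomly within a 300 µm radius (washing tissue structure out of the
illumination estimate), scaled to unit mean.

Pixel size and beam rotation are calibrated by normalized cross
correlation: templates on a centred 3 x 3 grid are tracked across frames
taken before and after known stage displacements.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.feature import match_template

from .errors import BeamCenteringError, CalibrationError, InvalidCorrectionError
from .geometry import normalize_angle_deg

log = logging.getLogger(__name__)

__all__ = [
    "CorrectionSet",
    "PixelCalibration",
    "BeamGeometry",
    "acquire_darkfield",
    "acquire_brightfield",
    "build_correction_set",
    "correct_frame",
    "calibrate_pixel_size",
    "measure_beam_rotation",
    "center_beam",
]


@dataclass
class CorrectionSet:
    """Darkfield/brightfield pair plus the 8-bit conversion gain."""

    darkfield: np.ndarray
    brightfield: np.ndarray
    acquired_at_ms: float
    gain_8bpp: float = 180.0

    def validate(self) -> None:
        if self.darkfield.shape != self.brightfield.shape:
            raise InvalidCorrectionError("darkfield/brightfield shape mismatch")
        denom = self.brightfield - self.darkfield
        if not np.all(denom > 0):
            raise InvalidCorrectionError(
                "brightfield - darkfield must be positive at every pixel"
            )

    def is_stale(self, clock_ms: float, max_age_ms: float) -> bool:
        return (clock_ms - self.acquired_at_ms) > max_age_ms

    def save(self, path: Path) -> None:
        """Persist as a 2-image TIFF pair plus a JSON sidecar."""
        import tifffile

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path / "darkfield.tif", self.darkfield.astype(np.float32))
        tifffile.imwrite(path / "brightfield.tif", self.brightfield.astype(np.float32))
        (path / "correction.json").write_text(
            json.dumps({"acquired_at_ms": self.acquired_at_ms, "gain_8bpp": self.gain_8bpp})
        )

    @classmethod
    def load(cls, path: Path) -> "CorrectionSet":
        import tifffile

        path = Path(path)
        meta = json.loads((path / "correction.json").read_text())
        return cls(
            darkfield=tifffile.imread(path / "darkfield.tif"),
            brightfield=tifffile.imread(path / "brightfield.tif"),
            acquired_at_ms=meta["acquired_at_ms"],
            gain_8bpp=meta["gain_8bpp"],
        )


@dataclass(frozen=True)
class PixelCalibration:
    """Measured pixel size with the per-axis template-vector scatter."""

    nm_per_px_x: float
    nm_per_px_y: float
    sd_x_px: float
    sd_y_px: float
    n_templates: int


@dataclass
class BeamGeometry:
    rotation_deg: float = 0.0
    beam_center_offset_px: tuple[float, float] = (0.0, 0.0)


# ---------------------------------------------------------------------------
# Dark / bright field acquisition
# ---------------------------------------------------------------------------


def acquire_darkfield(scope, n_frames: int = 16) -> np.ndarray:
    """Pixel-wise mean of ``n_frames`` beam-off frames."""
    acc = np.zeros((scope.frame_px, scope.frame_px), dtype=np.float64)
    for _ in range(n_frames):
        acc += scope.render_frame(beam_on=False).pixels.astype(np.float64)
    return acc / n_frames


def acquire_brightfield(
    scope,
    radius_um: float = 300.0,
    n_frames: int = 16,
    steps_per_frame: int = 6,
) -> np.ndarray:
    """Brightfield: mean of ``n_frames`` frames, each integrated while the
    stage wanders randomly within ``radius_um`` of the start, then scaled
    to unit mean.  The start position is restored afterwards."""
    start = scope.stage.position
    bounds = scope.stage.bounds
    acc = np.zeros((scope.frame_px, scope.frame_px), dtype=np.float64)
    for _ in range(n_frames):
        integ = np.zeros_like(acc)
        for _ in range(steps_per_frame):
            r = radius_um * math.sqrt(scope.rng.random())
            th = scope.rng.random() * 2.0 * math.pi
            tx = start[0] + r * math.cos(th)
            ty = start[1] + r * math.sin(th)
            cx = min(max(tx, bounds.x), np.nextafter(bounds.x1, -np.inf))
            cy = min(max(ty, bounds.y), np.nextafter(bounds.y1, -np.inf))
            if (cx, cy) != (tx, ty):
                log.warning("brightfield walk clipped to stage bounds")
            scope.move_stage((cx, cy))
            integ += scope.render_frame(beam_on=True).pixels.astype(np.float64)
        acc += integ / steps_per_frame
    scope.move_stage(start)
    bf = acc / n_frames
    return bf / bf.mean()


def build_correction_set(
    scope, gain_8bpp: float = 180.0, radius_um: float = 300.0, darkfield=None
) -> CorrectionSet:
    """Acquire (or reuse) a darkfield, acquire a fresh brightfield, and
    assemble a validated correction set.

    The brightfield here is stored in the same DN scale as raw frames
    (unit-mean shape times the mean signal level) so the Eq-ratio keeps
    its physical meaning of relative transmittance."""
    dark = acquire_darkfield(scope) if darkfield is None else darkfield
    shape = acquire_brightfield(scope, radius_um=radius_um)
    # rescale the unit-mean shape back to DN above dark
    probe = scope.render_frame(beam_on=True).pixels.astype(np.float64)
    level = max(probe.mean() - dark.mean(), 1.0)
    cset = CorrectionSet(
        darkfield=dark,
        brightfield=dark + shape * level,
        acquired_at_ms=scope.clock_ms,
        gain_8bpp=gain_8bpp,
    )
    cset.validate()
    return cset


def correct_frame(raw, correction_set: CorrectionSet) -> np.ndarray:
    """Flat-field correct a raw frame and convert to 8 bpp:
    ``clip(round(((raw - dark)/(bright - dark)) * gain), 0, 255)``."""
    correction_set.validate()
    img = raw.pixels if hasattr(raw, "pixels") else raw
    ratio = (np.asarray(img, dtype=np.float64) - correction_set.darkfield) / (
        correction_set.brightfield - correction_set.darkfield
    )
    return np.clip(np.round(ratio * correction_set.gain_8bpp), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Template displacement measurement
# ---------------------------------------------------------------------------


def _subpixel_peak(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Parabolic refinement of a correlation peak, per axis."""
    r, c = peak
    out = [float(r), float(c)]
    for axis, idx in ((0, r), (1, c)):
        if 0 < idx < corr.shape[axis] - 1:
            if axis == 0:
                y0, y1, y2 = corr[idx - 1, c], corr[idx, c], corr[idx + 1, c]
            else:
                y0, y1, y2 = corr[r, idx - 1], corr[r, idx], corr[r, idx + 1]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                out[axis] = idx + 0.5 * (y0 - y2) / denom
    return out[0], out[1]


def _find_template(
    frame: np.ndarray,
    template: np.ndarray,
    expected_tl: tuple[float, float],
    window_px: float,
) -> tuple[float, float, float] | None:
    """NCC-match ``template`` near ``expected_tl`` (top-left, row/col).

    Returns (row, col, ncc_peak) of the matched top-left position, or None
    if the window falls outside the frame or the match is degenerate."""
    th, tw = template.shape
    if template.std() == 0:
        return None
    r0 = int(math.floor(expected_tl[0] - window_px))
    c0 = int(math.floor(expected_tl[1] - window_px))
    r1 = int(math.ceil(expected_tl[0] + th + window_px))
    c1 = int(math.ceil(expected_tl[1] + tw + window_px))
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, frame.shape[0]), min(c1, frame.shape[1])
    if r1 - r0 < th or c1 - c0 < tw:
        return None
    region = frame[r0:r1, c0:c1]
    if region.std() == 0:
        return None
    corr = match_template(region.astype(np.float64), template.astype(np.float64))
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    ncc = float(corr[peak])
    pr, pc = _subpixel_peak(corr, peak)
    return (r0 + pr, c0 + pc, ncc)


def _grid_template_positions(frame_px: int, template_px: int) -> list[tuple[int, int]]:
    """Top-left corners of a centred 3x3 template grid with quarter-frame
    spacing."""
    centers = [frame_px / 2 - frame_px / 4, frame_px / 2, frame_px / 2 + frame_px / 4]
    return [
        (int(round(rc - template_px / 2)), int(round(cc - template_px / 2)))
        for rc in centers
        for cc in centers
    ]


def calibrate_pixel_size(
    scope,
    step_um: float,
    template_px: int = 128,
    correction_set: CorrectionSet | None = None,
    ncc_min: float = 0.5,
) -> PixelCalibration:
    """Measure nm/px per axis from known stage displacements.

    A reference frame is taken; the stage is then moved by ±``step_um``
    on each axis and the displacement of each template on a centred 3 x 3
    grid is measured by NCC (each template is used under whichever move
    sign keeps it inside the frame).  Returns per-axis
    ``nm/px = 1000 * step_um / mean(px displacement)`` and the sd of the
    per-template displacement vectors."""
    if step_um <= 0:
        raise ValueError("step_um must be positive")

    def grab() -> np.ndarray:
        raw = scope.render_frame(beam_on=True)
        if correction_set is not None:
            return correct_frame(raw, correction_set).astype(np.float64)
        return raw.pixels.astype(np.float64)

    start = scope.stage.position
    ref = grab()
    positions = _grid_template_positions(scope.frame_px, template_px)
    templates = [
        ref[r : r + template_px, c : c + template_px].copy() for r, c in positions
    ]

    # approximate displacement from the nominal pixel size; the NCC search
    # window is opened +-25% around it
    approx_px = step_um * 1000.0 / scope.nm_per_px
    window = 0.25 * approx_px + 32

    results: dict[int, dict[int, np.ndarray]] = {0: {}, 1: {}}  # axis -> tpl -> vec
    for axis in (0, 1):
        for sign in (+1.0, -1.0):
            target = list(start)
            target[axis] += sign * step_um
            scope.move_stage(tuple(target))
            moved = grab()
            scope.move_stage(start)
            # content displacement: stage +x shifts content -col, stage +y
            # shifts content +row (stage y is up, image row is down)
            exp_dcol = -sign * approx_px if axis == 0 else 0.0
            exp_drow = +sign * approx_px if axis == 1 else 0.0
            N = scope.frame_px
            for ti, ((r, c), tpl) in enumerate(zip(positions, templates)):
                if ti in results[axis]:
                    continue
                er, ec = r + exp_drow, c + exp_dcol
                # the template content must remain in view under this move
                # sign; otherwise measure it under the opposite sign
                if not (0 <= er and er + template_px <= N and 0 <= ec and ec + template_px <= N):
                    continue
                hit = _find_template(moved, tpl, (er, ec), window)
                if hit is None or hit[2] < ncc_min:
                    continue
                drow, dcol = hit[0] - r, hit[1] - c
                # normalize to the +step sense
                results[axis][ti] = np.array([dcol, drow]) * sign
    for axis in (0, 1):
        missing = [ti for ti in range(9) if ti not in results[axis]]
        if missing:
            raise CalibrationError(
                f"axis {'xy'[axis]}: template(s) {missing} failed to match"
            )

    vx = np.array([results[0][ti] for ti in range(9)])  # (dcol, drow) per template
    vy = np.array([results[1][ti] for ti in range(9)])
    mean_dx = float(np.abs(vx[:, 0]).mean())
    mean_dy = float(np.abs(vy[:, 1]).mean())
    return PixelCalibration(
        nm_per_px_x=1000.0 * step_um / mean_dx,
        nm_per_px_y=1000.0 * step_um / mean_dy,
        sd_x_px=float(vx[:, 0].std(ddof=0)),
        sd_y_px=float(vy[:, 1].std(ddof=0)),
        n_templates=9,
    )


def measure_beam_rotation(
    scope,
    step_um: float,
    template_px: int = 128,
    correction_set: CorrectionSet | None = None,
    ncc_min: float = 0.5,
) -> float:
    """Angle between a commanded +x stage move and the measured image
    displacement, normalized to (-180, 180] degrees."""
    if step_um <= 0:
        raise ValueError("step_um must be positive")

    def grab() -> np.ndarray:
        raw = scope.render_frame(beam_on=True)
        if correction_set is not None:
            return correct_frame(raw, correction_set).astype(np.float64)
        return raw.pixels.astype(np.float64)

    start = scope.stage.position
    ref = grab()
    approx_px = step_um * 1000.0 / scope.nm_per_px
    window = 0.35 * approx_px + 32
    positions = _grid_template_positions(scope.frame_px, template_px)
    templates = [ref[r : r + template_px, c : c + template_px] for r, c in positions]

    vecs = []
    for sign in (+1.0, -1.0):
        scope.move_stage((start[0] + sign * step_um, start[1]))
        moved = grab()
        scope.move_stage(start)
        for (r, c), tpl in zip(positions, templates):
            er, ec = r, c - sign * approx_px
            if not (
                0 <= ec and ec + template_px <= scope.frame_px and 0 <= er
                and er + template_px <= scope.frame_px
            ):
                continue
            hit = _find_template(moved, tpl, (er, ec), window)
            if hit is not None and hit[2] >= ncc_min:
                # measured stage-equivalent displacement: content shift is
                # the negative of the stage move in image axes
                m_col = -(hit[1] - c) * sign
                m_row = -(hit[0] - r) * sign
                vecs.append((m_col, m_row))
    if not vecs:
        raise CalibrationError("no template matched for beam-rotation measurement")
    v = np.mean(np.array(vecs), axis=0)
    # image rows grow downward, so atan2(row, col) measures the rotation of
    # the camera axes relative to the stage axes directly
    return normalize_angle_deg(math.degrees(math.atan2(v[1], v[0])))


# ---------------------------------------------------------------------------
# Beam centering
# ---------------------------------------------------------------------------


def center_beam(
    scope,
    threshold_frac: float = 0.02,
    max_retries: int = 4,
    gain: float = 1.8,
) -> tuple[float, float]:
    """Measure the intensity-weighted centroid of an open-beam frame
    relative to the frame centre and command the beam-shift correction
    until the residual offset is below ``threshold_frac`` of the frame.

    Raises :class:`BeamCenteringError` if the offset is not reduced below
    threshold within ``max_retries`` corrections."""
    N = scope.frame_px
    thresh = threshold_frac * N

    def measure() -> np.ndarray:
        frame = scope.render_frame(beam_on=True).pixels.astype(np.float64)
        w = frame - frame.min()
        total = w.sum()
        if total <= 0:
            raise BeamCenteringError("open-beam frame carries no intensity")
        yy, xx = np.mgrid[0:N, 0:N]
        cx = (w * xx).sum() / total - (N - 1) / 2.0
        cy = (w * yy).sum() / total - (N - 1) / 2.0
        return np.array([cx, cy])

    offset = measure()
    initial = float(np.hypot(*offset))
    for _ in range(max_retries):
        if np.hypot(*offset) <= thresh:
            return (float(offset[0]), float(offset[1]))
        scope.beam.shift_px = (
            scope.beam.shift_px[0] - gain * offset[0],
            scope.beam.shift_px[1] - gain * offset[1],
        )
        offset = measure()
    if np.hypot(*offset) <= thresh:
        return (float(offset[0]), float(offset[1]))
    if np.hypot(*offset) >= initial:
        raise BeamCenteringError(
            f"beam offset not reduced ({initial:.1f} -> {np.hypot(*offset):.1f} px)"
        )
    raise BeamCenteringError(
        f"beam offset {np.hypot(*offset):.1f} px still above threshold {thresh:.1f} px"
    )
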