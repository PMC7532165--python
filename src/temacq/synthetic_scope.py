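"""Seeded virtual transmission electron microscope.

Renders 16-bit camera frames from procedural ground-truth sections and
emulates the stage (move error, settle time), the beam (illumination
gradient, dark offsets, defocus blur, drift), and a barcoded tape of
sections with matching optical overview frames.  Every output is a pure
function of (seed, parameters), so the downstream calibration, focus, QC
and workflow algorithms can be exercised closed-loop and bit-reproducibly
without hardware.

The ground truth is a transmittance field in [0, 1] sampled at a fixed
base resolution (4 nm per sample by default); rendering at another pixel
size uses bilinear resampling.  Outside the aperture the tape is opaque
(transmittance 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import ndimage

from .errors import BarcodeNotFoundError, StageBoundsError
from .geometry import Rect

log = logging.getLogger(__name__)

__all__ = [
    "SectionParams",
    "TapeParams",
    "GroundTruthSection",
    "OpticalTapeFrame",
    "StageModel",
    "BeamModel",
    "RawFrame",
    "VirtualScope",
    "generate_section",
    "generate_tape",
    "encode_barcode_strip",
    "decode_barcode",
]

BASE_TRUTH_NM = 4.0

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


class SectionParams(BaseModel):
    """Parameters of one procedural ground-truth section.

    Densities are per 100 µm² of tissue; the texture band-pass is given as
    (low, high) feature wavelengths in nm, emulating membrane-scale
    contrast in a 40 nm ultrathin section.
    """

    aperture_um: tuple[float, float] = (20.0, 15.0)
    truth_nm: float = Field(default=BASE_TRUTH_NM, gt=0.5, le=64.0)
    substrate_level: float = Field(default=0.85, gt=0.0, le=1.0)
    # support-film granularity: weak texture outside the tissue, which is
    # what lets edge matching succeed on tissue-free substrate
    substrate_texture: float = Field(default=0.03, ge=0.0, le=0.2)
    tissue_level: float = Field(default=0.50, gt=0.0, lt=1.0)
    tissue_contrast: float = Field(default=0.22, ge=0.0, le=0.5)
    texture_band_nm: tuple[float, float] = (30.0, 200.0)
    soma_density_per_100um2: float = Field(default=1.0, ge=0.0)
    vessel_density_per_100um2: float = Field(default=0.8, ge=0.0)
    soma_radius_um: tuple[float, float] = (1.0, 2.0)
    vessel_radius_um: tuple[float, float] = (0.6, 1.4)
    tissue_fraction: float = Field(default=0.7, gt=0.0, le=1.0)
    has_tissue: bool = True
    aperture_offset_um: Optional[tuple[float, float]] = None
    focus_f0: float = 12.0
    focus_gradient: tuple[float, float] = (0.0, 0.0)

    @field_validator("aperture_um")
    @classmethod
    def _aperture_positive(cls, v):
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("aperture size must be positive")
        return v

    @field_validator("texture_band_nm", "soma_radius_um", "vessel_radius_um")
    @classmethod
    def _band_ordered(cls, v):
        if v[0] <= 0 or v[1] <= v[0]:
            raise ValueError("range must be positive and increasing")
        return v

    @model_validator(mode="after")
    def _grid_tractable(self):
        npx = self.aperture_um[0] * 1000.0 / self.truth_nm
        npy = self.aperture_um[1] * 1000.0 / self.truth_nm
        if npx * npy > 2**26:
            raise ValueError(
                "ground-truth grid exceeds 64 Msample; reduce the aperture or "
                "coarsen truth_nm"
            )
        return self


class TapeParams(BaseModel):
    """Parameters of a synthetic tape of barcoded sections."""

    section: SectionParams = SectionParams()
    start_barcode: int = Field(default=1, ge=0, lt=2**16)
    no_tissue_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    specimen_id: str = "specimen-001"
    media_id: str = "tape-001"
    optical_px_per_aperture: int = Field(default=200, ge=60)
    focus_f0_jitter: float = Field(default=0.0, ge=0.0)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthSection:
    """One virtual tape section: a transmittance field plus truth metadata."""

    section_id: int
    barcode: int
    truth_image: np.ndarray  # float32 in [0, 1], row 0 at the top (max y)
    tissue_mask: np.ndarray  # bool, same shape
    aperture_rect: Rect  # stage um
    optimal_focus_plane: tuple[float, float, float]  # (f0, gx, gy) per um
    truth_nm: float = BASE_TRUTH_NM

    @property
    def truth_um_per_sample(self) -> float:
        return self.truth_nm / 1000.0

    def f_opt(self, x_um: float, y_um: float) -> float:
        f0, gx, gy = self.optimal_focus_plane
        return f0 + gx * x_um + gy * y_um

    def stage_to_truth(self, x_um, y_um):
        """Map stage coordinates to fractional (row, col) truth indices."""
        s = self.truth_um_per_sample
        col = (np.asarray(x_um) - self.aperture_rect.x) / s
        row = (self.aperture_rect.y1 - np.asarray(y_um)) / s
        return row, col

    def tissue_centroid_um(self) -> Optional[tuple[float, float]]:
        if not self.tissue_mask.any():
            return None
        rows, cols = np.nonzero(self.tissue_mask)
        s = self.truth_um_per_sample
        x = self.aperture_rect.x + (cols.mean() + 0.5) * s
        y = self.aperture_rect.y1 - (rows.mean() + 0.5) * s
        return (float(x), float(y))


def _bandpass_texture(rng: np.random.Generator, shape, lo_px: float, hi_px: float):
    noise = rng.standard_normal(shape).astype(np.float32)
    fine = ndimage.gaussian_filter(noise, lo_px)
    coarse = ndimage.gaussian_filter(noise, hi_px)
    tex = fine - coarse
    sd = tex.std()
    if sd > 0:
        tex /= sd
    return np.clip(tex, -2.5, 2.5)


def generate_section(seed: int, params: SectionParams | None = None) -> GroundTruthSection:
    """Generate one ground-truth section (deterministic in ``seed``).

    The tissue is an elliptical patch of band-passed texture with darker
    somata; vessels are low-texture bright voids punched out of the tissue
    mask, mimicking the flat regions that defeat single-point autofocus.
    """
    params = params or SectionParams()
    rng = np.random.default_rng(seed)
    s_um = params.truth_nm / 1000.0
    w_px = int(round(params.aperture_um[0] / s_um))
    h_px = int(round(params.aperture_um[1] / s_um))

    truth = np.full((h_px, w_px), params.substrate_level, dtype=np.float32)
    if params.substrate_texture > 0:
        lo_px = max(0.6, params.texture_band_nm[0] / params.truth_nm / 2.0)
        hi_px = max(lo_px + 0.5, params.texture_band_nm[1] / params.truth_nm / 2.0)
        grain = _bandpass_texture(rng, truth.shape, lo_px, hi_px)
        truth += params.substrate_texture * 0.5 * grain
    tissue_mask = np.zeros((h_px, w_px), dtype=bool)

    if params.has_tissue:
        yy, xx = np.mgrid[0:h_px, 0:w_px].astype(np.float32)
        jx = rng.uniform(-0.05, 0.05) * w_px
        jy = rng.uniform(-0.05, 0.05) * h_px
        cx, cy = w_px / 2.0 + jx, h_px / 2.0 + jy
        ax = params.tissue_fraction * w_px / 2.0
        ay = params.tissue_fraction * h_px / 2.0
        ellipse = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        tissue_mask |= ellipse

        lo_px = max(0.6, params.texture_band_nm[0] / params.truth_nm / 2.0)
        hi_px = max(lo_px + 0.5, params.texture_band_nm[1] / params.truth_nm / 2.0)
        tex = _bandpass_texture(rng, truth.shape, lo_px, hi_px)
        truth[ellipse] = params.tissue_level + 0.5 * params.tissue_contrast * tex[ellipse]

        tissue_area_100um2 = ellipse.sum() * s_um * s_um / 100.0

        n_somata = rng.poisson(params.soma_density_per_100um2 * tissue_area_100um2)
        for _ in range(n_somata):
            r_um = rng.uniform(*params.soma_radius_um)
            sx = rng.uniform(cx - ax, cx + ax)
            sy = rng.uniform(cy - ay, cy + ay)
            r_px = r_um / s_um
            disk = (xx - sx) ** 2 + (yy - sy) ** 2 <= r_px**2
            disk &= ellipse
            truth[disk] = (
                params.tissue_level - 0.18 + 0.4 * params.tissue_contrast * tex[disk]
            )

        n_vessels = rng.poisson(params.vessel_density_per_100um2 * tissue_area_100um2)
        for _ in range(n_vessels):
            r_um = rng.uniform(*params.vessel_radius_um)
            vx = rng.uniform(cx - 0.8 * ax, cx + 0.8 * ax)
            vy = rng.uniform(cy - 0.8 * ay, cy + 0.8 * ay)
            r_px = r_um / s_um
            disk = (xx - vx) ** 2 + (yy - vy) ** 2 <= r_px**2
            truth[disk & ellipse] = min(1.0, params.substrate_level + 0.05)
            tissue_mask &= ~disk

    np.clip(truth, 0.0, 1.0, out=truth)

    if params.aperture_offset_um is not None:
        ox, oy = params.aperture_offset_um
    else:
        ox = rng.uniform(-0.1, 0.1) * params.aperture_um[0]
        oy = rng.uniform(-0.1, 0.1) * params.aperture_um[1]
    rect = Rect(
        ox - params.aperture_um[0] / 2.0,
        oy - params.aperture_um[1] / 2.0,
        params.aperture_um[0],
        params.aperture_um[1],
    )

    return GroundTruthSection(
        section_id=seed,
        barcode=-1,
        truth_image=truth,
        tissue_mask=tissue_mask,
        aperture_rect=rect,
        optimal_focus_plane=(params.focus_f0, *params.focus_gradient),
        truth_nm=params.truth_nm,
    )


# ---------------------------------------------------------------------------
# Stage and beam models
# ---------------------------------------------------------------------------


@dataclass
class StageModel:
    """Two-axis stage with Gaussian per-move error (truncated at 4 sd) and a
    Gaussian settle-time draw per move (simulated-clock bookkeeping only)."""

    position: tuple[float, float] = (0.0, 0.0)
    per_move_error_sd: float = 0.05  # um per axis
    settle_time_model: tuple[float, float] = (120.0, 25.0)  # ms mean, sd
    bounds: Rect = field(default_factory=lambda: Rect(-1500.0, -1500.0, 3000.0, 3000.0))


@dataclass
class BeamModel:
    """Illumination, dark level, defocus blur and drift of the virtual beam.

    The illumination gain surface is a normalized (mean 1, strictly
    positive) radial dome ``(1 - falloff) + falloff * exp(-r^2 / 2 sigma^2)``
    centred at the frame centre plus ``shift_px`` plus clock-driven drift.
    """

    illum_falloff: float = 0.25
    illum_sigma_frac: float = 0.7
    shift_px: tuple[float, float] = (0.0, 0.0)
    drift_rate_px_per_min: tuple[float, float] = (0.0, 0.0)
    dark_level: float = 400.0  # DN
    dark_fpn_sd: float = 15.0  # per-pixel fixed-pattern offsets, DN
    read_noise_sd: float = 25.0  # DN
    signal_full: float = 40000.0  # DN at transmittance 1
    dn_per_e: float = 2.0  # conversion gain for shot noise
    defocus_blur_coeff: float = 0.8  # rendered px of Gaussian sigma per focus unit
    image_rotation_deg: float = 0.0  # camera axes vs stage axes
    shot_noise: bool = True
    read_noise: bool = True
    beam_on: bool = True
    fpn_seed: int = 1234
    _fpn_cache: dict = field(default_factory=dict, repr=False)

    def dark_pattern(self, size_px: int) -> np.ndarray:
        if size_px not in self._fpn_cache:
            rng = np.random.default_rng(self.fpn_seed + size_px)
            fpn = rng.normal(0.0, self.dark_fpn_sd, (size_px, size_px))
            self._fpn_cache[size_px] = (self.dark_level + fpn).astype(np.float32)
        return self._fpn_cache[size_px]

    def illumination_field(self, size_px: int, clock_ms: float = 0.0) -> np.ndarray:
        minutes = clock_ms / 60000.0
        cx = (size_px - 1) / 2.0 + self.shift_px[0] + self.drift_rate_px_per_min[0] * minutes
        cy = (size_px - 1) / 2.0 + self.shift_px[1] + self.drift_rate_px_per_min[1] * minutes
        yy, xx = np.mgrid[0:size_px, 0:size_px].astype(np.float32)
        sigma = self.illum_sigma_frac * size_px
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        g = (1.0 - self.illum_falloff) + self.illum_falloff * np.exp(-r2 / (2.0 * sigma**2))
        g /= g.mean()
        return g


@dataclass
class RawFrame:
    """A camera frame straight off the (virtual) sensor."""

    pixels: np.ndarray  # uint16 (or float32 when quantization is off)
    stage_xy: tuple[float, float]
    focus_value: float
    beam_on: bool
    clock_ms: float
    exposure_ms: float


# ---------------------------------------------------------------------------
# Optical tape frames
# ---------------------------------------------------------------------------

_BARCODE_BITS = 16
_MODULE_PX = 6
# layout in modules: [start 3][sep 1][16 bits Manchester = 32][parity Manchester = 2][sep 1][stop 3]
_DATA_MODULES = 2 * _BARCODE_BITS + 2
_SPAN_MODULES = _DATA_MODULES + 2  # between end of start and begin of stop markers


def encode_barcode_strip(
    value: int, module_px: int = _MODULE_PX, height_px: int = 24
) -> np.ndarray:
    """Render a barcode strip (float image in [0,1], white background).

    Encoding: a 3-module start bar, Manchester-coded 16 data bits (MSB
    first; 1 = dark/light, 0 = light/dark), one even-parity bit, and a
    3-module stop bar, separated by single light modules and flanked by
    light quiet zones.
    """
    if not (0 <= value < 2**_BARCODE_BITS):
        raise ValueError(f"barcode {value} out of 16-bit range")
    bits = [(value >> (15 - i)) & 1 for i in range(_BARCODE_BITS)]
    parity = sum(bits) % 2
    modules = [1, 1, 1, 0]
    for b in bits + [parity]:
        modules += [1, 0] if b else [0, 1]
    modules += [0, 1, 1, 1]
    modules = [0, 0] + modules + [0, 0]  # quiet zones
    row = np.repeat(np.array(modules, dtype=np.float32), module_px)
    strip = np.tile(1.0 - row, (height_px, 1))
    return strip


def decode_barcode(strip_image: np.ndarray) -> int:
    """Decode a barcode strip (grayscale or RGB) by thresholded run-length
    analysis; raises :class:`BarcodeNotFoundError` on missing markers,
    invalid Manchester pairs, or parity failure."""
    img = np.asarray(strip_image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    lo0, hi0 = img.min(), img.max()
    if hi0 - lo0 < 1e-6:
        raise BarcodeNotFoundError("blank barcode strip")
    # trim to the bright strip background so dark tape margins around the
    # strip do not masquerade as marker bars
    bright = (img - lo0) / (hi0 - lo0) > 0.6
    if not bright.any():
        raise BarcodeNotFoundError("barcode markers not found")
    rows = np.nonzero(bright.any(axis=1))[0]
    cols = np.nonzero(bright.any(axis=0))[0]
    img = img[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    profile = img.mean(axis=0)
    lo, hi = profile.min(), profile.max()
    if hi - lo < 1e-6:
        raise BarcodeNotFoundError("blank barcode strip")
    dark = (profile - lo) / (hi - lo) < 0.5

    # runs of dark pixels
    d = np.diff(dark.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if dark[0]:
        starts.insert(0, 0)
    if dark[-1]:
        ends.append(len(dark))
    runs = [(s, e) for s, e in zip(starts, ends)]
    if len(runs) < 2:
        raise BarcodeNotFoundError("barcode markers not found")

    # start/stop markers are the widest bars; expect ~3 modules each
    widths = [e - s for s, e in runs]
    mguess = max(widths) / 3.0
    marker_runs = [r for r, w in zip(runs, widths) if w > 2.2 * mguess]
    if len(marker_runs) < 2:
        raise BarcodeNotFoundError("barcode markers not found")
    start_run, stop_run = marker_runs[0], marker_runs[-1]
    span = stop_run[0] - start_run[1]
    if span <= 0:
        raise BarcodeNotFoundError("barcode markers out of order")
    m = span / _SPAN_MODULES

    def sample(module_index: float) -> bool:
        x = start_run[1] + (module_index + 0.5) * m
        i = int(round(x))
        if not (0 <= i < len(dark)):
            raise BarcodeNotFoundError("barcode truncated")
        return bool(dark[i])

    bits = []
    for k in range(_BARCODE_BITS + 1):
        a = sample(1 + 2 * k)
        b = sample(1 + 2 * k + 1)
        if a == b:
            raise BarcodeNotFoundError("invalid Manchester pair in barcode")
        bits.append(1 if a else 0)
    value = 0
    for b in bits[:_BARCODE_BITS]:
        value = (value << 1) | b
    if sum(bits[:_BARCODE_BITS]) % 2 != bits[_BARCODE_BITS]:
        raise BarcodeNotFoundError("barcode parity check failed")
    return value


@dataclass
class OpticalTapeFrame:
    """RGB overview of one tape aperture as captured during sectioning,
    with ground-truth polygons recorded for test oracles."""

    rgb_image: np.ndarray  # uint8 (H, W, 3)
    aperture_polygon: np.ndarray  # (N, 2) float, (x, y) px
    tissue_polygon: Optional[np.ndarray]  # (N, 2) float or None
    barcode_strip_rect: tuple[int, int, int, int]  # (x, y, w, h) px
    specimen_id: str
    media_id: str
    barcode: int
    um_per_px: float  # physical scale linking optical px to stage um

    @property
    def aperture_centroid_px(self) -> tuple[float, float]:
        return tuple(self.aperture_polygon.mean(axis=0))

    @property
    def tissue_centroid_px(self) -> Optional[tuple[float, float]]:
        if self.tissue_polygon is None:
            return None
        return tuple(self.tissue_polygon.mean(axis=0))


def _polygon_mask(shape, polygon: np.ndarray) -> np.ndarray:
    from skimage.draw import polygon as sk_polygon

    rr, cc = sk_polygon(polygon[:, 1], polygon[:, 0], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


_TISSUE_RGB = np.array([168.0, 140.0, 196.0])  # light purple tint (HSV hue ~0.75)
_TAPE_RGB = np.array([70.0, 62.0, 55.0])
_APERTURE_RGB = np.array([232.0, 230.0, 226.0])


def _render_optical_frame(
    rng: np.random.Generator,
    section: GroundTruthSection,
    params: TapeParams,
) -> OpticalTapeFrame:
    ap_w_um, ap_h_um = section.aperture_rect.w, section.aperture_rect.h
    ap_w_px = params.optical_px_per_aperture
    um_per_px = ap_w_um / ap_w_px
    ap_h_px = int(round(ap_h_um / um_per_px))

    W = int(ap_w_px * 2.2)
    H = int(ap_h_px * 2.4)
    img = np.empty((H, W, 3), dtype=np.float32)
    img[:] = _TAPE_RGB
    img += rng.normal(0, 4.0, img.shape).astype(np.float32)

    # aperture rectangle near the horizontal centreline, with jitter
    acx = W / 2.0 + rng.uniform(-0.05, 0.05) * W
    acy = H / 2.0 + rng.uniform(-0.04, 0.04) * H
    ax0, ay0 = acx - ap_w_px / 2.0, acy - ap_h_px / 2.0
    aperture_poly = np.array(
        [
            [ax0, ay0],
            [ax0 + ap_w_px, ay0],
            [ax0 + ap_w_px, ay0 + ap_h_px],
            [ax0, ay0 + ap_h_px],
        ]
    )
    ap_mask = _polygon_mask((H, W), aperture_poly)
    img[ap_mask] = _APERTURE_RGB + rng.normal(0, 3.0, (int(ap_mask.sum()), 3))

    # bright distractor blobs off the centreline (smaller than the aperture)
    for _ in range(rng.integers(1, 3)):
        bw = rng.uniform(0.12, 0.25) * ap_w_px
        bx = rng.uniform(0.05 * W, 0.95 * W - bw)
        # bottom band only: clear of both the barcode strip and the aperture
        by = rng.uniform(0.88 * H, 0.94 * H)
        poly = np.array([[bx, by], [bx + bw, by], [bx + bw, by + bw * 0.6], [bx, by + bw * 0.6]])
        img[_polygon_mask((H, W), poly)] = _APERTURE_RGB * 0.95

    # tissue polygon: the EM-truth tissue ellipse mapped into optical px
    tissue_poly = None
    if section.tissue_mask.any():
        c_um = section.tissue_centroid_um()
        # relative position inside the aperture (optical y grows downward)
        fx = (c_um[0] - section.aperture_rect.x) / ap_w_um
        fy = (section.aperture_rect.y1 - c_um[1]) / ap_h_um
        tcx, tcy = ax0 + fx * ap_w_px, ay0 + fy * ap_h_px
        rows, cols = np.nonzero(section.tissue_mask)
        rx = (cols.max() - cols.min()) / 2.0 * section.truth_um_per_sample / um_per_px
        ry = (rows.max() - rows.min()) / 2.0 * section.truth_um_per_sample / um_per_px
        ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        wob = 1.0 + rng.uniform(-0.04, 0.04, ang.size)
        tissue_poly = np.stack(
            [tcx + rx * wob * np.cos(ang), tcy + ry * wob * np.sin(ang)], axis=1
        )
        t_mask = _polygon_mask((H, W), tissue_poly) & ap_mask
        img[t_mask] = _TISSUE_RGB + rng.normal(0, 5.0, (int(t_mask.sum()), 3))

    # barcode strip across the top of the frame
    strip = encode_barcode_strip(section.barcode)
    sh, sw = strip.shape
    sx = max(0, (W - sw) // 2)
    sy = 4
    strip_rgb = (strip[..., None] * 255.0).repeat(3, axis=2)
    img[sy : sy + sh, sx : sx + sw] = strip_rgb[:, : W - sx]
    strip_rect = (sx, sy, min(sw, W - sx), sh)

    rgb = np.clip(img, 0, 255).astype(np.uint8)
    return OpticalTapeFrame(
        rgb_image=rgb,
        aperture_polygon=aperture_poly,
        tissue_polygon=tissue_poly,
        barcode_strip_rect=strip_rect,
        specimen_id=params.specimen_id,
        media_id=params.media_id,
        barcode=section.barcode,
        um_per_px=um_per_px,
    )


def generate_tape(
    seed: int, n_sections: int, params: TapeParams | None = None
) -> tuple[list[GroundTruthSection], list[OpticalTapeFrame]]:
    """Generate a tape of ``n_sections`` barcoded sections plus matching
    optical overview frames.  Barcodes are unique and consecutive starting
    at ``params.start_barcode``; a configurable fraction of sections carry
    no tissue (their frames have no tissue polygon, exercising the
    empty-TAO path)."""
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    params = params or TapeParams()
    master = np.random.default_rng(seed)
    sections: list[GroundTruthSection] = []
    frames: list[OpticalTapeFrame] = []
    for i in range(n_sections):
        sub_seed = int(master.integers(0, 2**31))
        has_tissue = master.random() >= params.no_tissue_fraction
        f0 = params.section.focus_f0
        if params.focus_f0_jitter > 0:
            f0 += float(master.normal(0.0, params.focus_f0_jitter))
        sp = params.section.model_copy(update={"has_tissue": has_tissue, "focus_f0": f0})
        sec = generate_section(sub_seed, sp)
        sec.section_id = i
        sec.barcode = params.start_barcode + i
        sections.append(sec)
        frames.append(_render_optical_frame(np.random.default_rng(sub_seed + 1), sec, params))
    return sections, frames


# ---------------------------------------------------------------------------
# The virtual scope
# ---------------------------------------------------------------------------


@dataclass
class VirtualScope:
    """Simulator state: ground-truth tape, stage, beam, camera and clock.

    ``frame_px * nm_per_px`` defines the field of view consistently for
    every render; the simulated clock (ms) is monotone non-decreasing and
    replaces wall time so throughput bookkeeping is deterministic.
    """

    tape: list[GroundTruthSection]
    frame_px: int = 3840
    nm_per_px: float = 4.0
    rng_seed: int = 0
    stage: StageModel = field(default_factory=StageModel)
    beam: BeamModel = field(default_factory=BeamModel)
    current_section: int = 0
    exposure_ms: float = 100.0
    tape_step_ms: float = 2000.0
    quantize: bool = True
    clock_ms: float = 0.0
    monitor: dict = field(
        default_factory=lambda: {
            "stage_temp_c": 35.0,
            "beam_current_ua": 70.0,
            "vacuum_torr": 1.2e-7,
        }
    )

    def __post_init__(self):
        self.rng = np.random.default_rng(self.rng_seed)

    # -- properties ---------------------------------------------------------

    @property
    def fov_um(self) -> float:
        return self.frame_px * self.nm_per_px / 1000.0

    @property
    def section(self) -> GroundTruthSection:
        return self.tape[self.current_section]

    def advance_clock(self, ms: float) -> None:
        if ms < 0:
            raise ValueError("clock is monotone non-decreasing")
        self.clock_ms += ms

    # -- stage --------------------------------------------------------------

    def move_stage(self, target_xy: tuple[float, float]) -> tuple[float, float]:
        """Move the stage; achieved = target + truncated Gaussian error.

        Raises :class:`StageBoundsError` (position unchanged) for targets
        outside the stage range.  Advances the clock by a settle-time draw.
        """
        x, y = float(target_xy[0]), float(target_xy[1])
        b = self.stage.bounds
        if not b.contains(x, y):
            raise StageBoundsError(f"target ({x:.1f}, {y:.1f}) um outside stage bounds")
        sd = self.stage.per_move_error_sd
        if sd > 0:
            err = self.rng.normal(0.0, sd, 2)
            err = np.clip(err, -4.0 * sd, 4.0 * sd)
            x, y = x + err[0], y + err[1]
        x = min(max(x, b.x), np.nextafter(b.x1, -np.inf))
        y = min(max(y, b.y), np.nextafter(b.y1, -np.inf))
        mean, ssd = self.stage.settle_time_model
        settle = max(0.0, float(self.rng.normal(mean, ssd))) if ssd > 0 else mean
        self.advance_clock(settle)
        self.stage.position = (float(x), float(y))
        return self.stage.position

    # -- tape ---------------------------------------------------------------

    def seek_barcode(self, barcode: int) -> int:
        """Seek the tape (forward or backward) to the section carrying
        ``barcode``; returns the section index."""
        for idx, sec in enumerate(self.tape):
            if sec.barcode == barcode:
                steps = abs(idx - self.current_section)
                self.advance_clock(steps * self.tape_step_ms)
                self.current_section = idx
                return idx
        raise BarcodeNotFoundError(f"barcode {barcode} not on tape")

    # -- rendering ----------------------------------------------------------

    def render_frame(
        self,
        beam_on: bool | None = None,
        focus_value: float | None = None,
        size_px: int | None = None,
        quantize: bool | None = None,
    ) -> RawFrame:
        """Render a camera frame at the current stage position.

        pixel = clip(quantize(truth x illumination x signal + dark + noise));
        with the beam off only dark + read noise remain.  Defocus applies a
        Gaussian blur (sigma = blur_coeff x |f - f_opt| rendered px) to the
        ground truth before resampling.  Advances the clock by one exposure.
        """
        N = int(size_px or self.frame_px)
        beam_on = self.beam.beam_on if beam_on is None else beam_on
        quantize = self.quantize if quantize is None else quantize
        cx, cy = self.stage.position
        if not self.stage.bounds.contains(cx, cy):
            raise StageBoundsError("stage position outside bounds")
        sec = self.section
        if focus_value is None:
            focus_value = sec.f_opt(cx, cy)

        dark = self.beam.dark_pattern(N).astype(np.float64).copy()
        if self.beam.read_noise:
            dark = dark + self.rng.normal(0.0, self.beam.read_noise_sd, (N, N))

        if not beam_on:
            out = dark
        else:
            s_um = self.nm_per_px / 1000.0
            half = (N - 1) / 2.0
            u = (np.arange(N, dtype=np.float64) - half) * s_um  # +x right
            v = (half - np.arange(N, dtype=np.float64)) * s_um  # +y up (row down)
            th = np.radians(self.beam.image_rotation_deg)
            cth, sth = np.cos(th), np.sin(th)
            X = cx + cth * u[None, :] - sth * v[:, None]
            Y = cy + sth * u[None, :] + cth * v[:, None]
            rows, cols = sec.stage_to_truth(X, Y)

            truth = sec.truth_image
            sigma_px = self.beam.defocus_blur_coeff * abs(focus_value - sec.f_opt(cx, cy))
            if sigma_px > 1e-6:
                sigma_truth = sigma_px * (self.nm_per_px / sec.truth_nm)
                r0 = int(max(0, np.floor(rows.min()) - 4 * sigma_truth - 2))
                r1 = int(min(truth.shape[0], np.ceil(rows.max()) + 4 * sigma_truth + 2))
                c0 = int(max(0, np.floor(cols.min()) - 4 * sigma_truth - 2))
                c1 = int(min(truth.shape[1], np.ceil(cols.max()) + 4 * sigma_truth + 2))
                if r1 > r0 and c1 > c0:
                    crop = ndimage.gaussian_filter(
                        truth[r0:r1, c0:c1].astype(np.float64),
                        sigma_truth,
                        mode="constant",
                        cval=0.0,
                    )
                else:
                    crop, r0, c0 = np.zeros((1, 1)), 0, 0
                sample = ndimage.map_coordinates(
                    crop, [rows - r0, cols - c0], order=1, mode="constant", cval=0.0
                )
            else:
                sample = ndimage.map_coordinates(
                    truth.astype(np.float64), [rows, cols], order=1, mode="constant", cval=0.0
                )

            illum = self.beam.illumination_field(N, self.clock_ms).astype(np.float64)
            signal = sample * illum * self.beam.signal_full
            if self.beam.shot_noise:
                electrons = np.maximum(signal, 0.0) / self.beam.dn_per_e
                signal = self.rng.poisson(electrons).astype(np.float64) * self.beam.dn_per_e
            out = signal + dark

        if quantize:
            pixels = np.clip(np.round(out), 0, 65535).astype(np.uint16)
        else:
            pixels = out.astype(np.float32)
        self.advance_clock(self.exposure_ms)
        return RawFrame(
            pixels=pixels,
            stage_xy=self.stage.position,
            focus_value=float(focus_value),
            beam_on=beam_on,
            clock_ms=self.clock_ms,
            exposure_ms=self.exposure_ms,
        )
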