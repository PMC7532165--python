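"""TEM Acquisition Objects (TAOs), montage records, and their databases.

A TAO captures everything needed to image one aperture: its barcode, the
aperture centroid and bounding box measured on the optical tape image,
the tissue centroid, and the ROI definition (offset from the aperture
centroid in µm, size, rotation).  TAOs are created automatically from
optical tape frames by a fixed sequence: decode the barcode, threshold
the image into aperture candidates, pick the largest candidate nearest
the horizontal centreline, extract centroid and bounding box, segment
tissue by an HSV colour range, clean the mask morphologically (fill
small holes, trim thin tendrils), reject undersized tissue, and place a
fixed-size ROI at the tissue centroid.  When no suitable tissue is found
an empty placeholder TAO is stored for later manual ROI definition.

Both databases are append-only JSON-lines files with last-write-wins
semantics on the record key.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field
from scipy import ndimage
from skimage import morphology
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import RoiParseError, StateTransitionError
from .geometry import ROISpec
from .synthetic_scope import OpticalTapeFrame, decode_barcode  # noqa: F401  (re-export)

log = logging.getLogger(__name__)

__all__ = [
    "TAO",
    "MontageRecord",
    "TaoConfig",
    "auto_generate_tao",
    "decode_barcode",
    "parse_roi_ranges",
    "TaoDB",
    "TemDB",
]


class TAO(BaseModel):
    """Per-aperture acquisition object."""

    specimen_id: str
    media_id: str
    barcode: int
    aperture_centroid_px: tuple[float, float]
    aperture_bbox_px: tuple[int, int, int, int]  # (x, y, w, h)
    tissue_centroid_px: Optional[tuple[float, float]] = None
    rois: list[ROISpec] = Field(default_factory=list)
    status: Literal["auto", "manual", "empty_placeholder"] = "auto"
    um_per_px: float = 1.0

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.specimen_id, self.media_id, self.barcode)


class MontageRecord(BaseModel):
    """Record of one acquired (or pending/rejected) montage."""

    barcode: int
    thumbnail_path: Optional[str] = None
    metadata_path: Optional[str] = None
    qc_state: Literal["pending", "passed", "rejected_reimage"] = "pending"
    attempt: int = 1


class TaoConfig(BaseModel):
    """Configuration of the automatic ROI generation sequence.

    Morphology parameters default to fractions of the detected aperture
    area so they scale with the optical magnification."""

    barcode_strip_frac: float = 0.18  # top fraction of the frame holding the strip
    min_aperture_area_frac: float = 0.02  # of the whole frame
    hsv_hue_range: tuple[float, float] = (0.6, 0.9)
    hsv_sat_min: float = 0.10
    hsv_val_range: tuple[float, float] = (0.25, 0.95)
    hole_max_area_frac: float = 0.005  # of the aperture area
    tendril_radius_px: int = 2
    min_tissue_area_frac: float = 0.02  # of the aperture area
    fixed_roi_size_um: tuple[float, float] = (10.0, 8.0)
    tissue_compression_scale: float = 1.0  # isotropic scale applied to the ROI offset


def auto_generate_tao(frame: OpticalTapeFrame, cfg: TaoConfig | None = None) -> TAO:
    """Run the automatic TAO creation sequence on one optical tape frame.

    Raises :class:`~temacq.errors.BarcodeNotFoundError` if the barcode
    strip cannot be decoded (no TAO is created); any tissue-finding
    failure instead yields an ``empty_placeholder`` TAO."""
    cfg = cfg or TaoConfig()
    rgb = frame.rgb_image
    H, W = rgb.shape[:2]

    # (1) barcode
    strip_rows = int(cfg.barcode_strip_frac * H)
    barcode = decode_barcode(rgb[:strip_rows])

    # (2) threshold into aperture candidates (ignore the barcode strip)
    gray = rgb.astype(np.float64).mean(axis=2) / 255.0
    body = gray[strip_rows:]
    thr = threshold_otsu(body)
    binary = np.zeros_like(gray, dtype=bool)
    binary[strip_rows:] = body > thr

    # (3) largest candidate nearest the horizontal centreline
    lbl = label(binary)
    min_area = cfg.min_aperture_area_frac * H * W
    candidates = [r for r in regionprops(lbl) if r.area >= min_area]
    if not candidates:
        raise ValueError("no aperture candidate found above the area threshold")
    centerline = (H + strip_rows) / 2.0
    candidates.sort(key=lambda r: (abs(r.centroid[0] - centerline), -r.area))
    ap = candidates[0]

    # (4) centroid and bounding box
    acy, acx = ap.centroid
    r0, c0, r1, c1 = ap.bbox
    bbox = (int(c0), int(r0), int(c1 - c0), int(r1 - r0))
    ap_mask = lbl == ap.label

    # (5) HSV tissue segmentation inside the aperture
    hsv = rgb2hsv(rgb)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    tissue = (
        (h >= cfg.hsv_hue_range[0])
        & (h <= cfg.hsv_hue_range[1])
        & (s >= cfg.hsv_sat_min)
        & (v >= cfg.hsv_val_range[0])
        & (v <= cfg.hsv_val_range[1])
    )
    tissue &= ndimage.binary_dilation(ap_mask, iterations=2)

    def placeholder() -> TAO:
        return TAO(
            specimen_id=frame.specimen_id,
            media_id=frame.media_id,
            barcode=barcode,
            aperture_centroid_px=(float(acx), float(acy)),
            aperture_bbox_px=bbox,
            tissue_centroid_px=None,
            rois=[],
            status="empty_placeholder",
            um_per_px=frame.um_per_px,
        )

    if not tissue.any():
        return placeholder()

    # (6) fill small interior holes, trim thin outer tendrils
    ap_area = float(ap.area)
    hole_max = max(1, int(cfg.hole_max_area_frac * ap_area))
    tissue = morphology.remove_small_holes(tissue, max_size=hole_max)
    tissue = morphology.opening(tissue, morphology.disk(cfg.tendril_radius_px))
    if not tissue.any():
        return placeholder()
    tl = label(tissue)
    regions = regionprops(tl)
    best = max(regions, key=lambda r: r.area)

    # (7) minimum size criterion
    if best.area < cfg.min_tissue_area_frac * ap_area:
        return placeholder()

    tcy, tcx = best.centroid

    # (8) fixed-size ROI at the tissue centroid, offset in µm from the
    # aperture centroid (optical y grows down; stage y grows up)
    scale = frame.um_per_px * cfg.tissue_compression_scale
    offset_um = ((tcx - acx) * scale, (acy - tcy) * scale)
    roi = ROISpec(offset_um=offset_um, size_um=cfg.fixed_roi_size_um, rotation_deg=0.0)

    # (9) assemble
    return TAO(
        specimen_id=frame.specimen_id,
        media_id=frame.media_id,
        barcode=barcode,
        aperture_centroid_px=(float(acx), float(acy)),
        aperture_bbox_px=bbox,
        tissue_centroid_px=(float(tcx), float(tcy)),
        rois=[roi],
        status="auto",
        um_per_px=frame.um_per_px,
    )


# ---------------------------------------------------------------------------
# Acquisition-range parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"^\s*(\d+)\s*(?:[-–]\s*(\d+)\s*)?$")


def parse_roi_ranges(text: str) -> list[int]:
    """Parse a print-selection style range expression ("1-8, 13, 783-799")
    into a sorted, de-duplicated list of barcodes.  Hyphen and en-dash
    both delimit inclusive ranges; descending ranges and non-numeric
    tokens raise :class:`RoiParseError` naming the offending token."""
    out: set[int] = set()
    for token in text.split(","):
        if not token.strip():
            continue
        m = _TOKEN_RE.match(token)
        if not m:
            raise RoiParseError(f"cannot parse token {token.strip()!r}")
        a = int(m.group(1))
        b = int(m.group(2)) if m.group(2) is not None else a
        if b < a:
            raise RoiParseError(f"descending range {token.strip()!r}")
        out.update(range(a, b + 1))
    return sorted(out)


# ---------------------------------------------------------------------------
# JSON-lines databases
# ---------------------------------------------------------------------------


class _JsonlDB:
    """Append-only JSON-lines store with last-write-wins on the key."""

    key_fields: tuple[str, ...] = ()
    model: type[BaseModel] = BaseModel

    def __init__(self, path: Path):
        self.path = Path(path)
        self._records: dict[tuple, BaseModel] = {}
        if self.path.exists():
            for line in self.path.read_text().splitlines():
                if line.strip():
                    rec = self.model.model_validate_json(line)
                    self._records[self._key(rec)] = rec

    def _key(self, rec: BaseModel) -> tuple:
        return tuple(getattr(rec, f) for f in self.key_fields)

    def upsert(self, rec: BaseModel) -> None:
        rec = self.model.model_validate(rec)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with self.path.open("a") as fh:
            fh.write(rec.model_dump_json() + "\n")
        self._records[self._key(rec)] = rec

    def get(self, *key):
        return self._records.get(tuple(key))

    def list(self, predicate=None) -> list:
        recs = list(self._records.values())
        if predicate is not None:
            recs = [r for r in recs if predicate(r)]
        return recs

    def __len__(self) -> int:
        return len(self._records)


class TaoDB(_JsonlDB):
    """TAO store keyed by (specimen_id, media_id, barcode)."""

    key_fields = ("specimen_id", "media_id", "barcode")
    model = TAO

    def find_barcode(self, barcode: int) -> Optional[TAO]:
        for rec in self._records.values():
            if rec.barcode == barcode:
                return rec
        return None


class TemDB(_JsonlDB):
    """Montage-record store keyed by barcode, enforcing the QC state
    machine: pending -> passed | rejected_reimage; a re-imaging attempt
    returns a rejected record to pending and increments the counter."""

    key_fields = ("barcode",)
    model = MontageRecord

    _ALLOWED = {
        ("pending", "passed"),
        ("pending", "rejected_reimage"),
    }

    def set_qc_state(self, barcode: int, state: str) -> MontageRecord:
        rec = self.get(barcode)
        if rec is None:
            raise KeyError(f"no montage record for barcode {barcode}")
        if (rec.qc_state, state) not in self._ALLOWED:
            raise StateTransitionError(
                f"illegal qc_state transition {rec.qc_state} -> {state}"
            )
        updated = rec.model_copy(update={"qc_state": state})
        self.upsert(updated)
        return updated

    def begin_reattempt(self, barcode: int) -> MontageRecord:
        rec = self.get(barcode)
        if rec is None:
            raise KeyError(f"no montage record for barcode {barcode}")
        if rec.qc_state != "rejected_reimage":
            raise StateTransitionError(
                f"cannot re-attempt a montage in state {rec.qc_state}"
            )
        updated = rec.model_copy(update={"qc_state": "pending", "attempt": rec.attempt + 1})
        self.upsert(updated)
        return updated

    def rejected(self) -> list[MontageRecord]:
        return self.list(lambda r: r.qc_state == "rejected_reimage")
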