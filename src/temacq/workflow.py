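"""Closed-loop acquisition workflow.

For each requested barcode the state machine checks the environment
monitor, seeks the tape, finds the aperture centroid, refreshes the
flat-field correction, verifies beam centering, runs multi-point
autofocus (each initialization step retried with self-correction), then
raster-scans the montage: move, settle, expose, flat-field correct,
write the tile TIFF, and run the real-time QC filters.  A completed
montage is judged against the QC criteria and recorded as passed or
rejected for re-imaging; the run stops early once the failure budget is
exhausted or the monitor raises an alarm.  Rejected sections are always
re-imaged whole (never single tiles) by a batch re-imaging pass.

All timing is simulated-clock bookkeeping (ms), which makes the
throughput extrapolation in the run report exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from pydantic import BaseModel, Field

from . import calibration as cal
from . import qc as qcmod
from .errors import (
    AutofocusError,
    BarcodeNotFoundError,
    BeamCenteringError,
    CentroidError,
    InvalidCorrectionError,
    MontageFocusError,
    StageBoundsError,
    TemacqError,
)
from .focus import FocusSearch, focus_score, multi_point_focus
from .geometry import find_aperture_centroid, plan_montage, transform_roi
from .qc import MontageDecision, QCCriteria, TileQC
from .tao import MontageRecord, TaoDB, TemDB

log = logging.getLogger(__name__)

__all__ = [
    "AcquisitionConfig",
    "Stores",
    "MonitorVerdict",
    "TileRecord",
    "MontageMetadata",
    "RunReport",
    "check_monitor",
    "run_acquisition",
    "reimage_pass",
    "write_metadata",
    "load_metadata",
    "sections_per_week",
    "time_to_image_volume_days",
]


class AcquisitionConfig(BaseModel):
    """All acquisition parameters; validated at load and serialized into
    every montage metadata file."""

    frame_px: int = Field(default=3840, ge=32)
    nm_per_px: float = Field(default=4.0, gt=0)
    overlap_frac: float = Field(default=0.13, ge=0.0, lt=1.0)
    gain_8bpp: float = Field(default=180.0, gt=0)
    focus_range: tuple[float, float] = (0.0, 24.0)
    focus_coarse_step: Optional[float] = None
    focus_refine_frac: float = 0.01
    focus_min_contrast: float = 0.05
    n_satellites: int = Field(default=4, ge=0)
    beam_rotation_deg: float = 0.0
    qc: QCCriteria = QCCriteria()
    max_init_retries: int = Field(default=2, ge=0)
    darkfield_max_age_ms: float = 7 * 24 * 3600 * 1000.0  # refresh cadence
    brightfield_radius_um: float = 300.0
    monitor_thresholds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "stage_temp_c": (15.0, 45.0),
            "beam_current_ua": (40.0, 100.0),
            "vacuum_torr": (0.0, 5.0e-7),
        }
    )

    @property
    def fov_um(self) -> float:
        return self.frame_px * self.nm_per_px / 1000.0

    def focus_search(self) -> FocusSearch:
        return FocusSearch(
            range=self.focus_range,
            coarse_step=self.focus_coarse_step,
            refine_frac=self.focus_refine_frac,
            min_contrast=self.focus_min_contrast,
        )


@dataclass
class Stores:
    """Databases and the output directory layout of a run."""

    tao_db: TaoDB
    tem_db: TemDB
    out_dir: Path

    def montage_dir(self, barcode: int) -> Path:
        return Path(self.out_dir) / str(barcode)


@dataclass
class MonitorVerdict:
    ok: bool
    alarms: list[str]


def check_monitor(
    monitor: dict[str, float], thresholds: dict[str, tuple[float, float]]
) -> MonitorVerdict:
    """Pure threshold evaluation of the monitor channels; an alarm lists
    every channel outside its band."""
    alarms = [
        name
        for name, (lo, hi) in thresholds.items()
        if name in monitor and not (lo <= monitor[name] <= hi)
    ]
    return MonitorVerdict(ok=not alarms, alarms=alarms)


# ---------------------------------------------------------------------------
# Metadata schema
# ---------------------------------------------------------------------------


class EdgeMatchRecord(BaseModel):
    direction: str
    vectors_px: list[tuple[float, float]]
    ncc_peaks: list[Optional[float]]
    n_matched: int
    mean_px: Optional[tuple[float, float]] = None
    sd_px: Optional[tuple[float, float]] = None

    @classmethod
    def from_edge(cls, em) -> "EdgeMatchRecord":
        peaks = [None if (p != p) else float(p) for p in em.ncc_peaks]  # NaN -> None
        return cls(
            direction=em.direction,
            vectors_px=em.vectors_px,
            ncc_peaks=peaks,
            n_matched=em.n_matched,
            mean_px=em.mean_px,
            sd_px=em.sd_px,
        )


class TileRecord(BaseModel):
    row: int
    col: int
    ideal_center_um: tuple[float, float]
    achieved_center_um: tuple[float, float]
    focus_score: float
    intensity_mean: float
    intensity_sd: float
    intensity_spread: float
    edges: dict[str, EdgeMatchRecord] = Field(default_factory=dict)
    flags: list[str] = Field(default_factory=list)
    tile_path: Optional[str] = None


class MontageMetadata(BaseModel):
    barcode: int
    tao: dict
    plan: dict
    montage_focus: Optional[float] = None
    focus_points: list[dict] = Field(default_factory=list)
    tiles: list[TileRecord] = Field(default_factory=list)
    passed: bool = False
    reasons: list[str] = Field(default_factory=list)
    flagged_frac: float = 0.0
    abort_index: Optional[int] = None
    config: dict = Field(default_factory=dict)
    started_ms: float = 0.0
    finished_ms: float = 0.0


def write_metadata(montage: MontageMetadata, path: Path) -> Path:
    """Schema-validated JSON dump; re-loadable losslessly."""
    montage = MontageMetadata.model_validate(montage)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(montage.model_dump_json(indent=1))
    return path


def load_metadata(path: Path) -> MontageMetadata:
    return MontageMetadata.model_validate_json(Path(path).read_text())


class RunReport(BaseModel):
    barcodes_requested: list[int]
    passed: list[int] = Field(default_factory=list)
    rejected: list[int] = Field(default_factory=list)
    skipped_missing_tao: list[int] = Field(default_factory=list)
    barcode_failures: list[int] = Field(default_factory=list)
    stop_cause: Optional[str] = None
    tiles_written: int = 0
    simulated_ms: float = 0.0
    mean_ms_per_montage: Optional[float] = None
    sections_per_week_extrapolated: Optional[float] = None


# ---------------------------------------------------------------------------
# Throughput arithmetic
# ---------------------------------------------------------------------------


def sections_per_week(section_minutes: float, uptime: float = 1.0) -> float:
    """Continuous 24/7 section rate for a given per-section imaging time."""
    if section_minutes <= 0:
        raise ValueError("section_minutes must be positive")
    return 7.0 * 24.0 * 60.0 / section_minutes * uptime


def time_to_image_volume_days(
    n_sections: int,
    sections_per_week_rate: float,
    uptime: float = 1.0,
    n_scopes: int = 1,
) -> float:
    """Days to image ``n_sections`` at a 24/7 per-scope section rate,
    derated by the uptime fraction and divided across ``n_scopes``."""
    if sections_per_week_rate <= 0 or uptime <= 0 or n_scopes < 1:
        raise ValueError("rates, uptime and scope count must be positive")
    return n_sections / (sections_per_week_rate * uptime * n_scopes) * 7.0


# ---------------------------------------------------------------------------
# Montage acquisition
# ---------------------------------------------------------------------------


class _Session:
    """Mutable cross-montage state (darkfield cache) for one run."""

    def __init__(self):
        self.darkfield: Optional[np.ndarray] = None
        self.darkfield_at_ms: float = -np.inf


def _tile_stats(tile8: np.ndarray) -> tuple[float, float, float]:
    p1, p99 = np.percentile(tile8, [1, 99])
    return float(tile8.mean()), float(tile8.std()), float(p99 - p1)


def _acquire_montage(
    scope, tao, cfg: AcquisitionConfig, stores: Stores, session: _Session
) -> tuple[MontageMetadata, MontageDecision]:
    """Initialize and raster one montage; returns metadata + decision."""
    mdir = stores.montage_dir(tao.barcode)
    (mdir / "tiles").mkdir(parents=True, exist_ok=True)
    started = scope.clock_ms

    aborted_reason = None
    abort_index = None
    focus_result = None
    centroid = None
    cset = None

    for attempt in range(cfg.max_init_retries + 1):
        try:
            centroid = find_aperture_centroid(scope)
            if session.darkfield is None or (
                scope.clock_ms - session.darkfield_at_ms > cfg.darkfield_max_age_ms
            ):
                session.darkfield = cal.acquire_darkfield(scope)
                session.darkfield_at_ms = scope.clock_ms
            cal.center_beam(scope)
            cset = cal.build_correction_set(
                scope,
                gain_8bpp=cfg.gain_8bpp,
                radius_um=cfg.brightfield_radius_um,
                darkfield=session.darkfield,
            )
            roi = tao.rois[0]
            stage_roi = transform_roi(roi, centroid, cfg.beam_rotation_deg)
            focus_result = multi_point_focus(
                scope,
                stage_roi,
                n_satellites=cfg.n_satellites,
                search=cfg.focus_search(),
                correction_set=cset,
            )
            break
        except (
            AutofocusError,
            MontageFocusError,
            BeamCenteringError,
            InvalidCorrectionError,
        ) as exc:
            log.warning(
                "montage %d init attempt %d failed (%s); retrying",
                tao.barcode,
                attempt + 1,
                exc,
            )
            # self-correction: force fresh darkfield next attempt
            session.darkfield = None
            if attempt == cfg.max_init_retries:
                aborted_reason = f"init:{type(exc).__name__}"
        except (CentroidError, StageBoundsError) as exc:
            aborted_reason = f"init:{type(exc).__name__}:{exc}"
            break

    meta = MontageMetadata(
        barcode=tao.barcode,
        tao=tao.model_dump(),
        plan={},
        config=cfg.model_dump(),
        started_ms=started,
    )

    tiles: list[TileQC] = []
    plan = None
    if aborted_reason is None:
        roi = tao.rois[0]
        stage_roi = transform_roi(roi, centroid, cfg.beam_rotation_deg)
        plan = plan_montage(stage_roi, cfg.fov_um, cfg.overlap_frac, frame_px=cfg.frame_px)
        meta.plan = plan.to_dict()
        meta.montage_focus = focus_result.focus_value
        meta.focus_points = [
            {
                "position_um": p.position_um,
                "focus_value": p.focus_value,
                "score": p.score,
                "accepted": p.accepted,
                "reason": p.reason,
            }
            for p in focus_result.satellite_scores
        ]
        overlap_px = cfg.overlap_frac * cfg.frame_px

        prev_row: list[Optional[np.ndarray]] = [None] * plan.n_cols
        cur_row: list[Optional[np.ndarray]] = [None] * plan.n_cols
        for idx, (tx, ty) in enumerate(plan.tile_centers_um):
            row, col = divmod(idx, plan.n_cols)
            if col == 0:
                prev_row, cur_row = cur_row, [None] * plan.n_cols
            try:
                achieved = scope.move_stage((tx, ty))
                raw = scope.render_frame(beam_on=None, focus_value=focus_result.focus_value)
            except (StageBoundsError, TemacqError) as exc:
                aborted_reason = f"tile:{type(exc).__name__}"
                abort_index = idx
                break
            tile8 = cal.correct_frame(raw, cset)
            cur_row[col] = tile8
            tpath = mdir / "tiles" / f"r{row}_c{col}.tif"
            tifffile.imwrite(tpath, tile8)

            mean, sd, spread = _tile_stats(tile8)
            tqc = TileQC(
                row=row,
                col=col,
                ideal_center_um=(tx, ty),
                achieved_center_um=achieved,
                focus_score=focus_score(tile8),
                intensity_mean=mean,
                intensity_sd=sd,
                intensity_spread=spread,
            )
            if col > 0 and cur_row[col - 1] is not None:
                tqc.edges["left"] = qcmod.match_edge(
                    tile8, cur_row[col - 1], "left", cfg.overlap_frac, cfg.qc
                )
            if row > 0 and prev_row[col] is not None:
                tqc.edges["top"] = qcmod.match_edge(
                    tile8, prev_row[col], "top", cfg.overlap_frac, cfg.qc
                )
            qcmod.evaluate_tile(tqc, cfg.qc, overlap_px)
            tiles.append(tqc)

    if plan is not None:
        maps = qcmod.build_maps(tiles, plan.n_rows, plan.n_cols)
        qcmod.render_qc_maps(maps, mdir / "qc")
        _write_thumbnail(tiles, plan, mdir, stores)
    else:
        maps = qcmod.build_maps(tiles, 1, 1)
    decision = qcmod.montage_decision(
        maps, tiles, cfg.qc, aborted=aborted_reason is not None, abort_reason=aborted_reason
    )

    meta.tiles = [
        TileRecord(
            row=t.row,
            col=t.col,
            ideal_center_um=t.ideal_center_um,
            achieved_center_um=t.achieved_center_um,
            focus_score=t.focus_score,
            intensity_mean=t.intensity_mean,
            intensity_sd=t.intensity_sd,
            intensity_spread=t.intensity_spread,
            edges={d: EdgeMatchRecord.from_edge(e) for d, e in t.edges.items()},
            flags=sorted(t.flags),
            tile_path=f"tiles/r{t.row}_c{t.col}.tif",
        )
        for t in tiles
    ]
    meta.passed = decision.passed
    meta.reasons = decision.reasons
    meta.flagged_frac = decision.flagged_frac
    meta.abort_index = abort_index
    meta.finished_ms = scope.clock_ms
    write_metadata(meta, mdir / "metadata.json")
    return meta, decision


def _write_thumbnail(tiles, plan, mdir: Path, stores: Stores) -> None:
    import imageio.v3 as iio

    side = 24
    grid = np.zeros((plan.n_rows * side, plan.n_cols * side), dtype=np.uint8)
    for t in tiles:
        tile = tifffile.imread(mdir / "tiles" / f"r{t.row}_c{t.col}.tif")
        step = max(1, tile.shape[0] // side)
        small = tile[::step, ::step][:side, :side]
        grid[
            t.row * side : t.row * side + small.shape[0],
            t.col * side : t.col * side + small.shape[1],
        ] = small
    iio.imwrite(mdir / "overview.png", grid)


def _run_barcodes(
    scope, barcodes, cfg: AcquisitionConfig, stores: Stores, reattempt: bool = False
) -> RunReport:
    report = RunReport(barcodes_requested=list(barcodes))
    session = _Session()
    start_ms = scope.clock_ms
    failures = 0
    montage_times = []

    for barcode in barcodes:
        verdict = check_monitor(scope.monitor, cfg.monitor_thresholds)
        if not verdict.ok:
            scope.beam.beam_on = False  # safe condition
            report.stop_cause = f"monitor_alarm:{','.join(verdict.alarms)}"
            break

        tao = stores.tao_db.find_barcode(barcode)
        if tao is None or not tao.rois:
            log.warning("barcode %d: no TAO/ROI available; montage skipped", barcode)
            report.skipped_missing_tao.append(barcode)
            continue

        try:
            scope.seek_barcode(barcode)
        except BarcodeNotFoundError:
            report.barcode_failures.append(barcode)
            failures += 1
            if failures > cfg.qc.max_montage_failures:
                report.stop_cause = "failure_budget_exhausted"
                break
            continue

        if reattempt:
            stores.tem_db.begin_reattempt(barcode)
        else:
            existing = stores.tem_db.get(barcode)
            attempt = existing.attempt if existing and existing.qc_state == "pending" else 1
            stores.tem_db.upsert(
                MontageRecord(barcode=barcode, qc_state="pending", attempt=attempt)
            )

        t0 = scope.clock_ms
        meta, decision = _acquire_montage(scope, tao, cfg, stores, session)
        montage_times.append(scope.clock_ms - t0)
        report.tiles_written += len(meta.tiles)

        mdir = stores.montage_dir(barcode)
        rec = stores.tem_db.get(barcode)
        rec = rec.model_copy(
            update={
                "metadata_path": str(mdir / "metadata.json"),
                "thumbnail_path": str(mdir / "overview.png")
                if (mdir / "overview.png").exists()
                else None,
            }
        )
        stores.tem_db.upsert(rec)
        if decision.passed:
            stores.tem_db.set_qc_state(barcode, "passed")
            report.passed.append(barcode)
            # hand-off marker for the downstream stitching pipeline
            (mdir / "READY").write_text("passed\n")
        else:
            stores.tem_db.set_qc_state(barcode, "rejected_reimage")
            report.rejected.append(barcode)
            failures += 1
            if failures > cfg.qc.max_montage_failures:
                report.stop_cause = "failure_budget_exhausted"
                break

    report.simulated_ms = scope.clock_ms - start_ms
    if montage_times:
        mean_ms = float(np.mean(montage_times))
        report.mean_ms_per_montage = mean_ms
        report.sections_per_week_extrapolated = sections_per_week(mean_ms / 60000.0)
    return report


def run_acquisition(scope, barcodes, cfg: AcquisitionConfig, stores: Stores) -> RunReport:
    """Acquire montages for ``barcodes`` in order (see module docstring)."""
    return _run_barcodes(scope, barcodes, cfg, stores, reattempt=False)


def reimage_pass(scope, stores: Stores, cfg: AcquisitionConfig) -> RunReport:
    """Batch re-imaging of every rejected section (whole montages, never
    single tiles); successful re-runs flip the record to passed and the
    attempt counter is incremented."""
    rejected = sorted(r.barcode for r in stores.tem_db.rejected())
    if not rejected:
        return RunReport(barcodes_requested=[])
    return _run_barcodes(scope, rejected, cfg, stores, reattempt=True)
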