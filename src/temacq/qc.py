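"""Real-time montage quality control.

Each newly acquired tile is matched against its left and top neighbours
by normalized cross-correlation: three square templates are taken from
the new tile's overlap strip (at 1/4, 1/2 and 3/4 along the shared edge)
and searched for in the neighbour's strip of twice the overlap width.
The mean and standard deviation of the (up to three) matching vectors,
together with per-tile intensity and focus statistics, drive a set of
deterministic flags; four montage-level maps (match quality, focus,
x-offset and y-offset from ideal) summarize the grid, and the montage
passes or fails on the flagged-tile fraction.

Sign convention for offsets: positive means the template was found
beyond its expected position (rendered blue in the offset maps; red is
negative; intensity encodes magnitude).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field
from skimage.feature import match_template

log = logging.getLogger(__name__)

__all__ = [
    "QCCriteria",
    "EdgeMatch",
    "TileQC",
    "MontageQCMaps",
    "MontageDecision",
    "match_edge",
    "evaluate_tile",
    "build_maps",
    "render_qc_maps",
    "montage_decision",
]


class QCCriteria(BaseModel):
    """User-defined screening criteria; every threshold is explicit."""

    ncc_min: float = 0.5
    min_matched_per_edge: int = 2
    max_vector_sd_px: float = 2.0
    max_offset_frac_of_overlap: float = 0.10  # of the overlap-strip width
    dark_tile_max: float = 10.0  # mean 8-bit intensity below which a tile is dark
    intensity_band: tuple[float, float] = (10.0, 245.0)
    min_intensity_spread: float = 0.0  # p99 - p1 of the 8-bit histogram
    focus_min: float | None = None
    max_flagged_tiles_frac: float = 0.05
    max_montage_failures: int = Field(default=3, ge=0)

    def max_offset_px(self, overlap_px: float) -> float:
        return self.max_offset_frac_of_overlap * overlap_px


@dataclass
class EdgeMatch:
    """NCC match of one tile edge against a neighbour."""

    direction: str  # "left" or "top"
    vectors_px: list[tuple[float, float]]  # matched (dx, dy), found - expected
    ncc_peaks: list[float]  # per-template peak correlation (NaN if degenerate)
    n_matched: int
    mean_px: tuple[float, float] | None
    sd_px: tuple[float, float] | None


@dataclass
class TileQC:
    row: int
    col: int
    ideal_center_um: tuple[float, float]
    achieved_center_um: tuple[float, float]
    focus_score: float
    intensity_mean: float
    intensity_sd: float
    intensity_spread: float  # p99 - p1
    edges: dict = field(default_factory=dict)  # direction -> EdgeMatch
    flags: set = field(default_factory=set)


def _subpixel_peak(corr: np.ndarray, peak) -> tuple[float, float]:
    r, c = peak
    out = [float(r), float(c)]
    for axis, idx in ((0, r), (1, c)):
        if 0 < idx < corr.shape[axis] - 1:
            y0 = corr[idx - 1, c] if axis == 0 else corr[r, idx - 1]
            y1 = corr[idx, c] if axis == 0 else corr[r, idx]
            y2 = corr[idx + 1, c] if axis == 0 else corr[r, idx + 1]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                out[axis] = idx + 0.5 * (y0 - y2) / denom
    return out[0], out[1]


def match_edge(
    tile_img: np.ndarray,
    neighbor_img: np.ndarray,
    direction: str,
    overlap_frac: float,
    criteria: QCCriteria | None = None,
) -> EdgeMatch:
    """Match the new tile's overlap strip against a neighbour's.

    ``direction`` names where the neighbour sits relative to the new tile
    ("left" or "top").  Degenerate templates (zero variance, e.g. on a
    black tile) are counted as unmatched, never raised."""
    criteria = criteria or QCCriteria()
    if tile_img.shape != neighbor_img.shape:
        raise ValueError("tile and neighbour must have the same shape")
    if not (0.0 < overlap_frac < 1.0):
        raise ValueError("overlap_frac must be in (0, 1)")
    if direction not in ("left", "top"):
        raise ValueError("direction must be 'left' or 'top'")

    # work in a transposed view for the vertical case so the matching code
    # only ever handles a left neighbour
    transposed = direction == "top"
    tile = np.asarray(tile_img, dtype=np.float64)
    nbr = np.asarray(neighbor_img, dtype=np.float64)
    if transposed:
        tile, nbr = tile.T, nbr.T
    H, W = tile.shape
    w = max(4, int(round(overlap_frac * W)))
    t = max(3, w // 3)

    search = nbr[:, max(0, W - 2 * w) :]
    search_c0 = max(0, W - 2 * w)
    vectors: list[tuple[float, float]] = []
    peaks: list[float] = []
    for frac in (0.25, 0.5, 0.75):
        rc = int(round(frac * H - t / 2.0))
        rc = min(max(rc, 0), H - t)
        # template flush against the shared edge: content there stays
        # inside the neighbour for displacements up to the strip width
        cc = min(1, max(0, w - t))
        tpl = tile[rc : rc + t, cc : cc + t]
        # expected position of this content in the neighbour: the new
        # tile's strip coincides with the neighbour's far strip
        exp_row, exp_col = rc, W - w + cc
        if tpl.std() == 0 or search.std() == 0 or search.shape[0] < t or search.shape[1] < t:
            peaks.append(float("nan"))
            continue
        corr = match_template(search, tpl)
        pk = np.unravel_index(np.argmax(corr), corr.shape)
        ncc = float(corr[pk])
        peaks.append(ncc)
        if ncc < criteria.ncc_min:
            continue
        pr, pc = _subpixel_peak(corr, pk)
        drow = pr - exp_row  # search region spans all rows
        dcol = (pc + search_c0) - exp_col
        if transposed:
            dcol, drow = drow, dcol
        vectors.append((dcol, drow))

    n_matched = len(vectors)
    mean = sd = None
    if n_matched:
        arr = np.array(vectors)
        mean = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
        sd = (float(arr[:, 0].std(ddof=0)), float(arr[:, 1].std(ddof=0)))
    return EdgeMatch(
        direction=direction,
        vectors_px=vectors,
        ncc_peaks=peaks,
        n_matched=n_matched,
        mean_px=mean,
        sd_px=sd,
    )


def evaluate_tile(tile: TileQC, criteria: QCCriteria, overlap_px: float) -> TileQC:
    """Set the deterministic flag set of a tile from its statistics.

    The first tile of a montage has no edges and can only fail on focus
    or intensity; interior tiles additionally fail on match count/scatter
    (``match_fail``) and on offset outliers."""
    flags = set()
    max_off = criteria.max_offset_px(overlap_px)
    for em in tile.edges.values():
        if em.n_matched < criteria.min_matched_per_edge:
            flags.add("match_fail")
        if em.sd_px is not None and (
            em.sd_px[0] > criteria.max_vector_sd_px or em.sd_px[1] > criteria.max_vector_sd_px
        ):
            flags.add("match_fail")
        if em.mean_px is not None and (
            abs(em.mean_px[0]) > max_off or abs(em.mean_px[1]) > max_off
        ):
            flags.add("offset_outlier")
    if tile.intensity_mean < criteria.dark_tile_max:
        flags.add("dark_tile")
    lo, hi = criteria.intensity_band
    if not (lo <= tile.intensity_mean <= hi) or tile.intensity_spread < criteria.min_intensity_spread:
        flags.add("intensity_out_of_band")
    if criteria.focus_min is not None and tile.focus_score < criteria.focus_min:
        flags.add("focus_low")
    tile.flags = flags
    return tile


@dataclass
class MontageQCMaps:
    """The four per-montage QC grids (shape = (n_rows, n_cols))."""

    quality_map: np.ndarray  # 0 = pass, 1 = worst-edge match failure
    focus_map: np.ndarray
    dx_map: np.ndarray  # signed offset from ideal; positive = found beyond
    dy_map: np.ndarray


def build_maps(tiles: list[TileQC], n_rows: int, n_cols: int) -> MontageQCMaps:
    quality = np.zeros((n_rows, n_cols), dtype=np.int8)
    focus = np.full((n_rows, n_cols), np.nan)
    dx = np.full((n_rows, n_cols), np.nan)
    dy = np.full((n_rows, n_cols), np.nan)
    for t in tiles:
        focus[t.row, t.col] = t.focus_score
        if "match_fail" in t.flags:
            quality[t.row, t.col] = 1
        means = [em.mean_px for em in t.edges.values() if em.mean_px is not None]
        if means:
            dx[t.row, t.col] = float(np.mean([m[0] for m in means]))
            dy[t.row, t.col] = float(np.mean([m[1] for m in means]))
    return MontageQCMaps(quality_map=quality, focus_map=focus, dx_map=dx, dy_map=dy)


def render_qc_maps(maps: MontageQCMaps, out_dir: Path) -> dict[str, Path]:
    """Render the four QC maps as PNGs (diverging blue/red scale for the
    signed offset maps; blue = positive/beyond, red = negative/before)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, data, cmap, vmin=None, vmax=None):
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(data, cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest")
        ax.set_title(name.replace("_", " "))
        fig.colorbar(im, ax=ax, fraction=0.046)
        p = out_dir / f"{name}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths[name] = p

    save("quality_map", maps.quality_map, ListedColormap(["#2ca02c", "#d62728"]), 0, 1)
    save("focus_map", maps.focus_map, "viridis")
    for name, data in (("dx_map", maps.dx_map), ("dy_map", maps.dy_map)):
        finite = data[np.isfinite(data)]
        lim = max(1.0, float(np.abs(finite).max())) if finite.size else 1.0
        save(name, data, "RdBu", -lim, lim)  # high = blue = beyond expected
    return paths


@dataclass
class MontageDecision:
    passed: bool
    reasons: list[str]
    flagged_frac: float


def montage_decision(
    maps: MontageQCMaps,
    tiles: list[TileQC],
    criteria: QCCriteria,
    aborted: bool = False,
    abort_reason: str | None = None,
) -> MontageDecision:
    """Montage pass/fail: fail iff the flagged-tile fraction exceeds the
    criterion or the montage was aborted; reasons enumerate the failing
    rules."""
    reasons: list[str] = []
    n = max(1, len(tiles))
    flagged = sum(1 for t in tiles if t.flags)
    frac = flagged / n
    if aborted:
        reasons.append(f"aborted:{abort_reason or 'unknown'}")
    if frac > criteria.max_flagged_tiles_frac:
        reasons.append(
            f"flagged_fraction:{frac:.3f}>" f"{criteria.max_flagged_tiles_frac:.3f}"
        )
    return MontageDecision(passed=not reasons, reasons=reasons, flagged_frac=frac)
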