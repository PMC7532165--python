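"""Real-time QC: edge matching against a brute-force oracle, tile
flagging rules, QC maps, and the montage decision."""

import numpy as np
import pytest

from temacq import (
    QCCriteria,
    TileQC,
    build_maps,
    evaluate_tile,
    generate_section,
    match_edge,
    montage_decision,
    render_qc_maps,
)

from conftest import make_scope, small_params

OVERLAP = 0.13


def render_pair(direction="left", displacement_px=0.0, seed=2, noise=True,
                frame_px=256):
    """Render two neighbouring tiles at planned positions; the *new* tile
    is optionally displaced by ``displacement_px`` along the edge axis."""
    sec = generate_section(5, small_params(aperture_um=(30.0, 24.0)))
    scope = make_scope(section=sec, frame_px=frame_px, seed=seed, noise=noise)
    step = scope.fov_um * (1 - OVERLAP)
    d_um = displacement_px * scope.nm_per_px / 1000.0
    if direction == "left":
        scope.move_stage((-step / 2, 0.0))
        nbr = scope.render_frame().pixels
        scope.move_stage((step / 2 + d_um, 0.0))
        new = scope.render_frame().pixels
    else:
        scope.move_stage((0.0, step / 2))
        nbr = scope.render_frame().pixels
        scope.move_stage((0.0, -step / 2 - d_um))
        new = scope.render_frame().pixels
    return new, nbr


def brute_force_best_offset(search, template):
    """Exhaustive integer-offset NCC argmax (independent oracle)."""
    th, tw = template.shape
    t = (template - template.mean())
    tn = np.sqrt((t**2).sum())
    best, best_val = None, -np.inf
    for r in range(search.shape[0] - th + 1):
        for c in range(search.shape[1] - tw + 1):
            win = search[r : r + th, c : c + tw]
            w = win - win.mean()
            denom = np.sqrt((w**2).sum()) * tn
            if denom == 0:
                continue
            val = (w * t).sum() / denom
            if val > best_val:
                best_val, best = val, (r, c)
    return best, best_val


class TestMatchEdge:
    def test_perfect_registration(self):
        new, nbr = render_pair("left")
        em = match_edge(new, nbr, "left", OVERLAP)
        assert em.n_matched == 3
        assert abs(em.mean_px[0]) < 0.5 and abs(em.mean_px[1]) < 0.5
        assert em.sd_px[0] < 0.5 and em.sd_px[1] < 0.5

    @pytest.mark.parametrize("direction,axis", [("left", 0), ("top", 1)])
    def test_displacement_recovered_with_sign(self, direction, axis):
        new, nbr = render_pair(direction, displacement_px=20.0)
        em = match_edge(new, nbr, direction, OVERLAP)
        assert em.n_matched == 3
        assert em.mean_px[axis] == pytest.approx(20.0, abs=1.0)
        assert abs(em.mean_px[1 - axis]) < 1.0
        crit = QCCriteria()
        overlap_px = OVERLAP * new.shape[0]
        assert abs(em.mean_px[axis]) > crit.max_offset_px(overlap_px)

    def test_dark_tile_matches_nothing(self):
        _, nbr = render_pair("left")
        dark = np.zeros_like(nbr)
        em = match_edge(dark, nbr, "left", OVERLAP)
        assert em.n_matched == 0
        assert em.mean_px is None

    def test_substrate_only_still_matches_with_noise(self):
        # matching succeeds even without tissue: the shot-noise-free
        # substrate carries the fixed-pattern and illumination texture of
        # the sensor, and shot noise alone does not defeat NCC over real
        # common content
        sec = generate_section(9, small_params(aperture_um=(30.0, 24.0),
                                               has_tissue=False))
        scope = make_scope(section=sec, frame_px=256, seed=3, noise=True)
        step = scope.fov_um * (1 - OVERLAP)
        scope.move_stage((-step / 2, 0.0))
        nbr = scope.render_frame().pixels
        scope.move_stage((step / 2, 0.0))
        new = scope.render_frame().pixels
        em = match_edge(new, nbr, "left", OVERLAP)
        assert em.n_matched == 3

    def test_oracle_equivalence_random_fixtures(self):
        # NCC peak equals the exhaustive integer-offset search on 100
        # random textured fixtures
        rng = np.random.default_rng(0)
        from skimage.feature import match_template
        from scipy import ndimage as ndi

        for _ in range(100):
            search = ndi.gaussian_filter(rng.normal(size=(48, 48)), 1.2)
            r0, c0 = rng.integers(4, 30, 2)
            template = search[r0 : r0 + 12, c0 : c0 + 12] + rng.normal(
                0, 0.01, (12, 12)
            )
            corr = match_template(search, template)
            fast = np.unravel_index(np.argmax(corr), corr.shape)
            slow, _ = brute_force_best_offset(search, template)
            assert tuple(fast) == tuple(slow)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_edge(np.zeros((8, 8)), np.zeros((9, 9)), "left", 0.13)


class TestEvaluateTile:
    def make_tile(self, **kw):
        defaults = dict(
            row=1, col=1, ideal_center_um=(0, 0), achieved_center_um=(0, 0),
            focus_score=500.0, intensity_mean=128.0, intensity_sd=30.0,
            intensity_spread=90.0,
        )
        defaults.update(kw)
        return TileQC(**defaults)

    def edge(self, n_matched=3, mean=(0.0, 0.0), sd=(0.1, 0.1)):
        from temacq.qc import EdgeMatch

        return EdgeMatch(
            direction="left", vectors_px=[mean] * n_matched,
            ncc_peaks=[0.9] * 3, n_matched=n_matched,
            mean_px=mean if n_matched else None, sd_px=sd if n_matched else None,
        )

    def test_too_few_matches_flags_match_fail(self):
        tile = self.make_tile()
        tile.edges["left"] = self.edge(n_matched=1)
        evaluate_tile(tile, QCCriteria(), overlap_px=33)
        assert "match_fail" in tile.flags

    def test_high_vector_sd_flags_even_with_three_matches(self):
        tile = self.make_tile()
        tile.edges["left"] = self.edge(n_matched=3, sd=(3.0, 0.1))
        evaluate_tile(tile, QCCriteria(max_vector_sd_px=2.0), overlap_px=33)
        assert "match_fail" in tile.flags

    def test_offset_outlier(self):
        tile = self.make_tile()
        tile.edges["left"] = self.edge(mean=(5.0, 0.0))
        evaluate_tile(tile, QCCriteria(), overlap_px=33)  # max offset 3.3 px
        assert "offset_outlier" in tile.flags

    def test_clean_tile_has_no_flags(self):
        tile = self.make_tile()
        tile.edges["left"] = self.edge()
        evaluate_tile(tile, QCCriteria(), overlap_px=33)
        assert tile.flags == set()

    def test_first_tile_without_edges_can_only_fail_intensity_or_focus(self):
        tile = self.make_tile(intensity_mean=2.0)
        evaluate_tile(tile, QCCriteria(), overlap_px=33)
        assert tile.flags == {"dark_tile", "intensity_out_of_band"}


class TestMapsAndDecision:
    def grid_tiles(self, n=4, bias_row=None, bias_px=0.0):
        tiles = []
        for r in range(n):
            for c in range(n):
                t = TileQC(
                    row=r, col=c, ideal_center_um=(c, -r), achieved_center_um=(c, -r),
                    focus_score=100.0 + r, intensity_mean=128.0, intensity_sd=20.0,
                    intensity_spread=80.0,
                )
                from temacq.qc import EdgeMatch

                dx = bias_px if r == bias_row else 0.0
                if c > 0:
                    t.edges["left"] = EdgeMatch(
                        "left", [(dx, 0.0)] * 3, [0.9] * 3, 3, (dx, 0.0), (0.05, 0.05)
                    )
                tiles.append(t)
        return tiles

    def test_healthy_montage_maps_uniform_and_pass(self, tmp_path):
        tiles = self.grid_tiles()
        for t in tiles:
            evaluate_tile(t, QCCriteria(), overlap_px=33)
        maps = build_maps(tiles, 4, 4)
        assert np.all(maps.quality_map == 0)
        assert np.nanmax(np.abs(maps.dx_map)) == 0.0
        decision = montage_decision(maps, tiles, QCCriteria())
        assert decision.passed
        paths = render_qc_maps(maps, tmp_path)
        assert all(p.exists() for p in paths.values())

    def test_row_bias_shows_in_dx_map_and_flags(self):
        tiles = self.grid_tiles(bias_row=2, bias_px=5.0)
        crit = QCCriteria()
        for t in tiles:
            evaluate_tile(t, crit, overlap_px=33)
        maps = build_maps(tiles, 4, 4)
        assert np.nanmean(maps.dx_map[2]) > np.nanmax(np.abs(maps.dx_map[[0, 1, 3]]))
        flagged_rows = {t.row for t in tiles if t.flags}
        assert flagged_rows == {2}

    def test_focus_gradient_map_monotone(self):
        tiles = self.grid_tiles()
        maps = build_maps(tiles, 4, 4)
        col = maps.focus_map[:, 2]
        assert np.all(np.diff(col) > 0)

    def test_decision_thresholds(self):
        crit = QCCriteria(max_flagged_tiles_frac=0.10)
        tiles = self.grid_tiles()
        for i, t in enumerate(tiles):
            if i < 2:  # 2/16 = 12.5% flagged
                t.flags = {"match_fail"}
        maps = build_maps(tiles, 4, 4)
        decision = montage_decision(maps, tiles, crit)
        assert not decision.passed
        assert any(r.startswith("flagged_fraction") for r in decision.reasons)

    def test_abort_always_fails(self):
        tiles = self.grid_tiles()
        maps = build_maps(tiles, 4, 4)
        decision = montage_decision(maps, tiles, QCCriteria(), aborted=True,
                                    abort_reason="stage")
        assert not decision.passed
        assert decision.reasons == ["aborted:stage"]

    def test_zero_flagged_passes(self):
        tiles = self.grid_tiles()
        maps = build_maps(tiles, 4, 4)
        assert montage_decision(maps, tiles, QCCriteria()).passed
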