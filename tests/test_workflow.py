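"""Closed-loop acquisition state-machine scenarios."""

import numpy as np
import pytest
import tifffile

from temacq import (
    MontagePlan,
    check_monitor,
    load_metadata,
    reimage_pass,
    run_acquisition,
    sections_per_week,
    time_to_image_volume_days,
)
from temacq.workflow import MontageMetadata, TileRecord, write_metadata

from conftest import workflow_setup


def inject_alternating_stage_bias(scope, barcode, bias_um=0.08):
    """Perturb every second stage move while the tape sits on ``barcode``
    (emulating a stage fault on one section): neighbouring tiles then
    disagree by ~bias in x and the matcher must flag them."""
    orig = scope.move_stage
    state = {"n": 0}

    def biased(target):
        if scope.tape[scope.current_section].barcode == barcode:
            state["n"] += 1
            if state["n"] % 2:
                b = scope.stage.bounds
                target = (
                    min(max(target[0] + bias_um, b.x), np.nextafter(b.x1, -np.inf)),
                    target[1],
                )
        return orig(target)

    scope.move_stage = biased
    return lambda: setattr(scope, "move_stage", orig)


class TestCheckMonitor:
    THRESH = {"vacuum_torr": (0.0, 5e-7), "stage_temp_c": (15.0, 45.0)}

    def test_all_in_band(self):
        v = check_monitor({"vacuum_torr": 1e-7, "stage_temp_c": 35.0}, self.THRESH)
        assert v.ok and v.alarms == []

    def test_single_channel_alarm(self):
        v = check_monitor({"vacuum_torr": 1e-5, "stage_temp_c": 35.0}, self.THRESH)
        assert not v.ok and v.alarms == ["vacuum_torr"]

    def test_multiple_channels_listed(self):
        v = check_monitor({"vacuum_torr": 1e-5, "stage_temp_c": 60.0}, self.THRESH)
        assert set(v.alarms) == {"vacuum_torr", "stage_temp_c"}


class TestRunAcquisition:
    def test_healthy_sections_all_pass(self, tmp_path):
        scope, cfg, stores = workflow_setup(tmp_path, n_sections=3)
        report = run_acquisition(scope, [1, 2, 3], cfg, stores)
        assert report.passed == [1, 2, 3]
        assert report.rejected == []
        plans = [
            MontagePlan.from_dict(load_metadata(stores.montage_dir(b) / "metadata.json").plan)
            for b in (1, 2, 3)
        ]
        expected_tiles = sum(p.n_tiles for p in plans)
        assert report.tiles_written == expected_tiles
        written = list((stores.out_dir).glob("*/tiles/*.tif"))
        assert len(written) == expected_tiles
        # tiles are 8-bit TIFFs of the configured frame size
        tile = tifffile.imread(written[0])
        assert tile.dtype == np.uint8 and tile.shape == (256, 256)
        for b in (1, 2, 3):
            assert stores.tem_db.get(b).qc_state == "passed"
            assert (stores.montage_dir(b) / "READY").exists()
            assert (stores.montage_dir(b) / "qc" / "dx_map.png").exists()

    def test_stage_fault_on_one_section_only_rejects_it(self, tmp_path):
        scope, cfg, stores = workflow_setup(tmp_path, n_sections=3)
        restore = inject_alternating_stage_bias(scope, barcode=2)
        report = run_acquisition(scope, [1, 2, 3], cfg, stores)
        restore()
        assert report.passed == [1, 3]
        assert report.rejected == [2]
        assert stores.tem_db.get(2).qc_state == "rejected_reimage"

    def test_failure_budget_stops_the_run(self, tmp_path):
        scope, cfg, stores = workflow_setup(tmp_path, n_sections=5)
        cfg = cfg.model_copy(deep=True)
        cfg.qc.max_montage_failures = 2
        for b in (1, 2, 3, 4, 5):
            inject_alternating_stage_bias(scope, barcode=b)
        report = run_acquisition(scope, [1, 2, 3, 4, 5], cfg, stores)
        assert report.rejected == [1, 2, 3]
        assert report.stop_cause == "failure_budget_exhausted"
        # remaining barcodes untouched
        assert stores.tem_db.get(4) is None and stores.tem_db.get(5) is None

    def test_monitor_alarm_stops_before_montage(self, tmp_path):
        scope, cfg, stores = workflow_setup(tmp_path, n_sections=2)
        scope.monitor["vacuum_torr"] = 1e-5
        report = run_acquisition(scope, [1, 2], cfg, stores)
        assert report.stop_cause.startswith("monitor_alarm:vacuum_torr")
        assert report.passed == [] and report.tiles_written == 0
        assert scope.beam.beam_on is False  # safe condition

    def test_missing_tao_is_skipped(self, tmp_path):
        scope, cfg, stores = workflow_setup(tmp_path, n_sections=2)
        report = run_acquisition(scope, [1, 99], cfg, stores)
        assert report.passed == [1]
        assert report.skipped_missing_tao == [99]

    def test_stale_darkfield_is_refreshed_per_montage(self, tmp_path, monkeypatch):
        import temacq.workflow as wf

        calls = {"n": 0}
        orig = wf.cal.acquire_darkfield

        def counting(scope, n_frames=16):
            calls["n"] += 1
            return orig(scope, n_frames)

        monkeypatch.setattr(wf.cal, "acquire_darkfield", counting)
        scope, cfg, stores = workflow_setup(tmp_path, n_sections=2)
        cfg = cfg.model_copy(update={"darkfield_max_age_ms": 0.0})
        run_acquisition(scope, [1, 2], cfg, stores)
        assert calls["n"] == 2  # refreshed before every montage

        calls["n"] = 0
        scope2, cfg2, stores2 = workflow_setup(tmp_path / "fresh", n_sections=2)
        run_acquisition(scope2, [1, 2], cfg2, stores2)
        assert calls["n"] == 1  # week-scale cadence: acquired once


class TestReimagePass:
    def test_transient_fault_cleared_on_reimage(self, tmp_path):
        scope, cfg, stores = workflow_setup(tmp_path, n_sections=3)
        restore = inject_alternating_stage_bias(scope, barcode=2)
        run_acquisition(scope, [1, 2, 3], cfg, stores)
        restore()  # cause removed
        report = reimage_pass(scope, stores, cfg)
        assert report.passed == [2]
        rec = stores.tem_db.get(2)
        assert rec.qc_state == "passed"
        assert rec.attempt == 2
        assert stores.tem_db.rejected() == []

    def test_noop_without_rejections(self, tmp_path):
        scope, cfg, stores = workflow_setup(tmp_path, n_sections=2)
        run_acquisition(scope, [1, 2], cfg, stores)
        report = reimage_pass(scope, stores, cfg)
        assert report.barcodes_requested == []
        assert report.tiles_written == 0

    def test_persistent_fault_stays_rejected(self, tmp_path):
        scope, cfg, stores = workflow_setup(tmp_path, n_sections=2)
        inject_alternating_stage_bias(scope, barcode=2)
        run_acquisition(scope, [1, 2], cfg, stores)
        report = reimage_pass(scope, stores, cfg)
        assert report.rejected == [2]
        rec = stores.tem_db.get(2)
        assert rec.qc_state == "rejected_reimage"
        assert rec.attempt == 2


class TestMetadata:
    def test_round_trip(self, tmp_path):
        meta = MontageMetadata(
            barcode=7,
            tao={"barcode": 7},
            plan={"fov_um": 4.0},
            montage_focus=11.5,
            tiles=[
                TileRecord(
                    row=0, col=0, ideal_center_um=(0, 0), achieved_center_um=(0.01, 0),
                    focus_score=432.1, intensity_mean=128.0, intensity_sd=20.0,
                    intensity_spread=88.0, flags=["match_fail"],
                )
            ],
            passed=False,
            reasons=["flagged_fraction:1.000>0.050"],
            config={"frame_px": 256},
        )
        path = write_metadata(meta, tmp_path / "m.json")
        assert load_metadata(path) == meta

    def test_abort_truncates_tiles_consistently(self, tmp_path):
        from temacq.errors import StageBoundsError

        # learn the (deterministic) plan from a clean run, then fault the
        # stage exactly at one mid-montage tile move in a fresh replica
        scope, cfg, stores = workflow_setup(tmp_path / "clean", n_sections=1)
        run_acquisition(scope, [1], cfg, stores)
        plan = MontagePlan.from_dict(
            load_metadata(stores.montage_dir(1) / "metadata.json").plan
        )
        # an off-centre tile: the grid centre coincides with the focus
        # centroid probe position and would fault during initialization
        fault_target = plan.tile_centers_um[1]

        scope2, cfg2, stores2 = workflow_setup(tmp_path / "fault", n_sections=1)
        orig = scope2.move_stage

        def faulting(target):
            if np.hypot(target[0] - fault_target[0], target[1] - fault_target[1]) < 1e-6:
                raise StageBoundsError("injected stage fault")
            return orig(target)

        scope2.move_stage = faulting
        report = run_acquisition(scope2, [1], cfg2, stores2)
        meta = load_metadata(stores2.montage_dir(1) / "metadata.json")
        assert meta.abort_index == 1
        assert len(meta.tiles) == 1
        assert not meta.passed
        assert any(r.startswith("aborted:") for r in meta.reasons)
        assert report.rejected == [1]

    def test_config_snapshot_embedded(self, tmp_path):
        scope, cfg, stores = workflow_setup(tmp_path, n_sections=1)
        run_acquisition(scope, [1], cfg, stores)
        meta = load_metadata(stores.montage_dir(1) / "metadata.json")
        from temacq import AcquisitionConfig

        assert AcquisitionConfig.model_validate(meta.config).model_dump() == cfg.model_dump()


class TestThroughputArithmetic:
    def test_sections_per_week_from_section_time(self):
        # 35 minutes per 1 mm^2 section, 24/7 -> ~288 sections/week
        assert sections_per_week(35.0) == pytest.approx(288.0, abs=0.5)

    def test_report_extrapolation_is_pure_function_of_clock(self, tmp_path):
        scope, cfg, stores = workflow_setup(tmp_path, n_sections=1)
        report = run_acquisition(scope, [1], cfg, stores)
        minutes_per_montage = report.mean_ms_per_montage / 60000.0
        assert report.sections_per_week_extrapolated == pytest.approx(
            7 * 24 * 60.0 / minutes_per_montage
        )

    def test_time_to_volume(self):
        assert time_to_image_volume_days(25000, 300, 0.65) == pytest.approx(897.4, abs=0.1)
        assert time_to_image_volume_days(25000, 300, 0.65, 5) == pytest.approx(179.5, abs=0.1)
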