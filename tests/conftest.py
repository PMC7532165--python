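"""Shared fixtures: scaled-down virtual-scope setups.

The fixtures use a coarsened ground-truth sampling (16 nm) and small
camera frames (128-512 px) so closed-loop scenarios run in seconds; the
geometry and statistics under test are size-independent.  The stage
per-move error is scaled with the pixel size so the error-to-threshold
ratio matches a production-scale setup.
"""

from __future__ import annotations

import numpy as np
import pytest

from temacq import (
    SectionParams,
    TapeParams,
    VirtualScope,
    generate_section,
    generate_tape,
)

TRUTH_NM = 16.0


def small_params(**overrides) -> SectionParams:
    base = dict(
        aperture_um=(8.0, 6.0),
        truth_nm=TRUTH_NM,
        aperture_offset_um=(0.0, 0.0),
    )
    base.update(overrides)
    return SectionParams(**base)


def make_scope(
    section=None,
    frame_px: int = 128,
    nm_per_px: float = TRUTH_NM,
    seed: int = 0,
    noise: bool = True,
    stage_error_um: float = 0.0,
    **section_overrides,
) -> VirtualScope:
    if section is None:
        section = generate_section(1, small_params(**section_overrides))
    scope = VirtualScope(
        tape=[section], frame_px=frame_px, nm_per_px=nm_per_px, rng_seed=seed
    )
    scope.stage.per_move_error_sd = stage_error_um
    if not noise:
        scope.beam.shot_noise = False
        scope.beam.read_noise = False
    return scope


def quiet_beam(scope: VirtualScope) -> VirtualScope:
    """Strip every non-ideality: uniform illumination, zero dark, unit
    signal, no noise.  The render then equals the resampled ground truth."""
    scope.beam.shot_noise = False
    scope.beam.read_noise = False
    scope.beam.illum_falloff = 0.0
    scope.beam.dark_level = 0.0
    scope.beam.dark_fpn_sd = 0.0
    scope.beam.signal_full = 1.0
    scope.beam._fpn_cache.clear()
    return scope


@pytest.fixture
def scope_factory():
    return make_scope


@pytest.fixture
def textured_scope():
    """Noise-free 128 px scope over a textured section."""
    return make_scope(noise=False)


@pytest.fixture
def noisy_scope():
    return make_scope(noise=True)


@pytest.fixture
def small_tape():
    """Deterministic 6-section tape with matching optical frames."""
    params = TapeParams(section=small_params(aperture_offset_um=None), start_barcode=101)
    return generate_tape(42, 6, params)


def workflow_setup(tmp_path, seed=11, n_sections=3, frame_px=256, start_barcode=1,
                   stage_error_um=0.01, focus_f0=12.0):
    """Tape + scope + populated TAO db + config for closed-loop scenarios."""
    from temacq import AcquisitionConfig, Stores, TaoDB, TemDB, auto_generate_tao

    params = TapeParams(
        section=SectionParams(
            aperture_um=(20.0, 15.0), truth_nm=TRUTH_NM, focus_f0=focus_f0
        ),
        start_barcode=start_barcode,
    )
    sections, frames = generate_tape(seed, n_sections, params)
    scope = VirtualScope(
        tape=sections, frame_px=frame_px, nm_per_px=TRUTH_NM, rng_seed=seed
    )
    scope.stage.per_move_error_sd = stage_error_um
    tao_db = TaoDB(tmp_path / "tao.jsonl")
    tem_db = TemDB(tmp_path / "tem.jsonl")
    for fr in frames:
        tao_db.upsert(auto_generate_tao(fr))
    cfg = AcquisitionConfig(frame_px=frame_px, nm_per_px=TRUTH_NM, focus_range=(6.0, 18.0))
    stores = Stores(tao_db=tao_db, tem_db=tem_db, out_dir=tmp_path / "run")
    return scope, cfg, stores
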