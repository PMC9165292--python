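"""Shared synthetic fixtures.

Everything is generated at run time from seeded configurations; the heavier
end-to-end pipelines are session-scoped so several tests can share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from nucleoflow import (
    NoiseConfig,
    PipelineConfig,
    SynthConfig,
    generate_movie,
    run_pipeline,
)

# conditions of the packaged end-to-end benchmark: a confluent monolayer with
# a known strain-rate/divergence coupling m = 0.5 (e_n = 2)
E2E_SEED = 1
E2E_CFG = dict(n_nuclei=200, n_frames=100, coupling_m=0.5, seed=E2E_SEED)


@pytest.fixture(scope="session")
def small_clean_movie():
    """40 nuclei, 30 frames, no noise: fast fixture for stage tests."""
    cfg = SynthConfig(n_nuclei=40, frame_shape=(240, 240), n_frames=30,
                      seed=7, noise=NoiseConfig.none())
    seq, gt = generate_movie(cfg)
    return cfg, seq, gt


@pytest.fixture(scope="session")
def small_noisy_movie():
    cfg = SynthConfig(n_nuclei=40, frame_shape=(240, 240), n_frames=30, seed=7)
    seq, gt = generate_movie(cfg)
    return cfg, seq, gt


@pytest.fixture(scope="session")
def default_frame():
    """One frame of the default-density monolayer (200 nuclei, 512^2 px)."""
    cfg = SynthConfig(n_nuclei=200, n_frames=1, seed=E2E_SEED,
                      noise=NoiseConfig(jitter_sigma_px=0))
    seq, gt = generate_movie(cfg)
    return cfg, seq, gt


def _run_e2e(noise: bool):
    cfg = SynthConfig(noise=NoiseConfig() if noise else NoiseConfig.none(),
                      **E2E_CFG)
    seq, gt = generate_movie(cfg)
    pcfg = PipelineConfig(pixel_size_um=cfg.pixel_size_um, dt_min=cfg.dt_min,
                          n_windows=1, seed=0,
                          subtract_bg=noise, do_register=noise)
    res = run_pipeline(seq, pcfg)
    return cfg, gt, res


@pytest.fixture(scope="session")
def e2e_noisy():
    """Full pipeline on the default-noise benchmark movie (minutes)."""
    return _run_e2e(noise=True)


@pytest.fixture(scope="session")
def e2e_clean():
    """Full pipeline on the noise-free benchmark movie (minutes)."""
    return _run_e2e(noise=False)
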