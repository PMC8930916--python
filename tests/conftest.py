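"""Shared fixtures.

The two expensive session fixtures run the forward simulation once each:
``noiseless_recon`` drives the end-to-end accuracy checks, ``noisy_raw``
drives the self-gating checks under the generator's default noise/drift
conditions.  Everything else is small and fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from mtsms.config import preset
from mtsms.phantom import PhantomConfig, make_phantom, simulate_scan
from mtsms.sequence import SequenceConfig, build_schedule


@pytest.fixture(scope="session")
def tiny_cfg():
    cfg = preset("tiny", seed=7)
    return cfg


@pytest.fixture(scope="session")
def short_schedule():
    """Two-cycle schedule with the real timing (20 periods, 714 readouts each)."""
    return build_schedule(SequenceConfig(n_periods=20))


@pytest.fixture(scope="session")
def small_schedule():
    """Fast schedule for unit tests: real cycle structure, short periods."""
    return build_schedule(SequenceConfig(recovery_ms=350.0, n_periods=10))


@pytest.fixture(scope="session")
def static_phantom():
    return make_phantom(PhantomConfig(grid_n=48, contraction=0.0, resp_amp_mm=0.0,
                                      resp_drift=False, noise_rel=0.0, seed=3))


@pytest.fixture(scope="session")
def noisy_raw():
    """Default-condition simulation (noise, motion, drift) at desk scale."""
    cfg = preset("tiny", seed=7)
    from mtsms.pipeline import phantom_config, sequence_config

    schedule = build_schedule(sequence_config(cfg))
    phantom = make_phantom(phantom_config(cfg))
    return simulate_scan(phantom, schedule)


@pytest.fixture(scope="session")
def noiseless_pipeline():
    """Full noiseless tiny-preset pipeline: simulate -> reconstruct -> fit."""
    from mtsms.pipeline import (evaluate_against_truth, run_fit, run_reconstruct,
                                run_simulate)

    cfg = preset("tiny", seed=7)
    cfg.phantom.noise_rel = 0.0
    cfg.phantom.resp_drift = False
    raw = run_simulate(cfg)
    recon = run_reconstruct(raw, cfg)
    maps = run_fit(recon, cfg)
    metrics = evaluate_against_truth(recon, maps, cfg)
    return {"cfg": cfg, "raw": raw, "recon": recon, "maps": maps, "metrics": metrics}
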