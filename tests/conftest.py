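"""Shared fixtures: small synthetic scenes for unit tests and one full
stage series for the end-to-end recovery checks."""

from __future__ import annotations

import numpy as np
import pytest

import axonquant as aq

STAGES = ["baseline", "d3", "d6", "d9", "d12"]


@pytest.fixture(scope="session")
def run_config() -> aq.RunConfig:
    return aq.RunConfig(seed=1)


@pytest.fixture
def small_spec() -> aq.SceneSpec:
    """A cheap scene (3 tracks, ~120 um of nerve) for generator unit tests."""
    return aq.SceneSpec(
        stage="baseline",
        field_size_um=(24.0, 60.0, 120.0),
        n_tracks=3,
        seed=42,
    )


@pytest.fixture(scope="session")
def stage_runs(run_config):
    """Full-pipeline scores per stage at the default study conditions.

    Generated once per session; each entry is
    ``(planted_fraction, [LengthScore, ...])`` for 32 ROIs.
    """
    runs = {}
    for i, stage in enumerate(STAGES):
        spec = aq.scene_for_stage(stage, seed=1 + i)
        volume, gt = aq.generate_nerve_volume(spec)
        scores = aq.score_volume(volume, run_config, seed=1 + i)
        runs[stage] = (gt.planted_long_fraction, scores)
    return runs
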