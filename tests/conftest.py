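"""Shared fixtures: rendered flies with their full analysis context.

Rendering and analysing a fly takes a few seconds, so the fixtures are
session-scoped and shared across test modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from flywalk import bodyseg, frameqc, headmetrics
from flywalk.config import PipelineConfig
from flywalk.synthio import FlyGroundTruth, RenderConfig, render_sequence, sample_fly


@dataclass
class AnalyzedFly:
    truth: FlyGroundTruth
    seq: object
    valid: list
    model: object
    stack: object
    blue_al: np.ndarray
    red_al: np.ndarray
    brightest: int


def _analyze(seed_fly: int, seed_render: int, sex: str) -> AnalyzedFly:
    truth = sample_fly(seed_fly, sex=sex)
    seq = render_sequence(truth, RenderConfig(n_frames=5, seed=seed_render))
    results = frameqc.validate_sequence(seq)
    valid = [i for i, r in enumerate(results) if r.valid]
    model, stack = bodyseg.build_body_model(seq, valid)
    red_al = bodyseg.align_channel(seq, "red", stack, valid)
    blue_al = bodyseg.align_channel(seq, "blue", stack, valid)
    brightest = headmetrics.select_brightest_red_frame(red_al)
    return AnalyzedFly(
        truth=truth,
        seq=seq,
        valid=valid,
        model=model,
        stack=stack,
        blue_al=blue_al,
        red_al=red_al,
        brightest=brightest,
    )


@pytest.fixture(scope="session")
def female_fly() -> AnalyzedFly:
    return _analyze(101, 201, "female")


@pytest.fixture(scope="session")
def male_fly() -> AnalyzedFly:
    return _analyze(102, 202, "male")


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()
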