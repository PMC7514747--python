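"""Shared fixtures.

The full learning+fusion pipeline is expensive, so one desk-scale phantom
pair (96x96) is trained and fused once per session and shared by the fusion
and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from dictfuse import (
    FusionConfig,
    PhantomSpec,
    fuse,
    learn_fusion_dictionary,
    make_pair,
)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@dataclass
class PipelineRun:
    a: np.ndarray
    b: np.ndarray
    reference: np.ndarray
    cfg: FusionConfig
    dictionary: object
    fused: np.ndarray
    codes: object


@pytest.fixture(scope="session")
def pipeline_run() -> PipelineRun:
    """Train on a 96x96 phantom pair and fuse it (online-learning mode)."""
    cfg = FusionConfig(rng_seed=11)
    a, b, reference = make_pair(PhantomSpec(size=(96, 96), seed=11))
    dictionary = learn_fusion_dictionary([a, b], cfg)
    fused, codes = fuse([a, b], dictionary, cfg, return_codes=True)
    return PipelineRun(
        a=a,
        b=b,
        reference=reference,
        cfg=cfg,
        dictionary=dictionary,
        fused=fused,
        codes=codes,
    )
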