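"""Shared fixtures: tiny phantom cohorts and miniature networks."""

from __future__ import annotations

import numpy as np
import pytest

from qsmseg.config import demo_tiny_config
from qsmseg.phantom import generate_cohort, generate_subject


@pytest.fixture(scope="session")
def demo_cfg():
    return demo_tiny_config(seed=1)


@pytest.fixture(scope="session")
def tiny_subject(demo_cfg):
    """One reduced-grid target-domain phantom subject (volume, labels)."""
    return generate_subject(demo_cfg.target_phantom, 0)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory, demo_cfg):
    """Three reduced-grid target-domain subjects written to disk."""
    out = tmp_path_factory.mktemp("tiny_cohort")
    catalog = generate_cohort(demo_cfg.target_phantom, 3, seed=0, out_dir=out)
    return catalog


@pytest.fixture()
def rng():
    return np.random.default_rng(20240214)
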