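"""Shared fixtures: small gold-standard ensembles reused across tests.

The session-scoped sweep is deliberately modest (12 parents, 7 coverage
levels, one seed) so the whole suite stays fast; the acceptance script
runs the full-size ensembles.
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest

import recon


@pytest.fixture(scope="session")
def calibration_sweep():
    """Gold-standard sweep spanning 0.01x-10x coverage for profile tests."""
    specs = []
    for D in (1000, 10000):
        specs += [
            recon.ParentSpec(family="exponential", s=s, D=D, N=10**9)
            for s in (0.02, 0.05, 0.1, 0.2)
        ]
        specs += [
            recon.ParentSpec(family="bimodal", size_ratio=r, D=D, N=10**9)
            for r in (20, 30)
        ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = recon.run_validation_sweep(
            specs, [0.01, 0.03, 0.1, 0.3, 1, 3, 10], seeds=[0, 1]
        )
    ok = df[df["error"] == ""].copy()
    ok["prop_err"] = (ok["est_q0"] - ok["true_q0"]).abs() / ok["true_q0"]
    return ok


@pytest.fixture(scope="session")
def uniform_parent():
    """A 2,000-clone parent with all clones the same size."""
    return recon.CloneSizeDistribution({500_000: 2000})


def make_exponential(s: float, D: int) -> recon.CloneSizeDistribution:
    return recon.make_parent(
        recon.ParentSpec(family="exponential", s=s, D=D, N=10**9)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
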