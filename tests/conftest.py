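"""Shared fixtures.

The full-scale replicate runs (30 per hypothesis, default parameters) are
expensive, so they are produced once per session and shared by every test
that needs trajectory-level output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import recellsim as r


@pytest.fixture(scope="session")
def full_runs() -> dict[int, pd.DataFrame]:
    """30 replicate runs per hypothesis at the default study conditions
    (30,000 seeds, 95% engraftment, 32^3 lattice, 80 steps, records every 10
    steps on 30 interior z-slices, CVHV included)."""
    out = {}
    for hyp, label in ((1, "hypothesis1"), (2, "hypothesis2")):
        out[hyp] = r.run_replicates(label, n_replicates=30, seed=1000 + hyp)
    return out


@pytest.fixture()
def small_config() -> r.SimConfig:
    """A desk-size engine configuration for unit-level behavior tests."""
    return r.SimConfig(
        grid_size=12, n_cells=400, n_steps=10, record_every=5,
        n_slices=12, record_cvhv=False,
    )


class ScriptedRNG:
    """Deterministic stand-in for a Generator: replays scripted draws, and
    falls back to a real seeded generator for anything unscripted."""

    def __init__(self, uniforms=None, integers=None, normals=None, seed=0):
        self._uniform = list(uniforms or [])
        self._integers = list(integers or [])
        self._normal = list(normals or [])
        self._rng = np.random.default_rng(seed)

    def uniform(self, low=0.0, high=1.0, size=None):
        if self._uniform:
            return np.asarray(self._uniform.pop(0)) if size else self._uniform.pop(0)
        return self._rng.uniform(low, high, size)

    def integers(self, low, high=None, size=None):
        if self._integers:
            return self._integers.pop(0)
        return self._rng.integers(low, high, size)

    def normal(self, loc=0.0, scale=1.0, size=None):
        if self._normal:
            return np.asarray(self._normal.pop(0))
        return self._rng.normal(loc, scale, size)

    def permutation(self, x):
        return self._rng.permutation(x)

    def choice(self, *a, **k):
        return self._rng.choice(*a, **k)


@pytest.fixture()
def scripted_rng_cls():
    return ScriptedRNG
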