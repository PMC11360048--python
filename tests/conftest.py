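"""Shared fixtures: toy systems and reusable synthetic runs.

The expensive flat-sampling runs are session-scoped and shared between
unit and acceptance tests; every fixture is seeded, so the suite is
deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from crystalign import pipeline as pl
from crystalign import synthgen as sg
from crystalign.alignment import slab_molecule_geometry
from crystalign.config import RunConfig


@pytest.fixture(scope="session")
def toy_system():
    return sg.build_toy_slab(sg.SynthParams())


@pytest.fixture(scope="session")
def flat_run_medium():
    """Converged-sampling run, 2.5e5 frames (500 ps of toy dynamics)."""
    params = sg.SynthParams(n_steps=2_000_000, prefill=True, meta_height=0.0)
    return sg.run_biased_walker(params, seed=42)


@pytest.fixture(scope="session")
def flat_run_big():
    """Converged-sampling run at reference scale: 5e5 frames, 3750 ps."""
    params = sg.SynthParams(
        n_steps=15_000_000, save_stride=30, prefill=True, meta_height=0.0
    )
    return sg.run_biased_walker(params, seed=11)


def run_geometry(run: sg.SynthRun) -> pl.FrameGeometry:
    sys_ = run.system
    sol = sys_.solute_coords(run.rotations, run.positions)
    return pl.solute_geometry(
        sol, sys_.rings_template, sys_.masses[sys_.solute_atoms]
    )


def analyze_run(run: sg.SynthRun, config: RunConfig | None = None) -> pl.AnalysisResult:
    sys_ = run.system
    geom = run_geometry(run)
    slab_geom = slab_molecule_geometry(
        sys_.ref_xyz, sys_.slab, sys_.rings_template, sys_.masses
    )
    return pl.analyze(
        geom, run.cv, run.bias, sys_.slab, slab_geom, config or RunConfig()
    )


@pytest.fixture(scope="session")
def analysis_medium(flat_run_medium):
    return analyze_run(flat_run_medium)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
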