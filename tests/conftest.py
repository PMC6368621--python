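"""Shared fixtures: the default 20-mer retraction is computed once per session."""

import numpy as np
import pytest

import cryopeel as cp


@pytest.fixture(scope="session")
def default_run():
    """Full default retraction of the folded 20-mer (the reference study
    conditions), with conformation snapshots for geometry checks."""
    chain = cp.build_chain(20, 0.63, seed=1)
    surface = cp.SurfaceModel()
    tip = cp.TipModel()
    raw, snapshots = cp.retract(
        chain, surface, tip, z_max=13.5, dz=0.002, seed=1, snapshot_every=250
    )
    trace = cp.stiffness_from_force(cp.smooth_force(raw, 0.02))
    return {
        "chain": chain,
        "surface": surface,
        "tip": tip,
        "raw": raw,
        "trace": trace,
        "snapshots": snapshots,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
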