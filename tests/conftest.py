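import logging

import numpy as np
import pytest

import lingerlab as ll

logging.getLogger("lingerlab").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def geom():
    return ll.make_default_geometry()


@pytest.fixture(scope="session")
def small_experiment():
    """60-cell synthetic acquisition shared by read-only tests."""
    cfg = ll.SyntheticConfig(n_rbc=60, gamma_true=0.15, seed=42)
    table, truth = ll.generate_experiment(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def medium_experiment():
    """400-cell acquisition at the reference lingering fraction."""
    cfg = ll.SyntheticConfig(n_rbc=400, gamma_true=0.11, seed=7)
    table, truth = ll.generate_experiment(cfg)
    return cfg, table, truth


def make_trajectory(rbc_id, xy, u=None, frame0=0):
    """Hand-built trajectory from an (n, 2) position list (um)."""
    xy = np.asarray(xy, dtype=float)
    if u is None:
        u = np.full(len(xy), 0.5)
    return ll.Trajectory(
        rbc_id=rbc_id,
        frame=frame0 + np.arange(len(xy)),
        x=xy[:, 0],
        y=xy[:, 1],
        u=np.asarray(u, dtype=float),
    )
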