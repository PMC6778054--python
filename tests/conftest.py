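"""Shared fixtures: seeded phantoms at several sizes.

Expensive phantoms are session-scoped so the whole suite renders each
condition once.  All seeds are fixed constants.
"""

from __future__ import annotations

import numpy as np
import pytest

from fibgold.synthetic import PhantomSpec, generate_phantom


def match_particles(detected, truth, spacing=(90.0, 10.0, 10.0)):
    """Greedy one-to-one matching within one voxel per axis, same section.

    Returns (n_matched, recall, precision).
    """
    dz, dy, dx = spacing
    tp = 0
    for z in sorted(set(np.rint(truth["z_nm"] / dz).astype(int))):
        g = truth[np.rint(truth["z_nm"] / dz).astype(int) == z]
        d = detected[np.rint(detected["z_nm"] / dz).astype(int) == z]
        if len(g) == 0 or len(d) == 0:
            continue
        gy = g[["y_nm", "x_nm"]].to_numpy()
        pairs = []
        for yy, xx in d[["y_nm", "x_nm"]].to_numpy():
            dev = np.maximum(np.abs(gy[:, 0] - yy) / dy, np.abs(gy[:, 1] - xx) / dx)
            i = int(np.argmin(dev))
            pairs.append((dev[i], i))
        used = set()
        for dev, i in sorted(pairs):
            if dev <= 1.0 and i not in used:
                used.add(i)
                tp += 1
    recall = tp / len(truth) if len(truth) else float("nan")
    precision = tp / len(detected) if len(detected) else float("nan")
    return tp, recall, precision


@pytest.fixture(scope="session")
def small_spec():
    """Small drift-free nucleus used by fast unit tests."""
    return PhantomSpec(
        grid_shape=(16, 160, 160),
        nucleus_axes=(450.0, 450.0, 400.0),
        n_particles=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def standard_spec():
    """The standard detection phantom: 300 spots, no drift."""
    return PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def standard_phantom(standard_spec):
    return generate_phantom(standard_spec)


@pytest.fixture(scope="session")
def invagination_spec():
    """The full-workflow phantom: invaginations, association, drift."""
    return PhantomSpec(
        n_invaginations=5, invagination_fraction=0.4, drift_sigma=2.0, seed=0
    )


@pytest.fixture(scope="session")
def invagination_phantom(invagination_spec):
    return generate_phantom(invagination_spec)


@pytest.fixture(scope="session")
def invagination_analysis(invagination_phantom):
    """Full pipeline result on the invagination phantom (computed once)."""
    from fibgold.pipeline import PipelineConfig, analyze_stack

    grid, gt = invagination_phantom
    return analyze_stack(grid, PipelineConfig(save_volumes=False)), gt
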