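"""Shared fixtures: small designs and phantoms reused across test modules.

Phantom volumes are session-scoped because voxelization dominates test
runtime; tests must not mutate them in place.
"""

import numpy as np
import pytest

from mgscaffold.geometry import (
    ScaffoldDesign,
    build_design,
    straight_strut_graph,
)
from mgscaffold import phantom as ph


@pytest.fixture(scope="session")
def small_design() -> ScaffoldDesign:
    """Two-ring device: full topology at a fraction of the voxel cost."""
    return ScaffoldDesign(n_rings=2, ring_pitch=1.4, crown_amplitude=0.55)


@pytest.fixture(scope="session")
def small_graph(small_design):
    return build_design(small_design)


@pytest.fixture(scope="session")
def small_labels(small_graph) -> ph.LabelVolume:
    return ph.voxelize(small_graph, spacing=0.02)


@pytest.fixture(scope="session")
def strut_design() -> ScaffoldDesign:
    """Narrow-bore design so straight-strut volumes stay small."""
    return ScaffoldDesign(n_rings=1, nominal_diameter=0.8, crown_amplitude=0.2,
                          ring_pitch=1.0)


def make_strut_volume(design, spacing, phase=(0.0, 0.0), length=2.0):
    """Axis-centered straight strut with a controlled grid phase; the strut
    spans the whole z extent so the no-end-loss assumption of the area law
    holds."""
    graph = straight_strut_graph(design=design, length=length)
    vol = ph.voxelize(
        graph,
        spacing=spacing,
        pad=0.0,
        tissue_outer_margin=0.0,
        origin_shift=(phase[0], phase[1], 0.0),
    )
    return graph, vol


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240722)
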