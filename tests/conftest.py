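"""Shared fixtures: analytic tube stacks and the (expensive) default AAA study.

The heavy session fixtures (pre-stressed default aneurysm, paired FSI arms)
are computed once and shared between the module tests and the acceptance
suite; problem sizes are the package's coarse desk-scale defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

from aaafsi import geometry as geo
from aaafsi import hemodynamics as hemo
from aaafsi import wall_fem as wall
from aaafsi import pipeline as pl


def make_tube_stack(radius: float = 10.0, length: float = 100.0, n: int = 21) -> geo.ContourStack:
    """Straight circular tube along z, native span covering the whole tube."""
    zs = np.linspace(0.0, length, n)
    contours = [
        geo.Contour(np.array([0.0, 0.0, z]), radius, radius, np.array([0.0, 0.0, 1.0]), 0.0, z)
        for z in zs
    ]
    return geo.ContourStack(contours, spacing=length / (n - 1), native_span=(0.0, length))


@pytest.fixture(scope="session")
def thick_tube_mesh():
    """Short thick-walled tube: inner radius 10 mm, outer 12 mm."""
    stack = make_tube_stack(radius=10.0, length=20.0, n=5)
    surf = geo.build_lumen_surface(stack, target_edge=2.5)
    return geo.extrude_wall_mesh(surf, thickness=2.0, layers=2)


@pytest.fixture(scope="session")
def study_config() -> pl.RunConfig:
    """Desk-scale default study: moderate fusiform AAA, cohort-average BP."""
    return pl.RunConfig(seed=1, dt=0.01, n_cycles=3, target_edge=7.0)


@pytest.fixture(scope="session")
def study_context(study_config) -> pl.PipelineContext:
    """Meshes, material, BIM pre-stress and tuned Windkessels (built once)."""
    return pl.build_context(study_config)


@pytest.fixture(scope="session")
def paired_arms(study_context):
    """Both FSI arms of the default study (the expensive shared computation)."""
    res_pse = pl.run_arm(study_context, "pse")
    res_nopse = pl.run_arm(study_context, "nopse")
    return res_pse, res_nopse
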