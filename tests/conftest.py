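"""Shared fixtures: phantoms and solvers at two mesh densities.

The default phantom (5 mm target edge) is the study-condition mesh; the
coarse phantom (10 mm) keeps Monte-Carlo style tests affordable.
"""

from __future__ import annotations

import numpy as np
import pytest

from facefem.fem_core import ViscoelasticSolver, midrange_inputs
from facefem.phantom import GeometryParams, build_phantom


@pytest.fixture(scope="session")
def phantom_default():
    mesh, landmarks = build_phantom()
    return mesh, landmarks


@pytest.fixture(scope="session")
def solver_default(phantom_default):
    mesh, _ = phantom_default
    return ViscoelasticSolver(mesh)


@pytest.fixture(scope="session")
def phantom_coarse():
    mesh, landmarks = build_phantom(GeometryParams(edge_length=8.0))
    return mesh, landmarks


@pytest.fixture(scope="session")
def solver_coarse(phantom_coarse):
    mesh, _ = phantom_coarse
    return ViscoelasticSolver(mesh)


@pytest.fixture(scope="session")
def midrange():
    return midrange_inputs()


@pytest.fixture(scope="session")
def landmark_solution_default(phantom_default, solver_default, midrange):
    """Midrange-input landmark displacements on the default phantom."""
    from facefem.fem_core import extract_landmarks

    _, landmarks = phantom_default
    field = solver_default.solve(midrange)
    return extract_landmarks(field, landmarks)
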