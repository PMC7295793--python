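"""Shared fixtures: a small phantom realization and its kinematics products.

Everything is generated programmatically at test time; session scope keeps
the expensive products (analytic truth, finite-difference kinematics) shared
across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrspiro import kinematics, phantom
from mrspiro.grid_io import ImageGrid


@pytest.fixture(scope="session")
def small_spec() -> phantom.PhantomSpec:
    """Normal-breathing phantom on a coarse isotropic grid, 16 bins."""
    return phantom.PhantomSpec.preset(
        "normal",
        grid=ImageGrid((32, 32, 32), (6.0, 6.0, 6.0)),
        n_bins=16,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """(displacement field, analytic truth) for the small phantom."""
    return phantom.make_displacement(small_spec)


@pytest.fixture(scope="session")
def small_kinematics(small_phantom):
    """Finite-difference kinematics products of the small phantom."""
    u, truth = small_phantom
    F = kinematics.deformation_gradient(u, truth.mask)
    J = kinematics.jacobian(F)
    strain = kinematics.green_lagrange(F)
    principal = kinematics.principal_strains(strain)
    fa = kinematics.fractional_anisotropy(principal)
    return {"F": F, "J": J, "strain": strain, "principal": principal, "fa": fa}


@pytest.fixture(scope="session")
def random_tensors() -> np.ndarray:
    """1000 random moderate deformation gradients F = I + 0.3 * U(-1, 1)."""
    rng = np.random.default_rng(42)
    return np.eye(3) + 0.3 * rng.uniform(-1, 1, size=(1000, 3, 3))
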