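"""Deformation-gradient, strain, FA and smoothing: oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrspiro import kinematics, phantom
from mrspiro.grid_io import DisplacementField4D, ImageGrid, LungMask
from mrspiro.kinematics import (
    DeformationGradientField,
    StrainField,
    check_small_strain,
    deformation_gradient,
    fractional_anisotropy,
    green_lagrange,
    jacobian,
    principal_strains,
    smooth_fields_temporally,
)

# ---------------------------------------------------------------------------
# independent naive oracles
# ---------------------------------------------------------------------------

def det3_cofactor(m):
    """Brute-force cofactor expansion of a 3x3 determinant."""
    return (
        m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
        - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
        + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0])
    )


def eigvals_cardano(a):
    """Closed-form (trigonometric Cardano) eigenvalues of a symmetric 3x3."""
    p1 = a[0, 1] ** 2 + a[0, 2] ** 2 + a[1, 2] ** 2
    q = np.trace(a) / 3
    if p1 == 0:
        return np.sort(np.diag(a))[::-1]
    p2 = sum((a[i, i] - q) ** 2 for i in range(3)) + 2 * p1
    p = np.sqrt(p2 / 6)
    B = (a - q * np.eye(3)) / p
    r = np.clip(det3_cofactor(B) / 2, -1.0, 1.0)
    phi = np.arccos(r) / 3
    e1 = q + 2 * p * np.cos(phi)
    e3 = q + 2 * p * np.cos(phi + 2 * np.pi / 3)
    e2 = 3 * q - e1 - e3
    return np.array([e1, e2, e3])


def fa_naive(lams):
    l1, l2, l3 = lams
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    return np.sqrt(num / (2 * (l1**2 + l2**2 + l3**2)))


def wrap_tensors(F):
    """Package a (n, 3, 3) tensor batch as a 1-bin field on a line grid."""
    n = F.shape[0]
    grid = ImageGrid((n, 1, 1), (1.0, 1.0, 1.0))
    mask = LungMask(grid=grid, membership=np.ones((n, 1, 1), bool))
    return DeformationGradientField(
        grid=grid,
        F=F.reshape(1, n, 1, 1, 3, 3),
        mask=mask,
        interior=np.ones((n, 1, 1), bool),
        partial_stencil=np.zeros((n, 1, 1), bool),
    )


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def make_field(grid, us):
    return DisplacementField4D(grid=grid, u=np.stack(us), reference_bin=0)


class TestDeformationGradient:
    def test_zero_displacement_gives_identity(self):
        grid = ImageGrid((8, 8, 8), (2.0, 2.0, 2.0))
        mask = LungMask(grid=grid, membership=np.ones(grid.shape, bool))
        u = make_field(grid, [np.zeros(grid.shape + (3,))] * 3)
        F = deformation_gradient(u, mask)
        assert np.allclose(F.F, np.eye(3), atol=1e-15)

    def test_uniform_expansion_exact_everywhere(self):
        grid = ImageGrid((10, 9, 8), (2.0, 1.5, 3.0), origin=(-4.0, 0.0, 1.0))
        mask = LungMask(grid=grid, membership=np.ones(grid.shape, bool))
        X, Y, Z = grid.coordinates()
        u1 = 0.1 * np.stack([X, Y, Z], axis=-1)
        u = make_field(grid, [np.zeros_like(u1), u1, 2 * u1])
        F = deformation_gradient(u, mask)
        assert np.allclose(F.F[1], 1.1 * np.eye(3), atol=1e-12)
        assert np.allclose(F.F[2], 1.2 * np.eye(3), atol=1e-12)

    def test_thin_mask_rejected(self):
        grid = ImageGrid((8, 8, 8), (2.0, 2.0, 2.0))
        m = np.zeros(grid.shape, bool)
        m[:, :, 3] = True  # one voxel thick along z
        mask = LungMask(grid=grid, membership=m)
        u = make_field(grid, [np.zeros(grid.shape + (3,))] * 3)
        with pytest.raises(ValueError, match="thinner"):
            deformation_gradient(u, mask)

    def test_boundary_voxels_flagged(self, small_kinematics, small_phantom):
        F = small_kinematics["F"]
        _, truth = small_phantom
        assert F.partial_stencil.any()
        assert not (F.interior & F.partial_stencil).any()
        assert np.array_equal(F.interior | F.partial_stencil, truth.mask.membership)

    def test_second_order_convergence_against_truth(self):
        """Finite-difference error vs the analytic phantom shrinks ~4x per refinement."""
        errs = []
        for n in (16, 32):
            spacing = 186.0 / (n - 1)
            spec = phantom.PhantomSpec.preset(
                "normal", grid=ImageGrid((n, n, n), (spacing,) * 3), n_bins=4
            )
            u, truth = phantom.make_displacement(spec)
            F = deformation_gradient(u, truth.mask)
            k = 2  # end-inspiration
            F00, F20, F22 = phantom._gradient_entries(spec, truth.timing.times[k])
            F_true = np.zeros(spec.grid.shape + (3, 3))
            F_true[..., 0, 0] = F00
            F_true[..., 1, 1] = 1.0
            F_true[..., 2, 2] = F22
            F_true[..., 2, 0] = F20
            errs.append(np.max(np.abs(F.F[k] - F_true)[F.interior]))
        ratio = errs[0] / errs[1]
        assert 2.5 < ratio < 6.5  # h ratio ~2.07 -> error ratio ~4.3


class TestTensorOps:
    def test_jacobian_simple_cases(self):
        F = np.stack([np.eye(3), np.diag([1.1, 1.0, 1.1])])
        J = jacobian(wrap_tensors(F))
        np.testing.assert_allclose(J.J.ravel(), [1.0, 1.21])
        assert not J.folding_mask.any()

    def test_folding_flagged_not_hidden(self):
        F = np.stack([np.eye(3), np.diag([-0.5, 1.0, 1.0])])
        J = jacobian(wrap_tensors(F))
        assert J.folding_mask.ravel()[1]

    def test_det_matches_cofactor_oracle(self, random_tensors):
        J = jacobian(wrap_tensors(random_tensors)).J.ravel()
        oracle = np.array([det3_cofactor(f) for f in random_tensors])
        np.testing.assert_allclose(J, oracle, atol=1e-12)

    def test_green_lagrange_cases(self):
        F = np.stack([np.eye(3), np.diag([1.1, 1.0, 1.0])])
        eps = green_lagrange(wrap_tensors(F)).eps.reshape(2, 3, 3)
        np.testing.assert_allclose(eps[0], 0.0, atol=1e-15)
        np.testing.assert_allclose(eps[1, 0, 0], 0.105)
        assert np.all(eps[1][~np.eye(3, dtype=bool)] == 0)

    def test_rotation_produces_zero_strain(self):
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        eps = green_lagrange(wrap_tensors(R[None])).eps
        np.testing.assert_allclose(eps, 0.0, atol=1e-14)

    def test_principal_strain_oracles(self, random_tensors):
        field = wrap_tensors(random_tensors)
        strain = green_lagrange(field)
        p = principal_strains(strain)
        vals = p.eps_principal.reshape(-1, 3)
        lams = p.lam.reshape(-1, 3)
        eps_flat = strain.eps.reshape(-1, 3, 3)
        for i in range(0, 1000, 7):
            np.testing.assert_allclose(
                vals[i], eigvals_cardano(eps_flat[i]), atol=1e-10
            )
        # stretch ratios are the singular values of F, all 1000 samples
        sv = np.linalg.svd(random_tensors, compute_uv=False)
        np.testing.assert_allclose(lams, sv, atol=1e-8)
        # descending order and trace invariance
        assert np.all(np.diff(vals, axis=1) <= 1e-12)
        np.testing.assert_allclose(
            vals.sum(axis=1), np.trace(eps_flat, axis1=1, axis2=2), atol=1e-10
        )

    def test_eigenvectors_orthonormal(self, random_tensors):
        p = principal_strains(green_lagrange(wrap_tensors(random_tensors)))
        V = p.eigvec.reshape(-1, 3, 3)
        gram = np.einsum("nij,nik->njk", V, V)
        assert np.allclose(gram, np.eye(3), atol=1e-10)

    def test_nonphysical_flagged_not_clamped(self):
        eps = np.zeros((1, 1, 1, 1, 3, 3))
        eps[..., 2, 2] = -0.6  # 1 + 2 eps = -0.2
        strain = StrainField(grid=ImageGrid((1, 1, 1), (1.0, 1.0, 1.0)), eps=eps)
        p = principal_strains(strain)
        assert p.nonphysical.all()
        assert np.isnan(p.lam[..., 2]).all()
        assert p.nonphysical_report()["count"] == 1

    def test_fa_oracle_values(self, random_tensors):
        p = principal_strains(green_lagrange(wrap_tensors(random_tensors)))
        fa = fractional_anisotropy(p).FA.ravel()
        lams = p.lam.reshape(-1, 3)
        oracle = np.array([fa_naive(l) for l in lams])
        np.testing.assert_allclose(fa, oracle, atol=1e-10)

    def test_fa_point_cases(self):
        # isotropic stretch -> 0; lambda = (1.2, 1, 1) -> sqrt(0.08/6.88)
        F = np.stack([1.3 * np.eye(3), np.diag([1.2, 1.0, 1.0])])
        fa = fractional_anisotropy(
            principal_strains(green_lagrange(wrap_tensors(F)))
        ).FA.ravel()
        assert fa[0] == pytest.approx(0.0, abs=1e-12)
        assert fa[1] == pytest.approx(np.sqrt(0.08 / 6.88), abs=1e-12)

    @given(
        st.tuples(
            st.floats(0.2, 3.0), st.floats(0.2, 3.0), st.floats(0.2, 3.0)
        )
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_fa_bounded_for_valid_stretches(self, lams):
        fa = fa_naive(np.sort(lams)[::-1])
        assert 0.0 <= fa <= 1.0
        # module agrees with the direct formula
        eps = np.diag([(l**2 - 1) / 2 for l in lams])
        p = principal_strains(
            StrainField(
                grid=ImageGrid((1, 1, 1), (1.0, 1.0, 1.0)),
                eps=eps.reshape(1, 1, 1, 1, 3, 3),
            )
        )
        val = fractional_anisotropy(p).FA.ravel()[0]
        assert val == pytest.approx(fa, abs=1e-10)


class TestObjectivity:
    def test_quarter_turn_equivariance(self, small_spec):
        """Rotating the phantom rigidly permutes maps but leaves J and FA values."""
        spec = small_spec
        u, truth = phantom.make_displacement(spec)
        F = deformation_gradient(u, truth.mask)
        J = jacobian(F).J
        fa = fractional_anisotropy(
            principal_strains(green_lagrange(F))
        ).FA

        # rotate 90 degrees about y: (x, z) -> (z, -x); exact on a cube grid
        rot_u = np.rot90(u.u, k=1, axes=(1, 3))
        u_rot = np.empty_like(rot_u)
        u_rot[..., 0] = -rot_u[..., 2]
        u_rot[..., 1] = rot_u[..., 1]
        u_rot[..., 2] = rot_u[..., 0]
        mask_rot = LungMask(
            grid=spec.grid,
            membership=np.ascontiguousarray(
                np.rot90(truth.mask.membership, k=1, axes=(0, 2))
            ),
        )
        field_rot = DisplacementField4D(grid=spec.grid, u=u_rot, reference_bin=0)
        F2 = deformation_gradient(field_rot, mask_rot)
        J2 = jacobian(F2).J
        fa2 = fractional_anisotropy(
            principal_strains(green_lagrange(F2))
        ).FA
        np.testing.assert_allclose(J2, np.rot90(J, k=1, axes=(1, 3)), atol=1e-10)
        np.testing.assert_allclose(fa2, np.rot90(fa, k=1, axes=(1, 3)), atol=1e-8)


class TestPhantomPipeline:
    def test_jacobian_accuracy_and_volume_bookkeeping(
        self, small_phantom, small_kinematics
    ):
        u, truth = small_phantom
        F = small_kinematics["F"]
        J = small_kinematics["J"]
        err = np.abs(J.J[:, F.interior] - truth.J_true[:, F.interior])
        assert err.max() < 0.01
        # mean J over mask * reference volume tracks V_true to < 0.5%
        m = truth.mask.membership
        v0 = truth.mask.n_voxels * u.grid.voxel_volume_mm3
        V_num = J.J[:, m].mean(axis=1) * v0
        np.testing.assert_allclose(V_num, truth.V_true, rtol=5e-3)

    def test_monotone_jacobian_through_phases(self, small_phantom, small_kinematics):
        u, truth = small_phantom
        J = small_kinematics["J"].J
        m = truth.mask.membership
        n = u.n_bins
        peak = n // 2
        insp = J[: peak + 1, m]
        exp = J[peak:, m]
        assert np.all(np.diff(insp, axis=0) > 0)
        assert np.all(np.diff(exp, axis=0) < 0)
        assert np.all(J[-1][m] > J[0][m])  # still deflating toward wrap

    def test_small_strain_residual_quadratic_in_amplitude(self):
        maxima = []
        for scale in (1.0, 0.5):
            spec = phantom.PhantomSpec.preset(
                "normal",
                grid=ImageGrid((24, 24, 24), (8.0, 8.0, 8.0)),
                n_bins=4,
            )
            spec = phantom.PhantomSpec(
                grid=spec.grid,
                n_bins=4,
                amplitude_si=spec.amplitude_si * scale,
                amplitude_ap=spec.amplitude_ap * scale,
            )
            u, truth = phantom.make_displacement(spec)
            F = deformation_gradient(u, truth.mask)
            rep = check_small_strain(jacobian(F), green_lagrange(F), F.interior)
            maxima.append(rep.quantiles["max"].max())
        assert maxima[1] <= 0.3 * maxima[0]

    def test_small_strain_zero_for_zero_strain(self):
        F = wrap_tensors(np.eye(3)[None])
        rep = check_small_strain(jacobian(F), green_lagrange(F))
        assert rep.residual.max() == 0.0


class TestTemporalSmoothing:
    def grid_field(self, y):
        """(n_bins,) series replicated on a tiny grid as the x-displacement."""
        grid = ImageGrid((4, 4, 4), (1.0, 1.0, 1.0))
        u = np.zeros((y.size,) + grid.shape + (3,))
        u[..., 0] = y.reshape(-1, 1, 1, 1)
        u -= u[0]
        return DisplacementField4D(grid=grid, u=u, reference_bin=0)

    def test_zero_smoothing_is_identity(self):
        y = np.sin(2 * np.pi * np.arange(16) / 16)
        f = self.grid_field(y)
        out = smooth_fields_temporally(f, 0.0)
        np.testing.assert_array_equal(out.u, f.u)

    def test_constant_preserved(self):
        f = self.grid_field(np.zeros(16))
        u = f.u.copy()
        u[..., 1] = 2.5
        u -= u[0]
        f2 = DisplacementField4D(grid=f.grid, u=u, reference_bin=0)
        out = smooth_fields_temporally(f2, 10.0)
        np.testing.assert_allclose(out.u, f2.u, atol=1e-12)

    @pytest.mark.parametrize("s", [0.5, 2.0, 10.0])
    def test_noise_suppressed_on_periodic_signal(self, s):
        rng = np.random.default_rng(0)
        n = 32
        clean = np.sin(2 * np.pi * np.arange(n) / n)
        noisy = clean + 0.15 * rng.normal(size=n)
        f = self.grid_field(noisy)
        out = smooth_fields_temporally(f, s)
        series = out.u[:, 2, 2, 2, 0]
        clean_c = clean - clean[0]
        noisy_c = noisy - noisy[0]
        assert np.sqrt(np.mean((series - clean_c) ** 2)) < np.sqrt(
            np.mean((noisy_c - clean_c) ** 2)
        )

    def test_reference_bin_zero_reimposed(self):
        rng = np.random.default_rng(1)
        f = self.grid_field(rng.normal(size=16))
        out = smooth_fields_temporally(f, 3.0)
        np.testing.assert_array_equal(out.u[0], 0.0)

    def test_gcv_picks_finite_penalty(self):
        rng = np.random.default_rng(2)
        n = 32
        clean = np.sin(2 * np.pi * np.arange(n) / n)
        f = self.grid_field(clean + 0.2 * rng.normal(size=n))
        out = smooth_fields_temporally(f, "gcv")
        assert np.all(np.isfinite(out.u))
        assert not np.array_equal(out.u, f.u)
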