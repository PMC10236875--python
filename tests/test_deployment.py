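"""Contact solver: algebraic oracle, limits, conservation and determinism."""

import numpy as np
import pytest

import tavrsim as tv
from tavrsim.deployment import DeploymentConfig, DeploymentModel, extract_pressure
from tavrsim.errors import InvalidParameterError

from conftest import make_cylinder_params


def single_ring_setup(k_scale=1.0, free_diameter=29.0, plateau=60.0, knee=0.2):
    """A cylinder mesh and a 0.4 mm tall device covering exactly one ring."""
    params = make_cylinder_params(25.0)
    root = tv.generate_root(params)
    root.k_base *= k_scale
    dev = tv.THVDevice(
        model_name=f"ring-{k_scale}-{free_diameter}",
        size=29,
        frame_height=0.4,
        crimped_diameter=6.0,
        has_pericardial_wrap=False,
        profile=((0.0, free_diameter), (0.4, free_diameter)),
        plateau_n_per_mm=plateau,
        knee_fraction=knee,
    )
    cfg = DeploymentConfig(
        implantation_depth_target=0.2, convergence_tol=1e-9, n_retraction_steps=1
    )
    return root, dev, cfg


def ring_oracle(root, dev):
    """Closed-form 1-DOF equilibrium radius for a linear frame force segment.

    With frame force F(R) = a - b R (valid above the knee) balancing total
    wall stiffness k_r acting from rest radius r_w:  R* = (a + k_r r_w)/(b + k_r).
    """
    iz = int(np.argmin(np.abs(root.z)))
    k_r = root.k_base[iz, :].sum()
    D = dev.profile[0][1]
    knee_d = dev.knee_fraction * D
    b = 2.0 * dev.plateau_n_per_mm * root.dz / (D - knee_d)
    a = dev.plateau_n_per_mm * root.dz * D / (D - knee_d)
    r_w = root.radius[iz, 0]
    return (a + k_r * r_w) / (b + k_r)


class TestSingleRingEquilibrium:
    def test_solver_matches_algebraic_oracle(self):
        root, dev, cfg = single_ring_setup()
        res = DeploymentModel(root, dev, cfg).fit()
        assert res.frame.radius.size == 1
        r_star = ring_oracle(root, dev)
        assert res.frame.radius[0] == pytest.approx(r_star, abs=1e-6)

    def test_stiffer_wall_increases_contact_force(self):
        forces = []
        for k_scale in (0.5, 1.0, 2.0, 4.0):
            root, dev, cfg = single_ring_setup(k_scale=k_scale)
            res = DeploymentModel(root, dev, cfg).fit()
            forces.append(res.field.total_force())
        assert all(a < b for a, b in zip(forces, forces[1:]))

    def test_oracle_tracks_wall_stiffness(self):
        for k_scale in (0.5, 2.0, 8.0):
            root, dev, cfg = single_ring_setup(k_scale=k_scale)
            res = DeploymentModel(root, dev, cfg).fit()
            assert res.frame.radius[0] == pytest.approx(ring_oracle(root, dev), abs=1e-6)


class TestDeployLimits:
    def test_undersized_device_gives_zero_contact(self, reference_root):
        res = tv.deploy(reference_root, tv.get_device("EvolutPRO-23"))
        assert res.field.total_force() == 0.0
        assert np.all(res.field.pressure == 0.0)
        assert res.converged
        assert res.iterations == 0

    def test_rigid_wall_frame_conforms_and_force_matches_curve(self):
        root = tv.generate_root(make_cylinder_params(25.0))
        root.k_base[:] = 1e7
        dev = tv.get_device("EvolutPRO-29")
        res = tv.deploy(root, dev, DeploymentConfig(implantation_depth_target=6.0))
        iz = int(np.argmin(np.abs(root.z + 3.0)))
        ring = int(np.where(res.frame.level_index == iz)[0][0])
        assert 2.0 * res.frame.radius[ring] == pytest.approx(25.0, abs=0.01)
        f_ring = res.field.nodal_force[iz, :].sum()
        f_curve = float(
            dev.radial_force(res.frame.ring_height[ring], 25.0) * root.dz
        )
        assert f_ring == pytest.approx(f_curve, rel=0.01)

    def test_frame_never_exceeds_free_diameter(self, reference_deployment):
        f = reference_deployment.frame
        assert np.all(f.radius <= f.free_radius + 1e-9)

    def test_non_overlapping_frame_rejected(self, reference_root):
        cfg = DeploymentConfig(implantation_depth_target=200.0)
        with pytest.raises(InvalidParameterError):
            DeploymentModel(reference_root, tv.get_device("EvolutPRO-29"), cfg)


class TestConservationAndDeterminism:
    def test_force_conservation_on_reference_solve(self, reference_deployment):
        field = reference_deployment.field
        lhs = float((field.pressure * field.element_area).sum())
        assert lhs == pytest.approx(field.total_force(), rel=1e-3)

    def test_oversize_monotonicity(self, reference_root):
        cpmaxes = []
        for name in ("EvolutPRO-23", "EvolutPRO-26", "EvolutPRO-29", "EvolutR-34"):
            res = tv.deploy(reference_root, tv.get_device(name))
            cpmaxes.append(res.conduction_metrics().cpmax)
        assert all(a <= b + 1e-12 for a, b in zip(cpmaxes, cpmaxes[1:]))

    def test_identical_inputs_bitwise_identical_outputs(self, reference_root, device29):
        a = tv.deploy(reference_root, device29)
        b = tv.deploy(reference_root, device29)
        assert np.array_equal(a.field.pressure, b.field.pressure)
        assert np.array_equal(a.frame.radius, b.frame.radius)


class TestExtractPressure:
    def test_zero_forces_zero_pressure(self, cylinder_root):
        field = extract_pressure(np.zeros_like(cylinder_root.radius), cylinder_root)
        assert np.all(field.pressure == 0.0)

    def test_uniform_force_gives_uniform_pressure(self, cylinder_root):
        f = np.ones_like(cylinder_root.radius)
        field = extract_pressure(f, cylinder_root)
        # away from the z-boundary rows the pressure equals force per area
        expected = f.sum() / cylinder_root.total_area()
        interior = field.pressure[1:-1, :]
        assert np.allclose(interior, interior.flat[0], rtol=1e-9)
        assert interior.flat[0] == pytest.approx(expected, rel=0.02)
        assert field.check_conservation(rtol=1e-9)

    def test_pressure_halves_when_area_doubles(self, cylinder_root):
        f = np.ones_like(cylinder_root.radius)
        a = extract_pressure(f, cylinder_root)
        scaled = cylinder_root.copy()
        scaled.element_area = 2.0 * scaled.element_area
        b = extract_pressure(f, scaled)
        assert np.allclose(b.pressure, a.pressure / 2.0)

    def test_shape_mismatch_rejected(self, cylinder_root):
        with pytest.raises(InvalidParameterError):
            extract_pressure(np.zeros((3, 3)), cylinder_root)


class TestMeshSensitivity:
    def test_identical_resolution_zero_change(self, reference_params, device29):
        def gen(level):
            root = tv.generate_root(reference_params, n_circ=level[0], dz=level[1])
            return tv.place_calcium(root, reference_params, seed=0)

        table = tv.mesh_sensitivity(
            gen, device29, levels=[(36, 1.0), (36, 1.0)]
        )
        assert table["rel_change_cpi"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
        assert table["rel_change_cpmax"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
        assert table.attrs["passed"]

    def test_cylinder_cpmax_approaches_ring_oracle_with_refinement(self):
        params = make_cylinder_params(25.0)
        dev = tv.get_device("EvolutPRO-29")
        cfg = DeploymentConfig(implantation_depth_target=6.0)
        errors = []
        for n_circ, dz in ((36, 1.0), (72, 0.5)):
            root = tv.generate_root(params, n_circ=n_circ, dz=dz)
            res = tv.deploy(root, dev, cfg)
            roi = tv.build_roi(root)
            cpmax = tv.compute_cpmax(res.field, roi)
            # interior equilibrium pressure: stiffness-density * penetration
            iz = int(np.argmin(np.abs(root.z + 3.0)))
            ring = int(np.where(res.frame.level_index == iz)[0][0])
            u = res.frame.radius[ring] - root.radius[iz, 0]
            k_density = root.k_base[iz, 0] / root.node_area[iz, 0]
            errors.append(abs(cpmax - k_density * u) / (k_density * u))
        assert errors[-1] < 0.05
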