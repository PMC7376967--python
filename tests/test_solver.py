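"""Finite-volume solver: assembly, oracles, conservation, quasi-static check."""

import numpy as np
import pytest

from iacskit.phantom import TissueProperties, VoxelPhantom
from iacskit.solver import (
    NonConvergenceError,
    SingularSystemError,
    analytic_point_source,
    assemble_from_contacts,
    check_quasistatic,
    fields_from_potential,
    solve,
    surface_current,
)
from iacskit.synth import toy_phantom


@pytest.fixture(scope="module")
def cube_solution():
    phantom, contacts, expected = toy_phantom("uniform_cube")
    system = assemble_from_contacts(phantom, contacts, 1e-4)
    potential = solve(system, method="direct")
    return phantom, contacts, expected, system, potential


class TestAssembly:
    def test_homogeneous_operator_is_scaled_laplacian(self):
        phantom, contacts, _ = toy_phantom("uniform_cube", sigma=2.0, size_mm=3.0, voxel_mm=1.0)
        system = assemble_from_contacts(phantom, contacts, 1e-4)
        A = system.matrix.tocoo()
        h = phantom.voxel_size_m
        offdiag = A.data[A.row != A.col]
        # every face coupling of the uniform medium is -sigma * h
        assert np.allclose(offdiag, -2.0 * h)
        rowsum = np.asarray(system.matrix.sum(axis=1)).ravel()
        nonzero = np.flatnonzero(np.abs(rowsum) > 1e-15 * 2.0 * h)
        # only rows adjacent to the eliminated gauge voxel keep a net diagonal excess
        assert 1 <= nonzero.size <= 6
        assert np.allclose(rowsum[nonzero], 2.0 * h)

    def test_interface_face_conductance_is_harmonic_mean(self):
        phantom, contacts, _ = toy_phantom(
            "layered_slab", sigmas=(1.0, 0.5), thickness_mm=(1.0, 1.0), voxel_mm=0.5, side_mm=0.5
        )
        system = assemble_from_contacts(phantom, contacts, 1e-4)
        h = phantom.voxel_size_m
        expected_g = 2.0 * 1.0 * 0.5 / (1.0 + 0.5) * h
        vals = -system.matrix.toarray()
        np.fill_diagonal(vals, 0.0)
        # the interface coupling must appear with the harmonic-mean conductance
        assert np.isclose(vals[vals > 0], expected_g, rtol=1e-12).any()

    def test_rhs_balance(self, cube_solution):
        phantom, contacts, _, system, _ = cube_solution
        # the full right-hand side sums to zero; the reduced system misses
        # exactly the gauge voxel's share of the sink current
        n_sink = len(contacts[1][1])
        assert np.sum(system.rhs) == pytest.approx(1e-4 / n_sink, rel=1e-12)

    def test_disconnected_domain_rejected(self):
        labels = np.zeros((9, 3, 3), dtype=np.int16)
        labels[:4] = 1
        labels[5:] = 1  # gap at index 4 disconnects the two blocks
        phantom = VoxelPhantom(
            labels=labels,
            voxel_size_um=1000.0,
            bregma_voxel=(0.0, 0.0, 0.0),
            properties={1: TissueProperties(1, "medium", 1.0, 1.0)},
        )
        contacts = [
            ("source", np.array([[0, 1, 1]], dtype=np.intp)),
            ("sink", np.array([[8, 1, 1]], dtype=np.intp)),
        ]
        with pytest.raises(SingularSystemError):
            assemble_from_contacts(phantom, contacts, 1e-4)


class TestUniformCube:
    def test_linear_potential_and_total_drop(self, cube_solution):
        phantom, _, expected, _, potential = cube_solution
        phi = potential.phi
        h = phantom.voxel_size_m
        sigma, area = 1.0, (10e-3) ** 2
        # face-to-face drop: centre-to-centre plus the two electrode half-cells
        drop = (phi[:, :, -1].mean() - phi[:, :, 0].mean()) + 1e-4 * h / (sigma * area)
        assert drop == pytest.approx(expected["drop_V"], rel=1e-10)
        # potential is linear in depth: equal steps between layers
        steps = np.diff(phi[5, 5, :])
        assert np.allclose(steps, steps[0], rtol=1e-9)

    def test_uniform_current_density_and_field(self, cube_solution):
        phantom, _, expected, _, potential = cube_solution
        fields = fields_from_potential(potential, phantom)
        interior = np.zeros(phantom.labels.shape, dtype=bool)
        interior[:, :, 1:-1] = True
        assert np.allclose(fields.magJ[interior], expected["magJ_A_per_m2"], rtol=1e-9)
        assert np.allclose(fields.magE[interior], expected["magE_V_per_m"], rtol=1e-9)

    def test_zero_current_gives_zero_potential(self):
        phantom, contacts, _ = toy_phantom("uniform_cube", size_mm=5.0, voxel_mm=1.0)
        system = assemble_from_contacts(phantom, contacts, 0.0)
        potential = solve(system)
        assert np.all(potential.phi == 0.0)
        fields = fields_from_potential(potential, phantom)
        assert np.all(fields.magJ == 0.0)

    def test_linearity_in_current(self):
        phantom, contacts, _ = toy_phantom("uniform_cube", size_mm=5.0, voxel_mm=1.0)
        phi1 = solve(assemble_from_contacts(phantom, contacts, 1e-4), method="direct").phi
        phi2 = solve(assemble_from_contacts(phantom, contacts, 2e-4), method="direct").phi
        assert np.allclose(phi2, 2.0 * phi1, atol=1e-15)

    def test_constant_potential_gives_zero_fields(self, cube_solution):
        phantom, _, _, _, potential = cube_solution
        from iacskit.solver import PotentialField

        flat = PotentialField(
            phi=np.full(phantom.labels.shape, 0.7),
            residual=0.0,
            iterations=0,
            converged=True,
            gauge_flat=potential.gauge_flat,
        )
        fields = fields_from_potential(flat, phantom)
        assert np.all(fields.magE == 0.0)


class TestLayeredSlab:
    def test_series_resistance_drops_exact(self):
        phantom, contacts, expected = toy_phantom("layered_slab")
        system = assemble_from_contacts(phantom, contacts, 1e-4)
        potential = solve(system, method="direct")
        phi = potential.phi
        h = phantom.voxel_size_m
        area = (1e-3) ** 2
        current = 1e-4
        b = expected["layer_boundaries_vox"]  # cumulative layer boundaries
        s1, s2 = 1.0, 0.5
        # face potentials from voxel centres via exact 1-D half-cell resistances
        face_bottom = phi[0, 0, 0] - current * (h / 2) / (s1 * area)
        face_mid = phi[0, 0, b[1] - 1] + current * (h / 2) / (s1 * area)
        face_top = phi[0, 0, b[2] - 1] + current * (h / 2) / (s2 * area)
        drops = (face_mid - face_bottom, face_top - face_mid)
        assert drops[0] == pytest.approx(expected["layer_drops_V"][0], rel=1e-8)
        assert drops[1] == pytest.approx(expected["layer_drops_V"][1], rel=1e-8)

    def test_current_density_continuous_across_interface(self):
        phantom, contacts, expected = toy_phantom("layered_slab")
        potential = solve(assemble_from_contacts(phantom, contacts, 1e-4), method="direct")
        fields = fields_from_potential(potential, phantom)
        # |J| = I/A in both layers away from the injection planes
        inner = np.zeros(phantom.labels.shape, dtype=bool)
        inner[:, :, 1:-1] = True
        # exclude the interface voxels where the central difference spans both media
        inner[:, :, 3:5] = False
        assert np.allclose(fields.magJ[inner], expected["magJ_A_per_m2"], rtol=1e-9)


@pytest.fixture(scope="module")
def box():
    phantom, contacts, expected = toy_phantom("point_source_box")
    potential = solve(assemble_from_contacts(phantom, contacts, 1e-4), tol=1e-10)
    return phantom, expected, potential


class TestPointSource:
    def test_monopole_potential_within_5_percent(self, box):
        phantom, expected, potential = box
        phi = potential.phi
        c = expected["center_voxel"]
        h = phantom.voxel_size_m
        ref_off = (15, 0, 0)  # quarter-domain reference radius
        phi_ref = phi[c[0] + ref_off[0], c[1] + ref_off[1], c[2] + ref_off[2]]
        r_ref = np.linalg.norm(ref_off) * h
        for off in [(5, 0, 0), (0, 7, 0), (0, 0, 9), (4, 4, 4), (6, 6, 0), (3, 4, 5), (0, 0, 15)]:
            r = np.linalg.norm(off) * h
            numeric = phi[c[0] + off[0], c[1] + off[1], c[2] + off[2]] - phi_ref
            analytic = expected["phi_of_r"](r) - expected["phi_of_r"](r_ref)
            assert numeric == pytest.approx(analytic, abs=0.05 * expected["phi_of_r"](r))

    def test_current_conservation_on_nested_surfaces(self, box):
        phantom, expected, potential = box
        c = expected["center_voxel"]
        for half in (3, 9, 20):
            inside = np.zeros(phantom.labels.shape, dtype=bool)
            inside[
                c[0] - half : c[0] + half + 1,
                c[1] - half : c[1] + half + 1,
                c[2] - half : c[2] + half + 1,
            ] = True
            assert surface_current(potential, phantom, inside) == pytest.approx(1e-4, rel=1e-6)


class TestIterativeSolve:
    def test_cg_matches_direct(self):
        phantom, contacts, _ = toy_phantom("uniform_cube", size_mm=8.0, voxel_mm=1.0)
        system = assemble_from_contacts(phantom, contacts, 1e-4)
        direct = solve(system, method="direct").phi
        cg = solve(system, tol=1e-12).phi
        assert np.allclose(cg, direct, atol=1e-9 * np.abs(direct).max())

    def test_nonconvergence_raises_with_history(self):
        phantom, contacts, _ = toy_phantom("point_source_box", n_voxels=31)
        system = assemble_from_contacts(phantom, contacts, 1e-4)
        with pytest.raises(NonConvergenceError) as err:
            solve(system, tol=1e-12, maxiter=3)
        assert len(err.value.residual_history) == 3

    def test_solve_deterministic(self, default_solution):
        from iacskit.solver import solve as _solve

        again = _solve(default_solution["system"])
        assert np.array_equal(again.phi, default_solution["potential"].phi)


class TestDefaultPhantomFields:
    def test_mirror_symmetric_field_magnitudes(self, default_solution):
        magE = default_solution["fields"].magE
        asym = np.abs(magE - np.flip(magE, axis=1)).max()
        assert asym <= 1e-6 * magE.max()

    def test_current_conservation_through_midline(self, default_solution):
        phantom = default_solution["phantom"]
        potential = default_solution["potential"]
        placed = default_solution["placed"]
        montage = default_solution["montage"]
        source = placed[montage.electrodes[0]]
        # box tightly containing the source contact
        inside = np.zeros(phantom.labels.shape, dtype=bool)
        inside[source[:, 0], source[:, 1], source[:, 2]] = True
        assert surface_current(potential, phantom, inside) == pytest.approx(1e-4, rel=1e-6)
        # half-space containing the source side of the head
        half = np.zeros(phantom.labels.shape, dtype=bool)
        half[:, phantom.labels.shape[1] // 2 :, :] = True
        assert surface_current(potential, phantom, half) == pytest.approx(1e-4, rel=1e-6)

    def test_background_carries_no_field(self, default_solution):
        fields = default_solution["fields"]
        background = default_solution["phantom"].labels == 0
        assert np.all(fields.magE[background] == 0.0)
        assert np.all(fields.magJ[background] == 0.0)

    def test_J_equals_sigma_E(self, default_solution):
        phantom = default_solution["phantom"]
        fields = default_solution["fields"]
        sigma = phantom.sigma_volume()
        assert np.allclose(fields.magJ, sigma * fields.magE, rtol=1e-12)


class TestQuasistatic:
    def test_ratio_closed_form(self):
        props = [TissueProperties(1, "medium", 1.0, 80.0)]
        report = check_quasistatic(props, 40.0)
        assert report.loc[0, "ratio"] == pytest.approx(2 * np.pi * 40 * 8.8541878128e-12 * 80, rel=1e-12)
        assert report.loc[0, "ratio"] == pytest.approx(1.78e-7, rel=0.01)
        assert not report.loc[0, "flagged"]

    def test_zero_frequency_and_linearity(self):
        props = [TissueProperties(1, "medium", 0.5, 1000.0)]
        assert check_quasistatic(props, 0.0).loc[0, "ratio"] == 0.0
        r40 = check_quasistatic(props, 40.0).loc[0, "ratio"]
        r80 = check_quasistatic(props, 80.0).loc[0, "ratio"]
        assert r80 == pytest.approx(2 * r40, rel=1e-12)

    def test_default_tissues_quasistatic_at_40hz(self, default_phantom):
        report = check_quasistatic(default_phantom.properties, 40.0)
        assert not report["flagged"].any()


class TestAnalyticPointSource:
    def test_closed_form_value(self):
        assert analytic_point_source(0.3, 1e-4, 1e-3) == pytest.approx(2.653e-2, rel=1e-3)

    def test_scaling_laws(self):
        phi = analytic_point_source(0.3, 1e-4, 2e-3)
        assert analytic_point_source(0.3, 1e-4, 4e-3) == pytest.approx(phi / 2)
        assert analytic_point_source(0.6, 2e-4, 2e-3) == pytest.approx(phi)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            analytic_point_source(0.3, 1e-4, 0.0)
        with pytest.raises(ValueError):
            analytic_point_source(0.0, 1e-4, 1e-3)
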