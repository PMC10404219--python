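"""Forward solver: assembly, pair solves, conservation, analytic oracle,
lead-field superposition."""

import numpy as np
import pytest

import phasortacs as pt
from phasortacs.errors import ValidationError
from phasortacs.fem_forward import (
    assemble_system,
    cortical_normal_field,
    delivered_currents,
    distal_flux,
    element_stiffness,
    solve_pair,
)
from phasortacs.sphere_series import pair_potential


class TestAssembly:
    def test_rows_sum_to_zero(self, phantom61, tissue):
        system = assemble_system(phantom61, tissue)
        row_sums = np.abs(np.asarray(system.K.sum(axis=1))).max()
        assert row_sums < 1e-10

    def test_reference_tet_stiffness_matches_hand_computation(self):
        # unit right tetrahedron, sigma = 1: K = vol * G G^T with
        # g0=(-1,-1,-1), g1=e1, g2=e2, g3=e3, vol=1/6
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        expected = (1.0 / 6.0) * np.array(
            [[3, -1, -1, -1], [-1, 1, 0, 0], [-1, 0, 1, 0], [-1, 0, 0, 1]],
            dtype=float,
        )
        assert np.allclose(element_stiffness(coords), expected)

    def test_linear_in_conductivity(self, tissue):
        mesh = pt.build_layered_sphere([40.0], ["brain"], target_edge_length=12.0,
                                       seed=9)
        k1 = assemble_system(mesh, pt.TissueTable({"brain": 1.0})).K
        k2 = assemble_system(mesh, pt.TissueTable({"brain": 2.0})).K
        assert np.allclose((k2 - k1).toarray(), k1.toarray())

    def test_missing_conductivity_raises(self):
        mesh = pt.build_layered_sphere([40.0], ["mystery"], target_edge_length=12.0,
                                       seed=9)
        with pytest.raises(ValidationError):
            assemble_system(mesh, pt.TissueTable({"brain": 1.0}))


class TestPairSolve:
    def test_delivered_current_is_1mA(self, homog_pair):
        _, _, sol = homog_pair
        assert sol.current_ma == pytest.approx(1.0, abs=1e-9)

    def test_charge_conservation_reaction_forces(self, homog_pair):
        _, system, sol = homog_pair
        cur = delivered_currents(system, sol)
        assert abs(cur["A"] + cur["B"]) < 1e-3 * abs(cur["A"])

    def test_flux_integration_cross_check(self, homog_pair):
        """Surface integration of J.n over each distal face agrees with
        the reaction-force current within discretisation error, and the
        two faces balance to 0.1%."""
        _, system, sol = homog_pair
        fa = distal_flux(system, sol, "A")
        fb = distal_flux(system, sol, "B")
        assert fa == pytest.approx(1.0, rel=0.02)
        assert fa + fb == pytest.approx(0.0, abs=1e-3 * abs(fa))

    def test_potential_bounded_by_active_value(self, homog_pair):
        _, _, sol = homog_pair
        vmax = sol.V.max()
        assert sol.V.min() >= -1e-6 * vmax

    def test_equatorial_plane_at_half_potential(self, homog_pair):
        mesh, _, sol = homog_pair
        v_active = sol.V[mesh.electrode_nodes["A"]].mean()
        r = np.linalg.norm(mesh.nodes, axis=1)
        eq = (np.abs(mesh.nodes[:, 2]) < 2.0) & (r < 79.0)
        assert sol.V[eq].mean() == pytest.approx(0.5 * v_active, rel=0.02)

    def test_matches_analytic_series_solution(self, homog_pair, tissue):
        """Relative L2 agreement with the independent Legendre-series
        solution for antipodal point electrodes on a conducting sphere."""
        mesh, _, sol = homog_pair
        r = np.linalg.norm(mesh.nodes, axis=1)
        mask = r < 60.0  # well inside, away from the finite electrodes
        va = pair_potential(
            mesh.nodes[mask] * 1e-3, [0, 0, 1], [0, 0, -1],
            radius=80e-3, sigma=tissue["brain"], current=1e-3,
        )
        vf = sol.V[mask]
        num = np.linalg.norm((vf - vf.mean()) - (va - va.mean()))
        assert num / np.linalg.norm(va - va.mean()) < 0.05

    def test_convergence_under_refinement(self, tissue):
        """Halving the edge length monotonically reduces the L2
        discrepancy against the analytic sphere solution."""
        layout = pt.ElectrodeLayout(
            ["A", "B"], np.array([[0, 0, 1.0], [0, 0, -1.0]]),
            [5.0, 5.0], [25.0, 25.0],
        )
        errors = []
        for edge in (16.0, 11.0, 7.5):
            m = pt.build_layered_sphere([80.0], ["brain"],
                                        target_edge_length=edge, seed=3)
            m = pt.place_electrodes(m, layout)
            sol = solve_pair(assemble_system(m, tissue), "A", "B")
            r = np.linalg.norm(m.nodes, axis=1)
            mask = r < 60.0
            va = pair_potential(m.nodes[mask] * 1e-3, [0, 0, 1], [0, 0, -1],
                                80e-3, tissue["brain"], 1e-3)
            vf = sol.V[mask]
            errors.append(
                np.linalg.norm((vf - vf.mean()) - (va - va.mean()))
                / np.linalg.norm(va - va.mean())
            )
        assert errors[0] > errors[1] > errors[2]

    def test_same_electrode_rejected(self, homog_pair):
        _, system, _ = homog_pair
        with pytest.raises(ValidationError):
            solve_pair(system, "A", "A")


class TestCorticalField:
    def test_sign_flips_between_hemispheres(self, homog_pair):
        mesh, _, sol = homog_pair
        surf = pt.extract_cortical_surface(mesh, "brain")
        en = cortical_normal_field(sol, surf)
        z = surf.centroids[:, 2]
        near_top = z > 70.0
        near_bot = z < -70.0
        assert np.median(en[near_top]) * np.median(en[near_bot]) < 0

    def test_linear_in_solution_scale(self, homog_pair):
        mesh, _, sol = homog_pair
        surf = pt.extract_cortical_surface(mesh, "brain")
        en = cortical_normal_field(sol, surf)
        assert np.allclose(cortical_normal_field(sol.scaled(2.5), surf), 2.5 * en)

    def test_tangential_field_projects_to_zero(self, homog_pair):
        mesh, _, sol = homog_pair
        surf = pt.extract_cortical_surface(mesh, "brain")
        # in-plane edge vector of each triangle is exactly tangential
        p = mesh.nodes[surf.triangles]
        tang = p[:, 1] - p[:, 0]
        synthetic = sol.scaled(1.0)
        synthetic.E = np.zeros_like(sol.E)
        synthetic.E[surf.owner_tet] = tang
        # restrict to triangles whose owner tet is not shared
        owners, counts = np.unique(surf.owner_tet, return_counts=True)
        unique_owners = set(owners[counts == 1])
        mask = np.array([t in unique_owners for t in surf.owner_tet])
        en = cortical_normal_field(synthetic, surf)
        assert np.abs(en[mask]).max() < 1e-9


class TestLeadField:
    def test_has_60_columns(self, leadfield61):
        assert leadfield61.n_returns == 60
        assert leadfield61.active == "Fpz"

    def test_unit_current_reproduces_column(self, leadfield61):
        x = np.zeros(60)
        x[17] = 1.0
        assert np.array_equal(leadfield61.synthesize(x), leadfield61.matrix[:, 17])

    def test_montage_difference_is_column_difference(self, leadfield61):
        x = np.zeros(60)
        x[3], x[41] = 1.0, -1.0
        expected = leadfield61.matrix[:, 3] - leadfield61.matrix[:, 41]
        assert np.allclose(leadfield61.synthesize(x), expected, atol=1e-15)

    def test_superposed_columns_match_direct_pair_solve(self, tissue):
        """col(r1) - col(r2) reproduces a direct solve injecting 1 mA
        from r2 to r1, within 1%."""
        mesh = pt.build_layered_sphere(target_edge_length=9.0, seed=5)
        layout = pt.standard_10_10().subset(["Fpz", "P3", "P4"])
        mesh = pt.place_electrodes(mesh, layout)
        surf = pt.extract_cortical_surface(mesh, "brain")
        system = assemble_system(mesh, tissue)
        col_p3 = cortical_normal_field(solve_pair(system, "Fpz", "P3"), surf)
        col_p4 = cortical_normal_field(solve_pair(system, "Fpz", "P4"), surf)
        direct = cortical_normal_field(solve_pair(system, "P4", "P3"), surf)
        diff = col_p3 - col_p4
        assert (
            np.linalg.norm(direct - diff) / np.linalg.norm(direct) < 0.01
        )

    def test_save_load_round_trip(self, small_leadfield, tmp_path):
        small_leadfield.save(tmp_path / "lf")
        back = pt.LeadField.load(tmp_path / "lf")
        assert np.array_equal(back.matrix, small_leadfield.matrix)
        assert back.returns == small_leadfield.returns
        assert back.active == small_leadfield.active
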