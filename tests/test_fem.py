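"""FEM core: element stiffness, assembly, constraints, contact, stress."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

import torquecell as tc
from torquecell.fem import (UM, ConstrainedOperator, _von_mises_voigt,
                            elasticity_matrix)

X_HAT = np.array([1.0, 0.0, 0.0])


def distorted_hex(rng, scale=0.15):
    base = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)
    return base + scale * rng.standard_normal((8, 3))


class TestElementStiffness:
    def test_symmetric(self, polymer, rng):
        K = tc.element_stiffness(distorted_hex(rng), polymer)
        assert np.max(np.abs(K - K.T)) <= 1e-12 * np.max(np.abs(K))

    def test_nullspace_is_six_rigid_body_modes(self, polymer, rng):
        coords = distorted_hex(rng)
        K = tc.element_stiffness(coords, polymer)
        modes = [np.tile(t, 8) for t in np.eye(3)]
        for ax in range(3):
            w = np.zeros(3)
            w[ax] = 1.0
            modes.append(np.cross(np.tile(w, (8, 1)), coords).ravel())
        for m in modes:
            assert np.max(np.abs(K @ m)) <= 1e-9 * np.max(np.abs(K))
        # and exactly six: the 7th-smallest eigenvalue is strictly positive
        eig = np.linalg.eigvalsh(K)
        assert eig[5] <= 1e-9 * eig[-1] < eig[6]

    def test_matches_strain_energy_hessian(self, polymer, rng):
        """Central-difference Hessian of the quadrature strain energy."""
        coords = distorted_hex(rng)
        K = tc.element_stiffness(coords, polymer)
        D = elasticity_matrix(polymer)
        from torquecell.hexmesh import _DN_GP

        def energy(u):
            c = coords * UM
            e = 0.0
            for g in range(8):
                dN = _DN_GP[g]
                J = np.einsum("na,nb->ab", dN, c)
                grad = np.einsum("ba,na->nb", np.linalg.inv(J), dN)
                gu = np.einsum("nb,nc->bc", grad, u.reshape(8, 3))
                eps = 0.5 * (gu + gu.T)
                v = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                              2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[2, 0]])
                e += 0.5 * (v @ D @ v) * np.linalg.det(J)
            return e

        h = 1e-9
        H = np.zeros((24, 24))
        for i in range(24):
            for j in range(i + 1):
                ei = np.zeros(24)
                ei[i] = h
                ej = np.zeros(24)
                ej[j] = h
                H[i, j] = H[j, i] = (energy(ei + ej) - energy(ei)
                                     - energy(ej) + energy(ei * 0)) / h**2
        assert np.max(np.abs(H - K)) <= 1e-9 * np.max(np.abs(K))

    def test_inverted_element_rejected(self, polymer):
        coords = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                           [0, 0, -1], [1, 0, -1], [1, 1, -1], [0, 1, -1]],
                          float)
        with pytest.raises(ValueError, match="Jacobian"):
            tc.element_stiffness(coords, polymer)


class TestAssembly:
    def test_single_element_equals_element_matrix(self, polymer):
        mesh, _ = tc.build_fixture_mesh("single_element")
        system = tc.assemble(mesh, polymer)
        Ke = tc.element_stiffness(mesh.nodes[mesh.elems[0]], polymer)
        dofs = (3 * mesh.elems[0][:, None] + np.arange(3)).ravel()
        np.testing.assert_allclose(system.stiffness.toarray()[np.ix_(dofs, dofs)],
                                   Ke, rtol=1e-12, atol=1e-3)

    def test_all_inactive_gives_zero_operator(self, polymer):
        mesh, _ = tc.build_fixture_mesh("block", dims=(2, 2, 2),
                                        divisions=(2, 2, 2))
        mesh.active[:] = False
        assert tc.assemble(mesh, polymer).stiffness.nnz == 0

    def test_two_element_patch_matches_dense_hand_assembly(self, polymer):
        mesh, _ = tc.build_fixture_mesh("block", dims=(2, 1, 1),
                                        divisions=(2, 1, 1))
        system = tc.assemble(mesh, polymer)
        dense = np.zeros((3 * mesh.n_nodes, 3 * mesh.n_nodes))
        for conn in mesh.elems:
            Ke = tc.element_stiffness(mesh.nodes[conn], polymer)
            dofs = (3 * conn[:, None] + np.arange(3)).ravel()
            for a, da in enumerate(dofs):
                dense[da, dofs] += Ke[a]
        np.testing.assert_allclose(system.stiffness.toarray(), dense,
                                   rtol=1e-12, atol=1e-3)


class TestBoundaryConditions:
    def test_all_nodes_fixed_gives_zero_unknowns(self, polymer):
        mesh, _ = tc.build_fixture_mesh("single_element")
        system = tc.apply_boundary_conditions(
            tc.assemble(mesh, polymer), tc.BCSpec(fixed_nodes=np.arange(8)))
        assert system.n_free == 0
        state = tc.solve_static(system)
        np.testing.assert_array_equal(state.u_um, 0.0)

    def test_tied_pair_moves_identically(self, polymer):
        mesh, sets = tc.build_fixture_mesh("block", dims=(2, 1, 1),
                                           divisions=(2, 1, 1))
        pairs = np.column_stack([sets.side_x_min, sets.side_x_max])
        # drive one member of a tied pair; its partner must follow exactly
        bc = tc.BCSpec(fixed_nodes=sets.bottom, tied_pairs=pairs,
                       prescribed=[(int(sets.side_x_min[0]), 0, 0.25)])
        state = tc.solve_static(tc.apply_boundary_conditions(
            tc.assemble(mesh, polymer), bc))
        a, b = int(sets.side_x_min[0]), int(sets.side_x_max[0])
        np.testing.assert_allclose(state.u_um[a], state.u_um[b], atol=1e-14)
        assert state.u_um[a, 0] == pytest.approx(0.25, rel=1e-12)

    def test_constrained_operator_positive_definite_with_bench_bcs(
            self, polymer):
        mesh, sets = tc.build_fixture_mesh("block", dims=(1, 1, 1),
                                           divisions=(2, 2, 2))
        from torquecell.fracture import unit_cell_bc
        system = tc.apply_boundary_conditions(tc.assemble(mesh, polymer),
                                              unit_cell_bc(sets))
        A = (system.reduction.T @ system.stiffness @ system.reduction).toarray()
        eig = np.linalg.eigvalsh(A)
        assert eig[0] > 0

    def test_conflicting_prescriptions_rejected(self, polymer):
        mesh, _ = tc.build_fixture_mesh("single_element")
        bc = tc.BCSpec(prescribed=[(0, 0, 0.1), (0, 0, 0.2)])
        with pytest.raises(tc.ConstraintError):
            tc.apply_boundary_conditions(tc.assemble(mesh, polymer), bc)


def affine_bc(mesh, A):
    presc = [(int(n), c, float((A @ mesh.nodes[n])[c]))
             for n in range(mesh.n_nodes) for c in range(3)]
    return tc.BCSpec(prescribed=presc)


class TestPatchAndBeams:
    @pytest.mark.parametrize("divisions", [(1, 1, 1), (2, 2, 2)])
    def test_patch_test_reproduces_constant_stress(self, polymer, divisions):
        """Affine displacement BCs must reproduce the constant stress state
        exactly (to 1e-9 relative) on single-element and 2x2x2 patches."""
        mesh, _ = tc.build_fixture_mesh("block", dims=(1.0, 1.0, 1.0),
                                        divisions=divisions)
        A = np.array([[2.0e-3, 4.0e-4, -3.0e-4],
                      [7.0e-4, -1.0e-3, 5.0e-4],
                      [-2.0e-4, 3.0e-4, 1.5e-3]])
        system = tc.apply_boundary_conditions(tc.assemble(mesh, polymer),
                                              affine_bc(mesh, A))
        state = tc.solve_static(system)
        eps = 0.5 * (A + A.T)
        voigt = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                          2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[2, 0]])
        sig_mpa = (elasticity_matrix(polymer) @ voigt) / 1e6
        expected_vm = _von_mises_voigt(sig_mpa[None] * 1e6)[0] / 1e6
        vm = tc.von_mises_field(state, mesh, polymer)
        np.testing.assert_allclose(vm, expected_vm, rtol=1e-9)

    def test_uniaxial_stress_is_modulus_times_strain(self, polymer):
        """Free lateral faces, 1% axial strain -> sigma_xx = E*eps = 37.6 MPa,
        below the 40 MPa threshold; 1.1% -> 41.36 MPa, above it."""
        mesh, sets = tc.build_fixture_mesh("single_element")
        for eps, expect in ((0.01, 37.6), (0.011, 41.36)):
            curve = tc.run_uniaxial_ramp(mesh, sets, polymer, eps, 1,
                                         max_fracture_passes=1)
            force_mn = curve.force_pre_mn[1]
            # area = 1 um^2 -> stress MPa equals force in uN
            assert force_mn * 1e3 == pytest.approx(expect, rel=1e-9)

    def test_cantilever_tip_deflection_near_euler_bernoulli(self):
        """Tip-loaded 10:1 beam at 40x4x4 resolution within 10% of PL^3/3EI
        (shear flexibility and full-integration stiffness are the residual)."""
        material = tc.Material(3.76, 0.0, 40.0)  # nu=0 isolates bending
        mesh, sets = tc.build_fixture_mesh("cantilever")
        bc = tc.BCSpec(fixed_nodes=sets.side_x_min)
        system = tc.apply_boundary_conditions(tc.assemble(mesh, material), bc)
        tip = sets.side_x_max
        P_mn = 1e-3
        f = np.zeros((mesh.n_nodes, 3))
        f[tip, 2] = P_mn / len(tip)
        state = tc.solve_static(system, f)
        w_tip = np.mean(state.u_um[tip, 2])
        E = material.elastic_modulus_gpa * 1e9
        L, b, h = 10e-6, 1e-6, 1e-6
        inertia = b * h**3 / 12
        w_eb = (P_mn * 1e-3) * L**3 / (3 * E * inertia) / UM
        assert w_tip == pytest.approx(w_eb, rel=0.10)


class TestVonMises:
    @pytest.mark.parametrize("sig,expected", [
        ((100.0, 0, 0, 0, 0, 0), 100.0),            # uniaxial
        ((50.0, 50.0, 50.0, 0, 0, 0), 0.0),         # hydrostatic
        ((0, 0, 0, 30.0, 0, 0), 30.0 * np.sqrt(3)),  # pure shear
    ])
    def test_invariant_algebra(self, sig, expected):
        assert _von_mises_voigt(np.array(sig)[None])[0] == pytest.approx(
            expected, abs=1e-12)


class TestContact:
    def plane_fixture(self, polymer):
        mesh, sets = tc.build_fixture_mesh("block", dims=(2.0, 2.0, 1.0),
                                           divisions=(2, 2, 1))
        bc = tc.BCSpec(fixed_nodes=sets.bottom)
        system = tc.apply_boundary_conditions(tc.assemble(mesh, polymer), bc)
        n = np.array([0.13, 0.071, 1.0])
        n /= np.linalg.norm(n)
        surf = tc.PlaneSurface(tuple(n), offset_um=0.012)
        return mesh, sets, system, surf

    def test_no_penetration_means_zero_solution(self, polymer, bench_cell,
                                                bench_fit):
        mesh, sets = tc.build_unit_cell_mesh(bench_fit.cone, bench_cell, 0.8)
        from torquecell.fracture import unit_cell_bc
        system = tc.apply_boundary_conditions(tc.assemble(mesh, polymer),
                                              unit_cell_bc(sets))
        surf = tc.offset_surface(bench_fit.cone, 50.0, bench_cell)
        state = tc.solve_contact(system, surf, 0.0, polymer)
        assert state.converged
        np.testing.assert_array_equal(state.u_um, 0.0)
        assert tc.reaction_force(state, X_HAT) == 0.0

    def test_matches_exhaustive_active_set_oracle(self, polymer):
        """Dense enumeration of all active sets on a <=200-unknown fixture:
        exactly one set satisfies complementarity, and the contact solver
        reproduces its displacement field."""
        mesh, sets, system, surf = self.plane_fixture(polymer)
        state = tc.solve_contact(system, surf, 0.0, polymer)
        assert state.converged

        cand = sets.imprint_surface
        d0, nrm = surf.signed_distance(mesh.nodes[cand])
        k_p = state.penalty_n_per_m
        ndof = system.n_dof
        T = system.reduction
        assert T.shape[1] <= 200
        solutions = []
        for subset in itertools.product([0, 1], repeat=len(cand)):
            mask = np.array(subset, bool)
            if not mask.any():
                if (d0 >= 0).all():
                    solutions.append(np.zeros(ndof))
                continue
            idx = cand[mask]
            nn = nrm[mask]
            dofs = 3 * idx[:, None] + np.arange(3)
            Kc = sp.coo_matrix(
                (k_p * np.einsum("ia,ib->iab", nn, nn).ravel(),
                 (np.repeat(dofs, 3, axis=1).ravel(),
                  np.tile(dofs, (1, 3)).ravel())), shape=(ndof, ndof))
            f = np.zeros(ndof)
            np.add.at(f, dofs.ravel(),
                      (-k_p * (d0[mask] * UM)[:, None] * nn).ravel())
            A = (T.T @ (system.stiffness + Kc.tocsr()) @ T).toarray()
            u = T @ np.linalg.solve(A, T.T @ f)
            g = d0 + np.einsum("ij,ij->i", nrm, u.reshape(-1, 3)[cand] / UM)
            if (g[mask] < 0).all() and (g[~mask] >= 0).all():
                solutions.append(u)
        assert len(solutions) == 1
        np.testing.assert_allclose(solutions[0] / UM,
                                   state.u_um.reshape(-1), atol=1e-10)

    def test_newtons_third_law_and_residual_bookkeeping(self, polymer):
        """Support reactions balance the contact load: the sum of reactions
        equals the force on the master (equal and opposite to the resultant
        of the contact forces on the polymer)."""
        mesh, sets, system, surf = self.plane_fixture(polymer)
        state = tc.solve_contact(system, surf, 0.0, polymer)
        assert len(state.contact_nodes) > 0
        np.testing.assert_allclose(
            state.contact_force_on_master_mn.sum(axis=0),
            state.master_force_mn, rtol=1e-12)
        reactions = tc.support_reactions_mn(system, state).reshape(-1, 3)
        np.testing.assert_allclose(reactions.sum(axis=0),
                                   state.master_force_mn,
                                   rtol=1e-8, atol=1e-12)

    def test_reaction_force_orthogonal_direction_is_zero(self, polymer):
        mesh, sets, system, surf = self.plane_fixture(polymer)
        state = tc.solve_contact(system, surf, 0.0, polymer)
        fx = tc.reaction_force(state, X_HAT)
        # direction orthogonal to the resultant
        f = state.master_force_mn
        perp = np.cross(f, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) > 0:
            assert tc.reaction_force(state, perp) == pytest.approx(0.0,
                                                                   abs=1e-12)
        assert np.isfinite(fx)

    def test_penalty_insensitivity(self, polymer, bench_cell, bench_fit):
        """Reaction force changes < 1% when the penalty stiffness is
        multiplied by 10 at converged settings."""
        mesh, sets = tc.build_unit_cell_mesh(bench_fit.cone, bench_cell, 0.8)
        from torquecell.fracture import unit_cell_bc
        system = tc.apply_boundary_conditions(tc.assemble(mesh, polymer),
                                              unit_cell_bc(sets))
        surf = tc.offset_surface(bench_fit.cone, 10.0, bench_cell)
        forces = []
        for factor in (100.0, 1000.0):
            params = tc.ContactParams(penalty_factor=factor)
            state = tc.solve_contact(system, surf, 0.05, polymer, params)
            forces.append(-tc.reaction_force(state, X_HAT))
        assert forces[0] > 0
        assert abs(forces[1] - forces[0]) / forces[0] < 0.01
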