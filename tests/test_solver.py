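import dataclasses
import math

import numpy as np
import pytest

from osteobeam.solver import (
    IllConditionedSystemError,
    OvercriticalAxialForceError,
    ScrewBeamModel,
    assemble_system,
    batch_extremes,
    boundary_residuals,
    characteristic_roots,
    evaluate_fields,
    fields_at,
    solve_constants,
    _segment_fields,
)

from conftest import random_admissible_model


class TestCharacteristicRoots:
    def test_classical_winkler_unit_case(self):
        r = characteristic_roots(E=1.0, J_ZT=1.0, N=0.0, k=4.0)
        assert r.omega_R == pytest.approx(1.0, rel=1e-14)
        assert r.omega_I == pytest.approx(1.0, rel=1e-14)

    def test_zero_axial_force_degeneracy(self):
        r = characteristic_roots(E=200e9, J_ZT=2e-11, N=0.0, k=5e7)
        assert r.omega_R == r.omega_I  # identical expressions, bitwise
        beta = (5e7 / (4.0 * 200e9 * 2e-11)) ** 0.25
        assert r.omega_R == pytest.approx(beta, rel=1e-12)

    def test_roots_satisfy_characteristic_quartic(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            E = rng.uniform(50e9, 250e9)
            J = rng.uniform(1e-12, 1e-10)
            k = 10.0 ** rng.uniform(5.0, 9.0)
            N = rng.uniform(-0.99, 0.99) * math.sqrt(4.0 * E * J * k)
            r = characteristic_roots(E, J, N, k)
            EJ = E * J
            for lam in (
                r.omega_I + 1j * r.omega_R,
                r.omega_I - 1j * r.omega_R,
                -r.omega_I + 1j * r.omega_R,
                -r.omega_I - 1j * r.omega_R,
            ):
                residual = EJ * lam**4 - N * lam**2 + k
                assert abs(residual) <= 1e-10 * k
            # cross-check against a general polynomial root solver
            numeric = np.sort_complex(np.roots([EJ, 0.0, -N, 0.0, k]))
            mine = np.sort_complex(
                np.array(
                    [
                        r.omega_I + 1j * r.omega_R,
                        r.omega_I - 1j * r.omega_R,
                        -r.omega_I + 1j * r.omega_R,
                        -r.omega_I - 1j * r.omega_R,
                    ]
                )
            )
            assert np.allclose(numeric, mine, rtol=1e-8, atol=1e-8 * abs(mine).max())

    def test_overcritical_error(self):
        E, J, k = 200e9, 2e-11, 1e7
        N = -2.1 * math.sqrt(E * J * k)
        with pytest.raises(OvercriticalAxialForceError, match="overcritical"):
            characteristic_roots(E, J, N, k)

    def test_tension_accepted(self):
        r = characteristic_roots(E=200e9, J_ZT=2e-11, N=500.0, k=2e7)
        assert r.omega_I > r.omega_R > 0


class TestAssembly:
    def test_moment_row_pattern(self, ref_model):
        # literal (global-basis) assembly: M_o(0)=0 row reads (s, t, s, -t)
        model = dataclasses.replace(ref_model, N=-300.0)
        r = model.roots()
        s = r.omega_I**2 - r.omega_R**2
        t = 2.0 * r.omega_R * r.omega_I
        M, _ = assemble_system(model, recenter=False)
        assert M[0, :4] == pytest.approx([s, t, s, -t], rel=1e-12)
        assert np.all(M[0, 4:] == 0.0)

    def test_rhs_sparsity_pattern(self, ref_model):
        _, B = assemble_system(ref_model)
        nz = np.nonzero(B)[0]
        assert list(nz) == [5, 9]
        assert B[5] == pytest.approx(-B[9], rel=1e-14)

    def test_zero_load_gives_zero_solution(self, ref_model):
        model = dataclasses.replace(ref_model, F1=0.0)
        constants = solve_constants(model)
        assert np.max(np.abs(constants.A)) <= 1e-20
        sol = evaluate_fields(model, constants, 101)
        assert np.all(sol.v == 0.0)

    def test_literal_and_recentered_agree_on_short_beam(self, ref_model):
        c1 = solve_constants(ref_model, recenter=True)
        c2 = solve_constants(ref_model, recenter=False)
        x = np.linspace(0.0, ref_model.L, 301)
        f1 = fields_at(ref_model, c1, x)
        f2 = fields_at(ref_model, c2, x)
        for key in ("v", "slope", "M_o", "T"):
            scale = np.max(np.abs(f1[key]))
            assert np.allclose(f1[key], f2[key], atol=1e-8 * scale)

    def test_literal_assembly_ill_conditioned_for_stiff_long_beam(self):
        J = np.pi * (2.5e-3) ** 4 / 64.0
        model = ScrewBeamModel(
            L=0.15, L1=0.05, L2=0.10, k=2e10, E=200e9, J_ZT=J, F1=300.0, N=0.0
        )
        with pytest.raises(IllConditionedSystemError, match="condition"):
            assemble_system(model, recenter=False)
        solve_constants(model, recenter=True)  # re-centered basis handles it


class TestSolution:
    def test_boundary_residuals_small(self, fixture_set):
        from osteobeam.pipeline import build_model

        for f in fixture_set:
            model, _, _ = build_model(f.params)
            constants = solve_constants(model)
            res = boundary_residuals(model, constants)
            assert np.max(np.abs(res)) <= 1e-8, f.name

    def test_antisymmetry_for_symmetric_placement(self, ref_model):
        model = dataclasses.replace(ref_model, L1=0.025, L2=0.09 - 0.025, N=-250.0)
        constants = solve_constants(model)
        x = np.linspace(0.0, model.L, 2001)
        v = fields_at(model, constants, x)["v"]
        scale = np.max(np.abs(v))
        assert np.allclose(v, -v[::-1], atol=1e-8 * scale)

    def test_linearity_in_transverse_load(self, ref_model):
        model = dataclasses.replace(ref_model, N=-300.0)
        doubled = dataclasses.replace(model, F1=2.0 * model.F1)
        s1 = evaluate_fields(model, solve_constants(model), 201)
        s2 = evaluate_fields(doubled, solve_constants(doubled), 201)
        for key in ("v", "M_o", "T"):
            a = getattr(s1, key)
            b = getattr(s2, key)
            assert np.allclose(2.0 * a, b, rtol=1e-9, atol=1e-12 * np.max(np.abs(b)))

    def test_shear_jump_conditions(self, ref_model):
        model = dataclasses.replace(ref_model, N=-300.0)
        constants = solve_constants(model)
        # one-sided limits: left from the upstream segment, right from downstream
        TL1_left = _segment_fields(model, constants, 0, np.array([model.L1]))[3][0]
        TL1_right = _segment_fields(model, constants, 1, np.array([model.L1]))[3][0]
        TL2_left = _segment_fields(model, constants, 1, np.array([model.L2]))[3][0]
        TL2_right = _segment_fields(model, constants, 2, np.array([model.L2]))[3][0]
        assert TL1_left - TL1_right == pytest.approx(model.F1, rel=1e-9)
        assert TL2_left - TL2_right == pytest.approx(-model.F1, rel=1e-9)

    def test_free_end_fields(self, ref_model):
        sol = evaluate_fields(ref_model, solve_constants(ref_model), 501)
        scale_m = np.max(np.abs(sol.M_o))
        assert abs(sol.M_o[0]) <= 1e-10 * scale_m
        assert abs(sol.M_o[-1]) <= 1e-10 * scale_m
        assert abs(sol.T[0]) <= 1e-10 * ref_model.F1
        assert abs(sol.T[-1]) <= 1e-10 * ref_model.F1

    def test_equilibrium_of_foundation_reaction(self, ref_model):
        model = dataclasses.replace(ref_model, N=-300.0)
        constants = solve_constants(model)
        x = np.linspace(0.0, model.L, 20001)
        v = fields_at(model, constants, x)["v"]
        net = np.trapezoid(model.k * v, x)
        moment = np.trapezoid(model.k * v * x, x)
        assert abs(net) <= 1e-6 * model.F1
        # moment balance includes the 2nd-order axial couple N·(v(L)-v(0))
        expected = model.F1 * (model.L1 - model.L2) - model.N * (v[-1] - v[0])
        assert moment == pytest.approx(expected, rel=1e-6)

    def test_moment_balance_without_axial_force(self, ref_model):
        constants = solve_constants(ref_model)
        x = np.linspace(0.0, ref_model.L, 20001)
        v = fields_at(ref_model, constants, x)["v"]
        moment = np.trapezoid(ref_model.k * v * x, x)
        assert abs(moment) == pytest.approx(
            ref_model.F1 * (ref_model.L2 - ref_model.L1), rel=1e-6
        )

    def test_stiffer_foundation_smaller_deflection(self, ref_model):
        vmax = []
        for k in (1e6, 1e7, 1e8, 1e9):
            model = dataclasses.replace(ref_model, k=k)
            sol = evaluate_fields(model, solve_constants(model), 501)
            vmax.append(abs(sol.v_max.value))
        assert all(a > b for a, b in zip(vmax, vmax[1:]))

    def test_extrema_grid_independent(self, ref_model):
        model = dataclasses.replace(ref_model, N=-300.0)
        constants = solve_constants(model)
        a = evaluate_fields(model, constants, 1001)
        b = evaluate_fields(model, constants, 2001)
        for key in ("v_max", "M_o_max", "T_max"):
            va = abs(getattr(a, key).value)
            vb = abs(getattr(b, key).value)
            assert abs(va - vb) <= 1e-6 * vb

    def test_sampled_x_strictly_increasing_and_covers_span(self, ref_model):
        sol = evaluate_fields(ref_model, solve_constants(ref_model), 301)
        assert sol.x[0] == 0.0 and sol.x[-1] == ref_model.L
        assert np.all(np.diff(sol.x) > 0)

    def test_random_models_residuals(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            model = random_admissible_model(rng)
            res = boundary_residuals(model, solve_constants(model))
            assert np.max(np.abs(res)) <= 1e-8


class TestBatchEngine:
    def test_matches_scalar_path(self, fixture_set):
        from osteobeam.pipeline import build_model

        models = [build_model(f.params)[0] for f in fixture_set]
        vmax, Mmax, Tmax = batch_extremes(
            np.array([m.EJ for m in models]),
            np.array([m.N for m in models]),
            np.array([m.k for m in models]),
            np.array([m.L1 for m in models]),
            np.array([m.L2 for m in models]),
            np.array([m.L for m in models]),
            np.array([m.F1 for m in models]),
            n_samples_per_segment=901,
        )
        for i, m in enumerate(models):
            sol = evaluate_fields(m, solve_constants(m), 2001)
            assert vmax[i] == pytest.approx(abs(sol.v_max.value), rel=1e-4)
            assert Mmax[i] == pytest.approx(sol.M_o_max.value, rel=1e-3)
            assert Tmax[i] == pytest.approx(abs(sol.T_max.value), rel=1e-3)

    def test_rejects_overcritical(self):
        with pytest.raises(OvercriticalAxialForceError):
            batch_extremes(
                np.array([4.0]),
                np.array([-2e4]),
                np.array([1e7]),
                np.array([0.03]),
                np.array([0.06]),
                np.array([0.09]),
                np.array([300.0]),
            )
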