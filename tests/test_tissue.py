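"""Monodomain solver: operator, propagation, deformation coupling."""

import numpy as np
import pytest
import scipy.sparse as sp

from atriomech.fixtures import make_cable, make_sheet
from atriomech.tissue import (
    MonodomainSolver,
    StimulusEvent,
    assemble_operator,
    measure_cv,
    kinematic_deformation,
    project_field,
    run_coupled,
    prepaced_state,
)
from atriomech.cell import build_lut, pack_params, cell_step


def planar_stim(shape, axis=1, width=3, amplitude=8000.0):
    mask = np.zeros(shape, dtype=bool)
    if len(shape) == 1:
        mask[:width] = True
    elif axis == 1:
        mask[:, :width] = True
    else:
        mask[:width, :] = True
    return StimulusEvent(mask=mask, onset=0.0, duration=2.0, amplitude=amplitude)


def cable_cv(n=120, dx=0.25, d_l=1.26, C_lam=None, pre_beats=100):
    grid = make_cable(n, dx=dx, d_l=d_l)
    if C_lam is not None:
        grid.set_deformation(np.full(n, C_lam**2))
    solver = MonodomainSolver(grid, pre_beats=pre_beats)
    trace = solver.run(60.0, stimuli=(planar_stim((n,)),), record_dt=0.25)
    return measure_cv(grid, trace, n // 3, 2 * n // 3)


class TestOperator:
    def test_undeformed_axis_aligned_equals_standard_five_point(self):
        """With C = I and fibres along x, the deformation-aware operator
        degenerates to the plain anisotropic monodomain discretisation."""
        nx = ny = 7
        dx = 0.25
        grid = make_sheet(nx, ny, dx=dx, fibre_angle=0.0)
        L = assemble_operator(grid).toarray()

        d_l, d_t = 1.26, 0.42
        ref = np.zeros((nx * ny, nx * ny))
        for j in range(ny):
            for i in range(nx):
                p = j * nx + i
                for (jj, ii, d) in ((j, i + 1, d_l), (j, i - 1, d_l),
                                    (j + 1, i, d_t), (j - 1, i, d_t)):
                    if 0 <= jj < ny and 0 <= ii < nx:
                        q = jj * nx + ii
                        ref[p, q] += d / dx**2
                        ref[p, p] -= d / dx**2
        assert np.allclose(L, ref, atol=1e-12)

    def test_rows_sum_to_zero_with_rotated_fibres(self):
        grid = make_sheet(9, 8, dx=0.3, fibre_angle=30.0)
        L = assemble_operator(grid)
        assert np.allclose(np.asarray(L.sum(axis=1)).ravel(), 0.0, atol=1e-12)

    def test_non_spd_deformation_rejected(self):
        grid = make_cable(10)
        with pytest.raises(ValueError, match="positive"):
            grid.set_deformation(np.full(10, -1.0))

    def test_asymmetric_effective_tensor_rejected(self):
        grid = make_sheet(5, 5, fibre_angle=30.0)
        C = np.broadcast_to(np.array([[1.0, 0.3], [0.0, 1.0]]), (5, 5, 2, 2)).copy()
        with pytest.raises(ValueError, match="symmetric|positive"):
            grid.set_deformation(C)


class TestNoFluxConservation:
    def test_uniform_tissue_evolves_like_a_single_cell(self, rice):
        """No-flux boundaries + zero gradient: the sheet's uniform state must
        track the isolated cell exactly (diffusion contributes nothing)."""
        grid = make_sheet(6, 6, dx=0.25)
        solver = MonodomainSolver(grid, pre_beats=20)
        y_cell = solver.Y[0].copy()
        trace = solver.run(30.0, record_dt=1.0, merged=False)
        assert np.ptp(trace.V[-1]) < 1e-8  # stays spatially uniform

        pv = pack_params(__import__("atriomech").ionic.build_cell_parameters("RA/PM", "control"), rice)
        lut, aux = build_lut(solver.dt / 2.0)
        for _ in range(2 * int(round(30.0 / solver.dt))):
            cell_step(y_cell, pv, lut, aux, solver.dt / 2.0, 0.0)
        assert abs(trace.V[-1][0] - y_cell[0]) < 1e-6


class TestConductionVelocity:
    def test_anisotropy_ratio_is_sqrt3(self):
        cv_l = cable_cv(d_l=1.26)
        cv_t = cable_cv(d_l=0.42)
        assert abs(cv_l / cv_t - np.sqrt(3.0)) / np.sqrt(3.0) < 0.05

    def test_doubling_conductivity_scales_cv_by_sqrt2(self):
        cv1 = cable_cv(d_l=1.26)
        cv2 = cable_cv(d_l=2.52)
        assert abs(cv2 / cv1 - np.sqrt(2.0)) / np.sqrt(2.0) < 0.05

    def test_prescribed_stretch_rescales_cv_by_inverse_lambda(self):
        lam = 1.3
        cv1 = cable_cv()
        cv_lam = cable_cv(C_lam=lam)
        assert abs(cv_lam / cv1 - 1.0 / lam) < 0.05 / lam

    def test_cv_converged_on_half_grid(self):
        cv1 = cable_cv(n=120, dx=0.25)
        cv2 = cable_cv(n=240, dx=0.125)
        assert abs(cv2 - cv1) / cv2 < 0.03

    def test_unstimulated_cable_has_no_wave(self):
        grid = make_cable(40)
        solver = MonodomainSolver(grid, pre_beats=20)
        trace = solver.run(40.0, record_dt=0.5)
        with pytest.raises(RuntimeError, match="never activated"):
            measure_cv(grid, trace, 10, 30)

    def test_sheet_cv_matches_cable_along_fibre(self):
        grid = make_sheet(40, 20, dx=0.25, fibre_angle=0.0)
        solver = MonodomainSolver(grid, pre_beats=100)
        trace = solver.run(15.0, stimuli=(planar_stim((20, 40)),), record_dt=0.25)
        cv_sheet = measure_cv(grid, trace, (10, 12), (10, 32))
        assert abs(cv_sheet - cable_cv()) / cv_sheet < 0.03


class TestStrangSplitting:
    def test_merged_run_matches_explicit_strang_steps(self):
        grid_a = make_cable(40)
        grid_b = make_cable(40)
        sa = MonodomainSolver(grid_a, pre_beats=20)
        sb = MonodomainSolver(grid_b, pre_beats=20)
        stim = planar_stim((40,))
        ta = sa.run(20.0, stimuli=(stim,), record_dt=1.0, merged=True)
        tb = sb.run(20.0, stimuli=(stim,), record_dt=1.0, merged=False)
        assert np.max(np.abs(ta.V[-1] - tb.V[-1])) < 0.5  # mV

    def test_second_order_field_convergence_in_dt(self):
        fields = {}
        for dt in (0.01, 0.005):
            grid = make_cable(40)
            solver = MonodomainSolver(grid, dt=dt, pre_beats=20)
            tr = solver.run(20.0, stimuli=(planar_stim((40,)),), record_dt=2.0,
                            merged=False)
            fields[dt] = tr.V[-1]
        assert np.max(np.abs(fields[0.01] - fields[0.005])) < 1.0  # mV

    def test_dt_above_cap_rejected(self):
        with pytest.raises(ValueError, match="cap"):
            MonodomainSolver(make_cable(10), dt=0.02)


class TestHeterogeneousTissue:
    def test_activation_monotone_along_regional_cable(self):
        grid = make_cable(80, region_map=[(0, 40, "RA/PM"), (40, 80, "PV")])
        solver = MonodomainSolver(grid, pre_beats=100)
        trace = solver.run(40.0, stimuli=(planar_stim((80,)),), record_dt=0.25)
        act = trace.activation_time
        assert not np.any(np.isnan(act))
        assert np.all(np.diff(act[3:]) > 0)


class TestDeformationCoupling:
    def test_zero_gamma_maps_to_identity(self):
        grid = make_sheet(5, 5)
        C = kinematic_deformation(np.zeros((5, 5)), grid)
        assert np.allclose(C, np.eye(2))

    def test_fibre_shortening_preserves_area(self):
        grid = make_sheet(5, 5, fibre_angle=25.0)
        C = kinematic_deformation(np.full((5, 5), -0.1), grid)
        det = np.linalg.det(C)
        assert np.allclose(det, (1.0 + -0.1), atol=1e-12)  # det C = det(F)^2 = (1+g)

    def test_projection_identity_on_same_grid(self):
        a = make_sheet(6, 6)
        field = np.arange(36, dtype=float).reshape(6, 6)
        assert np.allclose(project_field(a, field, a), field)

    def test_projection_between_resolutions(self):
        a = make_sheet(11, 11, dx=0.5)
        b = make_sheet(21, 21, dx=0.25)
        y, x = np.mgrid[0:11, 0:11] * 0.5
        field = 0.3 * x + 0.1 * y
        proj = project_field(a, field, b)
        yb, xb = np.mgrid[0:21, 0:21] * 0.25
        assert np.allclose(proj, 0.3 * xb + 0.1 * yb, atol=1e-9)

    def test_projection_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="project"):
            project_field(make_cable(10), np.zeros(10), make_sheet(5, 5))

    def test_uncoupled_loop_equals_plain_run(self):
        ga, gb = make_sheet(8, 8), make_sheet(8, 8)
        sa = MonodomainSolver(ga, pre_beats=20)
        sb = MonodomainSolver(gb, pre_beats=20)
        stim = planar_stim((8, 8))
        ta = run_coupled(sa, 10.0, stimuli=(stim,), coupling="none")
        tb = sb.run(10.0, stimuli=(stim,), record_dt=1.0)
        assert np.allclose(ta.V[-1], tb.V[-1], atol=1e-9)

    def test_contraction_speeds_conduction_along_fibre(self):
        """Kinematic feedback (gamma < 0 -> C^-1 > 1 along f) raises CV in
        material coordinates, the analogue of the lambda rescaling law."""
        ga, gb = make_cable(60), make_cable(60)
        sa = MonodomainSolver(ga, pre_beats=100)
        sb = MonodomainSolver(gb, pre_beats=100)
        stim = planar_stim((60,))
        ta = run_coupled(sa, 30.0, stimuli=(stim,), coupling="kinematic")
        tb = run_coupled(sb, 30.0, stimuli=(stim,), coupling="none")
        # both runs activate; coupled activation can only be earlier or equal
        assert np.nanmax(ta.activation_time) <= np.nanmax(tb.activation_time) + 1e-6

    def test_coupled_outer_step_refinement_consistent(self):
        fields = {}
        for dtm in (1.0, 0.5):
            grid = make_sheet(8, 8)
            solver = MonodomainSolver(grid, pre_beats=20)
            tr = run_coupled(solver, 12.0, stimuli=(planar_stim((8, 8)),),
                             dt_mech=dtm)
            fields[dtm] = tr.V[-1]
        assert np.max(np.abs(fields[1.0] - fields[0.5])) < 1.0  # mV
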