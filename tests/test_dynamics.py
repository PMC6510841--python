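"""Normal-mode machinery: canonical form, spectra, analytic vs numeric solutions."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acmodes import (
    Regime,
    RunConfig,
    StimulusSpec,
    UnstableModeError,
    canonicalize,
    classify_mode,
    couple,
    decompose,
    integrate_numeric,
    make_fixture,
    map_mode_to_fields,
    mode_parameters,
    second_order_form,
    solve_modes,
)
from acmodes.dynamics import _segment_eval


class TestModeParameters:
    @pytest.mark.parametrize(
        "w_d, gamma, om2, delta",
        [
            # direct evaluations of the per-mode relations at the
            # within-column scalars (w_ei, w_ii, w_ie) = (1, 0.2, 1)
            (0.0, 0.1, 1.0, 0.99499),
            (-10.0, 5.1, 3.0, 4.7968740j),
        ],
    )
    def test_known_values(self, w_d, gamma, om2, delta):
        g, o, d = mode_parameters(np.array([w_d]), 1.0, 0.2, 1.0)
        assert g[0] == pytest.approx(gamma)
        assert o[0] == pytest.approx(om2)
        assert d[0] == pytest.approx(delta, abs=1e-5)

    @given(w=st.floats(-50, 50), w_ei=st.floats(0.1, 3), w_ii=st.floats(0.05, 3),
           w_ie=st.floats(0.1, 3))
    @settings(max_examples=200, deadline=None)
    def test_closure_relation(self, w, w_ei, w_ii, w_ie):
        g, o, d = mode_parameters(np.array([w]), w_ei, w_ii, w_ie)
        assert d[0] ** 2 + g[0] ** 2 == pytest.approx(o[0], rel=1e-12, abs=1e-12)


class TestClassifyMode:
    @pytest.mark.parametrize(
        "gamma, delta, regime",
        [
            (0.1, 0.995, Regime.UNDERDAMPED),
            (-0.05, 0.5, Regime.UNSTABLE),
            (0.0, 0.5, Regime.UNSTABLE),
            (5.1, 4.7968740j, Regime.OVERDAMPED_STABLE),
            (0.3, 0.0, Regime.CRITICALLY_DAMPED),
            (0.1, 0.5j, Regime.OVERDAMPED_UNSTABLE),
        ],
    )
    def test_regimes(self, gamma, delta, regime):
        assert classify_mode(gamma, delta) is regime

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_mode(float("nan"), 0.1)


class TestCanonicalize:
    def test_leak_absorbed(self, default_conn):
        sys = canonicalize(default_conn)
        n = default_conn.n
        assert np.allclose(sys.w_ac_tilde, default_conn.w_ac - np.eye(n))
        assert sys.w_ei == 1.0
        assert sys.w_ii == pytest.approx(1.2)  # 0.2 within-column + leak
        assert sys.w_ie == 1.0
        assert sys.tau_m == 40.0

    def test_degenerate_slope_rejected(self, default_conn):
        with pytest.raises(ValueError):
            canonicalize(default_conn, alpha=0.0)
        with pytest.raises(ValueError):
            canonicalize(default_conn, tau_m=0.0)

    def test_nonuniform_diagonal_rejected(self, default_conn):
        diag = default_conn.w_ei_diag.copy()
        diag[3] = 2.0
        bad = dataclasses.replace(default_conn, w_ei_diag=diag)
        with pytest.raises(ValueError, match="scalar"):
            canonicalize(bad)

    def test_single_column_system(self):
        # a 1-column network reduces the transform to scalar arithmetic
        lay, conn = make_fixture(2, 1, seed=0)
        sys = canonicalize(conn)
        assert sys.w_ac_tilde.shape == (2, 2)
        assert sys.w_ac_tilde[1, 1] == pytest.approx(conn.w_ac[1, 1] - 1.0)


class TestSpectrum:
    def test_closure_to_machine_precision(self, default_run):
        sp = default_run.spectrum
        under = [i for i, r in enumerate(sp.regimes) if r is Regime.UNDERDAMPED]
        lhs = sp.delta.real[under] ** 2 + sp.gamma[under] ** 2
        assert np.allclose(lhs, sp.omega0_sq[under], rtol=1e-12, atol=1e-12)

    def test_orthonormal_mixing(self, default_run):
        y = default_run.spectrum.mixing
        assert np.abs(y.T @ y - np.eye(y.shape[0])).max() < 1e-10

    def test_sorted_descending_with_sign_convention(self, default_run):
        sp = default_run.spectrum
        assert np.all(np.diff(sp.eigenvalues) <= 1e-12)
        for k in range(sp.n):
            col = sp.mixing[:, k]
            nz = np.flatnonzero(np.abs(col) > 1e-12)
            assert col[nz[0]] > 0

    def test_asymmetric_matrix_rejected(self, mini):
        w = mini["system"].w_ac_tilde.copy()
        w[0, 1] += 0.5
        bad = dataclasses.replace(mini["system"], w_ac_tilde=w)
        with pytest.raises(ValueError, match="symmetric"):
            decompose(bad)


class TestAnalyticSolution:
    def test_zero_input_stays_at_rest(self, mini):
        stim = dataclasses.replace(mini["stim"], amplitude=0.0)
        _, traj = solve_modes(mini["spectrum"], stim, mini["cfg"].time_grid())
        assert np.all(traj.u_d == 0) and np.all(traj.v_d == 0)

    def test_linearity_in_amplitude(self, mini):
        stim = mini["stim"]
        _, t1 = solve_modes(mini["spectrum"], stim, mini["cfg"].time_grid())
        stim2 = dataclasses.replace(stim, amplitude=2 * stim.amplitude)
        _, t2 = solve_modes(mini["spectrum"], stim2, mini["cfg"].time_grid())
        assert np.allclose(t2.u_d, 2 * t1.u_d, rtol=1e-12, atol=1e-300)

    def test_couple_roundtrip(self, mini):
        sp, traj = mini["spectrum"], mini["traj"]
        back = sp.mixing.T @ traj.u
        assert np.abs(back - traj.u_d).max() < 1e-10

    def test_identity_mixing_is_noop(self, mini):
        sp = mini["spectrum"]
        eye_sp = dataclasses.replace(sp, mixing=np.eye(sp.n))
        traj = couple(eye_sp, mini["traj"])
        assert np.array_equal(traj.u, mini["traj"].u_d)

    def test_unstable_spectrum_refused(self, mini):
        conn = mini["conn"]
        hot = dataclasses.replace(conn, w_ac=conn.w_ac + 3.0 * np.eye(conn.n))
        sp = decompose(canonicalize(hot))
        assert not sp.stable
        with pytest.raises(UnstableModeError):
            solve_modes(sp, mini["stim"], mini["cfg"].time_grid())

    def test_published_coefficient_formulas(self, mini):
        """Segment coefficients match the closed-form expressions in which the
        sine amplitude is written out in terms of the drive and initial state."""
        sp = mini["spectrum"]
        s = sp.system
        sol, _ = solve_modes(sp, mini["stim"], mini["cfg"].time_grid())
        seg = sol.segments[1]  # stimulus-on segment, nonzero drive and state
        w, om2, g, d = sp.eigenvalues, sp.omega0_sq, sp.gamma, sp.delta
        ie, ii, u0, v0 = seg.i_e, seg.i_i, seg.u0, seg.v0
        a_u_ref = (s.w_ei * g / (om2 * d) * ii
                   + (om2 + s.w_ei * s.w_ie - s.w_ii**2) / (2 * om2 * d) * ie
                   + (s.w_ii + w) / (2 * d) * u0
                   - s.w_ei / d * v0)
        b_u_ref = s.w_ei / om2 * ii - s.w_ii / om2 * ie + u0
        c_u_ref = -s.w_ei / om2 * ii + s.w_ii / om2 * ie
        c_v_ref = -w / om2 * ii + s.w_ie / om2 * ie
        assert np.allclose(seg.a_u, a_u_ref, rtol=1e-10)
        assert np.allclose(seg.b_u, b_u_ref, rtol=1e-10)
        assert np.allclose(seg.c_u, c_u_ref, rtol=1e-10)
        assert np.allclose(seg.c_v, c_v_ref, rtol=1e-10)

    def test_state_continuity_at_breakpoints(self, mini):
        stim = mini["stim"]
        fine = np.arange(0.0, 600.0001, 0.25)
        _, traj = solve_modes(mini["spectrum"], stim, fine)
        for tb in (stim.onset_ms, stim.onset_ms + stim.duration_ms):
            k = int(np.searchsorted(fine, tb))
            jump = np.abs(traj.u_d[:, k] - traj.u_d[:, k - 1]).max()
            assert jump < 1e-4  # continuous state, only derivative jumps

    def test_critical_damping_limit(self):
        # underdamped evaluation at delta -> 0+ converges to the critical form
        gamma = np.array([0.5])
        a = np.array([0.7 + 0j])
        b = np.array([0.3 + 0j])
        c = np.array([0.1 + 0j])
        t = np.linspace(0, 10, 201)
        eps = 1e-6
        under = _segment_eval(gamma, np.array([eps + 0j]), a / eps, b, c, t)
        crit = _segment_eval(gamma, np.array([0j]), a, b, c, t)
        denom = np.abs(crit).max()
        assert np.abs(under - crit).max() / denom < 1e-4

    def test_envelope_decays_after_stimulus(self, mini):
        traj = mini["traj"]
        t = traj.t_ms
        norm = np.linalg.norm(traj.u, axis=0)
        # sample the envelope well after stimulus offset
        late = [norm[(t >= a) & (t < a + 100)].max() for a in (200, 300, 400, 500)]
        assert np.all(np.diff(late) < 0)


class TestSecondOrderForm:
    def test_residual_of_analytic_solution(self, mini):
        stim = mini["stim"]
        fine = np.arange(0.0, 600.0001, 0.05)
        _, traj = solve_modes(mini["spectrum"], stim, fine)
        traj = couple(mini["spectrum"], traj)
        form = second_order_form(mini["system"], stim, fine)
        dt = 0.05 / mini["system"].tau_m  # dimensionless step
        u = traj.u
        du = np.gradient(u, dt, axis=1)
        ddu = np.gradient(du, dt, axis=1)
        resid = ddu + 2 * form.gamma_u @ du + form.omega0_sq_u @ u - form.q
        # interior of a constant-input segment, away from the breakpoints
        sel = (fine > 100) & (fine < 500)
        assert np.abs(resid[:, sel]).max() < 1e-8

    def test_zero_input_zero_drive(self, mini):
        stim = dataclasses.replace(mini["stim"], amplitude=0.0)
        form = second_order_form(mini["system"], stim, np.arange(0, 601.0))
        assert np.all(form.q == 0) and np.all(form.j == 0)


class TestNumericOracle:
    def test_linear_oracle_agreement_small(self):
        lay, conn = make_fixture(3, 4, seed=11)
        sys = canonicalize(conn)
        sp = decompose(sys)
        cfg = RunConfig()
        stim = StimulusSpec.centered(lay)
        _, traj = solve_modes(sp, stim, cfg.time_grid())
        traj = couple(sp, traj)
        num = integrate_numeric(sys, stim, cfg.time_grid())
        assert np.abs(num.u - traj.u).max() < 1e-8
        assert np.abs(num.v - traj.v).max() < 1e-8

    def test_zero_input_constant_rest(self, mini):
        stim = dataclasses.replace(mini["stim"], amplitude=0.0)
        num = integrate_numeric(mini["system"], stim, np.arange(0, 201.0))
        assert np.abs(num.u).max() < 1e-12

    def test_sigmoid_close_to_linear_at_low_amplitude(self, mini):
        stim = mini["stim"]  # amplitude 0.01, quasi-linear regime
        grid = np.arange(0, 401.0)
        lin = integrate_numeric(mini["system"], stim, grid, nonlinearity="linear")
        sig = integrate_numeric(mini["system"], stim, grid, nonlinearity="sigmoid",
                                rtol=1e-8, atol=1e-11)
        scale = np.abs(lin.u).max()
        assert np.abs(sig.u - lin.u).max() < 0.05 * scale


class TestModeToFieldMapping:
    def test_averaging_identity(self, default_run):
        lay = default_run.layout
        sp = default_run.spectrum
        fm = map_mode_to_fields(sp, 0, lay)
        total = sum(v * 16 for v in fm.values())
        cortical = lay.cortical_mask
        assert total == pytest.approx(sp.mixing[cortical, 0].sum(), abs=1e-12)

    def test_field_maps_span_structured_and_uniform_modes(self, default_run):
        """Normal modes differ strongly in how much across-field structure
        their mixing weights carry: between-field (graph) patterns produce
        sign changes across fields while local patterns average out."""
        sp = default_run.spectrum
        lay = default_run.layout

        def structure(idx):
            vals = np.array(list(map_mode_to_fields(sp, idx, lay).values()))
            return vals.std()

        stds = np.array([structure(i) for i in range(sp.n)])
        assert stds.max() > 5 * np.median(stds)
        # structured modes flip sign across fields
        k = int(np.argmax(stds))
        vals = np.array(list(map_mode_to_fields(sp, k, lay).values()))
        assert vals.min() < 0 < vals.max()

    def test_single_field_toy(self):
        lay, conn = make_fixture(2, 4, seed=0)
        sp = decompose(canonicalize(conn))
        fm = map_mode_to_fields(sp, 0, lay)
        assert len(fm) == 1

    def test_bad_index_rejected(self, mini):
        with pytest.raises(IndexError):
            map_mode_to_fields(mini["spectrum"], 10_000, mini["layout"])
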