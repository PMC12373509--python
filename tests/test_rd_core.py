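import numpy as np
import pytest
from scipy.special import erfc

import balwave as bw
from balwave.rd_core import cell_volumes


# ---------------------------------------------------------------------------
# initial condition


def test_initial_state_uniform_barcode_and_empty_invader(tiny_params):
    st = bw.initialize_state(tiny_params)
    vol = cell_volumes(st, tiny_params)
    # 1 mM barcode everywhere, expressed as lab-frame concentration
    assert np.allclose(st.m_free / vol, 1000.0)
    assert np.all(st.u == 0) and np.all(st.M_arr == 0) and np.all(st.M_sw == 0)
    assert np.allclose(st.w, tiny_params.L / tiny_params.n_cells)
    # total barcode amount equals m_total * L in cartesian geometry
    assert np.sum(st.m_free) == pytest.approx(1000.0 * tiny_params.L)


def test_zero_reservoir_concentration_is_a_fixed_point(tiny_params):
    p = tiny_params.replace(u_res=0.0, t_end=5e4, dt_out=1e4)
    res = bw.simulate_invasion(p)
    st = res.state
    assert np.all(st.u == 0) and np.all(st.M_arr == 0) and np.all(st.M_sw == 0)
    assert np.allclose(st.w, p.L / p.n_cells)
    assert np.all(res.kymograph.intensity == 0)


# ---------------------------------------------------------------------------
# reaction step: closed-form oracles


def _single_cell_state(u0, m0, M_arr0=0.0, M_sw0=0.0, n=12, w=1.0):
    # concentrations == amounts with unit cell width
    return bw.CondensateState(
        t=0.0,
        u=np.full(n, u0 * w),
        m_free=np.full(n, m0 * w),
        M_arr=np.full(n, M_arr0 * w),
        M_sw=np.full(n, M_sw0 * w),
        w=np.full(n, w),
    )


def test_no_binding_limit_only_swelling_conversion(tiny_params):
    p = tiny_params.replace(k_bind=0.0, k_swell=1e-3, L=12.0, n_cells=12)
    st = _single_cell_state(u0=0.5, m0=2.0, M_arr0=3.0)
    out = bw.reaction_step(st, p, dt=500.0)
    decay = np.exp(-1e-3 * 500.0)
    assert np.allclose(out.u, st.u)
    assert np.allclose(out.m_free, st.m_free)
    assert np.allclose(out.M_arr, 3.0 * decay)
    assert np.allclose(out.M_sw, 3.0 * (1 - decay))


def test_first_order_swelling_decay_is_exact(tiny_params):
    # u = 0: M_arr(t) = A0 exp(-k t) for any step size (Strang halves compose)
    p = tiny_params.replace(k_swell=2e-3, L=12.0, n_cells=12)
    st = _single_cell_state(u0=0.0, m0=1.0, M_arr0=5.0)
    out = st
    for _ in range(4):
        out = bw.reaction_step(out, p, dt=250.0)
    assert np.allclose(out.M_arr, 5.0 * np.exp(-2e-3 * 1000.0), rtol=1e-12)
    assert np.allclose(out.M_arr + out.M_sw, 5.0, rtol=1e-12)


def test_equal_concentration_binding_matches_closed_form_and_ode_oracle(tiny_params):
    # du/dt = -k u^2 with u0 = m0: u(t) = u0 / (1 + k u0 t)
    k, u0, t = 0.05, 3.0, 40.0
    p = tiny_params.replace(k_bind=k, k_swell=0.0, L=12.0, n_cells=12)
    st = _single_cell_state(u0=u0, m0=u0)
    out = bw.reaction_step(st, p, dt=t)
    expected = u0 / (1 + k * u0 * t)
    assert np.allclose(out.u, expected, rtol=1e-10)
    # independent fine-step explicit-Euler oracle
    u = u0
    n_sub = 200_000
    for _ in range(n_sub):
        u -= k * u * u * (t / n_sub)
    assert out.u[0] == pytest.approx(u, rel=1e-4)
    # bound amount ends up in M_arr, barcode total conserved
    assert np.allclose(out.M_arr, u0 - expected, rtol=1e-10)
    assert np.allclose(out.m_free + out.M_arr + out.M_sw, u0, rtol=1e-12)


@pytest.mark.parametrize("u0,m0", [(5.0, 1.0), (1.0, 5.0), (2.0, 2.0)])
def test_binding_never_produces_negative_species(tiny_params, u0, m0):
    p = tiny_params.replace(k_bind=10.0, k_swell=1.0, L=12.0, n_cells=12)
    st = _single_cell_state(u0=u0, m0=m0)
    out = bw.reaction_step(st, p, dt=1e6)  # wildly large step
    for f in (out.u, out.m_free, out.M_arr, out.M_sw):
        assert np.all(f >= 0)
    assert np.allclose(out.u - out.m_free, u0 - m0, rtol=1e-9)  # excess conserved


# ---------------------------------------------------------------------------
# diffusivity switch


def test_diffusivity_switch_and_harmonic_interface(tiny_params):
    p = tiny_params.replace(theta=0.5)
    st = _single_cell_state(u0=0.0, m0=1.0, n=12)
    D = bw.diffusivity_field(st, p)
    assert np.all(D == p.D0)  # nothing swollen
    st_full = _single_cell_state(u0=0.0, m0=0.0, M_sw0=1.0, n=12)
    assert np.all(bw.diffusivity_field(st_full, p) == p.D1)
    # phi = (0.4, 0.6) around theta=0.5 -> (D0, D1); interface harmonic mean
    st2 = _single_cell_state(u0=0.0, m0=1.0, n=12)
    st2.M_sw[:] = 0.4
    st2.m_free[:] = 0.6
    st2.M_sw[6:] = 0.6
    st2.m_free[6:] = 0.4
    D2 = bw.diffusivity_field(st2, p)
    assert D2[5] == p.D0 and D2[6] == p.D1
    iface = bw.interface_diffusivities(D2)
    assert iface[5] == pytest.approx(2 * p.D0 * p.D1 / (p.D0 + p.D1))


# ---------------------------------------------------------------------------
# swelling geometry


def test_swelling_geometry_cartesian_volumetric(tiny_params):
    p = tiny_params.replace(f_swell=4.0, L=12.0, n_cells=12)
    w0 = p.dx
    st = _single_cell_state(u0=0.0, m0=1.0, n=12, w=w0)
    st.m_free[:] = 1000.0 * w0
    out = bw.swelling_geometry_update(st, p)
    assert np.allclose(out.w, w0)  # phi = 0 everywhere

    # fully swollen: domain length 4 L, lab concentration diluted fourfold
    st_full = st.copy()
    st_full.M_sw[:] = st_full.m_free
    st_full.m_free[:] = 0.0
    out = bw.swelling_geometry_update(st_full, p)
    assert np.sum(out.w) == pytest.approx(4.0 * p.L)
    assert np.allclose(out.M_sw / out.w, 1000.0 / 4.0)

    # phi = 0.5 in one cell: w = w0 (1 + 1.5) = 2.5 w0
    st_half = st.copy()
    st_half.M_sw[3] = 0.5 * st_half.m_free[3]
    st_half.m_free[3] *= 0.5
    out = bw.swelling_geometry_update(st_half, p)
    assert out.w[3] == pytest.approx(2.5 * w0)
    assert out.w[0] == pytest.approx(w0)


# ---------------------------------------------------------------------------
# diffusion step


def test_uniform_concentration_without_gradient_is_stationary(tiny_params):
    p = tiny_params.replace(u_res=2.0, k_bind=0.0)
    st = bw.initialize_state(p)
    st.u = 2.0 * st.w  # concentration equal to the reservoir everywhere
    out = bw.diffusion_step(st, p, dt=100.0)
    assert np.allclose(out.u / out.w, 2.0, rtol=1e-12)


def test_diffusion_conserves_invader_against_boundary_influx(tiny_params):
    p = tiny_params.replace(k_bind=0.0)
    st = bw.initialize_state(p)
    for _ in range(50):
        st = bw.diffusion_step(st, p, dt=200.0)
    assert st.influx_total > 0
    assert st.invader_total == pytest.approx(st.influx_total, rel=1e-8)


def test_constant_source_diffusion_matches_erfc_solution():
    """Fine-grid pure diffusion against u_res * erfc(x / 2 sqrt(D t))."""
    p = bw.ModelParams(
        D0=1.0, D1=1.0, k_bind=0.0, k_swell=0.0, f_swell=1.0, theta=0.5,
        m_total=1.0, u_res=1.0, L=20.0, n_cells=400, t_end=4.0, dt_out=1.0,
    )
    st = bw.initialize_state(p)
    dt, t = 0.002, 0.0
    while t < 4.0 - 1e-9:
        st = bw.diffusion_step(st, p, dt)
        t += dt
    x = np.cumsum(st.w) - st.w / 2
    rms = np.sqrt(np.mean((st.u / st.w - erfc(x / (2 * np.sqrt(t)))) ** 2))
    assert rms < 0.01  # spec-level bound
    assert rms < 1e-3  # actual scheme accuracy


# ---------------------------------------------------------------------------
# full simulation


def test_simulation_is_deterministic():
    p = bw.load_preset("ballistic_front")
    a = bw.simulate_invasion(p)
    b = bw.simulate_invasion(p)
    assert np.array_equal(a.kymograph.intensity, b.kymograph.intensity)
    assert np.array_equal(a.state.u, b.state.u)


def test_simulation_conservation_diagnostics(tiny_params):
    p = tiny_params.replace(t_end=4e5, dt_out=2e4)
    res = bw.simulate_invasion(p)
    assert res.diagnostics["max_barcode_drift"] < 1e-8
    assert res.diagnostics["max_invader_balance_residual"] < 1e-6
    # widths monotone within bounds
    w0 = p.L / p.n_cells
    assert np.all(res.state.w >= w0 - 1e-12)
    assert np.all(res.state.w <= w0 * p.f_swell + 1e-12)


def test_front_position_converges_under_grid_and_step_refinement():
    """Halving dt and doubling n_cells moves the front by < 2%."""
    p = bw.load_preset("ballistic_wave", n_cells=640, t_end=2e6, dt_out=1e4)
    def end_position(q):
        res = bw.simulate_invasion(q)
        tr = bw.front_trace(res.kymograph)
        return tr.X_front[np.isfinite(tr.X_front)][-1]
    X1 = end_position(p)
    X2 = end_position(p.replace(n_cells=1280, dt_sim=p.resolved_dt_sim() / 2))
    assert abs(X2 - X1) / X1 < 0.02


def test_radial_geometry_conserves_and_swells_by_cube_root(tiny_params):
    p = tiny_params.replace(geometry="radial_1d", t_end=4e5, dt_out=4e4)
    res = bw.simulate_invasion(p)
    assert res.diagnostics["max_barcode_drift"] < 1e-8
    assert res.diagnostics["max_invader_balance_residual"] < 1e-6
    w0 = p.L / p.n_cells
    assert np.all(res.state.w <= w0 * p.f_swell ** (1 / 3) + 1e-12)
    assert np.all(np.isfinite(res.kymograph.intensity))


def test_non_finite_fields_abort_with_diagnostic(tiny_params):
    bad = tiny_params.replace(u_res=float("nan"))
    with pytest.raises(bw.SimulationError, match="non-finite"):
        bw.simulate_invasion(bad)


# ---------------------------------------------------------------------------
# phase scan


def test_phase_scan_single_point_matches_direct_classification():
    base = bw.load_preset("ballistic_front")
    df = bw.phase_scan(base, [base.D0], [base.D1], [base.k_swell])
    assert len(df) == 1
    row = df.iloc[0]
    t_end = bw.estimate_invasion_time(base.replace())
    p = base.replace(t_end=t_end, dt_out=t_end / 200)
    tr = bw.front_trace(bw.simulate_invasion(p).kymograph)
    assert row.regime == bw.classify_regime(tr)
    assert row.alpha == pytest.approx(tr.alpha)


def test_phase_scan_no_contrast_points_are_fickian():
    base = bw.load_preset("ballistic_front")
    df = bw.phase_scan(base, [base.D0], [base.D0, base.D1], [3e-3])
    by_D1 = df.set_index("D1")
    assert by_D1.loc[base.D0, "regime"] == "fickian"
    assert by_D1.loc[base.D1, "regime"].startswith("ballistic")


def test_phase_scan_records_failures_without_aborting(tiny_params):
    df = bw.phase_scan(tiny_params, [-1.0, tiny_params.D0], [tiny_params.D1], [3e-3])
    assert len(df) == 2
    bad = df[df.D0 < 0].iloc[0]
    assert bad.regime is None and bad.error != ""
    assert df[df.D0 > 0].iloc[0].regime is not None
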