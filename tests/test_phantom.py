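"""Electro-thermal simulator: conductivity law, field solvers, heat
stepping, impedance, and full treatment runs."""
import numpy as np
import pytest

from pulsetemp.geometry import (AGAR, NumericsConfig, PhantomGeometry,
                                ProbeGeometry, TreatmentCondition,
                                standard_conditions, update_conductivity)
from pulsetemp.mesh import (AGAR_NODE, AxiMesh, ELECTRODE_ACTIVE,
                            build_coaxial_mesh, build_phantom_mesh)
from pulsetemp.phantom import (TreatmentTrace, default_materials,
                               electric_field, joule_source,
                               phantom_resistance, run_treatment,
                               solve_potential, step_temperature)

COAX = dict(inner_radius=1e-3, outer_radius=10e-3, length=7e-3)
COAX_EXACT = np.log(10.0) / (2 * np.pi * 0.331 * 7e-3)  # 158.16 ohm


# ---------------------------------------------------------------- sigma(T)
@pytest.mark.parametrize("t, sigma0, alpha, t_ref, expected", [
    (37.0, 0.526, 0.02, 37.0, 0.526),      # identity at reference
    (18.8, 0.526, 0.02, 37.0, 0.334536),   # cooled agar
    (47.0, 0.122, 0.02, 37.0, 0.1464),     # warmed agar
])
def test_conductivity_temperature_scaling(t, sigma0, alpha, t_ref, expected):
    assert update_conductivity(t, sigma0, alpha, t_ref) == pytest.approx(
        expected, rel=1e-12)


def test_conductivity_guards():
    with pytest.raises(ValueError):
        update_conductivity(np.array([20.0, np.nan]), 0.5, 0.02, 37.0)
    with pytest.raises(ValueError):
        update_conductivity(20.0, -0.1, 0.02, 37.0)
    # extreme cooling clips at the floor instead of going negative
    assert update_conductivity(-5000.0, 0.5, 0.02, 37.0, floor=1e-6) == 1e-6


def test_condition_registry_implied_agar_temperatures():
    """The printed initial conductivities imply per-group pulse-time agar
    temperatures through the linear conductivity law."""
    conds = standard_conditions()
    assert conds["HV-HC"].agar_temperature == pytest.approx(18.46, abs=0.01)
    assert conds["LV-LC"].agar_temperature == pytest.approx(21.84, abs=0.01)
    assert conds["HV-LC"].agar_temperature == pytest.approx(25.11, abs=0.01)
    for cond in conds.values():
        # sigma_initial consistent with the law at the implied temperature
        back = update_conductivity(cond.agar_temperature, cond.sigma_ref,
                                   cond.alpha, 37.0)
        assert back == pytest.approx(cond.sigma_initial, rel=1e-9)


def test_voltage_to_distance_ratio(probe):
    """2500/1250 V across the 15 mm electrode spacing give the nominal
    1666/833 V/cm treatment intensities."""
    span_cm = probe.electrode_spacing * 100
    assert span_cm == pytest.approx(1.5)
    assert 2500 / span_cm == pytest.approx(1666.7, abs=0.1)
    assert 1250 / span_cm == pytest.approx(833.3, abs=0.1)


# ---------------------------------------------------------- potential solve
@pytest.fixture(scope="module")
def coax32():
    return build_coaxial_mesh(**COAX, n_radial=32, n_axial=4)


def test_coaxial_resistance_matches_closed_form(coax32):
    sigma = np.full(coax32.shape, 0.331)
    phi = solve_potential(coax32, sigma, 1.0)
    r = phantom_resistance(phi, sigma, coax32, 1.0)
    assert r == pytest.approx(COAX_EXACT, rel=5e-3)


def test_coaxial_convergence_under_refinement():
    errs = []
    for n in (16, 32, 64):
        mesh = build_coaxial_mesh(**COAX, n_radial=n, n_axial=4)
        sigma = np.full(mesh.shape, 0.331)
        phi = solve_potential(mesh, sigma, 1.0)
        errs.append(abs(phantom_resistance(phi, sigma, mesh, 1.0)
                        - COAX_EXACT) / COAX_EXACT)
    # first order or better under each halving of the spacing
    assert errs[1] <= errs[0] / 2 * 1.05
    assert errs[2] <= errs[1] / 2 * 1.05


def test_potential_linearity_and_max_principle(coax32):
    sigma = np.full(coax32.shape, 0.2)
    phi1 = solve_potential(coax32, sigma, 100.0)
    phi2 = solve_potential(coax32, sigma, 200.0)
    np.testing.assert_allclose(phi2, 2 * phi1, rtol=1e-12)
    assert phi1.min() >= -1e-9 and phi1.max() <= 100.0 + 1e-9
    # extrema sit on the electrodes
    assert phi1[0].max() == pytest.approx(100.0)
    assert abs(phi1[-1]).max() == pytest.approx(0.0, abs=1e-12)


def test_resistance_scales_inversely_with_conductivity(coax32):
    sigma = np.full(coax32.shape, 0.331)
    phi = solve_potential(coax32, sigma, 1.0)
    r1 = phantom_resistance(phi, sigma, coax32, 1.0)
    r2 = phantom_resistance(phi, 3.0 * sigma, coax32, 1.0)
    assert r2 == pytest.approx(r1 / 3.0, rel=1e-12)


def test_current_conserved_between_electrodes(coax32):
    sigma = np.full(coax32.shape, 0.331)
    phi = solve_potential(coax32, sigma, 5.0)
    r_active = phantom_resistance(phi, sigma, coax32, 5.0, electrode="active")
    r_ground = phantom_resistance(phi, sigma, coax32, 5.0, electrode="ground")
    assert r_active == pytest.approx(r_ground, rel=1e-10)


# ------------------------------------------------------------- |E| and QJ
def test_electric_field_uniform_and_ramp():
    r = np.linspace(1e-3, 2e-3, 5)
    z = np.linspace(0.0, 1e-2, 11)
    labels = np.zeros((5, 11), dtype=np.int8)
    labels[0, :] = 1
    labels[-1, :] = 2
    mesh = AxiMesh(r, z, labels, np.zeros((4, 11), np.int8),
                   np.zeros((5, 10), np.int8))
    np.testing.assert_allclose(
        electric_field(np.full(mesh.shape, 7.0), mesh), 0.0, atol=1e-9)
    phi = np.tile(100.0 * z / z[-1], (5, 1))  # 100 V over 1 cm along z
    np.testing.assert_allclose(electric_field(phi, mesh), 1e4, rtol=1e-9)


def test_joule_source_values():
    assert joule_source(0.331, 1e3, 100e-6, 1.0) == pytest.approx(33.1)
    assert joule_source(0.331, 0.0, 100e-6, 1.0) == 0.0
    assert joule_source(0.5, 10.0, 1.0, 1.0) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        joule_source(0.5, 10.0, 2.0, 1.0)


# ---------------------------------------------------------------- heat step
def test_heat_step_equilibrium_and_cooling(probe):
    phantom = PhantomGeometry()
    mesh = build_phantom_mesh(probe, phantom,
                              NumericsConfig(fine_spacing=1e-3,
                                             coarse_spacing=4e-3))
    mats = default_materials()
    t_amb = np.full(mesh.shape, phantom.ambient_temperature)
    out = step_temperature(mesh, t_amb, np.zeros(mesh.shape), 1.0, mats,
                           phantom)
    np.testing.assert_allclose(out, t_amb, rtol=0, atol=1e-10)
    hot = t_amb + 10.0
    cooled = step_temperature(mesh, hot, np.zeros(mesh.shape), 1.0, mats,
                              phantom)
    assert np.all(cooled <= hot + 1e-12)
    assert np.all(cooled >= t_amb - 1e-9)
    assert cooled.min() < hot.min()  # boundary actually cools


def test_heat_step_uniform_source_heats_one_degree(probe):
    """Adiabatic walls with a volumetric source equal to each node's heat
    capacity raise the whole field exactly 1 degC per second."""
    phantom = PhantomGeometry(convective_coefficient=0.0)
    mesh = build_phantom_mesh(probe, phantom,
                              NumericsConfig(fine_spacing=1e-3,
                                             coarse_spacing=4e-3))
    mats = default_materials()
    rho_cp = np.empty(mesh.shape)
    for label, m in mats.items():
        rho_cp[mesh.labels == label] = m.density * m.specific_heat
    t0 = np.full(mesh.shape, 20.0)
    t1 = step_temperature(mesh, t0, rho_cp, 1.0, mats, phantom)
    np.testing.assert_allclose(t1, 21.0, rtol=1e-9)


# ------------------------------------------------------------ run_treatment
def test_treatment_trace_has_one_hertz_samples(test_traces):
    for trace in test_traces.values():
        assert len(trace.time) == 301
        np.testing.assert_allclose(np.diff(trace.time), 1.0)


def test_zero_voltage_run_is_inert(coarse_numerics):
    cond = TreatmentCondition("null", 1e-9, 0.526, 0.526,
                              agar_temperature=18.8, duration=30.0)
    trace = run_treatment(cond, numerics=coarse_numerics)
    np.testing.assert_allclose(trace.T4, trace.T4[0], atol=1e-9)
    np.testing.assert_allclose(trace.T10, trace.T10[0], atol=1e-9)
    np.testing.assert_allclose(trace.dZ, 0.0, atol=1e-9)


def test_high_power_condition_dominates(coarse_numerics):
    conds = standard_conditions()
    short = {k: TreatmentCondition(k, c.applied_voltage, c.sigma_ref,
                                   c.sigma_initial, duration=60.0)
             for k, c in conds.items()}
    hv = run_treatment(short["HV-HC"], numerics=coarse_numerics)
    lv = run_treatment(short["LV-LC"], numerics=coarse_numerics)
    rise_hv = hv.T4 - hv.T4[0]
    rise_lv = lv.T4 - lv.T4[0]
    assert np.all(rise_hv[1:] > rise_lv[1:])
    assert np.all(hv.dZ[1:] < lv.dZ[1:])


def test_adiabatic_energy_balance(coarse_numerics, probe):
    """With no convective losses, the enthalpy gain of the phantom equals
    the time-integrated Joule power."""
    phantom = PhantomGeometry(convective_coefficient=0.0)
    cond = standard_conditions()["HV-HC"]
    cond = TreatmentCondition(cond.name, cond.applied_voltage,
                              cond.sigma_ref, cond.sigma_initial,
                              duration=60.0)
    mesh = build_phantom_mesh(probe, phantom, coarse_numerics)
    trace, state = run_treatment(cond, probe, phantom, coarse_numerics,
                                 mesh=mesh, full_output=True)
    mats = default_materials(cond.sigma_ref)
    rho_cp = np.empty(mesh.shape)
    for label, m in mats.items():
        rho_cp[mesh.labels == label] = m.density * m.specific_heat
    enthalpy = float(np.sum(rho_cp * mesh.volumes
                            * (state.temperature - cond.agar_temperature)))
    assert trace.deposited_energy > 0
    assert enthalpy == pytest.approx(trace.deposited_energy, rel=0.02)


def test_impedance_independent_of_voltage(default_mesh):
    """Quasi-static linearity: at a fixed conductivity field the computed
    impedance does not depend on the applied voltage."""
    sigma = np.full(default_mesh.shape, 0.331)
    z = []
    for v in (100.0, 2500.0):
        phi = solve_potential(default_mesh, sigma, v)
        z.append(phantom_resistance(phi, sigma, default_mesh, v))
    assert z[0] == pytest.approx(z[1], rel=1e-10)


def test_trace_csv_round_trip(tmp_path, test_traces):
    trace = test_traces["LV-HC"]
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == "time_s,T4_C,T10_C,Z_ohm,dZ_ohm"
    back = TreatmentTrace.from_csv(path, condition="LV-HC")
    np.testing.assert_allclose(back.T4, trace.T4, rtol=1e-12)
    np.testing.assert_allclose(back.dZ, trace.dZ, atol=1e-9)


def test_sensor_point_outside_mesh_rejected(default_mesh):
    with pytest.raises(ValueError, match="outside"):
        default_mesh.interpolate(np.zeros(default_mesh.shape), 1.0, 0.0)


def test_phantom_must_cover_sensors():
    with pytest.raises(ValueError):
        build_phantom_mesh(ProbeGeometry(), PhantomGeometry(radius=8e-3),
                           NumericsConfig())
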