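"""Resolved Nernst-Planck-Poisson and macroscopic jump-condition solvers."""

import numpy as np
import pytest

from donnanflux.donnan import partition_ratio, solve_donnan_equilibrium
from donnanflux.io import ProfileSeries
from donnanflux.parameters import BathComposition, get_parameter_set
from donnanflux.transport import (Geometry1D, InterfaceCondition,
                                  bulk_migration_flux_fraction,
                                  equilibrium_poly_concentration,
                                  jump_interface_solver, resolved_mesh,
                                  smoothed_mu_corr, solve_background_steady,
                                  solve_gd_transport, step_size_timeseries,
                                  time_to_fraction)

from conftest import make_ion


@pytest.fixture(scope="module")
def short_geometry():
    return Geometry1D(-2e-3, 0.0, 2e-3)


@pytest.fixture(scope="module")
def background_108(short_geometry):
    p = get_parameter_set("fcd-108")
    return solve_background_steady(short_geometry, p.bath, p.na, p.cl)


# -- chemical-potential smoothing -------------------------------------------


def test_smoothed_mu_corr_midpoint_limits_and_antisymmetry():
    ion = make_ion("G", -2, 1e-9, -0.25)
    w = 1e-9
    assert smoothed_mu_corr(0.0, ion, w) == pytest.approx(-0.125)
    # five widths into the salt side: essentially the salt value (0)
    assert abs(smoothed_mu_corr(5 * w, ion, w)) < 1e-11
    assert smoothed_mu_corr(-5 * w, ion, w) == pytest.approx(-0.25,
                                                             abs=1e-11)
    z = np.linspace(-4e-9, 4e-9, 33)
    total = smoothed_mu_corr(z, ion, w) + smoothed_mu_corr(-z, ion, w)
    assert np.allclose(total, -0.25)  # mu_p + mu_s for erf antisymmetry


# -- steady background -------------------------------------------------------


def test_mesh_resolves_interface_and_regions():
    geo = Geometry1D(-2e-3, 100e-6, 2e-3)
    faces = resolved_mesh(geo)
    assert faces[0] == pytest.approx(geo.z_poly_bottom)
    assert faces[-1] == pytest.approx(geo.d_salt)
    assert 0.0 in faces
    assert np.any(np.isclose(faces, geo.membrane_thickness))
    near = np.diff(faces)[np.argmin(np.abs(faces[:-1]))]
    assert near < 1e-9  # sub-nm next to the interface
    assert np.all(np.diff(faces) > 0)


def test_background_ideal_system_is_flat(short_geometry, ideal_bath):
    na, cl = make_ion("Na+", +1), make_ion("Cl-", -1)
    bg = solve_background_steady(short_geometry, ideal_bath, na, cl)
    assert np.max(np.abs(bg.psi)) < 1e-12
    assert np.allclose(bg.conc["Na+"], 150.0)
    assert np.allclose(bg.conc["Cl-"], 150.0)


def test_background_plateaus_match_donnan(background_108):
    """Bulk concentrations and the potential step equal the 0-D Donnan
    solution (223/115 mM, psi = -0.2755) far from the interface."""
    p = get_parameter_set("fcd-108")
    exact = solve_donnan_equilibrium(p.bath, p.na, p.cl)
    assert background_108.psi[0] == pytest.approx(exact.psi, abs=1e-6)
    assert background_108.psi[-1] == 0.0
    assert background_108.conc["Na+"][0] == pytest.approx(223.0, abs=0.1)
    assert background_108.conc["Cl-"][0] == pytest.approx(115.0, abs=0.1)
    # potential relaxes exponentially; fully settled ~20 Debye lengths out
    mid = np.abs(background_108.z) > 20 * background_108.debye
    plateau = np.where(background_108.z[mid] < 0, exact.psi, 0.0)
    assert np.max(np.abs(background_108.psi[mid] - plateau)) < 1e-6


def test_background_flux_is_zero(background_108):
    """Steady state: the electrochemical potential gradient of each
    background ion vanishes at every interior node."""
    p = get_parameter_set("fcd-108")
    for ion in (p.na, p.cl):
        mu = (np.log(background_108.conc[ion.name] / 150.0)
              + smoothed_mu_corr(background_108.z, ion,
                                 background_108.mu_width)
              - smoothed_mu_corr(background_108.z[-1], ion,
                                 background_108.mu_width)
              + ion.valence * background_108.psi)
        assert np.max(np.abs(np.diff(mu))) < 1e-12


# -- resolved contrast-agent transport ---------------------------------------


def test_uniform_ideal_profile_stays_uniform(short_geometry, ideal_bath):
    na, cl = make_ion("Na+", +1), make_ion("Cl-", -1)
    gd = make_ion("G", -2, 4.5e-10, 0.0)
    bg = solve_background_steady(short_geometry, ideal_bath, na, cl)
    n_cells = bg.z.size - 1
    ser = solve_gd_transport(short_geometry, ideal_bath, gd, bg, t_end=3600.0,
                             times=np.array([0.0, 1800.0, 3600.0]),
                             salt_boundary="closed",
                             c_init=np.full(n_cells, 0.2))
    assert np.allclose(ser.conc, 0.2, atol=1e-9)


def test_resolved_interface_ratio_is_time_invariant(short_geometry,
                                                    background_108):
    """The macroscopic concentration ratio across z = 0 equals the Donnan
    partition and does not drift while transport proceeds."""
    p = get_parameter_set("fcd-108")
    exact = solve_donnan_equilibrium(p.bath, p.na, p.cl)
    r_exact = partition_ratio(p.gd, exact)
    times = np.array([0.0, 1800.0, 3600.0, 7200.0, 10800.0])
    ser = solve_gd_transport(short_geometry, p.bath, p.gd, background_108,
                             t_end=times[-1], times=times)
    steps = step_size_timeseries(ser)
    ratios = steps["ratio"].to_numpy()[1:]
    assert np.max(np.abs(ratios - r_exact)) / r_exact < 1e-3


def test_resolved_closed_system_reaches_donnan_partition(ideal_bath):
    """Equilibrium limit on a micro-domain: c_poly/c_salt -> the Boltzmann
    partition everywhere (1e-3)."""
    p = get_parameter_set("fcd-108")
    geo = Geometry1D(-2e-4, 0.0, 2e-4)
    bg = solve_background_steady(geo, p.bath, p.na, p.cl)
    t_eq = 40.0 * (2e-4) ** 2 / p.gd.d_poly
    ser = solve_gd_transport(geo, p.bath, p.gd, bg, t_end=t_eq,
                             times=np.array([0.0, t_eq]),
                             salt_boundary="closed")
    exact = solve_donnan_equilibrium(p.bath, p.na, p.cl)
    r = partition_ratio(p.gd, exact)
    zc = ser.z
    bulk_p = zc < -1e-6
    bulk_s = zc > 1e-6
    c_p = ser.conc[-1][bulk_p].mean()
    c_s = ser.conc[-1][bulk_s].mean()
    assert c_p / c_s == pytest.approx(r, rel=1e-3)
    # spatially uniform within each phase
    assert np.ptp(ser.conc[-1][bulk_p]) / c_p < 1e-3
    assert np.ptp(ser.conc[-1][bulk_s]) / c_s < 1e-3


def test_electromigration_negligible_in_bulk(short_geometry, background_108):
    """Outside the double layer the drift flux is <1% of the Fickian flux
    at the experimental trace concentrations."""
    p = get_parameter_set("fcd-108")
    ser = solve_gd_transport(short_geometry, p.bath, p.gd, background_108,
                             t_end=10800.0,
                             times=np.array([0.0, 10800.0]))
    frac = bulk_migration_flux_fraction(background_108, p.gd, ser, 10800.0)
    assert frac < 0.01


# -- jump-condition tier ------------------------------------------------------


def test_jump_solver_matches_resolved_solver(short_geometry, background_108):
    """Tier equivalence: macroscopic jump solution within 0.5% of the
    resolved NPP solution everywhere outside the interface cell, t >= 1 h."""
    p = get_parameter_set("fcd-108")
    exact = solve_donnan_equilibrium(p.bath, p.na, p.cl)
    r = partition_ratio(p.gd, exact)
    times = np.array([0.0, 3600.0, 7200.0, 10800.0])
    res = solve_gd_transport(short_geometry, p.bath, p.gd, background_108,
                             t_end=times[-1], times=times)
    jump = jump_interface_solver(short_geometry, p.gd,
                                 InterfaceCondition(r), times=times,
                                 c_salt_initial=0.33, dz=2.5e-5)
    mask = np.abs(res.z) > 3e-5
    ji = jump.interp(res.z[mask])
    dev = np.abs(ji.conc[1:] - res.conc[1:][:, mask]) / 0.33
    assert dev.max() < 0.005


def test_jump_solver_conserves_mass_and_equilibrates():
    p = get_parameter_set("fcd-108")
    geo = Geometry1D(-2e-3, 0.0, 2e-3)
    times = np.linspace(0.0, 2e5, 11)
    ser = jump_interface_solver(geo, p.gd, 0.74, times=times,
                                c_salt_initial=0.33, boundary="closed",
                                dz=2.5e-5)
    mass = np.sum(ser.conc * ser.cell_dz, axis=1)
    assert np.max(np.abs(mass / mass[0] - 1.0)) < 1e-3
    eq = equilibrium_poly_concentration(geo, 0.74, 0.33, "closed")
    assert ser.conc[-1][ser.z < 0].mean() == pytest.approx(eq, rel=1e-3)


def test_jump_solver_continuous_when_ratio_is_one():
    gd = make_ion("G", -2, 4.5e-10, 0.0)
    geo = Geometry1D(-2e-3, 0.0, 2e-3)
    ser = jump_interface_solver(geo, gd, 1.0,
                                times=np.array([0.0, 3600.0]),
                                c_salt_initial=0.33, dz=2.5e-5)
    steps = step_size_timeseries(ser)
    assert abs(steps["step_mM"].iloc[-1]) < 1e-4


def test_invalid_ratio_rejected():
    gd = make_ion("G", -2)
    geo = Geometry1D(-2e-3, 0.0, 2e-3)
    with pytest.raises(ValueError):
        jump_interface_solver(geo, gd, -0.5, times=np.array([0.0, 10.0]))
    with pytest.raises(ValueError):
        InterfaceCondition(0.0)


def test_grid_refinement_convergence():
    """Halving the macroscopic spacing changes profiles by <0.2%."""
    p = get_parameter_set("fcd-108")
    geo = Geometry1D(-5e-3, 100e-6, 3e-3)
    times = 3600.0 * np.array([0.0, 1.0, 3.0, 6.0])
    a = jump_interface_solver(geo, p.gd, 0.74, times=times,
                              c_salt_initial=0.33, dz=1e-4)
    b = jump_interface_solver(geo, p.gd, 0.74, times=times,
                              c_salt_initial=0.33, dz=5e-5)
    mask = np.abs(a.z) > 2e-4
    bi = b.interp(a.z[mask])
    dev = np.abs(bi.conc - a.conc[:, mask]) / 0.33
    assert dev.max() < 0.002


def test_step_size_grows_against_far_wall():
    """|step| increases once the agent accumulates at the closed bottom."""
    p = get_parameter_set("fcd-108")
    geo = Geometry1D(-1e-3, 0.0, 4e-3)
    times = np.linspace(0.0, 4e4, 9)
    ser = jump_interface_solver(geo, p.gd, 0.74, times=times,
                                c_salt_initial=0.33, dz=2.5e-5)
    steps = step_size_timeseries(ser)["step_mM"].to_numpy()[1:]
    assert np.all(np.diff(np.abs(steps)) > 0)


# -- derived quantities -------------------------------------------------------


def test_time_to_fraction_contract():
    p = get_parameter_set("fcd-108")
    geo = Geometry1D(-2e-3, 0.0, 0.0)
    times = np.linspace(0.0, 5e4, 60)
    ser = jump_interface_solver(geo, p.gd, 0.74, times=times,
                                c_salt_initial=0.33,
                                boundary="interface_dirichlet",
                                boundary_value=0.33, dz=2.5e-5)
    eq = equilibrium_poly_concentration(geo, 0.74, 0.33,
                                        "interface_dirichlet")
    assert time_to_fraction(ser, 0.0, eq) == 0.0
    t50 = time_to_fraction(ser, 0.5, eq)
    t80 = time_to_fraction(ser, 0.8, eq)
    assert 0.0 < t50 < t80
    with pytest.raises(ValueError):
        time_to_fraction(ser, 0.999999, eq)


def test_equilibration_time_scales_as_length_squared():
    """Doubling the polyelectrolyte length quadruples the time to any fixed
    average fraction (semi-infinite feed, ratio 4 within 5%)."""
    p = get_parameter_set("fcd-108")

    def t_half(length):
        geo = Geometry1D(-length, 0.0, 0.0)
        times = np.linspace(0.0, 3.0 * length**2 / p.gd.d_poly, 240)
        ser = jump_interface_solver(geo, p.gd, 0.74, times=times,
                                    c_salt_initial=0.33,
                                    boundary="interface_dirichlet",
                                    boundary_value=0.33, dz=length / 80)
        eq = equilibrium_poly_concentration(geo, 0.74, 0.33,
                                            "interface_dirichlet")
        return time_to_fraction(ser, 0.5, eq)

    ratio = t_half(4e-3) / t_half(2e-3)
    assert ratio == pytest.approx(4.0, rel=0.05)


def test_full_geometry_halftime_is_tens_of_hours():
    """Order of magnitude: 10 mm polyelectrolyte, closed reservoir - the
    50% equilibration time lands in the tens of hours."""
    p = get_parameter_set("fcd-108")
    geo = Geometry1D(-10e-3, 100e-6, 13e-3)
    times = np.linspace(0.0, 3600.0 * 400, 120)
    ser = jump_interface_solver(geo, p.gd, 0.74, times=times,
                                c_salt_initial=0.33, boundary="closed",
                                dz=1e-4)
    eq = equilibrium_poly_concentration(geo, 0.74, 0.33, "closed")
    t50 = time_to_fraction(ser, 0.5, eq, z_range=(-10e-3, 0.0))
    assert 10.0 < t50 / 3600.0 < 100.0


def test_geometry_validation():
    with pytest.raises(ValueError):
        Geometry1D(z_poly_bottom=1e-3)
    with pytest.raises(ValueError):
        Geometry1D(-1e-3, 2e-4, 1e-4)
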