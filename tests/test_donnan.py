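"""Donnan equilibrium with excess-chemical-potential corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from donnanflux.donnan import (infer_delta_mu_cl, infer_delta_mu_gd,
                               linearized_donnan_potential,
                               linearized_partition_ratio, linearized_steps,
                               partition_ratio, solve_donnan_equilibrium)
from donnanflux.parameters import BathComposition, get_parameter_set

from conftest import SET_NAMES, PARAM_TABLE, make_ion


def bisection_psi_oracle(bath, na, cl, tol=1e-12):
    """Independent 1-D bisection on the electroneutrality residual in psi."""

    def res(psi):
        c = bath.c_nacl_salt
        return (c * np.exp(-na.delta_mu_corr - psi)
                - c * np.exp(-cl.delta_mu_corr + psi) + bath.fcd)

    lo, hi = -5.0, 5.0
    assert res(lo) * res(hi) < 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if res(lo) * res(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@pytest.mark.parametrize("fcd", sorted(PARAM_TABLE))
def test_equilibrium_reproduces_measured_concentrations(fcd):
    """Solved polyelectrolyte-side Na+/Cl- match the measured table to
    integer-mM rounding, and electroneutrality holds to 1e-10."""
    p = get_parameter_set(SET_NAMES[fcd])
    state = solve_donnan_equilibrium(p.bath, p.na, p.cl)
    c_na, c_cl = PARAM_TABLE[fcd][:2]
    assert round(state.c_na_poly) == c_na
    assert round(state.c_cl_poly) == c_cl
    assert abs(state.electroneutrality_residual) < 1e-10


def test_ideal_limit_is_symmetric(ideal_bath):
    """No fixed charge and ideal ions: zero potential, equal concentrations."""
    na = make_ion("Na+", +1)
    cl = make_ion("Cl-", -1)
    state = solve_donnan_equilibrium(ideal_bath, na, cl)
    assert state.psi == pytest.approx(0.0, abs=1e-12)
    assert state.c_na_poly == pytest.approx(150.0, rel=1e-12)
    assert state.c_cl_poly == pytest.approx(150.0, rel=1e-12)


def test_solver_matches_bisection_oracle(pset_108):
    """Frozen oracle value -0.2755 from independent bisection."""
    state = solve_donnan_equilibrium(pset_108.bath, pset_108.na, pset_108.cl)
    oracle = bisection_psi_oracle(pset_108.bath, pset_108.na, pset_108.cl)
    assert state.psi == pytest.approx(oracle, abs=1e-10)
    assert state.psi == pytest.approx(-0.2755, abs=5e-5)


@pytest.mark.parametrize("fcd", sorted(PARAM_TABLE))
def test_delta_mu_cl_inference_from_measured_concentrations(fcd):
    """Recovered dmu_Cl agrees with the tabulated values; the source
    concentrations are integer-rounded, which propagates ~0.004 RT."""
    c_na, c_cl, dmu_na, dmu_cl, *_ = PARAM_TABLE[fcd]
    got = infer_delta_mu_cl(c_na, c_cl, 150.0, dmu_na)
    assert got == pytest.approx(dmu_cl, abs=5e-3)


def test_delta_mu_cl_trivial_and_errors():
    assert infer_delta_mu_cl(150.0, 150.0, 150.0, 0.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        infer_delta_mu_cl(-1.0, 150.0, 150.0, 0.0)


def test_delta_mu_cl_roundtrip_through_solver(pset_108):
    """infer_delta_mu_cl o solve is the identity on dmu_Cl (1e-10)."""
    state = solve_donnan_equilibrium(pset_108.bath, pset_108.na, pset_108.cl)
    got = infer_delta_mu_cl(state.c_na_poly, state.c_cl_poly,
                            pset_108.bath.c_nacl_salt,
                            pset_108.na.delta_mu_corr)
    assert got == pytest.approx(pset_108.cl.delta_mu_corr, abs=1e-10)


@pytest.mark.parametrize("fcd", sorted(PARAM_TABLE))
def test_contrast_agent_partition_ratios(fcd):
    """Gd(DTPA)2- partition ratio 0.82/0.78/0.74 per FCD, +-0.005."""
    p = get_parameter_set(SET_NAMES[fcd])
    state = solve_donnan_equilibrium(p.bath, p.na, p.cl)
    assert partition_ratio(p.gd, state) == pytest.approx(
        PARAM_TABLE[fcd][6], abs=0.005)


def test_neutral_ion_partitions_unity(pset_108):
    state = solve_donnan_equilibrium(pset_108.bath, pset_108.na, pset_108.cl)
    assert partition_ratio(make_ion("N", 0, 1e-9, 0.0), state) == 1.0


def test_delta_mu_gd_roundtrip(pset_108):
    """infer_delta_mu_gd inverts partition_ratio exactly, and reproduces
    the tabulated -0.2500 RT from the 0.74 ratio."""
    state = solve_donnan_equilibrium(pset_108.bath, pset_108.na, pset_108.cl)
    r = partition_ratio(pset_108.gd, state)
    assert infer_delta_mu_gd(r * 0.2, 0.2, state) == pytest.approx(
        pset_108.gd.delta_mu_corr, abs=1e-10)
    assert infer_delta_mu_gd(0.74 * 1.0, 1.0, state) == pytest.approx(
        -0.2500, abs=2e-4)
    # ideal divalent ion: ratio = exp(2 psi) maps back to dmu = 0
    assert infer_delta_mu_gd(np.exp(2 * state.psi), 1.0, state) == (
        pytest.approx(0.0, abs=1e-12))


def test_linearized_potential_example(pset_108):
    psi_lin = linearized_donnan_potential(pset_108.bath, pset_108.na,
                                          pset_108.cl)
    assert psi_lin == pytest.approx(-0.3044, abs=1e-4)
    # exact solve differs in the expected direction and magnitude
    state = solve_donnan_equilibrium(pset_108.bath, pset_108.na, pset_108.cl)
    assert state.psi == pytest.approx(-0.2755, abs=1e-4)


def test_linearized_steps_arithmetic(pset_108):
    dna, dcl, dgd = linearized_steps(pset_108.bath, pset_108.na, pset_108.cl,
                                     pset_108.gd, 0.2)
    assert dgd == pytest.approx(0.2 * (0.3612 - 0.72), abs=1e-6)
    assert dna == pytest.approx(63.8, abs=0.1)
    # exact Na step for comparison: ~73 mM
    state = solve_donnan_equilibrium(pset_108.bath, pset_108.na, pset_108.cl)
    assert state.c_na_poly - 150.0 == pytest.approx(73.0, abs=0.1)


def test_linearized_steps_vanish_for_ideal_system(ideal_bath):
    na, cl, gd = make_ion("Na+", 1), make_ion("Cl-", -1), make_ion("G", -2)
    assert linearized_steps(ideal_bath, na, cl, gd, 0.2) == (0.0, 0.0, 0.0)


def test_linearization_error_is_second_order():
    """Relative error of the linearized psi and steps scales as
    O((FCD/C)^2): log-log slope >= 1.8 over FCD = -5, -10, -20 mM."""
    na = make_ion("Na+", +1)
    cl = make_ion("Cl-", -1)
    gd = make_ion("G", -2)
    fcds = np.array([-5.0, -10.0, -20.0])
    err_psi, err_ratio = [], []
    for fcd in fcds:
        bath = BathComposition(150.0, fcd)
        state = solve_donnan_equilibrium(bath, na, cl)
        psi_lin = linearized_donnan_potential(bath, na, cl)
        err_psi.append(abs(psi_lin - state.psi) / abs(state.psi))
        r_lin = linearized_partition_ratio(bath, na, cl, gd)
        r = partition_ratio(gd, state)
        err_ratio.append(abs(r_lin - r) / r)
    for err in (err_psi, err_ratio):
        slope = np.polyfit(np.log(-fcds), np.log(err), 1)[0]
        assert slope >= 1.8


def test_partition_ratio_mirror_symmetries():
    """For ideal ions the Donnan potential is odd in FCD, so negating
    either the FCD or the valence inverts the partition ratio, and
    negating both leaves it unchanged."""
    na, cl = make_ion("Na+", +1), make_ion("Cl-", -1)
    s_neg = solve_donnan_equilibrium(BathComposition(150.0, -80.0), na, cl)
    s_pos = solve_donnan_equilibrium(BathComposition(150.0, +80.0), na, cl)
    assert s_pos.psi == pytest.approx(-s_neg.psi, rel=1e-10)
    r = partition_ratio(make_ion("A", -2), s_neg)
    assert r * partition_ratio(make_ion("A", -2), s_pos) == pytest.approx(
        1.0, rel=1e-10)
    assert r * partition_ratio(make_ion("B", +2), s_neg) == pytest.approx(
        1.0, rel=1e-10)
    assert partition_ratio(make_ion("B", +2), s_pos) == pytest.approx(
        r, rel=1e-10)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(fcd=st.floats(-250.0, 0.0),
       dmu_na=st.floats(-0.4, 0.2),
       dmu_cl=st.floats(-0.4, 0.2),
       dmu_gd=st.floats(-0.6, 0.2))
def test_equilibrium_properties_hold_generically(fcd, dmu_na, dmu_cl, dmu_gd):
    """Electroneutrality and both inference round trips hold across the
    physical parameter range."""
    bath = BathComposition(150.0, fcd)
    na = make_ion("Na+", +1, 1.33e-9, dmu_na)
    cl = make_ion("Cl-", -1, 2.03e-9, dmu_cl)
    gd = make_ion("G", -2, 4.5e-10, dmu_gd)
    state = solve_donnan_equilibrium(bath, na, cl)
    assert abs(state.electroneutrality_residual) < 1e-10
    assert infer_delta_mu_cl(
        state.c_na_poly, state.c_cl_poly, 150.0, dmu_na
    ) == pytest.approx(dmu_cl, abs=1e-9)
    r = partition_ratio(gd, state)
    assert infer_delta_mu_gd(r, 1.0, state) == pytest.approx(dmu_gd, abs=1e-9)
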