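"""Rate-law unit tests: closed-form values, half-saturation identities,
monotonicity in composition and core load, and the independently coded
derivative oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferrisim import (
    KineticParameters,
    ModelState,
    atoms_per_cage,
    derivatives,
    mineralization_rate,
    nucleation_rate,
    oxidation_rate,
    reduction_rate,
    subunit_nucleation_factor,
    subunit_oxidation_factor,
)


@pytest.mark.parametrize(
    "H,rO,expected",
    [(24, 2.0, 1.0), (0, 2.0, 2.0 / 26.0), (4, 2.0, 6.0 / 26.0)],
)
def test_oxidation_factor_values(H, rO, expected):
    assert subunit_oxidation_factor(H, rO) == pytest.approx(expected, rel=1e-15)


@pytest.mark.parametrize(
    "H,rN,expected",
    [(0, 50.0, 1.0), (24, 50.0, 50.0 / 74.0), (12, 50.0, 62.0 / 74.0)],
)
def test_nucleation_factor_values(H, rN, expected):
    assert subunit_nucleation_factor(H, rN) == pytest.approx(expected, rel=1e-15)


def test_subunit_factors_monotone_in_H():
    ox = [subunit_oxidation_factor(h) for h in range(25)]
    nuc = [subunit_nucleation_factor(h) for h in range(25)]
    assert np.all(np.diff(ox) > 0)
    assert np.all(np.diff(nuc) < 0)
    # the L->H oxidation span is far wider than the nucleation span
    assert ox[-1] / ox[0] > 10 > nuc[0] / nuc[-1]


@pytest.mark.parametrize("H", [-1, 25])
def test_subunit_factor_rejects_bad_composition(H):
    with pytest.raises(ValueError):
        subunit_oxidation_factor(H)
    with pytest.raises(ValueError):
        subunit_nucleation_factor(H)


class TestOxidation:
    def test_zero_substrate_and_zero_catalyst(self, params):
        assert oxidation_rate(ModelState(0, 1e-6, 0, 1e-6), params) == 0.0
        assert oxidation_rate(ModelState(1e-3, 0, 0, 0), params) == 0.0

    def test_half_saturation_identity(self, params):
        """At LIP = Km the Hill term is exactly 1/2 regardless of n."""
        p = params.with_(H=24)
        st = ModelState(LIP=p.ox_Km, DFP=0, core=0, FT=4.2e-6)
        expected = 591.0 * 1.0 * 4.2e-6 * 0.5
        assert oxidation_rate(st, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.241e-3, rel=1e-3)

    def test_saturates_at_high_lip(self, params):
        st = ModelState(LIP=1.0, DFP=0, core=0, FT=1e-6)
        vmax = params.ox_kcat * subunit_oxidation_factor(params.H) * 1e-6
        assert oxidation_rate(st, params) == pytest.approx(vmax, rel=1e-3)


class TestReduction:
    def test_mass_action(self, params):
        assert reduction_rate(ModelState(0, 0, 0, 0), params) == 0.0
        v1 = reduction_rate(ModelState(0, 1e-6, 0, 0), params)
        v2 = reduction_rate(ModelState(0, 2e-6, 0, 0), params)
        assert v1 == pytest.approx(2.605e-7, rel=1e-12)
        assert v2 == pytest.approx(2.0 * v1, rel=1e-15)


class TestNucleation:
    def test_zero_substrate(self, params):
        assert nucleation_rate(ModelState(1e-3, 0, 1e-5, 1e-6), params) == 0.0

    def test_product_inhibition_half_at_Ki(self, params):
        base = ModelState(LIP=0, DFP=1e-6, core=0, FT=5e-9)
        at_ki = ModelState(LIP=0, DFP=1e-6, core=params.nuc_Ki, FT=5e-9)
        assert nucleation_rate(at_ki, params) == pytest.approx(
            0.5 * nucleation_rate(base, params), rel=1e-12
        )

    def test_l_homopolymer_value(self, params):
        p = params.with_(H=0)
        st = ModelState(LIP=0, DFP=1e-6, core=0, FT=5e-9)
        assert nucleation_rate(st, p) == pytest.approx(2.5e-13, rel=1e-12)

    def test_monotone_decreasing_in_core(self, params):
        cores = np.linspace(0, 5e-3, 30)
        rates = [
            nucleation_rate(ModelState(0, 1e-6, c, 5e-9), params) for c in cores
        ]
        assert np.all(np.diff(rates) < 0)


class TestMineralization:
    def test_needs_core_and_substrate(self, params):
        assert mineralization_rate(ModelState(0, 1e-5, 0, 1e-6), params) == 0.0
        assert mineralization_rate(ModelState(0, 0, 1e-5, 1e-6), params) == 0.0

    def test_full_cages_shut_off(self, params):
        ft = 5e-9
        st = ModelState(LIP=0, DFP=1e-5, core=params.capacity * ft, FT=ft)
        assert mineralization_rate(st, params) == 0.0

    def test_dfp_half_saturation_value(self, params):
        """At DFP = Km the hyperbolic term is exactly 1/2; at this small core
        the inhibition and capacity terms are within 1e-8 of unity."""
        st = ModelState(LIP=0, DFP=params.min_Km, core=1e-5, FT=2.32e-6)
        v = mineralization_rate(st, params)
        assert v == pytest.approx(5.078e-7, rel=1e-3)
        inhib = params.min_Ki**4 / (params.min_Ki**4 + (1e-5) ** 4)
        apc = 1e-5 / 2.32e-6
        cap = 1.0 - (apc / params.capacity) ** 8
        assert v == pytest.approx(
            params.min_kcat * 1e-5 * 0.5 * inhib * cap, rel=1e-12
        )

    def test_core_inhibition_half_at_Ki(self, params):
        """Factor out the core-proportional catalysis: the inhibition term
        alone halves the normalized rate at core = Ki."""
        ft = 1e3  # absurdly high cages so apc ~ 0 and the capacity term is 1
        v_ki = mineralization_rate(ModelState(0, 1e-5, params.min_Ki, ft), params)
        small = 1e-9
        v_small = mineralization_rate(ModelState(0, 1e-5, small, ft), params)
        ratio = (v_ki / params.min_Ki) / (v_small / small)
        assert ratio == pytest.approx(0.5, rel=1e-9)

    def test_vanishes_as_apc_approaches_capacity(self, params):
        ft = 2.32e-6
        apcs = np.linspace(3000, 4300, 14)
        rates = [
            mineralization_rate(ModelState(0, 1e-5, a * ft, ft), params) for a in apcs
        ]
        assert np.all(np.diff(rates) < 0)
        assert rates[-1] == 0.0


class TestAtomsPerCage:
    def test_fig_conditions(self):
        assert atoms_per_cage(1.09e-3, 2.32e-6) == pytest.approx(470.0, abs=0.5)

    def test_edge_cases(self):
        assert atoms_per_cage(0.0, 5e-9) == 0.0
        assert atoms_per_cage(4300 * 5e-9, 5e-9) == pytest.approx(4300.0, rel=1e-12)
        with pytest.raises(ValueError):
            atoms_per_cage(1e-6, 0.0)


def _oracle_derivatives(y, p):
    """Independently hand-coded rate laws and stoichiometry (kept deliberately
    separate from the package implementation)."""
    LIP, DFP, core, FT = y
    v_ox = (
        p.ox_kcat * (p.H + p.rO) / (24 + p.rO) * FT
        * LIP**p.ox_n / (p.ox_Km**p.ox_n + LIP**p.ox_n)
    )
    v_red = p.red_kdeg * DFP
    v_nuc = (
        p.nuc_kcat * DFP**2 * FT * (24 - p.H + p.rN) / (24 + p.rN)
        * p.nuc_Ki**p.nuc_n / (p.nuc_Ki**p.nuc_n + core**p.nuc_n)
    )
    apc = core / FT if FT > 0 else p.capacity
    v_min = (
        p.min_kcat * DFP / (p.min_Km + DFP) * core
        * p.min_Ki**p.min_n / (p.min_Ki**p.min_n + core**p.min_n)
        * max(0.0, (p.capacity**p.min_m - apc**p.min_m) / p.capacity**p.min_m)
    )
    rel = p.ft_kdeg * core
    return np.array(
        [
            -2 * v_ox + 2 * v_red + rel,
            v_ox - v_red - 2 * v_nuc - v_min,
            4 * v_nuc + 2 * v_min - rel,
            p.ft_ksyn - p.ft_kdeg * FT,
        ]
    )


@pytest.mark.parametrize("turnover", [False, True])
def test_derivatives_match_independent_oracle(turnover):
    """Derivative assembly agrees with a brute-force evaluation of the rate
    formulas on 100 random valid states to 1e-12 relative."""
    rng = np.random.default_rng(42)
    p = KineticParameters(
        H=int(rng.integers(0, 25)),
        ft_ksyn=6.015e-14 if turnover else 0.0,
        ft_kdeg=1.203e-5 if turnover else 0.0,
    )
    for _ in range(100):
        y = 10.0 ** rng.uniform(-9, -2, size=4)
        st = ModelState.from_array(y)
        got = derivatives(st, p)
        want = _oracle_derivatives(y, p)
        scale = np.maximum(np.abs(want), 1e-300)
        assert np.all(np.abs(got - want) / scale < 1e-12)


@pytest.mark.parametrize("turnover", [False, True])
def test_iron_conservation_by_construction(turnover):
    """d/dt (LIP + 2 DFP + core) vanishes for any state, with and without
    cage turnover (degraded cages return their core iron to the LIP)."""
    rng = np.random.default_rng(7)
    p = KineticParameters(
        ft_ksyn=1e-13 if turnover else 0.0, ft_kdeg=1.203e-5 if turnover else 0.0
    )
    for _ in range(50):
        st = ModelState.from_array(10.0 ** rng.uniform(-9, -2, size=4))
        d = derivatives(st, p)
        total = d[0] + 2 * d[1] + d[2]
        assert abs(total) < 1e-12 * max(abs(d[0]), abs(d[1]), abs(d[2]), 1e-300)


def test_turnover_only_fluxes(params):
    p = params.with_(ft_kdeg=1.203e-5)
    st = ModelState(LIP=0, DFP=0, core=1e-8, FT=5e-9)
    d = derivatives(st, p)
    assert d[0] == pytest.approx(1.203e-13, rel=1e-12)
    assert d[2] == pytest.approx(-1.203e-13, rel=1e-12)


def test_empty_state_is_stationary(params):
    d = derivatives(ModelState(0, 0, 0, 0), params)
    assert np.all(d == 0.0)


_conc = st.floats(min_value=0.0, max_value=1e-2, allow_nan=False)


@given(
    LIP=_conc,
    DFP=_conc,
    core=_conc,
    FT=st.floats(min_value=0.0, max_value=1e-3, allow_nan=False),
    H=st.integers(min_value=0, max_value=23),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_rate_law_invariants_hold_for_arbitrary_states(LIP, DFP, core, FT, H):
    """For any valid state: all fluxes are non-negative, total iron is
    conserved by the reaction stoichiometry, and adding a heavy subunit
    never slows oxidation nor speeds nucleation."""
    from ferrisim import reaction_rates

    st_ = ModelState(LIP, DFP, core, FT)
    p = KineticParameters(H=H)
    r = reaction_rates(st_, p)
    assert min(r.v_ox, r.v_red, r.v_nuc, r.v_min) >= 0.0
    d = derivatives(st_, p)
    total = d[0] + 2 * d[1] + d[2]
    assert abs(total) <= 1e-12 * max(abs(d[0]), 2 * abs(d[1]), abs(d[2]), 1e-300)
    r_up = reaction_rates(st_, p.with_(H=H + 1))
    assert r_up.v_ox >= r.v_ox
    assert r_up.v_nuc <= r.v_nuc


def test_state_rejects_negative_concentrations():
    with pytest.raises(ValueError):
        ModelState(-1e-9, 0, 0, 0)
    with pytest.raises(ValueError):
        ModelState(0, 0, 0, 1e-9, t=-1.0)


def test_packaged_default_parameter_file_matches_dataclass_defaults():
    from ferrisim import load_parameters

    assert load_parameters() == KineticParameters()


def test_parameter_file_roundtrip(tmp_path):
    from ferrisim import dump_parameters, load_parameters

    p = KineticParameters(H=12, ft_ksyn=6.015e-14, ft_kdeg=1.203e-5)
    path = tmp_path / "params.cfg"
    dump_parameters(p, path)
    assert load_parameters(path) == p


def test_parameters_validation():
    with pytest.raises(ValueError):
        KineticParameters(H=25)
    with pytest.raises(ValueError):
        KineticParameters(red_kdeg=-0.1)
    with pytest.raises(ValueError):
        KineticParameters.from_dict({"not_a_param": 1.0})
    assert KineticParameters(H=10).L == 14
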