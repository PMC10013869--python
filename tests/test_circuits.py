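"""State enumeration, rate-matrix assembly, and detailed-balance structure."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from burstinfo import (
    CircuitSpec,
    Concentrations,
    ParameterError,
    RateParameters,
    StructuralError,
    build_four_state_matrix,
    build_rate_matrix,
    detailed_balance_residual,
    enumerate_states,
    equilibrium_rate_matrix,
    equilibrium_sample,
    paper_state_order,
    random_equilibrium_parameters,
    stationary_distribution,
)
from burstinfo.circuits import EquilibriumParameters

from conftest import random_rate_params

log_rate = st.floats(-2.0, 2.0).map(lambda x: 10.0**x)


@pytest.mark.parametrize(
    "nb, na, noncog, expected",
    [
        (1, 1, False, 4),   # minimal MWC-like cycle
        (1, 1, True, 6),    # adds the wrong-activator pathway
        (5, 1, False, 12),  # (5+1)(1+1)
        (2, 1, True, 12),   # 3*4/2 occupancies x 2 conformations
        (2, 3, False, 12),
        (3, 2, True, 30),   # 4*5/2 x 3
    ],
)
def test_state_count_matches_occupancy_combinatorics(nb, na, noncog, expected):
    spec = CircuitSpec(n_binding_sites=nb, n_activation_steps=na,
                       include_noncognate=noncog)
    states = enumerate_states(spec)
    assert len(states) == expected == spec.n_states
    assert states == sorted(states, key=lambda s: (s[2], s[0], s[1]))
    assert all(nc + nw <= nb for nc, nw, _ in states)


def test_four_state_rates_are_the_eight_conventional_ones():
    """The four-state cycle carries exactly k_b c, k_u, k_a eta_ab, k_i eta_ib,
    k_u eta_ua, k_b c eta_ba, k_a, k_i on its eight directed edges."""
    spec = CircuitSpec()
    p = RateParameters(k_b=2.0, k_u=3.0, k_a=5.0, k_i=7.0,
                       eta_ab=11.0, eta_ib=0.5, eta_ua=13.0, eta_ba=17.0)
    conc = Concentrations(c=0.9)
    m = build_rate_matrix(spec, p, conc)
    s0, s1, s2, s3 = paper_state_order(spec)
    q = m.generator
    assert q[s0, s1] == pytest.approx(p.k_b * conc.c)
    assert q[s1, s0] == pytest.approx(p.k_u)
    assert q[s1, s2] == pytest.approx(p.k_a * p.eta_ab)
    assert q[s2, s1] == pytest.approx(p.k_i * p.eta_ib)
    assert q[s2, s3] == pytest.approx(p.k_u * p.eta_ua)
    assert q[s3, s2] == pytest.approx(p.k_b * conc.c * p.eta_ba)
    assert q[s0, s3] == pytest.approx(p.k_a)
    assert q[s3, s0] == pytest.approx(p.k_i)
    off = q[~np.eye(4, dtype=bool)]
    assert np.count_nonzero(off) == 8
    assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)


def test_single_interaction_modifies_single_edge():
    spec = CircuitSpec()
    base = build_rate_matrix(spec, RateParameters(), Concentrations())
    mod = build_rate_matrix(spec, RateParameters(eta_ab=2.0), Concentrations())
    diff = mod.generator - base.generator
    np.fill_diagonal(diff, 0.0)
    i, j = np.nonzero(diff)
    assert len(i) == 1
    s1 = paper_state_order(spec)[1]
    s2 = paper_state_order(spec)[2]
    assert (i[0], j[0]) == (s1, s2)
    assert mod.generator[s1, s2] == pytest.approx(2.0)


def test_general_builder_reduces_to_hand_coded_four_state(rng):
    for _ in range(20):
        p = random_rate_params(rng)
        conc = Concentrations(c=10.0 ** rng.uniform(-1, 1))
        g = build_rate_matrix(CircuitSpec(), p, conc)
        h = build_four_state_matrix(CircuitSpec(), p, conc)
        assert g.states == h.states
        assert np.allclose(g.generator, h.generator)
        assert np.array_equal(g.on_mask, h.on_mask)


def test_six_state_with_zero_w_behaves_as_four_state(rng, six_spec, four_spec):
    p = random_rate_params(rng)
    conc = Concentrations(c=1.3, w=0.0)
    m6 = build_rate_matrix(six_spec, p, conc)
    m4 = build_rate_matrix(four_spec, p, conc)
    pi6 = stationary_distribution(m6)
    pi4 = stationary_distribution(m4)
    lut6 = {s: i for i, s in enumerate(m6.states)}
    # W-bound states unreachable; cognate-state probabilities coincide
    for s, i4 in zip(m4.states, range(4)):
        assert pi6[lut6[s]] == pytest.approx(pi4[i4], abs=1e-12)
    for s, i in lut6.items():
        if s[1] > 0:
            assert pi6[i] == pytest.approx(0.0, abs=1e-12)


@given(eta_ab=st.floats(1.0, 1e3), eta_ua=log_rate, eta_ba=log_rate,
       eta_ib=st.floats(1e-3, 1.0), k=log_rate)
def test_four_state_cycle_affinity_formula(eta_ab, eta_ua, eta_ba, eta_ib, k):
    """The single-cycle affinity is ln(eta_ab eta_ua / (eta_ib eta_ba))
    for every parameter draw."""
    p = RateParameters(k_b=k, eta_ab=eta_ab, eta_ib=eta_ib,
                       eta_ua=eta_ua, eta_ba=eta_ba)
    m = build_rate_matrix(CircuitSpec(), p, Concentrations())
    expected = abs(math.log(eta_ab * eta_ua / (eta_ib * eta_ba)))
    assert detailed_balance_residual(m) == pytest.approx(expected, abs=1e-10)


def test_kolmogorov_balanced_cycle_has_zero_residual():
    p = RateParameters(eta_ab=4.0, eta_ua=3.0, eta_ib=2.0, eta_ba=6.0)
    m = build_rate_matrix(CircuitSpec(), p, Concentrations())
    assert detailed_balance_residual(m) == pytest.approx(0.0, abs=1e-12)


def _all_simple_cycle_affinities(q):
    """Independent oracle: DFS enumeration of simple cycles (length >= 3)."""
    n = q.shape[0]
    adj = [[j for j in range(n) if j != i and q[i, j] > 0] for i in range(n)]
    best = 0.0
    def dfs(start, node, visited, aff):
        nonlocal best
        for nxt in adj[node]:
            step = math.log(q[node, nxt]) - math.log(q[nxt, node])
            if nxt == start and len(visited) >= 3:
                best = max(best, abs(aff + step))
            elif nxt > start and nxt not in visited:
                dfs(start, nxt, visited | {nxt}, aff + step)
    for s in range(n):
        dfs(s, s, {s}, 0.0)
    return best


def test_residual_matches_simple_cycle_enumeration_oracle(rng, six_spec):
    for _ in range(5):
        p = random_rate_params(rng)
        conc = Concentrations(c=0.8, w=3.0)
        m = build_rate_matrix(six_spec, p, conc)
        oracle = _all_simple_cycle_affinities(m.generator)
        assert detailed_balance_residual(m) == pytest.approx(oracle, rel=1e-9)


def test_irreversible_edge_raises_structural_error():
    q = np.array([[-1.0, 1.0], [0.0, 0.0]])
    from burstinfo import LabeledRateMatrix

    m = LabeledRateMatrix(states=[(0, 0, 0), (0, 0, 1)], generator=q,
                          on_mask=np.array([False, True]))
    with pytest.raises(StructuralError):
        detailed_balance_residual(m)


class TestEquilibriumConstruction:
    def test_flat_energy_landscape_gives_unit_rates(self, four_spec):
        e_keys, b_keys, a_keys = EquilibriumParameters.class_shape(four_spec)
        ep = EquilibriumParameters(
            energies={k: 0.0 for k in e_keys},
            bind_barriers={k: 0.0 for k in b_keys},
            act_barriers={k: 0.0 for k in a_keys},
        )
        m = equilibrium_rate_matrix(four_spec, ep, Concentrations())
        off = m.generator[~np.eye(4, dtype=bool)]
        assert np.all(np.isin(np.round(off, 12), [0.0, 1.0]))
        assert detailed_balance_residual(m) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("noncog", [False, True])
    def test_random_draws_satisfy_detailed_balance(self, rng, noncog):
        spec = CircuitSpec(include_noncognate=noncog)
        conc = Concentrations(c=0.7, w=5.0 if noncog else 0.0)
        for _ in range(25):
            ep = random_equilibrium_parameters(spec, rng, scale=2.0)
            m = equilibrium_rate_matrix(spec, ep, conc)
            assert detailed_balance_residual(m) < 1e-10

    def test_stationary_law_is_boltzmann_with_concentration_factors(self, rng, four_spec):
        """pi_i proportional to c^{n_c} exp(-E_i) for every draw."""
        ep = random_equilibrium_parameters(four_spec, rng, scale=1.5)
        conc = Concentrations(c=1.7)
        m = equilibrium_rate_matrix(four_spec, ep, conc)
        pi = stationary_distribution(m)
        weights = np.array(
            [conc.c ** nc * math.exp(-ep.energies[(nc + nw, mm)])
             for nc, nw, mm in m.states]
        )
        weights /= weights.sum()
        assert np.allclose(pi, weights, rtol=1e-8)

    def test_eta_inversion_rebuilds_identical_generator(self, rng, four_spec):
        for _ in range(10):
            ep = random_equilibrium_parameters(four_spec, rng, scale=2.0)
            params = equilibrium_sample(four_spec, ep)
            direct = equilibrium_rate_matrix(four_spec, ep, Concentrations())
            rebuilt = build_rate_matrix(four_spec, params, Concentrations())
            assert np.allclose(direct.generator, rebuilt.generator, rtol=1e-12)

    def test_overflowing_energies_raise_parameter_error(self, four_spec):
        e_keys, b_keys, a_keys = EquilibriumParameters.class_shape(four_spec)
        ep = EquilibriumParameters(
            energies={k: 0.0 for k in e_keys},
            bind_barriers={k: -1e4 for k in b_keys},
            act_barriers={k: 0.0 for k in a_keys},
        )
        with pytest.raises(ParameterError):
            equilibrium_rate_matrix(four_spec, ep, Concentrations())


def test_species_swap_symmetry_when_alpha_is_one():
    """With alpha = 1 and equal concentrations, cognate and noncognate are
    statistically indistinguishable."""
    spec = CircuitSpec(include_noncognate=True, affinity_factor=1.0)
    p = RateParameters(k_b=0.5, k_u=2.0, k_a=1.2, k_i=0.8,
                       eta_ab=4.0, eta_ib=0.5, eta_ua=2.0, eta_ba=0.9)
    conc = Concentrations(c=0.7, w=0.7)
    m = build_rate_matrix(spec, p, conc)
    pi = stationary_distribution(m)
    lut = {s: i for i, s in enumerate(m.states)}
    for (nc, nw, mm), i in lut.items():
        assert pi[i] == pytest.approx(pi[lut[(nw, nc, mm)]], abs=1e-13)


def test_invalid_inputs_raise_parameter_errors():
    with pytest.raises(ParameterError):
        RateParameters(k_b=-1.0)
    with pytest.raises(ParameterError):
        RateParameters(eta_ab=0.0)
    with pytest.raises(ParameterError):
        CircuitSpec(n_binding_sites=0)
    with pytest.raises(ParameterError):
        Concentrations(c=0.0)
    with pytest.raises(ParameterError):
        Concentrations(w=-1.0)


def test_edge_dataframe_and_graphml_round_trip(tmp_path, four_spec):
    m = build_rate_matrix(four_spec, RateParameters(eta_ab=2.0), Concentrations())
    df = m.to_edge_dataframe()
    assert len(df) == 8
    assert set(df.columns) == {"from_state", "to_state", "rate", "provenance"}
    assert (df.provenance.str.len() > 0).all()
    out = tmp_path / "circuit.graphml"
    m.write_graphml(out)
    import networkx as nx

    g = nx.read_graphml(out)
    assert g.number_of_edges() == 8
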