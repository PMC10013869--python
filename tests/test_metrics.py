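"""Sharpness, precision, specificity, and the sharpness envelope."""

import math
from dataclasses import replace

import numpy as np
import pytest

from burstinfo import (
    CircuitSpec,
    Concentrations,
    LabeledRateMatrix,
    RateParameters,
    build_rate_matrix,
    cognate_fraction,
    equilibrium_rate_matrix,
    intrinsic_sharpness,
    occupancy,
    random_equilibrium_parameters,
    sharpness,
    sharpness_envelope,
    specificity,
    stationary_distribution,
    summarize,
    variance_rate,
)

from conftest import random_rate_params


def binding_telegraph(k_b, k_u, c):
    """Two-state circuit whose ON rate is k_b*c: the Hill-coefficient-1
    reference."""
    q = np.array([[-k_b * c, k_b * c], [k_u, -k_u]])
    c_mask = np.array([[False, True], [False, False]])
    return LabeledRateMatrix(states=[(0, 0, 0), (1, 0, 1)], generator=q,
                             on_mask=np.array([False, True]), c_mask=c_mask,
                             w_mask=np.zeros((2, 2)))


@pytest.mark.parametrize("c", [0.3, 1.0, 4.0])
def test_binding_telegraph_has_unit_normalized_sharpness(c):
    m = binding_telegraph(k_b=0.8, k_u=1.7, c=c)
    pi = stationary_distribution(m)
    pa = occupancy(m, pi)
    s = sharpness(m, pi, Concentrations(c=c))
    assert s / (pa * (1 - pa)) == pytest.approx(1.0, rel=1e-10)


@pytest.mark.parametrize("k_on, k_off", [(1.0, 1.0), (0.2, 3.0), (40.0, 0.7)])
def test_telegraph_normalized_precision_is_half_at_any_rates(k_on, k_off):
    """P = p * pi(1-pi) = 1/2 exactly for the two-state circuit: the
    variance-rate convention anchor."""
    q = np.array([[-k_on, k_on], [k_off, -k_off]])
    m = LabeledRateMatrix(states=[(0, 0, 0), (0, 0, 1)], generator=q,
                          on_mask=np.array([False, True]))
    pi = stationary_distribution(m)
    pa = pi[1]
    v = variance_rate(m, pi)
    assert v == pytest.approx(2.0 * pa**2 * (1 - pa) ** 2, rel=1e-10)
    p = 1.0 / math.sqrt(2.0 * v)
    assert p * pa * (1 - pa) == pytest.approx(0.5, rel=1e-10)


def test_sharpness_matches_central_finite_differences(rng, six_spec):
    conc = Concentrations(c=1.0, w=3.0)
    for _ in range(5):
        p = random_rate_params(rng)
        m = build_rate_matrix(six_spec, p, conc)
        pi = stationary_distribution(m)
        h = 1e-6

        def pa(cv):
            mm = build_rate_matrix(six_spec, p, replace(conc, c=cv))
            return occupancy(mm)

        fd = (pa(1 + h) - pa(1 - h)) / (2 * h)
        assert sharpness(m, pi, conc) == pytest.approx(fd, rel=1e-5)


def test_variance_rate_in_burst_units_is_rescaling_invariant(rng, four_spec, midpoint):
    p = random_rate_params(rng)
    m = build_rate_matrix(four_spec, p, midpoint)
    lam = 37.0
    scaled = RateParameters(
        k_b=lam * p.k_b, k_u=lam * p.k_u, k_a=lam * p.k_a, k_i=lam * p.k_i,
        eta_ab=p.eta_ab, eta_ib=p.eta_ib, eta_ua=p.eta_ua, eta_ba=p.eta_ba,
    )
    ms = build_rate_matrix(four_spec, scaled, midpoint)
    assert variance_rate(ms) == pytest.approx(variance_rate(m), rel=1e-9)


def test_poisson_shot_noise_term_is_additive_and_off_by_default(four_spec, midpoint):
    m = build_rate_matrix(four_spec, RateParameters(), midpoint)
    pi = stationary_distribution(m)
    v0 = variance_rate(m, pi)
    v1 = variance_rate(m, pi, include_poisson=True, r0=1.0)
    assert v1 > v0


class TestSpecificity:
    def test_equilibrium_specificity_equals_affinity_factor(self, rng, six_spec):
        conc = Concentrations(c=1.0, w=47.0)
        for _ in range(25):
            ep = random_equilibrium_parameters(six_spec, rng, scale=2.0)
            m = equilibrium_rate_matrix(six_spec, ep, conc)
            pi = stationary_distribution(m)
            f = specificity(m, pi, conc)
            assert abs(f - six_spec.affinity_factor) / six_spec.affinity_factor < 1e-8

    @pytest.mark.parametrize(
        "w_over_c, expected",
        [(47.0, 2.0 / 3.0), (698.0, 1.0 / 8.0), (1426.0, 1.0 / 15.0)],
    )
    def test_cognate_fraction_at_field_noncognate_loads(self, w_over_c, expected):
        """At alpha = 100: about 2/3 of binding events are cognate in the fly
        embryo, 1/8 in worms, 1/15 in mice."""
        assert cognate_fraction(100.0, w_over_c) == pytest.approx(expected, abs=0.02)

    def test_zero_w_limit_agrees_with_small_w_evaluation(self, rng, six_spec):
        p = random_rate_params(rng)
        m0 = build_rate_matrix(six_spec, p, Concentrations(c=1.0, w=0.0))
        f0 = specificity(m0, stationary_distribution(m0), Concentrations(c=1.0, w=0.0))
        eps = 1e-7
        m1 = build_rate_matrix(six_spec, p, Concentrations(c=1.0, w=eps))
        f1 = specificity(m1, stationary_distribution(m1), Concentrations(c=1.0, w=eps))
        assert f0 == pytest.approx(f1, rel=1e-4)


class TestSharpnessEnvelope:
    def test_equilibrium_anchor_at_heavy_interference(self):
        # f = alpha, S0 = 1 at w/c = 1000 gives the 0.09 equilibrium limit
        assert sharpness_envelope(1.0, 100.0, 1000.0) == pytest.approx(1.0 / 11.0)

    def test_nonequilibrium_anchor(self):
        # proofread specificity f = alpha^2 lifts the bound to 0.91
        assert sharpness_envelope(1.0, 1e4, 1000.0) == pytest.approx(10.0 / 11.0)

    def test_no_interference_returns_intrinsic_sharpness(self):
        assert sharpness_envelope(1.7, 100.0, 0.0) == pytest.approx(1.7)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            sharpness_envelope(0.0, 100.0, 10.0)

    def test_attainable_sharpness_stays_under_envelope_boundary(self):
        """The sweep-maximized observed sharpness at heavy interference
        respects (and approaches) the envelope over the intrinsic-sharpness /
        specificity tradeoff endpoints: 0.91 away from equilibrium
        (f -> alpha^2), 0.09 at equilibrium (f = alpha)."""
        from burstinfo import CircuitSpec, SweepConfig, maximize_metric

        spec = CircuitSpec(include_noncognate=True)
        conc = Concentrations(c=1.0, w=1000.0)
        cfg = SweepConfig(n_init=3000, n_generations=200, n_elite=20, seed=2)
        neq = maximize_metric(spec, "S", cfg, conc)
        env_neq = max(sharpness_envelope(2.0, 100.0, 1000.0),
                      sharpness_envelope(1.0, 100.0**2, 1000.0))
        assert 0.6 * env_neq < neq.value <= env_neq * (1 + 1e-6)
        eq = maximize_metric(
            spec, "S",
            SweepConfig(n_init=3000, n_generations=200, n_elite=20, seed=2,
                        equilibrium_only=True),
            conc,
        )
        env_eq = sharpness_envelope(1.0, 100.0, 1000.0)
        assert 0.6 * env_eq < eq.value <= env_eq * (1 + 1e-6)


def test_intrinsic_sharpness_equals_sharpness_without_noncognate(rng, four_spec, midpoint):
    p = random_rate_params(rng)
    rs = summarize(four_spec, p, midpoint)
    assert rs.S0 == pytest.approx(rs.S, rel=1e-12)


def test_equilibrium_intrinsic_sharpness_below_one(rng, six_spec):
    conc = Concentrations(c=1.0, w=10.0)
    for _ in range(15):
        ep = random_equilibrium_parameters(six_spec, rng, scale=2.0)
        s0 = intrinsic_sharpness(
            lambda cc: equilibrium_rate_matrix(six_spec, ep, cc), conc
        )
        assert s0 <= 1.0 + 1e-8


def test_summary_is_internally_consistent(rng, six_spec):
    p = random_rate_params(rng)
    conc = Concentrations(c=1.0, w=5.0)
    rs = summarize(six_spec, p, conc)
    assert rs.r_bar == pytest.approx(six_spec.max_rate * rs.pi_a)
    assert rs.p == pytest.approx(1.0 / math.sqrt(2.0 * rs.v))
    assert rs.S * rs.P == pytest.approx(rs.s * rs.p, rel=1e-12)
    assert rs.ir_bits == pytest.approx(rs.ir_nats / math.log(2.0))
    assert rs.f > 0 and rs.decision_time > 0
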