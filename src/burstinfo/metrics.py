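"""Input-output metrics of the transcriptional response.

For a circuit at midpoint cognate concentration c* the module computes:

- mean rate ``r_bar = r0 * pi_a`` with ``pi_a`` the ON-conformation occupancy;
- sharpness ``s = c* dpi_a/dc`` (analytic, from the differentiated balance
  equations) and its Hill-like normalization ``S = s / (pi_a (1 - pi_a))``;
- precision ``p = (2 v)^{-1/2}`` where ``v`` is the asymptotic variance rate
  of the time-averaged ON indicator in burst-time units, and
  ``P = p * pi_a (1 - pi_a)``;
- specificity ``f = (w/c) * pi_c / pi_w`` (concentration-normalized odds of
  cognate vs noncognate occupancy) and the cognate binding fraction
  ``p_c = f / (f + w/c)``;
- intrinsic sharpness ``S0`` (the same circuit's S with ``w = 0``) and the
  nonequilibrium sharpness envelope ``S <= f/(w/c + f) * S0``.

Conventions.  ``v`` is nondimensionalized by the burst cycle time
(``v = v_abs / tau_b``), fixed so the two-state telegraph circuit gives
``v = 2 pi^2 (1-pi)^2`` and hence ``P = 1/2`` exactly at any rates.  With
this convention the information rate is ``IR = (dc/c*)^2 s^2 p^2`` nats per
burst (see :mod:`burstinfo.information`).  ``p`` excludes the Poisson shot
noise of mRNA synthesis (small relative to locus-switching noise); an
optional additive term is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .circuits import (
    CircuitSpec,
    Concentrations,
    LabeledRateMatrix,
    RateParameters,
    StructuralError,
    build_rate_matrix,
)
from .steady_state import (
    burst_cycle_time,
    entropy_production,
    stationary_distribution,
)

__all__ = [
    "ResponseSummary",
    "occupancy",
    "sharpness",
    "variance_rate",
    "specificity",
    "cognate_fraction",
    "sharpness_envelope",
    "intrinsic_sharpness",
    "summarize",
]

Builder = Callable[[Concentrations], LabeledRateMatrix]


def occupancy(m: LabeledRateMatrix, pi: np.ndarray | None = None) -> float:
    """ON-conformation occupancy ``pi_a``."""
    if pi is None:
        pi = stationary_distribution(m)
    return float(pi[m.on_mask].sum())


def _occupancy_derivative(
    m: LabeledRateMatrix, pi: np.ndarray, dq: np.ndarray
) -> float:
    """d pi_a / d theta for a generator perturbation ``dq = dQ/d theta``."""
    q = m.generator
    n = q.shape[0]
    a = q.T.copy()
    a[-1, :] = 1.0
    b = -(dq.T @ pi)
    b[-1] = 0.0
    try:
        dpi = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as err:
        raise StructuralError("singular sensitivity system") from err
    return float(dpi[m.on_mask].sum())


def sharpness(
    m: LabeledRateMatrix,
    pi: np.ndarray | None = None,
    conc: Concentrations | None = None,
) -> float:
    """Sharpness ``s = c * dpi_a/dc`` at the build concentration.

    Concentrations are in c* units, so evaluating the builder at ``c = 1``
    gives the midpoint sharpness.  ``w`` is held fixed.
    """
    c = conc.c if conc is not None else 1.0
    if pi is None:
        pi = stationary_distribution(m)
    dq = m.dgenerator_dc(c)
    return c * _occupancy_derivative(m, pi, dq)


def variance_rate(
    m: LabeledRateMatrix,
    pi: np.ndarray | None = None,
    on_mask: np.ndarray | None = None,
    *,
    tau_b: float | None = None,
    include_poisson: bool = False,
    r0: float = 1.0,
) -> float:
    """Asymptotic variance rate ``v`` of the integrated ON indicator, in
    burst-time units.

    Solves the Poisson equation ``Q g = -(1_ON - pi_a)`` with ``pi^T g = 0``;
    the absolute-time rate is ``v_abs = 2 sum_i pi_i (1_ON,i - pi_a) g_i``
    and ``v = v_abs / tau_b``.  With ``include_poisson=True`` an additive
    ``pi_a / r0`` shot-noise term (mRNA-count output scaled by r0) enters
    ``v_abs``.
    """
    q = m.generator
    if pi is None:
        pi = stationary_distribution(m)
    on = m.on_mask if on_mask is None else np.asarray(on_mask, dtype=bool)
    pi_a = float(pi[on].sum())
    f = on.astype(float) - pi_a
    a = q.copy()
    a[-1, :] = pi
    b = -f
    b[-1] = 0.0
    try:
        g = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as err:
        raise StructuralError("singular Poisson system") from err
    v_abs = 2.0 * float(pi @ (f * g))
    if include_poisson:
        v_abs += pi_a / r0
    if tau_b is None:
        tau_b = burst_cycle_time(m, pi, on)
    v = v_abs / tau_b
    if v <= 0:
        raise StructuralError("nonpositive variance rate")
    return v


def _bound_probabilities(m: LabeledRateMatrix, pi: np.ndarray) -> tuple[float, float]:
    """Occupancy-weighted cognate / noncognate bound probabilities.

    ``pi_c = sum_i n_c(i) pi_i`` and likewise for ``n_w``; for a single
    binding site these are the total bound-state probabilities of Box-1.
    """
    n_c = np.array([s[0] for s in m.states], dtype=float)
    n_w = np.array([s[1] for s in m.states], dtype=float)
    return float(n_c @ pi), float(n_w @ pi)


def specificity(
    m: LabeledRateMatrix,
    pi: np.ndarray | None = None,
    conc: Concentrations | None = None,
) -> float:
    """Transcriptional specificity ``f = (w/c) * pi_c / pi_w``.

    At ``w = 0`` the ratio is taken in the analytic ``w -> 0`` limit:
    ``pi_w ~ w * dpi_w/dw``, evaluated from the structural w-derivative of
    the generator, so ``f`` remains finite and well defined.
    """
    conc = conc or Concentrations()
    if pi is None:
        pi = stationary_distribution(m)
    pi_c, pi_w = _bound_probabilities(m, pi)
    if conc.w > 0:
        if pi_w <= 0:
            raise StructuralError("noncognate states unoccupied at w > 0")
        return (conc.w / conc.c) * pi_c / pi_w
    # w -> 0 limit: pi_w(w) = w * (dpi_w/dw) + O(w^2)
    dq = m.dgenerator_dw()
    q = m.generator
    a = q.T.copy()
    a[-1, :] = 1.0
    b = -(dq.T @ pi)
    b[-1] = 0.0
    dpi = np.linalg.solve(a, b)
    n_w = np.array([s[1] for s in m.states], dtype=float)
    dpi_w = float(n_w @ dpi)
    if dpi_w <= 0:
        raise StructuralError("no noncognate pathway: specificity undefined")
    return pi_c / (conc.c * dpi_w)


def cognate_fraction(f: float, w_over_c: float) -> float:
    """Fraction of binding interactions due to the cognate activator,
    ``p_c = f / (f + w/c)``."""
    return f / (f + w_over_c)


def sharpness_envelope(s0: float, f: float, w_over_c: float) -> float:
    """Upper bound on observed normalized sharpness,
    ``S <= f / (w/c + f) * S0``."""
    if s0 <= 0 or f <= 0 or w_over_c < 0:
        raise ValueError("require S0 > 0, f > 0, w/c >= 0")
    return f / (w_over_c + f) * s0


def _normalized_sharpness(m: LabeledRateMatrix, pi: np.ndarray, conc: Concentrations) -> float:
    pi_a = occupancy(m, pi)
    s = sharpness(m, pi, conc)
    return s / (pi_a * (1.0 - pi_a))


def intrinsic_sharpness(build: Builder, conc: Concentrations | None = None) -> float:
    """Normalized sharpness the circuit shows with no noncognate binding
    (``w`` forced to 0)."""
    conc = conc or Concentrations()
    c0 = replace(conc, w=0.0)
    m = build(c0)
    pi = stationary_distribution(m)
    return _normalized_sharpness(m, pi, c0)


@dataclass
class ResponseSummary:
    """All scalar metrics of one circuit at one concentration point."""

    pi_a: float
    r_bar: float
    tau_b: float
    phi_rate: float
    phi_per_burst: float
    s: float
    v: float
    p: float
    S: float
    P: float
    f: float | None
    S0: float
    ir_nats: float
    ir_bits: float
    decision_time: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize(
    spec: CircuitSpec,
    params: RateParameters,
    conc: Concentrations | None = None,
    *,
    epsilon: float = 0.32,
    include_poisson: bool = False,
) -> ResponseSummary:
    """Evaluate the full response summary of one circuit realization."""
    from .information import decision_time as _decision_time
    from .information import information_rate as _information_rate

    conc = conc or Concentrations()

    def build(cc: Concentrations) -> LabeledRateMatrix:
        return build_rate_matrix(spec, params, cc)

    m = build(conc)
    pi = stationary_distribution(m)
    pi_a = occupancy(m, pi)
    tau_b = burst_cycle_time(m, pi)
    phi = entropy_production(m, pi)
    s = sharpness(m, pi, conc)
    v = variance_rate(m, pi, tau_b=tau_b,
                      include_poisson=include_poisson, r0=spec.max_rate)
    p = 1.0 / np.sqrt(2.0 * v)
    norm = pi_a * (1.0 - pi_a)
    f = specificity(m, pi, conc) if spec.include_noncognate else None
    s0 = (
        intrinsic_sharpness(build, conc)
        if spec.include_noncognate
        else s / norm
    )
    ir_nats, ir_bits = _information_rate(s, p, conc.delta_c_rel)
    return ResponseSummary(
        pi_a=pi_a,
        r_bar=spec.max_rate * pi_a,
        tau_b=tau_b,
        phi_rate=phi,
        phi_per_burst=phi * tau_b,
        s=s,
        v=v,
        p=p,
        S=s / norm,
        P=p * norm,
        f=f,
        S0=s0,
        ir_nats=ir_nats,
        ir_bits=ir_bits,
        decision_time=_decision_time(ir_nats, epsilon),
    )
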