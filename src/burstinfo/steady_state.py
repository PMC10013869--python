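"""Stationary distributions, entropy production, and the burst-cycle clock.

The stationary distribution solves the global balance equations
``pi^T Q = 0`` with normalization.  The free-energy dissipation rate is the
Schnakenberg entropy production

    Phi = sum_{i<j} (pi_i k_ij - pi_j k_ji) * ln(pi_i k_ij / (pi_j k_ji)),

strictly nonnegative and zero exactly at detailed balance.  For the
single-cycle four-state model it reduces to ``J * ln(eta_ab eta_ua /
(eta_ib eta_ba))`` with ``J`` the net cycle flux.

The burst cycle time ``tau_b`` — the mean time to complete one
ON -> OFF -> ON fluctuation — is the package's unit of time: it is computed
as the reciprocal of the stationary one-way OFF -> ON crossing frequency,
which coincides with the mean cycle time whenever ON and OFF form the two
macrostates of the renewal structure (the two-state closed form is a test
anchor).  Dissipation is reported both per unit time and per burst
(``Phi * tau_b``, in k_BT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuits import (
    CircuitSpec,
    Concentrations,
    LabeledRateMatrix,
    RateParameters,
    StructuralError,
    build_rate_matrix,
)

__all__ = [
    "StationarySolution",
    "stationary_distribution",
    "entropy_production",
    "burst_cycle_time",
    "cycle_flux",
    "solve_circuit",
]

#: Dissipation per burst below which a circuit is classified as equilibrium.
EQUILIBRIUM_PHI_TOL = 1e-8

_FLUX_TINY = 1e-300


def stationary_distribution(m: LabeledRateMatrix | np.ndarray) -> np.ndarray:
    """Unique stationary probability vector of the generator.

    Solves the bordered dense system (one balance equation replaced by the
    normalization row).  Raises :class:`StructuralError` when the chain has
    no unique stationary law (reducible generator).
    """
    q = m.generator if isinstance(m, LabeledRateMatrix) else m
    n = q.shape[0]
    a = q.T.copy()
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as err:
        raise StructuralError("reducible chain: stationary law not unique") from err
    # one step of iterative refinement guards ill-conditioned rate spans
    r = b - a @ pi
    if np.any(np.abs(r) > 1e-13):
        try:
            pi = pi + np.linalg.solve(a, r)
        except np.linalg.LinAlgError:
            pass
    scale = np.max(np.abs(q))
    if np.min(pi) < -1e-9 or not np.all(np.isfinite(pi)):
        raise StructuralError("stationary solve produced an invalid distribution")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = np.max(np.abs(pi @ q)) / max(scale, 1.0)
    if resid > 1e-10:
        raise StructuralError(f"stationary residual too large: {resid:.3g}")
    return pi


def entropy_production(m: LabeledRateMatrix | np.ndarray, pi: np.ndarray) -> float:
    """Schnakenberg entropy production rate, in k_BT per unit time."""
    q = m.generator if isinstance(m, LabeledRateMatrix) else m
    n = q.shape[0]
    phi = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            fij = pi[i] * q[i, j]
            fji = pi[j] * q[j, i]
            if fij < _FLUX_TINY and fji < _FLUX_TINY:
                continue
            if (q[i, j] > 0) != (q[j, i] > 0):
                raise StructuralError(
                    "one-sided edge carries flux: entropy production diverges"
                )
            if fij < _FLUX_TINY or fji < _FLUX_TINY:
                # flux into an unoccupied (transient) corner of state space
                continue
            phi += (fij - fji) * np.log(fij / fji)
    return max(phi, 0.0)


def burst_cycle_time(
    m: LabeledRateMatrix | np.ndarray,
    pi: np.ndarray,
    on_mask: np.ndarray | None = None,
) -> float:
    """Mean ON -> OFF -> ON cycle duration, ``1 / (one-way OFF->ON flux)``."""
    if isinstance(m, LabeledRateMatrix):
        q = m.generator
        if on_mask is None:
            on_mask = m.on_mask
    else:
        q = m
    if on_mask is None:
        raise ValueError("on_mask required")
    on = np.asarray(on_mask, dtype=bool)
    if not on.any() or on.all():
        raise StructuralError("ON set must be a nonempty proper subset")
    crossing = float(pi[~on] @ q[np.ix_(~on, on)].sum(axis=1))
    if crossing <= 0:
        raise StructuralError("no OFF -> ON flux: burst cycle time undefined")
    return 1.0 / crossing


def cycle_flux(m: LabeledRateMatrix, pi: np.ndarray) -> float:
    """Net cycle flux J of a single-cycle (four-state) model.

    Positive in the direction binding -> activation -> unbinding ->
    inactivation (the conventional clockwise orientation).
    """
    states = {s: i for i, s in enumerate(m.states)}
    try:
        i, j = states[(0, 0, 0)], states[(1, 0, 0)]
    except KeyError as err:
        raise StructuralError("cycle flux defined for the four-state model") from err
    q = m.generator
    return float(pi[i] * q[i, j] - pi[j] * q[j, i])


@dataclass
class StationarySolution:
    """Stationary summary of one circuit realization."""

    pi: np.ndarray
    edge_flux: np.ndarray
    J: float | None
    tau_b: float
    phi_rate: float
    phi_per_burst: float

    @property
    def is_equilibrium(self) -> bool:
        return self.phi_per_burst < EQUILIBRIUM_PHI_TOL

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "J": self.J,
            "tau_b": self.tau_b,
            "phi_rate": self.phi_rate,
            "phi_per_burst": self.phi_per_burst,
        }


def solve_circuit(
    m: LabeledRateMatrix | None = None,
    *,
    spec: CircuitSpec | None = None,
    params: RateParameters | None = None,
    conc: Concentrations | None = None,
) -> StationarySolution:
    """Solve a circuit to its stationary summary.

    Either pass a prebuilt :class:`LabeledRateMatrix`, or ``spec``/``params``
    (and optionally ``conc``) to build one.
    """
    if m is None:
        if spec is None or params is None:
            raise ValueError("pass a matrix or spec+params")
        m = build_rate_matrix(spec, params, conc or Concentrations())
    pi = stationary_distribution(m)
    q = m.generator
    flux = pi[:, None] * q - (pi[:, None] * q).T
    np.fill_diagonal(flux, 0.0)
    phi = entropy_production(m, pi)
    tau = burst_cycle_time(m, pi)
    j = cycle_flux(m, pi) if m.n_states == 4 else None
    return StationarySolution(
        pi=pi, edge_flux=flux, J=j, tau_b=tau, phi_rate=phi,
        phi_per_burst=phi * tau,
    )
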