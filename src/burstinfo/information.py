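"""Information transmission rate and the sequential-test decision time.

A cell deciding between two nearby activator concentrations ``c0 < c1``
(``delta_c = c1 - c0 = 0.1 c*`` by default) accumulates evidence from the
noisy transcriptional output.  Under the Gaussian approximation for the
integrated output, the Kullback-Leibler divergence between the two output
laws grows at the information rate

    IR = (delta_c / c*)^2 * s^2 * p^2    [nats per burst cycle],

with sharpness ``s`` and precision ``p = (2v)^{-1/2}`` as in
:mod:`burstinfo.metrics` (note ``s p = S P``, so the normalized metrics can
be used interchangeably).  The mean decision time of the optimal sequential
probability ratio test at symmetric error tolerance ``epsilon`` is

    T_bar = (1 - 2 epsilon) * ln((1 - epsilon)/epsilon) / IR    [bursts].

Computation is in nats; informational quantities are also reported in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DecisionProblem", "information_rate", "decision_time"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DecisionProblem:
    """Binary concentration-discrimination task, in c* units.

    The midpoint ``(c0 + c1)/2`` is the reference concentration c* = 1.
    ``epsilon`` is the tolerated probability of deciding wrongly
    (default 0.32, a "1 sigma" error level).
    """

    c0: float = 0.95
    c1: float = 1.05
    epsilon: float = 0.32

    def __post_init__(self) -> None:
        if not self.c0 < self.c1:
            raise ValueError("require c0 < c1")
        if abs((self.c0 + self.c1) / 2.0 - 1.0) > 1e-9:
            raise ValueError("hypothesis midpoint must be 1 in c* units")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 1/2)")

    @property
    def delta_c_rel(self) -> float:
        return self.c1 - self.c0

    @property
    def llr_threshold(self) -> float:
        """Symmetric SPRT stopping threshold ``ln((1-eps)/eps)`` in nats."""
        return math.log((1.0 - self.epsilon) / self.epsilon)


def information_rate(s: float, p: float, delta_c_rel: float = 0.1) -> tuple[float, float]:
    """Information rate from sharpness and precision.

    Returns ``(IR_nats, IR_bits)`` per burst cycle.  Accepts either the raw
    ``(s, p)`` or the normalized ``(S, P)`` pair (their products coincide).
    """
    ir_nats = (delta_c_rel * s * p) ** 2
    return ir_nats, ir_nats / LN2


def decision_time(ir_nats: float, epsilon: float = 0.32) -> float:
    """Lower bound on the mean decision time, in burst cycles."""
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 1/2)")
    if ir_nats <= 0:
        raise ValueError("information rate must be positive")
    return (1.0 - 2.0 * epsilon) * math.log((1.0 - epsilon) / epsilon) / ir_nats
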