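"""Gene-circuit state spaces and continuous-time Markov generators.

A gene locus is modeled as a continuous-time Markov chain over states
``(n_c, n_w, m)`` where ``n_c`` cognate and ``n_w`` noncognate activators are
bound (``n_c + n_w <= N_B``) and ``m`` of the ``N_A`` molecular activation
steps are engaged.  mRNA is produced at rate ``r0`` only in fully engaged
("ON") conformations, ``m = N_A``.

The minimal model has one binding site and one activation step: a four-state
MWC-like cycle in which a bound activator modulates the conformational rates
through dimensionless interaction factors (the ``eta`` terms) and, away from
detailed balance, the cycle carries a net probability flux that dissipates
free energy.  Adding a noncognate competitor species (aggregate concentration
``w``, unbinding faster by the affinity factor ``alpha``) yields a six-state
model with a "right" and a "wrong" activation pathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "CircuitSpec",
    "RateParameters",
    "Concentrations",
    "LabeledRateMatrix",
    "StructuralError",
    "ParameterError",
    "enumerate_states",
    "paper_state_order",
    "build_rate_matrix",
    "build_four_state_matrix",
    "detailed_balance_residual",
    "EquilibriumParameters",
    "equilibrium_rate_matrix",
    "equilibrium_sample",
    "random_equilibrium_parameters",
]


class StructuralError(ValueError):
    """The generator violates a structural requirement (connectivity, reversibility)."""


class ParameterError(ValueError):
    """A rate, interaction factor, or concentration is out of its admissible range."""


@dataclass(frozen=True)
class CircuitSpec:
    """Discrete topology of a gene circuit.

    Parameters
    ----------
    n_binding_sites : int
        Number of identical activator binding sites, ``N_B >= 1``.
    n_activation_steps : int
        Number of molecular activation steps, ``N_A >= 1``; all must be
        engaged for transcription.
    include_noncognate : bool
        Whether a competing noncognate activator species is modeled.
    affinity_factor : float
        ``alpha = k_u^w / k_u > 1``, the ratio of noncognate to cognate
        unbinding rates (default 100, the ~4.6 k_BT eukaryotic footprint
        difference).
    max_rate : float
        mRNA production rate ``r0`` in the ON conformation (default 1).
    """

    n_binding_sites: int = 1
    n_activation_steps: int = 1
    include_noncognate: bool = False
    affinity_factor: float = 100.0
    max_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.n_binding_sites < 1:
            raise ParameterError("n_binding_sites must be >= 1")
        if self.n_activation_steps < 1:
            raise ParameterError("n_activation_steps must be >= 1")
        if self.include_noncognate and self.affinity_factor < 1:
            raise ParameterError("affinity_factor must be >= 1")
        if self.max_rate <= 0:
            raise ParameterError("max_rate must be positive")

    @property
    def n_states(self) -> int:
        nb, na = self.n_binding_sites, self.n_activation_steps
        if self.include_noncognate:
            return (nb + 1) * (nb + 2) // 2 * (na + 1)
        return (nb + 1) * (na + 1)


@dataclass(frozen=True)
class RateParameters:
    """Basal rates and interaction factors of one circuit realization.

    ``k_b`` is the binding rate per unit concentration; ``k_u``, ``k_a`` and
    ``k_i`` are the cognate unbinding, activation and inactivation rates.
    The ``eta`` factors modify a basal reaction (first subscript) according
    to the state of another component (second subscript): e.g. ``eta_ab`` is
    the fold change of the activation rate per bound activator
    (``eta_ab > 1`` for an activator).  ``eta_ub`` is the pairwise
    activator-activator cooperativity acting on unbinding (used when
    ``N_B > 1``).  ``k_u_mut``, if set, replaces the *cognate* unbinding
    rate (binding-site mutation); noncognate unbinding stays ``alpha*k_u``.
    """

    k_b: float = 1.0
    k_u: float = 1.0
    k_a: float = 1.0
    k_i: float = 1.0
    eta_ab: float = 1.0
    eta_ib: float = 1.0
    eta_ua: float = 1.0
    eta_ba: float = 1.0
    eta_ub: float = 1.0
    k_u_mut: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_b", "k_u", "k_a", "k_i",
                     "eta_ab", "eta_ib", "eta_ua", "eta_ba", "eta_ub"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ParameterError(f"{name} must be positive and finite, got {v}")
        if self.k_u_mut is not None and not self.k_u_mut > 0:
            raise ParameterError("k_u_mut must be positive")

    def with_mutation(self, beta: float) -> "RateParameters":
        """Return parameters with cognate unbinding sped up by ``beta >= 1``."""
        if beta < 1:
            raise ParameterError("mutation strength beta must be >= 1")
        return replace(self, k_u_mut=beta * self.k_u)


@dataclass(frozen=True)
class Concentrations:
    """Activator concentrations in units of the midpoint concentration c*."""

    c: float = 1.0
    w: float = 0.0
    delta_c_rel: float = 0.1

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ParameterError("cognate concentration c must be positive")
        if self.w < 0:
            raise ParameterError("noncognate concentration w must be >= 0")


def enumerate_states(spec: CircuitSpec) -> list[tuple[int, int, int]]:
    """Canonically ordered state labels ``(n_c, n_w, m)``.

    Ordering is lexicographic in ``(m, n_c, n_w)`` so serialized results are
    reproducible across model variants.
    """
    nb, na = spec.n_binding_sites, spec.n_activation_steps
    nw_max = nb if spec.include_noncognate else 0
    states = [
        (n_c, n_w, m)
        for m in range(na + 1)
        for n_c in range(nb + 1)
        for n_w in range(nw_max + 1)
        if n_c + n_w <= nb
    ]
    return states


def paper_state_order(spec: CircuitSpec) -> list[int]:
    """Map the conventional 0..3 (four-state) / 0..5 (six-state) labels to
    canonical indices.

    Four-state: 0 (unbound, OFF), 1 (bound, OFF), 2 (bound, ON),
    3 (unbound, ON).  Six-state adds 4 (W-bound, ON), 5 (W-bound, OFF).
    """
    if spec.n_binding_sites != 1 or spec.n_activation_steps != 1:
        raise ValueError("conventional labels exist only for N_B = N_A = 1")
    states = enumerate_states(spec)
    idx = {s: i for i, s in enumerate(states)}
    order = [idx[(0, 0, 0)], idx[(1, 0, 0)], idx[(1, 0, 1)], idx[(0, 0, 1)]]
    if spec.include_noncognate:
        order += [idx[(0, 1, 1)], idx[(0, 1, 0)]]
    return order


@dataclass
class LabeledRateMatrix:
    """CTMC generator with state labels, ON mask, and edge provenance.

    ``generator`` rows sum to zero; off-diagonal entry ``[i, j]`` is the
    transition rate ``i -> j``.  ``c_mask``/``w_mask`` flag off-diagonal
    entries proportional to the cognate/noncognate concentration (used for
    analytic concentration derivatives).
    """

    states: list[tuple[int, int, int]]
    generator: np.ndarray
    on_mask: np.ndarray
    edge_labels: dict[tuple[int, int], str] = field(default_factory=dict)
    c_mask: np.ndarray | None = None
    w_mask: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return len(self.states)

    def dgenerator_dc(self, c: float) -> np.ndarray:
        """Derivative of the generator with respect to cognate concentration."""
        if self.c_mask is None:
            raise StructuralError("matrix carries no concentration provenance")
        d = np.where(self.c_mask, self.generator, 0.0) / c
        np.fill_diagonal(d, 0.0)
        np.fill_diagonal(d, -d.sum(axis=1))
        return d

    def dgenerator_dw(self) -> np.ndarray:
        """Derivative with respect to noncognate concentration.

        Entries are linear in ``w``, so this is the structural per-unit-w
        rate table (stored in ``w_mask``); valid at any ``w`` including 0.
        """
        if self.w_mask is None:
            raise StructuralError("matrix carries no noncognate provenance")
        d = np.array(self.w_mask, dtype=float)
        np.fill_diagonal(d, 0.0)
        np.fill_diagonal(d, -d.sum(axis=1))
        return d

    def to_edge_dataframe(self):
        """Edge list (from_state, to_state, rate, provenance) as a DataFrame."""
        import pandas as pd

        rows = []
        q = self.generator
        for i in range(self.n_states):
            for j in range(self.n_states):
                if i != j and q[i, j] > 0:
                    rows.append(
                        {
                            "from_state": str(self.states[i]),
                            "to_state": str(self.states[j]),
                            "rate": q[i, j],
                            "provenance": self.edge_labels.get((i, j), ""),
                        }
                    )
        return pd.DataFrame(rows)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for i, s in enumerate(self.states):
            g.add_node(i, label=str(s), on=bool(self.on_mask[i]))
        q = self.generator
        for i in range(self.n_states):
            for j in range(self.n_states):
                if i != j and q[i, j] > 0:
                    g.add_edge(i, j, rate=float(q[i, j]),
                               provenance=self.edge_labels.get((i, j), ""))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)


def _finalize(states, q, on, labels, c_prop, w_unit) -> LabeledRateMatrix:
    if np.any(q[~np.eye(len(states), dtype=bool)] < 0):
        raise ParameterError("negative off-diagonal rate")
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return LabeledRateMatrix(
        states=states, generator=q, on_mask=on, edge_labels=labels,
        c_mask=c_prop, w_mask=w_unit,
    )


def build_rate_matrix(
    spec: CircuitSpec, params: RateParameters, conc: Concentrations
) -> LabeledRateMatrix:
    """Assemble the CTMC generator for any ``(N_B, N_A)`` variant.

    Rate laws (reducing edge-for-edge to the four-state model at
    ``N_B = N_A = 1``), with ``n = n_c + n_w`` bound activators:

    - cognate binding: ``(N_B - n) * k_b * c``, times ``eta_ba`` iff fully ON;
    - cognate unbinding: ``n_c * k_u * eta_ub**(n-1)``, times ``eta_ua`` iff ON;
    - noncognate binding/unbinding: same laws with ``w`` and ``alpha * k_u``;
    - activation ``m -> m+1``: ``(N_A - m) * k_a * eta_ab**n``;
    - inactivation ``m+1 -> m``: ``(m+1) * k_i * eta_ib**n``.
    """
    states = enumerate_states(spec)
    index = {s: i for i, s in enumerate(states)}
    n_states = len(states)
    nb, na = spec.n_binding_sites, spec.n_activation_steps
    q = np.zeros((n_states, n_states))
    c_prop = np.zeros((n_states, n_states), dtype=bool)
    w_unit = np.zeros((n_states, n_states))
    labels: dict[tuple[int, int], str] = {}
    on = np.array([m == na for (_, _, m) in states])
    k_u_c = params.k_u if params.k_u_mut is None else params.k_u_mut
    k_u_w = spec.affinity_factor * params.k_u

    def add(i, j, rate, label, *, c_dep=False, w_rate=None):
        q[i, j] += rate
        labels[(i, j)] = label
        if c_dep:
            c_prop[i, j] = True
        if w_rate is not None:
            w_unit[i, j] += w_rate

    for s in states:
        n_c, n_w, m = s
        i = index[s]
        n = n_c + n_w
        top = m == na
        coop = params.eta_ub ** (n - 1) if n >= 1 else 1.0
        if n < nb:
            rate = (nb - n) * params.k_b * conc.c * (params.eta_ba if top else 1.0)
            add(i, index[(n_c + 1, n_w, m)], rate,
                f"({nb - n})*k_b*c" + ("*eta_ba" if top else ""), c_dep=True)
            if spec.include_noncognate:
                unit = (nb - n) * params.k_b * (params.eta_ba if top else 1.0)
                add(i, index[(n_c, n_w + 1, m)], unit * conc.w,
                    f"({nb - n})*k_b*w" + ("*eta_ba" if top else ""), w_rate=unit)
        if n_c >= 1:
            rate = n_c * k_u_c * coop * (params.eta_ua if top else 1.0)
            add(i, index[(n_c - 1, n_w, m)], rate,
                f"{n_c}*k_u" + ("*eta_ua" if top else ""))
        if n_w >= 1:
            rate = n_w * k_u_w * coop * (params.eta_ua if top else 1.0)
            add(i, index[(n_c, n_w - 1, m)], rate,
                f"{n_w}*alpha*k_u" + ("*eta_ua" if top else ""))
        if m < na:
            rate = (na - m) * params.k_a * params.eta_ab ** n
            add(i, index[(n_c, n_w, m + 1)], rate,
                f"({na - m})*k_a*eta_ab^{n}")
        if m >= 1:
            rate = m * params.k_i * params.eta_ib ** n
            add(i, index[(n_c, n_w, m - 1)], rate,
                f"{m}*k_i*eta_ib^{n}")
    return _finalize(states, q, on, labels, c_prop, w_unit)


def build_four_state_matrix(
    spec: CircuitSpec, params: RateParameters, conc: Concentrations
) -> LabeledRateMatrix:
    """Hand-coded four-state MWC-like cycle (cross-check for the general builder).

    In the conventional labels 0..3 the eight rates are
    0->1 ``k_b*c``, 1->0 ``k_u``, 1->2 ``k_a*eta_ab``, 2->1 ``k_i*eta_ib``,
    2->3 ``k_u*eta_ua``, 3->2 ``k_b*c*eta_ba``, 0->3 ``k_a``, 3->0 ``k_i``.
    """
    if spec.n_binding_sites != 1 or spec.n_activation_steps != 1 or spec.include_noncognate:
        raise ValueError("explicit builder covers only the four-state model")
    states = enumerate_states(spec)  # (0,0,0), (1,0,0), (0,0,1), (1,0,1)
    index = {s: i for i, s in enumerate(states)}
    s0, s1 = index[(0, 0, 0)], index[(1, 0, 0)]
    s3, s2 = index[(0, 0, 1)], index[(1, 0, 1)]
    ku = params.k_u if params.k_u_mut is None else params.k_u_mut
    n = len(states)
    q = np.zeros((n, n))
    c_prop = np.zeros((n, n), dtype=bool)
    labels = {}
    entries = [
        (s0, s1, params.k_b * conc.c, "k_b*c", True),
        (s1, s0, ku, "k_u", False),
        (s1, s2, params.k_a * params.eta_ab, "k_a*eta_ab", False),
        (s2, s1, params.k_i * params.eta_ib, "k_i*eta_ib", False),
        (s2, s3, ku * params.eta_ua, "k_u*eta_ua", False),
        (s3, s2, params.k_b * conc.c * params.eta_ba, "k_b*c*eta_ba", True),
        (s0, s3, params.k_a, "k_a", False),
        (s3, s0, params.k_i, "k_i", False),
    ]
    for i, j, rate, lab, cdep in entries:
        q[i, j] = rate
        labels[(i, j)] = lab
        c_prop[i, j] = cdep
    on = np.array([m == 1 for (_, _, m) in states])
    return _finalize(states, q, on, labels, c_prop, np.zeros((n, n)))


def detailed_balance_residual(m: LabeledRateMatrix) -> float:
    """Maximum absolute cycle affinity over all simple cycles of the rate graph.

    The affinity of a cycle is ``ln`` (product of forward rates / product
    of reverse rates); the maximum over simple cycles dominates any cycle
    basis (a composite cycle's affinity is the signed sum of basis
    affinities).  Zero iff the Kolmogorov criterion (detailed balance of
    the rate graph) holds.  Raises :class:`StructuralError` if any edge
    lacks its reverse.
    """
    q = m.generator
    n = m.n_states
    und = nx.Graph()
    und.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            fwd, rev = q[i, j], q[j, i]
            if (fwd > 0) != (rev > 0):
                raise StructuralError(
                    f"irreversible edge {m.states[i]} <-> {m.states[j]}"
                )
            if fwd > 0:
                und.add_edge(i, j)
    worst = 0.0
    for cycle in nx.simple_cycles(und):
        aff = 0.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            aff += math.log(q[a, b]) - math.log(q[b, a])
        worst = max(worst, abs(aff))
    return worst


@dataclass(frozen=True)
class EquilibriumParameters:
    """Equilibrium-by-construction parameterization.

    State energies and transition barriers are keyed by occupancy class
    ``(n, m)`` with ``n = n_c + n_w``, so noncognate-bound states mirror
    cognate-bound ones exactly (they differ only through the ``alpha``
    factor on unbinding).  Rates take the Arrhenius form
    ``k(i -> j) = phi_ij * exp(E_i - B_ij)`` with symmetric barriers, which
    satisfies detailed balance for every draw; ``phi_ij`` carries the
    combinatorial multiplicities and concentration/alpha factors, which are
    themselves an equilibrium (independent-unit) rate structure.

    ``energies[(n, m)]``; ``bind_barriers[(n, m)]`` for the undirected edge
    ``(n, m) <-> (n+1, m)``; ``act_barriers[(n, m)]`` for ``(n, m) <-> (n, m+1)``.
    All in units of k_BT.
    """

    energies: dict[tuple[int, int], float]
    bind_barriers: dict[tuple[int, int], float]
    act_barriers: dict[tuple[int, int], float]

    @staticmethod
    def class_shape(spec: CircuitSpec):
        nb, na = spec.n_binding_sites, spec.n_activation_steps
        e_keys = [(n, m) for n in range(nb + 1) for m in range(na + 1)]
        b_keys = [(n, m) for n in range(nb) for m in range(na + 1)]
        a_keys = [(n, m) for n in range(nb + 1) for m in range(na)]
        return e_keys, b_keys, a_keys

    @classmethod
    def from_vector(cls, spec: CircuitSpec, theta: np.ndarray) -> "EquilibriumParameters":
        e_keys, b_keys, a_keys = cls.class_shape(spec)
        ne, nbk = len(e_keys), len(b_keys)
        if theta.size != ne + nbk + len(a_keys):
            raise ParameterError("wrong equilibrium parameter vector length")
        return cls(
            energies=dict(zip(e_keys, theta[:ne])),
            bind_barriers=dict(zip(b_keys, theta[ne:ne + nbk])),
            act_barriers=dict(zip(a_keys, theta[ne + nbk:])),
        )

    def to_vector(self, spec: CircuitSpec) -> np.ndarray:
        e_keys, b_keys, a_keys = self.class_shape(spec)
        return np.array(
            [self.energies[k] for k in e_keys]
            + [self.bind_barriers[k] for k in b_keys]
            + [self.act_barriers[k] for k in a_keys]
        )


_EXP_LIMIT = 700.0  # beyond this, exp over/underflows a float64


def equilibrium_rate_matrix(
    spec: CircuitSpec, params: EquilibriumParameters, conc: Concentrations
) -> LabeledRateMatrix:
    """Generator of a detailed-balance circuit from energies and barriers."""
    states = enumerate_states(spec)
    index = {s: i for i, s in enumerate(states)}
    nb, na = spec.n_binding_sites, spec.n_activation_steps
    n_states = len(states)
    q = np.zeros((n_states, n_states))
    c_prop = np.zeros((n_states, n_states), dtype=bool)
    w_unit = np.zeros((n_states, n_states))
    labels: dict[tuple[int, int], str] = {}
    E, Bb, Ba = params.energies, params.bind_barriers, params.act_barriers

    def arr(e, b):
        x = e - b
        if abs(x) > _EXP_LIMIT:
            raise ParameterError("energy/barrier difference overflows exp()")
        return math.exp(x)

    for s in states:
        n_c, n_w, m = s
        i = index[s]
        n = n_c + n_w
        if n < nb:
            base = (nb - n) * arr(E[(n, m)], Bb[(n, m)])
            j = index[(n_c + 1, n_w, m)]
            q[i, j] += base * conc.c
            c_prop[i, j] = True
            labels[(i, j)] = f"bind_c E({n},{m})-B"
            if spec.include_noncognate:
                j = index[(n_c, n_w + 1, m)]
                q[i, j] += base * conc.w
                w_unit[i, j] += base
                labels[(i, j)] = f"bind_w E({n},{m})-B"
        if n_c >= 1:
            j = index[(n_c - 1, n_w, m)]
            q[i, j] += n_c * arr(E[(n, m)], Bb[(n - 1, m)])
            labels[(i, j)] = f"unbind_c E({n},{m})-B"
        if n_w >= 1:
            j = index[(n_c, n_w - 1, m)]
            q[i, j] += n_w * spec.affinity_factor * arr(E[(n, m)], Bb[(n - 1, m)])
            labels[(i, j)] = f"unbind_w alpha*E({n},{m})-B"
        if m < na:
            j = index[(n_c, n_w, m + 1)]
            q[i, j] += (na - m) * arr(E[(n, m)], Ba[(n, m)])
            labels[(i, j)] = f"act E({n},{m})-B"
        if m >= 1:
            j = index[(n_c, n_w, m - 1)]
            q[i, j] += m * arr(E[(n, m)], Ba[(n, m - 1)])
            labels[(i, j)] = f"deact E({n},{m})-B"
    on = np.array([m == na for (_, _, m) in states])
    return _finalize(states, q, on, labels, c_prop, w_unit)


def equilibrium_sample(
    spec: CircuitSpec, params: EquilibriumParameters
) -> RateParameters:
    """Invert an equilibrium draw to basal rates and ``eta`` factors.

    Only admissible for ``N_B = 1`` topologies, where the class-rate
    structure maps one-to-one onto :class:`RateParameters`; the resulting
    parameters rebuild the identical generator via
    :func:`build_rate_matrix` and have zero cycle affinity by construction.
    """
    if spec.n_binding_sites != 1 or spec.n_activation_steps != 1:
        raise ValueError("eta inversion admissible only for N_B = N_A = 1 topologies")
    E, Bb, Ba = params.energies, params.bind_barriers, params.act_barriers
    k_b = math.exp(E[(0, 0)] - Bb[(0, 0)])
    k_u = math.exp(E[(1, 0)] - Bb[(0, 0)])
    k_a = math.exp(E[(0, 0)] - Ba[(0, 0)])
    k_i = math.exp(E[(0, 1)] - Ba[(0, 0)])
    return RateParameters(
        k_b=k_b,
        k_u=k_u,
        k_a=k_a,
        k_i=k_i,
        eta_ab=math.exp(E[(1, 0)] - Ba[(1, 0)]) / k_a,
        eta_ib=math.exp(E[(1, 1)] - Ba[(1, 0)]) / k_i,
        eta_ua=math.exp(E[(1, 1)] - Bb[(0, 1)]) / k_u,
        eta_ba=math.exp(E[(0, 1)] - Bb[(0, 1)]) / k_b,
    )


def random_equilibrium_parameters(
    spec: CircuitSpec, rng: np.random.Generator, scale: float = 5.0
) -> EquilibriumParameters:
    """Draw energies and barriers uniformly on ``[-scale, scale] * ln(10)`` k_BT."""
    e_keys, b_keys, a_keys = EquilibriumParameters.class_shape(spec)
    lo, hi = -scale * math.log(10), scale * math.log(10)
    theta = rng.uniform(lo, hi, size=len(e_keys) + len(b_keys) + len(a_keys))
    return EquilibriumParameters.from_vector(spec, theta)
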