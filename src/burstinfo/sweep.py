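"""Parameter-space exploration: achievable regions and Pareto boundaries.

The sweep answers questions of the form "what is the largest information
rate a four-state circuit can reach at a given energy dissipation?" by
evolutionary boundary tracing: candidate circuits are drawn log-uniformly
inside the rate/interaction box constraints, scored, and an elitist archive
(one slot per x-axis bin, or a top-k list for scalar maximization) is
refined over generations by Gaussian mutation in log space with an
annealed step size.  Only the attained boundary is meaningful — the
algorithm makes no optimality claim beyond the archive it returns.

Two sampling branches are available.  The *nonequilibrium* branch
parameterizes the basal rates and ``eta`` interaction factors directly.
The *equilibrium* branch parameterizes state energies and edge barriers
(:class:`~burstinfo.circuits.EquilibriumParameters`), so every candidate
satisfies detailed balance by construction rather than by rejection.

Box constraints follow the study conditions: transition rates are bounded
by ``1e-5 <= k * tau_b <= 1e5`` (checked after evaluation, since the burst
time is itself rate dependent), interaction factors by
``1e-5 <= eta <= 1e5``, and the activator constraint ``eta_ab >= 1``,
``eta_ib <= 1`` holds for every candidate.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .circuits import (
    CircuitSpec,
    Concentrations,
    EquilibriumParameters,
    LabeledRateMatrix,
    RateParameters,
    StructuralError,
    build_rate_matrix,
    equilibrium_rate_matrix,
)
from .information import decision_time, information_rate
from .metrics import occupancy, sharpness, specificity, variance_rate
from .steady_state import burst_cycle_time, entropy_production, stationary_distribution

__all__ = [
    "SweepConfig",
    "ParetoBoundary",
    "MaximizeResult",
    "pareto_boundary",
    "maximize_metric",
    "scan_vs_wc",
    "evaluate_candidate",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class SweepConfig:
    """Knobs of the boundary-tracing sweep.

    ``mutation_scale`` is the (initial, final) Gaussian step in log10 units,
    annealed geometrically across generations.  ``n_elite`` is the archive
    size per bin (scalar maximization keeps that many leaders).  Bounds are
    half-open boxes in the natural parameters.
    """

    n_bins: int = 50
    n_init: int = 5000
    n_generations: int = 200
    n_elite: int = 24
    mutation_scale: tuple[float, float] = (0.8, 0.02)
    seed: int = 0
    rate_bounds: tuple[float, float] = (1e-5, 1e5)
    eta_bounds: tuple[float, float] = (1e-5, 1e5)
    equilibrium_only: bool = False
    half_max_constraint: bool = False
    half_max_tol: float = 0.01
    polish: bool = True
    n_restarts: int = 1
    x_range: tuple[float, float] | None = None
    log_x: bool = True
    epsilon: float = 0.32

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# candidate parameterizations


class _NoneqSpace:
    """Direct log10 parameterization of basal rates and eta factors."""

    def __init__(self, spec: CircuitSpec, config: SweepConfig):
        self.spec = spec
        self.config = config
        rlo, rhi = np.log10(config.rate_bounds)
        elo, ehi = np.log10(config.eta_bounds)
        names = ["k_b", "k_u", "k_a", "k_i", "eta_ab", "eta_ib", "eta_ua", "eta_ba"]
        lo = [rlo] * 4 + [0.0, elo, elo, elo]
        hi = [rhi] * 4 + [ehi, 0.0, ehi, ehi]
        if spec.n_binding_sites > 1:
            names.append("eta_ub")
            lo.append(elo)
            hi.append(ehi)
        self.names = names
        self.lo = np.array(lo)
        self.hi = np.array(hi)

    @property
    def dim(self) -> int:
        return len(self.names)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=(n, self.dim))

    def mutation_sigma(self, sigma_log10: float) -> np.ndarray:
        return np.full(self.dim, sigma_log10)  # coordinates are log10 rates

    def to_params(self, theta: np.ndarray) -> RateParameters:
        vals = 10.0 ** np.asarray(theta)
        return RateParameters(**dict(zip(self.names, vals)))

    def build(self, theta: np.ndarray, conc: Concentrations) -> LabeledRateMatrix:
        return build_rate_matrix(self.spec, self.to_params(theta), conc)

    def feasible(self, theta: np.ndarray, m: LabeledRateMatrix, tau_b: float) -> bool:
        lo, hi = self.config.rate_bounds
        rates = 10.0 ** np.asarray(theta[:4])
        kt = rates * tau_b
        return bool(np.all(kt >= lo) and np.all(kt <= hi))


class _EqSpace:
    """Energy/barrier parameterization: detailed balance and the activator
    constraint by construction.

    Detailed balance comes from the symmetric-barrier Arrhenius form.  The
    activator constraint (a bound activator speeds every activation step
    and slows every inactivation step, within the eta box) is built in:

    - state energies are supermodular in (occupancy, conformation) — the
      per-site binding free-energy drop ``g(n, m) = E(n+1, m) - E(n, m)``
      is nonincreasing in ``m`` by a nonnegative decrement ``delta(n, m)``
      (binding stabilizes the active conformation);
    - the activation-rate enhancement per bound activator is
      ``exp(u * delta)`` with ``u in [0, 1]``, which pins the matching
      inactivation fold change ``exp((u - 1) * delta)`` to at most 1.

    Coordinates (natural-log energy units unless noted): ``E(0, m)``;
    ``g(n, 0)``; ``delta(n, m) >= 0``; barrier *offsets* ``h`` measured
    from the midpoint of each edge's two state energies (binding edges and
    the unbound activation edges); and the dimensionless ``u(n, m)``.
    Midpoint anchoring keeps rates centered regardless of how large the
    composed state energies grow, so the scale-invariant ``k * tau_b``
    window only rejects circuits whose rate *spread* exceeds it.  The box
    keeps every implied eta within ``eta_bounds``.
    """

    def __init__(self, spec: CircuitSpec, config: SweepConfig):
        self.spec = spec
        self.config = config
        nb, na = spec.n_binding_sites, spec.n_activation_steps
        span = min(5.0, math.log10(config.eta_bounds[1])) * _LN10
        self.nb, self.na = nb, na
        sections = [
            ("e0", na + 1, -span, span),
            ("g0", nb, -span, span),
            ("delta", nb * na, 0.0, span),
            ("bb", nb * (na + 1), -span, span),
            ("ba0", na, -span, span),
            ("u", nb * na, 0.0, 1.0),
        ]
        lo, hi, slices, start = [], [], {}, 0
        for name, size, a, b in sections:
            slices[name] = slice(start, start + size)
            lo += [a] * size
            hi += [b] * size
            start += size
        self.slices = slices
        self.lo = np.array(lo)
        self.hi = np.array(hi)

    @property
    def dim(self) -> int:
        return self.lo.size

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=(n, self.dim))

    def mutation_sigma(self, sigma_log10: float) -> np.ndarray:
        # one decade of a 10-decade coordinate per unit sigma, scaled to
        # each coordinate's own range (u spans [0, 1])
        return sigma_log10 * (self.hi - self.lo) / 10.0

    def to_params(self, theta: np.ndarray) -> EquilibriumParameters:
        theta = np.asarray(theta)
        nb, na = self.nb, self.na
        sl = self.slices
        e0 = theta[sl["e0"]]
        g0 = theta[sl["g0"]]
        delta = theta[sl["delta"]].reshape(nb, na)
        bb = theta[sl["bb"]].reshape(nb, na + 1)
        ba0 = theta[sl["ba0"]]
        u = theta[sl["u"]].reshape(nb, na)
        g = np.empty((nb, na + 1))
        g[:, 0] = g0
        for mm in range(na):
            g[:, mm + 1] = g[:, mm] - delta[:, mm]
        energies = {}
        for mm in range(na + 1):
            acc = e0[mm]
            energies[(0, mm)] = acc
            for n in range(nb):
                acc += g[n, mm]
                energies[(n + 1, mm)] = acc
        bind_barriers = {
            (n, mm): 0.5 * (energies[(n, mm)] + energies[(n + 1, mm)]) + bb[n, mm]
            for n in range(nb)
            for mm in range(na + 1)
        }
        act_barriers = {}
        for mm in range(na):
            act_barriers[(0, mm)] = (
                0.5 * (energies[(0, mm)] + energies[(0, mm + 1)]) + ba0[mm]
            )
            for n in range(nb):
                log_r_act = u[n, mm] * delta[n, mm]
                act_barriers[(n + 1, mm)] = (
                    energies[(n + 1, mm)]
                    - log_r_act
                    - (energies[(n, mm)] - act_barriers[(n, mm)])
                )
        return EquilibriumParameters(
            energies=energies, bind_barriers=bind_barriers, act_barriers=act_barriers
        )

    def build(self, theta: np.ndarray, conc: Concentrations) -> LabeledRateMatrix:
        return equilibrium_rate_matrix(self.spec, self.to_params(theta), conc)

    def feasible(self, theta: np.ndarray, m: LabeledRateMatrix, tau_b: float) -> bool:
        """Post-hoc ``k * tau_b`` window on every per-class unit rate."""
        p = self.to_params(theta)
        lo, hi = self.config.rate_bounds
        unit_rates = []
        for (n, mm), b in p.bind_barriers.items():
            unit_rates.append(math.exp(p.energies[(n, mm)] - b))       # bind
            unit_rates.append(math.exp(p.energies[(n + 1, mm)] - b))   # unbind
        for (n, mm), b in p.act_barriers.items():
            unit_rates.append(math.exp(p.energies[(n, mm)] - b))       # activate
            unit_rates.append(math.exp(p.energies[(n, mm + 1)] - b))   # deactivate
        kt = np.array(unit_rates) * tau_b
        return bool(np.all(kt >= lo) and np.all(kt <= hi))


# ---------------------------------------------------------------------------
# candidate evaluation


def evaluate_candidate(
    space,
    theta: np.ndarray,
    conc: Concentrations,
    *,
    epsilon: float = 0.32,
    need_s0: bool = False,
) -> dict | None:
    """Score one candidate; None when the solve fails or constraints do."""
    try:
        m = space.build(theta, conc)
        pi = stationary_distribution(m)
        tau_b = burst_cycle_time(m, pi)
    except (StructuralError, np.linalg.LinAlgError, OverflowError, ValueError):
        return None
    if not space.feasible(theta, m, tau_b):
        return None
    try:
        pi_a = occupancy(m, pi)
        if not 1e-12 < pi_a < 1.0 - 1e-12:
            return None
        if space.config.half_max_constraint and abs(pi_a - 0.5) > space.config.half_max_tol:
            return None
        s = sharpness(m, pi, conc)
        v = variance_rate(m, pi, tau_b=tau_b)
        phi = entropy_production(m, pi)
    except (StructuralError, np.linalg.LinAlgError):
        return None
    p = 1.0 / math.sqrt(2.0 * v)
    norm = pi_a * (1.0 - pi_a)
    ir_nats, ir_bits = information_rate(s, p, conc.delta_c_rel)
    out = {
        "pi_a": pi_a,
        "r_bar": space.spec.max_rate * pi_a,
        "tau_b": tau_b,
        "phi_per_burst": phi * tau_b,
        "s": s,
        "p": p,
        "S": s / norm,
        "P": p * norm,
        "IR": ir_bits,
        "IR_nats": ir_nats,
        "T": decision_time(ir_nats, epsilon) if ir_nats > 0 else math.inf,
        "w_over_c": conc.w / conc.c,
    }
    if space.spec.include_noncognate:
        try:
            out["f"] = specificity(m, pi, conc)
            if need_s0:
                m0 = space.build(theta, replace(conc, w=0.0))
                pi0 = stationary_distribution(m0)
                pa0 = occupancy(m0, pi0)
                out["S0"] = sharpness(m0, pi0, replace(conc, w=0.0)) / (pa0 * (1 - pa0))
        except (StructuralError, np.linalg.LinAlgError):
            return None
    else:
        out["S0"] = out["S"]
    return out


def _make_space(spec: CircuitSpec, config: SweepConfig):
    return _EqSpace(spec, config) if config.equilibrium_only else _NoneqSpace(spec, config)


def _half_max_seeds(
    spec: CircuitSpec,
    config: SweepConfig,
    conc: Concentrations,
    rng: np.random.Generator,
    n_seeds: int = 12,
) -> list[np.ndarray]:
    """Hill-climb random candidates onto the half-max shell.

    The half-max condition |pi_a - 1/2| <= tol keeps only a thin slice of
    parameter space, so rejection sampling alone seeds the archive poorly;
    climbing |pi_a - 1/2| first gives the search usable starting points.
    """
    relaxed = _make_space(spec, replace(config, half_max_constraint=False))
    tol = config.half_max_tol

    def dist(theta):
        out = evaluate_candidate(relaxed, theta, conc, epsilon=config.epsilon)
        return abs(out["pi_a"] - 0.5) if out is not None else math.inf

    pool = sorted(
        ((dist(th), i, th) for i, th in enumerate(relaxed.sample(rng, config.n_init))),
        key=lambda e: (e[0], e[1]),
    )[:n_seeds]
    seeds = []
    for d0, _, theta in pool:
        d, cur = d0, theta
        for sigma in (0.5, 0.25, 0.1, 0.05, 0.02):
            for _ in range(40):
                if d <= tol:
                    break
                child = np.clip(
                    cur + rng.normal(0, 1, relaxed.dim) * relaxed.mutation_sigma(sigma),
                    relaxed.lo, relaxed.hi,
                )
                dc = dist(child)
                if dc < d:
                    d, cur = dc, child
        if d <= tol:
            seeds.append(cur)
    return seeds


def _anneal(config: SweepConfig, gen: int) -> float:
    s0, s1 = config.mutation_scale
    if config.n_generations <= 1:
        return s1
    frac = gen / (config.n_generations - 1)
    return s0 * (s1 / s0) ** frac


# ---------------------------------------------------------------------------
# results


@dataclass
class MaximizeResult:
    """Best circuit found for a scalar metric."""

    metric: str
    value: float
    theta: np.ndarray
    params: RateParameters | EquilibriumParameters
    summary: dict
    n_evaluations: int
    history: np.ndarray
    config: SweepConfig
    flagged_empty: bool = False


@dataclass
class ParetoBoundary:
    """Binned achievable-region boundary for a metric pair."""

    x_metric: str
    y_metric: str
    x_edges: np.ndarray
    y_max: np.ndarray
    y_min: np.ndarray
    thetas: list
    n_evaluations: int
    config: SweepConfig
    provenance: dict = field(default_factory=dict)
    flagged_empty: bool = False

    @property
    def x_centers(self) -> np.ndarray:
        if self.config.log_x:
            return np.sqrt(self.x_edges[:-1] * self.x_edges[1:])
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.x_centers,
                "y_max": self.y_max,
                "y_min": self.y_min,
            }
        )


# ---------------------------------------------------------------------------
# scalar maximization


def maximize_metric(
    spec: CircuitSpec,
    metric: str = "IR",
    config: SweepConfig | None = None,
    conc: Concentrations | None = None,
    *,
    sense: str = "max",
) -> MaximizeResult:
    """Evolutionary search for the extremal value of one scalar metric.

    Deterministic for a fixed ``config.seed``.  ``sense="min"`` flips the
    objective (decision time is minimized by maximizing IR, but any metric
    may be minimized directly).  ``config.n_restarts > 1`` repeats the
    search from independent deterministic substreams and keeps the best
    result — rugged landscapes (many energy/barrier coordinates) can trap
    a single run in a local boundary.
    """
    config = config or SweepConfig()
    if config.n_restarts > 1:
        best = None
        total = 0
        for k in range(config.n_restarts):
            sub = replace(config, n_restarts=1,
                          seed=(config.seed + 1_000_003 * k) % (2**31 - 1))
            r = _maximize_once(spec, metric, sub, conc, sense=sense)
            total += r.n_evaluations
            if best is None or (not r.flagged_empty and (
                    best.flagged_empty
                    or (r.value > best.value if sense == "max" else r.value < best.value))):
                best = r
        best.n_evaluations = total
        return best
    return _maximize_once(spec, metric, config, conc, sense=sense)


def _maximize_once(
    spec: CircuitSpec,
    metric: str,
    config: SweepConfig,
    conc: Concentrations | None,
    *,
    sense: str = "max",
) -> MaximizeResult:
    conc = conc or Concentrations()
    space = _make_space(spec, config)
    rng = np.random.default_rng(config.seed)
    sign = 1.0 if sense == "max" else -1.0
    need_s0 = metric in ("S0",)

    def score(theta):
        out = evaluate_candidate(space, theta, conc,
                                 epsilon=config.epsilon, need_s0=need_s0)
        if out is None or metric not in out or not math.isfinite(out[metric]):
            return None, None
        return sign * out[metric], out

    n_evals = 0
    elite: list[tuple[float, int, np.ndarray, dict]] = []  # (score, order, theta, out)

    def push(sc, theta, out):
        elite.append((sc, len(elite), theta, out))
        # stable: ties keep the earlier-evaluated circuit
        elite.sort(key=lambda e: (-e[0], e[1]))
        del elite[config.n_elite:]

    for theta in space.sample(rng, config.n_init):
        n_evals += 1
        sc, out = score(theta)
        if sc is not None:
            push(sc, theta, out)

    if config.half_max_constraint:
        for theta in _half_max_seeds(spec, config, conc, rng):
            n_evals += 1
            sc, out = score(theta)
            if sc is not None:
                push(sc, theta, out)

    history = np.full(config.n_generations, np.nan)
    for gen in range(config.n_generations):
        sigma = space.mutation_sigma(_anneal(config, gen))
        parents = [e[2] for e in elite] or [space.sample(rng, 1)[0]]
        for parent in parents:
            child = np.clip(parent + rng.normal(0.0, 1.0, space.dim) * sigma,
                            space.lo, space.hi)
            n_evals += 1
            sc, out = score(child)
            if sc is not None:
                push(sc, child, out)
        if elite:
            history[gen] = sign * elite[0][0]

    if not elite:
        return MaximizeResult(metric, math.nan, np.full(space.dim, np.nan),
                              None, {}, n_evals, history, config, flagged_empty=True)

    best_sc, _, best_theta, best_out = elite[0]
    if config.polish:
        def neg(theta):
            sc, _ = score(np.asarray(theta))
            return -sc if sc is not None else 1e9

        res = optimize.minimize(
            neg, best_theta, method="Powell",
            bounds=list(zip(space.lo, space.hi)),
            options={"maxfev": 4000, "xtol": 1e-6, "ftol": 1e-10},
        )
        n_evals += res.nfev
        sc, out = score(res.x)
        if sc is not None and sc > best_sc:
            best_sc, best_theta, best_out = sc, res.x, out

    return MaximizeResult(
        metric=metric,
        value=sign * best_sc,
        theta=np.asarray(best_theta),
        params=space.to_params(best_theta),
        summary=best_out,
        n_evaluations=n_evals,
        history=history,
        config=config,
    )


# ---------------------------------------------------------------------------
# boundary tracing


def pareto_boundary(
    spec: CircuitSpec,
    x_metric: str,
    y_metric: str,
    config: SweepConfig | None = None,
    conc: Concentrations | None = None,
) -> ParetoBoundary:
    """Trace the per-bin extremes of ``y_metric`` against ``x_metric``.

    The x-range is fixed from the feasible initial sample unless given in
    the config; candidates outside it are ignored for archiving but their
    mutations may re-enter.  An empty feasible set yields a flagged result.
    """
    config = config or SweepConfig()
    conc = conc or Concentrations()
    space = _make_space(spec, config)
    rng = np.random.default_rng(config.seed)
    need_s0 = "S0" in (x_metric, y_metric)

    def ev(theta):
        out = evaluate_candidate(space, theta, conc,
                                 epsilon=config.epsilon, need_s0=need_s0)
        if out is None:
            return None
        x, y = out.get(x_metric), out.get(y_metric)
        if x is None or y is None or not (math.isfinite(x) and math.isfinite(y)):
            return None
        return x, y, out

    n_evals = 0
    init: list[tuple[float, float, np.ndarray]] = []
    for theta in space.sample(rng, config.n_init):
        n_evals += 1
        r = ev(theta)
        if r is not None:
            init.append((r[0], r[1], theta))

    if not init and config.x_range is None:
        edges = np.linspace(0.0, 1.0, config.n_bins + 1)
        return ParetoBoundary(
            x_metric, y_metric, edges,
            np.full(config.n_bins, np.nan), np.full(config.n_bins, np.nan),
            [None] * config.n_bins, n_evals, config, flagged_empty=True,
        )

    if config.x_range is not None:
        x_lo, x_hi = config.x_range
    else:
        xs = np.array([r[0] for r in init])
        if config.log_x:
            xs = xs[xs > 0]
            x_lo, x_hi = (xs.min(), xs.max()) if xs.size else (1e-3, 1e3)
        else:
            x_lo, x_hi = xs.min(), xs.max()
    if config.log_x:
        edges = np.geomspace(max(x_lo, 1e-300), max(x_hi, x_lo * 1.0001), config.n_bins + 1)
    else:
        edges = np.linspace(x_lo, x_hi if x_hi > x_lo else x_lo + 1.0, config.n_bins + 1)

    hi_arch: list[tuple[float, int, np.ndarray] | None] = [None] * config.n_bins
    lo_arch: list[tuple[float, int, np.ndarray] | None] = [None] * config.n_bins
    order = 0

    def bin_of(x):
        if config.log_x and x <= 0:
            return None
        i = int(np.searchsorted(edges, x, side="right") - 1)
        return i if 0 <= i < config.n_bins else None

    def archive(x, y, theta):
        nonlocal order
        b = bin_of(x)
        if b is None:
            return
        order += 1
        cur = hi_arch[b]
        if cur is None or y > cur[0]:
            hi_arch[b] = (y, order, theta)
        cur = lo_arch[b]
        if cur is None or y < cur[0]:
            lo_arch[b] = (y, order, theta)

    for x, y, theta in init:
        archive(x, y, theta)

    for gen in range(config.n_generations):
        sigma = space.mutation_sigma(_anneal(config, gen))
        parents = [e[2] for e in hi_arch if e is not None]
        parents += [e[2] for e in lo_arch if e is not None]
        if not parents:
            parents = list(space.sample(rng, 8))
        for parent in parents:
            child = np.clip(parent + rng.normal(0.0, 1.0, space.dim) * sigma,
                            space.lo, space.hi)
            n_evals += 1
            r = ev(child)
            if r is not None:
                archive(r[0], r[1], child)

    y_max = np.array([e[0] if e else np.nan for e in hi_arch])
    y_min = np.array([e[0] if e else np.nan for e in lo_arch])
    thetas = [e[2] if e else None for e in hi_arch]
    return ParetoBoundary(
        x_metric=x_metric,
        y_metric=y_metric,
        x_edges=edges,
        y_max=y_max,
        y_min=y_min,
        thetas=thetas,
        n_evaluations=n_evals,
        config=config,
        provenance={"config_hash": config.config_hash(), "seed": config.seed},
        flagged_empty=not init,
    )


# ---------------------------------------------------------------------------
# noncognate interference scans


def scan_vs_wc(
    spec: CircuitSpec,
    wc_grid,
    config: SweepConfig | None = None,
) -> pd.DataFrame:
    """Maximum IR (equilibrium and nonequilibrium) vs noncognate load w/c.

    The cognate concentration is held at c*; each grid point runs a scalar
    IR maximization under both sampling branches and converts the optimum
    to a minimum decision time.  Returns one row per w/c value.
    """
    if not spec.include_noncognate:
        raise ValueError("scan_vs_wc requires a noncognate model")
    config = config or SweepConfig()
    rows = []
    for i, wc in enumerate(wc_grid):
        conc = Concentrations(c=1.0, w=float(wc))
        sub_eq = replace(config, equilibrium_only=True, seed=config.seed + 7919 * i)
        sub_ne = replace(config, equilibrium_only=False, seed=config.seed + 7919 * i + 1)
        r_eq = maximize_metric(spec, "IR", sub_eq, conc)
        r_ne = maximize_metric(spec, "IR", sub_ne, conc)
        rows.append(
            {
                "w_over_c": wc,
                "ir_eq_bits": r_eq.value,
                "ir_neq_bits": r_ne.value,
                "t_eq": decision_time(r_eq.summary.get("IR_nats", math.nan), config.epsilon)
                if r_eq.summary else math.nan,
                "t_neq": decision_time(r_ne.summary.get("IR_nats", math.nan), config.epsilon)
                if r_ne.summary else math.nan,
                "gain": r_ne.value / r_eq.value if r_eq.value else math.nan,
            }
        )
    return pd.DataFrame(rows)
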