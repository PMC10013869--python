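"""Binding-site mutation signatures of nonequilibrium regulation.

A point mutation in the activator binding site raises the cognate
unbinding rate by a factor ``beta = k_u_mut / k_u >= 1`` (noncognate
kinetics are untouched at ``alpha * k_u``).  The observable response is the
pair of fold changes in mean transcription rate (``r_bar_mut / r_bar``)
and normalized sharpness (``S_mut / S``); multiplying the sharpness fold
change by ``beta`` (i.e. dividing by ``k_u / k_u_mut``) puts different
mutation strengths on a common axis.  Equilibrium circuits occupy a
bounded region of this plane; information-optimal nonequilibrium circuits
fall outside it for every mutation strength and noncognate load, which
makes the pair an experimentally accessible nonequilibrium signature even
when ``w/c`` is unknown.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .circuits import (
    CircuitSpec,
    Concentrations,
    ParameterError,
    RateParameters,
    build_rate_matrix,
)
from .metrics import occupancy, sharpness
from .steady_state import stationary_distribution
from .sweep import SweepConfig, evaluate_candidate, maximize_metric, _EqSpace

__all__ = [
    "PerturbationResult",
    "perturbation_response",
    "equilibrium_response_region",
    "DEFAULT_BETAS",
]

#: Default mutation strengths: half a decade, one decade, and the full
#: cognate-to-noncognate conversion (beta = alpha = 100).
DEFAULT_BETAS = (10.0 ** 0.5, 10.0, 100.0)


@dataclass(frozen=True)
class PerturbationResult:
    """Fold-change response of one circuit to a binding-site mutation."""

    beta: float
    rate_fold: float
    sharp_fold: float
    sharp_fold_norm: float
    w_over_c: float
    equilibrium: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _rate_and_sharpness(
    spec: CircuitSpec, params: RateParameters, conc: Concentrations
) -> tuple[float, float]:
    m = build_rate_matrix(spec, params, conc)
    pi = stationary_distribution(m)
    pi_a = occupancy(m, pi)
    s = sharpness(m, pi, conc)
    return spec.max_rate * pi_a, s / (pi_a * (1.0 - pi_a))


def perturbation_response(
    spec: CircuitSpec,
    params: RateParameters,
    conc: Concentrations,
    beta: float,
    *,
    equilibrium: bool | None = None,
) -> PerturbationResult:
    """Fold changes in mean rate and normalized sharpness under ``k_u -> beta k_u``.

    Only specificity-*reducing* mutations (``beta >= 1``) are modeled; the
    identity ``beta = 1`` returns unit fold changes exactly.
    """
    if beta < 1:
        raise ParameterError("only specificity-reducing mutations (beta >= 1)")
    r_wt, s_wt = _rate_and_sharpness(spec, params, conc)
    mut = params.with_mutation(beta)
    r_mut, s_mut = _rate_and_sharpness(spec, mut, conc)
    if equilibrium is None:
        from .circuits import detailed_balance_residual

        try:
            equilibrium = detailed_balance_residual(build_rate_matrix(spec, params, conc)) < 1e-10
        except Exception:
            equilibrium = False
    sharp_fold = s_mut / s_wt
    return PerturbationResult(
        beta=beta,
        rate_fold=r_mut / r_wt,
        sharp_fold=sharp_fold,
        sharp_fold_norm=sharp_fold * beta,
        w_over_c=conc.w / conc.c,
        equilibrium=bool(equilibrium),
    )


def _mutated_folds_eq(space: _EqSpace, theta, conc: Concentrations, beta: float):
    """Fold changes for an equilibrium candidate (mutation scales the
    cognate unbinding barrier-crossing rate by beta)."""
    spec = space.spec
    m_wt = space.build(theta, conc)
    pi = stationary_distribution(m_wt)
    pi_a = occupancy(m_wt, pi)
    s_wt = sharpness(m_wt, pi, conc) / (pi_a * (1 - pi_a))
    r_wt = pi_a
    # mutation acts on the cognate species only: scale every cognate
    # unbinding edge of the equilibrium generator by beta
    from .circuits import equilibrium_rate_matrix

    m_mut = equilibrium_rate_matrix(spec, space.to_params(theta), conc)
    q = np.array(m_mut.generator)
    idx = {s: i for i, s in enumerate(m_mut.states)}
    for (n_c, n_w, mm), i in idx.items():
        if n_c >= 1:
            j = idx[(n_c - 1, n_w, mm)]
            q[i, j] *= beta
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    m_mut.generator = q
    pi_m = stationary_distribution(m_mut)
    pa_m = occupancy(m_mut, pi_m)
    s_mut = sharpness(m_mut, pi_m, conc) / (pa_m * (1 - pa_m))
    return pa_m / r_wt, s_mut / s_wt


def equilibrium_response_region(
    spec: CircuitSpec,
    beta: float,
    wc_grid,
    config: SweepConfig | None = None,
    *,
    n_rate_bins: int = 25,
) -> dict:
    """Equilibrium achievable region in (rate fold, normalized sharpness
    fold) space, plus the IR-optimal nonequilibrium point cloud.

    Equilibrium circuits are sampled by construction (energies/barriers)
    under the half-max condition ``|r_bar/r0 - 1/2| <= tol``; the region
    boundary is the per-rate-fold-bin envelope of the normalized sharpness
    fold ``(S_mut/S) * beta``.  For each ``w/c`` the IR-maximizing
    nonequilibrium circuit is located by sweep and its response point
    recorded.  Deterministic given ``config.seed``.
    """
    config = config or SweepConfig()
    # the half-max shell is too thin for rejection sampling: seed by
    # hill-climbing |pi_a - 1/2|, then random-walk along the shell
    config_eq = replace(config, equilibrium_only=True, half_max_constraint=False)
    tol = config.half_max_tol
    rng = np.random.default_rng(config_eq.seed)
    eq_points = []
    for wc in wc_grid:
        conc = Concentrations(c=1.0, w=float(wc))
        space = _EqSpace(spec, config_eq)

        def dist(theta):
            out = evaluate_candidate(space, theta, conc, epsilon=config_eq.epsilon)
            # a vanishing wild-type sharpness makes the fold change undefined
            if out is None or abs(out["S"]) < 1e-6:
                return math.inf, out
            return abs(out["pi_a"] - 0.5), out

        pool = sorted(
            ((dist(th)[0], i, th) for i, th in enumerate(space.sample(rng, config_eq.n_init))),
            key=lambda e: (e[0], e[1]),
        )[:8]
        kept = []
        for d0, _, theta in pool:
            d, cur = d0, theta
            for sigma in (0.5, 0.25, 0.1, 0.05, 0.02):
                for _ in range(40):
                    if d <= tol:
                        break
                    child = np.clip(cur + rng.normal(0, 1, space.dim)
                                    * space.mutation_sigma(sigma),
                                    space.lo, space.hi)
                    dc, _out = dist(child)
                    if dc < d:
                        d, cur = dc, child
            if d <= tol:
                kept.append(cur)
        # random walk along the shell to fill the achievable region
        for _ in range(config_eq.n_generations):
            if not kept:
                break
            parent = kept[int(rng.integers(len(kept)))]
            child = np.clip(parent + rng.normal(0, 1, space.dim)
                            * space.mutation_sigma(0.3),
                            space.lo, space.hi)
            dc, _out = dist(child)
            if dc <= tol:
                kept.append(child)
        for theta in kept:
            rf, sf = _mutated_folds_eq(space, theta, conc, beta)
            eq_points.append({"w_over_c": wc, "rate_fold": rf,
                              "sharp_fold_norm": sf * beta})
    eq_df = pd.DataFrame(eq_points)

    neq_points = []
    for i, wc in enumerate(wc_grid):
        conc = Concentrations(c=1.0, w=float(wc))
        sub = replace(config, equilibrium_only=False, half_max_constraint=True,
                      seed=config.seed + 104729 * (i + 1))
        best = maximize_metric(spec, "IR", sub, conc)
        if best.flagged_empty:
            continue
        res = perturbation_response(spec, best.params, conc, beta, equilibrium=False)
        neq_points.append({"w_over_c": wc, "rate_fold": res.rate_fold,
                           "sharp_fold_norm": res.sharp_fold_norm, "ir_bits": best.value})
    neq_df = pd.DataFrame(neq_points)

    if eq_df.empty:
        return {"beta": beta, "equilibrium_points": eq_df,
                "nonequilibrium_points": neq_df, "boundary": pd.DataFrame(),
                "flagged_empty": True}
    edges = np.linspace(eq_df.rate_fold.min(), eq_df.rate_fold.max() + 1e-12,
                        n_rate_bins + 1)
    which = np.clip(np.searchsorted(edges, eq_df.rate_fold, side="right") - 1,
                    0, n_rate_bins - 1)
    bound = (
        eq_df.assign(bin=which)
        .groupby("bin")["sharp_fold_norm"]
        .agg(["min", "max"])
        .reindex(range(n_rate_bins))
    )
    bound["rate_fold_center"] = 0.5 * (edges[:-1] + edges[1:])
    return {
        "beta": beta,
        "equilibrium_points": eq_df,
        "nonequilibrium_points": neq_df,
        "boundary": bound.reset_index(drop=True),
        "flagged_empty": False,
    }
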