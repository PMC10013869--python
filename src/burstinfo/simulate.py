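"""Exact stochastic simulation, empirical estimators, and sequential decisions.

This module is the package's synthetic-data generator and brute-force
oracle.  :func:`gillespie` produces exact jump trajectories of the locus
CTMC; :class:`Trajectory` derives the binary ON/OFF burst telegraph and the
accumulated-mRNA trace (deterministic integration of ``r0`` over ON dwell
time by default, matching the exclusion of synthesis shot noise from the
precision metric; Poisson emission optional).  :func:`estimate_metrics`
recovers occupancy, burst cycle time and the output variance rate with
bootstrap errors, and :func:`sprt_decision_times` runs sequential
probability ratio tests over trajectory ensembles to validate the
analytic decision-time bound.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .circuits import (
    CircuitSpec,
    Concentrations,
    LabeledRateMatrix,
    RateParameters,
    build_rate_matrix,
)
from .metrics import occupancy, variance_rate
from .steady_state import burst_cycle_time, stationary_distribution

__all__ = [
    "Trajectory",
    "gillespie",
    "estimate_metrics",
    "sprt_decision_times",
    "make_fixture",
    "load_fixture",
]


@dataclass
class Trajectory:
    """One exact jump trajectory of the locus chain.

    ``times[k]`` is the entry time into ``states[k]``; the trajectory is
    observed on ``[0, duration]`` (the final sojourn is truncated at
    ``duration``).
    """

    times: np.ndarray
    states: np.ndarray
    duration: float
    on_mask: np.ndarray
    seed: int | None = None

    def dwell_times(self) -> np.ndarray:
        ends = np.append(self.times[1:], self.duration)
        return ends - self.times

    def on_trace(self) -> np.ndarray:
        """Binary ON/OFF telegraph derived from the state sequence."""
        return self.on_mask[self.states]

    def integrated_on_time(self) -> float:
        return float(self.dwell_times() @ self.on_trace())

    def on_fraction(self) -> float:
        return self.integrated_on_time() / self.duration

    def mrna_trace(
        self,
        r0: float = 1.0,
        mode: str = "deterministic",
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Accumulated mRNA at each jump time.

        ``deterministic``: integrate ``r0`` over ON dwell time (default);
        ``poisson``: draw the per-dwell production count.
        """
        dw = self.dwell_times() * self.on_trace() * r0
        if mode == "poisson":
            if rng is None:
                rng = np.random.default_rng(self.seed)
            dw = rng.poisson(dw).astype(float)
        elif mode != "deterministic":
            raise ValueError(f"unknown mRNA accounting mode {mode!r}")
        acc = np.concatenate([[0.0], np.cumsum(dw)])
        t = np.append(self.times, self.duration)
        return t, acc


def gillespie(
    m: LabeledRateMatrix,
    duration: float,
    seed: int | np.random.Generator | None = None,
    *,
    initial_state: int | None = None,
    max_events: int = 50_000_000,
) -> Trajectory:
    """Exact stochastic simulation of the circuit CTMC.

    The initial state is drawn from the stationary law unless given.
    Deterministic for a fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = m.generator
    n = q.shape[0]
    exit_rates = -np.diag(q)
    jump_prob = np.where(np.eye(n, dtype=bool), 0.0, q)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_cum = np.cumsum(jump_prob / exit_rates[:, None], axis=1)
    if initial_state is None:
        pi = stationary_distribution(m)
        state = int(rng.choice(n, p=pi))
    else:
        state = int(initial_state)
    times = [0.0]
    seq = [state]
    t = 0.0
    mean_wait = [(1.0 / lam if lam > 0 else math.inf) for lam in exit_rates]
    cum_rows = [row for row in jump_cum]
    searchsorted = np.searchsorted
    expo, unif = rng.exponential, rng.random
    append_t, append_s = times.append, seq.append
    for _ in range(max_events):
        mw = mean_wait[state]
        if math.isinf(mw):
            break  # absorbing state
        t += expo(mw)
        if t >= duration:
            break
        state = int(searchsorted(cum_rows[state], unif()))
        append_t(t)
        append_s(state)
    else:
        raise RuntimeError("max_events exceeded before reaching duration")
    return Trajectory(
        times=np.array(times),
        states=np.array(seq, dtype=np.int64),
        duration=duration,
        on_mask=np.asarray(m.on_mask, dtype=bool),
        seed=seed if isinstance(seed, int) else None,
    )


def _cycle_times(traj: Trajectory) -> np.ndarray:
    """Durations of completed ON -> OFF -> ON cycles (between ON entries)."""
    on = traj.on_trace()
    entries = traj.times[1:][(~on[:-1]) & on[1:]]
    return np.diff(entries)


def estimate_metrics(
    trajectories: list[Trajectory],
    *,
    n_batches: int = 20,
    n_boot: int = 200,
    seed: int | None = None,
) -> dict:
    """Empirical occupancy, burst cycle time and variance rate with errors.

    The variance rate (in burst-time units, matching
    :func:`burstinfo.metrics.variance_rate`) comes from batch means of the
    integrated ON indicator; standard errors are bootstrap over
    trajectories (or over batches for a single trajectory).  Short
    trajectories yield wide errors, flagged via ``reliable=False``.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    rng = np.random.default_rng(seed)

    def pooled(trajs):
        total_t = sum(tr.duration for tr in trajs)
        pi_a = sum(tr.integrated_on_time() for tr in trajs) / total_t
        cycles = np.concatenate([_cycle_times(tr) for tr in trajs] or [[]])
        tau = float(np.mean(cycles)) if cycles.size else np.nan
        # batch-means variance of the time-averaged indicator
        xs = []
        for tr in trajs:
            edges = np.linspace(0.0, tr.duration, n_batches + 1)
            t = np.append(tr.times, tr.duration)
            on = np.append(tr.on_trace(), False)
            cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * on[:-1])])
            xs.append(np.diff(np.interp(edges, t, cum)))
        xs = np.concatenate(xs)
        bl = trajs[0].duration / n_batches
        v_abs = float(np.var(xs, ddof=1) / bl)
        return pi_a, tau, v_abs / tau if tau > 0 else np.nan

    pi_a, tau_b, v = pooled(trajectories)
    boots = []
    for _ in range(n_boot):
        if len(trajectories) > 1:
            idx = rng.integers(0, len(trajectories), len(trajectories))
            boots.append(pooled([trajectories[i] for i in idx]))
        else:
            break
    if boots:
        se = np.nanstd(np.array(boots, dtype=float), axis=0, ddof=1)
    else:
        n_cyc = _cycle_times(trajectories[0]).size
        se = np.array(
            [pi_a / np.sqrt(max(n_cyc, 1)), tau_b / np.sqrt(max(n_cyc, 1)), np.nan]
        )
    n_cycles = int(sum(_cycle_times(tr).size for tr in trajectories))
    return {
        "pi_a": pi_a, "pi_a_se": float(se[0]),
        "tau_b": tau_b, "tau_b_se": float(se[1]),
        "v": v, "v_se": float(se[2]),
        "n_cycles": n_cycles,
        "reliable": n_cycles >= 50,
    }


def sprt_decision_times(
    spec: CircuitSpec,
    params: RateParameters,
    c0: float = 0.95,
    c1: float = 1.05,
    epsilon: float = 0.32,
    n_rep: int = 200,
    seed: int | None = None,
    *,
    w: float = 0.0,
    max_bursts: float = 2000.0,
) -> dict:
    """Empirical mean decision time of the Gaussian-approximation SPRT.

    Half the replicates run under true concentration ``c0``, half under
    ``c1``.  Evidence is the integrated ON time ``x(t)``; the drift-
    diffusion log-likelihood ratio ``LLR(t) = (dmu / v_abs) (x(t) - mu_bar t)``
    (with ``dmu``, ``mu_bar`` the exact occupancy difference and midpoint
    and ``v_abs`` the midpoint variance rate) is stopped at the symmetric
    thresholds ``+/- ln((1-eps)/eps)``.  Crossings are located exactly
    within sojourns (LLR is piecewise linear in time).  Returns mean
    stopping time in burst-cycle units, the realized error fraction, and
    the fraction of replicates that hit the time cap.
    """
    if c0 >= c1:
        raise ValueError("degenerate problem: require c0 < c1")
    rng = np.random.default_rng(seed)
    mid = Concentrations(c=(c0 + c1) / 2.0, w=w)
    m_mid = build_rate_matrix(spec, params, mid)
    pi_mid = stationary_distribution(m_mid)
    tau_b = burst_cycle_time(m_mid, pi_mid)
    v_burst = variance_rate(m_mid, pi_mid, tau_b=tau_b)
    v_abs = v_burst * tau_b
    mats, mus = {}, {}
    for cv in (c0, c1):
        mm = build_rate_matrix(spec, params, replace(mid, c=cv))
        mats[cv] = mm
        mus[cv] = occupancy(mm)
    dmu = mus[c1] - mus[c0]
    mu_bar = 0.5 * (mus[c1] + mus[c0])
    k = dmu / v_abs
    a_thr = np.log((1.0 - epsilon) / epsilon)
    t_cap = max_bursts * tau_b

    # simulate in segments (~2x the predicted crossing time) so replicates
    # stop shortly after their decision instead of running to the cap
    drift = 0.5 * k * dmu  # mean LLR slope under either truth
    t_pred = (1.0 - 2.0 * epsilon) * a_thr / max(drift, 1e-300)
    seg = min(max(2.0 * t_pred, 20.0 * tau_b), t_cap)
    times, errors, capped = [], 0, 0
    for rep in range(n_rep):
        truth = c1 if rep % 2 == 0 else c0
        t_off, x_off = 0.0, 0.0
        state = None
        decided = False
        while t_off < t_cap and not decided:
            traj = gillespie(mats[truth], min(seg, t_cap - t_off), rng,
                             initial_state=state)
            t = np.append(traj.times, traj.duration)
            dt = np.diff(t)
            on = traj.on_trace().astype(float)
            x = x_off + np.concatenate([[0.0], np.cumsum(dt * on)])
            llr = k * (x - mu_bar * (t + t_off))
            hit = np.nonzero((llr[1:] >= a_thr) | (llr[1:] <= -a_thr))[0]
            if hit.size:
                i = int(hit[0])
                l0, l1 = llr[i], llr[i + 1]
                thr = a_thr if l1 >= a_thr else -a_thr
                frac = (thr - l0) / (l1 - l0)
                t_dec = t_off + t[i] + frac * dt[i]
                times.append(t_dec / tau_b)
                if (truth == c1) != (thr > 0):
                    errors += 1
                decided = True
            else:
                state = int(traj.states[-1])
                t_off += traj.duration
                x_off = x[-1]
        if not decided:
            capped += 1
            times.append(t_cap / tau_b)
    times = np.array(times)
    n_decided = n_rep - capped
    return {
        "mean_decision_time": float(times.mean()),
        "se_decision_time": float(times.std(ddof=1) / np.sqrt(len(times))),
        "error_rate": errors / n_decided if n_decided else np.nan,
        "cap_fraction": capped / n_rep,
        "tau_b": tau_b,
        "n_rep": n_rep,
    }


def make_fixture(
    spec: CircuitSpec,
    params: RateParameters,
    conc: Concentrations,
    durations: float | list[float],
    n_traj: int = 100,
    seed: int = 0,
    outdir: str | Path = ".",
) -> Path:
    """Write a reproducible synthetic trajectory dataset.

    Trajectories go to ``trajectories.csv`` (traj_id, time, state) with a
    ``metadata.json`` sidecar recording spec, parameters, concentrations,
    seed and a content checksum.  Regeneration with the same seed is
    bit-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if np.isscalar(durations):
        durations = [float(durations)] * n_traj
    if len(durations) != n_traj:
        raise ValueError("need one duration per trajectory")
    m = build_rate_matrix(spec, params, conc)
    rows = []
    root = np.random.SeedSequence(seed)
    for tid, (child, dur) in enumerate(zip(root.spawn(n_traj), durations)):
        traj = gillespie(m, dur, np.random.default_rng(child))
        rows.append(
            pd.DataFrame(
                {"traj_id": tid, "time": traj.times, "state": traj.states}
            )
        )
    table = pd.concat(rows, ignore_index=True)
    csv_path = outdir / "trajectories.csv"
    table.to_csv(csv_path, index=False, float_format="%.12g")
    checksum = hashlib.sha256(csv_path.read_bytes()).hexdigest()
    meta = {
        "spec": spec.__dict__,
        "params": {k: v for k, v in params.__dict__.items()},
        "conc": conc.__dict__,
        "durations": list(map(float, durations)),
        "n_traj": n_traj,
        "seed": seed,
        "on_states": [i for i, v in enumerate(m.on_mask) if v],
        "state_labels": [list(s) for s in m.states],
        "sha256": checksum,
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=1))
    return outdir


def load_fixture(path: str | Path) -> tuple[list[Trajectory], dict]:
    """Read a fixture written by :func:`make_fixture`."""
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    table = pd.read_csv(path / "trajectories.csv")
    n_states = len(meta["state_labels"])
    on_mask = np.zeros(n_states, dtype=bool)
    on_mask[meta["on_states"]] = True
    trajs = []
    for tid, grp in table.groupby("traj_id"):
        trajs.append(
            Trajectory(
                times=grp["time"].to_numpy(),
                states=grp["state"].to_numpy(),
                duration=meta["durations"][int(tid)],
                on_mask=on_mask,
                seed=meta["seed"],
            )
        )
    return trajs, meta
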