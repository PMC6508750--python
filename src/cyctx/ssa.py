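"""Exact stochastic simulation of a single cell lineage.

The simulator follows one cell through successive division cycles with the
Gillespie algorithm.  In S1 the gene has one copy, in S2 two copies that
switch and transcribe independently; the propensities are

    S1:  lam1*(1-I), gamma1*I, nu1*I, delta1*M, kappa1
    S2:  lam2*(2-I), gamma2*I, nu2*I, delta2*M, kappa2

On the duplication event (rate kappa1) the cell enters S2 with both copies
OFF; on the division event (rate kappa2) the transcript count is thinned
binomially with keep probability 1/2 (the lineage follows one daughter,
drawn in a single binomial variate -- distributionally identical to
per-molecule coin flips), the cell re-enters S1 and the promoter starts OFF.

Stationary stage-conditioned moments are estimated by time averages along
the lineage after a burn-in, with Monte-Carlo standard errors from batch
means over completed division cycles.  Ergodicity of the lineage process
(time average = stationary ensemble value) is assumed; the closed forms and
the master-equation oracle verify it empirically in the test suite.

The inner event loop is compiled with numba; identical seed and parameters
reproduce the trajectory exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import ModelParams, ParameterError

__all__ = [
    "Trajectory",
    "StageMomentEstimates",
    "EstimationError",
    "simulate_lineage",
    "estimate_stage_moments",
]


class EstimationError(RuntimeError):
    """Too few completed cycles to form the requested estimates."""


@njit(cache=True)
def _seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _sim_chunk(rates, t_max, t0, U0, I0, M0, out_t, out_U, out_I, out_M):
    """Advance the lineage until t_max or the buffer fills.

    Returns (number of recorded events, final t, U, I, M).  The RNG state is
    numba's thread-local generator, seeded once per run by the wrapper.
    """
    l1, g1, n1, d1, l2, g2, n2, d2, k1, k2 = (
        rates[0], rates[1], rates[2], rates[3], rates[4],
        rates[5], rates[6], rates[7], rates[8], rates[9],
    )
    t, U, I, M = t0, U0, I0, M0
    cap = out_t.shape[0]
    k = 0
    while k < cap:
        if U == 1:
            a0 = l1 * (1 - I)
            a1 = g1 * I
            a2 = n1 * I
            a3 = d1 * M
            a4 = k1
        else:
            a0 = l2 * (2 - I)
            a1 = g2 * I
            a2 = n2 * I
            a3 = d2 * M
            a4 = k2
        atot = a0 + a1 + a2 + a3 + a4
        t += np.random.exponential(1.0 / atot)
        if t >= t_max:
            t = t_max
            break
        u = np.random.random() * atot
        if u < a0:
            I += 1
        elif u < a0 + a1:
            I -= 1
        elif u < a0 + a1 + a2:
            M += 1
        elif u < a0 + a1 + a2 + a3:
            M -= 1
        else:
            if U == 1:
                U = 2
                I = 0  # both copies start OFF after duplication
            else:
                M = np.random.binomial(M, 0.5)
                U = 1
                I = 0  # promoter OFF at the start of the new cycle
        out_t[k] = t
        out_U[k] = U
        out_I[k] = I
        out_M[k] = M
        k += 1
    return k, t, U, I, M


@dataclass(frozen=True)
class Trajectory:
    """Piecewise-constant lineage path: state *after* each recorded event.

    Index 0 is the initial condition (t=0, S1, promoter OFF, no mRNA unless
    overridden); the final entry is the state at ``t_max``.
    """

    t: np.ndarray
    U: np.ndarray
    I: np.ndarray
    M: np.ndarray
    seed: int
    params: ModelParams = field(repr=False)

    @property
    def n_events(self) -> int:
        return self.t.size - 2  # exclude the initial and the t_max sentinel

    def division_indices(self) -> np.ndarray:
        """Indices of events at which the cell divided (entered S1 from S2)."""
        return np.nonzero((self.U[1:] == 1) & (self.U[:-1] == 2))[0] + 1


def simulate_lineage(
    params: ModelParams,
    t_max: float,
    seed: int,
    initial: tuple[int, int, int] = (1, 0, 0),
) -> Trajectory:
    """Run the exact lineage simulation up to ``t_max`` hours.

    ``initial`` is the starting ``(U, I, M)``; the default is the
    synchronized start in S1 with the promoter OFF and no transcripts.
    """
    if t_max <= 0:
        raise ParameterError("t_max must be positive")
    U0, I0, M0 = initial
    if U0 not in (1, 2) or I0 < 0 or I0 > (1 if U0 == 1 else 2) or M0 < 0:
        raise ParameterError(f"invalid initial state {initial!r}")
    s1, s2, c = params.stage1, params.stage2, params.cycle
    rates = np.array(
        [s1.lam, s1.gamma, s1.nu, s1.delta, s2.lam, s2.gamma, s2.nu, s2.delta,
         c.kappa1, c.kappa2],
        dtype=np.float64,
    )
    _seed_rng(np.uint32(seed))

    chunk = 1 << 20
    ts = [np.array([0.0])]
    Us = [np.array([U0], dtype=np.int8)]
    Is = [np.array([I0], dtype=np.int8)]
    Ms = [np.array([M0], dtype=np.int64)]
    t, U, I, M = 0.0, U0, I0, M0
    while t < t_max:
        bt = np.empty(chunk)
        bU = np.empty(chunk, dtype=np.int8)
        bI = np.empty(chunk, dtype=np.int8)
        bM = np.empty(chunk, dtype=np.int64)
        k, t, U, I, M = _sim_chunk(rates, t_max, t, U, I, M, bt, bU, bI, bM)
        if not np.isfinite(t):
            raise FloatingPointError("non-finite simulation clock")
        ts.append(bt[:k]); Us.append(bU[:k]); Is.append(bI[:k]); Ms.append(bM[:k])
    # close the path with a sentinel at t_max carrying the final state
    ts.append(np.array([t_max]))
    Us.append(np.array([U], dtype=np.int8))
    Is.append(np.array([I], dtype=np.int8))
    Ms.append(np.array([M], dtype=np.int64))
    return Trajectory(
        t=np.concatenate(ts), U=np.concatenate(Us), I=np.concatenate(Is),
        M=np.concatenate(Ms), seed=int(seed), params=params,
    )


@dataclass(frozen=True)
class StageMomentEstimates:
    """Time-average estimates of the stationary stage-conditioned moments.

    All ``se_*`` entries are batch-means Monte-Carlo standard errors over
    completed division cycles.  ``occupancy`` holds the fractions of time
    spent in S1 and S2 (they sum to 1 over the analysed window).
    """

    m1: float
    m2: float
    m: float
    mu1: float
    mu2: float
    mu: float
    var1: float
    var2: float
    var: float
    eta2_1: float
    eta2_2: float
    eta2: float
    phi1: float
    phi2: float
    phi: float
    se: dict[str, float]
    occupancy: tuple[float, float]
    n_cycles: int
    seed: int


def _weighted_stats(w: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    tot = w.sum()
    if tot <= 0:
        return np.nan, np.nan
    mean = float((w * x).sum() / tot)
    second = float((w * x.astype(float) ** 2).sum() / tot)
    return mean, second


def estimate_stage_moments(
    traj: Trajectory,
    burn_in_cycles: int = 20,
    n_batches: int = 20,
    min_cycles: int = 10,
) -> StageMomentEstimates:
    """Estimate stationary moments from a lineage trajectory.

    Discards everything before the ``burn_in_cycles``-th completed division,
    then forms time-weighted averages of M and M^2 conditioned on the stage.
    Standard errors come from ``n_batches`` contiguous batches of whole
    cycles.  Raises :class:`EstimationError` if fewer than ``min_cycles``
    cycles remain after burn-in.
    """
    div = traj.division_indices()
    if div.size <= burn_in_cycles + min_cycles:
        raise EstimationError(
            f"only {max(div.size - burn_in_cycles, 0)} completed cycles after "
            f"burn-in; need at least {min_cycles}"
        )
    start = div[burn_in_cycles]
    end = div[-1]  # analyse whole cycles only
    n_cycles = div.size - 1 - burn_in_cycles

    t, U, M = traj.t, traj.U, traj.M
    dt = t[start + 1 : end + 1] - t[start:end]
    stage = U[start:end]
    m = M[start:end].astype(float)

    in1 = stage == 1
    w1, w2 = dt * in1, dt * (~in1)
    mean1, sec1 = _weighted_stats(w1, m)
    mean2, sec2 = _weighted_stats(w2, m)
    mean, sec = _weighted_stats(dt, m)

    # batch means over contiguous groups of completed cycles
    cyc_edges = div[burn_in_cycles:]
    batch_of_cycle = np.minimum(
        (np.arange(n_cycles) * n_batches) // n_cycles, n_batches - 1
    )
    # map each interval to its cycle, then to its batch
    cyc_idx = np.searchsorted(cyc_edges[1:], np.arange(start, end), side="right")
    b = batch_of_cycle[cyc_idx]

    def batch_series(w: np.ndarray):
        tw = np.bincount(b, weights=w, minlength=n_batches)
        s1 = np.bincount(b, weights=w * m, minlength=n_batches)
        s2 = np.bincount(b, weights=w * m**2, minlength=n_batches)
        with np.errstate(invalid="ignore", divide="ignore"):
            mb = s1 / tw
            qb = s2 / tw
        return mb, qb

    def se_of(x: np.ndarray) -> float:
        x = x[np.isfinite(x)]
        if x.size < 2:
            return np.nan
        return float(np.std(x, ddof=1) / np.sqrt(x.size))

    se: dict[str, float] = {}
    results = {}
    for name, w, mn, sc in (("1", w1, mean1, sec1), ("2", w2, mean2, sec2), ("", dt, mean, sec)):
        mb, qb = batch_series(w)
        with np.errstate(invalid="ignore", divide="ignore"):
            phib = np.where(mb > 0, (qb - mb**2) / mb, np.where(mb == 0, 0.0, np.nan))
            eta2b = np.where(mb > 0, (qb - mb**2) / mb**2, np.nan)
        se[f"m{name}"] = se_of(mb)
        se[f"mu{name}"] = se_of(qb)
        se[f"phi{name}"] = se_of(phib)
        se[f"eta2_{name}" if name else "eta2"] = se_of(eta2b)
        var = sc - mn**2
        results[name] = (mn, sc, var)

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else (0.0 if num == 0 else np.nan)

    (m1, mu1, v1), (m2, mu2, v2), (mm, mmu, vv) = results["1"], results["2"], results[""]
    occ1 = float(w1.sum() / dt.sum())
    return StageMomentEstimates(
        m1=m1, m2=m2, m=mm, mu1=mu1, mu2=mu2, mu=mmu,
        var1=v1, var2=v2, var=vv,
        eta2_1=ratio(v1, m1**2), eta2_2=ratio(v2, m2**2), eta2=ratio(vv, mm**2),
        phi1=ratio(v1, m1), phi2=ratio(v2, m2), phi=ratio(vv, mm),
        se=se, occupancy=(occ1, 1.0 - occ1), n_cycles=n_cycles, seed=traj.seed,
    )
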