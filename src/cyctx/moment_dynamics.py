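"""Time-dependent moment dynamics from a synchronized start.

All cells start at t = 0 at the beginning of S1 with the promoter OFF and no
(newly counted) transcripts.  The joint stage-promoter probabilities, the
stage-partitioned first moments and the stage-partitioned second moments
each satisfy constant-coefficient linear ODE systems, driven in cascade:

* promoter occupancies  P10, P11 (S1) and P20, P21, P22 (S2);
* stage first moments   n1 = E[M; U=1], n2 = E[M; U=2], plus their
  promoter-resolved refinements n_ji = E[M; U=j, I=i];
* stage second moments  omega1 = E[M^2; U=1], omega2 = E[M^2; U=2].

Division (rate kappa2) thins the mRNA count binomially with keep
probability 1/2, which enters the moment systems through the exact factors
1/2 on n2 (mean) and omega2/4 + n2/4 (second moment).  The full cascade is
one 14-dimensional homogeneous linear system; it is propagated exactly with
matrix exponentials over each grid interval, so no integration tolerance is
involved.

Stage-conditioned moments follow by normalization: m_i(t) = n_i(t)/P_i(t)
and mu_i(t) = omega_i(t)/P_i(t).  At t = 0 the S2 conditionals are
undefined (P2(0) = 0) and are reported as NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .params import CellCycleRates, ModelParams, ParameterError

__all__ = [
    "STATE_NAMES",
    "build_moment_matrix",
    "stage_probabilities",
    "solve_moment_system",
    "solve_promoter_system",
    "solve_first_moments",
    "solve_second_moments",
    "conditional_moments",
]

#: Ordering of the cascade state vector.
STATE_NAMES = (
    "P10", "P11", "P20", "P21", "P22",
    "n1", "n2",
    "n10", "n11", "n20", "n21", "n22",
    "omega1", "omega2",
)

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


def build_moment_matrix(params: ModelParams) -> np.ndarray:
    """Generator matrix A of the cascade, d/dt x = A x, ordered as STATE_NAMES."""
    s1, s2, c = params.stage1, params.stage2, params.cycle
    l1, g1, n1, d1 = s1.lam, s1.gamma, s1.nu, s1.delta
    l2, g2, n2, d2 = s2.lam, s2.gamma, s2.nu, s2.delta
    k1, k2 = c.kappa1, c.kappa2

    A = np.zeros((14, 14))

    def put(row: str, **cols: float) -> None:
        for col, val in cols.items():
            A[_IDX[row], _IDX[col]] = val

    # Promoter occupancies.
    put("P10", P10=-(l1 + k1), P11=g1, P20=k2, P21=k2, P22=k2)
    put("P11", P10=l1, P11=-(g1 + k1))
    put("P20", P10=k1, P11=k1, P20=-(2 * l2 + k2), P21=g2)
    put("P21", P20=2 * l2, P21=-(l2 + g2 + k2), P22=2 * g2)
    put("P22", P21=l2, P22=-(2 * g2 + k2))

    # Stage first moments (division halves the mean: factor kappa2/2).
    put("n1", P11=n1, n1=-(d1 + k1), n2=k2 / 2.0)
    put("n2", P21=n2, P22=2 * n2, n1=k1, n2=-(d2 + k2))

    # Promoter-resolved first moments.
    put("n10", n2=k2 / 2.0, n10=-(d1 + l1 + k1), n11=g1)
    put("n11", P11=n1, n10=l1, n11=-(d1 + g1 + k1))
    put("n20", n1=k1, n20=-(d2 + 2 * l2 + k2), n21=g2)
    put("n21", P21=n2, n20=2 * l2, n21=-(d2 + l2 + g2 + k2), n22=2 * g2)
    put("n22", P22=2 * n2, n21=l2, n22=-(d2 + 2 * g2 + k2))

    # Stage second moments (binomial thinning: E[B(n,1/2)^2] = n^2/4 + n/4).
    put("omega1", P11=n1, n1=d1, n2=k2 / 4.0, n11=2 * n1,
        omega1=-(2 * d1 + k1), omega2=k2 / 4.0)
    put("omega2", P21=n2, P22=2 * n2, n2=d2, n21=2 * n2, n22=4 * n2,
        omega1=k1, omega2=-(2 * d2 + k2))
    return A


def stage_probabilities(t, cycle: CellCycleRates):
    """Closed-form stage occupancies ``(P1(t), P2(t))``, synchronized start.

    ``P1(t) = k2/(k1+k2) + k1/(k1+k2) * exp(-(k1+k2) t)`` with P1(0) = 1.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("time must be non-negative")
    k1, k2 = cycle.kappa1, cycle.kappa2
    tot = k1 + k2
    p1 = k2 / tot + (k1 / tot) * np.exp(-tot * t)
    return p1, 1.0 - p1


def _validate_grid(t_grid) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t.ndim != 1 or t.size == 0:
        raise ParameterError("time grid must be a non-empty 1-D array")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ParameterError("time grid must be non-negative and non-decreasing")
    return t


def solve_moment_system(t_grid, params: ModelParams) -> pd.DataFrame:
    """Propagate the full cascade over a time grid (hours).

    Returns a DataFrame indexed by row with columns ``t``, the 14 cascade
    states, the stage occupancies ``P1``/``P2``, and the conditional moments
    ``m1, m2, mu1, mu2`` together with the population moments ``m, mu``.
    Conditionals are NaN wherever the conditioning stage has zero
    probability (only t = 0 for S2).
    """
    t = _validate_grid(t_grid)
    A = build_moment_matrix(params)
    x = np.zeros(14)
    x[_IDX["P10"]] = 1.0

    out = np.empty((t.size, 14))
    prev_t = 0.0
    prev_dt = None
    step = None
    if t[0] == 0.0:
        out[0] = x
        start = 1
    else:
        start = 0
    for k in range(start, t.size):
        dt = t[k] - prev_t
        if dt > 0:
            if step is None or dt != prev_dt:
                step = expm(A * dt)
                prev_dt = dt
            x = step @ x
        out[k] = x
        prev_t = t[k]

    df = pd.DataFrame(out, columns=list(STATE_NAMES))
    df.insert(0, "t", t)
    df["P1"] = df["P10"] + df["P11"]
    df["P2"] = df["P20"] + df["P21"] + df["P22"]
    mass_drift = np.abs(df["P1"] + df["P2"] - 1.0).max()
    if mass_drift > 1e-9:
        raise FloatingPointError(
            f"probability conservation violated along trajectory (drift {mass_drift:.3e})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        df["m1"] = np.where(df["P1"] > 0, df["n1"] / df["P1"], np.nan)
        df["m2"] = np.where(df["P2"] > 0, df["n2"] / df["P2"], np.nan)
        df["mu1"] = np.where(df["P1"] > 0, df["omega1"] / df["P1"], np.nan)
        df["mu2"] = np.where(df["P2"] > 0, df["omega2"] / df["P2"], np.nan)
    df["m"] = df["n1"] + df["n2"]
    df["mu"] = df["omega1"] + df["omega2"]
    return df


def solve_promoter_system(t_grid, params: ModelParams) -> pd.DataFrame:
    """Joint stage-promoter probabilities over the grid.

    Columns: t, P10, P11, P20, P21, P22, P1, P2.
    """
    df = solve_moment_system(t_grid, params)
    return df[["t", "P10", "P11", "P20", "P21", "P22", "P1", "P2"]].copy()


def solve_first_moments(t_grid, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Stage-partitioned first moments ``(n1(t), n2(t))`` over the grid."""
    df = solve_moment_system(t_grid, params)
    return df["n1"].to_numpy(), df["n2"].to_numpy()


def solve_second_moments(t_grid, params: ModelParams):
    """Stage-partitioned second moments and promoter-resolved first moments.

    Returns ``(omega1, omega2, nji)`` where ``nji`` is a DataFrame with
    columns t, n10, n11, n20, n21, n22.
    """
    df = solve_moment_system(t_grid, params)
    nji = df[["t", "n10", "n11", "n20", "n21", "n22"]].copy()
    return df["omega1"].to_numpy(), df["omega2"].to_numpy(), nji


def conditional_moments(t_grid, params: ModelParams) -> pd.DataFrame:
    """Stage-conditioned means and second moments over the grid.

    Columns: t, m1, m2, mu1, mu2, m, mu.  The S2 entries are NaN at any
    time with P2(t) = 0 (the synchronized start).
    """
    df = solve_moment_system(t_grid, params)
    return df[["t", "m1", "m2", "mu1", "mu2", "m", "mu"]].copy()
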