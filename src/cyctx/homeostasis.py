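"""Transcription and concentration homeostasis, and the volume-growth model.

*Transcription homeostasis* means the stationary mean mRNA count is the same
in both cell-cycle stages, ``m1* = m2*`` -- the dosage doubling at gene
duplication is exactly compensated.  When compensation acts through a single
kinetic rate (synthesis, degradation, activation or inactivation) the
compensating S2 rate has a closed form in the shared remaining rates; these
are implemented in :func:`homeostasis_partner_rate`.

*Concentration homeostasis* instead requires the mean count to scale with
the mean cell volume: ``r* = r_v``, where ``r_v = V2/V1`` is the fold change
of the average volume across the stages.  Under exponential single-cell
growth ``V(t) = exp(a t)`` with exact doubling over one cycle and
exponential stage durations T1, T2 (rates kappa1, kappa2), renewal theory
gives

    a   = (kappa1 + kappa2 - sqrt(kappa1^2 + kappa2^2)) / 2,
    r_v = kappa2 / (kappa2 - a)            (always in (1, 2)).

:func:`solve_concentration_homeostasis` finds the single free rate that
attains ``r* = r_v``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .params import CellCycleRates, ModelParams, ParameterError, StageKinetics
from .steady_state import fold_change, noise_measures

__all__ = [
    "VolumeModel",
    "InfeasibleError",
    "AmbiguousRootError",
    "homeostasis_partner_rate",
    "build_homeostatic_params",
    "homeostasis_residual",
    "volume_growth",
    "cycle_length_cdf",
    "solve_concentration_homeostasis",
    "find_homeostasis_and_noise_minimum",
]

_PARTNER_RATES = ("nu", "delta", "lam", "gamma")


class InfeasibleError(ValueError):
    """No positive compensating rate exists for the requested channel."""


class AmbiguousRootError(RuntimeError):
    """The scanned bracket contains more than one solution."""

    def __init__(self, roots: list[float]):
        self.roots = roots
        super().__init__(f"multiple candidate roots found: {roots}")


def homeostasis_partner_rate(
    which: str, base: StageKinetics, cycle: CellCycleRates
) -> float:
    """Compensating S2 value of one kinetic rate for ``m1* = m2*``.

    ``base`` carries the S1 value of the varied rate *and* the shared values
    of the other three rates (shared means identical in both stages).  The
    closed forms, with ``s = lam + gamma`` evaluated from the shared rates:

    * ``which="nu"``:    nu2 = nu1 * delta (s + kappa2) / [(2 delta + kappa1)(s + kappa1)]
    * ``which="delta"``: delta2 = (2 delta1 + kappa1)(s + kappa1) / (s + kappa2)
    * ``which="lam"``:   1/lam2 = (2 delta + kappa1)(gamma + kappa1) / [lam1 delta (gamma + kappa2)]
      + (delta + kappa1) / [delta (gamma + kappa2)]
    * ``which="gamma"``: gamma2 = (2 delta + kappa1)(lam + gamma1 + kappa1)/delta - lam - kappa2

    The synthesis channel is proportional (halve production to offset the
    dosage doubling in the slow-cycling limit); the others are affine.  The
    inactivation channel can be infeasible (non-positive right side), which
    raises :class:`InfeasibleError`.
    """
    lam, gamma, nu, delta = base.lam, base.gamma, base.nu, base.delta
    k1, k2 = cycle.kappa1, cycle.kappa2
    s = lam + gamma
    if which == "nu":
        return nu * delta * (s + k2) / ((2.0 * delta + k1) * (s + k1))
    if which == "delta":
        return (2.0 * delta + k1) * (s + k1) / (s + k2)
    if which == "lam":
        inv = ((2.0 * delta + k1) * (gamma + k1) / (lam * delta * (gamma + k2))
               + (delta + k1) / (delta * (gamma + k2)))
        return 1.0 / inv
    if which == "gamma":
        g2 = (2.0 * delta + k1) * (lam + gamma + k1) / delta - lam - k2
        if g2 <= 0.0:
            raise InfeasibleError(
                f"no positive compensating inactivation rate exists (got {g2!r})"
            )
        return g2
    raise ValueError(f"unknown rate channel {which!r}; expected one of {_PARTNER_RATES}")


def build_homeostatic_params(
    which: str, base: StageKinetics, cycle: CellCycleRates
) -> ModelParams:
    """Full parameter set with the S2 rate replaced by its compensating value."""
    partner = homeostasis_partner_rate(which, base, cycle)
    kwargs = {f: getattr(base, f) for f in ("lam", "gamma", "nu", "delta")}
    kwargs[which] = partner
    return ModelParams(stage1=base, stage2=StageKinetics(**kwargs), cycle=cycle)


def homeostasis_residual(params: ModelParams) -> float:
    """Signed residual that vanishes exactly when ``m1* = m2*``.

    Equating the two stage-mean numerators and cancelling the common
    denominator leaves

        nu1 lam1 delta2 (lam2 + gamma2 + kappa2)
        - nu2 lam2 (2 delta1 + kappa1)(lam1 + gamma1 + kappa1),

    positive when S1 out-produces S2 per unit occupancy (``r* < 1``) and
    negative when duplication overshoots (``r* > 1``).
    """
    s1, s2, c = params.stage1, params.stage2, params.cycle
    return (
        s1.nu * s1.lam * s2.delta * (s2.lam + s2.gamma + c.kappa2)
        - s2.nu * s2.lam * (2.0 * s1.delta + c.kappa1) * (s1.lam + s1.gamma + c.kappa1)
    )


@dataclass(frozen=True)
class VolumeModel:
    """Exponential single-cell growth calibrated to exact doubling per cycle."""

    kappa1: float
    kappa2: float
    a: float
    r_v: float

    def expected_volume_s1_end(self) -> float:
        """E[V(T1)] = kappa1/(kappa1 - a): mean volume at gene duplication."""
        return self.kappa1 / (self.kappa1 - self.a)

    def sample_cycle_parts(self, rng: np.random.Generator, n: int):
        """Draw n independent (T1, T2) stage-duration pairs, in hours."""
        return (
            rng.exponential(1.0 / self.kappa1, size=n),
            rng.exponential(1.0 / self.kappa2, size=n),
        )


def volume_growth(cycle: CellCycleRates) -> VolumeModel:
    """Growth rate and volume fold change implied by the cycle rates.

    Solving E[V(T1+T2)] = 2 for exponential growth yields
    ``a = (k1 + k2 - sqrt(k1^2 + k2^2))/2``; the stage volume fold change is
    ``r_v = E[V(T1+T2)]/E[V(T1)] = k2/(k2 - a)``, strictly between 1 and 2.
    """
    k1, k2 = cycle.kappa1, cycle.kappa2
    a = (k1 + k2 - math.hypot(k1, k2)) / 2.0
    r_v = k2 / (k2 - a)
    return VolumeModel(kappa1=k1, kappa2=k2, a=a, r_v=r_v)


def cycle_length_cdf(t, cycle: CellCycleRates):
    """CDF of the total cycle length T1 + T2 (hypoexponential).

    ``F(t) = 1 - k2/(k2-k1) e^{-k1 t} - k1/(k1-k2) e^{-k2 t}`` for distinct
    rates; the analytic limit for equal rates is the Erlang-2 form
    ``1 - e^{-k t}(1 + k t)``.  Accepts scalars or arrays; F(t<0) = 0.
    """
    t = np.asarray(t, dtype=float)
    k1, k2 = cycle.kappa1, cycle.kappa2
    tt = np.clip(t, 0.0, None)
    if abs(k1 - k2) <= 1e-9 * (k1 + k2):
        k = 0.5 * (k1 + k2)
        out = 1.0 - np.exp(-k * tt) * (1.0 + k * tt)
    else:
        out = (1.0 - k2 / (k2 - k1) * np.exp(-k1 * tt)
               - k1 / (k1 - k2) * np.exp(-k2 * tt))
    out = np.where(t < 0, 0.0, np.clip(out, 0.0, 1.0))
    return float(out) if out.ndim == 0 else out


_FREE_RATES = {"lam2": "stage2.lam", "gamma2": "stage2.gamma",
               "nu2": "stage2.nu", "delta2": "stage2.delta"}


def solve_concentration_homeostasis(
    free_rate: str,
    params: ModelParams,
    bracket: tuple[float, float] = (1e-6, 1e3),
    n_scan: int = 200,
) -> float:
    """Value of one S2 rate that attains concentration homeostasis r* = r_v.

    A coarse log-spaced scan of ``n_scan`` points over ``bracket`` (per
    hour) locates sign changes of ``r*(x) - r_v`` before Brent refinement.
    Raises :class:`ParameterError` if no sign change exists in the bracket
    and :class:`AmbiguousRootError` (listing all refined roots) if several
    do -- multiple roots are surfaced, never silently resolved.
    """
    if free_rate not in _FREE_RATES:
        raise ValueError(f"free_rate must be one of {sorted(_FREE_RATES)}")
    path = _FREE_RATES[free_rate]
    target = volume_growth(params.cycle).r_v

    def f(x: float) -> float:
        return fold_change(params.replace_rate(path, x)) - target

    xs = np.geomspace(bracket[0], bracket[1], n_scan)
    fs = np.array([f(x) for x in xs])
    sign_changes = np.nonzero(np.sign(fs[:-1]) * np.sign(fs[1:]) < 0)[0]
    if sign_changes.size == 0:
        raise ParameterError(
            f"no solution for {free_rate}: r*(x) - r_v has no sign change over "
            f"[{bracket[0]:g}, {bracket[1]:g}] per hour "
            f"(range of residual: [{fs.min():.3g}, {fs.max():.3g}])"
        )
    roots = [
        brentq(f, xs[i], xs[i + 1], xtol=1e-300, rtol=1e-15, maxiter=200)
        for i in sign_changes
    ]
    if len(roots) > 1:
        raise AmbiguousRootError(roots)
    return roots[0]


_AXES = {"nu": "stage2.nu", "delta": "stage2.delta",
         "lam": "stage2.lam", "gamma": "stage2.gamma"}


def find_homeostasis_and_noise_minimum(
    axis: str,
    params: ModelParams,
    ratio_range: tuple[float, float] = (0.1, 10.0),
    n_scan: int = 200,
) -> dict[str, float]:
    """Locate the homeostasis point H and the noise minimum Z along one axis.

    The axis is the ratio of an S2 kinetic rate to its S1 counterpart,
    swept over ``ratio_range``; all other parameters stay fixed.  H is the
    root of the transcription-homeostasis residual; Z minimizes the overall
    stationary noise ``eta2*`` (golden-section refinement of a log-spaced
    grid).  Returns ``{"H": .., "Z": .., "eta2_H": .., "eta2_Z": ..}``;
    ``H`` is NaN (with ``eta2_H`` NaN) when no homeostasis root lies in the
    range.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    path = _AXES[axis]
    base_rate = params.rate(path.replace("stage2", "stage1"))

    def at_ratio(r: float) -> ModelParams:
        return params.replace_rate(path, r * base_rate)

    def resid(r: float) -> float:
        return homeostasis_residual(at_ratio(r))

    def eta2(r: float) -> float:
        return noise_measures(at_ratio(r))[2]

    lo, hi = ratio_range
    if lo <= 0 or hi <= lo:
        raise ParameterError("ratio_range must be positive and increasing")
    grid = np.geomspace(lo, hi, n_scan)

    # H: bracketed root of the residual
    rs = np.array([resid(g) for g in grid])
    idx = np.nonzero(np.sign(rs[:-1]) * np.sign(rs[1:]) < 0)[0]
    if idx.size > 0:
        H = brentq(resid, grid[idx[0]], grid[idx[0] + 1], xtol=1e-300, rtol=1e-15)
        eta2_H = eta2(H)
    else:
        H, eta2_H = math.nan, math.nan

    # Z: coarse grid minimum refined by bounded golden-section search
    es = np.array([eta2(g) for g in grid])
    j = int(np.argmin(es))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, n_scan - 1)]
    if a < b:
        res = minimize_scalar(
            lambda x: eta2(math.exp(x)),
            bounds=(math.log(a), math.log(b)), method="bounded",
            options={"xatol": 1e-12},
        )
        Z = math.exp(res.x)
        eta2_Z = float(res.fun)
        if es[j] < eta2_Z:  # guard against refinement landing worse
            Z, eta2_Z = float(grid[j]), float(es[j])
    else:
        Z, eta2_Z = float(grid[j]), float(es[j])
    return {"H": H, "Z": Z, "eta2_H": eta2_H, "eta2_Z": eta2_Z}
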