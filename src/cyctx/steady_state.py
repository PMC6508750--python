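"""Closed-form stationary moments, noise measures and the S1->S2 fold change.

All formulas are exact stationary solutions of the moment ODE system of the
cell-cycle-coupled telegraph model.  The population mean ``m*`` and second
moment ``mu*`` are mixtures of the stage-conditioned values weighted by the
stationary stage occupancies ``kappa2/(kappa1+kappa2)`` and
``kappa1/(kappa1+kappa2)``.

Noise conventions (for a random count N):

* noise (squared coefficient of variation) ``eta2 = Var[N]/E[N]^2``
* noise strength (Fano-type) ``phi = Var[N]/E[N]``, in mRNA-count units.

The closed forms are evaluated literally as derived, without algebraic
re-simplification, so that each quantity is traceable term by term; the
master-equation oracle (:mod:`cyctx.fsp`) and the stochastic simulator
(:mod:`cyctx.ssa`) adjudicate them independently in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from scipy.optimize import brentq

from .params import CellCycleRates, ModelParams, ParameterError, StageKinetics

__all__ = [
    "SteadyStateSummary",
    "stationary_means",
    "stationary_second_moments",
    "noise_measures",
    "summarize",
    "slow_cycling_limits",
    "fold_change",
    "fold_change_shared",
    "constitutive_fold_change",
    "params_for_fold_change",
    "fold_change_thresholds",
    "FoldChangeFlags",
]


def _unpack(params: ModelParams):
    s1, s2, c = params.stage1, params.stage2, params.cycle
    return (
        s1.lam, s1.gamma, s1.nu, s1.delta,
        s2.lam, s2.gamma, s2.nu, s2.delta,
        c.kappa1, c.kappa2,
    )


def stationary_means(params: ModelParams) -> tuple[float, float, float]:
    """Stationary mean mRNA counts ``(m1, m2, m)``.

    ``m1`` and ``m2`` are conditioned on the cell residing in S1 and S2;
    ``m`` is the population mean, their occupancy-weighted mixture.
    """
    l1, g1, n1, d1, l2, g2, n2, d2, k1, k2 = _unpack(params)
    den = (2.0 * (d1 + k1) * (d2 + k2) - k1 * k2) * (l1 + g1 + k1) * (l2 + g2 + k2)
    m1 = (2.0 * n1 * l1 * (d2 + k2) * (l2 + g2 + k2) + 2.0 * n2 * l2 * k1 * (l1 + g1 + k1)) / den
    m2 = (2.0 * n1 * l1 * k2 * (l2 + g2 + k2) + 4.0 * n2 * l2 * (d1 + k1) * (l1 + g1 + k1)) / den
    w1, w2 = params.cycle.stage_weights
    return m1, m2, m1 * w1 + m2 * w2


def stationary_second_moments(
    params: ModelParams,
) -> tuple[float, float, float, float, float, float]:
    """Stationary second moments ``(mu1, mu2, mu, ms1, ms2, p22)``.

    ``ms1`` and ``ms2`` are the stationary cross-moments E[I*M] between the
    active-copy count and the mRNA count in each stage, and ``p22`` is the
    stationary probability (conditioned on S2) that both gene copies are ON.
    """
    l1, g1, n1, d1, l2, g2, n2, d2, k1, k2 = _unpack(params)
    m1, m2, _ = stationary_means(params)
    p22 = 2.0 * l2**2 / ((k2 + l2 + g2) * (k2 + 2.0 * l2 + 2.0 * g2))
    ms1 = ((d1 + l1 + k1) * m1 - k1 * m2 / 2.0) / (d1 + l1 + g1 + k1)
    ms2 = ((d2 + k2 + 2.0 * l2) * m2 - k2 * m1 + 2.0 * n2 * p22) / (d2 + l2 + g2 + k2)
    den2 = 4.0 * (k1 + 2.0 * d1) * (k2 + 2.0 * d2) - k1 * k2
    mu1 = m1 + (8.0 * n1 * (k2 + 2.0 * d2) * ms1 + 2.0 * n2 * k1 * ms2) / den2
    mu2 = m2 + (8.0 * n1 * k2 * ms1 + 8.0 * n2 * (k1 + 2.0 * d1) * ms2) / den2
    w1, w2 = params.cycle.stage_weights
    return mu1, mu2, mu1 * w1 + mu2 * w2, ms1, ms2, p22


def noise_measures(
    params: ModelParams,
) -> tuple[float, float, float, float, float, float]:
    """Stationary noise ``(eta2_1, eta2_2, eta2, phi1, phi2, phi)``.

    The stage noise strengths are evaluated from the same driving term as the
    second moments, ``phi_i = 1 - m_i + (mu_i - m_i)/m_i``; the population
    values apply the defining ratios to the mixture moments.
    """
    l1, g1, n1, d1, l2, g2, n2, d2, k1, k2 = _unpack(params)
    m1, m2, m = stationary_means(params)
    if m1 <= 0.0 or m2 <= 0.0 or m <= 0.0:
        raise ParameterError("noise is undefined for zero stationary means")
    mu1, mu2, mu, ms1, ms2, _ = stationary_second_moments(params)
    den2 = 4.0 * (k1 + 2.0 * d1) * (k2 + 2.0 * d2) - k1 * k2
    drive1 = (8.0 * n1 * (k2 + 2.0 * d2) * ms1 + 2.0 * n2 * k1 * ms2) / den2
    drive2 = (8.0 * n1 * k2 * ms1 + 8.0 * n2 * (k1 + 2.0 * d1) * ms2) / den2
    phi1 = 1.0 - m1 + drive1 / m1
    phi2 = 1.0 - m2 + drive2 / m2
    eta2_1 = 1.0 / m1 - 1.0 + drive1 / m1**2
    eta2_2 = 1.0 / m2 - 1.0 + drive2 / m2**2
    phi = (mu - m * m) / m
    eta2 = phi / m
    return eta2_1, eta2_2, eta2, phi1, phi2, phi


@dataclass(frozen=True)
class SteadyStateSummary:
    """All stationary moments, noise measures and the fold change."""

    m1_star: float
    m2_star: float
    m_star: float
    mu1_star: float
    mu2_star: float
    mu_star: float
    ms1_star: float
    ms2_star: float
    p22_star: float
    eta2_1: float
    eta2_2: float
    eta2: float
    phi1: float
    phi2: float
    phi: float
    r_star: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def summarize(params: ModelParams) -> SteadyStateSummary:
    """Evaluate every stationary quantity for one parameter set."""
    m1, m2, m = stationary_means(params)
    mu1, mu2, mu, ms1, ms2, p22 = stationary_second_moments(params)
    eta2_1, eta2_2, eta2, phi1, phi2, phi = noise_measures(params)
    return SteadyStateSummary(
        m1_star=m1, m2_star=m2, m_star=m,
        mu1_star=mu1, mu2_star=mu2, mu_star=mu,
        ms1_star=ms1, ms2_star=ms2, p22_star=p22,
        eta2_1=eta2_1, eta2_2=eta2_2, eta2=eta2,
        phi1=phi1, phi2=phi2, phi=phi,
        r_star=fold_change(params),
    )


def slow_cycling_limits(kinetics: StageKinetics) -> tuple[float, float]:
    """Limits of ``m1`` and ``phi1`` as cycling becomes infinitely slow.

    With shared kinetics and ``kappa1 -> 0`` the S1-stage statistics reduce
    to the classical one-copy telegraph model:

    * mean: ``nu*lam / (delta*(lam+gamma))``
    * noise strength: ``1 + nu*gamma / ((lam+gamma)*(delta+lam+gamma))``

    The same noise-strength limit governs ``phi2`` as ``kappa2 -> 0`` (each
    of the two copies contributes independently, doubling both the mean and
    the variance).
    """
    lam, gamma, nu, delta = kinetics.lam, kinetics.gamma, kinetics.nu, kinetics.delta
    mean_limit = nu * lam / (delta * (lam + gamma))
    phi_limit = 1.0 + nu * gamma / ((lam + gamma) * (delta + lam + gamma))
    return mean_limit, phi_limit


# ---------------------------------------------------------------------------
# Fold change


def fold_change(params: ModelParams) -> float:
    """Stationary fold change ``r* = m2*/m1*`` of mean mRNA from S1 to S2.

    Evaluated from the explicit ratio formula in which the common
    denominator of the two stage means cancels; it involves all ten system
    parameters and is homogeneous of degree zero (invariant under a common
    rescaling of every rate).
    """
    l1, g1, n1, d1, l2, g2, n2, d2, k1, k2 = _unpack(params)
    num = n1 * l1 * k2 * (l2 + g2 + k2) + 2.0 * n2 * l2 * (d1 + k1) * (l1 + g1 + k1)
    den = n1 * l1 * (d2 + k2) * (l2 + g2 + k2) + n2 * l2 * k1 * (l1 + g1 + k1)
    return num / den


def fold_change_shared(kinetics: StageKinetics, cycle: CellCycleRates) -> float:
    """Fold change when both stages share the same telegraph kinetics.

    Depends on the kinetics only through ``s = lam + gamma`` and ``delta``:
    ``r* = [2(d+k1)(s+k1) + k2(s+k2)] / [k1(s+k1) + (d+k2)(s+k2)]``.
    """
    s = kinetics.lam + kinetics.gamma
    d = kinetics.delta
    k1, k2 = cycle.kappa1, cycle.kappa2
    return (2.0 * (d + k1) * (s + k1) + k2 * (s + k2)) / (k1 * (s + k1) + (d + k2) * (s + k2))


def constitutive_fold_change(
    nu1: float, nu2: float, delta: float, kappa1: float, kappa2: float
) -> tuple[float, float, float]:
    """Stage means and fold change for an always-active promoter.

    The limit ``lam1, lam2 -> infinity`` (constitutive transcription, shared
    degradation rate ``delta``) collapses the stage means to

    ``m1* = [2 nu1 (d+k2) + 2 nu2 k1] / [2(d+k1)(d+k2) - k1 k2]``
    ``m2* = [2 nu1 k2 + 4 nu2 (d+k1)] / [2(d+k1)(d+k2) - k1 k2]``

    and ``r* = [nu1 k2 + 2 nu2 (d+k1)] / [nu1 (d+k2) + nu2 k1]``.  Any
    consistent rate unit may be used; ``r*`` is dimensionless.
    """
    if min(nu1, nu2, delta, kappa1, kappa2) <= 0:
        raise ParameterError("constitutive fold change requires positive rates")
    den = 2.0 * (delta + kappa1) * (delta + kappa2) - kappa1 * kappa2
    m1 = (2.0 * nu1 * (delta + kappa2) + 2.0 * nu2 * kappa1) / den
    m2 = (2.0 * nu1 * kappa2 + 4.0 * nu2 * (delta + kappa1)) / den
    r = (nu1 * kappa2 + 2.0 * nu2 * (delta + kappa1)) / (nu1 * (delta + kappa2) + nu2 * kappa1)
    return m1, m2, r


def _shared_params(s: float, delta: float, k1: float, k2: float, nu: float = 1.0) -> ModelParams:
    kin = StageKinetics(lam=s / 2.0, gamma=s / 2.0, nu=nu, delta=delta)
    return ModelParams.shared(kin, CellCycleRates(k1, k2))


def params_for_fold_change(C: float, kappa1: float = 1.0) -> ModelParams:
    """Construct shared-kinetics parameters achieving a prescribed ``r* = C``.

    For ``C <= 1`` an explicit witness exists: ``lam + gamma = kappa1``,
    ``kappa2 = 4 kappa1 / C`` and ``delta = (16 - 12C - 2C^3) kappa1 / C^3``
    give ``r* = C`` identically.  For ``C > 1`` no similarly compact printed
    form is available, so the constructor fixes ``lam + gamma`` and ``delta``
    within a small family of scalings of ``kappa1`` and solves ``r*(kappa2) =
    C`` by bracketing and Brent's method (the shared-kinetics fold change is
    continuous and spans the needed range as ``kappa2`` varies).

    The returned parameters always satisfy the shared-kinetics constraint;
    the split ``lam = gamma`` and ``nu = 1`` are arbitrary since ``r*``
    depends only on ``lam + gamma``, ``delta`` and the cycle rates.
    """
    if C <= 0:
        raise ParameterError(f"target fold change must be positive, got {C!r}")
    kappa1 = float(kappa1)
    if C <= 1.0:
        s = kappa1
        kappa2 = 4.0 * kappa1 / C
        delta = (16.0 - 12.0 * C - 2.0 * C**3) * kappa1 / C**3
        return _shared_params(s, delta, kappa1, kappa2)

    # C > 1: search over (lam+gamma, delta) families for a kappa2 bracket.
    lo_k2, hi_k2 = 1e-12 * kappa1, 1e12 * kappa1
    for s_fac in (1.0, 0.1, 1e-2, 1e-3, 1e-4):
        for d_fac in (1.0, 10.0, 1e2, 1e3, 1e4, 1e6):
            s, delta = s_fac * kappa1, d_fac * kappa1
            kin = StageKinetics(lam=s / 2.0, gamma=s / 2.0, nu=1.0, delta=delta)

            def f(k2: float) -> float:
                return fold_change_shared(kin, CellCycleRates(kappa1, k2)) - C

            if f(lo_k2) * f(hi_k2) < 0.0:
                kappa2 = brentq(f, lo_k2, hi_k2, xtol=1e-300, rtol=1e-15, maxiter=300)
                return _shared_params(s, delta, kappa1, kappa2)
    raise ParameterError(f"could not bracket a shared-kinetics witness for r* = {C!r}")


@dataclass(frozen=True)
class FoldChangeFlags:
    """Threshold diagnosis of the shared-kinetics fold change.

    ``gt2`` is True iff ``r* > 2`` and ``lt1`` iff ``r* < 1``;
    ``kappa1_threshold`` is the value of ``kappa1`` (at the given ``kappa2``)
    above which ``r* > 2``, and ``kappa2_threshold`` the value of ``kappa2``
    (at the given ``kappa1``) above which ``r* < 1``.
    """

    gt2: bool
    lt1: bool
    kappa1_threshold: float
    kappa2_threshold: float


def fold_change_thresholds(kinetics: StageKinetics, cycle: CellCycleRates) -> FoldChangeFlags:
    """Necessary-and-sufficient threshold tests for ``r* > 2`` and ``r* < 1``.

    With shared kinetics (``s = lam + gamma``):

    * ``r* > 2``  iff  ``kappa1 > kappa2 + kappa2 (kappa2 + s) / (2 delta)``
    * ``r* < 1``  iff  ``kappa2 > 2 kappa1 + s + kappa1 (s + kappa1) / delta``

    A fast S1->S2 transition relative to S2->division piles probability into
    the two-copy stage before transcripts equilibrate, pushing the fold
    change above the naive dosage factor 2; the opposite asymmetry can push
    it below 1.  When ``kappa1 <= kappa2`` the fold change is strictly
    below 2.
    """
    s = kinetics.lam + kinetics.gamma
    d = kinetics.delta
    k1, k2 = cycle.kappa1, cycle.kappa2
    k1_thr = k2 + k2 * (k2 + s) / (2.0 * d)
    k2_thr = 2.0 * k1 + s + k1 * (s + k1) / d
    return FoldChangeFlags(
        gt2=k1 > k1_thr,
        lt1=k2 > k2_thr,
        kappa1_threshold=k1_thr,
        kappa2_threshold=k2_thr,
    )
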