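"""Analytical equilibrium theory of membrane-enhanced pair binding.

The central result is the exact relationship between the effective
association constant Ka_eff (which lumps solution and membrane complexes)
and the free-lipid concentration at equilibrium:

    Ka_eff / Ka_PP = [ gamma * K1 * K2 * M^2 + (K1 + K2) * M + 1 ]
                     / [ (1 + K1 * M) * (1 + K2 * M) ]

with K1 = Ka_P1M, K2 = Ka_P2M, M = [M]_eq and gamma = V/(2 A sigma).  The
relation is exact given the true [M]_eq; the approximate part of the theory
is the interpolation for [M]_eq between the no-complex limit (Ka_PP = 0,
single-site quadratic) and the all-complex "cooperative" limit
(Ka_PP = infinity, two-site cubic), weighted by the complexed fraction
lambda.

All functions take canonical internal units (um^3 constants, um^-3
concentrations); :class:`~kaeff.parameters.PairParameters` handles molar
I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .parameters import PairParameters
from .units import InvalidParameterError

__all__ = [
    "TheoryResult",
    "FitError",
    "m_eq_zero",
    "ka_pm_weighted_average",
    "m_eq_coop",
    "lambda_fraction",
    "m_eq",
    "MEqComponents",
    "enhancement_at",
    "ka_eff",
    "membrane_fraction_of_complexes",
    "critical_lipid_concentration",
    "fit_ka2d_from_enhancement",
    "FitResult",
]


class FitError(ValueError):
    """The measured enhancement is inconsistent with the model."""


def _binding_quadratic(a_tot: float, b_tot: float, ka: float) -> float:
    """Bound complex of A + B <-> AB at totals a_tot, b_tot.

    Cancellation-free root of Ka*x^2 - (a+b+1/Ka)Ka*x + Ka*a*b = 0 written
    as 2ab / (S + sqrt(S^2 - 4ab)) with S = a + b + 1/Ka; stable for Ka
    spanning 0..1e15 M^-1.
    """
    if ka == 0.0 or a_tot == 0.0 or b_tot == 0.0:
        return 0.0
    s = a_tot + b_tot + 1.0 / ka
    disc = s * s - 4.0 * a_tot * b_tot
    disc = max(disc, 0.0)
    return 2.0 * a_tot * b_tot / (s + math.sqrt(disc))


def m_eq_zero(m_tot: float, p_tot: float, ka_pm_av: float) -> float:
    """Free lipid in the no-complex limit (Ka_PP = 0).

    Single-site balance M + P <-> MP with the averaged protein-lipid
    constant; the non-negative quadratic root.  Recovers m_tot when lipids
    are in great excess, and m_tot when ka_pm_av = 0 (no binding).
    """
    if m_tot < 0 or p_tot < 0 or ka_pm_av < 0:
        raise InvalidParameterError("m_eq_zero inputs must be non-negative")
    if ka_pm_av == 0.0:
        return m_tot
    bound = _binding_quadratic(m_tot, p_tot, ka_pm_av)
    return m_tot - bound


def ka_pm_weighted_average(
    ka1: float, ka2: float, p1: float, p2: float
) -> float:
    """Concentration-weighted average protein-lipid association constant.

    Weights are the protein concentrations (equilibrium values when
    available are more accurate than totals).  With p1 + p2 = 0 the
    unweighted mean is returned.
    """
    if p1 < 0 or p2 < 0:
        raise InvalidParameterError("protein concentrations must be non-negative")
    if p1 + p2 == 0.0:
        return 0.5 * (ka1 + ka2)
    return (ka1 * p1 + ka2 * p2) / (p1 + p2)


def m_eq_coop(params: PairParameters) -> float:
    """Free lipid in the all-complex limit (Ka_PP -> infinity).

    All pairable protein is treated as a two-site complex C at concentration
    min(P1_0, P2_0) equilibrating with the membrane through

        C + M <-> MC   (Ka_P1M)        C + M <-> CM   (Ka_P2M)
        MC + M <-> MCM (gamma Ka_P2M)  CM + M <-> MCM (gamma Ka_P1M)

    and any unpaired protein surplus binds lipid with its own single-site
    constant.  The lipid balance closes to a cubic in [M] when the totals
    match; the unique root in [0, m_tot] is returned, falling back to
    monotone bracketing on the mass-balance residual otherwise.
    """
    m0 = params.m_tot_volume
    k1, k2 = params.ka_p1m, params.ka_p2m
    g = params.gamma
    c_tot = min(params.p1_tot, params.p2_tot)
    e_tot = abs(params.p1_tot - params.p2_tot)
    ka_e = k1 if params.p1_tot > params.p2_tot else k2

    if m0 == 0.0:
        return 0.0
    if k1 == 0.0 and k2 == 0.0 and (ka_e == 0.0 or e_tot == 0.0):
        return m0

    a = k1 + k2
    b = g * k1 * k2

    def residual(m: float) -> float:
        denom = 1.0 + a * m + b * m * m
        bound_c = c_tot * (a * m + 2.0 * b * m * m) / denom
        bound_e = e_tot * ka_e * m / (1.0 + ka_e * m) if e_tot else 0.0
        return m + bound_c + bound_e - m0

    if e_tot == 0.0 and b > 0.0:
        # (m - m0)(1 + a m + b m^2) + c_tot (a m + 2 b m^2) = 0
        coeffs = [
            b,
            a - b * m0 + 2.0 * c_tot * b,
            1.0 - a * m0 + c_tot * a,
            -m0,
        ]
        roots = np.roots(coeffs)
        real = roots[np.abs(roots.imag) < 1e-9 * np.abs(roots.real).max()].real
        candidates = [r for r in real if -1e-12 * m0 <= r <= m0 * (1 + 1e-12)]
        if candidates:
            return float(min(max(min(candidates), 0.0), m0))
    # monotone residual: residual(0) = -m0 < 0, residual(m0) >= 0
    return brentq(residual, 0.0, m0, xtol=1e-300, rtol=1e-14)


def lambda_fraction(p1_tot: float, p2_tot: float, ka_eff_val: float) -> float:
    """Fraction of the maximum possible complexes formed at Ka_eff.

    Quadratic root of P1 + P2 <-> P1P2 with constant Ka_eff, divided by
    min(P1_0, P2_0); clamped to [0, 1] against floating-point drift.
    """
    lo = min(p1_tot, p2_tot)
    if lo == 0.0:
        return 0.0
    if ka_eff_val < 0:
        raise InvalidParameterError("Ka_eff must be non-negative")
    if math.isinf(ka_eff_val):
        return 1.0
    lam = _binding_quadratic(p1_tot, p2_tot, ka_eff_val) / lo
    return min(max(lam, 0.0), 1.0)


def enhancement_at(params: PairParameters, m_free: float, m2_free: float | None = None) -> float:
    """Ka_eff / Ka_PP evaluated at a given free-lipid concentration.

    Exact given the true [M]_eq.  With distinct lipid pools the two [M]
    values are subscripted per protein.
    """
    k1, k2, g = params.ka_p1m, params.ka_p2m, params.gamma
    m1 = m_free
    m2 = m_free if m2_free is None else m2_free
    num = g * k1 * k2 * m1 * m2 + k1 * m1 + k2 * m2 + 1.0
    den = (1.0 + k1 * m1) * (1.0 + k2 * m2)
    return num / den


@dataclass(frozen=True)
class MEqComponents:
    """Free-lipid interpolation pieces (volume units)."""

    m_eq: float
    m_eq_zero: float
    m_eq_coop: float
    lam: float
    converged: bool = True
    m2_eq: float | None = None  # second pool, distinct-lipids mode


def _m_eq_zero_distinct(params: PairParameters) -> tuple[float, float]:
    mz1 = m_eq_zero(params.m_tot_volume, params.p1_tot, params.ka_p1m)
    mz2 = m_eq_zero(params.m2_tot_volume, params.p2_tot, params.ka_p2m)
    return mz1, mz2


def _m_eq_coop_distinct(params: PairParameters) -> tuple[float, float]:
    """Cooperative limit with independent lipid pools (2D root finding)."""
    k1, k2, g = params.ka_p1m, params.ka_p2m, params.gamma
    m10, m20 = params.m_tot_volume, params.m2_tot_volume
    c_tot = min(params.p1_tot, params.p2_tot)
    e_tot = abs(params.p1_tot - params.p2_tot)
    p1_excess = params.p1_tot > params.p2_tot

    def residuals(m1: float, m2: float) -> tuple[float, float]:
        denom = 1.0 + k1 * m1 + k2 * m2 + g * k1 * k2 * m1 * m2
        b1 = c_tot * (k1 * m1 + g * k1 * k2 * m1 * m2) / denom
        b2 = c_tot * (k2 * m2 + g * k1 * k2 * m1 * m2) / denom
        if e_tot:
            if p1_excess:
                b1 += e_tot * k1 * m1 / (1.0 + k1 * m1)
            else:
                b2 += e_tot * k2 * m2 / (1.0 + k2 * m2)
        return m1 + b1 - m10, m2 + b2 - m20

    # alternate 1D monotone solves; each residual is increasing in its own m
    m1, m2 = m10, m20
    for _ in range(200):
        m1_new = brentq(lambda x: residuals(x, m2)[0], 0.0, m10, rtol=1e-14) if m10 else 0.0
        m2_new = brentq(lambda x: residuals(m1_new, x)[1], 0.0, m20, rtol=1e-14) if m20 else 0.0
        if abs(m1_new - m1) <= 1e-13 * max(m1_new, 1e-300) and abs(
            m2_new - m2
        ) <= 1e-13 * max(m2_new, 1e-300):
            m1, m2 = m1_new, m2_new
            break
        m1, m2 = m1_new, m2_new
    return m1, m2


def m_eq(
    params: PairParameters,
    self_consistent: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> MEqComponents:
    """Interpolated free-lipid concentration at equilibrium.

    [M]_eq = [M]_eq^0 (1 - lambda) + [M]_eq^Coop lambda, where lambda is
    evaluated from Ka_eff with [M]_eq^0 plugged into the exact enhancement
    relation (the single-pass definition used for all headline results).
    ``self_consistent=True`` feeds the resulting Ka_eff back into lambda
    until the interpolate converges to relative tolerance ``tol``.
    """
    if params.distinct_lipids:
        mz1, mz2 = _m_eq_zero_distinct(params)
        mc1, mc2 = _m_eq_coop_distinct(params)
        lam = (
            0.0
            if params.ka_pp == 0.0
            else lambda_fraction(
                params.p1_tot, params.p2_tot,
                params.ka_pp * enhancement_at(params, mz1, mz2),
            )
        )
        m1 = mz1 * (1 - lam) + mc1 * lam
        m2 = mz2 * (1 - lam) + mc2 * lam
        converged = True
        if self_consistent and params.ka_pp > 0.0:
            converged = False
            for _ in range(max_iter):
                lam_new = lambda_fraction(
                    params.p1_tot, params.p2_tot,
                    params.ka_pp * enhancement_at(params, m1, m2),
                )
                m1n = mz1 * (1 - lam_new) + mc1 * lam_new
                m2n = mz2 * (1 - lam_new) + mc2 * lam_new
                if abs(m1n - m1) <= tol * max(m1n, 1e-300) and abs(
                    m2n - m2
                ) <= tol * max(m2n, 1e-300):
                    m1, m2, lam = m1n, m2n, lam_new
                    converged = True
                    break
                m1, m2, lam = m1n, m2n, lam_new
        return MEqComponents(m1, mz1, mc1, lam, converged, m2_eq=m2)

    k1, k2 = params.ka_p1m, params.ka_p2m
    ka_av = ka_pm_weighted_average(k1, k2, params.p1_tot, params.p2_tot)
    mz = m_eq_zero(params.m_tot_volume, params.p1_tot + params.p2_tot, ka_av)
    # re-weight the average by the equilibrium (free) protein levels, which
    # is markedly more accurate than totals when the two affinities differ
    for _ in range(2):
        w1 = params.p1_tot / (1.0 + k1 * mz)
        w2 = params.p2_tot / (1.0 + k2 * mz)
        ka_av = ka_pm_weighted_average(k1, k2, w1, w2)
        mz = m_eq_zero(params.m_tot_volume, params.p1_tot + params.p2_tot, ka_av)
    if params.ka_pp == 0.0:
        return MEqComponents(mz, mz, m_eq_coop(params), 0.0)
    mc = m_eq_coop(params)
    lam = lambda_fraction(
        params.p1_tot, params.p2_tot, params.ka_pp * enhancement_at(params, mz)
    )
    m = mz * (1 - lam) + mc * lam
    converged = True
    if self_consistent:
        converged = False
        for _ in range(max_iter):
            lam_new = lambda_fraction(
                params.p1_tot, params.p2_tot,
                params.ka_pp * enhancement_at(params, m),
            )
            m_new = mz * (1 - lam_new) + mc * lam_new
            if abs(m_new - m) <= tol * max(m_new, 1e-300):
                m, lam = m_new, lam_new
                converged = True
                break
            m, lam = m_new, lam_new
    return MEqComponents(m, mz, mc, lam, converged)


@dataclass(frozen=True)
class TheoryResult:
    """Full analytical-theory output for one parameter set."""

    ka_eff: float            #: effective association constant, um^3
    enhancement: float       #: ka_eff / ka_pp (1.0 when ka_pp = 0)
    m_eq: float              #: free lipid, um^-3
    m_eq_zero: float
    m_eq_coop: float
    lam: float               #: interpolation fraction in [0, 1]
    complex_total: float     #: [P1P2]^(sol+mem), um^-3
    pct_complexation: float  #: 100 * complex_total / min(P1_0, P2_0)
    membrane_fraction: float | None  #: complexes on membrane / all complexes
    stickiness_1: float      #: Ka_P1M * [M]_eq
    stickiness_2: float
    gamma: float
    converged: bool = True
    m2_eq: float | None = None


def _membrane_fraction(params: PairParameters, m1: float, m2: float) -> float | None:
    k1, k2, g = params.ka_p1m, params.ka_p2m, params.gamma
    num = g * k1 * k2 * m1 * m2 + k1 * m1 + k2 * m2 + 1.0
    return (num - 1.0) / num


def ka_eff(
    params: PairParameters,
    self_consistent: bool = False,
) -> TheoryResult:
    """Evaluate the complete equilibrium theory for one parameter set.

    Computes [M]_eq (interpolation), Ka_eff (exact relation), the total
    complex concentration (binding quadratic at Ka_eff), percent
    complexation, the membrane fraction of complexes, and the membrane
    stickiness of each protein.
    """
    comp = m_eq(params, self_consistent=self_consistent)
    m1 = comp.m_eq
    m2 = comp.m2_eq if comp.m2_eq is not None else comp.m_eq
    if min(params.p1_tot, params.p2_tot) == 0.0 or params.ka_pp == 0.0:
        enh = enhancement_at(params, m1, m2) if params.ka_pp else 1.0
        ka = params.ka_pp * enh
        complex_total = 0.0
    else:
        enh = enhancement_at(params, m1, m2)
        ka = params.ka_pp * enh
        complex_total = _binding_quadratic(params.p1_tot, params.p2_tot, ka)
    lo = min(params.p1_tot, params.p2_tot)
    pct = 100.0 * complex_total / lo if lo > 0 else 0.0
    mem_frac = _membrane_fraction(params, m1, m2) if complex_total > 0 else None
    return TheoryResult(
        ka_eff=ka,
        enhancement=enh if params.ka_pp > 0 else 1.0,
        m_eq=m1,
        m_eq_zero=comp.m_eq_zero,
        m_eq_coop=comp.m_eq_coop,
        lam=comp.lam,
        complex_total=complex_total,
        pct_complexation=min(pct, 100.0),
        membrane_fraction=mem_frac,
        stickiness_1=params.ka_p1m * m1,
        stickiness_2=params.ka_p2m * m2,
        gamma=params.gamma,
        converged=comp.converged,
        m2_eq=comp.m2_eq,
    )


def membrane_fraction_of_complexes(
    params: PairParameters, theory: TheoryResult
) -> float | None:
    """Fraction of P1P2 complexes located on the membrane.

    From the pairwise equilibria at [M]_eq the complex species stand in the
    ratios 1 : K1 M : K2 M : gamma K1 K2 M^2 (solution, two singly lipid
    anchored, doubly anchored), so the membrane share is (num - 1)/num with
    num the numerator of the enhancement relation.  Returns None (flagged
    null) when no complexes form.
    """
    if theory.complex_total <= 0.0:
        return None
    m2 = theory.m2_eq if theory.m2_eq is not None else theory.m_eq
    return _membrane_fraction(params, theory.m_eq, m2)


def critical_lipid_concentration(
    params: PairParameters, epsilon: float = 0.01
) -> float | None:
    """Smallest total lipid at which Ka_eff reaches (1 - epsilon) gamma Ka_PP.

    The enhancement grows monotonically with the lipid pool toward the
    ceiling gamma; the threshold crossing is bracketed geometrically and
    refined by bisection.  Returns None (flagged null) if the target is
    unreachable (gamma <= 1, epsilon out of range is an error, or a protein
    that does not bind lipid).
    """
    if not 0.0 < epsilon <= 1.0:
        raise InvalidParameterError("epsilon must be in (0, 1]")
    if epsilon == 1.0:
        return 0.0
    g = params.gamma
    if g <= 1.0:
        return None
    if params.ka_p1m == 0.0 or params.ka_p2m == 0.0:
        return None
    target = (1.0 - epsilon) * g

    def enh_at_m0(m0: float) -> float:
        return ka_eff(params.with_(m_tot=m0, m_tot_per_area=None)).enhancement

    hi = max(params.p1_tot + params.p2_tot, 1.0 / max(params.ka_p1m, params.ka_p2m))
    for _ in range(200):
        if enh_at_m0(hi) >= target:
            break
        hi *= 2.0
    else:
        return None
    return brentq(lambda m0: enh_at_m0(m0) - target, 0.0, hi, rtol=1e-12)


@dataclass(frozen=True)
class FitResult:
    sigma: float        #: um
    gamma: float
    ka_2d_pp: float | None  #: um^2; None if ka_pp not supplied


def fit_ka2d_from_enhancement(
    measured_enhancement: float,
    geometry,
    ka_pp: float | None = None,
    stickiness: tuple[float, float] | None = None,
) -> FitResult:
    """Extract sigma and the 2D protein-protein constant from a measured
    enhancement.

    In the saturated (full-membrane) regime the enhancement equals gamma, so
    sigma = V / (2 A * enhancement).  If the membrane stickiness values
    (K1 M, K2 M) are known, the exact relation is inverted for gamma
    instead.  Requires measured_enhancement > 1; an enhancement at or below
    the no-membrane floor is inconsistent with the model and raises
    :class:`FitError`.
    """
    if not measured_enhancement > 1.0:
        raise FitError(
            f"measured enhancement must exceed 1 (got {measured_enhancement}); "
            "values <= 1 carry no membrane-localization signal to invert"
        )
    if stickiness is None:
        g = measured_enhancement
    else:
        x1, x2 = stickiness
        if x1 <= 0 or x2 <= 0:
            raise FitError("stickiness values must be positive")
        g = (
            measured_enhancement * (1.0 + x1) * (1.0 + x2) - (1.0 + x1 + x2)
        ) / (x1 * x2)
        floor = (1.0 + x1 + x2) / ((1.0 + x1) * (1.0 + x2))
        if g <= 0.0:
            raise FitError(
                f"enhancement {measured_enhancement} is below the sticky-limit "
                f"floor {floor:.4g} for stickiness ({x1}, {x2})"
            )
    sigma = geometry.V / (2.0 * geometry.A * g)
    ka2d = None if ka_pp is None else ka_pp / (2.0 * sigma)
    return FitResult(sigma=sigma, gamma=g, ka_2d_pp=ka2d)
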