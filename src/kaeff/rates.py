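"""Intrinsic vs. macroscopic rate constants in 3D and 2D.

Smoluchowski-type relations connect the intrinsic (contact-reactivity)
rates k_a, k_b to the macroscopic (observable) rates k_on, k_off:

    k_on^3D = (1/k_a^3D + 1/(4 pi sigma D_tot^3D))^-1
    k_off   = k_on / K_a                          (every dimension)
    k_a^2D  = k_a^3D / (2 sigma),   k_b^2D = k_b^3D

In 2D there is no system-size-independent macroscopic rate; the standard
steady-state construction uses a screening length b set by the density of
the more abundant reactant.  All conversions preserve the equilibrium
constants exactly, so equilibria of downstream simulations are independent
of the kinetic parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import PairParameters
from .units import InvalidParameterError

__all__ = [
    "RateSet",
    "kon3d_macroscopic",
    "ka3d_intrinsic_from_kon",
    "koff_from_kon",
    "b_screening_length",
    "kon2d_macroscopic",
    "ka2d_intrinsic",
    "kb2d_intrinsic",
    "build_rate_set",
    "PAIR_REACTION_LABELS",
]

#: default per-species diffusion constants, um^2/s
D3D_DEFAULT = 50.0
D2D_DEFAULT = 0.5


def kon3d_macroscopic(ka_3d: float, sigma: float, d_tot_3d: float) -> float:
    """Macroscopic 3D on-rate: harmonic mean of intrinsic and diffusion-limited.

    k_on saturates at the Smoluchowski limit 4 pi sigma D_tot for large
    intrinsic reactivity and reduces to k_a in the reaction-limited regime.
    """
    if sigma <= 0 or d_tot_3d <= 0:
        raise InvalidParameterError("sigma and D must be positive")
    if ka_3d < 0:
        raise InvalidParameterError("ka must be non-negative")
    if ka_3d == 0.0:
        return 0.0
    k_diff = 4.0 * math.pi * sigma * d_tot_3d
    if math.isinf(ka_3d):
        return k_diff
    return 1.0 / (1.0 / ka_3d + 1.0 / k_diff)


def ka3d_intrinsic_from_kon(kon_3d: float, sigma: float, d_tot_3d: float) -> float:
    """Invert :func:`kon3d_macroscopic`; k_on at the diffusion limit maps to
    infinite intrinsic reactivity."""
    if kon_3d == 0.0:
        return 0.0
    k_diff = 4.0 * math.pi * sigma * d_tot_3d
    if kon_3d >= k_diff:
        return math.inf
    return 1.0 / (1.0 / kon_3d - 1.0 / k_diff)


def koff_from_kon(kon: float, ka: float) -> float:
    """Macroscopic off-rate k_off = k_on / K_a (s^-1 in every dimension)."""
    if ka <= 0:
        raise InvalidParameterError("Ka must be positive (no bound state otherwise)")
    return kon / ka


def b_screening_length(
    area: float, n_p1: float, n_p2: float, sigma: float
) -> float | None:
    """2D screening length b = sqrt(2A / (pi max(N)) + sigma^2).

    Set by the surface density of the more abundant reactant; always exceeds
    the binding radius sigma and approaches it from above as the surface
    crowds.  Returns None (flagged null) with zero copies, in which case the
    macroscopic 2D rate defaults to the intrinsic one.
    """
    if area <= 0:
        raise InvalidParameterError("area must be positive")
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    n = max(n_p1, n_p2)
    if n < 1:
        return None
    return math.sqrt(2.0 * area / (math.pi * n) + sigma * sigma)


def kon2d_macroscopic(
    ka_2d: float, sigma: float, d_tot_2d: float, b: float | None
) -> float:
    """Macroscopic 2D on-rate from the steady-state pair theory.

    The diffusive resistance term is

        (1/(8 pi D_tot^2D)) * [4 ln(b/sigma)/(1 - sigma^2/b^2)^2
                               - 2/(1 - sigma^2/b^2) - 1]

    whose bracket vanishes as b -> sigma+ (crowded limit, k_on -> k_a) and
    as D -> infinity.  ``b=None`` (no surface copies) returns the intrinsic
    rate.
    """
    if ka_2d < 0:
        raise InvalidParameterError("ka must be non-negative")
    if ka_2d == 0.0:
        return 0.0
    if b is None:
        return ka_2d
    if b <= sigma:
        raise InvalidParameterError(f"b ({b}) must exceed sigma ({sigma})")
    if d_tot_2d <= 0:
        raise InvalidParameterError("D must be positive")
    q = (b * b - sigma * sigma) / (b * b)
    if q < 1e-3:
        # series of the bracket in q = 1 - sigma^2/b^2; the closed form
        # cancels catastrophically as b -> sigma+
        bracket = q * (2.0 / 3.0 + q * (0.5 + 0.4 * q))
    else:
        bracket = 4.0 * math.log(b / sigma) / (q * q) - 2.0 / q - 1.0
    resistance = bracket / (8.0 * math.pi * d_tot_2d)
    if math.isinf(ka_2d):
        return 1.0 / resistance if resistance > 0 else math.inf
    return 1.0 / (1.0 / ka_2d + resistance)


def ka2d_intrinsic(ka_3d: float, sigma: float) -> float:
    """Intrinsic 2D association rate k_a^2D = k_a^3D / (2 sigma), um^2/s."""
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    return ka_3d / (2.0 * sigma)


def kb2d_intrinsic(kb_3d: float) -> float:
    """Intrinsic dissociation is dimension-independent: k_b^2D = k_b^3D."""
    return kb_3d


@dataclass(frozen=True)
class RateSet:
    """Complete kinetic parameterization of one reversible reaction."""

    label: str
    ka_eq_3d: float          #: 3D equilibrium constant, um^3
    kon_3d: float            #: um^3/s
    koff_3d: float           #: s^-1
    ka_intrinsic_3d: float   #: um^3/s (inf at the diffusion limit)
    kb_intrinsic_3d: float   #: s^-1
    is_2d: bool = False
    ka_eq_2d: float | None = None   #: um^2
    kon_2d: float | None = None     #: um^2/s
    koff_2d: float | None = None    #: s^-1
    ka_intrinsic_2d: float | None = None
    b: float | None = None
    sigma: float | None = None
    capped: bool = False     #: True if kon was clipped at the diffusion limit


PAIR_REACTION_LABELS = (
    "P1+P2->P1P2",       # 5.1  Ka_PP
    "M+P1->MP1",         # 5.2  Ka_P1M
    "M+P2->P2M",         # 5.3  Ka_P2M
    "M+P1P2->MP1P2",     # 5.4  Ka_P1M
    "P1P2+M->P1P2M",     # 5.5  Ka_P2M
    "MP1+P2->MP1P2",     # 5.6  Ka_PP
    "P1+P2M->P1P2M",     # 5.7  Ka_PP
    "MP1+P2M->MP1P2M",   # 5.8  Ka_PP/(2 sigma)   2D
    "M+P1P2M->MP1P2M",   # 5.9  Ka_P1M/(2 sigma)  2D
    "MP1P2+M->MP1P2M",   # 5.10 Ka_P2M/(2 sigma)  2D
)


def _one_rate_set(
    label: str,
    ka_eq: float,
    sigma: float,
    koff_default: float,
    d3_tot: float,
    d2_tot: float,
    is_2d: bool,
    n_surface: float,
    area: float,
    kon2d_mode: str,
) -> RateSet:
    """Kinetics for a single reaction at fixed equilibrium constant."""
    if ka_eq == 0.0:
        return RateSet(label, 0.0, 0.0, koff_default, 0.0, koff_default,
                       is_2d=is_2d, sigma=sigma)
    kon = koff_default * ka_eq
    koff = koff_default
    capped = False
    k_diff = 4.0 * math.pi * sigma * d3_tot
    if kon >= k_diff:
        kon = k_diff
        koff = kon / ka_eq  # preserve Ka exactly
        capped = True
    ka_i3 = ka3d_intrinsic_from_kon(kon, sigma, d3_tot)
    kb_i3 = ka_i3 / ka_eq if math.isfinite(ka_i3) else math.inf
    out = dict(
        label=label, ka_eq_3d=ka_eq, kon_3d=kon, koff_3d=koff,
        ka_intrinsic_3d=ka_i3, kb_intrinsic_3d=kb_i3,
        is_2d=is_2d, sigma=sigma, capped=capped,
    )
    if is_2d:
        ka_eq_2d = ka_eq / (2.0 * sigma)
        if kon2d_mode == "equilibrium":
            kon2 = kon / (2.0 * sigma)
            b = None
        elif kon2d_mode == "smoluchowski":
            ka_i2 = ka2d_intrinsic(ka_i3, sigma)
            b = b_screening_length(area, n_surface, n_surface, sigma)
            kon2 = kon2d_macroscopic(ka_i2, sigma, d2_tot, b)
            out["ka_intrinsic_2d"] = ka_i2
        else:
            raise InvalidParameterError(f"unknown kon2d_mode {kon2d_mode!r}")
        out.update(
            ka_eq_2d=ka_eq_2d,
            kon_2d=kon2,
            koff_2d=kon2 / ka_eq_2d,
            b=b,
        )
    return RateSet(**out)


def build_rate_set(
    params: PairParameters,
    koff_default: float = 1.0,
    d3: float = D3D_DEFAULT,
    d2: float = D2D_DEFAULT,
    kon2d_mode: str = "equilibrium",
) -> dict[str, RateSet]:
    """Kinetic parameterization for all ten pair-model reactions.

    Each reaction gets k_off = ``koff_default`` and k_on = k_off * K_a,
    clipped at the diffusion limit 4 pi sigma D_tot (in which case k_off is
    rescaled so the equilibrium constant is preserved exactly).  Intrinsic
    rates follow by inverting the Smoluchowski relation.  2D on-rates use
    either the shortcut k_on^2D = k_on^3D/(2 sigma) (``"equilibrium"``, the
    default used for equilibrium measurements) or the screened pair theory
    (``"smoluchowski"``) with surface copy numbers estimated from the totals.

    ``d3``/``d2`` are per-species diffusion constants; D_tot sums the two
    reactants.
    """
    if koff_default <= 0:
        raise InvalidParameterError("koff_default must be positive")
    g = params.gamma
    sigma = params.sigma_pp
    d3_tot, d2_tot = 2.0 * d3, 2.0 * d2
    area = params.geometry.A
    n1 = params.p1_tot * params.geometry.V
    n2 = params.p2_tot * params.geometry.V
    # volume-unit equilibrium constants; 2D reactions carry the V/A factor
    # through gamma when propagated to volume units by the network builder
    kas = {
        "P1+P2->P1P2": (params.ka_pp, False),
        "M+P1->MP1": (params.ka_p1m, False),
        "M+P2->P2M": (params.ka_p2m, False),
        "M+P1P2->MP1P2": (params.ka_p1m, False),
        "P1P2+M->P1P2M": (params.ka_p2m, False),
        "MP1+P2->MP1P2": (params.ka_pp, False),
        "P1+P2M->P1P2M": (params.ka_pp, False),
        "MP1+P2M->MP1P2M": (params.ka_pp, True),
        "M+P1P2M->MP1P2M": (params.ka_p1m, True),
        "MP1P2+M->MP1P2M": (params.ka_p2m, True),
    }
    assert set(kas) == set(PAIR_REACTION_LABELS) and g > 0
    return {
        label: _one_rate_set(
            label, ka, sigma, koff_default, d3_tot, d2_tot, is_2d,
            max(n1, n2), area, kon2d_mode,
        )
        for label, (ka, is_2d) in kas.items()
    }
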