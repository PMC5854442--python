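"""Geometry, the pair-model parameter container, and config I/O.

The pair model describes two soluble proteins P1 and P2 that bind each other
in solution (Ka_PP) and each bind a membrane lipid M (Ka_P1M, Ka_P2M).  On
the membrane the same interactions proceed in 2D with constants reduced by
the length scale sigma: Ka_2D = Ka_3D / (2 sigma).  The dimensionless
gamma = V / (2 A sigma) is the ceiling on the binding enhancement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import yaml

from .units import (
    InvalidParameterError,
    ka_molar_to_um3,
    molar_to_per_um3,
    nm_to_um,
)

__all__ = [
    "Geometry",
    "PairParameters",
    "gamma",
    "ka2d_from_3d",
    "ka3d_from_2d",
    "to_volume_density",
    "to_surface_density",
    "load_pair_config",
]


@dataclass(frozen=True)
class Geometry:
    """Solution volume and membrane surface area.

    Only the ratio V/A enters equilibrium results; the absolute sizes matter
    for kinetics and for converting concentrations to copy numbers.
    """

    V: float  #: solution volume, um^3
    A: float  #: membrane surface area, um^2

    def __post_init__(self) -> None:
        if not (self.V > 0 and self.A > 0):
            raise InvalidParameterError(
                f"V and A must be positive, got V={self.V}, A={self.A}"
            )

    @property
    def v_over_a(self) -> float:
        """Volume-to-surface-area ratio, um."""
        return self.V / self.A


def gamma(geometry: Geometry, sigma_pp: float) -> float:
    """Dimensionless gamma = V / (2 A sigma).

    gamma is the maximum achievable enhancement Ka_eff/Ka_PP, reached when
    all proteins are membrane-bound.  gamma < 1 (V/A < 2 sigma) means
    localization reduces complexation.

    Parameters
    ----------
    geometry : Geometry
    sigma_pp : float
        Length scale relating the 3D and 2D protein-protein constants, um.
    """
    if not sigma_pp > 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma_pp}")
    return geometry.V / (2.0 * geometry.A * sigma_pp)


def ka2d_from_3d(ka_3d: float, sigma: float) -> float:
    """2D association constant (um^2) from a 3D one (um^3): Ka_3D / (2 sigma)."""
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    if ka_3d < 0:
        raise InvalidParameterError(f"Ka must be non-negative, got {ka_3d}")
    return ka_3d / (2.0 * sigma)


def ka3d_from_2d(ka_2d: float, sigma: float) -> float:
    """Inverse of :func:`ka2d_from_3d`."""
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    return ka_2d * 2.0 * sigma


def to_volume_density(d_per_um2: float, geometry: Geometry) -> float:
    """Convert a surface density (um^-2) to an equivalent volume density.

    A species confined to the membrane at d copies/um^2 corresponds to
    d * A / V copies/um^3 when all species are book-kept in volume units.
    """
    if d_per_um2 < 0:
        raise InvalidParameterError(f"density must be non-negative, got {d_per_um2}")
    return d_per_um2 * geometry.A / geometry.V


def to_surface_density(d_per_um3: float, geometry: Geometry) -> float:
    """Inverse of :func:`to_volume_density`."""
    if d_per_um3 < 0:
        raise InvalidParameterError(f"density must be non-negative, got {d_per_um3}")
    return d_per_um3 * geometry.V / geometry.A


@dataclass(frozen=True)
class PairParameters:
    """All thermodynamic inputs of the two-protein / one-lipid model.

    Everything is in canonical internal units (um^3 association constants,
    um^-3 concentrations, um lengths).  Use :meth:`from_molar` or
    :func:`load_pair_config` for molar/nm inputs.  The total lipid pool must
    be given with an explicit unit tag: pass exactly one of ``m_tot``
    (volume units, um^-3) or ``m_tot_per_area`` (um^-2); holding the lipid
    pool fixed per-area versus per-volume changes how results depend on V/A.

    By default a single shared lipid pool serves both proteins; with
    ``distinct_lipids=True`` each protein targets its own pool and a second
    total (``m2_tot``/``m2_tot_per_area``) may be supplied (defaults to the
    first).
    """

    ka_pp: float        #: protein-protein 3D association constant, um^3
    ka_p1m: float       #: P1-lipid 3D association constant, um^3
    ka_p2m: float       #: P2-lipid 3D association constant, um^3
    p1_tot: float       #: total P1, um^-3
    p2_tot: float       #: total P2, um^-3
    geometry: Geometry
    sigma_pp: float = nm_to_um(1.0)   #: um
    sigma_p1m: float | None = None    #: defaults to sigma_pp
    sigma_p2m: float | None = None
    m_tot: float | None = None            #: total lipid, um^-3
    m_tot_per_area: float | None = None   #: total lipid, um^-2
    distinct_lipids: bool = False
    m2_tot: float | None = None
    m2_tot_per_area: float | None = None
    allow_unequal_sigma: bool = False

    def __post_init__(self) -> None:
        for name in ("ka_pp", "ka_p1m", "ka_p2m", "p1_tot", "p2_tot"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if not self.sigma_pp > 0:
            raise InvalidParameterError("sigma_pp must be positive")
        if (self.m_tot is None) == (self.m_tot_per_area is None):
            raise InvalidParameterError(
                "exactly one of m_tot (um^-3) or m_tot_per_area (um^-2) "
                "must be given; the lipid pool needs an explicit unit tag"
            )
        tagged = self.m_tot if self.m_tot is not None else self.m_tot_per_area
        if tagged < 0:
            raise InvalidParameterError("lipid total must be non-negative")
        # default the lipid sigmas to sigma_pp (detailed balance requires
        # equal sigma across the three interactions)
        object.__setattr__(
            self, "sigma_p1m",
            self.sigma_p1m if self.sigma_p1m is not None else self.sigma_pp)
        object.__setattr__(
            self, "sigma_p2m",
            self.sigma_p2m if self.sigma_p2m is not None else self.sigma_pp)
        if not (self.sigma_p1m > 0 and self.sigma_p2m > 0):
            raise InvalidParameterError("sigma values must be positive")
        if not self.equal_sigmas:
            if not self.allow_unequal_sigma:
                raise InvalidParameterError(
                    "unequal sigma values break detailed balance; pass "
                    "allow_unequal_sigma=True to override"
                )
            warnings.warn(
                "unequal sigma values: the reaction network has no true "
                "equilibrium steady state (detailed balance violated)",
                stacklevel=2,
            )

    @property
    def equal_sigmas(self) -> bool:
        return math.isclose(self.sigma_pp, self.sigma_p1m) and math.isclose(
            self.sigma_pp, self.sigma_p2m
        )

    @property
    def gamma(self) -> float:
        return gamma(self.geometry, self.sigma_pp)

    @property
    def m_tot_volume(self) -> float:
        """Total lipid of pool 1 in volume units (um^-3)."""
        if self.m_tot is not None:
            return self.m_tot
        return to_volume_density(self.m_tot_per_area, self.geometry)

    @property
    def m2_tot_volume(self) -> float:
        """Total lipid of pool 2 in volume units; equals pool 1 unless set."""
        if self.m2_tot is not None:
            return self.m2_tot
        if self.m2_tot_per_area is not None:
            return to_volume_density(self.m2_tot_per_area, self.geometry)
        return self.m_tot_volume

    def with_(self, **changes) -> "PairParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    @classmethod
    def from_molar(
        cls,
        ka_pp_per_molar: float,
        ka_p1m_per_molar: float,
        ka_p2m_per_molar: float,
        p1_tot_molar: float,
        p2_tot_molar: float,
        geometry: Geometry,
        sigma_nm: float = 1.0,
        m_tot_molar: float | None = None,
        m_tot_per_um2: float | None = None,
        **kwargs,
    ) -> "PairParameters":
        """Build from molar constants/concentrations and sigma in nm."""
        return cls(
            ka_pp=ka_molar_to_um3(ka_pp_per_molar),
            ka_p1m=ka_molar_to_um3(ka_p1m_per_molar),
            ka_p2m=ka_molar_to_um3(ka_p2m_per_molar),
            p1_tot=molar_to_per_um3(p1_tot_molar),
            p2_tot=molar_to_per_um3(p2_tot_molar),
            geometry=geometry,
            sigma_pp=nm_to_um(sigma_nm),
            m_tot=None if m_tot_molar is None else molar_to_per_um3(m_tot_molar),
            m_tot_per_area=m_tot_per_um2,
            **kwargs,
        )


_CONFIG_KEYS = {
    "Ka_PP", "Ka_P1M", "Ka_P2M", "sigma_nm", "P1_0", "P2_0", "M_0",
    "V_um3", "A_um2",
}
_KA_UNITS = {"1/M": ka_molar_to_um3, "um3": lambda x: x}
_CONC_UNITS = {"M": molar_to_per_um3, "um-3": lambda x: x}


def _tagged(entry, units: dict, key: str) -> float:
    if not isinstance(entry, dict) or set(entry) != {"value", "unit"}:
        raise InvalidParameterError(
            f"config key {key!r} must be a mapping with 'value' and 'unit'"
        )
    unit = entry["unit"]
    if unit not in units:
        raise InvalidParameterError(
            f"config key {key!r}: unknown unit {unit!r}; allowed: {sorted(units)}"
        )
    return units[unit](float(entry["value"]))


def load_pair_config(source) -> PairParameters:
    """Parse a YAML/JSON pair-model config (path, file object, or dict).

    Required keys: Ka_PP, Ka_P1M, Ka_P2M (value + unit "1/M" or "um3"),
    sigma_nm, P1_0, P2_0 (value + unit "M" or "um-3"), M_0 (value + unit
    "um-2" or "M"), V_um3, A_um2.  Unknown keys are rejected.
    """
    if isinstance(source, dict):
        cfg = dict(source)
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidParameterError("config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    missing = _CONFIG_KEYS - set(cfg)
    if missing:
        raise InvalidParameterError(f"missing config keys: {sorted(missing)}")

    geometry = Geometry(V=float(cfg["V_um3"]), A=float(cfg["A_um2"]))
    m_entry = cfg["M_0"]
    m_units = {"M": molar_to_per_um3, "um-2": lambda x: x}
    m_value = _tagged(m_entry, m_units, "M_0")
    per_area = m_entry["unit"] == "um-2"
    return PairParameters(
        ka_pp=_tagged(cfg["Ka_PP"], _KA_UNITS, "Ka_PP"),
        ka_p1m=_tagged(cfg["Ka_P1M"], _KA_UNITS, "Ka_P1M"),
        ka_p2m=_tagged(cfg["Ka_P2M"], _KA_UNITS, "Ka_P2M"),
        p1_tot=_tagged(cfg["P1_0"], _CONC_UNITS, "P1_0"),
        p2_tot=_tagged(cfg["P2_0"], _CONC_UNITS, "P2_0"),
        geometry=geometry,
        sigma_pp=nm_to_um(float(cfg["sigma_nm"])),
        m_tot=None if per_area else m_value,
        m_tot_per_area=m_value if per_area else None,
    )
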