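"""Deterministic mass-action reaction networks and their equilibria.

Two models are built here:

* the 9-species / 10-reaction pair network (P1, P2, lipid M and all their
  complexes), the exact counterpart of the analytical theory; and
* the 14-species scaffold network (P3, P4, scaffold S, lipid M) in which a
  non-lipid-binding scaffold bridges two peripheral membrane proteins.

All species are book-kept in volume units; a 2D reaction's equilibrium
constant carries the gamma = V/(2 A sigma) factor when expressed in volume
units.  Detailed balance (cycle products of equilibrium constants equal 1)
is asserted at build time by checking that every species has a
path-independent formation constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .parameters import PairParameters, Geometry
from .rates import RateSet, build_rate_set
from .units import InvalidParameterError, ka_molar_to_um3, molar_to_per_um3, nm_to_um

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "NetworkState",
    "TimeSeries",
    "DetailedBalanceError",
    "build_pair_network",
    "simulate",
    "solve_equilibrium",
    "ka_eff_from_state",
    "equilibration_time",
    "ScaffoldParameters",
    "build_scaffold_network",
    "ScaffoldMetrics",
    "scaffold_metrics",
    "PAIR_SPECIES",
]


class DetailedBalanceError(ValueError):
    """The reaction network admits no equilibrium steady state."""


@dataclass(frozen=True)
class Species:
    name: str
    compartment: str                 #: "solution" | "membrane"
    composition: dict[str, int]      #: counts of basis units (P1, P2, M, ...)


@dataclass(frozen=True)
class Reaction:
    label: str
    reactants: tuple[int, int]
    product: int
    kon: float      #: volume-units association rate, um^3/s
    koff: float     #: s^-1
    ka_vol: float   #: volume-units equilibrium constant, um^3
    dim: str        #: "3D" | "2D"


@dataclass
class ReactionNetwork:
    """Species, reactions and conservation totals of one mass-action model."""

    species: list[Species]
    reactions: list[Reaction]
    basis: tuple[str, ...]
    totals: dict[str, float]    #: conserved totals in volume units
    geometry: Geometry
    formation_log: np.ndarray = field(default=None)  # ln formation constants

    def __post_init__(self) -> None:
        self.index = {s.name: i for i, s in enumerate(self.species)}
        self.formation_log = self._check_detailed_balance()

    # -- detailed balance ------------------------------------------------
    def _check_detailed_balance(self, tol: float = 1e-9) -> np.ndarray:
        """Assign ln formation constants; any path inconsistency means a
        cycle of equilibrium constants whose product differs from 1."""
        n = len(self.species)
        lnf = np.full(n, np.nan)
        for name in self.basis:
            lnf[self.index[name]] = 0.0
        pending = list(self.reactions)
        for _ in range(n + 1):
            if not pending:
                break
            rest = []
            for rx in pending:
                i, j = rx.reactants
                k = rx.product
                if np.isnan(lnf[i]) or np.isnan(lnf[j]):
                    rest.append(rx)
                    continue
                lnk = math.log(rx.ka_vol) if rx.ka_vol > 0 else -math.inf
                val = lnf[i] + lnf[j] + lnk
                if np.isnan(lnf[k]):
                    lnf[k] = val
                else:
                    a, b = lnf[k], val
                    if a == b:  # covers -inf == -inf
                        continue
                    if abs(a - b) > tol * max(1.0, abs(a), abs(b)):
                        raise DetailedBalanceError(
                            f"species {self.species[k].name}: formation "
                            f"constant differs between paths ({a} vs {b} in "
                            f"log units) — a reaction cycle violates "
                            f"detailed balance"
                        )
            pending = rest
        if any(np.isnan(lnf)):
            raise DetailedBalanceError("species unreachable from the basis")
        return lnf

    def conservation_matrix(self) -> np.ndarray:
        """(n_basis, n_species) matrix of basis-unit counts per species."""
        return np.array(
            [[s.composition.get(b, 0) for s in self.species] for b in self.basis],
            dtype=float,
        )

    def initial_concentrations(self) -> np.ndarray:
        """Default start: all basis units free and unbound."""
        c0 = np.zeros(len(self.species))
        for b in self.basis:
            c0[self.index[b]] = self.totals[b]
        return c0


@dataclass
class NetworkState:
    """Concentrations of every species at one time point (volume units)."""

    network: ReactionNetwork
    concentrations: np.ndarray
    time: float = math.inf

    def __getitem__(self, name: str) -> float:
        return float(self.concentrations[self.network.index[name]])

    def conservation_error(self) -> float:
        """Max relative drift of the conserved totals."""
        cm = self.network.conservation_matrix()
        now = cm @ self.concentrations
        ref = np.array([self.network.totals[b] for b in self.network.basis])
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(now - ref) / np.where(ref > 0, ref, 1.0)
        return float(np.max(rel))

    def species_total(self, unit: str, compartment: str | None = None) -> float:
        """Summed concentration of all species containing a basis unit."""
        tot = 0.0
        for s, c in zip(self.network.species, self.concentrations):
            if s.composition.get(unit, 0) == 0:
                continue
            if compartment is not None and s.compartment != compartment:
                continue
            tot += s.composition[unit] * c if unit == "M" else c
        return tot

    def complex_total(self, unit_a: str = "P1", unit_b: str = "P2") -> float:
        """Species containing both protein units (bound complexes)."""
        return float(
            sum(
                c
                for s, c in zip(self.network.species, self.concentrations)
                if s.composition.get(unit_a, 0) and s.composition.get(unit_b, 0)
            )
        )


@dataclass
class TimeSeries:
    network: ReactionNetwork
    times: np.ndarray
    concentrations: np.ndarray  #: shape (n_times, n_species)

    def state(self, i: int = -1) -> NetworkState:
        return NetworkState(self.network, self.concentrations[i], self.times[i])

    def observable(self, fn) -> np.ndarray:
        return np.array([fn(self.state(i)) for i in range(len(self.times))])

    def complex_series(self, unit_a: str = "P1", unit_b: str = "P2") -> np.ndarray:
        return self.observable(lambda st: st.complex_total(unit_a, unit_b))


# ---------------------------------------------------------------------------
# pair network
# ---------------------------------------------------------------------------

PAIR_SPECIES = (
    ("P1", "solution", {"P1": 1}),
    ("P2", "solution", {"P2": 1}),
    ("M", "membrane", {"M": 1}),
    ("P1P2", "solution", {"P1": 1, "P2": 1}),
    ("MP1", "membrane", {"P1": 1, "M": 1}),
    ("P2M", "membrane", {"P2": 1, "M": 1}),
    ("MP1P2", "membrane", {"P1": 1, "P2": 1, "M": 1}),
    ("P1P2M", "membrane", {"P1": 1, "P2": 1, "M": 1}),
    ("MP1P2M", "membrane", {"P1": 1, "P2": 1, "M": 2}),
)

_PAIR_REACTIONS = (
    # label, A, B, product, base-constant key, 2D?
    ("P1+P2->P1P2", "P1", "P2", "P1P2", "PP", False),
    ("M+P1->MP1", "M", "P1", "MP1", "P1M", False),
    ("M+P2->P2M", "M", "P2", "P2M", "P2M", False),
    ("M+P1P2->MP1P2", "M", "P1P2", "MP1P2", "P1M", False),
    ("P1P2+M->P1P2M", "P1P2", "M", "P1P2M", "P2M", False),
    ("MP1+P2->MP1P2", "MP1", "P2", "MP1P2", "PP", False),
    ("P1+P2M->P1P2M", "P1", "P2M", "P1P2M", "PP", False),
    ("MP1+P2M->MP1P2M", "MP1", "P2M", "MP1P2M", "PP", True),
    ("M+P1P2M->MP1P2M", "M", "P1P2M", "MP1P2M", "P1M", True),
    ("MP1P2+M->MP1P2M", "MP1P2", "M", "MP1P2M", "P2M", True),
)


def build_pair_network(
    params: PairParameters,
    rates: dict[str, RateSet] | None = None,
    koff_default: float = 1.0,
    kon2d_mode: str = "equilibrium",
) -> ReactionNetwork:
    """The 9-species / 10-reaction pair model in volume units.

    The three 2D reactions use the sigma-reduced constants multiplied by
    V/A, i.e. gamma * Ka_3D in volume units.  Unequal sigma values (allowed
    only with the PairParameters override) break detailed balance and raise
    at build time.
    """
    if params.distinct_lipids:
        raise InvalidParameterError(
            "the ODE pair network models a single shared lipid pool"
        )
    if rates is None:
        rates = build_rate_set(params, koff_default=koff_default,
                               kon2d_mode=kon2d_mode)
    species = [Species(*s) for s in PAIR_SPECIES]
    idx = {s.name: i for i, s in enumerate(species)}
    v_over_a = params.geometry.v_over_a
    sigma_of = {"PP": params.sigma_pp, "P1M": params.sigma_p1m,
                "P2M": params.sigma_p2m}
    reactions = []
    for label, a, b, prod, key, is_2d in _PAIR_REACTIONS:
        rs = rates[label]
        if is_2d:
            # per-interaction sigma enters here; unequal sigmas yield
            # inconsistent formation constants caught by the balance check
            ka_vol = rs.ka_eq_3d / (2.0 * sigma_of[key]) * v_over_a
            kon2 = rs.kon_2d if rs.kon_2d is not None else 0.0
            kon_vol = kon2 * v_over_a * (params.sigma_pp / sigma_of[key])
            koff = kon_vol / ka_vol if ka_vol > 0 else rs.koff_3d
            dim = "2D"
        else:
            ka_vol, kon_vol, koff, dim = rs.ka_eq_3d, rs.kon_3d, rs.koff_3d, "3D"
        reactions.append(
            Reaction(label, (idx[a], idx[b]), idx[prod], kon_vol, koff,
                     ka_vol, dim)
        )
    assert len(species) == 9 and len(reactions) == 10
    totals = {"P1": params.p1_tot, "P2": params.p2_tot, "M": params.m_tot_volume}
    return ReactionNetwork(species, reactions, ("P1", "P2", "M"), totals,
                           params.geometry)


# ---------------------------------------------------------------------------
# integration and equilibrium
# ---------------------------------------------------------------------------


def _rhs_factory(network: ReactionNetwork):
    n = len(network.species)
    ra = np.array([rx.reactants[0] for rx in network.reactions])
    rb = np.array([rx.reactants[1] for rx in network.reactions])
    pr = np.array([rx.product for rx in network.reactions])
    kon = np.array([rx.kon for rx in network.reactions])
    koff = np.array([rx.koff for rx in network.reactions])

    def rhs(_t, c):
        flux = kon * c[ra] * c[rb] - koff * c[pr]
        dc = np.zeros(n)
        np.add.at(dc, ra, -flux)
        np.add.at(dc, rb, -flux)
        np.add.at(dc, pr, flux)
        return dc

    def jac(_t, c):
        J = np.zeros((n, n))
        for m in range(len(kon)):
            i, j, k = ra[m], rb[m], pr[m]
            dfi, dfj, dfk = kon[m] * c[j], kon[m] * c[i], -koff[m]
            for tgt, sgn in ((i, -1), (j, -1), (k, +1)):
                J[tgt, i] += sgn * dfi
                J[tgt, j] += sgn * dfj
                J[tgt, k] += sgn * dfk
        return J

    return rhs, jac


def simulate(
    network: ReactionNetwork,
    t_end: float,
    init: np.ndarray | None = None,
    n_points: int = 300,
    rtol: float = 1e-10,
) -> TimeSeries:
    """Integrate the mass-action ODEs with a stiff-capable solver.

    Default initial condition: all proteins and lipids unbound, proteins in
    solution.  Output times are log-spaced (plus t=0).
    """
    c0 = network.initial_concentrations() if init is None else np.asarray(init, float)
    rhs, jac = _rhs_factory(network)
    scale = max(max(network.totals.values()), 1.0)
    t_eval = np.concatenate([[0.0], np.geomspace(max(t_end * 1e-8, 1e-12), t_end, n_points - 1)])
    sol = solve_ivp(
        rhs, (0.0, t_end), c0, method="LSODA", jac=jac, t_eval=t_eval,
        rtol=rtol, atol=scale * 1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return TimeSeries(network, sol.t, sol.y.T)


def solve_equilibrium(network: ReactionNetwork) -> NetworkState:
    """Algebraic equilibrium: every species follows from the free basis
    concentrations through its formation constant; the basis values solve
    the conservation equations by damped root finding (long integration as
    a fallback)."""
    basis = network.basis
    lnf = network.formation_log
    cm = network.conservation_matrix()
    totals = np.array([network.totals[b] for b in basis])
    active = totals > 0.0
    reachable = np.isfinite(lnf)
    # composition of each species over the basis
    comp = cm.T  # (n_species, n_basis)

    def conc(u):
        # u: ln free conc for active basis members; inactive units get an
        # effectively-zero free concentration so their species vanish
        ufull = np.empty(len(basis))
        ufull[active] = u
        ufull[~active] = -746.0
        ln_c = np.where(reachable, lnf, -np.inf) + comp @ ufull
        with np.errstate(over="ignore"):
            return np.where(np.isfinite(ln_c), np.exp(np.minimum(ln_c, 700.0)), 0.0)

    def residual(u):
        c = conc(u)
        got = cm[active] @ c
        return np.log(np.maximum(got, 1e-300)) - np.log(totals[active])

    if not active.any():
        return NetworkState(network, np.zeros(len(network.species)))
    u0 = np.log(totals[active] * 0.5)
    sol = root(residual, u0, method="hybr", tol=1e-13)
    u = sol.x if sol.success else u0.copy()
    # polish with damped fixed-point steps so that conservation holds to
    # near machine precision (the exactness tests rely on this)
    best, best_r = u.copy(), np.max(np.abs(residual(u)))
    for _ in range(20000):
        r = residual(u)
        rmax = np.max(np.abs(r))
        if rmax < best_r:
            best, best_r = u.copy(), rmax
        if rmax < 1e-14:
            break
        u -= 0.5 * r
    if best_r < 1e-9:
        return NetworkState(network, conc(best))
    # last resort: long integration with steady-state detection
    ts = simulate(network, t_end=1e7, n_points=50)
    return ts.state(-1)


def ka_eff_from_state(
    state: NetworkState, unit_a: str = "P1", unit_b: str = "P2"
) -> float | None:
    """Effective association constant from equilibrium species sums:
    [complexes] / ([A]_0 - [complexes]) ([B]_0 - [complexes]).

    The unbound totals are evaluated directly as the sums of the species
    containing one protein unit but not the other (e.g. P1 + MP1), which
    equals [A]_0 - [complexes] without the catastrophic cancellation that
    the subtraction suffers when nearly all protein is complexed.  Returns
    None (flagged null) on a vanishing denominator.
    """
    cx = state.complex_total(unit_a, unit_b)

    def unbound(unit, other):
        return sum(
            c
            for s, c in zip(state.network.species, state.concentrations)
            if s.composition.get(unit, 0) and not s.composition.get(other, 0)
        )

    fa = unbound(unit_a, unit_b)
    fb = unbound(unit_b, unit_a)
    if fa <= 0.0 or fb <= 0.0:
        return None
    return cx / (fa * fb)


def equilibration_time(
    series: TimeSeries,
    threshold_fraction: float = 0.01,
    observable=None,
) -> float | None:
    """First time after which the observable (default: total complexes)
    stays within ``threshold_fraction`` of its final value.

    Returns 0.0 for a pre-equilibrated start and None (flagged null) if the
    band is never permanently entered.
    """
    obs = (
        series.complex_series()
        if observable is None
        else series.observable(observable)
    )
    c_eq = obs[-1]
    band = threshold_fraction * abs(c_eq) if c_eq != 0 else threshold_fraction
    outside = np.abs(obs - c_eq) > band
    if not outside.any():
        return 0.0
    last_out = int(np.max(np.nonzero(outside)[0]))
    if last_out == len(obs) - 1:
        return None
    return float(series.times[last_out + 1])


# ---------------------------------------------------------------------------
# scaffold network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaffoldParameters:
    """Inputs of the scaffold model: P3 and P4 bind lipid M (not each
    other); the scaffold S binds P3 and P4 at independent sites and does
    not bind lipid."""

    ka_sp3: float   #: S-P3, um^3
    ka_sp4: float   #: S-P4, um^3
    ka_p3m: float   #: P3-lipid, um^3
    ka_p4m: float   #: P4-lipid, um^3
    p3_tot: float
    p4_tot: float
    s_tot: float
    geometry: Geometry
    sigma: float = nm_to_um(1.0)
    m_tot: float | None = None
    m_tot_per_area: float | None = None

    def __post_init__(self) -> None:
        if (self.m_tot is None) == (self.m_tot_per_area is None):
            raise InvalidParameterError(
                "exactly one of m_tot / m_tot_per_area must be given"
            )

    @property
    def gamma(self) -> float:
        return self.geometry.V / (2.0 * self.geometry.A * self.sigma)

    @property
    def m_tot_volume(self) -> float:
        if self.m_tot is not None:
            return self.m_tot
        return self.m_tot_per_area * self.geometry.A / self.geometry.V

    @classmethod
    def from_molar(cls, ka_sp3, ka_sp4, ka_p3m, ka_p4m, p3_tot, p4_tot,
                   s_tot, geometry, sigma_nm=1.0, m_tot_molar=None,
                   m_tot_per_um2=None):
        return cls(
            ka_sp3=ka_molar_to_um3(ka_sp3), ka_sp4=ka_molar_to_um3(ka_sp4),
            ka_p3m=ka_molar_to_um3(ka_p3m), ka_p4m=ka_molar_to_um3(ka_p4m),
            p3_tot=molar_to_per_um3(p3_tot), p4_tot=molar_to_per_um3(p4_tot),
            s_tot=molar_to_per_um3(s_tot), geometry=geometry,
            sigma=nm_to_um(sigma_nm),
            m_tot=None if m_tot_molar is None else molar_to_per_um3(m_tot_molar),
            m_tot_per_area=m_tot_per_um2,
        )


def _scaffold_name(st: tuple[int, int, int, int, int]) -> str:
    s, p3, m3, p4, m4 = st
    if s == 0 and p3 == 0 and p4 == 0:
        return "M"
    name = ""
    if m3:
        name += "M"
    if p3:
        name += "P3"
    if s:
        name += "S"
    if p4:
        name += "P4"
    if m4:
        name += "M"
    return name


def build_scaffold_network(
    params: ScaffoldParameters, koff_default: float = 1.0
) -> ReactionNetwork:
    """Enumerate the 14 species of the scaffold model and all binding
    reactions between them.

    A reaction runs in 2D (gamma-scaled constant) iff both reactant
    complexes are membrane-associated (carry at least one bound lipid);
    recruitment from solution is a 3D search.  Detailed balance holds by
    construction with a single sigma and is asserted at build time.
    """
    # species state: (s, p3, m3, p4, m4); m3 requires p3, m4 requires p4;
    # without the scaffold a species is a single protein (or free lipid)
    states = [(0, 0, 0, 0, 0)]  # free lipid M
    for p3, m3 in ((1, 0), (1, 1)):
        states.append((0, p3, m3, 0, 0))
    for p4, m4 in ((1, 0), (1, 1)):
        states.append((0, 0, 0, p4, m4))
    for p3, m3 in ((0, 0), (1, 0), (1, 1)):
        for p4, m4 in ((0, 0), (1, 0), (1, 1)):
            states.append((1, p3, m3, p4, m4))
    if len(states) != 14:
        raise DetailedBalanceError(
            f"scaffold species enumeration gave {len(states)} species, not 14"
        )

    def comp(st):
        s, p3, m3, p4, m4 = st
        c = {}
        if p3:
            c["P3"] = 1
        if p4:
            c["P4"] = 1
        if s:
            c["S"] = 1
        n_m = m3 + m4 + (1 if st == (0, 0, 0, 0, 0) else 0)
        if n_m:
            c["M"] = n_m
        return c

    def on_membrane(st):
        return st == (0, 0, 0, 0, 0) or st[2] or st[4]

    species = [
        Species(_scaffold_name(st), "membrane" if on_membrane(st) else "solution",
                comp(st))
        for st in states
    ]
    # free monomers P3, P4, S are 'solution' species without lipid
    state_idx = {st: i for i, st in enumerate(states)}
    g, va = params.gamma, params.geometry.v_over_a
    lipid = (0, 0, 0, 0, 0)

    reactions = []

    def add(a_st, b_st, p_st, base_ka, kind):
        both_mem = on_membrane(a_st) and on_membrane(b_st)
        ka_vol = base_ka * (g if both_mem else 1.0)
        kon = koff_default * ka_vol
        label = f"{_scaffold_name(a_st)}+{_scaffold_name(b_st)}->{_scaffold_name(p_st)} ({kind})"
        reactions.append(
            Reaction(label, (state_idx[a_st], state_idx[b_st]),
                     state_idx[p_st], kon, koff_default, ka_vol,
                     "2D" if both_mem else "3D")
        )

    for st in states:
        s, p3, m3, p4, m4 = st
        # scaffold complex gains a P3 unit
        if s and not p3:
            for um3 in (0, 1):
                unit = (0, 1, um3, 0, 0)
                add(st, unit, (1, 1, um3, p4, m4), params.ka_sp3, "S-P3")
        if s and not p4:
            for um4 in (0, 1):
                unit = (0, 0, 0, 1, um4)
                add(st, unit, (1, p3, m3, 1, um4), params.ka_sp4, "S-P4")
        # lipid binding
        if p3 and not m3:
            add(st, lipid, (s, 1, 1, p4, m4), params.ka_p3m, "P3-M")
        if p4 and not m4:
            add(st, lipid, (s, p3, m3, 1, 1), params.ka_p4m, "P4-M")

    totals = {"P3": params.p3_tot, "P4": params.p4_tot, "S": params.s_tot,
              "M": params.m_tot_volume}
    return ReactionNetwork(species, reactions, ("P3", "P4", "S", "M"), totals,
                           params.geometry)


@dataclass(frozen=True)
class ScaffoldMetrics:
    ka_eff_sp: float | None     #: um^6 (M^-2 after conversion)
    pct_complexation: float
    triples: float
    ka_sol_sp: float | None = None
    enhancement: float | None = None


def scaffold_metrics(
    state: NetworkState, solution_state: NetworkState | None = None
) -> ScaffoldMetrics:
    """Bridged-triple statistics of a scaffold-model equilibrium.

    Ka_eff_SP = [P3.S.P4 triples] / ([P3 not in a triple] [S not in a
    triple] [P4 not in a triple]) (units um^6); the solution reference
    (network built without lipid binding) defines Ka_sol_SP and the
    enhancement ratio.  Not a true equilibrium constant; computed from
    simulation output only.
    """

    def triple_stats(st: NetworkState):
        trip = 0.0
        by_unit = {"P3": 0.0, "P4": 0.0, "S": 0.0}
        for sp, c in zip(st.network.species, st.concentrations):
            has = {u: sp.composition.get(u, 0) > 0 for u in by_unit}
            if all(has.values()):
                trip += c
            else:
                for u in by_unit:
                    if has[u]:
                        by_unit[u] += c
        free = {u: st.network.totals[u] - trip for u in by_unit}
        return trip, free

    trip, free = triple_stats(state)
    denom = free["P3"] * free["S"] * free["P4"]
    ka_eff_sp = trip / denom if denom > 0 and trip >= 0 else None
    lo = min(state.network.totals["P3"], state.network.totals["P4"],
             state.network.totals["S"])
    pct = 100.0 * trip / lo if lo > 0 else 0.0
    ka_sol = enh = None
    if solution_state is not None:
        t2, f2 = triple_stats(solution_state)
        d2 = f2["P3"] * f2["S"] * f2["P4"]
        ka_sol = t2 / d2 if d2 > 0 else None
        if ka_sol and ka_eff_sp:
            enh = ka_eff_sp / ka_sol
    return ScaffoldMetrics(ka_eff_sp, pct, trip, ka_sol, enh)
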