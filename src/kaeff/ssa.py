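"""Rule-based stochastic simulation of multivalent assembly.

An exact Gillespie algorithm over site-level binding rules.  Molecules are
instances of a type with named sites; a rule joins a site on one type to a
site on another (or the same) type.  The simulation is non-spatial:

* lipids are a population count on the membrane; a complex (connected
  component of the bond graph) is membrane-associated iff it contains at
  least one bound lipid;
* bimolecular propensities scale as kon_3D / V when at least one partner is
  in solution (recruitment is a 3D search) and kon_2D / A when both are on
  the membrane;
* bonds form only between distinct complexes by default — the non-spatial
  model cannot assess the geometric compatibility of ring closure — with an
  opt-in first-order ring-closure rate.

Copy numbers of every molecule type are conserved, and trajectories are
reproducible given a seed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .units import InvalidParameterError

__all__ = [
    "MoleculeDef",
    "BindingRule",
    "RuleModel",
    "SSAState",
    "Trajectory",
    "ssa_run",
    "percent_oligomerization",
    "complex_size_distribution",
]


@dataclass(frozen=True)
class MoleculeDef:
    """A molecule type: named binding sites and an initial copy number."""

    name: str
    sites: tuple[str, ...]
    copies: int
    is_lipid: bool = False

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise InvalidParameterError("copies must be non-negative")
        if len(set(self.sites)) != len(self.sites):
            raise InvalidParameterError("site names must be unique per type")


@dataclass(frozen=True)
class BindingRule:
    """Reversible binding between two site classes.

    kon_3d is a volume-units macroscopic rate (um^3/s), kon_2d an area-units
    one (um^2/s, defaulting to kon_3d / (2 sigma) at the model's sigma);
    koff is s^-1 and is dimension-independent.
    """

    type_a: str
    site_a: str
    type_b: str
    site_b: str
    kon_3d: float
    koff: float
    kon_2d: float | None = None

    def __post_init__(self) -> None:
        if self.kon_3d < 0 or self.koff < 0:
            raise InvalidParameterError("rates must be non-negative")

    @property
    def homotypic(self) -> bool:
        return self.type_a == self.type_b and self.site_a == self.site_b


@dataclass(frozen=True)
class RuleModel:
    molecules: tuple[MoleculeDef, ...]
    rules: tuple[BindingRule, ...]
    V: float            #: um^3
    A: float            #: um^2
    sigma: float = 1e-3  #: um, sets the default kon_2d
    allow_ring_closure: bool = False
    ring_closure_rate: float = 0.0  #: s^-1 per eligible intra-complex pair

    def __post_init__(self) -> None:
        if self.V <= 0 or self.A <= 0:
            raise InvalidParameterError("V and A must be positive")
        names = {m.name for m in self.molecules}
        if len(names) != len(self.molecules):
            raise InvalidParameterError("molecule type names must be unique")
        for r in self.rules:
            for t, s in ((r.type_a, r.site_a), (r.type_b, r.site_b)):
                mt = next((m for m in self.molecules if m.name == t), None)
                if mt is None or s not in mt.sites:
                    raise InvalidParameterError(f"rule references unknown site {t}.{s}")


class _IndexedSet:
    """Set with O(1) add/discard/uniform-random-choice."""

    __slots__ = ("items", "pos")

    def __init__(self) -> None:
        self.items: list = []
        self.pos: dict = {}

    def add(self, x) -> None:
        if x in self.pos:
            return
        self.pos[x] = len(self.items)
        self.items.append(x)

    def discard(self, x) -> None:
        i = self.pos.pop(x)
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last] = i

    def choice(self, rng) -> object:
        return self.items[rng.integers(len(self.items))]

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, x) -> bool:
        return x in self.pos

    def __iter__(self):
        return iter(self.items)


class _Complex:
    __slots__ = ("members", "n_lipid", "free")

    def __init__(self) -> None:
        self.members: set[int] = set()
        self.n_lipid: int = 0
        self.free: Counter = Counter()  # (type_idx, site_idx) -> free sites

    @property
    def on_membrane(self) -> bool:
        return self.n_lipid > 0


def _pair_count(fa: int, fb: int, homotypic: bool) -> float:
    return fa * (fa - 1) / 2.0 if homotypic else fa * fb


class SSAState:
    """Full molecule/bond/complex bookkeeping of one stochastic trajectory."""

    def __init__(self, model: RuleModel, seed: int) -> None:
        self.model = model
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.time = 0.0
        self.event_count = 0
        self.type_index = {m.name: i for i, m in enumerate(model.molecules)}
        self.site_index = [
            {s: j for j, s in enumerate(m.sites)} for m in model.molecules
        ]
        # molecule arrays
        self.mol_type: list[int] = []
        self.partner: list[list] = []      # per molecule: per site, (mol, site) or None
        self.cid: list[int] = []
        self.complexes: dict[int, _Complex] = {}
        self._next_cid = 0
        # pools of free sites keyed by (type_idx, site_idx, on_membrane)
        self.pools: dict[tuple[int, int, bool], _IndexedSet] = {}
        # per-rule bond registry and intra-complex pair sums by membrane flag
        self.bonds: list[_IndexedSet] = [_IndexedSet() for _ in model.rules]
        self.intra: list[dict[bool, float]] = [
            {False: 0.0, True: 0.0} for _ in model.rules
        ]
        # nucleation bookkeeping: per rule, counts of bind events by the
        # membrane status of the two partners before the bond
        self.bind_events: list[Counter] = [Counter() for _ in model.rules]
        self._rule_keys = [
            (
                (self.type_index[r.type_a], self.site_index[self.type_index[r.type_a]][r.site_a]),
                (self.type_index[r.type_b], self.site_index[self.type_index[r.type_b]][r.site_b]),
            )
            for r in model.rules
        ]
        self._kon2 = [
            r.kon_2d if r.kon_2d is not None else r.kon_3d / (2.0 * model.sigma)
            for r in model.rules
        ]
        for ti, mdef in enumerate(model.molecules):
            for si in range(len(mdef.sites)):
                self.pools[(ti, si, False)] = _IndexedSet()
                self.pools[(ti, si, True)] = _IndexedSet()
        for ti, mdef in enumerate(model.molecules):
            for _ in range(mdef.copies):
                self._new_molecule(ti, mdef)

    # -- construction ----------------------------------------------------
    def _new_molecule(self, ti: int, mdef: MoleculeDef) -> None:
        mid = len(self.mol_type)
        self.mol_type.append(ti)
        self.partner.append([None] * len(mdef.sites))
        cx = _Complex()
        cx.members.add(mid)
        if mdef.is_lipid:
            cx.n_lipid = 1
        for si in range(len(mdef.sites)):
            cx.free[(ti, si)] += 1
        cid = self._next_cid
        self._next_cid += 1
        self.complexes[cid] = cx
        self.cid.append(cid)
        mem = cx.on_membrane
        for si in range(len(mdef.sites)):
            self.pools[(ti, si, mem)].add((mid, si))
        self._intra_update(cx, +1)

    # -- intra-complex pair bookkeeping ----------------------------------
    def _intra_update(self, cx: _Complex, sign: int) -> None:
        mem = cx.on_membrane
        for ri, ((ka, kb)) in enumerate(self._rule_keys):
            fa = cx.free.get(ka, 0)
            fb = cx.free.get(kb, 0)
            n = _pair_count(fa, fb, ka == kb)
            if n:
                self.intra[ri][mem] += sign * n

    # -- complex surgery --------------------------------------------------
    def _set_membrane(self, cid: int, cx: _Complex, new_mem: bool) -> None:
        """Move all free sites of a complex between sol/mem pools."""
        for mid in cx.members:
            ti = self.mol_type[mid]
            for si, p in enumerate(self.partner[mid]):
                if p is None:
                    self.pools[(ti, si, not new_mem)].discard((mid, si))
                    self.pools[(ti, si, new_mem)].add((mid, si))

    def _merge(self, cid_a: int, cid_b: int) -> int:
        """Merge complex b into a (a chosen as the larger)."""
        if len(self.complexes[cid_a].members) < len(self.complexes[cid_b].members):
            cid_a, cid_b = cid_b, cid_a
        ca, cb = self.complexes[cid_a], self.complexes[cid_b]
        self._intra_update(ca, -1)
        self._intra_update(cb, -1)
        mem_before = ca.on_membrane
        ca.n_lipid += cb.n_lipid
        # move pools before member sets are merged, each part separately
        if ca.on_membrane != mem_before:
            self._set_membrane(cid_a, ca, ca.on_membrane)
        if cb.on_membrane != ca.on_membrane:
            self._set_membrane(cid_b, cb, ca.on_membrane)
        for mid in cb.members:
            self.cid[mid] = cid_a
        ca.members |= cb.members
        ca.free += cb.free
        del self.complexes[cid_b]
        self._intra_update(ca, +1)
        return cid_a

    def _rebuild_complex(self, members: set[int]) -> int:
        """Create a fresh complex record for a connected member set."""
        cx = _Complex()
        cx.members = members
        cid = self._next_cid
        self._next_cid += 1
        self.complexes[cid] = cx
        for mid in members:
            self.cid[mid] = cid
            ti = self.mol_type[mid]
            if self.model.molecules[ti].is_lipid:
                cx.n_lipid += 1
            for si, p in enumerate(self.partner[mid]):
                if p is None:
                    cx.free[(ti, si)] += 1
        return cid

    def _component(self, start: int, limit: set[int]) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            mid = stack.pop()
            for p in self.partner[mid]:
                if p is not None and p[0] not in seen and p[0] in limit:
                    seen.add(p[0])
                    stack.append(p[0])
        return seen

    # -- propensities -----------------------------------------------------
    def _channel_counts(self, ri: int) -> tuple[float, float]:
        """Eligible (3D, 2D) pair counts for a rule, same-complex excluded."""
        (ta, sa), (tb, sb) = self._rule_keys[ri]
        homo = (ta, sa) == (tb, sb)
        nas = len(self.pools[(ta, sa, False)])
        nam = len(self.pools[(ta, sa, True)])
        nbs = len(self.pools[(tb, sb, False)])
        nbm = len(self.pools[(tb, sb, True)])
        if homo:
            p3 = nas * (nas - 1) / 2.0 + nas * nam - self.intra[ri][False]
            p2 = nam * (nam - 1) / 2.0 - self.intra[ri][True]
        else:
            p3 = nas * nbs + nas * nbm + nam * nbs - self.intra[ri][False]
            p2 = nam * nbm - self.intra[ri][True]
        return max(p3, 0.0), max(p2, 0.0)

    def propensities(self) -> np.ndarray:
        """Flat array: per rule [bind3D, bind2D, unbind] (+ ring closure)."""
        model = self.model
        out = []
        for ri, rule in enumerate(model.rules):
            p3, p2 = self._channel_counts(ri)
            out.append(rule.kon_3d / model.V * p3)
            out.append(self._kon2[ri] / model.A * p2)
            out.append(rule.koff * len(self.bonds[ri]))
            if model.allow_ring_closure:
                out.append(
                    model.ring_closure_rate
                    * (self.intra[ri][False] + self.intra[ri][True])
                )
        a = np.array(out)
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise RuntimeError("propensity overflow or negative rate")
        return a

    # -- event execution ---------------------------------------------------
    def _sample_pair(self, ri: int, mem_channel: bool):
        """Uniform eligible (siteA, siteB) pair for a bind channel."""
        (ta, sa), (tb, sb) = self._rule_keys[ri]
        homo = (ta, sa) == (tb, sb)
        rng = self.rng
        for _ in range(100000):
            if mem_channel:
                pa = self.pools[(ta, sa, True)]
                pb = self.pools[(tb, sb, True)]
                a = pa.choice(rng)
                b = pb.choice(rng)
            else:
                # choose a sub-channel proportional to raw pair products
                nas = len(self.pools[(ta, sa, False)])
                nam = len(self.pools[(ta, sa, True)])
                nbs = len(self.pools[(tb, sb, False)])
                nbm = len(self.pools[(tb, sb, True)])
                if homo:
                    w = np.array([nas * (nas - 1) / 2.0, nas * nam])
                    combos = [(False, False), (False, True)]
                else:
                    w = np.array(
                        [nas * nbs, nas * nbm, nam * nbs], dtype=float
                    )
                    combos = [(False, False), (False, True), (True, False)]
                tot = w.sum()
                if tot <= 0:
                    raise RuntimeError("inconsistent propensity bookkeeping")
                ma, mb = combos[int(rng.choice(len(w), p=w / tot))]
                a = self.pools[(ta, sa, ma)].choice(rng)
                b = self.pools[(tb, sb, mb)].choice(rng)
            if a == b:
                continue
            if self.cid[a[0]] == self.cid[b[0]]:
                continue  # intra-complex pairs handled by ring closure only
            return a, b
        raise RuntimeError("pair sampling failed to find an eligible pair")

    def _bind(self, ri: int, a, b) -> None:
        (amid, asite), (bmid, bsite) = a, b
        ca, cb = self.cid[amid], self.cid[bmid]
        mem_a = self.complexes[ca].on_membrane
        mem_b = self.complexes[cb].on_membrane
        self.bind_events[ri][(mem_a, mem_b)] += 1
        # remove sites from pools, update free counts
        for (mid, si), cid in ((a, ca), (b, cb)):
            ti = self.mol_type[mid]
            cx = self.complexes[cid]
            self._intra_update(cx, -1)
            self.pools[(ti, si, cx.on_membrane)].discard((mid, si))
            cx.free[(ti, si)] -= 1
            self._intra_update(cx, +1)
        self.partner[amid][asite] = (bmid, bsite)
        self.partner[bmid][bsite] = (amid, asite)
        self._merge(ca, cb)
        key = (amid, asite, bmid, bsite) if amid < bmid else (bmid, bsite, amid, asite)
        self.bonds[ri].add(key)

    def _unbind(self, ri: int) -> None:
        key = self.bonds[ri].choice(self.rng)
        self.bonds[ri].discard(key)
        amid, asite, bmid, bsite = key
        cid_old = self.cid[amid]
        cx_old = self.complexes[cid_old]
        mem_old = cx_old.on_membrane
        self._intra_update(cx_old, -1)
        self.partner[amid][asite] = None
        self.partner[bmid][bsite] = None
        # freed sites re-enter the pools under the old membrane flag; a
        # status change after splitting moves them with the whole complex
        for mid, si in ((amid, asite), (bmid, bsite)):
            self.pools[(self.mol_type[mid], si, mem_old)].add((mid, si))
        side_a = self._component(amid, cx_old.members)
        if bmid in side_a:
            cx_old.free[(self.mol_type[amid], asite)] += 1
            cx_old.free[(self.mol_type[bmid], bsite)] += 1
            self._intra_update(cx_old, +1)
            return
        side_b = cx_old.members - side_a
        del self.complexes[cid_old]
        for members in (side_a, side_b):
            cid = self._rebuild_complex(members)
            cx = self.complexes[cid]
            if cx.on_membrane != mem_old:
                self._set_membrane(cid, cx, cx.on_membrane)
            self._intra_update(cx, +1)

    def _ring_close(self, ri: int) -> None:
        """Pick an eligible intra-complex pair uniformly and bond it."""
        (ta, sa), (tb, sb) = self._rule_keys[ri]
        homo = (ta, sa) == (tb, sb)
        weights = []
        cids = []
        for cid, cx in self.complexes.items():
            n = _pair_count(cx.free.get((ta, sa), 0), cx.free.get((tb, sb), 0), homo)
            if n > 0:
                weights.append(n)
                cids.append(cid)
        w = np.array(weights, dtype=float)
        cid = cids[int(self.rng.choice(len(w), p=w / w.sum()))]
        cx = self.complexes[cid]
        sites_a = [
            (mid, si)
            for mid in cx.members
            for si, p in enumerate(self.partner[mid])
            if p is None and (self.mol_type[mid], si) == (ta, sa)
        ]
        sites_b = [
            (mid, si)
            for mid in cx.members
            for si, p in enumerate(self.partner[mid])
            if p is None and (self.mol_type[mid], si) == (tb, sb)
        ]
        for _ in range(10000):
            a = sites_a[self.rng.integers(len(sites_a))]
            b = sites_b[self.rng.integers(len(sites_b))]
            if a != b and a[0] != b[0]:
                break
        else:
            return
        self._bind(ri, a, b)

    def step(self, t_max: float = math.inf) -> bool:
        """One Gillespie event; returns False when no event fires by t_max."""
        a = self.propensities()
        a_tot = a.sum()
        if a_tot <= 0.0:
            if math.isfinite(t_max):
                self.time = t_max
            return False
        dt = self.rng.exponential(1.0 / a_tot)
        if self.time + dt > t_max:
            self.time = t_max
            return False
        self.time += dt
        ch = int(self.rng.choice(len(a), p=a / a_tot))
        per_rule = 4 if self.model.allow_ring_closure else 3
        ri, kind = divmod(ch, per_rule)
        if kind == 0:
            self._bind(ri, *self._sample_pair(ri, mem_channel=False))
        elif kind == 1:
            self._bind(ri, *self._sample_pair(ri, mem_channel=True))
        elif kind == 2:
            self._unbind(ri)
        else:
            self._ring_close(ri)
        self.event_count += 1
        return True

    # -- readouts ----------------------------------------------------------
    def copies_of(self, type_name: str) -> int:
        ti = self.type_index[type_name]
        return sum(1 for t in self.mol_type if t == ti)

    def molecules_of(self, type_name: str) -> list[int]:
        ti = self.type_index[type_name]
        return [m for m, t in enumerate(self.mol_type) if t == ti]

    def on_membrane_fraction(self, type_name: str) -> float:
        mids = self.molecules_of(type_name)
        if not mids:
            return 0.0
        n = sum(1 for m in mids if self.complexes[self.cid[m]].on_membrane)
        return n / len(mids)

    def bound_fraction(self, type_name: str, site: str) -> float:
        ti = self.type_index[type_name]
        si = self.site_index[ti][site]
        mids = self.molecules_of(type_name)
        if not mids:
            return 0.0
        return sum(1 for m in mids if self.partner[m][si] is not None) / len(mids)

    def n_bonds(self, rule_index: int) -> int:
        return len(self.bonds[rule_index])

    def polymerized_fraction(self, type_name: str, site_prefix: str) -> float:
        """Fraction of a type with at least one bond on sites matching a
        name prefix (e.g. clathrin 'leg')."""
        ti = self.type_index[type_name]
        sites = [si for s, si in self.site_index[ti].items()
                 if s.startswith(site_prefix)]
        mids = self.molecules_of(type_name)
        if not mids:
            return 0.0
        n = sum(
            1 for m in mids if any(self.partner[m][si] is not None for si in sites)
        )
        return n / len(mids)

    def check_consistency(self) -> None:
        """Recompute complex membership from the bond graph and compare."""
        all_m = set(range(len(self.mol_type)))
        seen: set[int] = set()
        for cid, cx in self.complexes.items():
            for mid in cx.members:
                assert self.cid[mid] == cid
                comp = self._component(mid, all_m)
                assert comp == cx.members, "complex membership inconsistent"
                break
            n_lip = sum(
                1 for m in cx.members
                if self.model.molecules[self.mol_type[m]].is_lipid
            )
            assert n_lip == cx.n_lipid
            seen |= cx.members
        assert seen == all_m


@dataclass
class Trajectory:
    state: SSAState
    times: list[float] = field(default_factory=list)
    records: list[dict] = field(default_factory=list)


def ssa_run(
    model: RuleModel,
    t_end: float,
    seed: int,
    record_times: np.ndarray | None = None,
    record_fn=None,
    max_events: int | None = None,
) -> Trajectory:
    """Exact stochastic trajectory of a rule model up to t_end.

    ``record_fn(state) -> dict`` is evaluated whenever the simulation
    crosses a requested record time (and once at the end).
    """
    state = SSAState(model, seed)
    traj = Trajectory(state)
    rec = list(record_times) if record_times is not None else []
    rec_i = 0

    def record(t):
        if record_fn is not None:
            traj.times.append(t)
            traj.records.append(record_fn(state))

    while state.time < t_end:
        if max_events is not None and state.event_count >= max_events:
            break
        t_before = state.time
        fired = state.step(t_max=t_end)
        while rec_i < len(rec) and t_before <= rec[rec_i] < state.time:
            record(rec[rec_i])
            rec_i += 1
        if not fired:
            break
    while rec_i < len(rec) and rec[rec_i] <= t_end:
        record(rec[rec_i])
        rec_i += 1
    record(state.time)
    return traj


def percent_oligomerization(state: SSAState, partner_low: str, site: str) -> float | None:
    """100 x (bound oligomer sites on the lower-concentration species) /
    (its total copies).  Returns None (flagged null) with zero copies."""
    n = state.copies_of(partner_low)
    if n == 0:
        return None
    ti = state.type_index[partner_low]
    si = state.site_index[ti][site]
    bound = sum(
        1 for m in state.molecules_of(partner_low)
        if state.partner[m][si] is not None
    )
    return 100.0 * bound / n


def complex_size_distribution(state: SSAState) -> Counter:
    """Histogram of complexes by protein (non-lipid) molecule count; pure
    lipid 'complexes' are excluded."""
    hist: Counter = Counter()
    for cx in state.complexes.values():
        n_prot = sum(
            1 for m in cx.members
            if not state.model.molecules[state.mol_type[m]].is_lipid
        )
        if n_prot > 0:
            hist[n_prot] += 1
    return hist
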