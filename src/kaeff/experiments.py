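"""Prebuilt rule models and stochastic experiments.

Covers the higher-order assembly systems beyond the analytic pair theory:

* the pair model itself as a rule model (cross-check against the ODE
  network);
* trimeric clathrin + AP-2 + PIP2 lattice nucleation mimicking the in
  vitro conditions (V/A = 9.46 um, 54,668 lipids/um^2, 0.4 uM clathrin and
  AP-2, clathrin:AP-2 Kd = 22 uM, clathrin-clathrin Kd swept 10-100 uM);
* dimer/oligomer-forming BAR-domain proteins (endophilin homodimers,
  FCHo1/FCHo2 heterodimers) with a weak non-competing oligomer contact.

Copy numbers are set by choosing a simulation volume; concentrations, the
V/A ratio and all equilibrium constants follow the stated conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import PairParameters
from .ssa import (
    BindingRule,
    MoleculeDef,
    RuleModel,
    SSAState,
    ssa_run,
)
from .units import molar_to_per_um3, ka_molar_to_um3, nm_to_um

__all__ = [
    "pair_rule_model",
    "dimer_rule_model",
    "ClathrinConfig",
    "ClathrinSummary",
    "clathrin_experiment",
    "bar_rule_model",
    "retromer_rule_model",
]


def _kon_pair(ka_um3: float, koff: float) -> float:
    return koff * ka_um3


def pair_rule_model(
    params: PairParameters, volume: float, koff: float = 1.0
) -> RuleModel:
    """The two-protein / one-lipid pair system as a rule model.

    Copy numbers are rounded from the concentrations at the requested
    simulation volume; the area follows from the parameter set's V/A.
    """
    area = volume / params.geometry.v_over_a
    n1 = round(params.p1_tot * volume)
    n2 = round(params.p2_tot * volume)
    nm = round(params.m_tot_volume * volume)
    mols = (
        MoleculeDef("P1", ("pp", "lip"), n1),
        MoleculeDef("P2", ("pp", "lip"), n2),
        MoleculeDef("L", ("head",), nm, is_lipid=True),
    )
    rules = (
        BindingRule("P1", "pp", "P2", "pp", _kon_pair(params.ka_pp, koff), koff),
        BindingRule("P1", "lip", "L", "head", _kon_pair(params.ka_p1m, koff), koff),
        BindingRule("P2", "lip", "L", "head", _kon_pair(params.ka_p2m, koff), koff),
    )
    return RuleModel(mols, rules, V=volume, A=area, sigma=params.sigma_pp)


def dimer_rule_model(
    n_a: int, n_b: int, ka_um3: float, volume: float, koff: float = 1.0
) -> RuleModel:
    """Minimal A + B <-> AB solution system (closed-form oracle exists)."""
    mols = (
        MoleculeDef("Adim", ("s",), n_a),
        MoleculeDef("Bdim", ("s",), n_b),
    )
    rules = (BindingRule("Adim", "s", "Bdim", "s", koff * ka_um3, koff),)
    return RuleModel(mols, rules, V=volume, A=volume)  # area unused: no lipid


@dataclass(frozen=True)
class ClathrinConfig:
    """In vitro clathrin + AP-2 polymerization conditions."""

    v_over_a: float = 9.46                 #: um
    lipid_per_um2: float = 54668.0
    clathrin_molar: float = 0.4e-6
    ap2_molar: float = 0.4e-6
    kd_clathrin_ap2_molar: float = 22e-6
    kd_cc_molar: float = 30e-6             #: clathrin-clathrin, swept 10-100 uM
    kd_ap2_lipid_molar: float = 2.86e-6    #: AP-2 : PIP2
    sigma_nm: float = 1.0
    koff: float = 1.0
    volume: float = 0.25                   #: um^3, sets copy numbers
    with_membrane: bool = True


def clathrin_rule_model(cfg: ClathrinConfig) -> RuleModel:
    """Trimeric clathrin (3 legs + 3 non-competing adaptor sites), AP-2
    (one clathrin site, one lipid site), PIP2 lipids."""
    area = cfg.volume / cfg.v_over_a
    n_cla = round(molar_to_per_um3(cfg.clathrin_molar) * cfg.volume)
    n_ap2 = round(molar_to_per_um3(cfg.ap2_molar) * cfg.volume)
    n_lip = round(cfg.lipid_per_um2 * area) if cfg.with_membrane else 0
    mols = (
        MoleculeDef(
            "clathrin",
            ("leg1", "leg2", "leg3", "ap1", "ap2", "ap3"),
            n_cla,
        ),
        MoleculeDef("AP2", ("cla", "lip"), n_ap2),
        MoleculeDef("PIP2", ("head",), n_lip, is_lipid=True),
    )
    koff = cfg.koff
    ka_cc = ka_molar_to_um3(1.0 / cfg.kd_cc_molar)
    ka_ca = ka_molar_to_um3(1.0 / cfg.kd_clathrin_ap2_molar)
    ka_al = ka_molar_to_um3(1.0 / cfg.kd_ap2_lipid_molar)
    rules = []
    # any leg binds any other clathrin's legs: 3x3 site-class pairs
    for i in (1, 2, 3):
        for j in (1, 2, 3):
            if i > j:
                continue
            rules.append(
                BindingRule("clathrin", f"leg{i}", "clathrin", f"leg{j}",
                            koff * ka_cc, koff)
            )
    for k in (1, 2, 3):
        rules.append(
            BindingRule("clathrin", f"ap{k}", "AP2", "cla", koff * ka_ca, koff)
        )
    rules.append(BindingRule("AP2", "lip", "PIP2", "head", koff * ka_al, koff))
    return RuleModel(tuple(mols), tuple(rules), V=cfg.volume, A=area,
                     sigma=nm_to_um(cfg.sigma_nm))


@dataclass
class ClathrinSummary:
    kd_cc_molar: float
    with_membrane: bool
    polymerized_fraction: float       #: clathrin with >= 1 leg-leg bond
    membrane_fraction: float          #: clathrin in lipid-containing complexes
    nucleation_membrane_2d: int       #: leg-leg bonds formed with both on membrane
    nucleation_direct_recruitment: int  #: one partner recruited from solution
    nucleation_solution: int
    n_clathrin: int
    events: int
    seed: int


def clathrin_experiment(
    cfg: ClathrinConfig, t_end: float, seed: int
) -> ClathrinSummary:
    """One stochastic trajectory of the clathrin system; the polymerized
    and membrane-bound clathrin fractions and the tally of leg-leg bond
    events by nucleation pathway (2D membrane-localized dimerization vs
    direct recruitment of a solution trimer)."""
    model = clathrin_rule_model(cfg)
    traj = ssa_run(model, t_end=t_end, seed=seed)
    st = traj.state
    n_leg_rules = 6  # leg-leg site-class pairs come first in the rule list
    mem2d = direct = sol = 0
    for ri in range(n_leg_rules):
        for (ma, mb), n in st.bind_events[ri].items():
            if ma and mb:
                mem2d += n
            elif ma or mb:
                direct += n
            else:
                sol += n
    return ClathrinSummary(
        kd_cc_molar=cfg.kd_cc_molar,
        with_membrane=cfg.with_membrane,
        polymerized_fraction=st.polymerized_fraction("clathrin", "leg"),
        membrane_fraction=st.on_membrane_fraction("clathrin"),
        nucleation_membrane_2d=mem2d,
        nucleation_direct_recruitment=direct,
        nucleation_solution=sol,
        n_clathrin=st.copies_of("clathrin"),
        events=st.event_count,
        seed=seed,
    )


def bar_rule_model(
    n_a: int,
    n_b: int | None,
    kd_dimer_molar: float,
    kd_oligomer_molar: float,
    kd_lipid_molar: float | None,
    volume: float,
    v_over_a: float = 9.46,
    lipid_per_um2: float = 25000.0,
    koff: float = 1.0,
    sigma_nm: float = 1.0,
) -> RuleModel:
    """BAR-domain proteins with a dimer site, a non-competing oligomer
    site, and a lipid site.

    ``n_b=None`` builds a homodimer system (e.g. endophilin); otherwise two
    types with a cross-type dimer contact and a cross-type oligomer contact
    linking dimers into filaments (e.g. FCHo1/FCHo2).
    ``kd_lipid_molar=None`` omits the membrane entirely (solution-only).
    """
    area = volume / v_over_a
    with_mem = kd_lipid_molar is not None
    n_lip = round(lipid_per_um2 * area) if with_mem else 0
    sites = ("dimer", "olig", "lip")
    mols = [MoleculeDef("BAR_A", sites, n_a)]
    homo = n_b is None
    if not homo:
        mols.append(MoleculeDef("BAR_B", sites, n_b))
    mols.append(MoleculeDef("L", ("head",), n_lip, is_lipid=True))
    ka_d = ka_molar_to_um3(1.0 / kd_dimer_molar)
    ka_o = ka_molar_to_um3(1.0 / kd_oligomer_molar)
    other = "BAR_A" if homo else "BAR_B"
    rules = [
        BindingRule("BAR_A", "dimer", other, "dimer", koff * ka_d, koff),
        BindingRule("BAR_A", "olig", other, "olig", koff * ka_o, koff),
    ]
    if with_mem:
        ka_l = ka_molar_to_um3(1.0 / kd_lipid_molar)
        rules.append(BindingRule("BAR_A", "lip", "L", "head", koff * ka_l, koff))
        if not homo:
            rules.append(
                BindingRule("BAR_B", "lip", "L", "head", koff * ka_l, koff)
            )
    return RuleModel(tuple(mols), tuple(rules), V=volume, A=area,
                     sigma=nm_to_um(sigma_nm))


def retromer_rule_model(
    n_vps17: int,
    n_vps5: int,
    n_snx3: int,
    kd_dimer_molar: float = 10e-6,
    kd_weak_lipid_molar: float = 100e-6,
    kd_snx3_lipid_molar: float = 2e-6,
    kd_snx3_vps17_molar: float = 10e-6,
    volume: float = 0.5,
    v_over_a: float = 0.5,
    lipid_per_um2: float = 1e4,
    koff: float = 1.0,
    sigma_nm: float = 1.0,
) -> RuleModel:
    """Retromer recruitment to the endosome: the VPS17/VPS5 coat dimer
    binds PI(3)P only weakly (Kd > 100 uM), while the cargo adaptor SNX3
    binds it strongly (~2 uM).  A putative SNX3-VPS17 contact lets the
    pre-assembled solution complex piggy-back on SNX3's lipid anchor.
    ``n_snx3 = 0`` removes the adaptor."""
    area = volume / v_over_a
    n_lip = round(lipid_per_um2 * area)
    mols = (
        MoleculeDef("VPS17", ("dimer", "snx3", "lip"), n_vps17),
        MoleculeDef("VPS5", ("dimer", "lip"), n_vps5),
        MoleculeDef("SNX3", ("vps17", "lip"), n_snx3),
        MoleculeDef("PI3P", ("head",), n_lip, is_lipid=True),
    )
    k = ka_molar_to_um3
    rules = (
        BindingRule("VPS17", "dimer", "VPS5", "dimer",
                    koff * k(1.0 / kd_dimer_molar), koff),
        BindingRule("VPS17", "snx3", "SNX3", "vps17",
                    koff * k(1.0 / kd_snx3_vps17_molar), koff),
        BindingRule("VPS17", "lip", "PI3P", "head",
                    koff * k(1.0 / kd_weak_lipid_molar), koff),
        BindingRule("VPS5", "lip", "PI3P", "head",
                    koff * k(1.0 / kd_weak_lipid_molar), koff),
        BindingRule("SNX3", "lip", "PI3P", "head",
                    koff * k(1.0 / kd_snx3_lipid_molar), koff),
    )
    return RuleModel(mols, rules, V=volume, A=area, sigma=nm_to_um(sigma_nm))
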