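"""Rule-based Gillespie engine: exactness, conservation, assembly metrics."""

import math
from collections import Counter

import numpy as np
import pytest

from kaeff.experiments import (
    bar_rule_model,
    dimer_rule_model,
    pair_rule_model,
    retromer_rule_model,
)
from kaeff.network import build_pair_network, solve_equilibrium
from kaeff.parameters import Geometry, PairParameters
from kaeff.ssa import (
    BindingRule,
    MoleculeDef,
    RuleModel,
    complex_size_distribution,
    percent_oligomerization,
    ssa_run,
)
from kaeff.units import ka_molar_to_um3


def exact_dimer_mean(n_a: int, n_b: int, ka: float, volume: float) -> float:
    """Exact equilibrium mean bond count of A + B <-> AB from the chemical
    master equation partition sum (the finite-copy-number oracle)."""
    x = ka / volume
    log_w = [0.0]
    for n in range(1, min(n_a, n_b) + 1):
        log_w.append(
            log_w[-1]
            + math.log((n_a - n + 1) * (n_b - n + 1) * x / n)
        )
    w = np.exp(np.array(log_w) - max(log_w))
    n = np.arange(len(w))
    return float((n * w).sum() / w.sum())


@pytest.fixture
def small_pair_params(unit_geometry):
    return PairParameters.from_molar(
        1e6, 1e6, 1e6, 1e-6, 1e-6, unit_geometry, sigma_nm=1.0,
        m_tot_per_um2=5e3,
    )


class TestEngineBasics:
    def test_zero_rates_never_bond(self):
        model = dimer_rule_model(50, 50, 0.0, 1.0)
        traj = ssa_run(model, t_end=10.0, seed=3)
        assert traj.state.n_bonds(0) == 0
        assert traj.state.time == 10.0

    def test_determinism_under_fixed_seed(self, small_pair_params):
        model = pair_rule_model(small_pair_params, volume=0.05)
        a = ssa_run(model, t_end=2.0, seed=11).state
        b = ssa_run(model, t_end=2.0, seed=11).state
        assert a.event_count == b.event_count
        assert a.n_bonds(0) == b.n_bonds(0)
        c = ssa_run(model, t_end=2.0, seed=12).state
        assert (a.event_count, a.time) != (c.event_count, c.time)

    def test_copy_number_conservation_and_graph_consistency(
        self, small_pair_params
    ):
        model = pair_rule_model(small_pair_params, volume=0.05)
        st = ssa_run(model, t_end=5.0, seed=5).state
        st.check_consistency()
        for mdef in model.molecules:
            assert st.copies_of(mdef.name) == mdef.copies

    def test_dimer_matches_partition_function_oracle(self):
        n, V = 100, 1.0
        ka = ka_molar_to_um3(1e7)
        model = dimer_rule_model(n, n, ka, V)
        vals = [
            ssa_run(model, t_end=30.0, seed=200 + s).state.n_bonds(0)
            for s in range(24)
        ]
        mean, se = np.mean(vals), np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert mean == pytest.approx(
            exact_dimer_mean(n, n, ka, V), abs=max(3 * se, 0.5)
        )

    def test_pair_model_matches_ode_equilibrium(self, small_pair_params):
        V = 0.25
        model = pair_rule_model(small_pair_params, volume=V)
        vals = [
            ssa_run(model, t_end=10.0, seed=s).state.n_bonds(0)
            for s in range(8)
        ]
        ode = solve_equilibrium(build_pair_network(small_pair_params))
        expected = ode.complex_total() * V
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(expected, abs=max(3 * se, 1.0))

    def test_equilibrium_independent_of_koff_rescaling(self, small_pair_params):
        V = 0.1
        slow = pair_rule_model(small_pair_params, volume=V, koff=1.0)
        fast = pair_rule_model(small_pair_params, volume=V, koff=5.0)
        b_slow = [
            ssa_run(slow, t_end=10.0, seed=s).state.n_bonds(0) for s in range(6)
        ]
        b_fast = [
            ssa_run(fast, t_end=2.0, seed=s).state.n_bonds(0) for s in range(6)
        ]
        se = math.sqrt(
            np.var(b_slow, ddof=1) / 6 + np.var(b_fast, ddof=1) / 6
        )
        assert abs(np.mean(b_slow) - np.mean(b_fast)) < max(3 * se, 2.0)


class TestMembraneStatus:
    def test_membrane_association_requires_a_lipid(self, small_pair_params):
        st = ssa_run(
            pair_rule_model(small_pair_params, volume=0.05), t_end=5.0, seed=9
        ).state
        for cid, cx in st.complexes.items():
            has_lipid = any(
                st.model.molecules[st.mol_type[m]].is_lipid for m in cx.members
            )
            assert cx.on_membrane == has_lipid

    def test_no_lipids_means_nobody_on_membrane(self):
        model = dimer_rule_model(30, 30, ka_molar_to_um3(1e6), 0.5)
        st = ssa_run(model, t_end=5.0, seed=2).state
        assert st.on_membrane_fraction("Adim") == 0.0


class TestOligomerization:
    def test_no_bonds_no_oligomerization(self):
        model = bar_rule_model(
            n_a=50, n_b=None, kd_dimer_molar=1e-6, kd_oligomer_molar=500e-6,
            kd_lipid_molar=1e-6, volume=0.1,
        )
        st = ssa_run(model, t_end=0.0, seed=1).state
        assert percent_oligomerization(st, "BAR_A", "olig") == 0.0

    def test_fully_chained_system_approaches_100(self):
        # irreversible-ish oligomer contacts: almost every olig site pairs
        model = bar_rule_model(
            n_a=60, n_b=None, kd_dimer_molar=1e-3, kd_oligomer_molar=1e-12,
            kd_lipid_molar=None, volume=0.01,
        )
        st = ssa_run(model, t_end=50.0, seed=4).state
        assert percent_oligomerization(st, "BAR_A", "olig") > 90.0

    def test_solution_endophilin_barely_oligomerizes(self):
        # in vivo concentration (~77 nM) with a 500 uM oligomer Kd: the
        # chain equilibrium predicts a bound-site fraction around Ka*c,
        # far below 1 percent
        c = 55621 / (6.02214076e8 * 1200.0)  # M
        volume = 10.0
        n = round(c * 6.02214076e8 * volume)
        model = bar_rule_model(
            n_a=n, n_b=None, kd_dimer_molar=500e-6, kd_oligomer_molar=500e-6,
            kd_lipid_molar=None, volume=volume,
        )
        st = ssa_run(model, t_end=20.0, seed=6).state
        pct = percent_oligomerization(st, "BAR_A", "olig")
        analytic_pct = 100.0 * c / 500e-6  # first-order chain estimate
        assert pct < 1.0
        assert pct <= max(10 * analytic_pct, 1.0)

    def test_zero_copies_flagged_null(self):
        model = bar_rule_model(
            n_a=10, n_b=0, kd_dimer_molar=1e-6, kd_oligomer_molar=500e-6,
            kd_lipid_molar=None, volume=0.1,
        )
        st = ssa_run(model, t_end=0.0, seed=1).state
        assert percent_oligomerization(st, "BAR_B", "olig") is None


class TestComplexSizes:
    def test_monomeric_start_all_size_one(self):
        model = dimer_rule_model(25, 25, ka_molar_to_um3(1e6), 1.0)
        st = ssa_run(model, t_end=0.0, seed=1).state
        assert complex_size_distribution(st) == Counter({1: 50})

    def test_size_times_count_conserves_proteins(self, small_pair_params):
        model = pair_rule_model(small_pair_params, volume=0.1)
        st = ssa_run(model, t_end=5.0, seed=8).state
        hist = complex_size_distribution(st)
        total = sum(size * count for size, count in hist.items())
        assert total == sum(m.copies for m in model.molecules if not m.is_lipid)

    def test_matched_homodimers_outgrow_mismatched_heterodimers(self):
        # endophilin-style matched stoichiometry vs the FCHo1/FCHo2
        # disparity (3706 vs 36302 copies, scaled to simulation size)
        kw = dict(
            kd_dimer_molar=1e-6, kd_oligomer_molar=20e-6,
            kd_lipid_molar=1e-6, volume=0.05, v_over_a=1.5645,
        )
        matched = bar_rule_model(n_a=200, n_b=None, **kw)
        mismatched = bar_rule_model(n_a=20, n_b=196, **kw)

        def largest(model, seeds):
            return np.mean([
                max(complex_size_distribution(
                    ssa_run(model, t_end=20.0, seed=s).state
                ))
                for s in seeds
            ])

        assert largest(matched, range(3)) > largest(mismatched, range(3))


class TestRetromer:
    def test_snx3_boosts_vps17_recruitment(self):
        """The strong PI(3)P binder SNX3 drags the weakly binding VPS17
        onto the endosome through their protein-protein contact."""

        def recruitment(n_snx3, seeds=range(3)):
            model = retromer_rule_model(
                n_vps17=80, n_vps5=80, n_snx3=n_snx3, volume=0.25
            )
            return np.mean([
                ssa_run(model, t_end=15.0, seed=s).state.on_membrane_fraction(
                    "VPS17"
                )
                for s in seeds
            ])

        assert recruitment(80) > recruitment(0) + 0.05


class TestRuleValidation:
    def test_unknown_site_rejected(self):
        from kaeff.units import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            RuleModel(
                (MoleculeDef("X", ("s",), 5),),
                (BindingRule("X", "nope", "X", "s", 1.0, 1.0),),
                V=1.0, A=1.0,
            )

    def test_negative_rate_rejected(self):
        from kaeff.units import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            BindingRule("X", "s", "X", "s", -1.0, 1.0)
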