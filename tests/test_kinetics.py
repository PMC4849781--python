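import numpy as np
import pytest

from tracekin.kinetics import (ExpressionLaw, KineticsError, MassAction,
                               MichaelisMenten, ParameterGroups, ParameterSet,
                               ReversibleMichaelisMenten, evaluate_fluxes,
                               haldane_reverse_capacity)
from tracekin.models import make_demo_model
from tracekin.network import Compartment, Metabolite, Network, Reaction


def uni_uni_net():
    comps = [Compartment("c")]
    mets = [Metabolite("S", "c", initial_concentration=1.0),
            Metabolite("P", "c")]
    return Network(comps, mets, [Reaction("r", [("S", 1)], [("P", 1)],
                                          reversible=True)])


class TestClosedForms:
    def test_michaelis_menten_half_saturation(self):
        net = uni_uni_net()
        net.reactions[0].reversible = False
        laws = {"r": MichaelisMenten("r", ["S"])}
        p = ParameterSet({"r.Vmax": 2.0, "r.Km_S": 0.5})
        out = evaluate_fluxes(net, {"S": 0.5, "P": 0.0}, laws, p)
        assert out["r"][0] == pytest.approx(1.0)
        assert out["r"][1] == 0.0

    def test_reversible_law_zero_net_flux_at_equilibrium(self):
        net = uni_uni_net()
        laws = {"r": ReversibleMichaelisMenten("r", ["S"], ["P"])}
        p = ParameterSet({"r.Vmax": 3.0, "r.keq": 2.5, "r.Km_S": 0.4,
                          "r.Km_P": 1.1})
        rng = np.random.default_rng(0)
        for s in rng.uniform(0.01, 10.0, size=20):
            out = evaluate_fluxes(net, {"S": s, "P": 2.5 * s}, laws, p)
            vf, vr = out["r"]
            assert vf == pytest.approx(vr, rel=1e-12)

    def test_mass_action_zero_at_zero_substrate(self):
        net = uni_uni_net()
        net.reactions[0].reversible = False
        laws = {"r": MassAction("r", [("S", 1)])}
        p = ParameterSet({"r.k": 5.0})
        out = evaluate_fluxes(net, {"S": 0.0, "P": 1.0}, laws, p)
        assert out["r"] == (0.0, 0.0)

    def test_negative_trial_concentrations_clamped(self):
        net = uni_uni_net()
        net.reactions[0].reversible = False
        laws = {"r": MassAction("r", [("S", 1)])}
        p = ParameterSet({"r.k": 5.0})
        out = evaluate_fluxes(net, np.array([-0.3, 1.0]), laws, p)
        assert out["r"][0] == 0.0


class TestHaldane:
    @pytest.mark.parametrize(
        "vf,keq,ks,kp,expected",
        [(1.0, 1.0, 1.0, 1.0, 1.0), (2.0, 4.0, 1.0, 2.0, 1.0),
         (5.0, 10.0, 0.5, 2.0, 2.0)],
    )
    def test_uni_uni_identity(self, vf, keq, ks, kp, expected):
        assert haldane_reverse_capacity(vf, keq, ks, kp) == pytest.approx(expected)

    def test_invalid_keq_rejected(self):
        with pytest.raises(KineticsError):
            haldane_reverse_capacity(1.0, 0.0, 1.0, 1.0)
        with pytest.raises(KineticsError):
            haldane_reverse_capacity(1.0, -2.0, 1.0, 1.0)

    def test_derived_capacity_gives_equilibrium_over_grid(self):
        # a law built with Vmax_r from the Haldane identity must have zero
        # net rate wherever [P]/[S] = Keq, for any substrate level
        net = uni_uni_net()
        laws = {"r": ReversibleMichaelisMenten("r", ["S"], ["P"])}
        p = ParameterSet({"r.Vmax": 2.0, "r.keq": 4.0, "r.Km_S": 1.0,
                          "r.Km_P": 2.0})
        vr_cap = haldane_reverse_capacity(2.0, 4.0, 1.0, 2.0)
        assert vr_cap == pytest.approx(1.0)
        for s in np.linspace(0.05, 8.0, 15):
            vf, vr = evaluate_fluxes(net, {"S": s, "P": 4.0 * s}, laws, p)["r"]
            assert vf - vr == pytest.approx(0.0, abs=1e-12)


class TestParameterGroups:
    def test_members_scaled_by_factor_times_weight(self):
        g = ParameterGroups([("chain", [("gapdh.Vmax", 1.0), ("pgk.Vmax", 2.0)])])
        p = g.apply(ParameterSet({"gapdh.Vmax": 0.0, "pgk.Vmax": 0.0,
                                  "other": 7.0}), [3.0])
        assert p["gapdh.Vmax"] == 3.0 and p["pgk.Vmax"] == 6.0
        assert p["other"] == 7.0

    def test_zero_factor_silences_chain(self):
        g = ParameterGroups([("chain", [("a.Vmax", 1.0), ("b.Vmax", 0.5)])])
        p = g.apply(ParameterSet({"a.Vmax": 1, "b.Vmax": 1}), [0.0])
        assert p["a.Vmax"] == 0.0 and p["b.Vmax"] == 0.0

    def test_group_application_order_irrelevant(self):
        g1 = ParameterGroups([("x", [("a.k", 1.0)]), ("y", [("b.k", 2.0)])])
        g2 = ParameterGroups([("y", [("b.k", 2.0)]), ("x", [("a.k", 1.0)])])
        base = ParameterSet({"a.k": 0, "b.k": 0})
        assert g1.apply(base, [2.0, 5.0]) == g2.apply(base, [5.0, 2.0])

    def test_parameter_in_two_groups_rejected(self):
        with pytest.raises(KineticsError):
            ParameterGroups([("x", [("a.k", 1.0)]), ("y", [("a.k", 1.0)])])

    def test_factor_count_mismatch_rejected(self):
        g = ParameterGroups([("x", [("a.k", 1.0)])])
        with pytest.raises(KineticsError):
            g.apply(ParameterSet({"a.k": 1.0}), [1.0, 2.0])


class TestProperties:
    def test_capacity_homogeneity_on_demo_model(self):
        # doubling every capacity/rate-constant parameter doubles all fluxes
        model = make_demo_model()
        net = model.network
        rng = np.random.default_rng(3)
        conc = {m.id: rng.uniform(0.01, 3.0) for m in net.metabolites}
        doubled = ParameterSet({
            k: (2 * v if k.endswith(".Vmax") or k.endswith(".k") else v)
            for k, v in model.params.items()
        })
        f1 = evaluate_fluxes(net, conc, model.rate_laws, model.params)
        f2 = evaluate_fluxes(net, conc, model.rate_laws, doubled)
        for rid in f1:
            assert f2[rid][0] == pytest.approx(2 * f1[rid][0], rel=1e-12)
            assert f2[rid][1] == pytest.approx(2 * f1[rid][1], rel=1e-12)

    def test_evaluation_is_deterministic_and_side_effect_free(self):
        model = make_demo_model()
        conc = {m.id: m.initial_concentration for m in model.network.metabolites}
        a = evaluate_fluxes(model.network, conc, model.rate_laws, model.params)
        b = evaluate_fluxes(model.network, conc, model.rate_laws, model.params)
        assert a == b


class TestExpressionLaw:
    def test_unknown_symbol_is_hard_error(self):
        net = uni_uni_net()
        net.reactions[0].reversible = False
        laws = {"r": ExpressionLaw("r", "k * S * BOGUS", None, ["k"])}
        with pytest.raises(KineticsError, match="BOGUS"):
            evaluate_fluxes(net, {"S": 1.0, "P": 0.0}, laws,
                            ParameterSet({"r.k": 1.0}))

    def test_division_by_zero_names_reaction(self):
        net = uni_uni_net()
        net.reactions[0].reversible = False
        laws = {"r": ExpressionLaw("r", "k / P", None, ["k"])}
        with pytest.raises(KineticsError, match="'r'"):
            evaluate_fluxes(net, {"S": 1.0, "P": 0.0}, laws,
                            ParameterSet({"r.k": 1.0}))

    def test_parsed_expression_matches_template(self):
        net = uni_uni_net()
        net.reactions[0].reversible = False
        expr = ExpressionLaw("r", "Vmax * S / (Km + S)", None, ["Vmax", "Km"])
        tmpl = MichaelisMenten("r", ["S"])
        p = ParameterSet({"r.Vmax": 1.7, "r.Km": 0.3, "r.Km_S": 0.3})
        for s in (0.0, 0.1, 2.0):
            ve = evaluate_fluxes(net, {"S": s, "P": 0}, {"r": expr}, p)["r"][0]
            vt = evaluate_fluxes(net, {"S": s, "P": 0}, {"r": tmpl}, p)["r"][0]
            assert ve == pytest.approx(vt)
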