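import numpy as np
import pytest

from tracekin.io import load_model, save_model
from tracekin.models import data_path, make_demo_model, make_toy
from tracekin.network import (AtomTransitionMap, Compartment, Metabolite,
                              Network, NetworkError, Reaction,
                              stoichiometric_matrix, validate_atom_maps)


def two_met_network(**kw):
    comps = [Compartment("c", volume=1.0)]
    mets = [
        Metabolite("A", "c", n_carbons=3, labelable=True,
                   initial_concentration=1.0),
        Metabolite("B", "c", n_carbons=3, labelable=True),
    ]
    rxns = [Reaction("r", [("A", 1)], [("B", 1)])]
    return Network(comps, mets, rxns, **kw)


class TestValidation:
    def test_minimal_network_builds(self):
        net = two_met_network()
        assert len(net.reactions) == 1 and len(net.metabolites) == 2

    def test_unknown_metabolite_named_in_error(self):
        comps = [Compartment("c")]
        mets = [Metabolite("A", "c")]
        with pytest.raises(NetworkError, match="'X'"):
            Network(comps, mets, [Reaction("r", [("A", 1)], [("X", 1)])])

    def test_duplicate_ids_rejected(self):
        comps = [Compartment("c")]
        mets = [Metabolite("A", "c"), Metabolite("A", "c")]
        with pytest.raises(NetworkError, match="duplicate"):
            Network(comps, mets, [])

    def test_fractional_stoichiometry_rejected(self):
        with pytest.raises(NetworkError, match="positive integer"):
            Reaction("r", [("A", 1.5)], [("B", 1)])

    def test_invisible_requires_zero_net_stoichiometry(self):
        comps = [Compartment("c")]
        mets = [Metabolite("A", "c"), Metabolite("B", "c")]
        with pytest.raises(NetworkError, match="invisible"):
            Network(comps, mets,
                    [Reaction("r", [("A", 1)], [("B", 1)], invisible=True)])

    def test_volume_must_be_positive(self):
        with pytest.raises(NetworkError):
            Compartment("c", volume=0.0)


class TestStoichiometricMatrix:
    def test_simple_conversion_column(self):
        net = two_met_network()
        N = stoichiometric_matrix(net)
        assert N[:, 0].tolist() == [-1.0, 1.0]

    def test_constant_metabolite_row_zeroed(self):
        model = make_toy("chain3")  # A is a constant feed
        N = stoichiometric_matrix(model.network)
        a_row = [m.id for m in model.network.metabolites].index("A")
        assert np.all(N[a_row, :] == 0)

    def test_invisible_reaction_zero_column_with_atom_map(self):
        model = make_toy("loop_exchange")
        N = stoichiometric_matrix(model.network)
        assert np.all(N[:, 0] == 0)
        assert len(model.network.reactions[0].atom_map) > 0

    def test_multisubstrate_signs(self):
        # pyruvate-dehydrogenase-style stoichiometry: consumed cofactors get
        # -1, products +1
        comps = [Compartment("m")]
        mets = [Metabolite(x, "m") for x in
                ("mPyr", "mNAD", "mCoA", "mACoA", "mNADH", "CO2")]
        rxn = Reaction("pdh", [("mPyr", 1), ("mNAD", 1), ("mCoA", 1)],
                       [("mACoA", 1), ("mNADH", 1), ("CO2", 1)])
        net = Network(comps, mets, [rxn])
        col = stoichiometric_matrix(net)[:, 0]
        assert col.tolist() == [-1, -1, -1, 1, 1, 1]


class TestAtomMaps:
    def _aldolase(self, drop_c6=False):
        comps = [Compartment("c")]
        mets = [
            Metabolite("F16BP", "c", n_carbons=6, labelable=True),
            Metabolite("DHAP", "c", n_carbons=3, labelable=True),
            Metabolite("GAP", "c", n_carbons=3, labelable=True),
        ]
        amap = AtomTransitionMap()
        for c, pc in ((1, 3), (2, 2), (3, 1)):
            amap.add("F16BP#1", c, "DHAP#1", pc)
        for c in (4, 5) + (() if drop_c6 else (6,)):
            amap.add("F16BP#1", c, "GAP#1", c - 3)
        rxn = Reaction("ald", [("F16BP", 1)], [("DHAP", 1), ("GAP", 1)],
                       atom_map=amap)
        return Network(comps, mets, [rxn])

    def test_balanced_cleavage_map_is_valid(self):
        assert validate_atom_maps(self._aldolase()) == []

    def test_unmapped_substrate_carbon_reported(self):
        issues = validate_atom_maps(self._aldolase(drop_c6=True))
        assert any("unmapped" in s for s in issues)

    def test_decarboxylation_to_nonlabelable_sink_is_valid(self):
        # pyruvate C1 leaves as CO2 (declared non-labelable); C2,C3 map to
        # the two acetyl carbons
        comps = [Compartment("m")]
        mets = [
            Metabolite("Pyr", "m", n_carbons=3, labelable=True),
            Metabolite("ACoA", "m", n_carbons=2, labelable=True),
            Metabolite("CO2", "m", n_carbons=1, labelable=False),
        ]
        amap = AtomTransitionMap()
        amap.add("Pyr#1", 1, "CO2#1", 1)
        amap.add("Pyr#1", 2, "ACoA#1", 1)
        amap.add("Pyr#1", 3, "ACoA#1", 2)
        rxn = Reaction("pdh", [("Pyr", 1)], [("ACoA", 1), ("CO2", 1)],
                       atom_map=amap)
        assert validate_atom_maps(Network(comps, mets, [rxn])) == []

    def test_duplicate_product_carbon_reported(self):
        net = self._aldolase()
        net.reactions[0].atom_map.add("F16BP#1", 6, "GAP#1", 2)
        assert any("mapped twice" in s or "unmapped" in s
                   for s in validate_atom_maps(net))

    def test_all_shipped_networks_have_valid_maps(self):
        for name in ("chain3", "loop_exchange", "symmetric_krebs_stub"):
            assert validate_atom_maps(make_toy(name).network) == []
        assert validate_atom_maps(make_demo_model().network) == []


class TestRoundTrip:
    def test_stoichiometry_preserved_through_writer(self, tmp_path):
        model = make_demo_model()
        save_model(model, tmp_path / "m.yaml", tmp_path / "m.tsv")
        again = load_model(tmp_path / "m.yaml", tmp_path / "m.tsv")
        assert np.array_equal(stoichiometric_matrix(model.network),
                              stoichiometric_matrix(again.network))
        assert model.params == again.params

    def test_writer_is_deterministic(self, tmp_path):
        model = make_demo_model()
        save_model(model, tmp_path / "a.yaml", tmp_path / "a.tsv")
        save_model(load_model(tmp_path / "a.yaml", tmp_path / "a.tsv"),
                   tmp_path / "b.yaml", tmp_path / "b.tsv")
        assert (tmp_path / "a.yaml").read_bytes() == (tmp_path / "b.yaml").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_shipped_config_matches_builder(self):
        shipped = load_model(data_path("hepatocyte_demo.yaml"),
                             data_path("hepatocyte_demo_atom_maps.tsv"))
        built = make_demo_model()
        assert np.array_equal(stoichiometric_matrix(shipped.network),
                              stoichiometric_matrix(built.network))
        assert shipped.params == built.params
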