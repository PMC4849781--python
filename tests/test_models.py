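import numpy as np
import pytest

from conftest import CHAIN3_CONDITION, CHAIN3_OBSERVABLES, chain3_problem
from tracekin.experiments import Condition
from tracekin.fitting import FitProblem, objective
from tracekin.kinetics import KineticsError
from tracekin.labeling import simulate_labeling
from tracekin.measurement import observables_at
from tracekin.models import (condition_library, demo_observables,
                             generate_synthetic_dataset, make_demo_model,
                             make_toy)
from tracekin.models.hepato import MASK_12, MASK_U6
from tracekin.network import validate_atom_maps


class TestDemoModel:
    def test_default_build_is_validated_and_labelable(self, demo_model):
        assert validate_atom_maps(demo_model.network) == []
        mets = demo_model.network.metabolite_index
        for mid in ("eGlc", "eFru", "Glyc", "eLac"):
            assert mets[mid].labelable

    def test_unknown_override_rejected(self):
        with pytest.raises(KineticsError, match="bogus"):
            make_demo_model({"bogus.Vmax": 1.0})

    def test_override_is_applied(self):
        m = make_demo_model({"atpase.Vmax": 1.25e-12})
        assert m.params["atpase.Vmax"] == 1.25e-12

    def test_three_compartments(self, demo_model):
        assert len(demo_model.network.compartments) == 3

    def test_group_factors_default_to_one(self, demo_model):
        f = demo_model.groups.extract_factors(demo_model.params)
        assert np.allclose(f, 1.0)


class TestConditionLibrary:
    def test_a1_a2_differ_only_in_tracers(self):
        lib = condition_library()
        a1, a2 = lib["A1"], lib["A2"]
        assert a1.initial == a2.initial
        assert a1.t_end == a2.t_end
        assert a1.tracers != a2.tracers

    def test_tracer_masks_match_stated_media(self):
        lib = condition_library()
        assert MASK_12 == 0b000011 and MASK_U6 == 0b111111
        assert lib["A1"].tracers["eGlc"] == [(MASK_12, 0.5), (0, 0.5)]
        assert lib["A2"].tracers["eFru"] == [(MASK_U6, 0.5), (0, 0.5)]
        assert lib["B"].initial["eFru"] == 20.0

    def test_initial_isotopomer_vectors(self, demo_model, demo_conditions):
        from tracekin.labeling import build_joint_odes

        sys_ = build_joint_odes(demo_model, demo_conditions["A1"])
        y0 = sys_.y0
        sl = sys_.layout.iso_slice["eGlc"]
        vec = y0[sl]
        assert vec[MASK_12] == pytest.approx(10.0)
        assert vec[0] == pytest.approx(10.0)
        assert vec.sum() == pytest.approx(20.0)


class TestFructosePhenotype:
    def test_high_fructose_depletes_atp_and_pi(self, traj_A1, traj_B):
        assert traj_B.endpoint("cATP") < traj_A1.endpoint("cATP")
        assert traj_B.endpoint("cPi") < traj_A1.endpoint("cPi")

    def test_high_fructose_accumulates_fru1p(self, traj_A1, traj_B):
        assert traj_B.endpoint("Fru1P") > traj_A1.endpoint("Fru1P")

    def test_high_fructose_suppresses_glycogen(self, traj_A1, traj_B):
        assert traj_B.endpoint("Glyc") < traj_A1.endpoint("Glyc")

    def test_atp_falls_below_initial_under_high_fructose(self, traj_B):
        atp = traj_B.concentration("cATP")
        assert atp[-1] < atp[0]

    def test_a_conditions_share_fluxes_and_concentrations(self, traj_A1,
                                                          traj_A2):
        # A1 and A2 differ only in labelling, so totals must agree
        a = traj_A1.concentrations.to_numpy()
        b = traj_A2.concentrations[traj_A1.concentrations.columns].to_numpy()
        assert np.allclose(a, b, rtol=1e-4, atol=1e-6)

    def test_concentrations_stay_below_rejection_ceiling(self, traj_A1,
                                                         traj_B):
        for traj in (traj_A1, traj_B):
            assert traj.concentrations.to_numpy().max() < 50.0


class TestDemoObservables:
    def test_full_panel_evaluates_on_every_condition(self, traj_A1, traj_A2,
                                                     traj_B):
        obs = demo_observables()
        for traj in (traj_A1, traj_A2, traj_B):
            vals = observables_at(traj, obs, 120.0)
            assert len(vals) == len(obs)
            # each MID family sums to 1
            for met, frag, size in (("eGlc", (1, 6), 7), ("Glyc", (1, 4), 5),
                                    ("eLac", (1, 3), 4)):
                ids = [o.id for o in obs if o.kind == "mid"
                       and o.metabolite == met and o.fragment == frag
                       and o.pooled_with is None]
                if ids:
                    assert sum(vals[i] for i in ids) == pytest.approx(1.0,
                                                                      abs=1e-9)

    def test_sorbitol_pool_under_fructose_tracer(self, traj_A2):
        obs = [o for o in demo_observables() if o.pooled_with == "eFru"]
        vals = observables_at(traj_A2, obs, 120.0)
        assert sum(vals.values()) == pytest.approx(1.0, abs=1e-9)


class TestMoietyConservation:
    def test_adenine_pool_conserved_on_demo_path(self, traj_A1):
        # UDP-glucose holds one adenosine-equivalent in the lumped
        # nucleotide treatment, so the conserved sum includes it
        c = traj_A1.concentrations
        pool = c["cATP"] + c["cADP"] + c["cAMP"] + c["UDPG"]
        assert np.abs(pool - pool.iloc[0]).max() < 1e-5 * pool.iloc[0]

    def test_phosphate_moiety_conserved_in_closed_subsystem(self):
        # with medium phosphate exchange silenced the weighted phosphate
        # pool (cytosol + mitochondria, mole-weighted) is invariant
        model = make_demo_model({"pimtr.Vmax": 0.0})
        cond = condition_library()["A1"]
        traj = simulate_labeling(model, cond, (0.0, 40.0),
                                 t_eval=np.linspace(0, 40, 5),
                                 rtol=1e-7, atol=1e-9)
        c = traj.concentrations
        weights = {
            "cATP": 3, "cADP": 2, "cAMP": 1, "cPi": 1, "PPi": 2,
            "G6Pa": 1, "G6Pb": 1, "F6Pa": 1, "F6Pb": 1, "FBPa": 2,
            "FBPb": 2, "Fru1P": 1, "G1P": 1, "UDPG": 2, "DHAP": 1,
            "GAP": 1, "BPG": 2, "PG3": 1, "PG2": 1, "PEP": 1,
        }
        vol = {m.id: model.network.volume_of(m.id)
               for m in model.network.metabolites}
        total = sum(c[met] * w * vol[met] for met, w in weights.items())
        total = total + c["mPi"] * vol["mPi"]
        drift = np.abs(total - total.iloc[0]).max() / total.iloc[0]
        assert drift < 1e-6


class TestToys:
    def test_unknown_toy_rejected(self):
        with pytest.raises(ValueError, match="unknown toy"):
            make_toy("nope")

    def test_chain3_structure(self):
        m = make_toy("chain3")
        assert [r.id for r in m.network.reactions] == ["r1", "r2", "r3"]
        assert m.groups.n_factors == 3

    def test_loop_exchange_totals_invariant(self):
        m = make_toy("loop_exchange")
        assert m.network.reactions[0].invisible


class TestSyntheticData:
    def test_noise_free_data_scores_zero_at_truth(self):
        prob = chain3_problem(0.0, seed=5)
        assert objective(np.ones(3), prob) == pytest.approx(0.0, abs=1e-8)

    def test_fixed_seed_reproducible(self):
        m = make_toy("chain3")
        d1 = generate_synthetic_dataset(m, [CHAIN3_CONDITION],
                                        CHAIN3_OBSERVABLES, noise_sd=0.02,
                                        seed=9)
        d2 = generate_synthetic_dataset(m, [CHAIN3_CONDITION],
                                        CHAIN3_OBSERVABLES, noise_sd=0.02,
                                        seed=9)
        assert [x.value for x in d1] == [x.value for x in d2]

    def test_recorded_sd_floored(self):
        m = make_toy("chain3")
        ds = generate_synthetic_dataset(m, [CHAIN3_CONDITION],
                                        CHAIN3_OBSERVABLES, noise_sd=0.001,
                                        seed=2)
        assert all(x.sd == 0.01 for x in ds)

    def test_replicate_noise_magnitude(self):
        # empirical scatter across replicate datasets reflects the nominal
        # noise level within a factor of three
        m = make_toy("chain3")
        reps = [
            generate_synthetic_dataset(m, [CHAIN3_CONDITION],
                                       CHAIN3_OBSERVABLES[:4],
                                       noise_sd=0.01, seed=100 + k,
                                       times=(60.0,))
            for k in range(30)
        ]
        values = np.array([[x.value for x in ds] for ds in reps])
        sds = values.std(axis=0)
        assert np.all(sds < 0.03)
        assert np.all(sds > 0.01 / 3)

    def test_negative_noise_rejected(self):
        m = make_toy("chain3")
        with pytest.raises(ValueError):
            generate_synthetic_dataset(m, [CHAIN3_CONDITION],
                                       CHAIN3_OBSERVABLES, noise_sd=-1.0,
                                       seed=0)
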