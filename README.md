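# tracekin

Dynamic kinetic modelling of compartmentalized metabolic networks with
nonstationary ¹³C label propagation, multi-condition parameter fitting by
simulated annealing, and profile-likelihood identifiability analysis.

`tracekin` is for metabolic modellers who want to confront a kinetic model
— ODEs over metabolite concentrations with mechanistic rate laws — with
¹³C tracer experiments *without* assuming metabolic or isotopic steady
state.  Concentrations evolve as

    dc/dt = N · j(c, p) · ncell / vol

(`N` stoichiometric matrix, `j` per-cell reaction rates in
mmol·cell⁻¹·min⁻¹, `ncell` cells, `vol` compartment volumes), and every
reaction's flux is decomposed into isotopomer fluxes through per-reaction
carbon atom-transition maps, giving a joint stiff ODE over totals and all
2ⁿ positional isotopomers of each labelled species.  Predictions are
collapsed to what GC/MS actually measures — mass-isotopomer distributions
(MIDs) of whole molecules or fragments such as glucose C1-C4 — and fitted
against measured concentrations and isotopologue fractions from several
incubation conditions at once:

    X² = Σᵢ ((Yᵢ − Zᵢ(E₁…E_m)) / σᵢ)²,   σᵢ ≥ 0.01

where the free parameters E₁…E_m scale *groups* of enzyme activities
(unbranched reaction chains collapse to one factor).  Reverse capacities
of reversible laws are always derived via the Haldane relationship, so
thermodynamic consistency is built in.  Confidence intervals come from the
profile likelihood: a factor is identifiable when
{θ : X²(θ) − X²_bf < χ²(α, 1 df)} is finite; parameter sets accepted along
the profiles also yield min/max envelopes for predicted concentrations,
fluxes and MIDs.

The package ships a reduced hepatocyte glucose/fructose demonstration
model (three compartments; two channelled hexose-phosphate pools; the
three net aldolase reactions; fructokinase/triokinase; glycogen branch;
a closed ATP/ADP/AMP + phosphate energy subsystem) and the three classic
incubation conditions — 20 mM glucose with 3 mM or 20 mM fructose, with
50% [1,2-¹³C₂]-glucose or 50% [U-¹³C₆]-fructose tracers.

## Worked example

Simulate the demonstration hepatocyte for 2 h under low (3 mM) and high
(20 mM) medium fructose and look at the endpoint:

```python
from tracekin.labeling import simulate_labeling
from tracekin.measurement import to_isotopologues
from tracekin.models import condition_library, make_demo_model

model = make_demo_model()
conds = condition_library()
for cid in ("A1", "B"):
    traj = simulate_labeling(model, conds[cid])
    m2 = to_isotopologues(traj.isotopomers["eLac"][-1])[2]
    print(cid, traj.endpoint("cATP"), traj.endpoint("Fru1P"), m2)
```

Formatted, this prints (concentrations in mM at t = 120 min):

```
condition      cATP    cPi   Fru1P  glycogen  lactate m2
A1 (3 mM)      2.48   1.92    7.20     19.66       0.096
B (20 mM)      0.14   0.97   34.71      7.72       0.046
```

At 3 mM fructose the cell holds its energy charge (cATP 2.5 mM) and
accumulates glycogen; about 9.6% of medium lactate is m2 — the signature
of [1,2-¹³C₂]-glucose passing through glycolysis.  At 20 mM fructose the
unregulated fructokinase flux piles up fructose 1-phosphate (35 mM),
sequestering phosphate and throttling mitochondrial ATP regeneration:
cytosolic ATP and Pi are depleted, glycogen synthesis drops ~2.5-fold, and
the m2 lactate enrichment halves because the ATP-starved glucokinase and
phosphofructokinase steps no longer push labelled glucose carbon down to
lactate.

Fitting and identifiability use the statsmodels-style facade:

```python
from tracekin import DynamicLabelingModel
from tracekin.models import make_toy, generate_synthetic_dataset

km = make_toy("chain3")
data = generate_synthetic_dataset(km, [condition], observables,
                                  noise_sd=0.01, seed=1)
res = DynamicLabelingModel(km, [condition], data).fit(seed=2)
print(res.summary())        # factors, X², evaluations
prof = res.profile("k2")    # 95% profile-likelihood interval
```

A command-line interface mirrors the library
(`tracekin simulate|fit|profile --config run.yaml`), writing TSV
trajectories, MID tables, fit JSON and profile/envelope tables plus a
manifest for reproduction.

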