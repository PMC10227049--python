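# chirsep

Quantile dual-graph neural networks for predicting chiral-molecule HPLC
retention times and recommending enantioseparation conditions.

## The problem

Separating a pair of enantiomers by normal-phase HPLC on a
polysaccharide chiral stationary phase (CSP) means guessing a column,
an eluent ratio and a flow rate, running a ~30-minute injection, and
repeating until the two mirror images resolve. `chirsep` is for
synthetic chemists and cheminformaticians who want that guesswork
ranked by a model: given two enantiomer SMILES and a set of candidate
conditions, it predicts each enantiomer's retention time with an
uncertainty band and scores every condition by a separation
probability.

## The model

Retention is learned on the flow-invariant scale **RTv = RT × v**
(retention time × flow rate, min·mL/min), which the chromatographic
process equation RT ≈ (V_m + K·V_s)/v makes approximately constant
across flow rates. Each molecule becomes two coupled graphs: an
atom-bond graph G (9 atom features including the chiral tag; bond
features plus the elution proportion) and a bond-angle graph H whose
nodes are G's bonds (bond lengths from a seeded 3D conformer) and
whose edges carry bond angles plus five molecular descriptors. GIN
convolutions x′_i = MLP((1+ε)·x_i + Σ_{j∈N(i)} (x_j + e_ji)) run on
both graphs, with H's node states bridged into G's edge
representations each layer; sum-pooled G states feed a 3-output head:
the 10th percentile, the point prediction, and the 90th percentile of
RTv. Training minimizes squared error on the point head, pinball
losses for the two quantile heads, ReLU penalties enforcing
y10 ≤ pred ≤ y90, and a dead-time penalty ReLU(2 − pred).

From the two enantiomers' predicted RT bands, the separation
probability is the non-overlapping fraction of the union span,

    S_p = 1 − max(0, RT90_min − RT10_max) / (RT90_max − RT10_min),

with S_p > 0.38 called separable. For multi-column models the column's
packing size, substrate and connection type augment G's edge features
and the CSP's descriptor vector augments H's.

Everything runs on numpy (a built-in minimal autodiff core — no deep
learning framework required); molecules are handled with RDKit.

## Worked example

Train a reduced model (2 layers, width 32, 200 epochs) on 2,000
synthetic records with known ground truth, then assess a pair of
1-phenylethanol enantiomers on an ODH column — about a minute on one
CPU:

```python
from chirsep import (SynthConfig, generate, ModelConfig, TrainConfig, train,
                     evaluate, load_column_registry, separation_probability,
                     build_dual_graph, Condition)
from chirsep.training_pipeline import coverage

records, truth = generate(SynthConfig(n_pairs=1000, seed=11))
result = train(records, ModelConfig(num_layers=2, embed_dim=32, multi_column=True),
               TrainConfig(epochs=200, seed=3))
m = evaluate(result.model, result.folds[2])
print(f"test MAE {m.mae:.2f} RTv units, MRE {100*m.mre:.1f}%, R2 {m.r2:.2f}")
print(f"10-90 band coverage: {100*coverage(result.model, result.folds[2]):.0f}%")

registry = load_column_registry()
pair = ("C[C@H](O)c1ccccc1", "C[C@@H](O)c1ccccc1")
preds = [result.model.forward(build_dual_graph(s, Condition(0.05, 1.0), seed=0,
                                               column=registry["ODH"]))
         for s in pair]
for s, p in zip(pair, preds):
    print(f"{s}: RT band [{p.q10:.1f}, {p.q90:.1f}] min, point {p.pred:.1f} min")
a = separation_probability(preds[0], preds[1], flow_rate=1.0)
print(f"S_p = {a.sp:.3f} -> {a.call}")
```

Output:

```
test MAE 0.89 RTv units, MRE 2.9%, R2 0.93
10-90 band coverage: 88%
C[C@H](O)c1ccccc1: RT band [22.6, 26.6] min, point 23.0 min
C[C@@H](O)c1ccccc1: RT band [22.8, 24.8] min, point 21.2 min
S_p = 0.506 -> separable
```

Reading it: the model recovers the generator's structure–retention
signal (R² 0.93 on held-out records), its 10–90 bands cover 88% of
held-out observations (ideal: 80%), and for this pair on ODH the two
RT bands overlap over roughly half the union span, so the pair is
called separable at the 0.38 threshold — with S_p quantifying how
confidently.

The same operations are available from a CLI (`chirsep simulate`,
`train`, `evaluate`, `separate`, `parse`); real datasets are read from
CSV with one observation per row (SMILES, column, elution proportion,
flow rate, retention time). `chirsep parse` extracts candidate records
from plain-text HPLC reports of the kind found in supporting
information, keyed on the (S)/(R) name marker and the token "HPLC".

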