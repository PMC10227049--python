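# Methods

## Problem and model

Normal-phase HPLC on polysaccharide chiral stationary phases (CSPs) is
the standard way to separate enantiomers, but condition selection
(column, eluent ratio, flow rate) is trial-and-error. `chirsep` models
the molecule → retention-time relationship with enough chirality
awareness to tell mirror images apart, attaches an uncertainty band to
every prediction, and converts paired bands into a separation
probability for ranking candidate conditions.

### Target transformation

By the chromatographic process equation, RT ≈ (V_m + K·V_s)/v, so the
product RTv = RT × v (min·mL/min) is approximately invariant to flow
rate under otherwise fixed conditions. All learning happens on the RTv
scale; retention times are recovered by dividing by the condition's
flow rate. `cmrt_data.chrom_equation_error` quantifies how well a
dataset obeys this invariance: it groups repeated measurements of the
same molecule/column/eluent at different flow rates and reports all
pairwise |ΔRTv|, whose median would be zero for ideal data.

### Dual-graph representation

Each molecule under a condition becomes two coupled graphs:

* **Graph G** — atoms as nodes with 9 integer-coded features (atomic
  number, chiral tag, degree, explicit valence, formal charge,
  hybridization, implicit valence, aromaticity, attached-H count);
  bonds as bidirectional edges with direction, type and ring membership
  plus the elution proportion broadcast per edge (width 4).
* **Graph H** — G's bonds as nodes (feature: 3D bond length from an
  ETKDGv3 distance-geometry conformer, deterministic per seed); edges
  join every bond pair sharing an atom, both directions, carrying the
  bond angle and five molecular descriptors (width 6).

Chirality enters twice: through the chiral-tag node feature and through
the 3D geometry feeding Graph H. For multi-column models the column's
packing size, substrate code (0 amylose / 1 cellulose) and connection
code (0 immobilized / 1 coated) are appended to G's edges (width 7) and
the CSP's own 5-descriptor vector to H's edges (width 11).

### Descriptors

The five 2D descriptors broadcast onto H edges are TPSA; relative polar
surface area (Labute ASA contribution of N/O/S/P atoms over total);
relative hydrophobic surface area (contribution of C and halogens over
total); a carbon–carbon molecular distance-edge statistic, n_pairs
divided by the squared geometric mean of topological distances; and the
Moran lag-1 autocorrelation of atomic mass. The literature behind this
descriptor set does not pin down exact variants, so the definitions
above are package configuration: they satisfy the documented invariants
(finite, fractions in [0, 1], identical for enantiomers) and their role
is to carry coarse polarity/branching information, not to be
bit-compatible with any external package. The CSP descriptor vectors
shipped in `data/columns.yaml` were computed by the same code on
methyl-capped glucopyranose monomer units of each CSP polymer and are
editable configuration.

### Network

Message passing is GIN-style: `x'_i = MLP((1+ε)·x_i + Σ_j (x_j +
proj(e_ji)))` with ε = 0, a per-layer affine edge projection into the
embedding space, and a two-affine-layer MLP with interior ReLU. Per
layer, H nodes are updated first; the **previous layer's** H states are
added to G's edge representations (the geometry bridge — the printed
recurrence uses the k−1 superscript, and we follow it; a consequence is
that the final layer's H update cannot influence the output, so those
parameters are omitted). G nodes are then updated, and after K layers
the G states are sum-pooled and a fully connected layer emits three
outputs on the RTv scale: 10th percentile, point prediction, 90th
percentile. Defaults: K = 5, embedding 128; the desk-scale experiments
use K = 2, embedding 32.

The whole network and its training loop run on a ~200-line numpy
reverse-mode autodiff core (`_autograd.py`) providing exactly the
needed operators (affine, ReLU, gather, segment-sum); gradients are
unit-tested against finite differences. ReLU's subgradient at 0 is 0,
so the composite loss has finite gradients everywhere including its
kinks.

### Loss

Per batch of size N the objective is

    mean (y − y_pred)²                      (point head, squared error)
  + pinball(y, y90; 0.9) + pinball(y, y10; 0.1)      (batch means)
  + mean ReLU(y10 − y_pred) + mean ReLU(y_pred − y90)  (ordering)
  + mean ReLU(2 − y_pred)                   (dead-time bound on RTv)

with pinball(y, q; τ) = mean(τ·ReLU(y−q) + (1−τ)·ReLU(q−y)). The
nonnegative pinball form is used; a literal reading of the printed
quantile loss would carry a negative coefficient on the over-prediction
branch, rewarding overestimation. Quantile terms are batch means (not
sums) so all six terms share the 1/N scale; per-term weights are
exposed in `LossConfig` and default to 1.

### Separation probability

With both enantiomers' RT bands [q10, q90] (RTv divided by flow rate),

    S_p = 1 − max(0, RT90_min − RT10_max) / (RT90_max − RT10_min),

i.e. one minus the overlap fraction of the union span — equal to direct
interval arithmetic, which the tests verify exactly on 10,000 random
band pairs. S_p ∈ [0, 1]; disjoint bands give 1, identical bands 0; it
is symmetric in the pair and invariant to positive rescaling of all
four extremes. The separable call uses strict S_p > 0.38 (a practical
calibration, kept as a configurable default). When one band strictly
contains the other the formula is applied literally. Degenerate inputs:
an inverted band (q10 > q90) raises; a zero-width band warns and
follows the interval limit; four equal extremes warn and return 0
(total collapse = complete overlap). Condition ranking sorts by S_p
descending with ties broken toward the smaller mean predicted RT.

## Synthetic generator

The generator emits enantiomer pairs from ~50 hand-curated chiral
scaffolds (α-substituted acids, alcohols, amines; exactly one assigned
stereocenter each; the mirror image is the inverted chiral tag). The
true target is

    RTv = 22 + [3, 2, 2, −1.5, 1]·z(descriptors) + column + eluent + s·δ

with column = 3·substrate + 2·connection + 0.5·(packing−5), eluent =
−8·(proportion − 0.1) (stronger eluent elutes faster), s = ±1 by
handedness, clipped at the dead-time bound 2. Defaults: δ = 1.5
min·mL/min (a realistic enantiomer RTv gap on these CSPs, ~1–2 min at
typical flows), noise ε = 0.1 per ŷ = y + ε·std(y)·N(0,1) (the level
at which robustness is probed), proportions in [0.02, 0.2] and flows in
[0.5, 1.0] mL/min — typical normal-phase screening ranges. Records are
deterministic per seed, byte-identical on re-generation.

What it emulates: flow-invariant RTv, a handedness-linked offset
visible only through chiral features, column- and eluent-dependent
retention, homoscedastic measurement noise with analytically known
10–90 band (80% coverage by construction). What it does not: real
retention physics, conformer-dependent effects, heteroscedastic or
laboratory-correlated noise, and the structural diversity of literature
data — so passing recovery tests demonstrates that the pipeline can
learn its assumed structure, not that it matches any real column.

## Desk-scale experiment sizes

The recovery experiment trains the reduced network (2 layers, width 32)
for 200 epochs on 2,000 generator records (1,000 pairs, four columns),
split 90/5/5 pair-aware; it reaches R² ≈ 0.9 and band coverage ≈ 86%
on held-out records in about a minute on one CPU. These sizes are the
package's standing desk-scale configuration; full-scale defaults (K=5,
width 128, 1500 epochs) remain available. The three-output head bias is
initialized at the training targets' empirical 10%/mean/90% so that
short runs refine structure rather than hunting the output scale; with
that initialization the squared-error and pinball terms converge
together.

## Splitting and evaluation

The default `keep_pairs_together` policy allocates whole enantiomer
pairs to folds, preventing mirror-image leakage between train and test;
`record_level` reproduces a literal 90/5/5 row split (exact sizes).
Published per-column benchmarks rest on unpublished split seeds, so
literature metrics are reference points, not reproduction targets. Metrics: MAE
and R² on RTv, median relative error as a fraction (percent in
reports). Tanimoto similarity grouping (2048-bit Morgan radius 2 by
default, MACCS optional; group sizes are only comparable within one
fingerprint type) stratifies test molecules by their nearest training
neighbor; on the generator, structurally nearer scaffolds have nearer
targets, which is the premise of similarity-stratified evaluation.

## Known limitations

* Descriptor variants and CSP vectors are configuration, not literature
  values; swapping them changes multi-column models.
* The report parser's pattern table covers one common reporting dialect;
  real supplementary-information corpora need per-journal patterns
  (they are configurable).
* Conformers are single ETKDGv3 embeddings; no ensemble averaging.
  Molecules with unassigned stereocenters pass through untouched.
* The numpy core is CPU-only and single-threaded beyond BLAS; the
  full-scale configuration (25k records, width 128) is hours-scale.
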