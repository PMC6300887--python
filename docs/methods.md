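# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `neuralfp`, and what the synthetic benchmarks do and do
not demonstrate.

## Molecular representation

Molecules are heavy-atom graphs parsed by RDKit and renumbered by canonical
atom rank, so any SMILES alias of a molecule produces bit-identical
features. Atom rows concatenate one-hot blocks: element (default vocabulary
C, N, O, S, F, Cl, Br, I, P, B, Si), heavy-atom degree 0–5, attached
hydrogens 0–4, implicit valence 0–5, plus an aromaticity flag (d₁ = 29).
Values outside these ranges raise rather than clip: silently bucketing an
exotic atom would corrupt the featurization of exactly the inputs a
structural-alert tool most needs to flag. Bond rows are one-hot order
(single/double/triple/aromatic) plus conjugation and ring flags. Hydrogens
are implicit, matching the circular-fingerprint conventions the raw
features mimic. Multi-fragment inputs (salts) are rejected by default; a
`strip_salts` option keeps the largest fragment.

## Fingerprint network

R stacked convolution layers (default R = 4, i.e. substructures up to
radius 4) with one dense filter per atom degree 1–5 at each layer.
Degree-0 atoms (single-atom molecules) reuse the degree-1 filter with a
zero neighbor block. Neighbor order inside the concatenation is ascending
canonical atom index; note that exact invariance to *neighbor* permutation
is not a property of concatenation + dense filter — invariance to input
atom ordering is instead guaranteed by canonical renumbering, and the test
suite checks it to 1e-10.

Writes: at every level 0..R (level 0 = raw features, radius-0
substructures) each atom writes softmax(x·F_l) over the K bits (default
K = 50). Including level 0 means the back-trace can attribute a bit to
radius-0 through radius-R substructures, and fixes the conservation law
sum(z) = n_atoms·(R+1), which the tests verify to 1e-9 under arbitrary
weights. The write levels are configurable (`write_levels`).

The smoothing nonlinearity is tanh (relu available). Filters are drawn
from a normal scaled by 1/sqrt(fan-in); biases start at zero; everything
is reproducible from a seed. The forward/backward passes are hand-written
reverse-mode NumPy over molecules packed into degree-grouped flat arrays,
so a minibatch is a handful of dense matrix products; analytic gradients
agree with central finite differences to better than 1e-6 in practice
(the tests demand 1e-4).

## Per-ADR classifier

Each ADR gets its own fingerprint network and head, trained jointly —
labels shape the fingerprint. The head is logistic, optionally with one
hidden layer (default 100 units, relu) whose pre-activations are
batch-normalized (momentum 0.9; inference uses running statistics, making
prediction deterministic). The loss is

  mean cross-entropy + λ₁‖w‖² + λ₂ Σᵢ‖zᵢ‖²,

defaults λ₁ = 1e-4 (weight shrinkage) and λ₂ = 1e-2. Because sum(z) is
conserved, the λ₂ penalty cannot shrink a fingerprint's mass — it pushes
the attention writes to spread over bits, acting as an entropy-like
regularizer on the attention rather than a sparsifier of predictions.
Optimization is ADAM (lr 1e-3) on minibatches of 100 for 50 epochs;
epochs and learning rate are package defaults chosen from training-loss
convergence on the synthetic corpus. No class weighting or resampling is
applied; the label-metric threshold defaults to 0.5. Cross-validation is
stratified per ADR with a fixed seed; ADRs with fewer positives than folds
fall back to fewer folds with a warning. A grid helper selects
hyper-parameters by cross-validated F1, breaking ties toward stronger
regularization.

## Back-tracing and bit importance

For a chosen bit, the per-(atom, level) softmax write values from the
forward pass locate where the bit is written; the induced subgraph within
`level` bonds of the atom is emitted as a canonical SMARTS (elements,
aromaticity and bond orders kept; charges and stereochemistry dropped —
the raw features contain neither, so patterns cannot be more specific than
the representation). Every emitted pattern substructure-matches its source
molecule by construction.

Bit importance for a linear head is |w|. For a hidden-layer head it is the
first-order path sum |Σ_h W1[k,h]·(γ_h/σ_h)·W2[h]| with the batch-norm
scale folded in. On a freshly constructed head this tracks a zero-one
ablation oracle (Spearman ρ ≥ 0.8, tested); on a heavily trained head with
saturated logits any linearization degrades (top-10 overlap with ablation
was ~6/10 in our checks), which is acceptable here because the downstream
association statistics — not the raw ranking — decide which substructures
are reported.

## Association statistics

Substructure presence is a binary SMARTS match (≥ 1 occurrence). For the
2×2 table the test is Pearson's χ² with Yates continuity correction
(df = 1), which reproduces the reference case-study p-value of 1.20×10⁻²²
for the table (3, 15, 2, 1410); without the correction that table gives
≈3.8×10⁻³², so the correction choice is observable and is kept on by
default (switchable). The odds ratio uses Haldane–Anscombe +0.5 on all
cells only when a cell is zero, and only for the OR — the χ² statistic is
left untouched. Empty margins give p = 1 with a warning. Significance is
raw p ≤ 0.05 by default; Benjamini–Hochberg FDR is available behind a
flag, since the default protocol applies no multiplicity control.
Fisher's exact test is available as a cross-check, not the default.

## Biclustering

Significant substructure–ADR pairs form a binary bipartite adjacency.
Cheng–Church biclustering minimizes the mean squared residue
H(I,J) = mean (a_ij − rowmean − colmean + mean)², via multiple node
deletion (drop rows/cols with mean residue > α·H, α = 1.2), single node
deletion until H ≤ δ (δ = 0.05 for binary matrices), then node addition;
each found region is masked with Bernoulli(0.5) draws before the next
round (the binary analogue of uniform-range masking), all deterministic
from a seed.

One degeneracy matters on binary adjacencies: MSR cannot distinguish an
all-ones block from the same block padded with all-zero rows or columns —
both are perfectly additive (H ≈ 0) — so the raw low-residue bicluster is
typically a block/background mixture, and on sparse matrices the first
find is the background itself. Because the objects of interest here are
bicliques (dense blocks), each found region is refined against the
original matrix: rows/columns with in-bicluster mean < 0.5 are trimmed,
then any row/column dense against the core is re-added; regions whose core
density stays below `min_density` (default 0.5) are treated as trivial
background — masked, but not reported. With this refinement, two planted
8×6 blocks under 5% flip noise are recovered at Jaccard ≥ 0.89 on 10/10
seeds; without it recovery stalls around Jaccard 0.3–0.6. Setting
`min_density=None` restores the raw behaviour. Reported biclusters are
sorted by area, and each stored residue is recomputed on the original
(unmasked) matrix.

## Evaluation protocol

Three views over an N×M label matrix and score matrix: global (flattened),
column-wise (per ADR) and row-wise (per drug), the latter reporting
retrieval metrics including precision-at-K (default K = 10, ties broken by
ADR index with a stable sort). Averages are unweighted (macro). Undefined
quantities follow fixed conventions: precision/recall/F1 are 0 when their
denominator is 0; columns with a single label class are excluded from AUC
averaging and counted in the report rather than imputed. All metrics are
checked exactly against exhaustive loop oracles.

## Synthetic corpus

The generator emulates a SIDER-like study: valence-correct molecules built
from weighted scaffolds (benzene .30, pyridine .20, furan .20, cyclohexane
.10, C3–C6 chains .05 each — aromatic scaffolds upweighted) with 0–3
single-bonded substituents (F .25, Cl .20, Br .15, OH, NH₂, CHO, OCH₃ .10
each) at open carbon positions. Labels follow planted causal motifs —
halogen or heteroatom substituents on an aromatic carbon, one per ADR
(default map: cF, cCl, cBr, cN, cO) — with P(label=1 | motif) = 0.9 and
P(label=1 | no motif) = 0.05. Under these weights each motif is present in
roughly 25–30% of molecules, so a 400-molecule corpus yields ~100 motif
positives and well-populated contingency tables. Defaults: 400 molecules,
5 ADRs; everything deterministic from one seed.

What the benchmark shows — and does not. Because labels depend on the
molecule only through motif presence, the Bayes-optimal score is the motif
indicator, whose asymptotic AUC under these noise rates is ≈0.92; measured
held-out AUCs of 0.88–0.95 across seeds therefore mean the model sits at
or near the information ceiling, not that it is mediocre. Passing the
planted-motif tests demonstrates that end-to-end training, attention
back-tracing and the association statistics jointly recover a known causal
substructure from noisy labels. It does not demonstrate performance on
real pharmacovigilance data: the generator has no molecule-size or
scaffold diversity matching real drugs, no correlated ADRs, no
confounding between co-occurring substituents, and its label noise is
independent Bernoulli — all far kinder than drug-label mining. Results on
real SIDER-scale data additionally depend on the ADR prevalence filter
(keep ADRs with > 10 positive drugs) applied before modeling.

## Numerical conventions and degenerate inputs

Softmax is computed with max-subtraction; the logistic loss uses the
log1p(exp(−|x|)) form; probabilities are produced by a numerically stable
sigmoid. Non-finite activations or losses abort immediately with a
diagnostic rather than propagate. Ties are deterministic everywhere: bit
ranking by (−|importance|, bit index), substructure candidates by
(−activation, molecule, atom, level), P@K by ADR index. Degenerate label
vectors (single class) are allowed in the loss (logged) but rejected for
training (< 2 positives or negatives). Checkpoints are a single zip
archive of arrays keyed `H.l.deg`, `F.l`, `b.l` plus a JSON header, and
round-trip bit-exactly.

## Known limitations

- Neighbor-order sensitivity: two molecules can in principle place
  equivalent neighborhoods in different concatenation orders; canonical
  renumbering makes this deterministic but not symmetric.
- The λ₂ penalty interacts with mass conservation as described above; it
  does not produce literally sparse fingerprints.
- Linearized bit importance degrades on saturated heads (see above).
- Cheng–Church with biclique refinement targets dense blocks; coherent
  but non-dense (checkerboard-like) biclusters are out of scope.
- Per-ADR training scales linearly in the number of ADRs. A
  shared-fingerprint multi-task mode would amortize that cost but would
  entangle the per-ADR attributions, so it is not implemented; each ADR's
  model and back-trace are self-contained.
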