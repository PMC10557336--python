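# Methods

This note documents the model, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## Graph construction

A complex is two heavy-atom clouds. Hydrogens are excluded throughout:
the 9-element one-hot (C, N, O, S, P, I, Cl, B, F for ligands; C, N, O, S
for proteins) cannot represent them, and heavy-atom graphs are standard
for this task. Atoms with out-of-vocabulary elements (metal ions,
selenium, …) are dropped by the readers with a logged warning rather than
raising — real PDB files contain them and the type system cannot.

The interaction graph keeps all ligand atoms plus protein atoms within
d = 5 Å of at least one ligand atom, with directed edges both ways between
every retained pair at distance ≤ d. Intramolecular edges are kept: only
the interaction matrix and the pairwise pooling head are restricted to
intermolecular pairs. Self-edges are excluded (distance-0 loops carry no
distance or angle information). Distinct atoms closer than 10⁻³ Å are
rejected as invalid geometry, which guards every later division by a
distance or vector norm.

The interaction matrix Z counts (protein element, ligand element) pairs at
distance strictly below d_ρ = 12 Å — the Heaviside convention Θ(d_ρ − d)
with Θ(0) = 0 — normalised to sum to 1; it is all-zero when no pair
qualifies. The strict inequality differs from a "≤" reading only on a
measure-zero set of geometries.

## Curvature

Forman–Ricci curvature uses the clique-complex form limited to triangles:
4 − deg(a₁) − deg(a₂) + 3Δ, where Δ is counted by exact common-neighbour
enumeration; the triangle-free form is the Δ = 0 special case. Values are
integers on simple graphs.

Ollivier–Ricci curvature is 1 − W/d with idleness α (default 0.5, the
standard choice in the ORC literature; configurable). The graph distance
d is the unweighted hop count by default (a distance-weighted variant is
available), and W is solved exactly as a transportation linear program
(HiGHS) over the two lazy random-walk measures. The test suite
cross-checks this against an independent route: masses are scaled to exact
integers with rational arithmetic and the transport problem is solved as
an integer min-cost flow (network simplex), so agreement to 1e-8 is
evidence both solvers are correct.

The multiscale profile evaluates the curvature of each edge inside the
nested subgraphs obtained by keeping edges of weight ≤ l_k, for the 50
thresholds l_k = 0.1·k Å (k = 0..49); entries are exactly 0 while the edge
is absent. Curvature is computed on the undirected simple graph
underlying the directed interaction graph and both orientations share one
profile, since both curvature definitions are stated for undirected
edges. Note that with a 5 Å cutoff, edges longer than 4.9 Å never enter
any filtration subgraph and carry an all-zero profile; they still carry
distance information through the curvature block's distance one-hot.

## The network

The curvature block embeds the 50-dim profile (dense layer, leaky ReLU,
softmax over the embedding components — the softmax normalises the single
edge's embedding, not a distribution over edges) and the distance
(one-hot of ⌊d⌋ over ⌊cutoff⌋+1 = 6 bins, dense layer), then fuses both
with a dense + ReLU into the edge context crt_ij.

Angle-domain attention: line-graph arcs e_ki → e_ij (k ≠ j; the
backtracking arc k = j is excluded, as in directional message passing,
toggleable) are labelled with the angle at the shared atom and binned into
N = 6 half-open domains (180(q−1)/N, 180q/N], with a numerically exact 0°
assigned to domain 1. Within each domain the attention coefficient is a
tanh *vector* (one coefficient per feature), Hadamard-combined with the
neighbouring edge state; each domain adds the residual edge state once and
the N domain blocks are concatenated. The edge2node head count defaults
to 8; 4 is one configuration flag away.

PiPool pools the final representations of directed protein→ligand edges
into the 4×9 element-pair cells and normalises cell scores with a softmax,
so Z̃ is always a probability table; with no intermolecular edges all
scores are 0 and Z̃ is uniform. The affinity head sum-pools node states
into a graph embedding and applies a two-hidden-layer MLP (128→64→1 at
default width, scaled with the configuration otherwise).

The loss is ℒ_a + λℒ_b with ℒ_a the summed absolute affinity error, ℒ_b
the summed L2 norm of the flattened interaction-matrix difference (L1
selectable), and λ = 1.75.

Implementation: the whole network runs on a small reverse-mode autodiff
engine over numpy arrays written for this package (the environment's deep
learning needs are modest: dense layers, gathers, segment sums). Message
passing is expressed with precomputed scatter plans (argsort +
`np.add.reduceat`) so repeated passes over a fixed graph avoid
`np.add.at`. Gradients of every layer are verified against central
differences in the test suite. Initialization is Glorot-uniform for
matrices and zeros for biases under a seeded generator; dropout (0.2) is
applied to node and edge representations after each attention layer in
training mode only; the optimizer is Adam (lr 0.001, batch 32), with
validation-RMSE model selection and early stopping (patience 30) in the
epoch-based loop.

## Ablation variants

* `no-curvature` removes crt_ij from both the edge construction and the
  attention logits; the forward pass is then bit-independent of the
  curvature profiles (verified by perturbing them).
* `vanilla-gat` replaces the tanh attention vector in edge2edge with
  softmax-normalised scalar attention (leaky-ReLU logits).
* `scalar-adaptive` keeps the tanh form but collapses the vector to a
  scalar per neighbour.

## Synthetic complexes

The generator emulates only the geometry the model consumes: a ligand
cloud uniform in a box (default 10 atoms, 6 Å box), a protein shell
(default 40 atoms) in which each atom is placed in contact range (< 5 Å of
the ligand) with probability `contact_fraction` (default 0.5) and
otherwise strictly outside it, a 1.2 Å minimum separation enforced by
rejection, and element/descriptor draws from fixed C-dominant frequencies.
Labels are y = w₁·(# intermolecular pairs < 4 Å) + w₂·(mean inverse
intermolecular distance) + 𝒩(0, noise_sd), clipped to the pK_a-like range
[2, 12]; the default weights (0.08, 10.0) put labels around 7 ± 1.3, and
noise_sd defaults to 0.3 (≈ experimental reproducibility on that scale),
with 0 used where tests need exact geometric labels.

What this shows — and does not: passing tests demonstrate that the
architecture is implemented correctly (oracle equivalence, invariances,
identities) and that it can learn a geometry-determined signal end to end.
The generator has no bonds, no secondary structure, no chemistry beyond
element frequencies, so nothing here measures accuracy on real
protein–ligand complexes; benchmark-scale training on PDBbind-style data
is out of scope.

## Problem sizes

Experiments in the test suite and `scripts/acceptance.py` use a desk-scale
configuration chosen as this package's standard CPU setting: 2 attention
layers, 2 heads, node/edge/curvature embeddings 32/16/16, MLP 64→32→1,
6 angle domains, trained for 500 Adam steps on 50 complexes. The
full-scale configuration (4 layers, 8 heads, 128-dim embeddings)
remains the library default.

## Known limitations

* Ollivier curvature solves one LP per edge per filtration level; it is
  the right tool for correctness, not for throughput. Forman is the
  default for profiles for the same reason.
* The readers take structures as given: no protonation, no bond-order
  perception beyond the file's own records, no pocket detection beyond the
  distance rule.
* Training is single-threaded numpy; it is sized for toy data, not for
  benchmark datasets.
* A single cutoff d applies to intra- and intermolecular edges alike; the
  definitions place no origin restriction on the edge set.
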