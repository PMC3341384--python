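# Methods

`regsnap` identifies regulatory modules from two inputs: a gene × time-point
expression matrix and a directed network of documented regulatory
associations. It proceeds in three stages — temporal biclustering,
per-time-point transcription-factor (TF) prioritization, and snapshot
rendering — each usable on its own through the library API or the CLI.

## Temporal biclustering (CCC-biclusters)

**Model.** Expression values M′ are converted to a transition matrix M over
Σ = {D, N, U}: column c of M encodes whether a gene's expression falls
(`D`), stays (`N`) or rises (`U`) between time points c and c+1, relative
to a threshold τ. A *CCC-bicluster* B = (I, J) is a set of genes I sharing
an identical symbol pattern over a contiguous interval J of transition
columns; it is *maximal* when no gene can be added (row-maximality) and
extending J one column left or right strictly shrinks I
(left-/right-maximality). Single-gene patterns are discarded.

**Algorithm.** Each symbol is stamped with its column index, so a pattern
starting with (σ, c) can only occur at column c. Rows of the stamped matrix,
each closed by a unique terminator, are inserted into one generalized
suffix tree (Ukkonen's online construction over token sequences; amortized
linear in the total token count). Every internal node is then exactly one
right- and row-maximal CCC-bicluster with ≥ 2 rows: its genes are the rows
of the leaves below it (an Euler-tour leaf ordering makes this a contiguous
array slice), its interval follows from the first token's stamp and the
node's token depth. Left-maximality is decided from suffix links: a node
for pattern P is reported iff every node αP linking into it covers strictly
fewer leaves — an incoming link with an equal leaf count means every
occurrence of P is preceded by the same symbol α, so P extends left without
losing genes and is not maximal. The enumeration is cross-validated
exactly against an exhaustive-search oracle on random instances, and
measured to scale linearly in the number of genes.

**Parameters.** τ ≥ 0 (default 0): with τ = 0 any strict increase is `U`,
any strict decrease `D`, an exact tie `N`. Under τ = 0 and continuous
noise, ties are rare in background rows, which makes `N` the most
informative symbol; plateau-containing patterns are therefore much easier
to separate from chance than pure up/down patterns. Rows are normalized
per gene to zero mean and unit standard deviation (sample convention,
divisor n−1, configurable); normalization rescales but never re-signs
differences, so it commutes with τ = 0 discretization. Constant rows carry
no trend and are dropped.

## Bicluster significance and filtering

Under a null model with independent columns and per-column empirical symbol
frequencies f_c(σ), a random gene matches pattern P on columns J with
probability p(P) = ∏_{c∈J} f_c(P_c), and the pattern p-value is the
binomial upper tail P(X ≥ |I|), X ~ Binomial(n_genes, p(P)), evaluated via
the survival function. The independence model is the simplest one
consistent with "a matrix of equal size"; it is validated against a
Monte-Carlo simulation of the null and exposed as a replaceable component
(a first-order Markov chain over columns is a natural refinement).
P-values are Bonferroni-corrected by the number of enumerated maximal
biclusters — the family of tests actually performed. Filtering removes
biclusters with corrected p above 0.01, fewer than a minimum number of
genes, or too short a time span, then greedily scans the rest in ascending
corrected-p order and discards any bicluster whose cell-wise Jaccard
similarity (on (gene, column) cells) with an already-kept one exceeds 0.25
— of two overlapping biclusters the more significant survives.

Annotation enrichment per module uses the upper-tail hypergeometric test
(population = all analyzed genes by default, configurable), Bonferroni
corrected over tested terms; terms with corrected p < 0.01 are flagged
highly significant.

## TF prioritization (heat-kernel personalized ranking)

The network N = (V, E) has weighted directed edges from regulators to
targets; the regulator set R is derived as the vertices with outgoing
edges. The random-walk matrix W normalizes each row by the vertex's total
outgoing weight; vertices without outgoing edges get zero rows, so mass
reaching them decays (no teleportation — rankings compare regulator scores,
for which uniform decay is harmless).

For a module at time point ℓ, the preference vector p₀ places the
*absolute* expression value |e(u)| at ℓ on every module gene u present in
the network (scores are additive, so signs would cancel mass; a
clip-negatives mode exists for exploration). Genes absent from the network
are excluded with a warning; a time point with no usable seed is skipped.
Mass is diffused over the *transposed* network — regulations traversed in
reverse, so a target's mass splits among its regulators in proportion to
the incoming regulation weights (W is recomputed on the transposed graph) —
with the discrete heat-kernel update

    p ← p (I − (t/Z)(I − W)),   repeated Z times,

which converges to the heat-kernel rank p₀·exp(−t(I−W)) as Z → ∞. The
diffusion coefficient t controls the reach of the walk (small t favors
proximal regulators); defaults t = 0.25, Z = 100. Scores restricted to R,
sorted descending with lexicographic tie-breaking, give one TF ranking per
time point spanned by the module (transition interval [c₁, c₂] covers time
points c₁ … c₂+1).

**Numerical behaviour.** The update is exactly linear (homogeneous) in p₀,
leaves p₀ unchanged at t = 0, keeps entries non-negative for t/Z ≤ 1, and
conserves total mass when W has no zero rows. Its deviation from the exact
exponential has leading term (t²/2Z)·‖p₀ L² e^{−tL}‖ — about 3·10⁻⁴ in L1
at the defaults for a unit-mass seed — which is orders of magnitude below
the score gaps that determine ranks; rankings are insensitive to Z beyond
the default.

## Snapshots

A snapshot shows one module at one time point as a double semicircle: TFs
on the outer top arc, left to right in decreasing score (top radius 1.25×
the bottom radius; nodes evenly spaced by angle), module targets on the
bottom arc, and regulation edges as cubic arcs between them. Complexity is
controlled by keeping the top-k regulators (default 30) or a score
threshold. Orange arcs mark "regulates" relations; the incoming edges of an
explicitly highlighted node set are drawn green ("regulated by"). Output is
plain SVG 1.1 text with fixed coordinate rounding, so identical inputs give
byte-identical files; a rank-trajectory TSV (TF × time matrix of ranks)
accompanies each series.

## Synthetic data

The generator emulates exactly the structure the method assumes, so the
whole pipeline is testable without external data. Planted expression
modules follow a shared cumulative-sum trajectory whose steps are
±(τ + margin) for U/D and 0 for N, plus a per-gene offset and Gaussian
noise of standard deviation `noise_sd`; the margin defaults to
max(3·noise_sd, 0.5) so U/D symbols survive discretization with high
probability (N symbols additionally need τ > ~3·noise_sd, since exact ties
break under any noise at τ = 0 — noiseless instances preserve them
exactly). Outside the planted window each planted gene continues as a
unit-variance random walk from the window's endpoints, so the transitions
adjacent to the window are independent fair coin flips per gene; without
this the window's endpoint displacement would bias all module genes toward
the same adjacent-column symbol and leak the module into columns where
nothing was planted. Background genes are i.i.d. standard normal. Planted
networks give one dominant TF an edge to every module gene, with background
TF→target edges appearing independently with probability `background_p`
and optionally capped to a fraction of the module, which guarantees the
planted TF's identifiability by construction. All randomness flows from
one explicit seed.

The default end-to-end study plants two 50-gene modules (with plateau-
containing patterns, spanning 4 and 5 transition columns) among 250 genes
over 8 time points, with a 12-TF network at background 0.05 capped at 20%
module coverage — module size follows the convention that modules under 50
genes are too small to be biologically interesting, and the matrix keeps
enumeration plus diffusion comfortably fast on one CPU. What passing these
tests shows is that the machinery recovers exactly what was planted under
its own assumptions; it does not show robustness to the texture of real
data (correlated genes, heteroscedastic noise, missing-at-random patterns,
evidence-biased network coverage).

## Design choices and known limitations

- **Left-maximality tie case.** A node whose incoming suffix links all
  carry strictly fewer leaves is reported; equal-leaf sources suppress the
  node. This is the only reading consistent with the definition of
  left-maximality, and the one the exhaustive oracle confirms.
- **Diffusion normalization.** W is recomputed on the transposed graph
  (a target's mass splits across its regulators by incoming weight),
  rather than transposing the forward-walk W; the alternative would weight
  regulators by their out-degree on the forward graph.
- **Overlap filter is greedy.** Scanning ascending by corrected p is
  order-dependent: a chance one-column extension of a large subset of a
  true module occasionally (≈1% per module boundary on synthetic data)
  scores as more significant under the independence null and displaces the
  exact module, capping its recovered Jaccard near 0.6. A Markov-chain
  null or a containment-aware filter would remove most such cases.
- **Zero-frequency symbols** give pattern probability 0 and p-value 0;
  this is logged, not treated as an error.
- **Dangling-vertex decay** means total mass is not conserved on networks
  with sink vertices; scores remain comparable within a ranking because
  every ranking uses the same walk.
- **Determinism.** All orderings (vertex order, bicluster output order,
  tie-breaks, SVG coordinates) are fixed functions of the input; two runs
  with the same inputs and configuration produce byte-identical outputs.
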