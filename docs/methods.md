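# Methods

## Model and assumptions

The package treats a condition as a weighted undirected gene network (an
unsigned co-expression adjacency, `a_ij = |cor(x_i, x_j)|^β` thresholded at
a floor) plus a disjoint module partition supplied by the user.  Module
detection itself is out of scope: partitions are inputs, and the synthetic
generator plants them.  All pair scoring happens on the thresholded
adjacency, not on a topological-overlap transform.

Coordination between two modules is decomposed into a direct channel (edges
spanning the pair, summarized by SW) and an indirect channel (external genes
touching both modules, summarized by PS over 3-node paths and by the
degree-centered consistency score CT).  The decomposition assumes the
network weights are comparable across the condition — SW, PS and CT are all
sums of weights or weight ratios — which holds when every condition's
adjacency is built with the same correlation measure and floor.

Three structural conventions are fixed where the construction is open:

* PS mediators must lie outside both modules; the outset and end are in
  different (disjoint) modules, so paths never degenerate; an edge between
  outset and end is irrelevant (paths, not triangles).  Per mediator the
  contribution factorizes as `(Σ_o W_mo)(Σ_e W_me) / W_m²`, and each single
  path term is bounded by ¼ since the two probabilities sum to at most 1.
* CT sums over genes outside both modules (shared-partner semantics); the
  token coupling a gene's links to the modules is read as
  `min(CM_x − (S/C)·CL, CM_y − (T/C)·CL) · (CM_x·CM_y / CL) · W`, i.e. the
  null-centered minimum times the link product over degree, scaled by the
  gene's weighted degree.  Genes with no link into one of the modules
  contribute zero through the multiplicative factor.
* Isolated genes stay in the network: the total gene count `C` and the gene
  set of CT range over all genes, connected or not.  Because plain edge
  lists cannot carry isolated nodes, condition loading re-attaches partition
  genes missing from the edge list as isolated nodes.

## Screening

Direct and indirect coordination are screened before integration:

* SW: upper-tail hypergeometric test on the pair's cross-edge count.  Per
  pair, x = observed cross edges and n = |M_x|·|M_y| possible ones; the
  population is condition-wide: M = all observed inter-module edges, N = all
  possible cross-module gene pairs, summed over **all** module pairs (not
  only the scored ones) — a pair is enriched relative to the whole map.
  Unordered gene pairs throughout.
* PS: same test with node counts — x = observed mediators, n = external
  genes adjacent to at least one of the two modules, M/N the corresponding
  condition-wide totals.
* CT: fixed cutoff, valid when CT > 10 strictly (a pair sitting exactly on
  the cutoff is not valid).

Validity requires p < 0.05 on the raw p-values; no multiplicity correction
is applied across pairs.  A pair enters the scored table when it has at
least one cross edge or one shared external partner — mediator-only pairs
are scorable, which is what lets the indirect statistics supply
relationships beyond those visible to SW.

## Integration and calibration

SW and CT live on different scales, so both are min-max normalized across
the condition's scored pairs (a constant column maps to all zeros to avoid
0/0).  `IMCC1 = α·SW′ + β·CT′` with `α + β = 1`, `ρ = α/β`;
`IMCC2 = SW + PS` needs no weighting since both terms are sums of weights.
The final score is emitted for pairs passing **both** the SW and CT screens
(a single-valid fallback exists behind `ScreeningConfig.require_both=False`
for sensitivity analysis) and, at the calibrated ρ = 1, equals
`SW′ + CT′` — twice the ρ = 1 blend, hence rank-identical to it.  Ties in
the final ranking break by raw SW, then lexicographic pair label, so output
order is deterministic.

ρ is calibrated against module annotations: for each grid value
(1/10 … 10/1) the Jaccard similarity of the two modules' category sets is
fit against the integrated score with the four standard curve-estimation
models (linear, logarithmic, power, exponential; the nonlinear ones fit in
their linearized form, R² evaluated on the original y scale).  Outliers are
removed in one pass by externally studentized residual > 3 under the current
model, refusing when fewer than three points would remain — the removal rule
is this package's choice.  The best ρ maximizes the logarithmic-model R²,
ties resolving toward ρ = 1.  IMASP (mean gene-level shortest-path hop count
between two modules' members, unreachable pairs excluded) provides a
topological cross-check; a weighted variant with edge length 1/weight sits
behind a flag, and the IMASP-vs-score comparison fits IMASP on log2(score).

## Modular map and rewiring

Map nodes are the partition's modules (isolated modules allowed); edges
carry the final IMCC and exist only where it is positive.  The topology
table uses unweighted conventions: mean degree, density 2E/(n(n−1)),
characteristic path length and diameter over connected pairs, mean
normalized betweenness, mean local clustering, Freeman degree centralization
`Σ(k_max − k_i)/((n−1)(n−2))` (the "centrality" column; maximal 1 on stars,
0 on cliques, matching a core–periphery reading; a betweenness-
centralization variant is available), and mean edge weight.

Score-distribution shifts are tested on −log2-transformed final scores
binned into four right-closed intervals; default edges are the reference
condition's quartiles, and explicit edges are accepted.  The 2×4 chi-square
uses counts without continuity correction, merging a column with the nearest
neighbor when its expected count falls below 1.  PCA of the per-condition
relative frequencies is centered, unscaled, with each component's sign fixed
so its largest-magnitude loading is positive.  The architecture distance
min-max normalizes (avg_weight, density, centrality) across conditions and
takes the Euclidean distance to a reference; zero distance occurs exactly
when all three normalized indexes coincide.

## Connectors, PMP and dissociation

Betweenness connectors are the top ⌈0.10·n⌉ modules by normalized
betweenness, ties at the cut included (degenerate all-equal maps are
warned).  VRCD deletes each module in turn: Δs and Δt are the relative
changes of characteristic path length and density, η = Δs/Δt, and modules
with η above twice the signed mean of the defined η values are called.
Modules with Δt = 0, or whose removal leaves no connected pair, have
undefined η and are excluded from the mean; when every defined η is equal —
the clique-like case — the set is empty.  After deletion, path length is
computed over the pairs that remain connected; this convention is stated
rather than inherited.  Weight connectors are modules incident to a map edge
heavier than 0.1.  The consensus is the three-way intersection; the PMP is
the consensus pair joined by the heaviest edge, and is reported as absent
rather than forced when no such edge exists.

Tracing maps each PMP gene of the reference partition into another
condition's partition; genes absent there land under a reserved "lost"
label, excluded from the landing count, and dispersion fractions are taken
over placed genes (they sum to 1).  `DR = (n_B/n_A) · (N_A/N_B)` corrects
the landing-module ratio by the conditions' total module counts and is
invariant under jointly scaling `n_B` and `N_B`.

## Synthetic data

The generator emulates a focused co-expression study: 374 genes, tens of
modules, with planted inter-module coordination.  Intra-module edges are
dense with weights uniform on (0.4, 0.9); a planted pair of strength s gets
`round(s · min(S,T))` cross edges with weights scaled by s, and
`round(4·s)` mediator genes wired to three genes in each module.  Mediators
live in a reserved unassigned pool so planting a pair never pollutes
third-party pairs.  Expression matrices are block-Gaussian (one latent
factor per module plus noise; 50 samples and noise SD 0.5 by default), sized
so soft-threshold adjacency recovers the planted blocks.  Annotation sets
are drawn from a 200-category universe (8 per module) with sharing forced in
proportion to planted strength, so Jaccard similarity rises with
coordination.  Condition rewiring has an aggregate mode (uniform cross-edge
addition toward a clique-like gene network) and a disperse mode (a chosen
pair's genes scattered round-robin over k landing modules, its direct edges
removed, surviving cross edges upweighted), both emitting ground truth.

What the generator does **not** emulate: microarray noise physics,
correlation structure between modules' latent factors, hub-degree
heterogeneity inside modules, or annotation databases' hierarchical
structure.  Passing tests therefore demonstrate that the statistics recover
planted orderings and ground truth under clean modular structure, not that
any particular biological dataset will calibrate at ρ = 1.

A deliberate subtlety the synthetic experiments expose: because the SW
screen is an enrichment test, adding cross edges *uniformly* between all
pairs (aggregate mode at high intensity) flattens the signal and can thin
the screened modular map even as the gene network densifies.  Enrichment
against the condition-wide background is relative by construction.

## Numerical choices and problem sizes

Hypergeometric tails come from the survival function with a log-space
fallback against underflow; x = 0 returns exactly 1.  Boundary values in
binning fall into the lower (right-closed) interval.  All generators thread
a single integer seed through one RNG stream per call; writers emit
stable-sorted rows, so equal seeds give byte-identical files.  Tests and
examples run at the study scale (374 genes, 15–20 modules, ≤ 50 samples),
where the full pipeline completes in well under a second per condition;
oracle suites use 8–18-node fixtures where exhaustive enumeration is exact.

## Known limitations

* The hypergeometric parameterizations treat edges (and mediators) as
  exchangeable draws, ignoring degree heterogeneity; a degree-preserving
  null would be stricter.
* CT's cutoff (10) is a fixed convention, not a calibrated quantity; its
  scale depends on network size and weight distribution.
* VRCD's η is sign-sensitive: in maps where deleting a hub lengthens the
  surviving paths rather than disconnecting them, hubs can score negative η
  and escape the 2×-mean cutoff.  The three-method consensus mitigates this.
* Min-max normalization makes the final score condition-relative; absolute
  IMCC values are not comparable across conditions, only rankings and
  distributional summaries are.
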