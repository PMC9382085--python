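# Methods

This note documents the models and procedures `netpharm` implements, the
conventions chosen where several are in circulation, what the synthetic
data generator does and does not emulate, and the package's known
limitations.

## Pipeline model

The pipeline treats a multi-compound drug's mechanism inference as a
sequence of set and graph operations over gene symbols:

1. **Drug-side targets.** Compound→target evidence rows carry an optional
   prediction score (in the source database's own units) and a source
   label. Per compound, scored rows pass when `score > score_min`
   (default 60, strict); when no scored row clears the bar, the `top_k`
   (default 50) highest-scored rows pass instead — the two rules are
   alternatives, with the fallback covering compounds whose predictions
   are informative only by rank. Curated (unscored) rows always pass.
   The union over compounds, with per-symbol source provenance, is the
   drug target set; herb–compound and compound–target pairs additionally
   form a tripartite network with a `layer` node attribute.
2. **Disease-side targets.** Curated disease–gene rows merge (union with
   provenance) with the genes shared by every expression dataset's
   differential-expression screen (below).
3. **Subnetwork expansion.** Each target set expands against a
   user-supplied interactome to the seeds present in it plus their
   depth-1 neighbors (depth configurable), with all induced edges. Seeds
   absent from the interactome are reported, not silently kept.
4. **Intersection and two-stage screen.** The two expanded networks
   intersect node- and edge-wise; the core-target screen (below) runs on
   the intersection.
5. **Enrichment.** Core targets are tested for pathway over-representation
   and the significant terms grouped by kappa agreement (below).
6. **DEG×drug overlap.** The genes common to the shared-DEG set and the
   drug target set, with their induced interactome subgraph, are emitted
   as a separate small network.

Every stage reads and writes plain TSV/JSON; a run is a pure function of
(config, seed) and reproduces byte-identically.

## Centrality conventions

Six indices are computed on undirected simple graphs (self-loops dropped
at parse time, duplicate edges collapsed):

- `DC(v)`: degree.
- `BC(v)`: betweenness over *unordered* source–target pairs, unnormalized
  (`Σ σ_st(v)/σ_st`), computed by Brandes' dependency accumulation and
  halved, so a star center with k leaves scores exactly C(k,2).
- `CC(v)`: closeness normalized by the node's connected-component size,
  `(n_c − 1)/Σ_{u∈comp(v)} d(v,u)`; an isolated node scores 0.
- `EC(v)`: the nonnegative principal eigenvector of the adjacency matrix,
  computed per connected component by shifted power iteration on `A + I`
  (identical eigenvectors; the shift makes the Perron root strictly
  dominant so bipartite components cannot oscillate), deterministic
  uniform start, tolerance 1e-10, at most 10,000 iterations, scaled to
  unit Euclidean norm within each component block; single-node components
  score 0.
- `LAC(v)`: mean degree of v's neighbors within the subgraph induced on
  those neighbors; 0 for an isolated node.
- `NC(v)`: sum over v's edges of the edge clustering coefficient
  `ECC(u,v) = |common neighbors| / min(DC(u)−1, DC(v)−1)`, with ECC
  defined as 0 when the denominator is 0.

All six are validated against an independent graph library (DC/BC/CC/EC)
and against direct brute-force evaluations of their formulas (LAC/NC, and
BC by explicit shortest-path enumeration) on random and closed-form
graphs.

**Medians.** Thresholds are `multiplier × median` with the even-length
median taken as the midpoint of the two central order statistics.
Comparisons are inclusive (`≥`). Stage 2 recomputes all six indices *on
the hub network* rather than inheriting full-network values; this matches
the observation that a degree cutoff re-derived on the denser hub
subnetwork exceeds the stage-1 cutoff.

**A structural note on stage 2.** Under component-normalized closeness, a
connected hub network can never contain a node with `CC ≥ 2 × median(CC)`:
if any node approaches universal adjacency every node's closeness rises
to ≥ ~0.5, pushing the threshold above 1. Consequently the six-index
screen selects nodes of *dense modules that separate from the hub
network's bulk* — protein-complex-like clusters — rather than lone
high-degree stars. This is the behavior the synthetic interactome is
designed to exercise (below), and it matches the character of reported
core networks in this analysis style, which are dense near-cliques rather
than hub-and-spoke sets.

## Differential-expression screen

Expression values are taken as already log2-scaled (log2 intensity, or
log2(count+1) for RNA-seq-like input). The per-gene test is Welch's
two-sided t (Student's t optional) with `log2FC = mean(case) −
mean(control)`; the screen applies `|log2FC| > fc_min` AND `p < p_max`,
both strict, with `fc_min = 1` (microarray mode) or `log2(1.5)` (RNA-seq
mode) and `p_max = 0.05`. Raw p-values are used by design — the screening
criteria this emulates are stated on raw p — though Holm/Bonferroni/BH
corrections are available in the enrichment module. Degenerate genes with
zero variance in both groups score p=1 when means agree and p=0 (logged)
when they differ. Fold change is computed as the difference of log2 means;
"fold change > 1.5" is read as magnitude in either direction. No
normalization, batch correction, or count modeling is attempted; inputs
are assumed preprocessed.

The Venn intersection reports all `2^K − 1` exclusive region sizes keyed
by membership mask, alongside the full intersection.

## Enrichment and kappa grouping

Over-representation is the one-sided upper hypergeometric tail, evaluated
exactly in log space; the universe defaults to all genes in the library
(configurable, e.g. to the interactome node set), and query or term genes
outside the universe are dropped first. The default correction is Holm.
Cohen's kappa between two terms is computed on their hit-gene membership
vectors over the query set (with the convention kappa=1 when chance
agreement is exactly 1, i.e. both sets empty or both the full query).
Significant terms (`p_adj ≤ 0.05`) are grouped by single-linkage: an edge
wherever pairwise kappa ≥ 0.4, groups = connected components, the leading
term having the smallest adjusted p (ties: larger hit count, then
lexicographic id). Single-linkage components were chosen over iterative
leading-group merging because they are deterministic, order-independent,
and need only the kappa threshold.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (config, seed) and emit the exact
file formats the pipeline reads, plus a `manifest.json` sufficient to
recover every planted ground truth.

**Interactome.** A preferential-attachment scaffold (default n=2000,
m=2 — heavy-tailed degrees, as in real interactomes) carrying two planted
structures: a clique of 20 hub genes, each degree-boosted with 30 spoke
edges to low-degree scaffold nodes (the ground-truth core module), and 40
pendant 9-cliques emulating protein complexes, each doubly anchored to
top-degree scaffold nodes and degree-boosted with 3 spokes per member.
The complexes dominate the hub network and set its medians — the role
complex-derived dense neighborhoods play in real PPI cores — while the
module, whose hub-network component is its own clique, clears every
median-multiple threshold. Spoke partners are capped at 3 spokes each and
drawn from degree ≤ m+1 nodes so boosting never pushes them over hub
thresholds. What this does not emulate: edge weights/confidence scores,
direct module–complex interconnection, and literature-bias degree
artifacts.

**Expression.** K=5 datasets (mirroring a five-series microarray
meta-screen), 2000 genes × 10+10 samples, baseline N(8, 1) on the log2
scale, planted genes shifted by ±2 log2 units in cases (sign per gene per
dataset), 120 planted genes per dataset of which exactly 66 are shared by
all five. Gaussian log2 intensities emulate microarrays; RNA-seq count
dispersion is not simulated. At these conditions the per-dataset screen
has ~97–98% sensitivity, so the *screened* five-way intersection recovers
~58–62 of the 66 planted shared genes — the manifest, not the screen
output, carries the exact ground truth. Passing tests therefore show the
screen is calibrated (null pass rate ≈ p_max × P(|log2FC|>1 | null)) and
powerful at the planted effect, not that real microarray meta-analyses
recover their shared signature exactly.

**Evidence tables.** 22 compounds (≈ a serum-constituent panel) × 18
targets, ~50% carrying Uniform(0,100) prediction scores under a
prediction-server label, the rest curated/unscored; 10 herbs; 150 disease
targets with 30% drawn from the drug pool and sources cycling over five
database labels. Each planted complex contributes one member to each
side's targets, and 10 module members appear on each side, as curated
records: the planted structures are drug- and disease-relevant *by
construction*, which is the premise of the method (drug and disease
targets converging on shared modules). With purely uniform target draws
the complex coverage of the intersection network is left to chance and
the screen's behavior becomes unstable at desk scale.

**Gene-set library.** 41 uniform background terms (sizes 10–60) plus one
planted term holding 20 members of the hub module, over the interactome
universe — so a recovered core yields exactly one significant pathway,
the planted one.

## Problem sizes and tolerances

Default study conditions (2,000-node interactome, five 2,000-gene
datasets, 42-term library) complete end-to-end in ~1 s; the test suite's
replicated checks (20-replicate screen self-consistency and hub recovery,
50-graph centrality cross-validation, 100,000-draw Monte-Carlo enrichment
checks) run in well under a minute. Numerical comparisons against
reference implementations use 1e-8 absolute tolerance (eigenvector up to
sign); Monte-Carlo agreement is asserted at 3σ; the seeded DEG
sensitivity check allows ±0.03 around its simulation-oracle expectation.

## Known limitations

- Identifier handling assumes symbol-keyed inputs; no protein↔gene ID
  resolution is attempted. Mouse→human conversion uses a user-supplied
  two-column ortholog map (case-preserved sources, since mouse symbols
  are case-significant; unmapped symbols dropped by default).
- Centralities are unweighted and undirected only.
- The per-compound reading of the top-k fallback is one interpretation of
  "score > 60 or top 50"; it is configurable. Note that the fallback makes
  target counts non-monotone in `score_min` at the point where the strict
  filter empties.
- Whether stage-2 thresholds should be re-derived on the hub network or
  inherited is a modeling choice (re-derived here, flagged in config);
  historical threshold values from database snapshots cannot be
  reproduced and are not targets.
- The kappa universe is the query set; tools differ on this and results
  shift slightly with the alternative (annotated-query) convention.
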