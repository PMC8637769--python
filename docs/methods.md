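# Methods

`colitiskit` implements the computational core of a network-pharmacology +
gut-microbiome study of an herbal formula in DSS-induced murine colitis: ADME
screening of herb compounds, a tripartite herb–ingredient–target (HIT) graph,
confidence-filtered PPI hub extraction by iterated six-centrality median
filtering, hypergeometric over-representation analysis, downstream 16S
statistics (diversity, ordination, clustering, biomarker discovery), and the
disease-activity-index (DAI) rubric. All stages run on synthetic inputs with
planted ground truth, so every claim the test suite makes is checkable
without external database snapshots.

## Network pharmacology branch

**ADME screen.** A compound is "active" when oral bioavailability
OB ≥ 20 % and drug-likeness DL ≥ 0.18, both cutoffs inclusive. Gene symbols
are normalized by trim + uppercase only; alias resolution is deliberately out
of scope, so two true aliases count as distinct symbols (a documented
limitation).

**Disease-gene collation.** Sources (GeneCards-style pulls) are unioned;
Venn region counts (genes in exactly a given subset of sources) are reported
for all 2^k − 1 regions and always sum to the union size.

**HIT graph.** Tripartite herb→compound→target graph restricted to a kept
target set; compounds without retained targets and herbs without compounds
are pruned, and a compound shared by several herbs is a single node with one
edge per herb. Per-herb coverage is the fraction of the pooled target set
reachable from that herb (fractions may sum above 1; the union of all herbs
covers exactly 1).

**PPI filtering and centralities.** Edges with confidence ≥ 0.7 are kept
(STRING-style 0–1000 scores are auto-rescaled), self-loops dropped,
duplicates merged at max confidence, isolated nodes removed. Six per-node
indices:

- DC — degree;
- BC — unnormalized shortest-path betweenness over unordered pairs
  (disconnected pairs contribute 0);
- CC — per-component closeness (n_comp − 1) / Σ d(v,u);
- EC — principal adjacency eigenvector, rescaled to max = 1;
- LAC — mean degree of v's neighbours inside the subgraph induced by N(v);
- NC — Σ over incident edges of the edge clustering coefficient
  ECC(u,v) = #triangles(uv) / min(deg u − 1, deg v − 1), with 0/0 → 0.

The table is rounded to 12 decimals so eigensolver jitter (~1e−16) cannot
break median ties on symmetric graphs. All six indices are verified against
brute-force oracles (path enumeration, triangle counting, power iteration on
A + I — the shift keeps the Perron value strictly dominant on bipartite
graphs) on 100 random connected graphs with n ≤ 30.

**Hub extraction.** One round keeps the nodes whose scores beat the
per-index median on *all six* indices (strictly by default; an inclusive
comparator is available because strictness necessarily empties
vertex-transitive graphs). The subgraph is induced on the survivors,
isolated nodes re-removed, and the round repeated (default three times,
matching the workflow it reproduces). Early stop on empty, unchanged, or
sub-minimum survivor sets returns the last valid sub-network; the full trace
(per-round medians and survivor sets) is always emitted.

*Known limitation.* On sparse backgrounds with a planted dense module, the
strict all-six rule systematically sheds module-interior nodes in later
rounds: once the survivor subgraph thins, interior members of a clique lie
on no shortest path, their betweenness is exactly 0, and "strictly above the
BC median" eliminates them. Measured on ER(200, 0.03) + a planted 12-clique,
3-round strict extraction recovers ≥ 10/12 planted nodes in only about half
of seeds (the trace makes each loss auditable). The inclusive comparator is
worse — it retains diluting background. Users who want module recovery
rather than a small hub core should inspect the trace and use the round-1 or
round-2 survivor set.

**Enrichment.** One-sided hypergeometric upper tail P(X ≥ k) for a query of
size n against a term of size K in a universe of size N (default universe:
union of collection members; overridable). Terms with zero hits are excluded
from both the output and the BH family; Benjamini–Hochberg is applied
separately within each category (BP / CC / MF / pathway); significance means
adjusted p < 0.05. Null calibration is demonstrated with 2000 uniform-null
query replicates over 60 terms of sizes 50–200 in a 2000-gene universe —
sizes chosen so the discrete tail is near-continuous; with small terms the
sub-0.05 mass sits visibly below 5 % and the check would measure
discreteness, not calibration. Observed rates run slightly below nominal
(~3.9–4.5 %), as expected for a discrete one-sided test.

## Microbiome branch

**Filtration.** Features whose table-wide total falls below 0.005 % of the
grand read total are dropped (boundary kept). The threshold is measured
against the whole table, matching the single stated filtration figure.

**Composition profiles.** Counts are aggregated at phylum or genus rank from
greengenes-style lineage strings, ranked by mean relative abundance, and the
top 10 kept with the remainder merged into "Others"; per-sample columns sum
to 1.

**Alpha diversity.** Good's coverage 1 − F1/N; Chao1 bias-corrected
S + F1(F1−1)/(2(F2+1)) by default (classic S + F1²/(2F2) by flag, falling
back to the bias-corrected form when F2 = 0); ACE with rare/abundant cutoff
at 10 reads, C_ace = 1 − F1/N_rare, γ² floored at 0, and a Chao1 fallback
when C_ace degenerates to 0 (warned); Shannon with natural log; Simpson
reported as Gini–Simpson 1 − Σp² so that higher = more diverse (classic Σp²
by flag). Rarefaction is the exact hypergeometric expectation
E[S_n] = S − Σ C(N−N_i, n)/C(N, n), evaluated with log-gamma.

**Beta diversity and ordination.** Binary Jaccard d = 1 − |A∩B|/|A∪B| on
presence/absence (two empty samples are at distance 0). PCoA Gower-centres
−D²/2, eigendecomposes, scales eigenvectors by √λ; negative eigenvalues are
reported but contribute no axes; reconstruction of Euclidean inputs is exact
to 1e−9. NMDS minimizes Kruskal stress-1 √(Σ(d−d̂)²/Σd²) by SMACOF
majorization alternated with isotonic regression of configuration distances
on the dissimilarity order (ties averaged); one PCoA start plus 20 random
starts; a run stops as soon as stress fails to decrease (tolerance 1e−6), so
the recorded trajectory is non-increasing and the best configuration is
kept. The configuration is re-centred and re-scaled each iteration (stress-1
is scale-invariant) — without this the iteration can drift into a
numerically collapsed configuration whose clamped distances read as constant
and fake near-zero stress. Stress < 0.2 sets the validity flag. Note that
binary Jaccard on small communities produces heavily tied dissimilarities;
with ties the monotone fit is weak and very low stress values are expected
and legitimate.

**UPGMA.** Average-linkage agglomeration (scipy linkage); node height is
half the merge distance so cophenetic distances reproduce ultrametric inputs
exactly; Newick children are ordered by smallest leaf label for determinism.

**LEfSe variant.** Two classes only (the study design), relative abundances
scaled to 1e6. Stage 1: Kruskal–Wallis screen at α = 0.05. Stage 2, for
screened features: over 30 bootstrap resamples (within-class, with
replacement) a one-feature LDA is fitted and the effect recorded as the mean
of |class-mean gap along the discriminant| and |raw class-mean gap|; the
effect size is log10 of the bootstrap average, floored at 1, and
significance requires effect ≥ 2. The enriched group is the one with the
higher mean. This is a reimplementation variant; bit-parity with the
original tool is a non-goal. Because the screen is a rank test at α = 0.05
and the effect gate is permissive on the 1e6 scale, the false-call floor is
≈ 0.05 × (number of non-differential taxa the screen can reach); biomarker
FDR near 10 % therefore requires genus-scale communities (tens, not
hundreds, of taxa), which is how the synthetic tables are sized.

## DAI scoring

Stool (normal 0, soft 1, very soft/semi-formed 2, liquid/sticky 3), weight
loss in lower-inclusive bins (0 → 0, (0,5) → 1, [5,10) → 2, [10,20] → 3,
>20 → 4 — exactly 20 % scores 3 because the top bin is strictly ">20 %"),
occult blood (timed colorimetric categories 0–3), histology as four 0–3
subscores (epithelial destruction, edema, crypt loss, mucosal infiltration)
summed to 0–12. The source rubric names the histology criteria without a
point scale; the 0–3-per-criterion scale is this package's choice and is
validated only internally. Total = unweighted component sum, range [0, 22],
monotone in every field (verified by exhaustive grid enumeration). Cohort
summaries report per-group mean ± sd of the total and each component.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (parameters, seed); one master seed
fans out to independent per-generator streams (`default_rng([seed, tag])`),
so adding a generator never perturbs another's output. Planted truth is
returned beside the data.

- **Compound tables** — OB ~ Gamma(2, 12) clipped to [0, 100] (right-skewed,
  most compounds failing the 20 % cutoff, as in real ADME exports);
  DL ~ Beta(1.5, 4); ~15 % of compounds drawn from a shared pool so they
  recur across herbs; 6 herbs × 20 compounds over a 300-gene target
  universe.
- **Disease sources** — five named sources of 400 genes each drawn from a
  shared pool of size 400/overlap (overlap 0.4), realized Venn regions
  recorded as truth. The pipeline preset seeds the pool with the compound
  target universe plus genome-like filler so formula and disease intersect.
- **PPI layer** — ER(200, 0.03) background with a planted 12-clique;
  background confidences U(0.3, 1) (thinned by the 0.7 cutoff), module
  confidences U(0.75, 1) (module survives filtering intact).
- **OTU tables** — Dirichlet-multinomial: baseline proportions
  lognormal(0, 2.5) renormalized (few dominants, long rare tail), total
  concentration 100 (overdispersion typical of stool 16S), lognormal library
  sizes around 20 000 reads, 10 samples per group, 15 taxa at genus-like
  resolution over a 6-phylum / 12-genus taxonomy. Differential taxa (5 by
  default) are drawn from the moderately rare baseline-share band
  [1e−3, 2e−2] and receive the fold change split symmetrically — ×√F in one
  group, ÷√F in the other, directions alternating — so the between-group
  fold is F while compositional closure stays near zero (an unbalanced ×F on
  abundant taxa would depress every null feature and make "false" positives
  genuinely differential).
- **DAI cohorts** — three arms (control / dss / dss_treated) of 15 mice with
  categorical severity profiles; the control profile is exactly healthy.

Not emulated: read-level sequencing artifacts (chimeras, primer errors),
taxonomic misassignment, phylogenetic structure (no UniFrac), inter-sample
correlation (cages/litters), compound-structure realism, and database alias
noise. Passing tests therefore certify the statistics pipeline downstream of
an OTU table and curated input files, not the upstream bioinformatics.

## Numerical choices and degenerate inputs

- Hypergeometric tails via scipy's survival function (log-space; stable to
  N ~ 1e5); inconsistent counts are validation errors.
- BH via statsmodels step-up with monotonicity enforcement; input order
  preserved.
- All-zero count vectors, empty graphs, empty universes, >2 LEfSe groups,
  rarefaction beyond depth, asymmetric distance matrices and out-of-range
  confidences raise errors naming the offending quantity; empty filter
  results and empty HIT networks warn instead.
- Kruskal–Wallis on a feature with zero spread returns p = 1 rather than an
  error; features failing the screen carry effect = NaN.
- LDA with singular within-class scatter falls back to the raw mean gap.
- Problem sizes used by the checks (100 oracle graphs at n ≤ 30, 20
  extraction/biomarker seeds, 2000 null-calibration replicates, 140
  null-table KW replicates) were chosen to give stable rates at interactive
  runtimes.

## Pipeline determinism

`run_pipeline` executes the two independent branches, writes all stage
outputs with fixed float formatting, and emits a manifest (package version,
seed, thresholds, SHA-256 of every input and output — no timestamps).
Identical config + inputs give byte-identical bundles; the test suite
asserts this end to end.
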