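# Methods

## Reference network

A metabolic model (metabolites, reactions, enzymes, pathways) is converted
to an undirected metabolite-centric graph: every reaction contributes an
edge for each (reactant, product) pair, deduplicated, with reaction ids
and enzyme ECs unioned on edges.  Reactant–reactant pairs are *not*
joined: substrates of one reaction are not interconverted by it.  A
configurable currency list (default: H2O, H+, CO2, O2, ATP, ADP, AMP,
NAD(P)+/NAD(P)H, CoA, phosphate, diphosphate; matched by id or name) is
excluded from edges, since ubiquitous cofactors would otherwise connect
nearly everything within two steps and defeat the path-length bound below.
Metabolites without a monoisotopic mass stay in the graph as possible
intermediates but can never match a feature.  Edge directionality and flux
semantics are out of scope.

## Feature matching

Observed m/z is compared with theoretical derivative m/z
(M + shift)/charge under a relative tolerance
|obs − theo|/theo ≤ ppm_tol·10⁻⁶ (default 10 ppm, instrument-dependent and
configurable).  The default form tables (positive: M+H, M(¹³C)+H, M+Na,
M+K, M+NH4, M+H−H2O, M+2H, M+ACN+H; negative: M−H, M(¹³C)−H, M+Cl,
M−H2O−H, M+formate) fold the electron mass into the proton constant
1.00728 Da; the ¹³C substitution adds 1.00336 Da.  Tables are explicit and
user-replaceable.  Matching is deliberately many-to-many and retention
time is never used; with `enforce_primary` ("-z"), metabolites whose
primary ion (M+H[1+]/M−H[−]) matches nothing in L_ref are dropped
entirely.

## Module analysis

Input metabolites = tentative matches of L_sig.  Candidate modules are
collected three ways and pooled as a set (deduplicated by node set):

1. *connecting subnetworks*: for k = 1…4, the subgraph induced by the
   seeds plus all nodes on shortest paths of length ≤ k between seed
   pairs; connected components with ≥ 2 seeds are kept.  "All subnetworks
   that can connect" the inputs is realized as shortest-path semantics —
   enumerating all paths is exponential, and at four steps most metabolite
   pairs in genome-scale networks are already reachable, so deeper search
   adds little but noise.
2. *spectral splits* of each subnetwork: recursive leading-eigenvector
   bipartitioning of the modularity matrix, with Kernighan–Lin-style
   fine-tuning repeated to convergence; recursion stops when no split has
   positive modularity (of the part as a standalone graph) or a part would
   drop below the minimum size.  Intermediate and leaf parts all enter the
   candidate pool ("many modules of different sizes").  A greedy-modularity
   (CNM) splitter is provided as a drop-in alternative to probe robustness.
3. each candidate is then *pruned*: non-seed leaves are removed
   iteratively, since protruding edges that reach no input metabolite
   cannot contribute to the score.

Minimum module size is 3 nodes with ≥ 2 seeds — a "module" connecting a
single input, or a bare dyad, carries no modular information and would
dominate the permutation null.

Scoring: Q = E_M/E − (Σ k_i/2E)², computed against the *whole-network*
E and degrees, times the enrichment m/N, times N^(−1/2).  Raw modularity
grows with module size; the N^(−1/2) factor counteracts that bias.  The
scorer is a pluggable strategy (`scorer=` argument) so any
enrichment-times-modularity form can be substituted without touching the
search; the package's tests only rely on monotonicity in m and
isomorphism invariance, which hold for the whole family.

Null calibration: each permutation draws |L_sig| features uniformly
without replacement from L_ref (unmatched features included — the draw
models the experiment's selection step, not the matchable subset), reruns
matching and the full module search, and pools *all* candidate scores.
Default 100 permutations, seed-controlled.  A two-parameter Gamma
(shape, scale; location fixed at 0) is fitted by MLE to the strictly
positive pooled scores (non-positive scores are dropped and counted — a
negative-modularity module is below-background by definition); the
module p-value is the fitted survival function at the observed score,
which can extrapolate below 1/n_null.  With fewer than 20 positive
scores, or a degenerate pool, the empirical tail rank
(1 + #{null ≥ A})/(1 + n) is used instead.  No multiple-testing
correction is applied across modules: p-values are raw
permutation-calibrated quantities, and module significance (default
p < 0.05) only feeds the activity-network collection step.

## Pathway analysis

For each pathway: K = |pathway ∩ matchable(L_ref)| and
N_tot = |matchable(L_ref)| — the universe is what the experiment can see,
not the model.  n = number of tentative L_sig metabolites; the overlap k
is min(#overlapping metabolites, #distinct supporting features), because
one feature matching several members of the same pathway would otherwise
inflate the count.  Fisher's exact right tail P(X ≥ k) under
Hypergeom(N_tot, K, n) and the EASE score (same tail with k−1) are both
reported.  The permutation loop is shared with the module analysis (the
same random draws serve both nulls); every pathway's Fisher p-value from
every permutation enters one pool — not only each permutation's minimum,
because pathway sizes vary too much for the extreme-value scheme to be
stable.  A Gamma is fitted to the pooled p-values exactly as stated even
though their support is bounded — fidelity to the calibration procedure
over distributional elegance, with the empirical-rank fallback guarding
degeneracy — and adjusted_p = Gamma-CDF(EASE).  Pathways are ranked by
adjusted_p (with FET as tie-breaker); both are reported.  Because the
observed statistic is the conservative EASE while the null pool is built
from plain FET p-values, adjusted_p errs on the conservative side — the
type-I test asserts the two-sided 3-SE band and, at the fixture's pathway
counts, conservatism keeps the rate near zero, within the band.

## Activity network

Metabolites of significant modules and pathways are unioned, then each is
rated from its derivative forms present in L_ref: **high** = primary ion
plus its ¹³C partner (isotopologue co-occurrence is strong evidence the
mass is real); **medium** = primary alone, or ≥ 2 distinct non-primary
forms; **low** = one non-primary form.  Qualified = high or medium;
`enforce_primary` additionally requires the primary form.  Only the
"high" case and the primary-ion rule are canonical; the rest of the table
is this package's declared extension and is overridable.  Qualified
metabolites inherit their reference-network edges (enzyme ECs attached);
qualified-but-disconnected nodes are kept as flagged isolates.  Every node
records its provenance (contributing modules/pathways) and supporting
features.  Exports: GraphML, SIF, TSV node/edge tables.
`compare_to_annotation` tallies agreed / disagreed / not-annotated against
an independent feature annotation, excluding unannotated predictions from
the agreement denominator.

## Synthetic benchmark

`fixtures.generate_toy_model` builds a planted-partition network — default
4 blocks of 6 metabolites, within-block edge probability 0.8 (plus a
spanning path guaranteeing block connectivity), between-block 0.02, one
pathway per block — realized as 1-reactant/1-product reactions.  Masses
are drawn uniformly on 100–800 Da with > 0.05 Da separation, also enforced
after offsetting by every pairwise difference of the emitted-form shifts,
so no emitted ion of one metabolite can fall into another's emitted-form
window: matching on the fixture is unambiguous by construction.
`simulate_feature_table` emits the primary ion with probability 0.95, the
¹³C form with 0.5 and M+Na with 0.3 per metabolite, at theoretical m/z
with ±0.3 ppm jitter; decoys (3× the true-feature count, echoing that most
real features match no model metabolite) avoid a 3×-tolerance window
around every theoretical m/z.  Planted-block features receive
p = u·10^(−effect) with u ~ U(0,1) (default effect 2, i.e. all planted
features clear the 0.05 cutoff while background features are uniform);
effect = 0 is an exact null and effect = ∞ the noise-free limit (all
background features non-significant), used by limit-case tests.

What the fixture does *not* emulate: chromatography and ionization
physics, isotope-envelope intensities, correlated noise between forms of
one metabolite, mass-dependent tolerance structure, and the heavy
ambiguity of real genome-scale mass lists (an ambiguity mode with
deliberately colliding masses can be requested by lowering the spacing).
Passing tests therefore demonstrate the statistical machinery recovers
planted signal under clean matching, not instrument-level performance.

## Numerical choices and problem sizes

Hypergeometric tails come from scipy (`hypergeom.sf`); the test suite
checks them against exact rational enumeration for every table with
N_tot ≤ 25.  Gamma fitting uses `scipy.stats.gamma.fit(floc=0)`.
P-values are clipped into (0, 1].  Spectral bipartitions use `numpy.eigh`
on the modularity matrix with deterministic tie-breaking (sign of the
leading eigenvector, greedy KL passes with index-ordered tie-break), and
agree with exhaustive maximum-modularity bipartition on random graphs of
≤ 10 nodes in the suite.  All randomness flows through
`numpy.random.default_rng(seed)`; pipeline runs are byte-reproducible
given the seed.  Simulation-based tests use the default fixture (24
metabolites, ~140 features) with 100 permutations and 20 replicate seeds —
sizes chosen so the full statistical battery stays in the tens of seconds
while leaving binomial error bands narrow enough to be informative.

## Known limitations

- Matching ignores retention time and isotope-pattern intensities; it is
  tentative by design and resolved only statistically.
- The Gamma model for pooled pathway p-values is a pragmatic fit to a
  bounded-support quantity; its CDF at EASE scores is conservative.
- Reaction reversibility, compartments, tissue specificity and mass-flow
  balance are not modeled.
- The activity score's exact anti-size-bias form is a declared package
  default; alternative scorers can be injected, and downstream predictions
  are empirically robust to the module-finding algorithm (tested).
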