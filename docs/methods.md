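# Methods

This note documents the models and procedures implemented in
`cosmos-causal`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic benchmarks do and do not demonstrate.

## Footprint activity estimation

Regulator activities are estimated from the differential statistics of their
direct targets.  All measured features form the rank universe; statistics
are converted to fractional ranks r/(N+1) (average ties) and mapped through
the standard-normal quantile function to z-values.  The score of a regulator
with targets i, weights wᵢ ∈ (0,1] and modes mᵢ ∈ {−1,+1} is

    NES = Σ wᵢ mᵢ zᵢ / √(Σ wᵢ²).

Under a random permutation of the statistic vector the target z-values are
draws without replacement from a near-standard-normal population, so the
score is approximately standard normal.  The approximation errs in two
small, known ways: the empirical z population has variance slightly below 1
(quantile discretization) and without-replacement draws are weakly
negatively correlated.  `footprint.permutation_nes` provides the exact
empirical calibration; across random 10-target regulons on 200 features the
analytic score stays within ~0.07 of the 100,000-permutation z-score, and
null NES over 1,000 random regulons have |mean| < 0.03 and sd ≈ 0.97.

Assumptions: a one-tailed reading of signed statistics (an activator's
targets move with the regulator, a repressed target moves against it);
independence of targets under the null; no pleiotropy correction.  Defaults:
minimum 25 measured targets for TF regulons and 5 for kinase/phosphatase
regulons (sparser substrate coverage), both overridable.

Per-sample activities z-score each feature row across samples (sd with one
delta degree of freedom; constant rows dropped; at least 3 samples) and feed
each sample's z-column through the same estimator, so activities are
relative to the other samples.

Input selection for the causal runs keeps regulators with |NES| > 1.7
(strict) and metabolites with uncorrected p < 0.05 (strict); both cutoffs
are run parameters.

## Meta PKN construction

Three layers merge into one signed directed graph with node kinds
protein / metabolite / enzyme_instance / complex:

* **Protein–protein** (ppi / transcriptional provenance): only rows flagged
  as stimulation and/or inhibition are kept; a doubly-flagged row yields
  both edges.
* **Allosteric** (metabolite → protein): rows at or above a combined
  confidence score, default 900; the action-label → sign mapping is
  configuration because source databases do not standardise labels.
* **Metabolic**: each reaction's GPR rule is parsed (AND/OR, parentheses to
  depth 10) and expanded to its minimal disjunctive normal form — for
  monotone rules the distributive expansion plus absorption is exactly
  truth-table minimization.  Every disjunct becomes one catalytic node named
  `GENES__REACTION` (sorted genes joined by `_`), so enzymes catalyzing
  several reactions never share a node and reactants of one reaction cannot
  leak to products of another.  Exchange reactions are further suffixed with
  the exchanged metabolite.  Edges are reactant →(+1)→ catalytic node and
  catalytic node →(+1)→ product: reactant presence enables the enzyme, and
  product abundance follows enzyme activity.

Coenzymes (caller-supplied id set) are removed before edge creation.  After
edge creation, metabolites with degree above a threshold (default 338,
anchored at the most-connected central-carbon metabolite of a genome-scale
human network) are removed with all incident edges; degree is counted on the
converted metabolic layer only, so allosteric edges do not make a metabolite
"promiscuous".  Metabolite identifiers carry the `metab__` prefix and are
otherwise treated opaquely (compartment handling is the caller's choice);
using one identifier both as metabolite and protein is an error.  Duplicate
edges across layers are stored once; all provenances are recorded and the
first-listed layer's tag is primary.  Reversible reactions are not modeled —
encode them as two reaction records.

## Contextualization

1. **Filtering** — an interaction is kept only if every gene it touches
   (complex members included) has mean count ≥ 50 across all provided
   samples, conditions pooled; genes absent from the count matrix fail.
   Metabolite-only edges are untouched.
2. **Reduction** — keep exactly the nodes within k directed steps of any
   input (vertex-induced subgraph); k defaults to 8 for forward runs and 7
   for backward runs.
3. **Correction** — a transcriptional edge (TF, s, gene) is removed iff the
   TF has a known activity sign a, the target transcript is significant
   (p < 0.05 uncorrected by default; log-fold-change sign only, no magnitude
   threshold) and sign(logFC) ≠ a·s.  An edge is treated as transcriptional
   if any of its provenances is.  A pre-run of the optimizer (forward
   direction) can supply consensus TF states from the solution pool for a
   second correction pass; an empty or infeasible pre-run leaves the network
   unchanged.

Each step only removes edges, so the pipeline is monotone in edge count.

## The optimization

Given fixed input states and weighted measurement signs, the ILP minimizes

    Σ_m w_m |t_m − x_m|  +  β Σ_u (u⁺ + u⁻)

with per-node up/down binaries (u⁺ + u⁻ ≤ 1; inputs fixed), per-edge
activation/inhibition carriers gated by the source state, support
constraints (a stated non-input node needs an active incoming carrier), and
big-M order variables that forbid cycles.  Because t ∈ {−1,+1} and
x = v⁺ − v⁻ ∈ {−1,0,+1}, the mismatch linearizes exactly as
w(1 − t(v⁺ − v⁻)).  Inputs are hard constraints and therefore always count
toward the size term.  Measurements weigh |NES| for activity nodes and 1 for
metabolites by default.

**Solution convention.**  Edges do not enter the objective, so without a
convention the pool would contain arbitrary redundant-edge variants of the
same explanation.  A solution here is (node states, active edges) where
every stated non-input node has exactly one supporting incoming edge, every
active edge is sign-consistent, no active edge points into an input, and the
active subgraph is acyclic — the minimal supports of the state assignment.
The MILP backend (HiGHS via `scipy.optimize.milp`) enumerates optimal state
assignments with no-good cuts and reconstructs each assignment's minimal
supports; the exhaustive backend enumerates edge subsets directly (≤ 20
edges) and checks the same invariants, serving as the independent oracle.
On 50 random instances per seed the two return identical objectives and
identical solution sets.  Pools are truncated at `pool_cap` (default 100)
solutions; edge weight = 100 × pool frequency.  Defaults β = 0.2 and time
limits 7,200 s (forward) / 21,800 s (backward), mirroring the original
protocol; tests and the robustness harness override the limits to seconds.

Determinism: node and edge orderings are sorted everywhere, so repeated runs
(either backend) produce byte-identical outputs on instances solved to
optimality.

## Forward, backward, merge, ORA

The forward run fixes deregulated regulators as inputs and deregulated
metabolites as unit-weight measurements; the backward run swaps the roles
(metabolite statistic signs as inputs, regulators as |NES|-weighted
measurements).  The merged network is the union of the two weighted edge
sets; per-run weights are both kept, and the displayed combined weight is
their maximum (a display convention — the union of two independently
optimal pools has no principled joint frequency).  Nodes whose consensus
states (sign of the summed pool states) disagree between runs are reported
as sign conflicts, not resolved.  Over-representation of solution genes uses
the hypergeometric upper tail against a caller-supplied universe (default:
gene-kind nodes of the contextualized PKN; catalytic node ids are mapped
back to member genes) with Benjamini–Hochberg adjustment across gene sets.

## Evaluation

*Co-regulation coherence*: children sharing a parent in the solution network
should have correlated per-sample activities.  The TPR of predicted pairs is
computed over absolute Pearson correlation thresholds 0…1 in 0.01 steps
(Spearman optional) and compared with the mean TPR of uniformly drawn random
node pairs (default 1,000 repeats, 2.5/97.5 percentile band).

*Robustness*: `shuffle_pkn` selects ⌈fraction·|E|⌉ edges uniformly and
permutes their target endpoints among themselves (signs stay with sources,
in-degree multiset of the selected subset conserved; full random rewiring is
available behind a flag).  Duplicates/self-loops created by the permutation
are dropped and counted.  Runs on shuffled networks are compared to the
reference by per-edge |Δweight| over the edge union (absent edge = 0):
median, fraction zero, fraction flipped (0 ↔ 100).

## Synthetic studies

`generate_random_pkn` builds a layered signed graph (protein→protein,
metabolite→protein, and gene→enzyme-instance→metabolite reaction motifs)
with an exact edge budget.  `plant_causal_instance` grows a random
bounded-depth tree from random protein inputs, propagates the input signs,
marks planted metabolites as measurements, and then removes every non-tree
edge that points into a planted node.  With tree depth ≤ 4, β = 0.2 and unit
measurement weights, explaining any measurement costs at most 0.8 < 1 (its
mismatch if dropped), so the planted tree is provably the *unique* optimum
and the optimal objective equals β × (planted node count) exactly — this is
what the recovery benchmarks assert.  Planted activity tables give inputs
NES ±3 plus sub-threshold decoys; metabolite tables give measurements
p = 0.001 plus insignificant decoys; counts clear the expression filter.

The co-regulation design drives each parent's two children with a shared
latent factor at correlation ρ = 0.8 over 20 samples.  Twenty samples (not
the ~11 of a typical patient cohort) keep the pairwise correlation estimates
stable enough that a 0.01-step threshold sweep is meaningful; at small
sample counts both the planted curve and the baseline are dominated by
estimation noise in the extreme-threshold tail.

What these generators do *not* emulate: measurement noise on the planted
causal instance (the pipeline consumes noise-free planted signs), feedback
loops, missing or wrong prior knowledge on planted paths, correlated
regulons, batch effects, and realistic metabolic stoichiometry.  Passing the
planted benchmarks therefore shows the machinery is correct and calibrated,
not that real-data solutions are biologically right.

## Numerical choices and degenerate inputs

Objective comparisons use absolute tolerance 1e-6 (pool membership) and
reported objectives are rounded to 9 decimals; ranks use average ties; NES
of an all-tied statistic vector is exactly 0.  Empty input or measurement
selections refuse to run with an actionable message; measurements absent
from the PKN are warned about and charged their full mismatch; an infeasible
or timed-out solve is reported in the pool status rather than raised.  The
exhaustive solver refuses instances above 20 edges (2²⁰ subsets).  Problem
sizes in the test and acceptance suites (12–14-edge oracle instances,
~40-node planted studies, 100k-permutation nulls) were chosen so the whole
suite runs in well under a minute per component on a single CPU.

## Known limitations

* The solution-pool semantics commit to minimal supports; tools that also
  enumerate redundant-edge variants will report different (larger) pools
  with the same objective and node states.
* CPLEX-style incumbent pools under a time limit are inherently
  solver-ordered; this implementation is deterministic but caps enumeration
  at `pool_cap`, so on highly degenerate instances the reported weights
  depend on that cap.
* Measurement weighting (|NES| vs uniform) is configuration; no ground truth
  fixes it.
* Compartment handling for metabolite identifiers is left to the caller.
* SBML/MAT parsing of genome-scale models and live database retrieval are
  out of scope; only the table dialects are parsed.
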