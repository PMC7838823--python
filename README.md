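# cosmos-causal

Causal integration of transcriptomics, phosphoproteomics and metabolomics:
footprint-based activity estimation, a multi-layer causal prior-knowledge
network (PKN), and integer-linear-programming (ILP) selection of the
smallest sign-consistent subnetworks that connect deregulated signaling
regulators with deregulated metabolites.

## Who this is for

Systems biologists who have differential statistics from two or more omics
layers of the same samples and want *mechanistic hypotheses* — directed,
signed molecular paths — rather than lists of correlated features.  The
package is a complete, self-contained re-implementation of the approach as a
tested Python library plus a `cosmos` command line, exercisable end to end on
synthetic studies with planted ground truth (no database downloads needed).

## The method

**Footprint activities.** A regulator's activity is inferred from its
*regulon* — its direct targets with a mode of regulation (±1) and a weight.
With fractional ranks of the differential statistics mapped through the
standard-normal quantile function (z<sub>i</sub>), the normalized enrichment
score of regulator *R* is

    NES(R) = Σᵢ wᵢ·modeᵢ·zᵢ / √(Σᵢ wᵢ²)

which is standard-normal under a random permutation of the statistics (an
empirical permutation calibration is included).  Regulators with |NES| > 1.7
and metabolites with uncorrected p < 0.05 are "deregulated".

**Meta PKN.** Three interaction layers are merged into one signed directed
graph: curated protein–protein and TF–target interactions; high-confidence
(combined score ≥ 900) metabolite→protein allosteric regulations; and a
genome-scale metabolic network converted to causal edges
`reactant →(+1)→ enzyme` and `enzyme →(+1)→ product`, where each minimal
catalyzing gene set of the GPR rule (AND = complex, OR = isozymes) becomes a
reaction-unique catalytic node, coenzymes are excluded, and metabolites with
more than 338 interactions are dropped as hyper-promiscuous.

**Contextualization and optimization.** The PKN is filtered to expressed
genes (mean count ≥ 50), reduced to nodes within 8 (forward) or 7 (backward)
steps of the inputs, and cleansed of transcriptional edges that contradict
the measured transcript changes (including a pre-run of the optimizer to
predict TF states).  The ILP then minimizes

    Σ_m w_m·|t_m − x_m|  +  β·#(stated nodes),      x_m ∈ {−1,0,+1}

over loop-free, sign-consistent subnetworks with the input states fixed,
enumerates *all* equally optimal networks (the solution pool) and reports
each edge's pool frequency as a 0–100 weight.  A forward run
(signaling → metabolites) and a backward run (metabolites → signaling) are
merged by union, keeping any between-run sign conflict as an attribute
rather than resolving it.  Solution nodes can be tested for pathway
over-representation (hypergeometric + Benjamini–Hochberg), and robustness is
assessed by rerunning on partially shuffled PKNs and by comparing predicted
co-regulation against activity correlations (TPR sweep vs a random-pair
baseline).

Two solver backends implement identical semantics: a MILP formulation solved
with HiGHS (`scipy.optimize.milp`) and an exhaustive subset-enumeration
solver that doubles as the ground-truth oracle on small instances.

## Worked example

```bash
cosmos simulate --preset tiny --seed 1 --out study
cosmos run --study study --direction forward --backend exhaustive --out fwd
cosmos run --study study --direction backward --backend exhaustive --out bwd
cosmos merge --forward fwd --backward bwd --out merged
```

prints

```
study written to study (11 PKN edges)
forward: status=optimal objective=1 pool=1 -> fwd
backward: status=optimal objective=6.2 pool=1 -> bwd
3 merged edges, 0 sign conflicts -> merged
```

The simulated study plants a causal chain inside a random PKN: two fixed
signaling inputs (`P003` up, `P004` down) and one deregulated metabolite.
The forward objective 1 = 0.2 × 5 stated nodes with zero mismatch — the
optimizer explained the metabolite exactly, and `fwd/edges.tsv` is the
planted chain, every edge at pool weight 100:

```
source	sign	target	weight
P003	-1	P006	100
P006	1	P006__R001	100
P006__R001	1	metab__m001	100
```

`fwd/nodes.tsv` adds the predicted node states: `P003` (+1, input) represses
`P006` (−1), switching off its catalytic instance `P006__R001` and lowering
the product `metab__m001` (−1), which matches the measured sign.  The
backward run pays 6.2 because on this tiny network no causal path leads from
the metabolite back to the regulators, so their mismatch is charged in full.

The same workflow scales to real tables: `cosmos build-pkn` assembles the
meta PKN from OmniPath-style, STITCH-style and reaction-table TSVs,
`cosmos activities` computes NES from regulon + statistic tables, and
`cosmos ora` tests solution nodes against GMT gene sets.

## Layout

- `cosmos.pkn`, `cosmos.gpr` — interaction-source parsing, GPR → DNF
  conversion, meta-PKN assembly
- `cosmos.footprint` — NES estimation, per-sample activities, input selection
- `cosmos.preprocess` — expression filter, reachability reduction,
  transcriptional-coherence correction (with optimizer pre-run)
- `cosmos.ilp` — the ILP formulation, MILP and exhaustive backends,
  solution pools
- `cosmos.pipeline` — forward/backward orchestration, merging, ORA
- `cosmos.evaluation` — TPR sweeps, random baselines, PKN shuffling
- `cosmos.synthetic` — generators with planted ground truth
- `cosmos.cli` — the `cosmos` command

See `docs/methods.md` for the model, its assumptions, parameter defaults and
known limitations.
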