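# Methods

`clonecn` infers allele-specific integer copy numbers for every clone of a
fixed tumour phylogeny from multi-sample bulk sequencing summaries. This
note records the model, the algorithmic choices, the synthetic-data
conditions and the known limits of what the test suite demonstrates.

## Model

A tumour is a set of clones on a rooted tree `T = (V, E)`. The root is the
normal diploid clone (`c^A = c^B = 1` in every segment); its single child is
the MRCA of all tumour cells. Each tumour clone `i` carries unknown integer
copy numbers `c^A_{s,i}, c^B_{s,i} ≥ 0` per genomic segment `s`. Bulk sample
`r` mixes clones with proportions `u_{i,r}` (summing, with the normal
fraction, to 1), so the observable allele-specific fractional copy number is
the mixture

    f^A_{s,r} = Σ_{i≥1} c^A_{s,i} u_{i,r}        (same for B).

SCNA callers supply noisy estimates `f̂` together with interval bounds
`[f⁻, f⁺]`. The evolutionary model imposes:

* **LOH persistence** — an allele at copy 0 in a clone stays at 0 in all
  descendants;
* **bounded sign alternation** — on any root-to-node path, the per-edge
  changes of one segment-allele form at most 2 maximal same-sign runs
  (one direction of change may recur; the other may appear once); edges
  with no change are transparent to the run count;
* **hom-del eligibility** — the state (0,0) is allowed only in segments
  shorter than 50 Mb and only for clones that (themselves or through a
  descendant) are present in a sample whose fractional copy number is below
  1 on both alleles;
* **parsimony** — among explanations of equal fit, the fewest unit
  copy-number events (`Σ_edges |Δc^A| + |Δc^B|`) wins.

### Per-segment optimisation

Segments are independent given the tree, so each is solved separately.
For a fixed event budget λ the solver finds integer states minimising,
lexicographically,

1. the number of samples whose predicted mixture falls outside the observed
   interval for either allele,
2. the Manhattan distance `Σ_{r,allele} |f̂ − Σ c u|`.

The search is exact. Two interchangeable engines are used:

* for small budgets (λ ≤ 4 by default), all assignments of net integer
  changes to (edge, allele) slots are enumerated, filtered by the
  evolutionary constraints, and scored vectorised — a few thousand
  candidates per segment;
* otherwise a mixed-integer linear programme (HiGHS via
  `scipy.optimize.milp`). The lexicographic order is enforced with two
  stages: stage 1 minimises the violation count, stage 2 minimises the
  Manhattan distance with the violation count capped at the stage-1
  optimum. Structural constraints (zero indicators for LOH persistence and
  hom-del eligibility, gain/loss indicators, sign-state recursions and run
  counters for the alternation bound) are first dropped; if the relaxed
  optimum already satisfies them — the common case — it is provably the
  full optimum, otherwise the full encoding is solved. Budget 0 forces the
  all-diploid labelling and is returned without a solve, and once stage 1
  reaches zero violations it is skipped for all larger budgets (the
  feasible set only grows).

Both engines agree exactly; the test suite cross-checks them against a
brute-force enumeration over all labellings on small instances.

Copy numbers are capped per segment at
`c_max = min(40, ceil(max f⁺ / max(0.05, min positive u)))`, refined per
clone to `ceil(max f⁺ / max(0.05, max_r u_{j,r}))`: a clone's copy number is
only identifiable up to what the observed upper bounds can support at its
maximal prevalence. Clones with `u = 0` everywhere keep the segment-level
cap and are canonicalised after the solve: they take their parent's state
whenever that preserves both objective values and every constraint.

### Model selection over the event budget

The true number of events per segment is unknown. The budget is swept
upwards from 0; the optimum is non-increasing in λ. The sweep stops early
when the fit is perfect, when the combined objective has not improved
materially for `patience = 3` consecutive budgets, or when the selected
budget (recomputed on the growing curve) has been stable for 3 extensions
and the sweep has explored 3 budgets past it.

The budget `λ̂` is the Kneedle knee (sensitivity 1.0) of the decreasing
convex objective-2 curve, lower-bounded by the smallest λ attaining the
minimal objective 1. A knee beyond that base is accepted only when its mean
objective-2 improvement per added event exceeds a materiality threshold

    min_drop = (mean interval half-width) / 2 · sqrt(k) / 2,

i.e. half the stated measurement uncertainty at k = 4 samples, scaled with
`sqrt(k)` because the best spurious single-event improvement grows with the
number of per-sample residuals available to chase. Degenerate curves fall
back to parsimony: a constant curve selects the base budget; a knee-free
but materially decreasing (linear) curve selects the smallest budget within
1e−6 of the minimal objective 2.

Objective 2 (with objective 1 as the primary filter) is the Kneedle input;
using the violation count itself as the knee signal would discard the
information in the residuals.

## Preprocessing

Implemented as described in the interface documentation: unweighted
bin-to-segment averaging of read depth and BAF (a bin contributes to every
segment it overlaps by ≥ 1 bp); depth-to-copy-number scaling through the
per-sample mean of `F_ref / R`; a one-sample t-test per allele and sample
against the nearest integer (P < 1e−4) flagging subclonal segments; a
two-sample t-test between alleles (P < 1e−3) flagging allelic imbalance;
and the rebalancing of subclonal, balanced segments (allele B snapped to
its nearest integer when both alleles sit above their nearest integers,
allele A when both sit below; the remainder goes to the other allele so the
total is conserved exactly). Segments with one allele above and one below
its nearest integer are left unchanged and logged — the rule is undefined
there. Segments without within-segment replicates are untestable and
treated as clonal/balanced. "Nearest integer" is round-half-to-even
throughout the package.

## Synthetic data

The generator emulates the benchmark conditions end to end:

* random rooted clone tree (diploid root, MRCA child, remaining clones
  attached uniformly at random);
* ~100 segments with log-uniform lengths (0.5–40 Mb) across 22 chromosomes
  with p/q arms;
* interval events per edge: Poisson(8) on the truncal edge, Poisson(2) on
  subclonal edges, gains and losses equiprobable, geometric run lengths
  (mean 3 segments), at most one event per segment-allele per edge;
  a whole-genome doubling with probability 0.4 on the truncal edge
  (between the LUAD and LUSC rates of non-small cell lung cancer);
  LOH persistence and the alternation bound hold by construction;
* sample composition: each sample holds the union of the root paths of 1–3
  randomly drawn clones (ancestor-closed, as a physical sample carries a
  clone's ancestral lineage remnants), Dirichlet(1.5) weights floored at
  0.05 of the tumour fraction, purity uniform on (0.4, 0.9); every clone is
  raised to at least 10% of the tumour fraction in its best sample,
  mirroring the detection limit of the SNV-based clone calling that
  upstream clone proportions come from;
* reads per segment and sample: `t ~ Poisson(f_all / ρ · γ)` with
  coverage `γ = 1000` and sample ploidy ρ (the length-weighted mean of the
  all-cell total fractional copy number), and an observed BAF
  `Binomial(γ, β)/γ` with `β = y_all / f_all`. Observed totals are
  `(t/γ)·ρ`, split by the observed BAF. The printed rescaling without the
  `1/γ` factor is available behind `literal_formula=True` but inflates
  estimates by γ; the default is unbiased, which the calibration tests
  verify. The constant normal-cell contribution (one copy per allele times
  the normal fraction) is subtracted and the result censored at zero to put
  estimates on the tumour-mixture scale the solver fits;
* interval bounds: estimate ± 1.96 × 0.1, floored at 0.

What the generator does not emulate: segmentation errors (segment
boundaries are exact and shared across samples), errors in the tree
topology or clone proportions (inference receives the truth), GC/mappability
bias, and SNP-level heterogeneity within segments. Passing tests therefore
demonstrate correct recovery given correct upstream inputs, not robustness
to upstream errors.

### Identifiability under the benchmark conditions

With coverage 1000 the per-allele read noise has sd ≈ 0.05–0.09 (larger in
genome-doubled tumours), while a clone at 5–10% prevalence shifts the
mixture by 0.05–0.1 per copy in the samples that contain it. Events private
to such clones are at the edge of identifiability: for a few percent of
(segment, clone) entries the noise makes a wrong labelling genuinely optimal
under the model objectives. An oracle experiment (solving every segment at
the true event count) bounds what any budget-selection rule can achieve;
the selection described above operates within a few tenths of a percentage
point of that bound on hard cohorts. Cohort-level exact-match concordance
is reported by `scripts/acceptance.py`.

## Downstream analytics

Clone ploidy is the segment-length-weighted mean total copy number. WGD
calls compare each clone to its parent (length-weighted mean ratio > 1.5)
and, failing that, to its grandparent (ratio > 1.5 with an unflagged
parent), skipping segments where the ancestor total is 0. Per-edge events:
gain/loss on any allele change; LOH when an allele drops from > 0 to 0;
amplification when an allele more than doubles, reaches ≥ 4 and exceeds the
child's ploidy. Arm-level calls require ≥ 90% of the analysed arm length
affected (for LOH additionally ≤ 20% of the arm at 0 in the parent);
sample-level arm LOH requires ≥ 98% of the arm below fractional 0.5 for a
single allele. The number of SCNAs on an edge counts maximal runs of
consecutive same-chromosome segments with identical non-zero deltas, per
allele (amplitude changes break runs; arm boundaries do not). Clone
classification uses clone-or-descendant presence (`u` above a configurable
threshold, default 0): shared clones appear in both primary and metastatic
compartments; seeding clones are the most recent shared clones (possibly
the MRCA itself); the rest are compartment-specific. CCD is the maximum
pairwise Euclidean distance between concatenated allele A + allele B
copy-number vectors over genomically sorted segments, unweighted by length
(a length-weighted variant is available); lymph-node-only clones should be
excluded by the caller.

## Benchmark metrics

* **accuracy** — segment-length-weighted mean Jaccard overlap between the
  sets of distinct (c^A, c^B) states of true and inferred clones; invariant
  to clone labels.
* **matched-clone HD** — for each true clone the minimal fraction of
  mismatching (segment, allele) entries against any predicted clone,
  averaged over true clones; unweighted by length by default (the
  length-weighted variant is a flag), extra predicted clones are free.
* **TVD** — per segment and sample, half the L1 distance between the
  distributions over (c^A, c^B) states with masses given by tumour-clone
  proportions renormalised by purity, averaged over segments and samples.

## Numerical choices

Rounding ties: half-to-even everywhere. Proportion columns must sum to 1
within 1e−6. Interval membership uses a 1e−9 slack. MILP gap 1e−6 by
default (0 in oracle-equivalence tests); per-solve time limit 60 s, after
which the best incumbent is returned and flagged. A rare backend solve
error is retried once with presolve disabled. All randomness flows from a
single integer seed per simulated tumour; solver and enumeration are
deterministic, so repeated runs are bit-identical and segment results do
not depend on execution order.

## Limitations

The tree topology and clone proportions are trusted as given; errors in
them propagate directly. The alternation bound is applied per allele
(whether the published model couples alleles on a path is ambiguous).
Fractional copy numbers are assumed to be on the tumour-mixture scale
(purity-corrected); inputs on the whole-sample scale must be corrected
upstream. Runtime grows steeply with clone count for segments needing
budgets beyond the enumeration range.
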