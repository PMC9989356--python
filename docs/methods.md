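# Methods

This note documents the models, defaults and numerical choices behind
`stemkv`, and what the synthetic benchmarks do and do not demonstrate.

## The ancestral-count statistic

Given a rooted gene-family tree with tip labels resolvable to species and
per-node supports (posterior probabilities in [0, 1]), and a partition of
species into two focal lineages (here Anthozoa and Medusozoa), an
*ancestral ortholog group* is a minimal element, under clade containment,
of the candidate set

> { clades C : support(C) ≥ θ, C contains ≥ 1 tip from each focal
>   lineage, C not dissolved by a merge directive }.

Because the clades of one tree form a laminar family, minimal candidates
are exactly the candidates with no candidate strict descendant, and they
are pairwise disjoint; both facts are exercised by a brute-force
enumeration oracle (`brute_force_groups`) on hundreds of random trees.
The group count estimates the gene count of the focal-split ancestor:
one group = one ancestral gene with surviving descendants on both sides.

Decisions a user should know about:

* **Threshold comparison is inclusive (≥ θ, default θ = 0.95).** Strict
  (> θ) is available as a flag. A clade at exactly 0.95 therefore counts
  by default.
* **Per-clade overrides** lower θ for a single clade identified by its
  exact tip set, reproducing the common practice of accepting one
  slightly sub-threshold clade on external evidence without loosening
  the genome-wide rule. **Merge directives** dissolve all proper
  subclades of a named tip set, so a species-rich clade with weak
  internal resolution is evaluated only at its joint ancestor.
* **Unannotated nodes fail the threshold** (consensus-tree semantics: an
  unannotated node is unresolved). This is configurable
  (`unannotated_support`, CLI `--assume-support`); a tree with no
  supports at all is a hard error rather than a silent all-pass.
* **The root counts as a clade with support 1.0**, so a family with a
  single ancestral gene is countable.
* **Rooting** (`root_by_outgroup`) reassigns supports by bipartition:
  supports annotate bipartitions, which rerooting does not change, so
  each internal node of the rerooted tree receives the support of the
  bipartition it now represents.

Known bias, shared with the method itself: if an ancestral gene lost all
descendants in one focal lineage, no clade witnesses it and it cannot be
counted; conversely if two ancestral genes each survive in only one
(different) lineage, their joint ancestor is the smallest dual-lineage
clade and the two genes are counted as one. The simulator's bookkeeping
makes both effects measurable (below).

## Classification

The built-in scorer is exact Smith–Waterman (affine gaps) via
`Bio.Align.PairwiseAligner`, BLOSUM62 with gap open 11 / extend 1, and
Karlin–Altschul E-values E = K·m·n·e^(−λS) using the published ungapped
BLOSUM62 constants (λ = 0.3176, K = 0.134) with the reference database's
total residue count as n. These E-values are a ranking statistic for
desk-scale reciprocal searches, not calibrated BLAST statistics; the
acceptance rule (E < 0.01, strict) is applied to them. A query's call is
the annotation of its best reference hit, accepted when the reference's
best back-hit lands in the query's cohort: in **cohort** mode (default)
the back-hit must carry the same proposed family/subfamily call; in
**strict** mode it must be the query itself. Score ties break by
lexicographic target id and are logged.

Diagnostic-domain presence is scored by local alignment against a
profile consensus (per-column plurality of an aligned reference block).
Score thresholds are not hard-coded: they are set at a quantile (default
99.9%) of an empirical null built from residue-shuffled copies of the
consensus, seeded and logged. Completeness then requires S1–S6 core plus
T1 (Kv), core plus coiled-coil (KCNQ), or core plus C-linker/CNBHD
(EAG) — the eag/PAS domain is deliberately not required because it has
been lost repeatedly in Erg-subfamily channels. The missing-data filter
removes aligned sequences whose gap/X fraction strictly exceeds 10% of
the aligned columns (a sequence at exactly 10% survives).

## Gate scoring

The S6 activation-gate consensus is the per-column plurality over
designated α-subunits within an explicit 1-based column window; the
window is a required input, not auto-detected, because it is an
alignment-specific choice. The admissible chemical classes at a column
are those observed among α-subunits. A position in a candidate gate is
nonconservative when its residue's class is not admissible, or when the
consensus residue is structurally special (P or G — both set backbone
geometry at the bundle crossing) and the residue differs at all. One
nonconservative position makes a sequence `degenerate`; an all-missing
gate is `missing_data` and is excluded from group-level calls. A group
is `ancestral_degenerate` when each focal lineage contributes at least
one degenerate member — the sequence-level signature that the R-subunit
phenotype predates the lineage split. The default class partition
(hydrophobic AVLIMFWYC / polar STNQ / basic KRH / acidic DE / P / G) is
one reasonable chemistry; it is fully configurable, and any claim about
a specific dataset should report sensitivity to it.

## The simulator

`simulate_gene_tree` runs a per-lineage Gillespie process: within each
species-tree branch every gene lineage waits Exp(λ + μ); a duplication
splits it, a loss ends it, and at a speciation all survivors copy into
both daughters. n₀ genes start at the species-tree root, which is the
Anthozoa/Medusozoa split, so the recorded truth — per-gene survival and
the number of root genes with surviving tips in both focal lineages
(`dual_survivors`) — is exactly what the group counter should recover.
Surviving per-gene subtrees are joined at a root polytomy. The expected
per-species tip count is n₀·e^{(λ−μ)T} (T = root depth, 1.0 by default);
the empirical mean over 2000 replicates sits within three standard
errors of this closed form in the acceptance battery.

The default species tree is the eight-species cnidarian topology with
unit depth and equal internal timings (no published divergence times are
assumed). Supports are Beta draws with mean 0.99 and concentration 200
(most nodes ≥ 0.95, occasional weaker ones), with an optional fraction
of nodes forced uniformly below θ; `concentration=None` makes draws
deterministic, which with mean 1.0 gives perfect supports for recovery
tests. The truth-recovery battery simulates single-gene families
(n₀ = 1) across a λ/μ grid because that is the regime where recovery is
an exact identity; for multi-gene simulations the root-polytomy clade
can merge genes that each survive in only one lineage (the bias noted
above), which is a property of the statistic, not of the simulator.

Emitted proteins are concatenations of frozen synthetic domain blocks:
T1 + S1–S6 core for Kv (135 aa), PAS + core + C-linker/CNBHD for EAG
(180 aa), core + coiled-coil for KCNQ (125 aa). Family cores descend
from one ancestral core (≈ 75% cross-family identity) and subfamily
cores from their family core (≈ 88% within-family identity), giving
reciprocal best-hit search realistic contrast; the cytoplasmic blocks
are family-specific and unrelated across families. The core carries the
Shaker-type gate motif PVPVIV at fixed columns (112–117 of the Kv
concatenation). Along each branch every site substitutes with
probability 1 − e^(−r·L) (default r = 0.05 per site per unit time);
there are no indels, so family-wise output is alignment-ready without
running an aligner. Tips of R-flagged Kv genes receive forced
nonconservative substitutions at two gate positions (a proline column
and a hydrophobic column).

What the synthetic benchmarks do **not** show: the emitted sequences
have uniform site rates, no indels, no compositional bias and no
alignment error, and the support model is not a posterior from a real
MCMC run. Passing the batteries therefore demonstrates correctness of
the algorithms under the stated models, not robustness of the biology to
alignment or inference artifacts in real data; the deposited-data
recomputation is the check against reality and requires the original
supplementary archive.

## Problem sizes and determinism

Default batteries use 500 random ≤ 16-tip trees for oracle equivalence,
100 trees for θ-monotonicity, 200 single-gene families for recovery,
2000 replicates for the birth–death mean, and ~150–200 emitted sequences
for classification accuracy; all complete in seconds on one CPU. Every
stochastic component takes an integer seed (numpy `default_rng` /
`SeedSequence`); identical seeds reproduce trees, supports, sequences
and benchmark bundles byte for byte.
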