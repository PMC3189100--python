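# Methods

## Model

Let `P ∈ {0,1}^{N×M}` be the immutable gene-by-pathway membership snapshot
(`p_ij = 1` iff gene *i* belongs to pathway *j*) and `G` a vector of per-gene
log2 ratios for one experiment. Genes are discretized by a threshold
`c > 0`:

```
X(i) = +1 if G(i) > c,   −1 if G(i) < −c,   0 otherwise
```

with *strict* inequalities, so a ratio landing exactly on ±c is stable.

An allocation `A ∈ {0,1}^{N×M}` states which member pathways each gene is
currently serving. It is *valid* when `A ≤ P` entrywise, every expressed
gene keeps at least one pathway (the all-zero row is rejected), expressed
single-membership genes keep their only pathway, and stable genes are not
allocated at all. Stable genes are removed from the search state entirely
but retained in the per-pathway reports, where a stable gene is counted in
every pathway it belongs to (the report describes the membership, not the
allocation). In module mode, validity additionally requires that no gene
occupies both members of a declared opposing pair — modules such as
glycolysis and gluconeogenesis are never active simultaneously, so a shared
expressed gene may serve at most one.

The consensus fitness is

```
F(A) = Σ_j | net_j |,    net_j = Σ_i H(a_ij),    H(a_ij) = X(i)·a_ij
```

`net_j` is the number of allocated up-regulated genes minus allocated
down-regulated genes in pathway *j*. Summing |net_j| rewards filling each
pathway with genes of agreeing direction, whichever direction that is; the
signed nets (and their plain signed sum) are exposed on `FitnessValue` for
callers who want the raw quantity. Ties between equal-fitness allocations
are left to the searches' acceptance rules — the fitness has no secondary
objective.

## Searches

All three methods move only the expressed multi-membership genes; a problem
with none of those is reported as "nothing to optimize" and returns the
fixed allocation unchanged.

**Initialization.** Each free gene's row is drawn uniformly from its
`2^n − 1` non-empty binary strings — uniform because the null model below
counts all valid strings equally. In module mode a row violating an
opposing pair is resampled until valid, which preserves uniformity over the
remaining valid rows (a deterministic repair would not).

**Moves.** A free gene and one of its member pathways are chosen uniformly
and the bit is toggled. A removal that would empty the row triggers
reassignment to a uniformly chosen member pathway (possibly the same one, in
which case the move is a no-op — the literal reading of the reassignment
step). In module mode an add (including a forced reassignment) evicts the
gene from the opposing module. Move deltas are computed incrementally from
the affected pathways' nets; a property test asserts the delta equals a full
re-evaluation.

**Hill climbing** accepts a move unless it strictly decreases fitness;
plateau moves are accepted, so the current fitness — and hence the trace —
is non-decreasing.

**Simulated annealing** additionally accepts a fitness loss ΔF with
probability `exp(−ΔF/T)`. The temperature follows the geometric schedule
`T_t = T0·λ^t`, `λ = exp((ln T_final − ln T0)/I)`, with defaults `T0 = 1`,
`T_final = 0.01`, `I = 10000` iterations. The best-so-far allocation is
tracked separately from the current one and returned. Proposal and
acceptance draws come from separate child generators of the seed, so in the
`T → 0` limit annealing replays hill climbing bit-for-bit on the same seed
(a unit test asserts this).

**Genetic algorithm** (defaults: 100 individuals, 400 generations). Each
generation every parent is mutated — each free gene with probability
1/(number of free genes) flips one uniformly chosen member-pathway bit, so
on average one gene mutates per individual; a flip that would empty a row is
redrawn. Mutated individuals are paired by a random permutation and crossed
over at a single cut point on the gene order (rows are inherited whole, so
offspring are always valid; an odd leftover passes through unchanged).
Parents, mutated individuals and offspring are pooled, sorted by fitness
(stable sort; ties keep pool order) and truncated to the population size.
Retaining parents makes the per-generation best fitness non-decreasing.

Determinism: equal (method, config, seed, inputs) give bit-identical
results. Traces are reported per iteration (HC/SA) or per generation (GA);
`n_fitness_evaluations` is also recorded so convergence can be compared
across methods on a common axis of fitness calls.

## Exact Hamming-distance null

For one gene with `n` member pathways there are `2^n − 1` valid rows. Over
all `(2^n − 1)²` ordered pairs of valid rows, the number at Hamming
distance `r` is

```
r = 0:   2^n − 1
r ≥ 1:   C(n, r)·(2^n − 2)
```

(among all `2^n` strings there are `2^n·C(n,r)` ordered pairs at distance r,
of which `2·C(n,r)` involve the forbidden zero string). The counts sum to
`(2^n − 1)²` exactly — asserted for n = 1..12 — and the closed form is
cross-checked against exhaustive enumeration in the tests. Counts are kept
as exact Python integers and probabilities as exact rationals at any n; the
whole-experiment null convolves the per-gene counts over expressed
multi-membership genes only (all other rows are identical in any pair of
valid allocations and contribute distance zero). The reported tail is the
*lower* tail P(distance ≤ observed) — "at least this similar by chance" —
with the complementary tail available from the same exact CDF.

A note on printed precision: the exact two-gene combined masses are 9/81,
24/81, 28/81, 16/81, 4/81, i.e. 0.111 / 0.296 / 0.346 / 0.198 / 0.049 at
three decimals. Merging the per-gene table *after* rounding it to three
decimals instead yields 0.345 and 0.197 at distances 2 and 3 — the form in
which such combined tables are conventionally printed. The library computes
the exact values; the acceptance script reproduces the printed-precision
merge explicitly.

## Fuzzy adjusted Rand index

The pair-counting agreement between two allocations, extended to
multi-assignment. Each allocation is read as a fuzzy partition with equal
weights: a gene allocated to k pathways has membership 1/k in each. For a
gene pair, the co-membership degree in one partition is
`s = Σ_j min(u_ij, u_i'j)`. Per pair we accumulate agreement-together
`min(s_D, s_E)`, agreement-apart `min(1−s_D, 1−s_E)`, and the residual
`|s_D − s_E|` split by sign into the two disagreement cells — the four cells
always sum to one — then apply the pair-count form of the adjusted Rand
index, `ARI = 2(ad − bc)/((a+b)(b+d) + (a+c)(c+d))`.

This variant was chosen (among several published fuzzy ARI extensions)
because it satisfies three contracts simultaneously: it reduces *exactly* to
the classical adjusted Rand index on hard partitions (tested against an
independent implementation to 1e−10), it scores exactly 1 for identical
allocations (b = c = 0), and it is invariant to consistent pathway
relabelling. A purely min-based cell decomposition fails the second
contract for genuinely fuzzy rows. Its mean over independent random
partitions is ≈ 0. The variant identifier is exported as
`pathalloc.stats.FARI_VARIANT`. Genes allocated nowhere in both matrices
(stable genes) are excluded from the comparison; a gene empty on one side
only is an input error.

Because FARI counts co-placement rather than positions, two runs that keep
the same gene groups together but swap which pathway each group occupies
score FARI 1 while the Hamming similarity collapses — a directional test
fixes this behaviour.

## Enrichment

`enrichment_pvalue` evaluates the hypergeometric upper tail — the
probability of observing at least k category genes in a set of n drawn from
a genome of G containing C category genes — directly in log space
(log-binomials via `gammaln`, summed from the upper end), which is
mathematically identical to the complement of the lower sum and numerically
sound for small p. k = 0 returns exactly 1. The test suite checks 1000
random queries against an independent hypergeometric survival-function
implementation to 1e−10; that oracle is never used inside the package.

## Synthetic instances

The generator emulates the net-effect premise: every pathway gets an
activation direction ±1 (optionally 0 for inactive), each gene is planted in
a subset of its member pathways, and its log2 ratio is
`sign(net) · (c·(1+1e−6) + |N(0, σ)|)` where `net` sums the planted
directions. The microscopic relative margin keeps the zero-noise limit
strictly past the strict discretization cutoff; with `net = 0` (possible
under the `"random"` planting rule) the ratio is drawn uniformly inside the
stable band. Defaults: 60 genes, 8 pathways, 40 % multi-membership with at
most 3 memberships per gene, noise σ = 0.25 (a quarter of the default
threshold c = 1), chosen as a desk-scale instance on which the searches'
behaviour is representative yet enumeration-adjacent checks stay fast.

Under the default `"consensus"` planting rule a gene's regulatory demand is
the direction of one randomly chosen member pathway and the gene is planted
in *every* member pathway sharing that direction. This makes the planted
allocation the optimum of the consensus fitness, so planted-structure
recovery measures search quality directly rather than conflating it with
model mismatch. The `"random"` rule (uniform non-empty subsets, cancellation
possible) exercises the stable-gene path.

What the generator does **not** emulate: probe-level noise and
normalisation artefacts, correlated noise across genes, repressor genes and
isoenzymes whose expression legitimately contradicts their pathway's
direction, and the scale of real KEGG snapshots (hundreds of pathways,
thousands of genes). Passing recovery tests therefore demonstrates that the
searches optimise the stated objective and that the statistics behave as
specified — not that the biological allocations inferred from any real
dataset are correct.

## Problem sizes used in the tests

Enumeration-backed optimality checks use 50 random instances with at most
12 free allocation bits (exhaustive enumeration is the independent oracle);
annealing and hill climbing run their default 10000 iterations, the genetic
algorithm a reduced 60×150 regime, ample for these search spaces. Recovery
and reproducibility suites use the default 60×8 synthetic instance over 10
seeds. A frozen 7-free-gene instance on which hill climbing stalls below
the enumerated optimum on a fair share of seeds — while annealing attains it
on all tried seeds — is kept as a regression fixture.

## Numerical and degenerate-input choices

* Exact integer/rational arithmetic throughout the null machinery; floats
  only appear on output.
* `temperature_schedule` endpoints are exact to ~1e−15 relative error;
  `acceptance_probability` underflows gracefully to 0 for large ΔF/T.
* Degenerate problems (no expressed multi-membership genes) short-circuit
  with a constant trace rather than erroring.
* File outputs are byte-identical across identical runs (version, seed and
  a config hash in the header; no timestamps).

## Known limitations

* The fitness treats all genes equally; repressor-aware weighting is out of
  scope.
* Only set membership is modelled — no pathway topology, reactions or
  stoichiometry.
* The exact null assumes both compared allocations are uniform over valid
  rows; search outputs are concentrated near optima, so the null is a
  calibration reference, not a sampling distribution of search results.
* Live KEGG retrieval, GEO parsing and figure rendering are intentionally
  absent; inputs are plain GMT/TSV.
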