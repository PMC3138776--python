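# Methods

## The statistical model

A "community" here is the set of taxa sharing one medicinal use category
(or one named condition such as malaria) — a subset of the tips of a rooted
phylogeny with branch lengths. The null hypothesis throughout is that such
a community is a uniform draw of *n* tips from the *N*-tip pool: usage is
unrelated to phylogeny. Two departures from that null are tested.

**Clumping of the whole community.** For a community S with |S| = n ≥ 2 and
patristic distance d(i, j):

- MPD(S) = mean of d(i, j) over all pairs {i, j} ⊂ S;
- MNTD(S) = mean over i ∈ S of min_{j ∈ S, j≠i} d(i, j).

MPD responds to co-occurrence in deep clades, MNTD to tight clusters near
the tips; both shrink when the community is clumped. The permutation test
draws R random n-subsets, and reports the one-tailed clumping p-value

    p = (k + 1) / (R + 1),   k = #{null draws with metric ≤ observed},

the add-one form that cannot return 0 and counts ties conservatively as
"at least as clumped". Standardized effect sizes use the NRI/NTI sign
convention SES = (mean_null − obs) / sd_null (sd via the sample estimator,
ddof = 1; SES defined as 0 when sd_null = 0, which occurs only in the
degenerate n = N case). Both metrics are evaluated on the *same* null
draws, as randomization-based implementations of this test conventionally
do. For small problems `exact_signal_p` enumerates all C(N, n) subsets
(default cap 10^6) and returns the exact tie-inclusive tail probability;
the permutation estimate converges to it as R grows, which the test suite
checks at R = 20,000 within 3 Monte-Carlo standard errors.

**Localization (hot nodes).** For each internal node v with descendant tip
count D_v, 2 ≤ D_v ≤ N−1 (the root is excluded — it contains every
community trivially), the count X_v of community members below v is
compared with the uniform-draw null, under which X_v is exactly
Hypergeometric(N, D_v, n). Two modes are provided and agree in the limit:

- `exact`: p_more = P(X ≥ X_v) from the hypergeometric upper tail;
  flag `MORE` when p_more ≤ 0.025.
- `permutation`: R random n-subsets; p_more = (#{null X ≥ X_v} + 1)/(R + 1);
  flag `MORE` when the observed count strictly exceeds the null count in at
  least 97.5% of runs — the convention of the randomization tool this stage
  mirrors, with "strictly greater" as the tie rule.

Underabundance (`LESS`) is computed symmetrically and reported but never
highlighted. No multiple-testing correction is applied across nodes or
samples by default (raw p matches the classical reports this pipeline
emulates); Benjamini–Hochberg columns are available behind a flag.

## Null model choice

The randomization scheme is a uniform draw of n distinct tips from the
full pool (`pool_draw`). For presence/absence data this coincides with
shuffling tip labels across the whole tree, and `label_shuffle` is exposed
as an explicit alternative code path; the two are distributionally
identical here and exist separately only so the choice is visible in
provenance headers. R defaults to 999. Per-sample RNG substreams are
derived from (seed, sample name) via CRC32, so adding or removing one
sample never perturbs another sample's p-values.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `runs` (R) | 999 | null randomizations per test; p resolution is 1/(R+1) |
| `alpha` | 0.05 | significance level used by calibration summaries |
| `model` | `pool_draw` | randomization scheme (see above) |
| `flag_fraction` | 0.975 | MORE threshold: observed > null in ≥ this fraction of runs (≙ p ≤ 0.025 exact) |
| `birth_rate` λ | 1.0 | Yule speciation rate; only sets the time unit |
| `clump_fraction` f | — | fraction of a synthetic community drawn from one focal clade |

Distances carry the input tree's branch-length units. Every p-value and
SES is invariant under multiplying all branch lengths by a positive
constant (tested), so only relative lengths matter.

## Synthetic data and calibration

`simulate_yule_tree` grows a pure-birth tree forward in time (waiting time
Exponential(k·λ) with k extant lineages, uniform choice of the splitting
lineage, growth stopped at N tips plus one final waiting time so pendant
edges are positive). The result is ultrametric by construction. Pure birth
was chosen over birth–death because extinction only rescales and reshapes
branch lengths, to which the tests are largely insensitive, and the
simpler model is fully reproducible from a single generator.

`simulate_community` plants clumping directly: m = ceil(f·n) members come
from one focal clade chosen uniformly among internal nodes whose size D
satisfies m ≤ D ≤ N − (n − m) (both the clade and its complement can
supply their shares; ceiling rounding guarantees at least the requested
clumped fraction), and the remaining n − m members are drawn uniformly
outside it. f = 0 reduces exactly to the null (uniform draw, no focal
clade).

The calibration harness pairs a fresh tree with a fresh community per
replicate and records the rejection rate of each metric at alpha, with
Clopper–Pearson 99% intervals. The study conditions used in the tests and
the acceptance script are 100-tip trees, n = 10, R = 999, alpha = 0.05 and
500 replicates; under f = 0 the MNTD rejection rate sits inside the exact
binomial 99% interval around 0.05, and under f = 1 power exceeds size by a
wide margin for both metrics (typically ≈ 0.8–0.95).

What the generator does *not* emulate: real use matrices have few tips
(tens, not hundreds), correlated samples (the same taxa recur across
categories), accession-level tips for single species, and trees that are
additive but not ultrametric. Passing calibration therefore shows the
machinery is statistically correct under its own null, not that any
particular empirical dataset will yield signal.

A note on metric power ordering: MNTD is often described as the
tips-sensitive metric and MPD as the deep-node metric. In this generator,
when the whole community is confined to one small clade both metrics
saturate near power 1, and averaged over uniformly chosen focal clades MPD
is at least as powerful as MNTD (a fully contained clade is also a deep
signal). The tests therefore assert the robust orderings only —
power(f=1) > size(f=0) for each metric — and leave the MNTD-vs-MPD
contrast as a reported, scenario-dependent quantity.

## Numerical and design choices

- **Patristic distances** are computed in one post-order pass: each node
  carries (tip index, distance-to-node) arrays and cross-child blocks fill
  the matrix, so no per-pair traversal occurs. Verified against naive
  parent-pointer path enumeration on random trees.
- **Ties.** Permutation and enumeration counts treat values within a
  relative 1e-12 of the observed metric as ties (counted toward clumping);
  exact ties are real, e.g. exchangeable sister tips on ultrametric trees.
- **Zero-length branches** are permitted (common in ML trees) with a
  warning, since they make distinct tips equidistant and MNTD ties likely.
- **Missing branch lengths** are an error by default; an explicit
  unit-branch-length fallback substitutes 1 for every edge and is
  documented as changing all distances.
- **Tip labels** are normalized (outer whitespace stripped, inner spaces →
  underscores) on both tree and matrix sides before matching. A species
  scored once in a use matrix can be expanded to all its accession tips
  through a mapping table; unmatched taxa are an error unless pruning is
  requested.
- **Rooting.** The input tree is used as rooted as written. Outgroup
  removal is the caller's choice (`--prune`), because whether outgroups
  belong in the tip pool is a study-design question: keeping them dilutes
  the null toward overdispersion, pruning restricts inference to the
  ingroup. The provenance header records the choice.
- **Samples with n < 2** are skipped with a warning by the signal stage
  (the metrics are undefined); the node stage runs for any n ≥ 1.
- **Determinism.** All outputs are byte-reproducible for a fixed seed;
  provenance headers carry seed, R, null model, version and input
  checksums, and deliberately no timestamps.

## Known limitations

- Presence-based only: report counts and informant consensus never weight
  the tests.
- The node test uses tip counts, not branch lengths; a hot node's support
  does not depend on how divergent its descendants are.
- Raw p-values across ~17 samples and ~N nodes imply some false positives
  at 0.05; the optional BH columns address this at the cost of departing
  from the classical reporting convention.
- The exact enumeration oracle is limited to C(N, n) ≤ 10^6 by design.
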