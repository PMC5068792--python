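# Methods

## The question and the statistical objects

Along a stress gradient such as soil pH, the *nestedness* hypothesis says the
communities of harsher sites are subsets of those at milder sites: the taxa
that tolerate acid soil are habitat generalists present everywhere, while
acid-sensitive taxa drop out as pH falls.  The package tests this on a
phylotype-by-group community matrix whose **column order is imposed by the
hypothesis** (decreasing pH; in a two-inoculum experiment, one column block
per inoculum, each internally sorted by pH) and whose rows are sorted by
phylotype occurrence.  Two complementary indices are computed on the same
matrices: NODF over columns on presence/absence (are species-poor communities
subsets of species-rich ones?) and weighted NODF over rows on relative
abundance (is the abundance ranking of each phylotype consistent across
sites?).  A nested species pool can still show *anti-nested* abundance — a
negative WNODF Z — when local dominants differ along the gradient.

### Index conventions

For an ordered pair with `left` the element placed earlier:

* paired NODF = `100 · |shared presences| / fill(right)` if
  `fill(right) < fill(left)`, else 0;
* paired WNODF = `100 · #{k : 0 < right_k < left_k} / #{k : right_k > 0}` if
  `sum(right) < sum(left)`, else 0 (cells tied at a positive value do not
  count as nested);
* the matrix index is the unweighted mean of paired terms over all ordered
  pairs along the chosen axis (`both` pools row and column pairs), so it lies
  in [0, 100].  An empty right vector contributes 0 (degenerate, logged).

Because the orientation follows the given order, the index measures
nestedness *with respect to the gradient hypothesis*.  `ordering="by_marginal_total"`
re-packs rows and columns by totals first, recovering the conventional
maximally-packed index; that variant is invariant to input permutations
(ties zero the pair in either orientation, so tie order is immaterial).

## Null models and significance

* **Binary fixed–fixed**: uniform over all 0/1 matrices with the observed row
  and column totals.  Sampler: curveball trades (default) or 2×2 checkerboard
  swaps with rejection.  Both proposals are symmetric, so with self-loops
  counted the chain's stationary law is exactly uniform; `burn_in` (default
  `5·max(rows, cols)`) and `thin` (default 10) count *attempted* moves —
  counting only accepted moves would re-weight states by their acceptance
  probability and bias the ensemble.
* **Quantitative margins-fixed** (WNODF default): uniform over non-negative
  integer matrices with the observed row and column totals, sampled by ±1
  transfers on random 2×2 submatrices (a symmetric, irreducible chain on the
  transportation polytope's lattice points; defaults `burn_in = 20·cells`,
  `thin = cells`).  This extends the same margin constraint the binary test
  uses to the quantitative matrix.  When the analyzed matrix is a normalized
  percentage matrix, the pipeline randomizes the underlying occurrence counts
  and pushes every null sample through the identical per-column
  normalization, so observed and null are on the same scale.  Two alternative
  schemes are selectable: `skeleton_shuffle` (fixed–fixed skeleton plus
  random reassignment of the observed positive values — preserves fill and
  the value multiset but not margins; on dominance-turnover data its null is
  so disordered that observed WNODF sits *above* it, masking
  anti-nestedness, which is why it is not the default) and
  `cell_permute_within_rows`.
* **Significance**: `Z = (obs − mean)/SD` over `n_null` samples (default
  1000); `p_upper = (#{null ≥ obs}+1)/(n_null+1)` and the analogous
  `p_lower`, never 0 by construction.  A null with zero spread reports
  `Z = None` with the p-values still valid.  A matrix admitting no
  perturbation (e.g. perfectly nested margins) yields a singleton ensemble
  and a warning.

The fixed–fixed family is deliberately conservative: the margins themselves
encode much of a filtering-induced nested structure, so realistic gradient
data of ~50 taxa × 6 sites typically yields Z around 1–2 even when the
generating process is strongly nested.  Users should treat a modest positive
Z with a small `p_upper` as the expected signature, not demand large Z.

## SDR simplex

Per unordered column pair: binary `S = a/n`, `D = |b−c|/n`,
`R = 2·min(b,c)/n` with `n = a+b+c`; abundance mode replaces the counts by
Ruzicka components `A = Σ min`, `B = Σ (x−y)⁺`, `C = Σ (y−x)⁺`.  S+D+R = 1
per pair; percentage contributions of turnover (1−S), agreement (1−D) and
nestedness (1−R) are unweighted means over pairs (×100), so the three sum to
200.  A totals-weighted (ratio-of-sums) aggregation is available behind
`aggregate="pooled"`.  Pairs with an empty union are excluded and logged.
This nestedness component is a different quantity from NODF/WNODF and the two
are not numerically comparable.

## PERMANOVA, Mantel, distances

One-way PERMANOVA uses the direct distance-based partition
(`SS_total = Σ_{i<j} d²/N`, within-group analogue per group) and pseudo-F
against `N − a` residual df; the two-way crossed balanced form partitions
among-level SS per factor, interaction as among-cell SS minus main effects,
residual as within-cell SS, each term tested against the residual mean
square.  P-values come from unrestricted permutation of observations (9999
by default, add-one corrected); `n_perm="exhaustive"` enumerates all distinct
relabelings for small designs, and then p is the exact ensemble fraction
(identity included).  Mantel correlates the strict upper triangles and
permutes one matrix's labels (two-sided by default).  Distances implemented:
Jaccard (sample-level presence/absence), Morisita–Horn (pooled site
frequencies; clipped to [0, 1] against floating-point overshoot), Ruzicka.
pH is treated as a plain real number throughout, and the Mantel
environmental distance is the absolute difference of per-site summaries
(mean pH by default; any per-site scalar can be supplied).

## Rarefaction and generality

Hypergeometric rarefaction: `E[S_n] = Σ_i (1 − q_i)` with
`q_i = C(N−N_i, n)/C(N, n)`, and
`Var[S_n] = Σ_i q_i(1−q_i) + 2 Σ_{i<j} [C(N−N_i−N_j, n)/C(N, n) − q_i q_j]`;
binomial coefficients are evaluated via log-gamma, so clone totals in the
thousands are safe.  The sufficiency criterion compares the 95% CI half-width
(`1.96·√Var`) to a threshold (default 0.4 taxa) at a configurable point of
the curve; the default evaluation point is the penultimate subsample size
(`n = N − 1`) — the variance at `n = N` is identically zero, so the
penultimate point is the closest determinate reading of an "endpoint CI"
criterion — and a fractional point (`at=0.67` etc.) is available.

Generality profiles record, per phylotype, the number of occupied samples,
the lowest occupied pH (acid tolerance) and the SD of occupied-sample pH
(niche breadth, sample SD with n−1).  Profiles with fewer than 3 occurrences
(configurable) are excluded from the Pearson correlation of breadth against
tolerance; p comes from the t distribution with n−2 df.  A significantly
negative r is the generalist signature.

## Synthetic data generator

The generator emulates a six-site trap-culture survey: site mean pH evenly
spaced 3.2–7.2, 12 samples per site with Normal(site mean, 0.2) sample pH,
50 phylotypes with lower tolerance limits `L_j ~ U(3.0, 7.0)`.  Mechanisms,
each with its default:

* **Regimes** — `nested`: a phylotype can colonize any sample with
  `pH ≥ L_j`; `turnover`: only within `[L_j, L_j + 1.5]`; `random`: pH is
  ignored.
* **Site availability** (0.6) — each phylotype's propagules reach a given
  site independently of pH, the dispersal/soil-type patchiness that keeps
  real pooled matrices imperfectly nested.  Calibrated once so the pooled
  presence matrix's NODF (~55) and the abundance matrix's WNODF (~30, with
  dominance on) match the magnitudes typical of field surveys of this shape.
* **Occupancy thinning** (Bernoulli, p = 0.6 per sample) — pooled frequencies
  vary over 0..n rather than saturating.  An optional niche-edge ramp
  (`occupancy_ramp`, off by default) thins occupancy toward each phylotype's
  limit; it is off because it superimposes a pH-aligned frequency gradient
  that cancels the dominance-turnover signature.
* **Clone-limited detection** (25 clones per sample) — clones are allocated
  multinomially among colonists and a colonist drawing zero clones goes
  unrecorded, as in a real clone library.  This is the only channel through
  which abundance structure reaches the pooled frequency matrix (pooling
  counts samples-with-detection) and the main source of imperfect nestedness
  at rich sites.  `detection="complete"` guarantees every colonist a clone,
  making occupancy and detection coincide; with full occupancy and
  availability the pooled presence matrix is then perfectly nested by
  construction (used as an exactness check).
* **Dominance shift** (off by default) — multinomial clone weights are a
  Gaussian (width 0.5 pH) around a per-phylotype optimum at `L_j + 0.25`,
  plus a floor of 0.3 that keeps off-optimum colonists detectable.  Optima
  near the tolerance limit mean acid-tolerant taxa dominate acid sites and
  are subordinate at neutral sites: incidence stays nested while abundance
  is anti-nested.

What the generator does **not** emulate: phylogenetic correlation among
phylotypes, spatial autocorrelation within sites, host-plant effects (the
emulated design holds the host constant), inter-annual variation, PCR or
chimera artifacts, and upper pH limits in the nested regime (acid-tolerant
taxa are pure generalists).  Tests passing on this generator therefore
demonstrate correctness of the statistical machinery and recoverability of
gradient structure under idealized sampling, not robustness to those
real-data complications.

Ground truth (limits, optima, sample pH) is always returned; all randomness
flows from one seeded generator, and output is byte-identical across runs
with the same seed.

## Numerical and design choices

* Tie-breaks in both hypothesis sorts: marginal total descending, then label
  — determinism matters because the imposed order enters the index.
* Empty rows/columns are dropped with a logged warning rather than erroring
  (pooling subsets of samples can orphan phylotypes).
* Records with a clone count of zero are rejected at read time; an absent
  taxon has no row.
* All Monte-Carlo p-values use the add-one correction; seeds are recorded in
  every result object for replay.
* `scripts/acceptance.py` uses `n_null = 1000` and `n_perm = 9999` and
  finishes in well under a minute; the pytest suite scales its replicate
  counts (e.g. 20 nested-regime replicates at `n_null = 200`) to keep a full
  run at a few minutes.
* The pH-manipulation emulation in the acceptance script grows one
  18-phylotype pool (limits U(3.0, 5.4)) at pH 3.4/4.0/5.5 and derives the
  acidic-inoculum communities by restricting to phylotypes with
  `L_j ≤ 3.9` (the survivors of an acidic source soil); pots are pooled per
  inoculum × pH cell, and cells are trimmed to equal size before the two-way
  PERMANOVA so the crossed design stays balanced even if a pot yields no
  detections.

## Known limitations

* The fixed–fixed NODF test has low power at small column counts (see
  above); with six sites, detecting nestedness beyond the margins requires a
  strong or lucky signal.  This is a property of the null model, not of the
  implementation.
* The margins-fixed quantitative null requires integer matrices; normalized
  matrices must be randomized through their underlying counts (the pipeline
  does this automatically).
* Two-way PERMANOVA supports balanced crossed designs only, with unrestricted
  permutation of raw observations; restricted permutation schemes are not
  implemented.
* Rarefaction assumes exchangeable clones within a pooled library; it does
  not model per-sample library structure.
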