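# Methods

## Problem setting and model

The package detects gene conversion — non-reciprocal replacement of a
sequence tract by a diverged homolog — between two groups of aligned
sequences with low within-group and high between-group diversity. All
statistics operate on a directed triplet `(target, parentA, parentB)`:
`parentA` represents the target's own group (its consensus, or an
explicit group member), `parentB` the putative donor group. The triplet
is reduced to its informative sites: columns where `parentA ≠ parentB`,
all three characters are unambiguous bases, and the target equals
exactly one parent. Columns with gaps, N or IUPAC ambiguity codes in any
of the three sequences are excluded, as are columns where the target
matches neither parent — such sites carry no signal about which parent
the target locally resembles and would dilute the background proportion.
Coordinates are 0-based half-open internally and 1-based inclusive in
reports.

## The window statistic

For a window of `N` informative sites containing `M` donor matches out
of `L` total sites, with background `p` = donor-match proportion among
the `L − N` sites outside the window, the score is the binomial tail
`Pr(X ≥ M)`, `X ~ Binomial(N, p)` (scipy's survival function, exact
1.0 at `M = 0`). Two multiple-window corrections are applied
multiplicatively and capped at 1: `L/N` (count of non-overlapping
windows) and `L − N` (count of sliding windows). Sliding windows are
positively correlated, so the effective number of tests lies between the
two factors; whenever `N(L − N) ≥ L` the `L − N` value is the larger
(more conservative) of the two. Reports carry both; by default a
segment must clear alpha under both.

Estimating `p` outside the examined window prevents a genuine tract from
inflating its own background. The cost is extra stochastic error: when
few matches exist overall, excluding a chance cluster makes the outside
estimate much smaller than the whole-profile value, which is the
dominant source of false positives at low divergence (quantified below).
The original fixed-background variant (`p` over the whole profile,
`L/N` only) is retained as `whole_profile_p` for head-to-head
comparison.

Degenerate backgrounds are clamped by half a count: zero outside matches
give `p = 1/(2(L−N))`, all-outside-matches give the mirror image. This
keeps tails non-degenerate without inventing signal.

## Window admissibility

The scan evaluates, from every start site, all windows of at least
`min_window` informative sites (default 3; one- and two-site windows are
dominated by the clamping rule), keeping per start the window with the
smallest selected P (`L − N` value by default; ties break to the
narrower, then earlier window). Two structural rules define which
windows are candidate tracts at all:

- **Half-profile bound** (`max_window_frac = 0.5`): a window may cover at
  most half the informative sites. A conversion tract is a minority
  segment of a gene, and the background must be estimated from at least
  as much data as the window scores. Without the bound, near-total
  windows leave a handful of outside sites, the background estimate
  collapses, and the scan fires on essentially every profile.
- **Window majority** (`require_window_majority`): inside the window the
  target must match the donor at more than half the sites. A donor
  tract locally favors the donor; windows that merely enrich a sparse
  background are not tract hypotheses.

Per-start winners whose uncorrected P-values clear alpha become
candidates; candidates are then selected greedily in ascending P with
overlapping windows suppressed, and mapped to the alignment columns of
their first and last informative site.

## Program modes and multiple-testing correction

All modes share the statistic and differ in the parent pairs examined
and the Bonferroni `k`:

- **mtcpconv** — each sequence vs (own-group consensus, other-group
  consensus); `k` = number of sequences examined. The consensus is the
  per-column plurality character among {A,C,G,T,-} (ambiguity codes
  never vote), ties broken by the fixed order A<C<G<T<-; downstream
  statistics only use match/mismatch, so any deterministic rule is
  equivalent, and this one is the package's contract.
- **twopop** — each sequence vs every (own-group member, other-group
  member) pair; `k = n1(n1−1)n2 + n2(n2−1)n1`. Per reported window span
  the best triplet's P is kept; distinct overlapping spans from
  different triplets are retained as competing tract hypotheses.
- **onepop / seq3comp** — every triplet within one group (`k = C(n,3)`),
  or exactly one triplet (`k = 1`). Each sequence takes the target role
  with both parent orientations. Within a triplet, overlapping candidate
  windows from different roles describe one event seen from different
  sides (a conversion makes recipient and donor mirror-detect each
  other); the event is attributed to the role with the smallest P,
  which in practice is the true recipient's comparison by many orders
  of magnitude.

Corrected P-values are `min(1, k·P)`; a segment is significant when its
corrected value(s) clear alpha under the configured rule. The
within-sequence multiple-window problem is handled by the `L/N` and
`L − N` factors, never by `k`.

## Simulation harness

The simulator draws a root sequence with equal base frequencies and
evolves it along a three-taxon tree — two close taxa (branches
`b_close1`, `b_close2`, default 0.01 each, i.e. pairwise distance 0.02)
and one distant taxon (`b_distant`) — under the Kimura two-parameter
model. Branch lengths are expected substitutions per site. The
transition/transversion *ratio* R (default 2) follows the Seq-Gen
convention; under equal base frequencies the rate ratio is `kappa = 2R`.
Sequences are 1500 nt by default.

A conversion event replaces the first `segment_length` columns
(30–75 nt in the study grid) of one close taxon with the distant
taxon's columns and re-evolves the tract for `residual_branch`
substitutions/site — 0.01 for a "recent" event, 0.05 for an "ancient"
one. This realizes the observable signature of conversion age (tract
similarity to the donor decays with time) without simulating a second
tree.

Evaluation scans the directed core comparison the consensus method makes
(recipient taxon vs close relative vs distant donor), with `k = 1` and
window-level alpha = 0.05. In false-positive runs any detection counts
against the statistic; in power runs a detection entirely inside the
planted tract counts toward power and anything else as a false positive.
Three statistic variants are compared on identical data: the original
whole-profile background with `L/N`, and the out-of-window background
with `L/N` and with `L − N`. Per-iteration RNG streams are derived from
one master seed by counter, so conditions differing only in statistic,
tract length or timing see the same base alignments (paired
comparisons).

Study conditions: distant-branch grid {0.1, 0.2, 0.4} (three divergence
levels, doubling), 1000 iterations per level for false-positive rates,
300 for the paired power orderings in the test suite. At these sizes the
whole simulation study runs in well under a minute on one core; the
binomial tails for all admissible windows of a profile are computed in
one vectorised call.

What the simulations do and do not emulate: equal base frequencies, no
rate heterogeneity across sites, no indels, no heterotachy, a star-like
three-taxon history. Passing tests therefore demonstrate the statistic's
behavior under its own model assumptions, not robustness to
lineage-specific rate shifts (heterotachy is a known false-positive
mechanism for this family of methods) or to alignment error.

The two-group generator used for end-to-end tests
(`simulate_two_groups`) is simpler still: independent uniform ancestral
states, a fixed fraction of between-group differences, independent
per-sequence noise, and an optional tract copied from the other group's
ancestor. It emulates the "low within, high between" regime the method
assumes; it does not emulate phylogenetic structure within groups.

## Numerical and design choices

- Binomial tails come from `scipy.stats.binom.sf`, accurate to ~1e-14
  relative; the test suite checks agreement with direct pmf summation to
  1e-12 for all `N ≤ 50`.
- P-value comparisons use exact floats; ties break structurally
  (narrower window, earlier start) rather than by epsilon.
- The selection key during window growth is the conservative `L − N`
  value when that correction is active, else `L/N`; which of the two the
  variable-width rule should minimize is genuinely open, and the
  conservative choice is the default.
- Empty or too-short profiles (fewer than `min_window + 1` informative
  sites) yield an empty result, not an error: a sequence identical to
  its group consensus is simply unexaminable.
- Determinism: every simulation entry point is reproducible from
  `(config, seed)`; derived seeds stay below 2^31.

## Known limitations

- **Boundary bias.** Because the background excludes the examined
  window, the minimal-P window sometimes extends past a true tract to
  swallow an isolated nearby donor match (emptying the outside
  background outweighs diluting the window). On the 10+10 planted-tract
  fixture this widens the top exhaustive-triplet span on roughly 15% of
  generator seeds; the tract-interior window is still reported as a
  competing span. Reported boundaries should be read as the informative
  sites consistent with conversion, not as base-exact breakpoints.
- **Recipient/donor ambiguity.** Triplet modes attribute each event to
  the smallest-P role; with nearly symmetric divergence the attribution
  can flip.
- **False positives at low divergence.** The out-of-window background is
  noisy when few informative sites differ; with the `L/N` correction the
  per-dataset false-positive rate reaches ~20% at close-taxa branch
  length 0.01, dropping to single digits with `L − N` — use the
  conservative correction (or demand both) on low-diversity data.
- The method assumes pre-aligned input and never realigns; misalignment
  mimics conversion.
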