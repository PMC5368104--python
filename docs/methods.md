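# Methods

## The evaluation model

A contest consists of challenges; each challenge is an MS/MS spectrum with a
known correct structure and a provided candidate list guaranteed to contain
that structure. A submission assigns a non-negative score to any subset of
candidates, higher meaning better. Because none of the evaluated methods can
distinguish stereoisomers analytically, all identity comparisons run on the
*skeleton key* — the first 14-character block of the InChIKey, which is
invariant under stereochemistry. Submissions are collapsed to one score per
skeleton, retaining the maximum over a skeleton's stereoisomers.

The rank of the correct candidate is tie-averaged: with `B` candidates
scoring strictly higher and `t` candidates (correct one included) sharing
its score, the rank is `B + (t + 1)/2`, the mean position over all orderings
of the tied block. This is exactly the "average" rank convention of
`scipy.stats.rankdata` applied to descending scores, and the tests verify
the two agree. Wherever an integer rank is required (Top-X counts, Formula 1
and Medal scores), non-integer ranks are rounded **up** (`ceil`): a two-way
tie at the top (rank 1.5) counts as rank 2 — i.e. Top 3 but not Top 1.

Relative ranking position `RRP = (TC − r)/(TC − 1)` maps rank `r` on a
`TC`-candidate list into [0, 1] (1 best, 0 worst); a single-candidate list
is defined as 1.0. Missing results (correct structure not submitted, or the
challenge not submitted at all) are carried explicitly and never silently
imputed: they are excluded from mean/median/quantile statistics by default
(a sensitivity mode substitutes the candidate count, the same convention the
rank-matrix export uses), treated as worst at medal time, and replaced by
the candidate count only in the heat-map matrix.

Medals are assigned per challenge: every entry tied at the minimal average
rank gets gold, so a winner exists even when no method ranked the correct
candidate first. Joint medals use *competition* position counting: after k
joint golds the next distinct rank holds position k+1 (two golds ⇒ no
silver). The alternative "dense" scheme (next distinct rank ⇒ next medal) is
available as an option; the choice between them is a genuine convention
choice, and competition counting was adopted as the standard sports-ranking
convention. The overall standings sort by gold count, then silver, then
bronze; the best entry per participant is the highest-placed one.

## Point schemes

* **Formula 1 Score** — ranks 1–10 earn 25, 18, 15, 12, 10, 8, 6, 4, 2, 1
  points; missing results and ranks above 10 earn 0.
* **Medal Score** — 5/3/1 points for ranks 1/2/3. This is an entry-level
  statistic, distinct from the per-challenge gold tally that declares the
  winner.

Quantiles of the rank distribution (Q10–Q90) use numpy's linear
interpolation between order statistics; the estimator used for the
originally published quantiles is not specified anywhere, so published
quantile values are not bit-targeted.

## Score fusion

Heterogeneous scores are made commensurable by dividing each component's
scores by its per-challenge maximum (an order-preserving map into [0, 1];
an all-zero component is left unchanged). The fused score is a weighted sum
over the union of candidate skeletons, with candidates missing from a
component contributing a configurable `missing_value` (default 0: penalized
but not excluded). Max-normalization is the simplest scheme with these
properties, but it is a design choice — the normalization actually used to
produce the original combined entries is not printed in the main text, so
fused scores here should be treated as non-canonical in functional form
(the structure — equal-weight consensus over normalized component scores —
is as specified).

Metadata scorers produce submission-shaped score maps: reference counts are
used as-is (absent count ⇒ 0 with a warning); the lowest-identifier rule is
implemented as `1/id`, which satisfies the non-negative/higher-better
contract, and any strictly decreasing transform induces the same ranking
(tested); database presence earns 10 points per listed database containing
the candidate, designed for additive combination with a fragmenter score.
The retention-time score fits `RT = a·descriptor + b` by least squares
(`scipy.stats.linregress`, ≥ 3 pairs, non-degenerate descriptor variance
required) and scores each candidate `max(0, 1 − |RT_challenge −
RT_predicted| / w)` with window `w = 2` minutes by default; the exact
functional form of the original RT score is only given in supplementary
material, so this form is likewise labelled non-canonical. Weight fitting
enumerates the weight simplex at resolution `1/g` and maximizes the Top-1
count on training challenges, breaking ties by Formula 1 score.

An external similarity-propagation library score is deliberately *not*
reimplemented (it is defined in other work); any per-candidate score table
can be plugged in as a component, and the spectra module's plain library
similarity serves as a stand-in.

## Spectra

Peak lists are read from two-column plain text or MGF (via `pyteomics`).
Similarity is a ppm-tolerant cosine: peak pairs within `tol_ppm` (relative
to the larger m/z of the pair) are candidate matches, accepted greedily by
descending intensity product with each peak used at most once; the score is
the matched dot product over the product of full vector norms, so
self-similarity is exactly 1 and tolerance-disjoint spectra score exactly 0.
Intensities are square-root scaled by default (a common variance-stabilizing
convention; raw mode is a switch, since the original scaling is not
printed). On spectra whose peaks are well separated relative to the
tolerance the greedy matching equals the exhaustive optimal one-to-one
assignment, which the tests verify on ≤ 6-peak spectra.

Library search filters the library to precursors within a ppm window
(default 10 ppm) of the query, requires ion-mode agreement when both sides
are annotated, and ranks survivors by cosine. Every survivor is reported: a
single candidate in the window is a "hit" regardless of similarity.

The training/challenge split sends a spectrum to training iff its best
library similarity is **strictly above** the threshold (default 0.85 — a
spectrum at exactly 0.85 stays a challenge), except for ids on an explicit
exception list, which are forced into the challenge set. The original split
used a different (MetFusion-family) similarity, so this module's cosine
stand-in will not reproduce the official membership; the rule itself is
faithful. Deduplication removes byte-identical peak lists and collapses
repeated measurements of one substance in one ion mode to the
highest-maximum-intensity spectrum; quality predicates drop single-peak
spectra and spectra whose maximum intensity is below 1e5 counts (both
configurable).

## Synthetic contest generator

The generator's defaults are the study conditions: 208 challenges, 127
positive / 81 negative ion mode, candidate-list sizes lognormal with
log-mean 6.5 and log-sd 1.0 (mean ≈ 1100 candidates, matching the ≈ 1114
average of the real candidate lists), 312 RT training pairs. Other defaults,
chosen once as realistic for this kind of benchmark data and documented
here:

* stereo-duplicate rate 0.15 extra isomer rows per skeleton (Poisson);
* reference counts `ref_scale·(1 + Pareto(1))` (heavy-tailed, shape 1),
  with the true compound's count multiplied by `ref_boost = 100` — enough
  that a refs-only scorer puts the true compound in the top 2 for the large
  majority of challenges, the qualitative behavior observed on real,
  well-studied compounds;
* identifiers: true compounds uniform on [1, 1e5], decoys on (1e5, 1e7]
  (well-known compounds entered databases early, hence low ids);
* database presence: true compound in each of 5 databases with p = 0.8,
  decoys with p = 0.2;
* RT model `RT = 1.5·descriptor + 2.0 + N(0, 0.3)` minutes with descriptors
  N(2.0, 1.5) — a plausible reversed-phase logP→RT calibration.

Method quality is a one-parameter model: the true candidate's score quantile
among Uniform(0, 1) decoy scores is Beta(α, 1); α = 1 is an uninformative
method (uniform rank — verified distributionally by a KS test), α → ∞ a
perfect one, and the family is stochastically ordered in α. Ties are
injected by quantizing a challenge's scores to two decimals with probability
`tie_prob`; `coverage` drops whole challenges; `top_k_truncation` keeps only
the k best rows and can drop the correct answer. This is a modeling
stand-in for participant behavior, not a claim about any real fragmenter:
passing tests show the *evaluation machinery* is correct and statistically
well-behaved, not that any real method has these properties. Real
submissions differ in ways the generator does not emulate — correlated
errors across methods sharing training data, compound-class-dependent
difficulty, candidate-list-size dependence of method quality, and
chemically meaningful spectra (library spectra here are random peaks with
configurable ppm/intensity noise, sufficient for exercising matching,
search and split logic only).

InChIKeys are syntactically valid but fake, made collision-free by encoding
a running counter in base 26 into the tail of each block. One global seed
fans out through `numpy.random.SeedSequence([seed, stage])` to independent
per-stage streams, so contest, submissions and spectra are individually
reproducible and byte-identical across runs.

## Numerical choices and degenerate inputs

* Tie detection compares parsed score values exactly by default; an optional
  `epsilon` widens equality to `|s_i − s_j| ≤ ε` for tools that emit
  effectively-equal floats. Default 0 (off).
* Submitted candidates absent from the official candidate list stay in the
  ranking; a strict mode rejects them (whether the original evaluation
  pruned them is unrecorded, so both behaviors exist).
* Empty submission files are valid "no submission" markers; all-missing
  challenges award no medals; an empty rank set is an error in
  `summarize_entry`.
* Files are UTF-8, decimal point `.`, no thousands separators; floats are
  written with `repr` so round-trips are exact.
* Structure strings are captured verbatim; skeleton derivation requires an
  InChIKey or an explicit converter adapter — the evaluation never depends
  on a chemistry engine. (An RDKit-based converter can be passed as
  `key_converter` but is not a dependency.)

## Problem sizes used in tests

The 100-replicate acceptance study uses 200 challenges per contest with
candidate lists at log-mean 4.0 (≈ 65 candidates per challenge) — the
ordering-recovery and consensus properties under test concern rank
*comparisons across methods* and are insensitive to the list size, and this
size keeps the full study near two minutes on one CPU. Unit tests use
contests of 15–40 challenges. RT parameter recovery uses 300 training pairs.

## Known limitations

* The cosine stand-in similarity will not reproduce the official
  training/challenge membership of any real contest (different similarity
  function upstream).
* Fusion normalization and the RT-score form are the package's own
  conventions (see above), prominently non-canonical.
* No significance testing between entries is provided, and hierarchical
  clustering/plotting of the rank matrix is left to downstream tools — only
  the matrix and an optional pairwise-distance export are produced.
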