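# Methods

## The instrument model

A checklist instrument is a list of categories, each with a non-negative
point value, and a set of problems, each owned by exactly one category. A
patient assessment is a *set* of problem ids; the score is

    score(A) = Σ over categories C with problems(C) ∩ A ≠ ∅ of points(C).

Category-once semantics are deliberate: the bundled nursing score's per-row
totals equal the per-category point values and the printed maximum (16)
equals the sum of category points, which is only coherent if a category
contributes its points at most once however many of its member problems are
present. Two urinary devices are not twice the nursing burden of one; the
category encodes "this kind of care is needed at all".

Points are `decimal.Decimal` end to end. Half-point categories (2.5) are
part of the instrument, and a float representation would eventually print
`7.499999…` in a clinical report. Config files may write points as numbers
or strings; both parse exactly via the string round-trip.

Unknown problem ids are a hard error listing every offending id. A silent
skip would understate care burden — the failure mode this instrument exists
to prevent.

The bundled default has 7 categories and 22 problems summing to 16 points.
Membership follows the instrument's operational table (e.g. complex wound
care includes fistulas, tracheostomy, colostomy and grade III/IV pressure
ulcers, not only the ulcers); practices delivered sporadically (enemas,
bisphosphonates) are simply absent. The category points (5, 1, 1, 2.5, 2,
2.5, 2) are instrument content, not tunables.

## Likert summaries and the consensus rule

Ratings are integers on a declared scale (the validation design: 1–10,
1 = strongly disagree). Per item we report:

- **median, P25, P75** by linear interpolation between closest order
  statistics, i.e. quantile position `1 + q·(n−1)` (R type 7, numpy's
  default). The convention is chosen for consistency with published
  half-point quartiles: with n = 19 the quartile positions are 5.5 and
  14.5, which is the only standard convention producing values like 6.5 or
  8.5 from integer ratings of a 19-member panel.
- **agreement**: the count and percentage of ratings at or above the
  rating cutoff (default 7). Percentages are rounded half-up to one
  decimal (16/19 → 84.2), but the consensus decision is taken on the exact
  fraction: `n_agree / n_respondents ≥ 4/5` compared as rationals, so a
  panel at exactly 80 % (4 of 5) is consensus and no binary-float wobble
  can flip a boundary case. A float cutoff passed in config is parsed via
  its decimal string (0.8 → 4/5), never via its binary expansion.

An item's denominator is its respondent count, not the panel roster: if a
rater skips an item, the item is judged on the ratings it actually
received, and `n_respondents` is reported so attrition is visible.

## Aiken's V and its exact significance

For n judges on a c-category scale with lowest value l,

    V = Σᵢ (rᵢ − l) / (n·(c − 1)) ∈ [0, 1],

the mean rating rescaled to the unit interval. V is invariant to shifting
the scale, and is reported both exactly and rounded half-up to two decimals
(the convention of published validity tables).

Significance is computed against the standard exact null for this
statistic: judges rate independently and uniformly over the c categories.
The p-value is the right tail P(S ≥ s) of S = Σ(rᵢ − l), a sum of n iid
uniforms on {0, …, c−1}. The distribution of S is obtained by iterated
convolution of the single-judge count vector using Python integers — exact
at any panel size (the outcome count c^n overflows 64-bit arithmetic
already at n = 19, c = 10) — and the tail is a `Fraction` converted to
float only on output. For c = 2 this reduces to a binomial(n, ½) tail,
which serves as an independent closed-form cross-check in the tests, as
does full enumeration of all c^n rating vectors at small sizes.

A normal approximation with continuity correction
(mean n(c−1)/2, variance n(c²−1)/12) is provided for very large panels and
is flagged as approximate; it is accurate near the bulk and, like any CLT
bound, relatively worse far out in the tail. The exact routine is the
default everywhere.

The p-value renderer prints `<0.001` below that threshold, matching
validity-table convention. Which round's ratings feed the validity table is
a user choice (the `validate` command defaults to round 1, where every item
still has ratings); the computation itself is generic in scale width, and
the tests exercise both a 10-point and a dichotomous reconstruction of the
published coefficients since a printed V of 0.95 with n = 19 is consistent
with either.

## The Delphi round engine

Round r receives ratings for the items still open after round r−1 (round
1: all items). Items meeting the consensus rule settle and are never
re-rated — ratings submitted for an already-settled item are skipped with a
warning rather than an error, since a stray column in a survey export
should not abort an analysis. Two carryover policies exist:

- **failed_consensus** (default): exactly the items failing the rule carry
  over.
- **low_agreement**: additionally re-presents items whose interquartile
  range is wide (width ≥ a configurable threshold, default 3 scale points)
  even when the percentage rule passed — for panels that prefer to keep
  debating items with scattered ratings. Published Delphi processes
  describe their second round both ways ("items without consensus" and
  "items with the lowest inter-rater agreement"), so the choice is an
  explicit config field rather than a hard-coded rule.

After the maximum number of rounds (default 4), an open item whose
agreement moved less than `stagnation_delta` percentage points (default 5)
since the previous round *and* whose median is unchanged is marked
**excluded** — the operationalisation of "no significant variation across
rounds", which the source methodology states as a principle without a
formula. Both thresholds are configurable and echoed in every CLI run.

Feedback reports contain aggregates only (median, quartiles, counts,
percentages) and never individual ratings, preserving panel anonymity. The
markdown report and the summaries CSV are generated from the same frame, so
their values cannot drift apart.

A note on reproducing published two-round tables: such tables typically put
each round's median (P25–P75) in its own column and the *final* round's
agreement in the last column. A row like "7 (5–10) … 16 (84.2%)" therefore
mixes rounds: under type-7 quantiles no single 19-rating vector can have
P25 = 5 and 16/19 ratings ≥ 7 (P25 = 5 forces at least five ratings below
7, capping agreement at 14/19). The test suite checks each round's report
row against a rating vector consistent with that round.

Roster summaries report computed percentages (half-up, one decimal): 18 of
19 is 94.7 %, 13 of 19 is 68.4 %. Published tables occasionally print
inconsistent cells (e.g. 94.9 % for 18 of 19); this package always reports
the arithmetic value.

## The synthetic panel generator

Each rater×item rating is an independent draw from a two-component
mixture: with probability θ (the item's agreement level) from an *endorse*
distribution, else from a *dissent* distribution. Defaults emulate the
validation design this package was built around: 19 raters, the 7 candidate
categories, a 1–10 scale, endorse uniform on {7, …, 10}, dissent uniform on
{1, …, 10}, θ = 0.85 (a strongly but not perfectly agreeing panel — the
regime in which the published rounds sit, with agreement between 84 % and
100 %).

The mixture is chosen for tractability: the probability that one rating
clears the cutoff is

    p = θ·P(endorse ≥ cutoff) + (1−θ)·P(dissent ≥ cutoff)
      = θ + (1−θ)·0.4  under the defaults,

so panel-level quantities are exact binomial tails — e.g. a θ = 0.5 panel
of 19 spuriously reaches the 80 %/≥7 rule with probability
P(X ≥ 16; 19, 0.7), the closed form the stochastic tests compare against
at Monte-Carlo-standard-error tolerance (2,000 replicate panels, a few
seconds on one CPU).

What the generator does *not* model: rater-level random effects
(consistently harsh or generous judges), item correlation within rater,
round-to-round feedback dynamics (each simulated round is independent),
and missing responses. Passing tests therefore demonstrate that the
analysis machinery is correct under independent mixture ratings, not that
real expert panels behave this way; in particular, real-panel convergence
between rounds is a behavioural phenomenon the engine analyses but the
generator does not produce.

Determinism: the model carries its own seed and `simulate_panel` is a pure
function of model + seed; replicate studies pass an explicit
`numpy.random.Generator` instead. No global RNG state is touched.

## Numerical choices and edge cases

- Half-up rounding (via `decimal`) for all user-facing percentages and
  two-decimal V values; Python's builtin banker's rounding is never used
  for display.
- Empty rating vectors, out-of-scale ratings, duplicate (item, rater)
  pairs, degenerate scales (width < 2) and invalid mixture distributions
  are hard errors naming the offender.
- An empty roster or an empty round yields an empty table/report, not an
  error.
- Exclusion requires a previous-round summary for the same item; an item
  first rated in the final round can only settle or stay open.

## Limitations

- The mapping from a patient's score to a number of nursing visits is out
  of scope: the instrument quantifies burden, and visit allocation is a
  service-level decision layered on top.
- No inter-rater reliability coefficients (κ, ICC): the Delphi analysis
  summarises with medians/IQRs by design; V covers content validity.
- No confidence intervals for V (a documented extension point).
- Survey delivery, collection and respondent management are not included;
  the package starts at the ratings CSV.
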