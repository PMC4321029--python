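# Methods

## The screen and its statistic

The assay is a single outcross of a balanced master stock in which the F1
sex determines genotype: females carry an X-linked Gal80 and are unaffected
controls, males express the sensitizing transgene and are only partially
viable. Under Mendelian segregation males are conceived at 50%; transgene
semilethality reduces the adult male share to a baseline of 22% of all F1
adults (established from pooled wild-type outcrosses, 314 males / 1123
females). A deficiency (heterozygous deletion) co-inherited by the F1
changes the male share if the deleted region contains a dose-sensitive
interactor.

Per line the statistic is the unrounded percentage of F1 males,
`pct = 100·males/(males+females)`, and the fold change is `pct / 22` — the
baseline divisor is the stated 22.0, not the pooled control ratio (21.85),
because that is how the screen was scored and it reproduces more of the
published fold values.

### Display rounding and thresholds

Classification operates on *display-rounded* values, because the published
cutoffs (fold ≤ 0.5 enhancer, ≥ 1.9 suppressor) were applied to the printed
table: percentages round half-up to integers; folds round half-up to one
decimal place when that rounding reaches 1.0 and to two decimal places
otherwise. The two-regime rule is forced by the data: lines with raw folds
of 0.93–0.94 print two decimals while raw 0.95–0.99 prints "1.0". In raw
terms the cutoffs are therefore fold ≤ 0.505 and ≥ 1.85; the 1.85 edge
matters (a line at raw 1.864 is a suppressor).

Recomputing every row from its raw counts reproduces every printed
percentage and all but three printed folds, which are typos in the source
table (the raw counts, printed totals and percentages are internally
consistent in each case): one row printing 0.50 where the counts give 0.48,
one printing 0.45 where they give 0.44 (the companion submapping table
prints 0.44 for the same counts), and one printing 2.0 where they give 1.9
(that value was evidently derived from the *rounded* percentage,
43/22 = 1.95). None of the three changes a classification. Two fixture rows
carry a corrected female count because the printed male/female/total triple
was inconsistent and the total and percentage agree with each other; the
printed columns are retained verbatim for side-by-side comparison.

Classification is never gated on significance: the screen counts 33
suppressors and 28 enhancers by threshold while flagging the handful that
miss p < 0.05. Significance uses the classic equal-variance two-sample
Student's t-test (two-tailed) on per-cross male percentages; no
multiple-testing correction is applied, matching the original analysis. The
per-line replicate tallies behind the published P values were not released,
so the t-test is validated against a closed-form oracle rather than against
the table.

The alternative `"sd"` threshold mode implements the rule the fold cutoffs
approximate — one sample SD (n−1 denominator) above/below the screen mean,
recomputed from the supplied lines (the screen's own values, mean 26.1%,
SD 15.2%, match the published 26%/15%). The fixed values can be pinned via
`ScreenConfig.sd_mean`/`sd_sd`.

## Cytogenetic coordinates

Bands are ordered by (chromosome, division, letter, band) with absent
components treated as span edges. Two deliberate conventions:

* **No fabricated map detail.** How many numbered bands a lettered
  subdivision contains is map-dependent, so a letter-only endpoint ("46C")
  expands to a half-open whole-subdivision span — a start edge sorting
  before band 1 and an end edge sorting after every numbered band — rather
  than to an invented terminal band. Interval arithmetic is exact at this
  resolution; the cost is that a piece abutting such an edge prints the
  subdivision token instead of a concrete neighbouring band (the published
  tables occasionally print the successor band from the real map, e.g.
  35C1 after a breakpoint at 35B10).
* **Breakpoint bands are uncertain.** A deficiency's *maximal* extent runs
  from the earliest proximal to the latest distal candidate band; the
  *minimal* extent from the latest proximal to the earliest distal one, and
  may be empty for degenerate deletions ("41A;41A"). Subtraction removes
  only the *open interior* of the subtracted range: the boundary bands,
  where breakpoints sit, cannot be exonerated and survive, and a flanking
  piece is emitted only when the cut falls strictly inside. Hence a range
  minus itself is empty, but subtracting "23C5;23E3" from "23C1–23E2"
  leaves 23C1–23C5 inclusive — exactly the published refinement.

A telomere token ("3Rt") is an arm-maximum sentinel; centromeric divisions
get no special handling. Ordering across chromosomes is an error; overlap
across chromosomes is simply false. The X and 4th chromosomes are out of
scope. The hyphen in "49C1-4" is breakpoint-position uncertainty, not a
deleted sub-interval. A handful of dialect irregularities in the source
tables are accepted verbatim: a comma separator, a bare-hyphen separator,
and a two-letter token ("45DE3" → 45D–45E3).

## Hotspot refinement

Given a parent modifier and classified smaller overlapping deletions:

* **Same-class subs** localise the modifier. The refined interval is the
  *intersection* of the maximal extents of the parent and every same-class
  sub — the parsimony assumption that one shared gene explains all of them,
  which is how the published cases were reduced (e.g. the triple
  intersection 46C1–46C7 containing *Mef2*). Maximal extents keep the
  candidate list inclusive under breakpoint uncertainty.
* **Nonmodifier subs** exonerate only the bands they certainly delete: the
  open interior of their minimal extent is subtracted.
* **Opposite-class subs** reveal an independent second modifier. Its
  interval (the opposite subs' shared maximal extent clipped to the parent)
  is reported under its own class, minus same-class sub extents whose
  modification is attributed to the parent class. The parent-class region
  cedes territory to opposite subs only when the parent's evidence is the
  coarse deletion alone — a same-class sub is direct evidence and is not
  second-guessed.

Each sub gets a comment code (1 same class, 2 nonmodifier, 3 opposite); the
case keeps the full set because the published per-row codes mix relations
within one case, and the scalar `comment_code` gives precedence 3 > 1 > 2.
A known degenerate case: when a nonmodifier sub shares the parent's
proximal breakpoint and covers it distally, the refined set is empty where
the source table prints a single-band interval at the shared breakpoint —
the strict-piece rule does not manufacture a piece out of two coincident
uncertain boundaries.

Candidate genes are annotated by interval *intersection* (edge genes
included) against a symbol → band-interval table; symbols beginning "mir-"
are tagged miRNA so that gene counts can exclude them (the published
"five genes" at 50D1–50D5 excludes the one miRNA among six entries).

## The generative cross model

Parameters (all dimensionless unless noted):

| parameter | meaning | default |
|---|---|---|
| `v` | baseline male relative viability | 0.28205 (= 0.22/0.78) |
| `m` | modifier effect multiplying male viability | 1 |
| `f` | female relative viability | 1 |
| `clutch_n` | conceived F1 zygotes per line (count) | 300 |
| `poisson_clutch` | sample clutch size ~ Poisson(clutch_n) | off |

Zygote sex is Binomial(clutch, ½) — the Gal80 X-balancing makes sex
determine genotype deterministically, and no transmission distortion is
modeled. Survival is Bernoulli per zygote with male survival `min(1, v·m)`
and female survival `min(1, f)`; the cap encodes that viability cannot
exceed the control class. The closed-form expected male fraction is
`s/(s+f′)`, equal to ½ exactly at equal survivals, and inverting it at the
observed 22% baseline gives `v = p/(1−p)`. Temperature dependence of the
Gal4 driver is folded into `v`. Effects are multiplicative; a suppressed
line approaches (and by sampling noise can exceed) 50% males, as the
strongest published suppressors do. Whether control females ever bear a
viability cost is unknown; `f` exists as a parameter but defaults to 1.

The effect estimator is method-of-moments under `f = 1`:
`m̂ = (males/females)/v`, consistent whenever `v·m ≤ 1`. Detection power
and the false-positive rate are Monte-Carlo proportions of simulated
crosses classified by the same `classify` routine as real data, reported
with a binomial standard error. Randomness uses one seed with per-line
counter-derived substreams (`default_rng([seed, i])`), so simulated screens
are byte-reproducible and stable under line reordering.

### What the generator emulates — and does not

It reproduces the screen's statistical structure: the 1:1 conceived sex
ratio, female viability ≈ 1, male viability calibrated to the 22% baseline,
multiplicative modifier effects, and binomial sampling at realistic clutch
sizes (the published per-line totals span roughly 50–500 adults; the
Poisson variant mimics that spread). It does not model larval lethality
timing, Gal80 leakiness, shared-environment (vial) effects, between-cross
heterogeneity beyond clutch size, or linkage between tested deficiencies —
so passing recovery/power tests demonstrate correctness of the inference
under the stated model, not robustness to those real-world violations.

Problem sizes used by the test suite: 10⁴ Monte-Carlo replicates for
parameter recovery (median `m̂` within 5% of truth over
m ∈ {0.2, 0.5, 1.5, 2, 3} at clutch 300) and for the false-positive bound
(< 5% at clutch 150), 3×10³ lines for the Monte-Carlo-vs-closed-form mean
check.

## Numerical and design notes

* Rounding is decimal half-up throughout (`Decimal.quantize`), not
  banker's rounding, to match the printed tables.
* Threshold comparisons on display-rounded folds use a 10⁻⁹ tolerance to
  absorb float→Decimal conversion noise.
* The t-test short-circuits to p = 1 for two identical constant groups
  (zero variance, zero t); other degenerate inputs follow scipy.
* `estimate_effect` requires at least one female; a simulated cross with
  zero total survivors raises rather than silently retrying.
* Screen TSVs are UTF-8 with a header; the canonical writer/reader
  round-trips byte-for-byte. Validation reports every offending row with
  its line number in one error.
* Exit codes of the CLI: 0 success, 2 validation error, 3 computation
  error; logs go to stderr and include input checksums for provenance.

## Known limitations

* Interval arithmetic is exact only at the resolution of the published
  notation; conversions to base-pair coordinates or a concrete band census
  per subdivision are out of scope, as are X/4th-chromosome coordinates and
  external annotation retrieval.
* The screen summary recomputed from the packaged table (mean 26.1%,
  SD 15.2%) is the package's reference; the published figures round these.
* Whether a fold exactly at p = 0.05 counts as significant is ambiguous in
  the source analysis; the package flags significance strictly as
  p < alpha and leaves the classification untouched either way.
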