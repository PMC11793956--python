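# Methods

## The decomposition model

For one trait and one consecutive pair of periods, let the *roster* of a
period be the set of authors with a (possibly interpolated) value in that
period's cell of the period–author matrix. With n the earlier roster size,
n′ the later one, and the earlier roster split into continuing and exiting
authors (the later roster adds entrants), define

    r = |continuing| / n,   e = |exiting| / n,   i = |entering| / n,
    R = n′ / n  (so r + e = 1 and R = r + i).

The change in the roster-mean trait value obeys the exact identity

    R (φ̄′ − φ̄) = i (φ̄_I − φ̄) − e (φ̄_E − φ̄) + r δ̄,

with φ̄ the earlier-period mean, φ̄_I / φ̄_E the entrant / exiter means
(entrants measured in the later period, exiters in the earlier one) and δ̄
the mean of (value′ − value) over continuing authors. The entrance and exit
terms are population covariances between the trait and the entry/exit
indicators over the respective rosters; both are centred on the *earlier*
period's mean, which is the unique centring under which the three terms sum
exactly to R Δφ̄ (the test suite verifies the covariance form and an
independent per-individual summation oracle to 10⁻¹³).

Assumptions worth making explicit:

* each active author counts once per period regardless of how many works
  they published in it (cells are per-author means, so the roster mean is
  author-weighted, not book-weighted);
* "exit" is simply absence from the next period's roster — the model does
  not distinguish death from retirement;
* pairs whose earlier roster is empty have undefined rates and are skipped
  with a warning rather than zero-filled; when the *later* roster is empty
  the identity's left side is exactly 0 (R = 0 and n′ φ̄′ vanishes) and is
  recorded as such rather than as 0 × NaN.

Per trait, relative effect weights are the across-pair absolute sums
Σ|effect_k| normalized to 1. Signed alternatives cancel opposing lobes (a
trait that rises and falls by entrances alone would score zero), so
magnitude shares are used. Weights map to the ternary plane with corners
entrance = (0, 0), individual = (1, 0), exit = (1/2, √3/2); the rotation is
cosmetic.

## The career simulator

The simulator emulates a literary population with stationary demography:

| parameter | default | units | why |
|---|---|---|---|
| n_authors | 10 000 | — | large enough for a stable ≈2 900-author plateau |
| entry_window | 1850–2000 | year | uniform entry, matching the corpus era |
| career_start_age | 19 | years | first possible publication age |
| gompertz_eta (η) | 1/20 | — | shape of the Gompertz career-length law |
| gompertz_b | 1/17 | 1/year | rate of the Gompertz law |
| productivity_mean | 0.1 | works/year | one work per decade on average |
| fixed_career_length | 44 | years | Gompertz mean, for the equal-careers variant |

Career lengths T follow the Gompertz law S(t) = exp(−η(e^{bt} − 1)),
sampled by the inverse CDF T = (1/b) ln(1 − ln U / η). With the defaults,
numerical integration gives E[T] = 44.11 and sd[T] = 17.36, so lifespans
(19 + T) are 63 ± 17 years — a realistic human lifespan distribution — and
the entry rate (10 000/150 per year) times the mean career length implies
≈ 2 940 simultaneously active authors, flat from about 1925 once the
initial ramp-up has washed out. Per-author productivity rates are
exponential (mean 0.1/year), so work counts are highly unequal; work times
are the event times of a homogeneous Poisson process, i.e. uniform over the
career conditional on their number.

A `career_model="fixed"` variant gives every author exactly the mean career
length (44 years), used to study the effect of career-length inequality;
`"uniform"` draws lengths uniformly with the same mean and is exposed for
exploration only.

## Trait-generation processes

Functional forms, chosen as the minimal shapes matching the intended
dynamics:

* **single-cohort** — an author entering at year y adopts the trait with
  probability `max_adopt_prob · exp(−(y − focal)² / 2σ²)` (defaults
  max_adopt 0.9, σ = 10 y); an adopter's works each carry the trait with
  probability 0.95, independent of career stage. Defaults place the focal
  year at 1925, the centre of the demographic plateau, so the full rise and
  fall of the trait (entries ≈ 1895–1955, exits into the 1990s) happens
  under stationary turnover rather than during the 1850–1894 ramp-up, where
  entry rates are inflated relative to the still-growing roster.
* **disruptive-event** — every work independently carries the trait with
  probability `baseline` before the event year and
  `baseline + (peak − baseline) e^{−(t − event)/τ}` after it (defaults
  event 1915, τ = 10 y, peak 0.9, baseline 0.01).

Both return work-level 0/1 traits; period cells then hold the fraction of
an author's works in the period carrying the trait, mirroring mean topic
proportions in [0, 1]. A callable hook accepts arbitrary
`(author, work_year, rng) → value` rules for additional processes.

What the generator does *not* emulate: real corpora have uneven temporal
coverage, correlated multi-topic structure per work (θ vectors summing
to 1), attribution noise, and selection effects in what survives to be
digitized. Passing tests therefore demonstrate that the decomposition
machinery is exact and that it discriminates the two idealized processes —
not that any particular real-world trait is cohort-driven.

## Panel construction

Periods are half-open [start, start + width), labeled by start year, width
5 by default. Works outside the grid are dropped and counted. Authors
observed in only one period are removed *before* interpolation (a single
anchor cannot be interpolated, and contributes no within-author change);
interior gaps are then filled by linear interpolation on period index, with
no extrapolation beyond an author's first/last observed period. Filled
cells stay distinguishable through the observation mask, and interpolated
values are used when computing δ̄ — that is interpolation's purpose: keeping
a sparse author in the continuing roster instead of counting a publication
gap as an exit plus a re-entrance. For external topic tables, chunk-level θ
rows are averaged per book (unweighted), and an optional uniform per-period
subsample (e.g. 412 books per period) counters uneven coverage before any
pooled model fit.

## Numerical and design choices

* Exactness first: effects are computed from rates and means exactly as in
  the identity; the per-pair residual is carried in the effects table and
  asserted < 10⁻¹² in tests.
* Determinism: one `numpy` Generator per run seed; the pipeline spawns
  per-trait child seeds via `SeedSequence`, so runs are reproducible
  byte-for-byte and traits are independent. Population work times are drawn
  in one vectorized batch (same law as the per-career operation).
* Decomposition-plot bars are anchored at the trajectory value of the
  arrival period; positives stack upward in the fixed order entrance →
  individual → exit, negatives downward in the same order, so the signed
  bar heights of a pair sum to R Δφ̄.
* CSV tables round-trip at full float precision (`round_trip` parsing) with
  missing cells as empty fields; every artifact embeds the config hash and
  seed in `#`-comment header lines.

Problem sizes used by the shipped test suite: the lifespan calibration uses
10⁵ draws; the plateau check one 10⁴-author population; process
discrimination 100 + 100 traits, each on its own 10⁴-author population;
the career-length-inequality comparison 20 + 20 such traits; identity and
oracle checks use thousands of small randomized panels.

## Known limitations

* **Entrance/exit asymmetry has a small structural component.** Because
  both covariance terms are centred on the earlier period's mean, each
  entrance effect absorbs a drift term i Δφ̄ signed with the trend
  (entrants are measured against the mean of a roster they had not yet
  joined). Under equal fixed-length careers — where entrances and exits
  should mirror each other — this, together with the unequal *observed*
  activity spans produced by sparse sampling (0.1 works/year leaves first
  and last works well inside the true career), leaves the pooled
  Σ|entrance| / Σ|exit| ratio near 1.25 rather than exactly 1. At higher
  productivity (0.3–0.5 works/year) the ratio drops to ≈ 1.2. The
  qualitative contrast — Gompertz-career inequality pushes the ratio to
  ≈ 2, equal careers restore near-symmetry — is robust.
* Rates are undefined across empty-roster gaps, so traits observed in
  disconnected eras decompose era by era.
* No uncertainty quantification: effects are exact identities of the
  observed panel, and no sampling error is propagated from the upstream
  topic model or corpus selection.
* The real-data adapter starts from book-level (or chunk-level) trait
  tables; text processing and topic-model fitting are upstream concerns.
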