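# Methods

## The scoring model

`cescore` scores the severity of a complex emergency from eight
country-level indicators, four per dimension:

- **vulnerability** — how susceptible the population already was
  (development and health indicators);
- **exposure** — how large the crisis footprint is (uprooted people and
  people in need, absolute and as population shares).

Each raw value is classified onto a three-level ordinal scale
(low/medium < high < extreme) using two per-indicator cut-offs in native
units, the levels are mapped to weights 0.5 / 1.0 / 1.5, the four weights
of each dimension are summed (each sum in [2, 6]) and the sums are
multiplied:

    severity = vulnerability_sum × exposure_sum       ∈ [4, 36]
    need     = severity × people_in_need_millions     ≥ 0

The multiplicative form encodes the model's central assumption: a crisis is
severe when a *vulnerable* population is *exposed* — the same displacement
footprint in a resilient middle-income country and in a country with low
literacy and high child malnutrition should not score the same. Because the
sums cannot reach zero, neither dimension can be fully compensated by the
other. The need score deliberately reuses the people-in-need figure (it
enters once through an exposure indicator and once as the multiplier); this
double use is a known structural limitation of the model, accepted for lack
of an independent magnitude measure.

All arithmetic is exact in binary floating point: weights are multiples of
0.5, sums are multiples of 0.5 in [2, 6], severity is a multiple of 0.25 in
[4, 36]. No internal rounding occurs; CSV output formats scores to two
decimals only for presentation and reproducible diffs.

## Cut-offs are configuration

The classification thresholds are data, not code. The packaged defaults
(`src/cescore/data/default_config.yaml`) are **provisional** values chosen
to be plausible for the least-developed-country range of each indicator
(e.g. extreme when GNI per capita PPP ≤ $1,500, adult literacy ≤ 50%, child
underweight ≥ 25%, under-5 mortality ≥ 100/1000, or ≥ 25% of the population
in need). They exist so the engine runs out of the box and so tests can
exercise realistic configurations; any real assessment should substitute
audited cut-offs via `--config`. The engine only requires, per indicator, a
direction and two cut-offs ordered consistently with it.

Two of the eight default indicator identities (under-5 mortality for
vulnerability, people-in-need proportion for exposure) are this package's
own named slots; the configuration schema makes every slot replaceable
without code changes.

### Boundary convention

A value exactly at a cut-off is assigned the **severer** level, in both
directions (e.g. underweight exactly 25% is extreme; literacy exactly 50%
is extreme). A tie-break had to be fixed for the map to be total; erring
severe is the conservative choice in a humanitarian triage setting. The
colour bins for score bar charts use the same convention: severity 10 and
20, and need 50 and 150, take the severer colour (half-open bins
[10, 20), [20, ∞), etc.).

### Missing data

The default policy is **strict**: any unresolved indicator level leaves the
dimension sum, and hence the severity score, unresolved — a score is never
silently computed from fewer than eight classifications. The alternative
policies impute a configured level for missing values, most commonly
*extreme* (`--missing-policy impute-extreme`): when a statistic has not
been published for years in a collapsed state, the absence itself is
informative. Every imputation is recorded on the scored record and in the
CSV output, and the heat map still shows the cell as blank (na) — the
figure reports what was observed, the score reports what was assumed.

## Visualisation

Heat maps show countries as rows and the eight indicators as columns
(vulnerability block then exposure block, in configuration order), one
aligned panel per assessment date, cells coloured yellow / orange / red by
level and left blank for na. Cell colours are taken from the classified
levels stored on the scored records, never recomputed from raw values, so
figure and score cannot disagree. Row order is alphabetical by default; a
sort key can impose e.g. score order. Outputs are PNG/SVG via matplotlib or
a standalone HTML table.

## Reliability validation

A severity score is useful if it *orders* emergencies the way realised
outcomes do. The accepted (if noisy and late) outcome measure is excess
mortality: direct plus indirect deaths above the pre-crisis baseline, per
100,000 people per year. `compare_with_mortality` joins scored contexts to
a mortality table by name and reports:

- **Spearman's ρ** between severity score and mortality rate (average ranks
  for ties; computed via scipy);
- **rank-window concordance**: a context is concordant when
  |severity rank − mortality rank| ≤ window (default 1). "The score follows
  mortality" is inherently a judgement about orderings; the window rule
  turns it into a reproducible count and names the discordant contexts.

The window default of 1 tolerates adjacent-rank swaps (well within the
uncertainty of mortality estimation) while flagging genuine re-orderings.
Fewer than 3 matched contexts is refused; a constant series, where ρ is
undefined, is reported as 1 (both constant) or 0 (one constant). Both
statistics are reported so users can inspect the raw ordering rather than
trust a single number.

## The synthetic-data generator

Historical indicator tables and mortality estimates for real emergencies
are not redistributable, so the test bench runs on synthetic panels with
known ground truth. `generate_panel` draws, per country-year and indicator,
a true level from a three-point distribution, then a raw value *inside*
that level's cut-off interval (uniformly; the interval beyond the extreme
cut-off is bounded by one cut-off span), then applies independent
missingness. Draws respect the boundary convention on the correct side, so
with zero missingness classification recovers the true level — and scoring
recovers the true severity — *exactly*, not just almost surely. This
round-trip is the core oracle of the test suite.

Defaults emulate the assessment setting the model targets: 16 countries ×
3 years (the size of a multi-year appeal panel); level probabilities
0.40 / 0.35 / 0.25 (leaning low/medium with a solid extreme tail, as real
panels do); 5% scattered missingness (most indicator data is available);
people in need uniform on 0.1–12 million (the range seen across UN response
plans). `generate_mortality` maps true severity through a fixed increasing
base curve, 4·exp(0.122·s) deaths/100k/yr (≈6 at the minimum score 4, ≈320
at the maximum 36, spanning the observed order of magnitude for major
emergencies), and multiplies by log-normal noise (sd 0.25 on the log
scale by default; sd 0 gives a strictly co-monotone series, the ρ = 1
limit used in tests).

One seed drives everything through independent `SeedSequence` substreams
(levels, raw values, missingness, people in need, mortality noise), so
components can be regenerated independently and every output is exactly
reproducible.

What the generator does **not** emulate: cross-indicator correlation within
a country (real vulnerability indicators co-move), temporal persistence
across years, informative missingness (real na concentrates in the worst
contexts), or calibration of raw-value distributions to any actual country.
Passing tests therefore demonstrate the *engine's* correctness —
classification, aggregation, policy handling, rank comparison — not the
epidemiological validity of any particular cut-off choice on real data.

## Numerical and interface choices

- Scores are exact multiples of 0.25; equality assertions in tests are
  exact, not approximate.
- Scored CSV output is deterministic: rows sorted by (country, date),
  scores formatted to two decimals, list fields semicolon-joined —
  re-scoring the same input is byte-identical.
- The per-sector "affected" median helper uses the lower central value for
  even-length inputs (appeal figures are whole-person counts;
  interpolation would invent a fractional person); `rule="interpolate"`
  restores the conventional average.
- Configuration is validated with explicit field-level checks (exactly 4+4
  indicators, unique names, cut-offs ordered consistently with direction,
  finite numbers) raising `ConfigError`; data problems raise `InputError`;
  the CLI maps these to exit codes 2 and 1.
- Problem sizes in the test suite (e.g. 1,000-country round-trip panels,
  200-replicate noise studies, exhaustive 3⁸ enumeration) were chosen as
  the smallest that make the properties sharp: the enumeration is complete
  rather than sampled, and the Monte-Carlo sizes give stable means.

## Known limitations

- The model is national-scale by construction: no sub-national variation,
  no qualitative context (human-rights violations, access constraints,
  donor fatigue, geopolitics).
- The need score uses the people-in-need estimate twice (see above), and
  that estimate is itself subjective and methodology-dependent.
- A low severity score among "the worst of the worst" does not imply
  absence of need; the score ranks, it does not measure absolute funding
  requirements.
- The default cut-offs are provisional and unvalidated; conclusions drawn
  from them should be treated as illustrative until replaced by audited
  values.
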