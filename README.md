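# cescore

Composite **severity** and **level-of-need** scoring for complex
emergencies, with heat-map visualisation and reliability validation against
excess-mortality rankings.

## The problem

Humanitarian donors are asked to allocate funding across many simultaneous
complex emergencies (conflicts with breakdown of authority, displacement,
food insecurity and elevated civilian mortality). Allocation is supposed to
follow need, but there is no common, transparent yardstick for *how bad*
one crisis is relative to another. `cescore` implements a deliberately
simple, auditable scoring model built from eight readily available
country-level indicators:

- **Vulnerability** (pre-existing susceptibility of the population): GNI
  per capita (PPP), adult literacy, child underweight, under-5 mortality.
- **Exposure** (the crisis footprint): uprooted people (refugees + IDPs) in
  millions and as a share of population, people in need in millions and as
  a share of population.

Each indicator value is classified onto a three-level ordinal scale via
per-indicator cut-offs — low/medium, high, extreme — with numeric weights
0.5, 1.0 and 1.5. Writing `v_i` and `e_j` for the weights of the four
vulnerability and four exposure indicators:

```
severity = (v1 + v2 + v3 + v4) × (e1 + e2 + e3 + e4)        ∈ [4, 36]
need     = severity × (people in need, in millions)
```

A value exactly at a cut-off takes the severer level. Missing (na)
indicators leave the score unresolved under the default *strict* policy, or
can be imputed (typically as *extreme* — the assumption made when a value is
unobtainable precisely because the situation is dire). Cut-offs are
configuration, not code: the packaged defaults are provisional and meant to
be replaced by audited values (see `docs/methods.md`).

The package also implements the standard presentations — country ×
indicator heat maps (yellow / orange / red, blank = na) and score bar
charts (severity: yellow < 10 ≤ orange < 20 ≤ red; need: yellow < 50 ≤
orange < 150 ≤ red) — and a reliability check: Spearman rank correlation
and rank-window concordance between severity scores and excess-mortality
rates (deaths per 100,000 per year) across a set of emergencies. A
synthetic-panel generator with known ground truth makes the whole pipeline
testable without any external data.

## Worked example

```python
from cescore import (CountryYearRecord, MissingPolicy, default_config,
                     score_country)

config = default_config()
record = CountryYearRecord(
    country="Country A",
    assessment_date="2015",
    values={
        "gni_per_capita_ppp": None,      # not published for years -> na
        "adult_literacy": 38.0,          # percent
        "child_underweight": 32.0,       # percent of under-5s
        "under5_mortality": 137.0,       # per 1000 live births
        "uprooted_millions": 2.1,
        "uprooted_proportion": 17.0,     # percent of population
        "in_need_millions": 4.9,
        "in_need_proportion": 20.0,      # percent of population
    },
    people_in_need_millions=4.9,
)
scored = score_country(record, config, MissingPolicy.impute_extreme())
```

Printing the result gives:

```
  gni_per_capita_ppp     na
  adult_literacy         extreme
  child_underweight      extreme
  under5_mortality       extreme
  uprooted_millions      extreme
  uprooted_proportion    extreme
  in_need_millions       extreme
  in_need_proportion     high
vulnerability sum: 6.0
exposure sum     : 5.5
severity score   : 33.0
need score       : 161.7
imputed          : ('gni_per_capita_ppp',)
```

Three vulnerability indicators classify as extreme and the missing GNI
value is imputed as extreme, so the vulnerability sum is the maximum 6.0
(4 × 1.5). Exposure has three extreme levels and one high (5.5), giving
severity 6.0 × 5.5 = 33 — a near-worst crisis — and need 33 × 4.9 ≈ 162,
i.e. a red bar on both charts. The imputation is recorded on the result,
and the heat map leaves the imputed cell blank.

## Command line

```bash
cescore simulate --n-countries 16 --n-years 3 --seed 7 \
    --out-panel panel.csv --out-truth truth.csv --out-mortality mortality.csv
cescore score   --input panel.csv --out scored.csv --missing-policy impute-extreme
cescore heatmap --input panel.csv --out heatmap.png        # or .html
cescore bars    --input panel.csv --which severity --out severity.svg
cescore validate --input panel.csv --mortality mortality.csv
cescore median-affected 120000 80000 310000 95000          # per-sector helper
```

Exit codes: 0 ok, 1 input error, 2 configuration error. Pass
`--config my_cutoffs.yaml` to any subcommand to use your own cut-offs
(same schema as `src/cescore/data/default_config.yaml`).

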