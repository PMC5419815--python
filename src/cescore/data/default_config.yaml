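# Default model configuration: 4 vulnerability + 4 exposure indicators.
#
# Cut-offs are PROVISIONAL defaults expressed in each indicator's native
# units; they split the range into low/medium, high and extreme severity.
# Direction semantics:
#   higher_is_worse: value <  cutoff_lo -> low_medium
#                    value >= cutoff_hi -> extreme
#   lower_is_worse:  value >  cutoff_lo -> low_medium
#                    value <= cutoff_hi -> extreme
# A value exactly at a cut-off takes the severer level (both directions).
#
# Replace this file (cescore --config my_config.yaml ...) to use audited
# cut-offs for a real assessment.
indicators:
  # --- vulnerability: pre-existing susceptibility of the population ---
  - name: gni_per_capita_ppp
    dimension: vulnerability
    direction: lower_is_worse
    cutoff_lo: 3000
    cutoff_hi: 1500
    units: international dollars (PPP) per person per year
  - name: adult_literacy
    dimension: vulnerability
    direction: lower_is_worse
    cutoff_lo: 70
    cutoff_hi: 50
    units: percent of adults literate
  - name: child_underweight
    dimension: vulnerability
    direction: higher_is_worse
    cutoff_lo: 10
    cutoff_hi: 25
    units: percent of under-5 children underweight
  - name: under5_mortality
    dimension: vulnerability
    direction: higher_is_worse
    cutoff_lo: 50
    cutoff_hi: 100
    units: deaths per 1000 live births
  # --- exposure: the crisis footprint ---
  - name: uprooted_millions
    dimension: exposure
    direction: higher_is_worse
    cutoff_lo: 0.5
    cutoff_hi: 1.5
    units: refugees + IDPs, millions of persons
  - name: uprooted_proportion
    dimension: exposure
    direction: higher_is_worse
    cutoff_lo: 5
    cutoff_hi: 15
    units: percent of total population uprooted
  - name: in_need_millions
    dimension: exposure
    direction: higher_is_worse
    cutoff_lo: 1
    cutoff_hi: 4
    units: people in need, millions of persons
  - name: in_need_proportion
    dimension: exposure
    direction: higher_is_worse
    cutoff_lo: 10
    cutoff_hi: 25
    units: percent of total population in need
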