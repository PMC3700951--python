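# Published MEFV epidemiology.  q_strict: mutated-allele frequency counting
# unambiguous mutations only, from population surveys; q_inclusive: counting
# E148Q as a mutation.  The q_inclusive values were never published directly —
# they are back-derived from the published calculated-prevalence cells and
# flagged as such.  Observed prevalences come from clinical reports (only the
# Turkish and Sephardic populations have one).
populations:
  - name: Armenian
    q_strict: 0.07
    source_note: "allele-frequency survey of the Armenian population"
  - name: Sephardic
    q_strict: 0.09
    q_inclusive: 0.14
    prevalence_observed_low: 0.001
    prevalence_observed_high: 0.004
    source_note: >-
      q_inclusive back-derived from the published recessive cell 0.02
      (0.14^2 = 0.0196); note the published recessive cell 0.005 is
      inconsistent with q_strict = 0.09 (q^2 = 0.0081), and no q reproduces
      both published E148Q cells under half-up display
  - name: Arab
    q_strict: 0.04
    source_note: "allele-frequency survey of Arab populations"
  - name: Turkish
    q_strict: 0.05
    q_inclusive: 0.1
    prevalence_observed_low: 0.001
    prevalence_observed_high: 0.001
    source_note: >-
      q_inclusive back-derived from the published recessive cell 0.01
      (0.1^2 = 0.01)
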