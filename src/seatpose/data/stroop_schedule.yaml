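# Default Stroop-test slide schedule.
# Each row expands to n_slides identical slides shown for `seconds` each;
# rows appear in presentation order (black -> congruent -> incongruent).
# Instruction screens (lead_in before the test, mid_instruction before the
# incongruent phase) default to 0 s; they offset the analysis windows but
# never change their durations.
lead_in: 0
mid_instruction: 0
slides:
  - {phase: black, words: 3, n_slides: 2, seconds: 2}
  - {phase: black, words: 4, n_slides: 2, seconds: 2.5}
  - {phase: black, words: 5, n_slides: 1, seconds: 3}
  - {phase: black, words: 6, n_slides: 1, seconds: 3.5}
  - {phase: congruent, words: 3, n_slides: 2, seconds: 2}
  - {phase: congruent, words: 4, n_slides: 2, seconds: 2.5}
  - {phase: congruent, words: 5, n_slides: 1, seconds: 3}
  - {phase: congruent, words: 6, n_slides: 1, seconds: 3.5}
  - {phase: incongruent, words: 3, n_slides: 2, seconds: 2.5}
  - {phase: incongruent, words: 4, n_slides: 2, seconds: 3}
  - {phase: incongruent, words: 5, n_slides: 2, seconds: 3.5}
  - {phase: incongruent, words: 6, n_slides: 2, seconds: 4}
  - {phase: incongruent, words: 9, n_slides: 2, seconds: 6}
  - {phase: incongruent, words: 12, n_slides: 2, seconds: 8}
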