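label: leukemia-two-round
min_publications: 1
exclude_zero_target_mirnas: true
rounds:
- label: round1-broader
  term_id: leukemia
  mode: broader
  max_depth: 1
- label: round2-exact
  term_id: leukemia
  mode: exact
  max_depth: unbounded
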