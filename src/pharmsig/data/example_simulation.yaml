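# Example synthetic-database config for `pharmsig simulate`.
# Three common antihypertensives with one planted association:
# furosemide reports carry gout at 6x the background rate.
n_reports: 5000
vocabulary: example
pt_catalog: [hyperuricaemia, gout, nausea, headache]
drug_marginals:
  Furosemide: 0.15
  Losartan: 0.20
  Amlodipine: 0.25
background_event_prob: 0.01
planted:
  - {drug: Furosemide, pt: gout, multiplier: 6.0}
synonym_noise: 0.3
duplicate_case_prob: 0.0
seed: 42
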