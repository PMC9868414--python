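# Adverse-event definitions: label -> MedDRA Preferred Terms.
# The urate-related study events are each a single PT; the combined
# definition unions all five.
hyperuricaemia:
  - hyperuricaemia
gout:
  - gout
gouty arthritis:
  - gouty arthritis
gouty tophus:
  - gouty tophus
urate nephropathy:
  - urate nephropathy
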