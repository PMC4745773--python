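# Term dictionaries for the two-tier localization cascade (v1).
# The source annotations give example terms, not a closed list; edit and
# version this file to change the classification vocabulary.
secreted_terms:
  - secreted
  - extracellular region
  - extracellular space
  - extracellular matrix
membrane_terms:
  - plasma membrane
  - cell membrane
  - cell junction
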