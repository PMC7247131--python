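# R-proteins previously established as r-leader ligands (experimentally
# verified leaders or published predicted alignments), and declared
# obligate-dimer ligands.  The list is an editable, best-effort
# transcription of the published record and can be replaced by a fuller
# user-supplied table.
known_ligands:
  - L1
  - L4
  - L10
  - L13
  - L19
  - L20
  - L25
  - S2
  - S4
  - S6:S18
  - S7
  - S8
  - S10
  - S15
# Dimer ligands: when both member proteins are encoded in one operon they
# collapse to the joint ligand name before the decision procedure runs.
dimers:
  - [S6, S18, "S6:S18"]
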