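# Canonical central-pair backbone torsion angles (degrees) for the five
# common four-residue chain-reversal (beta-turn) types, given as
# [phi(i+1), psi(i+1), phi(i+2), psi(i+2)] per the standard turn
# taxonomy (Hutchinson & Thornton lineage).  Overridable via config.
canonical_turn_angles:
  "I":    [-60, -30, -90, 0]
  "II":   [-60, 120, 80, 0]
  "I'":   [60, 30, 90, 0]
  "II'":  [60, -120, -80, 0]
  "VIII": [-60, -30, -120, 120]
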