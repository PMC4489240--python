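# Optional positional preferences of amino acids at the two central
# positions of each turn type.  Used only as a tie-break between turn
# types whose total angular deviations are equal, and only when
# use_turn_propensity is enabled (off by default).  Each string lists
# residues favoured at that position.
propensity:
  "I":    {central1: "DNSTC", central2: "DNSTG"}
  "II":   {central1: "PKS", central2: "GN"}
  "I'":   {central1: "NGD", central2: "G"}
  "II'":  {central1: "G", central2: "NDS"}
  "VIII": {central1: "PDN", central2: "VLI"}
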