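# Default emission model for the synthetic-protein generator.
#
# Secondary-shift magnitudes are expressed as multiples of the per-nucleus
# ternary-filter cutoff so that zero-noise emissions invert exactly under
# the default pipeline thresholds:
#   * helix / interior-strand residues emit 3x the cutoff (well above the
#     filter cutoff and large enough that the order-parameter estimate
#     exceeds the 0.90 "rigid" gate),
#   * edge-strand residues emit 1.2x (significant, but flexible enough to
#     stay below the rigid gate; HA signs alternate along the strand),
#   * ordered coil emits 0.9x with random signs (index 0, but order
#     parameter above the 0.7 turn gate),
#   * disordered residues emit 0 (order parameter collapses to 0).
state_multipliers:
  helix: 3.0
  strand_interior: 3.0
  strand_edge: 1.2
  coil: 0.9
  disordered: 0.0
# Representative backbone torsions emitted per state (degrees).  The
# generic coil pair is chosen to be far from every canonical turn type.
torsions:
  helix: [-63.0, -42.0]
  strand: [-120.0, 135.0]
  coil: [-75.0, 160.0]
# Glycine HA is emitted as an HA2/HA3 pair split symmetrically about the
# intended value by +/- this amount (ppm).
gly_ha_split: 0.01
# Residue alphabets sampled (cyclically) per element kind.
sequences:
  helix: "AELK"
  strand_interior: "VIL"
  strand_edge_polar: "KE"
  strand_edge_apolar: "VI"
  coil: "GSNT"
  turn_central: "NG"
  disordered: "GS"
# Noise defaults: gaussian sd on each emitted secondary shift equals
# shift_noise x the nucleus cutoff; gaussian sd on each emitted torsion
# angle is angle_noise_deg degrees.
shift_noise: 0.0
angle_noise_deg: 0.0
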