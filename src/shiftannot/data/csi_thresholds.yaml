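# Per-nucleus cutoffs (ppm) for the ternary chemical-shift-index filter.
# A secondary shift strictly above the cutoff scores +1, strictly below
# the negated cutoff scores -1, anything else 0.  Values follow the
# classic chemical-shift-index cutoffs (Wishart, Sykes & Richards 1992;
# Wishart & Sykes 1994) and are fully overridable via config.
provenance: "Classic chemical-shift-index cutoffs (Wishart & Sykes lineage)"
thresholds: {HA: 0.1, CA: 0.7, CB: 0.7, C: 0.5}
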