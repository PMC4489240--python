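# Random-coil reference chemical shifts (ppm), one entry per standard
# amino acid.  Values follow the classic peptide random-coil compilations
# (Wishart & Sykes, Methods Enzymol. 1994; RefDB-era revisions).  Glycine
# has no CB; proline's amide-proton entry is a placeholder (no amide H).
provenance: "Classic random-coil shift compilation (Wishart & Sykes 1994 lineage)"
shifts:
  A: {H: 8.24, HA: 4.32, CA: 52.5, CB: 19.0, C: 177.8, N: 123.8}
  R: {H: 8.23, HA: 4.34, CA: 56.0, CB: 30.9, C: 176.3, N: 120.5}
  N: {H: 8.40, HA: 4.74, CA: 52.8, CB: 37.9, C: 175.2, N: 118.7}
  D: {H: 8.34, HA: 4.64, CA: 54.2, CB: 41.1, C: 176.3, N: 120.4}
  C: {H: 8.32, HA: 4.55, CA: 58.2, CB: 28.0, C: 174.6, N: 118.8}
  Q: {H: 8.32, HA: 4.34, CA: 55.7, CB: 29.4, C: 176.0, N: 119.8}
  E: {H: 8.42, HA: 4.35, CA: 56.6, CB: 29.9, C: 176.6, N: 120.2}
  G: {H: 8.33, HA: 3.96, CA: 45.1, C: 174.9, N: 108.8}
  H: {H: 8.42, HA: 4.73, CA: 55.0, CB: 29.0, C: 174.8, N: 118.2}
  I: {H: 8.00, HA: 4.17, CA: 61.1, CB: 38.8, C: 176.4, N: 119.9}
  L: {H: 8.16, HA: 4.32, CA: 55.1, CB: 42.4, C: 177.6, N: 121.8}
  K: {H: 8.29, HA: 4.32, CA: 56.2, CB: 33.1, C: 176.6, N: 120.4}
  M: {H: 8.28, HA: 4.48, CA: 55.4, CB: 32.9, C: 176.3, N: 119.6}
  F: {H: 8.30, HA: 4.62, CA: 57.7, CB: 39.6, C: 175.8, N: 120.3}
  P: {H: 8.10, HA: 4.42, CA: 63.3, CB: 32.1, C: 177.3, N: 128.1}
  S: {H: 8.31, HA: 4.47, CA: 58.3, CB: 63.8, C: 174.6, N: 115.7}
  T: {H: 8.15, HA: 4.35, CA: 61.8, CB: 69.8, C: 174.7, N: 113.6}
  W: {H: 8.25, HA: 4.66, CA: 57.5, CB: 29.6, C: 176.1, N: 121.3}
  Y: {H: 8.12, HA: 4.55, CA: 57.9, CB: 38.8, C: 175.9, N: 120.3}
  V: {H: 8.03, HA: 4.12, CA: 62.2, CB: 32.9, C: 176.3, N: 119.2}
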