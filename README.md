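# shiftannot

Secondary and super-secondary structure annotation of protein chains from
assigned backbone NMR chemical shifts.

Starting from an assigned-shift file (NMR-STAR 2.1, NMR-STAR 3.1 or SHIFTY)
and an optional backbone torsion prediction table (TALOS-style), the
pipeline produces an 11-class annotation:

* helix, β-strand, coil (ternary chemical-shift-index filter + consensus
  vote + run-length rules; β-runs of ≤2 residues are coil),
* the five common β-turn types I, II, I′, II′ and VIII (typed from the
  central pair's φ/ψ angles: three of four deviations within 30°, the
  remaining one within 45°, gated to well-ordered coil with S² > 0.7),
* β-hairpins (two sequential strands joined by ≤6 loop residues
  containing a selected turn),
* edge vs. interior β-strands (seven-criterion evidence score over Hα
  alternation, exposure, rigidity, hydropathy periodicity, charge
  pattern and strand length; score > 4 ⇒ edge).

Backbone flexibility (S²) and fractional accessible surface area (fASA)
are estimated from secondary-shift magnitudes by simple, documented,
fully configurable surrogates; both can instead be supplied as
per-residue TSVs if you have outputs from dedicated predictors.

A forward-model generator (`shiftannot.synth`) emits synthetic chains —
shift files in all three dialects, torsion tables and ground-truth
annotations — that invert exactly under the pipeline at zero noise; it
backs the test suite and the degradation analysis, so nothing external
is downloaded.

## CLI

```sh
# annotate a shift file (dialect auto-detected)
shiftannot annotate shifts.str --torsions torsions.tab --out-dir out/ --plot

# generate a synthetic fixture from a YAML topology description
shiftannot simulate topology.yaml --out-dir sim/ --seed 7

# Qn agreement between two annotation TSVs
shiftannot evaluate out/annotation.tsv sim/truth.tsv

# re-render the bar-graph SVG from a run directory
shiftannot plot out/
```

`annotate` writes `csi_index.tsv` (per-residue ternary indices +
consensus), `profiles.tsv` (S², fASA), `annotation.tsv` (per-residue
11-class output), `features.txt` (feature lists) and optionally
`csi_plot.svg`. Exit codes: 0 ok, 2 parse error, 3 torsions required but
missing, 4 internal invariant violation, 5 bad configuration.

Every threshold (filter cutoffs, turn tolerances, gate values, edge
criteria, canonical turn angles) can be overridden via `--config`:

```yaml
thresholds: {HA: 0.12}
context:
  s2_turn_gate: 0.75
  strict_mirror_turns: true
```

Example topology description for `simulate`:

```yaml
elements:
  - {kind: coil, length: 3}
  - {kind: helix, length: 6}
  - {kind: coil, length: 2}
  - {kind: hairpin, length: 5, loop_len: 4, turn_type: "I'"}
  - {kind: coil, length: 3}
strand_roles: {0: edge, 1: edge}
```

## Layout

| module | role |
| --- | --- |
| `shiftannot.shiftio` | shift/torsion file parsing, writers, completeness |
| `shiftannot.shift_profiles` | secondary shifts, ternary filter, 3-state assignment |
| `shiftannot.dynamics` | S² and fASA surrogate estimators, profile TSV I/O |
| `shiftannot.context_assign` | turn typing, hairpins, edge/interior, merge |
| `shiftannot.synth` | synthetic-chain generator, noise sweep |
| `shiftannot.pipeline_cli` | stage orchestration, Qn scoring |
| `shiftannot.cli`, `shiftannot.plot` | command line, SVG rendering |

Reference tables (random-coil shifts, filter cutoffs, canonical turn
angles, hydropathy scale, generator emission model) live as YAML under
`src/shiftannot/data/` and are the single source of those constants.
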