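"""Forward-model generator of synthetic chains with known annotations.

Given a topology layout (helices, strands with edge/interior roles,
coil, typed turns, hairpins, disordered spans) the generator emits a
chemical-shift dataset, a torsion table and a ground-truth annotation
that are mutually consistent: at zero noise, running the full pipeline
on the emitted data recovers the ground truth exactly.  This closed loop
is the central oracle of the test suite.

All emission magnitudes live in ``data/generator_model.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _data
from . import dynamics, shift_profiles, shiftio
from .context_assign import (
    Annotation,
    HairpinAssignment,
    StrandTopology,
    TurnAssignment,
    merge_annotation,
)
from .shift_profiles import SSAssignment
from .shiftio import ShiftDataset, TorsionEntry, TorsionTable


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class Element:
    kind: str  # helix | strand | coil | turn | hairpin
    length: int = 0
    turn_type: str | None = None
    loop_len: int = 0


@dataclass
class TopologySpec:
    elements: list[Element]
    strand_roles: dict[int, str] = field(default_factory=dict)  # ordinal -> role
    disordered_spans: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0
    chain_id: str = "SYNTH"


@dataclass
class GeneratorModel:
    state_multipliers: dict[str, float]
    torsions: dict[str, tuple[float, float]]
    gly_ha_split: float
    sequences: dict[str, str]
    shift_noise: float = 0.0
    angle_noise_deg: float = 0.0

    @classmethod
    def default(cls, **overrides) -> "GeneratorModel":
        raw = _data.generator_model_defaults()
        kw = dict(
            state_multipliers=dict(raw["state_multipliers"]),
            torsions={k: tuple(v) for k, v in raw["torsions"].items()},
            gly_ha_split=float(raw["gly_ha_split"]),
            sequences=dict(raw["sequences"]),
            shift_noise=float(raw["shift_noise"]),
            angle_noise_deg=float(raw["angle_noise_deg"]),
        )
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **kw) -> "GeneratorModel":
        return replace(self, **kw)


@dataclass
class _PlanRes:
    state: str  # H | B | C
    substate: str  # helix | strand_interior | strand_edge | coil | turn_central | disordered
    strand_ordinal: int | None = None
    strand_pos: int = 0
    turn_type: str | None = None  # set on the two central residues of a turn
    turn_slot: int = 0  # 0 = first central residue, 1 = second
    aa: str = ""


@dataclass
class SynthResult:
    spec: TopologySpec
    model: GeneratorModel
    dataset: ShiftDataset
    torsion_table: TorsionTable
    torsion_text: str
    truth: Annotation

    def write(self, outdir) -> None:
        from pathlib import Path

        from .context_assign import annotation_tsv

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "shifts.star3").write_text(shiftio.write_nmrstar3(self.dataset))
        (out / "shifts.star2").write_text(shiftio.write_nmrstar2(self.dataset))
        (out / "shifts.shifty").write_text(shiftio.write_shifty(self.dataset))
        (out / "torsions.tab").write_text(self.torsion_text)
        (out / "truth.tsv").write_text(annotation_tsv(self.truth))


# ---------------------------------------------------------------------------
# plan expansion and validation


def _expand(spec: TopologySpec) -> list[_PlanRes]:
    plan: list[_PlanRes] = []
    ordinal = 0

    def add_strand(length: int):
        nonlocal ordinal
        role = spec.strand_roles.get(ordinal)
        if role not in ("edge", "interior"):
            raise SpecError(f"strand ordinal {ordinal} has no edge/interior role")
        if length < 3:
            raise SpecError("strand length must be >= 3")
        if role == "interior" and length < 5:
            raise SpecError("interior strands must be >= 5 residues")
        for pos in range(length):
            plan.append(
                _PlanRes("B", f"strand_{role}", strand_ordinal=ordinal, strand_pos=pos)
            )
        ordinal += 1

    def add_turn(turn_type: str):
        from .context_assign import TURN_TYPES

        if turn_type not in TURN_TYPES:
            raise SpecError(f"unknown turn type {turn_type!r}")
        for slot in range(2):
            plan.append(
                _PlanRes("C", "turn_central", turn_type=turn_type, turn_slot=slot)
            )

    for el in spec.elements:
        if el.kind == "helix":
            if el.length < 4:
                raise SpecError("helix length must be >= 4")
            plan.extend(_PlanRes("H", "helix") for _ in range(el.length))
        elif el.kind == "strand":
            add_strand(el.length)
        elif el.kind == "coil":
            if el.length < 1:
                raise SpecError("coil length must be >= 1")
            plan.extend(_PlanRes("C", "coil") for _ in range(el.length))
        elif el.kind == "turn":
            add_turn(el.turn_type or "I")
        elif el.kind == "hairpin":
            if not 2 <= el.loop_len <= 6:
                raise SpecError(
                    "hairpin loop must be 2..6 residues (the turn's central "
                    "pair must fit inside the loop)"
                )
            add_strand(el.length)
            pre = (el.loop_len - 2) // 2
            post = el.loop_len - 2 - pre
            plan.extend(_PlanRes("C", "coil") for _ in range(pre))
            add_turn(el.turn_type or "I'")
            plan.extend(_PlanRes("C", "coil") for _ in range(post))
            add_strand(el.length)
        else:
            raise SpecError(f"unknown element kind {el.kind!r}")

    for lo, hi in spec.disordered_spans:
        if not 1 <= lo <= hi <= len(plan):
            raise SpecError(f"disordered span {(lo, hi)} out of range")
        for i in range(lo - 1, hi):
            if plan[i].state != "C" or plan[i].substate == "turn_central":
                raise SpecError(
                    f"disordered span {(lo, hi)} overlaps non-coil residue {i + 1}"
                )
            plan[i].substate = "disordered"

    # turn centrals need a flanking residue on each side for their window
    for i, r in enumerate(plan):
        if r.substate == "turn_central" and (i == 0 or i == len(plan) - 1):
            raise SpecError("turn central pair may not touch the chain termini")
    # adjacent strand elements would merge into one run and break the truth
    for a, b in zip(plan, plan[1:]):
        if (
            a.state == "B"
            and b.state == "B"
            and a.strand_ordinal != b.strand_ordinal
        ):
            raise SpecError("two strand elements may not be adjacent")
    if not plan:
        raise SpecError("empty topology")
    return plan


def _assign_sequence(plan: list[_PlanRes], model: GeneratorModel) -> None:
    counters: dict[str, int] = {}

    def take(alphabet: str) -> str:
        k = counters.get(alphabet, 0)
        counters[alphabet] = k + 1
        return alphabet[k % len(alphabet)]

    seqs = model.sequences
    for r in plan:
        if r.substate == "helix":
            r.aa = take(seqs["helix"])
        elif r.substate == "strand_interior":
            r.aa = take(seqs["strand_interior"])
        elif r.substate == "strand_edge":
            # alternating polar(charged)/apolar pattern, polar first so that
            # odd-length strands carry a polar majority and a central charge
            key = "strand_edge_polar" if r.strand_pos % 2 == 0 else "strand_edge_apolar"
            r.aa = take(seqs[key])
        elif r.substate == "turn_central":
            r.aa = take(seqs["turn_central"])
        elif r.substate == "disordered":
            r.aa = take(seqs["disordered"])
        else:
            r.aa = take(seqs["coil"])


# ---------------------------------------------------------------------------
# emission

#: Sign of the emitted secondary shift per state and nucleus.
_HELIX_SIGNS = {"HA": -1, "CB": -1, "CA": +1, "C": +1}
_STRAND_SIGNS = {"HA": +1, "CB": +1, "CA": -1, "C": -1}


def generate(spec: TopologySpec, model: GeneratorModel | None = None) -> SynthResult:
    """Emit shifts, torsions and ground truth for a topology layout."""
    model = model or GeneratorModel.default()
    plan = _expand(spec)
    _assign_sequence(plan, model)
    rng = np.random.default_rng(spec.seed)
    thresholds = shift_profiles.default_thresholds()
    rc = shift_profiles.RandomCoilTable.default()
    n = len(plan)
    sequence = "".join(r.aa for r in plan)

    shifts: dict[tuple[int, str], float] = {}
    torsion_rows: list[tuple[int, str, float, float, str]] = []
    entries: dict[int, TorsionEntry] = {}
    dropped = 0

    for idx, r in enumerate(plan, 1):
        mult_key = {
            "helix": "helix",
            "strand_interior": "strand_interior",
            "strand_edge": "strand_edge",
            "coil": "coil",
            "turn_central": "coil",
            "disordered": "disordered",
        }[r.substate]
        mult = model.state_multipliers[mult_key]
        deltas: dict[str, float] = {}
        for nucleus in ("HA", "CA", "CB", "C"):
            if r.substate == "helix":
                sign = _HELIX_SIGNS[nucleus]
            elif r.substate in ("strand_interior", "strand_edge"):
                sign = _STRAND_SIGNS[nucleus]
                if r.substate == "strand_edge" and nucleus == "HA":
                    sign = +1 if r.strand_pos % 2 == 0 else -1
            else:
                sign = int(rng.choice((-1, 1)))
            d = sign * mult * thresholds[nucleus]
            if model.shift_noise > 0:
                d += rng.normal(0.0, model.shift_noise * thresholds[nucleus])
            deltas[nucleus] = d
        # amide shifts are emitted at their random-coil values; they are
        # parsed but never filtered, so they only affect completeness
        for atom in ("H", "N"):
            ref = rc.get(r.aa, atom)
            if ref is not None:
                shifts[(idx, atom)] = round(ref, 3)
        for nucleus, d in deltas.items():
            if nucleus == "CB" and r.aa == "G":
                continue
            ref = rc.get(r.aa, nucleus)
            value = ref + d
            if nucleus == "HA" and r.aa == "G":
                shifts[(idx, "HA2")] = round(value + model.gly_ha_split, 3)
                shifts[(idx, "HA3")] = round(value - model.gly_ha_split, 3)
            else:
                shifts[(idx, nucleus)] = round(value, 3)

        # torsions
        if r.substate == "disordered":
            torsion_rows.append((idx, r.aa, 9999.0, 9999.0, "None"))
            dropped += 1
            continue
        if r.substate == "turn_central":
            canon = _data.canonical_turn_angles()[r.turn_type]
            phi, psi = canon[2 * r.turn_slot], canon[2 * r.turn_slot + 1]
        elif r.state == "H":
            phi, psi = model.torsions["helix"]
        elif r.state == "B":
            phi, psi = model.torsions["strand"]
        else:
            phi, psi = model.torsions["coil"]
        if model.angle_noise_deg > 0:
            phi += rng.normal(0.0, model.angle_noise_deg)
            psi += rng.normal(0.0, model.angle_noise_deg)
        phi = shiftio.normalize_angle(phi)
        psi = shiftio.normalize_angle(psi)
        torsion_rows.append((idx, r.aa, round(phi, 3), round(psi, 3), "Strong"))
        entries[idx] = TorsionEntry(round(phi, 3), round(psi, 3), "Strong")

    dataset = ShiftDataset(
        chain_id=spec.chain_id,
        sequence=sequence,
        shifts=shifts,
        source_format=None,
    )
    torsion_table = TorsionTable(entries=entries, dropped=dropped)
    torsion_text = shiftio.write_torsion_table(torsion_rows)
    truth = _ground_truth(plan, sequence)
    return SynthResult(
        spec=spec,
        model=model,
        dataset=dataset,
        torsion_table=torsion_table,
        torsion_text=torsion_text,
        truth=truth,
    )


def _ground_truth(plan: list[_PlanRes], sequence: str) -> Annotation:
    ss = SSAssignment("".join(r.state for r in plan))
    turns: list[TurnAssignment] = []
    i = 0
    while i < len(plan):
        if plan[i].substate == "turn_central":
            turns.append(
                TurnAssignment(
                    start=i,  # 1-based window start = central1 - 1 = (i+1) - 1
                    turn_type=plan[i].turn_type,
                    deviations=(0.0, 0.0, 0.0, 0.0),
                    total_deviation=0.0,
                )
            )
            i += 2
        else:
            i += 1
    topologies = []
    spans = ss.strand_spans()
    for span in spans:
        role = plan[span[0] - 1].substate.removeprefix("strand_")
        topologies.append(
            StrandTopology(span=span, criteria={}, edge_score=7 if role == "edge" else 0,
                           call=role)
        )
    hairpins = []
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        loop = (e1 + 1, s2 - 1)
        if not 1 <= loop[1] - loop[0] + 1 <= 6:
            continue
        inside = [
            t for t in turns if t.central[0] >= loop[0] and t.central[1] <= loop[1]
        ]
        if inside:
            hairpins.append(
                HairpinAssignment((s1, e1), loop, (s2, e2), inside[0])
            )
    return merge_annotation(ss, turns, hairpins, topologies, sequence)


# ---------------------------------------------------------------------------
# degradation harness


def noise_sweep(
    spec: TopologySpec,
    model: GeneratorModel | None = None,
    sds: list[float] | None = None,
    reps: int = 10,
    seed: int = 0,
    angle_noise_per_unit: float = 15.0,
) -> list[dict]:
    """Mean per-class recovery of the ground truth vs. noise level.

    Each noise level scales the per-nucleus shift sd (in cutoff units)
    and the torsion sd (``angle_noise_per_unit`` degrees per unit).
    """
    from . import pipeline_cli

    if reps < 1:
        raise SpecError("reps must be >= 1")
    model = model or GeneratorModel.default()
    sds = sds if sds is not None else [0.0, 0.5, 1.0, 2.0]
    rows = []
    for li, sd in enumerate(sds):
        acc = {"three_state": 0.0, "turn": 0.0, "hairpin": 0.0, "topology": 0.0}
        for rep in range(reps):
            m = model.replace(
                shift_noise=sd, angle_noise_deg=sd * angle_noise_per_unit
            )
            s = replace(spec, seed=seed * 1_000_003 + li * 7919 + rep)
            res = generate(s, m)
            result = pipeline_cli.annotate_dataset(res.dataset, res.torsion_table)
            rec = recovery(result.annotation, res.truth)
            for key in acc:
                acc[key] += rec[key]
        row = {"noise": sd}
        row.update({k: v / reps for k, v in acc.items()})
        rows.append(row)
    return rows


def recovery(pred: Annotation, truth: Annotation) -> dict[str, float]:
    """Fraction of ground-truth residues recovered, per class family."""
    n = truth.n_residues
    if pred.n_residues != n:
        raise ValueError("length mismatch")
    three = sum(1 for i in range(n) if pred.states[i] == truth.states[i]) / n

    turn_idx = [i for i in range(n) if truth.turn_labels[i] is not None]
    turn = (
        sum(1 for i in turn_idx if pred.turn_labels[i] == truth.turn_labels[i])
        / len(turn_idx)
        if turn_idx
        else 1.0
    )
    hp_idx = [i for i in range(n) if truth.hairpin_flags[i]]
    hairpin = (
        sum(1 for i in hp_idx if pred.hairpin_flags[i]) / len(hp_idx)
        if hp_idx
        else 1.0
    )
    st_idx = [i for i in range(n) if truth.strand_classes[i] is not None]
    topology = (
        sum(1 for i in st_idx if pred.strand_classes[i] == truth.strand_classes[i])
        / len(st_idx)
        if st_idx
        else 1.0
    )
    return {
        "three_state": three,
        "turn": turn,
        "hairpin": hairpin,
        "topology": topology,
    }
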