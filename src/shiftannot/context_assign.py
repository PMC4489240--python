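"""Contextual assignment: turn typing, hairpins, edge/interior strands.

This is the second phase of the pipeline.  It consumes the 3-state
assignment plus the order-parameter, exposure and torsion profiles and
produces the final 11-class annotation:

* four-residue chain reversals typed I/II/I'/II'/VIII from the central
  pair's torsion angles (3-of-4 within the primary tolerance, the
  remaining angle within the relaxed tolerance);
* hairpins: two sequential strands joined by a short loop containing a
  selected turn;
* per-strand edge/interior calls from a seven-criterion evidence score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import _data
from .dynamics import FasaProfile, OrderProfile
from .shift_profiles import SecondaryShiftProfile, SSAssignment
from .shiftio import TorsionTable

TURN_TYPES = ("I", "II", "I'", "II'", "VIII")

CHARGED_RESIDUES = set("DEKRH")


class AnnotationError(Exception):
    """Internal inconsistency between merged annotation layers."""


@dataclass
class ContextConfig:
    s2_turn_gate: float = 0.7
    tol_primary_deg: float = 30.0
    tol_relaxed_deg: float = 45.0
    hairpin_max_loop: int = 6
    fasa_exposed: float = 0.25
    fasa_edge_avg: float = 0.3
    exposed_majority: float = 0.50
    s2_rigid: float = 0.90
    rigid_frac_max: float = 0.40
    short_strand_len: int = 5
    edge_score_threshold: int = 4
    ha_alternation_frac: float = 0.7
    hydropathy_alternation_frac: float = 0.7
    charge_fraction: float = 0.25
    strict_mirror_turns: bool = False
    use_turn_propensity: bool = False
    canonical_turn_angles: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_data.canonical_turn_angles
    )

    def __post_init__(self):
        if self.tol_primary_deg <= 0 or self.tol_relaxed_deg < self.tol_primary_deg:
            raise ValueError("tolerances must be positive with relaxed >= primary")

    def replace(self, **kw) -> "ContextConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class TurnAssignment:
    start: int  # turn spans start..start+3
    turn_type: str
    deviations: tuple[float, float, float, float]
    total_deviation: float

    @property
    def central(self) -> tuple[int, int]:
        return (self.start + 1, self.start + 2)


@dataclass(frozen=True)
class HairpinAssignment:
    strand1: tuple[int, int]
    loop: tuple[int, int]
    strand2: tuple[int, int]
    turn: TurnAssignment


@dataclass(frozen=True)
class StrandTopology:
    span: tuple[int, int]
    criteria: dict
    edge_score: int
    call: str  # "edge" | "interior"


@dataclass
class Annotation:
    sequence: str
    states: str
    turn_labels: list[str | None]
    hairpin_flags: list[bool]
    strand_classes: list[str | None]
    turns: list[TurnAssignment]
    hairpins: list[HairpinAssignment]
    strands: list[StrandTopology]
    s2: list[float | None] | None = None
    fasa: list[float] | None = None

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# turn typing


def angular_deviation(a: float, b: float) -> float:
    """Minimal absolute separation of two degree angles on the circle."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def classify_turn(
    phi1: float, psi1: float, phi2: float, psi2: float, cfg: ContextConfig | None = None
) -> tuple[str | None, tuple[float, float, float, float] | None]:
    """Type the central-pair torsions against the five canonical turns.

    A type matches iff at least three of the four angular deviations are
    within the primary tolerance and the remaining one within the relaxed
    tolerance (bounds inclusive).  Of several matches the one with the
    smallest total deviation wins (canonical table order breaks exact
    ties).
    """
    cfg = cfg or ContextConfig()
    best: tuple[float, int, str, tuple] | None = None
    for order, ttype in enumerate(TURN_TYPES):
        canon = cfg.canonical_turn_angles[ttype]
        devs = (
            angular_deviation(phi1, canon[0]),
            angular_deviation(psi1, canon[1]),
            angular_deviation(phi2, canon[2]),
            angular_deviation(psi2, canon[3]),
        )
        within_primary = sum(1 for d in devs if d <= cfg.tol_primary_deg)
        if within_primary < 3 or max(devs) > cfg.tol_relaxed_deg:
            continue
        key = (sum(devs), order, ttype, devs)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[2], best[3]


def _propensity_bonus(ttype: str, aa1: str, aa2: str) -> int:
    table = _data.turn_propensity().get(ttype, {})
    bonus = 0
    if aa1 in table.get("central1", ""):
        bonus += 1
    if aa2 in table.get("central2", ""):
        bonus += 1
    return bonus


def _classify_with_propensity(
    angles: tuple[float, float, float, float],
    aa1: str,
    aa2: str,
    cfg: ContextConfig,
) -> tuple[str | None, tuple | None]:
    # Enumerate all matching types; prefer smallest total deviation, then
    # (optionally) higher positional propensity, then canonical order.
    matches = []
    for order, ttype in enumerate(TURN_TYPES):
        canon = cfg.canonical_turn_angles[ttype]
        devs = tuple(angular_deviation(a, c) for a, c in zip(angles, canon))
        within = sum(1 for d in devs if d <= cfg.tol_primary_deg)
        if within < 3 or max(devs) > cfg.tol_relaxed_deg:
            continue
        matches.append((sum(devs), -_propensity_bonus(ttype, aa1, aa2), order, ttype, devs))
    if not matches:
        return None, None
    _, _, _, ttype, devs = min(matches)
    return ttype, devs


def find_turns(
    ss: SSAssignment,
    o: OrderProfile,
    t: TorsionTable,
    cfg: ContextConfig | None = None,
    sequence: str | None = None,
) -> list[TurnAssignment]:
    """Scan coil windows, classify, and select non-overlapping turns.

    A window i..i+3 is evaluated when both central residues are coil,
    strictly pass the order-parameter gate (undefined s2 fails) and have
    torsion entries.  Selection is greedy by ascending total deviation,
    then start index; two turns conflict iff their central pairs share a
    residue.
    """
    cfg = cfg or ContextConfig()
    candidates: list[TurnAssignment] = []
    n = ss.n_residues
    for start in range(1, n - 2):
        c1, c2 = start + 1, start + 2
        if ss.state(c1) != "C" or ss.state(c2) != "C":
            continue
        s2a, s2b = o.get(c1), o.get(c2)
        if s2a is None or s2b is None or s2a <= cfg.s2_turn_gate or s2b <= cfg.s2_turn_gate:
            continue
        e1, e2 = t.get(c1), t.get(c2)
        if e1 is None or e2 is None:
            continue
        angles = (e1.phi, e1.psi, e2.phi, e2.psi)
        if cfg.use_turn_propensity and sequence is not None:
            ttype, devs = _classify_with_propensity(
                angles, sequence[c1 - 1], sequence[c2 - 1], cfg
            )
        else:
            ttype, devs = classify_turn(*angles, cfg)
        if ttype is None:
            continue
        candidates.append(
            TurnAssignment(start=start, turn_type=ttype, deviations=devs,
                           total_deviation=sum(devs))
        )
    selected: list[TurnAssignment] = []
    used: set[int] = set()
    for cand in sorted(candidates, key=lambda c: (c.total_deviation, c.start)):
        a, b = cand.central
        if a in used or b in used:
            continue
        selected.append(cand)
        used.update((a, b))
    return sorted(selected, key=lambda c: c.start)


# ---------------------------------------------------------------------------
# hairpins


def detect_hairpins(
    ss: SSAssignment,
    turns: list[TurnAssignment],
    cfg: ContextConfig | None = None,
) -> list[HairpinAssignment]:
    """Pair consecutive strands joined by a short loop holding a turn.

    The loop must be at most ``hairpin_max_loop`` residues and contain a
    selected turn whose central pair lies wholly inside it; the turn with
    the smallest total deviation (then start) is recorded.  A strict mode
    limits licensing turns to the mirror types I'/II'.
    """
    cfg = cfg or ContextConfig()
    strands = ss.strand_spans()
    hairpins = []
    for (s1, e1), (s2, e2) in zip(strands, strands[1:]):
        loop = (e1 + 1, s2 - 1)
        loop_len = loop[1] - loop[0] + 1
        if loop_len < 1 or loop_len > cfg.hairpin_max_loop:
            continue
        inside = [
            t
            for t in turns
            if t.central[0] >= loop[0] and t.central[1] <= loop[1]
        ]
        if cfg.strict_mirror_turns:
            inside = [t for t in inside if t.turn_type in ("I'", "II'")]
        if not inside:
            continue
        best = min(inside, key=lambda t: (t.total_deviation, t.start))
        hairpins.append(
            HairpinAssignment(strand1=(s1, e1), loop=loop, strand2=(s2, e2), turn=best)
        )
    return hairpins


# ---------------------------------------------------------------------------
# edge / interior strands


def _alternation_fraction(signs: list[int | None]) -> float | None:
    """Fraction of consecutive available pairs whose signs strictly flip."""
    pairs = 0
    alternating = 0
    for a, b in zip(signs, signs[1:]):
        if a is None or b is None:
            continue
        pairs += 1
        if a * b < 0:
            alternating += 1
    if pairs == 0:
        return None
    return alternating / pairs


def ha_alternation(
    span: tuple[int, int],
    p: SecondaryShiftProfile,
    frac_cutoff: float = 0.7,
) -> bool:
    """True iff HA secondary-shift signs alternate along the strand."""
    signs: list[int | None] = []
    for i in range(span[0], span[1] + 1):
        d = p.get(i, "HA")
        if d is None:
            signs.append(None)
        else:
            signs.append(1 if d > 0 else -1 if d < 0 else 0)
    frac = _alternation_fraction(signs)
    return frac is not None and frac >= frac_cutoff


def hydropathy_periodicity(seq_segment: str, frac_cutoff: float = 0.7) -> bool:
    """True iff hydrophobic/hydrophilic classes alternate along the span."""
    scale = _data.hydropathy_scale()
    signs = [1 if scale[aa] > 0 else -1 for aa in seq_segment]
    frac = _alternation_fraction(signs)
    return frac is not None and frac >= frac_cutoff


def charge_pattern(
    seq_segment: str,
    charge_fraction: float = 0.25,
) -> bool:
    """Charged-residue evidence: overall proportion or a central charge."""
    n = len(seq_segment)
    charged = sum(1 for aa in seq_segment if aa in CHARGED_RESIDUES)
    if n and charged / n >= charge_fraction:
        return True
    third = n // 3
    central = seq_segment[third : n - third]
    return any(aa in CHARGED_RESIDUES for aa in central)


def edge_criteria(
    span: tuple[int, int],
    p: SecondaryShiftProfile,
    o: OrderProfile,
    f: FasaProfile,
    sequence: str,
    cfg: ContextConfig | None = None,
) -> StrandTopology:
    """Seven-criterion edge-strand evidence score for one strand span.

    Each criterion contributes one point; a strand whose score strictly
    exceeds the threshold (default 4, i.e. at least 5 of 7) is called an
    edge strand, all others interior.
    """
    cfg = cfg or ContextConfig()
    lo, hi = span
    length = hi - lo + 1
    seg = sequence[lo - 1 : hi]
    fasa = [f.get(i) for i in range(lo, hi + 1)]
    s2 = [o.get(i) for i in range(lo, hi + 1)]
    exposed_frac = sum(1 for v in fasa if v > cfg.fasa_exposed) / length
    rigid_frac = sum(1 for v in s2 if v is not None and v > cfg.s2_rigid) / length
    criteria = {
        "ha_alternation": ha_alternation(span, p, cfg.ha_alternation_frac),
        "high_avg_fasa": (sum(fasa) / length) > cfg.fasa_edge_avg,
        "exposed_majority": exposed_frac > cfg.exposed_majority,
        "low_rigid_fraction": rigid_frac < cfg.rigid_frac_max,
        "hydropathy_periodicity": hydropathy_periodicity(
            seg, cfg.hydropathy_alternation_frac
        ),
        "charge_pattern": charge_pattern(seg, cfg.charge_fraction),
        "short_strand": length < cfg.short_strand_len,
    }
    score = sum(criteria.values())
    call = "edge" if score > cfg.edge_score_threshold else "interior"
    return StrandTopology(span=span, criteria=criteria, edge_score=score, call=call)


# ---------------------------------------------------------------------------
# merge


def merge_annotation(
    ss: SSAssignment,
    turns: list[TurnAssignment],
    hairpins: list[HairpinAssignment],
    topologies: list[StrandTopology],
    sequence: str,
    s2: list[float | None] | None = None,
    fasa: list[float] | None = None,
) -> Annotation:
    """Merge layers into one annotation, enforcing partition invariants."""
    n = ss.n_residues
    if len(sequence) != n:
        raise AnnotationError("sequence/state length mismatch")
    turn_labels: list[str | None] = [None] * n
    for t in turns:
        for i in t.central:
            if ss.state(i) != "C":
                raise AnnotationError(
                    f"turn label on residue {i} with state {ss.state(i)}"
                )
            if turn_labels[i - 1] is not None:
                raise AnnotationError(f"overlapping turn labels at residue {i}")
            turn_labels[i - 1] = t.turn_type
    strand_spans = ss.strand_spans()
    topo_spans = [t.span for t in topologies]
    if sorted(topo_spans) != strand_spans:
        raise AnnotationError(
            f"strand topology spans {sorted(topo_spans)} do not match "
            f"strand runs {strand_spans}"
        )
    strand_classes: list[str | None] = [None] * n
    for t in topologies:
        for i in range(t.span[0], t.span[1] + 1):
            strand_classes[i - 1] = t.call
    hairpin_flags = [False] * n
    strand_set = set(strand_spans)
    for h in hairpins:
        if h.strand1 not in strand_set or h.strand2 not in strand_set:
            raise AnnotationError(f"hairpin references non-strand span {h}")
        for i in range(h.strand1[0], h.strand2[1] + 1):
            hairpin_flags[i - 1] = True
    return Annotation(
        sequence=sequence,
        states=ss.states,
        turn_labels=turn_labels,
        hairpin_flags=hairpin_flags,
        strand_classes=strand_classes,
        turns=list(turns),
        hairpins=list(hairpins),
        strands=list(topologies),
        s2=s2,
        fasa=fasa,
    )


# ---------------------------------------------------------------------------
# annotation interchange


def annotation_tsv(ann: Annotation) -> str:
    lines = ["residue\taa\tstate\tturn_type\thairpin\tstrand_class\ts2\tfasa"]
    for i in range(1, ann.n_residues + 1):
        s2 = ann.s2[i - 1] if ann.s2 else None
        fasa = ann.fasa[i - 1] if ann.fasa else None
        lines.append(
            "\t".join(
                [
                    str(i),
                    ann.sequence[i - 1],
                    ann.states[i - 1],
                    ann.turn_labels[i - 1] or ".",
                    "1" if ann.hairpin_flags[i - 1] else "0",
                    ann.strand_classes[i - 1] or ".",
                    "NA" if s2 is None else f"{s2:.4f}",
                    "NA" if fasa is None else f"{fasa:.4f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def parse_annotation_tsv(text: str) -> Annotation:
    """Read the per-residue layers back (feature lists are reconstructed
    only as far as scoring needs them)."""
    seq, states = [], []
    turn_labels: list[str | None] = []
    hairpin_flags: list[bool] = []
    strand_classes: list[str | None] = []
    s2: list[float | None] = []
    fasa: list[float | None] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        s = raw.strip()
        if not s or s.startswith("residue\t"):
            continue
        parts = s.split("\t")
        if len(parts) != 8:
            raise ValueError(f"line {lineno}: expected 8 columns")
        seq.append(parts[1])
        states.append(parts[2])
        turn_labels.append(None if parts[3] == "." else parts[3])
        hairpin_flags.append(parts[4] == "1")
        strand_classes.append(None if parts[5] == "." else parts[5])
        s2.append(None if parts[6] == "NA" else float(parts[6]))
        fasa.append(None if parts[7] == "NA" else float(parts[7]))
    return Annotation(
        sequence="".join(seq),
        states="".join(states),
        turn_labels=turn_labels,
        hairpin_flags=hairpin_flags,
        strand_classes=strand_classes,
        turns=[],
        hairpins=[],
        strands=[],
        s2=s2,
        fasa=None if any(v is None for v in fasa) else fasa,  # type: ignore[arg-type]
    )


def feature_summary(ann: Annotation) -> str:
    out = []
    out.append(f"# chain length: {ann.n_residues}")
    helices = SSAssignment(ann.states).runs_of("H")
    out.append(f"helices ({len(helices)}):")
    for s, e in helices:
        out.append(f"  {s}-{e}")
    out.append(f"strands ({len(ann.strands)}):")
    for t in ann.strands:
        out.append(f"  {t.span[0]}-{t.span[1]}  {t.call}  score={t.edge_score}")
    out.append(f"turns ({len(ann.turns)}):")
    for t in ann.turns:
        out.append(
            f"  {t.start}-{t.start + 3}  type {t.turn_type}  "
            f"total_dev={t.total_deviation:.1f}"
        )
    out.append(f"hairpins ({len(ann.hairpins)}):")
    for h in ann.hairpins:
        out.append(
            f"  strand {h.strand1[0]}-{h.strand1[1]} | loop {h.loop[0]}-{h.loop[1]}"
            f" (turn {h.turn.turn_type}) | strand {h.strand2[0]}-{h.strand2[1]}"
        )
    return "\n".join(out) + "\n"
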