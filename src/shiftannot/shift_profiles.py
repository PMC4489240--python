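"""Secondary shifts, the ternary index filter and 3-state assignment.

The first pipeline stage: observed shifts are referenced against a
random-coil table, each nucleus is passed through a ternary digital
filter (+1 downfield / -1 upfield / 0 insignificant), the per-nucleus
indices are harmonized and voted into a per-residue consensus, and
maximal runs of consensus values become helix/strand/coil states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import _data
from .shiftio import ShiftDataset

#: Nuclei consumed by the ternary filter.  Amide 15N/1H shifts are parsed
#: but deliberately not filtered.
FILTER_NUCLEI = ("HA", "CA", "CB", "C")

#: Maps a downfield (+1) index to its structural meaning under the
#: strand(+1)/helix(-1) consensus convention: downfield HA/CB is strand
#: evidence, downfield CA/C is helix evidence.
_STRAND_SIGN = {"HA": +1, "CB": +1, "CA": -1, "C": -1}

DELTA_ATOMS = ("H", "HA", "CA", "CB", "C", "N")


class ConfigError(Exception):
    pass


@dataclass
class RandomCoilTable:
    values: dict[tuple[str, str], float]
    provenance: str

    @classmethod
    def default(cls) -> "RandomCoilTable":
        raw = _data.random_coil_shifts()
        values = {
            (aa, atom): float(v)
            for aa, atoms in raw["shifts"].items()
            for atom, v in atoms.items()
        }
        return cls(values=values, provenance=raw["provenance"])

    def get(self, aa: str, atom: str) -> float | None:
        return self.values.get((aa, atom))


@dataclass
class SecondaryShiftProfile:
    """Observed minus random-coil shift, where an observation exists."""

    delta: dict[tuple[int, str], float]
    n_residues: int

    def get(self, index: int, atom: str) -> float | None:
        return self.delta.get((index, atom))


@dataclass
class CsiIndexProfile:
    index: dict[tuple[int, str], int]
    thresholds: dict[str, float]
    n_residues: int

    def get(self, index: int, nucleus: str) -> int:
        return self.index.get((index, nucleus), 0)


@dataclass
class SSAssignment:
    """Per-residue 3-state string over {H, B, C}."""

    states: str

    @property
    def n_residues(self) -> int:
        return len(self.states)

    def state(self, index: int) -> str:
        return self.states[index - 1]

    def strand_spans(self) -> list[tuple[int, int]]:
        return self.runs_of("B")

    def runs_of(self, state: str) -> list[tuple[int, int]]:
        spans = []
        start = None
        for i, s in enumerate(self.states + "\x00", 1):
            if s == state and start is None:
                start = i
            elif s != state and start is not None:
                spans.append((start, i - 1))
                start = None
        return spans


def default_thresholds() -> dict[str, float]:
    return _data.csi_thresholds()


def secondary_shifts(
    ds: ShiftDataset, rc: RandomCoilTable | None = None
) -> SecondaryShiftProfile:
    """Observed minus random-coil shift for every assigned backbone atom.

    Glycine HA is the mean of HA2/HA3 when both are present (either one
    alone stands in for HA).  A residue type without a random-coil entry
    for an observed atom is a configuration error.
    """
    rc = rc or RandomCoilTable.default()
    delta: dict[tuple[int, str], float] = {}
    for i in range(1, ds.n_residues + 1):
        aa = ds.residue_type(i)
        for atom in DELTA_ATOMS:
            if atom == "HA" and aa == "G":
                ha2, ha3 = ds.get(i, "HA2"), ds.get(i, "HA3")
                if ha2 is not None and ha3 is not None:
                    obs = 0.5 * (ha2 + ha3)
                elif ha2 is not None:
                    obs = ha2
                elif ha3 is not None:
                    obs = ha3
                else:
                    obs = ds.get(i, "HA")
            else:
                obs = ds.get(i, atom)
            if obs is None:
                continue
            ref = rc.get(aa, atom)
            if ref is None:
                raise ConfigError(
                    f"random-coil table has no entry for residue {aa} atom {atom}"
                )
            delta[(i, atom)] = obs - ref
    return SecondaryShiftProfile(delta=delta, n_residues=ds.n_residues)


def csi_filter(
    p: SecondaryShiftProfile, thresholds: dict[str, float] | None = None
) -> CsiIndexProfile:
    """Ternary filter: strictly beyond the cutoff scores +/-1, else 0."""
    thresholds = thresholds or default_thresholds()
    for nucleus, cut in thresholds.items():
        if cut <= 0:
            raise ConfigError(f"threshold for {nucleus} must be positive")
    index: dict[tuple[int, str], int] = {}
    for i in range(1, p.n_residues + 1):
        for nucleus in FILTER_NUCLEI:
            d = p.get(i, nucleus)
            if d is None:
                continue
            cut = thresholds[nucleus]
            if d > cut:
                index[(i, nucleus)] = 1
            elif d < -cut:
                index[(i, nucleus)] = -1
            else:
                index[(i, nucleus)] = 0
    return CsiIndexProfile(index=index, thresholds=dict(thresholds), n_residues=p.n_residues)


def consensus_index(p: CsiIndexProfile) -> list[int]:
    """Per-residue majority vote, +1 strand / -1 helix / 0 otherwise.

    Each nucleus votes with its sign harmonized by `_STRAND_SIGN`; ties
    and all-zero residues give 0.
    """
    out = []
    for i in range(1, p.n_residues + 1):
        strand = helix = 0
        for nucleus in FILTER_NUCLEI:
            vote = p.get(i, nucleus) * _STRAND_SIGN[nucleus]
            if vote > 0:
                strand += 1
            elif vote < 0:
                helix += 1
        if strand > helix:
            out.append(1)
        elif helix > strand:
            out.append(-1)
        else:
            out.append(0)
    return out


def assign_sse(
    consensus: list[int], min_helix_len: int = 4, min_strand_len: int = 3
) -> SSAssignment:
    """Run-length conversion of the consensus vector into H/B/C states.

    Maximal runs of -1 of length >= *min_helix_len* become helix; maximal
    runs of +1 of length >= *min_strand_len* become strand (short strand
    runs — isolated bridges — are coil); everything else is coil.
    """
    n = len(consensus)
    states = ["C"] * n
    i = 0
    while i < n:
        v = consensus[i]
        j = i
        while j < n and consensus[j] == v:
            j += 1
        run = j - i
        if v == -1 and run >= min_helix_len:
            states[i:j] = ["H"] * run
        elif v == 1 and run >= min_strand_len:
            states[i:j] = ["B"] * run
        i = j
    return SSAssignment(states="".join(states))


def index_profile_tsv(p: CsiIndexProfile, consensus: list[int]) -> str:
    """TSV of the per-residue ternary indices (bar-graph input)."""
    lines = ["residue\tHA\tCA\tCB\tC\tconsensus"]
    for i in range(1, p.n_residues + 1):
        cells = [str(i)]
        for nucleus in ("HA", "CA", "CB", "C"):
            cells.append(str(p.index.get((i, nucleus), 0)))
        cells.append(str(consensus[i - 1]))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
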