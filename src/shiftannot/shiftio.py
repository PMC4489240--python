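"""Readers and writers for assigned-shift and torsion-angle tables.

Three shift-file dialects are accepted — NMR-STAR 2.1, NMR-STAR 3.1 and
the columnar SHIFTY layout — plus TALOS-style backbone torsion
prediction tables.  Everything is normalized to a single contiguous
chain with 1-based residue numbering; author numbering from STAR files
is remapped (the offset is retained for reporting).

Only backbone atoms are kept (H, HA, HA2/HA3, N, CA, CB, C); other atom
names are ignored with a logged warning and counted as rejects so that
no record is ever dropped silently.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

log = logging.getLogger("shiftannot.shiftio")

ALLOWED_ATOMS = ("H", "HA", "HA2", "HA3", "N", "CA", "CB", "C")
#: Canonical-name map for common synonyms (carbonyl carbon, amide proton).
ATOM_SYNONYMS = {"CO": "C", "C'": "C", "HN": "H"}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

MISSING_MARKERS = {".", "?", ""}


class ShiftFileError(Exception):
    """Base class for shift/torsion file problems."""


class FormatDetectionError(ShiftFileError):
    pass


class ShiftParseError(ShiftFileError):
    def __init__(self, lineno: int | None, message: str):
        self.lineno = lineno
        where = f"line {lineno}: " if lineno is not None else ""
        super().__init__(where + message)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ShiftDataset:
    """One contiguous polypeptide chain with per-residue assigned shifts."""

    chain_id: str
    sequence: str
    shifts: dict[tuple[int, str], float]
    source_format: str | None = None
    #: author residue numbering = internal index + author_offset
    author_offset: int = 0
    #: (lineno, reason) for every in-file record not stored
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def residue_type(self, index: int) -> str:
        return self.sequence[index - 1]

    def get(self, index: int, atom: str) -> float | None:
        return self.shifts.get((index, atom))


@dataclass(frozen=True)
class TorsionEntry:
    phi: float
    psi: float
    class_label: str | None = None


@dataclass
class TorsionTable:
    entries: dict[int, TorsionEntry]
    dropped: int = 0

    def coverage(self, n_residues: int) -> float:
        if n_residues <= 0:
            return 0.0
        return len(self.entries) / n_residues

    def get(self, index: int) -> TorsionEntry | None:
        return self.entries.get(index)


@dataclass
class CompletenessReport:
    overall_pct: float
    per_atom_pct: dict[str, float]
    missing: list[tuple[int, str]]


# ---------------------------------------------------------------------------
# format detection


def detect_format(text: str) -> str:
    """Return the dialect (``nmrstar3``/``nmrstar2``/``shifty``) of *text*."""
    if not text.strip():
        raise FormatDetectionError("empty input")
    if "_Atom_chem_shift." in text:
        return "nmrstar3"
    if "_Chem_shift_value" in text:
        return "nmrstar2"
    for line in text.splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            head = s.lstrip("#").split()
            if len(head) >= 2 and head[0].upper() == "NUM" and head[1].upper() == "AA":
                return "shifty"
            continue
        parts = s.split()
        if (
            len(parts) >= 3
            and re.fullmatch(r"-?\d+", parts[0])
            and parts[1].upper() in AA1_TO_3
        ):
            return "shifty"
        break
    raise FormatDetectionError("unrecognized shift-file format")


# ---------------------------------------------------------------------------
# STAR tokenizing (minimal: tags, loops, quoted values, comments)

_TOKEN_RE = re.compile(r"'[^']*'|\"[^\"]*\"|\S+")


def _star_tokens(text: str):
    in_semi = False
    for lineno, raw in enumerate(text.splitlines(), 1):
        if in_semi:
            if raw.startswith(";"):
                in_semi = False
            continue
        if raw.startswith(";"):
            in_semi = True
            continue
        for m in _TOKEN_RE.finditer(raw):
            tok = m.group(0)
            if tok.startswith("#"):
                break
            if tok[0] in "'\"" and len(tok) >= 2 and tok[-1] == tok[0]:
                tok = tok[1:-1]
            yield lineno, tok


def _star_loops(text: str) -> list[tuple[list[str], list[list[tuple[int, str]]]]]:
    toks = list(_star_tokens(text))
    loops = []
    i = 0
    n = len(toks)
    while i < n:
        if toks[i][1].lower() != "loop_":
            i += 1
            continue
        i += 1
        tags: list[str] = []
        while i < n and toks[i][1].startswith("_"):
            tags.append(toks[i][1])
            i += 1
        values: list[tuple[int, str]] = []
        while i < n:
            lineno, tok = toks[i]
            low = tok.lower()
            if (
                low in ("stop_", "loop_")
                or tok.startswith("_")
                or low.startswith(("save_", "data_", "global_"))
            ):
                break
            values.append((lineno, tok))
            i += 1
        if i < n and toks[i][1].lower() == "stop_":
            i += 1
        if not tags or not values:
            continue
        if len(values) % len(tags) != 0:
            raise ShiftParseError(
                values[-1][0], "loop value count is not a multiple of its tag count"
            )
        rows = [values[j : j + len(tags)] for j in range(0, len(values), len(tags))]
        loops.append((tags, rows))
    return loops


def _find_column(tags: list[str], *suffixes: str) -> int | None:
    for suf in suffixes:
        for k, tag in enumerate(tags):
            if tag.lower().endswith(suf.lower()):
                return k
    return None


# ---------------------------------------------------------------------------
# shift parsing


@dataclass(frozen=True)
class _Record:
    lineno: int
    seq_code: int
    aa: str
    atom: str
    value: str


def _res_letter(lineno: int, label: str) -> str:
    up = label.upper()
    if up in AA3_TO_1:
        return AA3_TO_1[up]
    if up in AA1_TO_3:
        return up
    raise ShiftParseError(lineno, f"unknown residue type {label!r}")


def _records_nmrstar3(text: str) -> tuple[list[_Record], str]:
    for tags, rows in _star_loops(text):
        if _find_column(tags, "_Atom_chem_shift.Val") is None:
            continue
        i_seq = _find_column(tags, ".Comp_index_ID", ".Seq_ID")
        i_comp = _find_column(tags, ".Comp_ID")
        i_atom = _find_column(tags, ".Atom_ID")
        i_val = _find_column(tags, ".Val")
        i_ent = _find_column(tags, ".Entity_ID")
        if None in (i_seq, i_comp, i_atom):
            raise ShiftParseError(rows[0][0][0], "shift loop lacks residue/atom tags")
        entity = None
        if i_ent is not None:
            entities = sorted({r[i_ent][1] for r in rows})
            entity = entities[0]
            if len(entities) > 1:
                log.warning(
                    "multiple entities %s in STAR file; reading entity %s only",
                    entities, entity,
                )
        records = []
        for row in rows:
            if entity is not None and row[i_ent][1] != entity:
                continue
            lineno = row[i_seq][0]
            try:
                seq_code = int(row[i_seq][1])
            except ValueError:
                raise ShiftParseError(lineno, f"bad residue number {row[i_seq][1]!r}")
            records.append(
                _Record(lineno, seq_code, _res_letter(lineno, row[i_comp][1]),
                        row[i_atom][1], row[i_val][1])
            )
        return records, "nmrstar3"
    raise ShiftParseError(None, "no _Atom_chem_shift loop found")


def _records_nmrstar2(text: str) -> tuple[list[_Record], str]:
    for tags, rows in _star_loops(text):
        if _find_column(tags, "_Chem_shift_value") is None:
            continue
        i_seq = _find_column(tags, "_Residue_seq_code")
        i_comp = _find_column(tags, "_Residue_label")
        i_atom = _find_column(tags, "_Atom_name")
        i_val = next(
            k for k, t in enumerate(tags) if t.lower() == "_chem_shift_value"
        )
        if None in (i_seq, i_comp, i_atom):
            raise ShiftParseError(rows[0][0][0], "shift loop lacks residue/atom tags")
        records = []
        for row in rows:
            lineno = row[i_seq][0]
            try:
                seq_code = int(row[i_seq][1])
            except ValueError:
                raise ShiftParseError(lineno, f"bad residue number {row[i_seq][1]!r}")
            records.append(
                _Record(lineno, seq_code, _res_letter(lineno, row[i_comp][1]),
                        row[i_atom][1], row[i_val][1])
            )
        return records, "nmrstar2"
    raise ShiftParseError(None, "no _Chem_shift_value loop found")


def _records_shifty(text: str) -> tuple[list[_Record], str]:
    columns: list[str] | None = None
    records: list[_Record] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        s = raw.strip()
        if not s:
            continue
        if s.startswith("#"):
            head = s.lstrip("#").split()
            if len(head) >= 3 and head[0].upper() == "NUM" and head[1].upper() == "AA":
                columns = [c.upper() for c in head[2:]]
            continue
        if columns is None:
            raise ShiftParseError(lineno, "SHIFTY data before #NUM AA header")
        parts = s.split()
        if len(parts) != 2 + len(columns):
            raise ShiftParseError(
                lineno, f"expected {2 + len(columns)} fields, got {len(parts)}"
            )
        try:
            seq_code = int(parts[0])
        except ValueError:
            raise ShiftParseError(lineno, f"bad residue number {parts[0]!r}")
        aa = _res_letter(lineno, parts[1])
        for atom, val in zip(columns, parts[2:]):
            if val in MISSING_MARKERS:
                continue
            records.append(_Record(lineno, seq_code, aa, atom, val))
    if columns is None:
        raise ShiftParseError(None, "missing SHIFTY #NUM AA header")
    return records, "shifty"


def _dataset_from_records(
    records: list[_Record], fmt: str, chain_id: str
) -> ShiftDataset:
    if not records:
        raise ShiftParseError(None, "no shift records found")
    codes = sorted({r.seq_code for r in records})
    if codes[-1] - codes[0] + 1 != len(codes):
        have = set(codes)
        gaps = [c for c in range(codes[0], codes[-1] + 1) if c not in have]
        raise ShiftParseError(
            None,
            "sequence cannot be reconstructed contiguously; missing residue "
            f"numbers {gaps[:10]}",
        )
    offset = codes[0] - 1
    n = len(codes)
    seq = [None] * n
    shifts: dict[tuple[int, str], float] = {}
    rejected: list[tuple[int, str]] = []
    for rec in records:
        idx = rec.seq_code - offset
        if seq[idx - 1] is None:
            seq[idx - 1] = rec.aa
        elif seq[idx - 1] != rec.aa:
            raise ShiftParseError(
                rec.lineno,
                f"conflicting residue type at position {rec.seq_code}: "
                f"{seq[idx - 1]} vs {rec.aa}",
            )
        atom = ATOM_SYNONYMS.get(rec.atom.upper(), rec.atom.upper())
        if atom not in ALLOWED_ATOMS:
            log.warning("ignoring atom %s (line %d)", rec.atom, rec.lineno)
            rejected.append((rec.lineno, f"ignored atom {rec.atom}"))
            continue
        if rec.value in MISSING_MARKERS:
            rejected.append((rec.lineno, f"missing value for {atom}"))
            continue
        try:
            value = float(rec.value)
        except ValueError:
            raise ShiftParseError(rec.lineno, f"bad shift value {rec.value!r}")
        if not math.isfinite(value):
            raise ShiftParseError(rec.lineno, f"non-finite shift value {rec.value!r}")
        if (idx, atom) in shifts:
            raise ShiftParseError(
                rec.lineno, f"duplicate shift for residue {rec.seq_code} atom {atom}"
            )
        shifts[(idx, atom)] = value
    ds = ShiftDataset(
        chain_id=chain_id,
        sequence="".join(seq),
        shifts=shifts,
        source_format=fmt,
        author_offset=offset,
        rejected=rejected,
    )
    _validate_ha(ds)
    return ds


def _validate_ha(ds: ShiftDataset) -> None:
    for i in range(1, ds.n_residues + 1):
        has_ha = (i, "HA") in ds.shifts
        has_pair = (i, "HA2") in ds.shifts or (i, "HA3") in ds.shifts
        if ds.residue_type(i) == "G":
            if has_ha and has_pair:
                raise ShiftParseError(
                    None, f"glycine {i} carries both HA and HA2/HA3"
                )
        elif has_pair:
            raise ShiftParseError(
                None, f"residue {i} ({ds.residue_type(i)}) carries HA2/HA3"
            )


def parse_shifts(text: str, fmt: str | None = None, chain_id: str = "A") -> ShiftDataset:
    """Parse *text* in the given (or auto-detected) dialect."""
    if fmt is None:
        fmt = detect_format(text)
    if fmt == "nmrstar3":
        records, fmt = _records_nmrstar3(text)
    elif fmt == "nmrstar2":
        records, fmt = _records_nmrstar2(text)
    elif fmt == "shifty":
        records, fmt = _records_shifty(text)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _dataset_from_records(records, fmt, chain_id)


def apply_reference_offset(ds: ShiftDataset, offsets: dict[str, float]) -> ShiftDataset:
    """Return a copy with a user-supplied per-nucleus referencing offset added.

    Keys are atom names (``CA``/``CB``/``C`` for carbons, etc.).  Inputs are
    otherwise assumed to be correctly referenced.
    """
    shifts = {
        key: val + offsets.get(key[1], 0.0) for key, val in ds.shifts.items()
    }
    return ShiftDataset(
        chain_id=ds.chain_id,
        sequence=ds.sequence,
        shifts=shifts,
        source_format=ds.source_format,
        author_offset=ds.author_offset,
        rejected=list(ds.rejected),
    )


# ---------------------------------------------------------------------------
# completeness


def completeness(ds: ShiftDataset) -> CompletenessReport:
    """Fraction of the expected backbone shift set that is present.

    Expected atoms per residue are H, HA, CA, CB, C, N with CB excluded
    for glycine; glycine's HA requirement is satisfied by HA, HA2 or HA3.
    """
    expected_atoms = ("H", "HA", "CA", "CB", "C", "N")
    per_atom_have: dict[str, int] = {a: 0 for a in expected_atoms}
    per_atom_want: dict[str, int] = {a: 0 for a in expected_atoms}
    missing: list[tuple[int, str]] = []
    for i in range(1, ds.n_residues + 1):
        gly = ds.residue_type(i) == "G"
        for atom in expected_atoms:
            if atom == "CB" and gly:
                continue
            per_atom_want[atom] += 1
            if atom == "HA":
                present = any(
                    (i, a) in ds.shifts for a in ("HA", "HA2", "HA3")
                )
            else:
                present = (i, atom) in ds.shifts
            if present:
                per_atom_have[atom] += 1
            else:
                missing.append((i, atom))
    per_atom_pct = {
        a: (100.0 * per_atom_have[a] / per_atom_want[a]) if per_atom_want[a] else 100.0
        for a in expected_atoms
    }
    total_want = sum(per_atom_want.values())
    total_have = sum(per_atom_have.values())
    overall = 100.0 * total_have / total_want if total_want else 100.0
    return CompletenessReport(overall, per_atom_pct, missing)


# ---------------------------------------------------------------------------
# torsion table


def normalize_angle(a: float) -> float:
    """Wrap a degree angle into [-180, 180)."""
    return (a + 180.0) % 360.0 - 180.0


_HEADER_WORDS = {"REMARK", "DATA", "VARS", "FORMAT"}


def parse_torsion_table(text: str) -> TorsionTable:
    """Parse a TALOS-style prediction table.

    Rows are ``resid resname phi psi [...] class``; rows whose class label
    is ``None`` (or whose angles carry an out-of-range sentinel such as
    9999) are dropped as unreliable.
    """
    entries: dict[int, TorsionEntry] = {}
    dropped = 0
    for lineno, raw in enumerate(text.splitlines(), 1):
        s = raw.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if parts[0].upper() in _HEADER_WORDS:
            continue
        if len(parts) < 4:
            raise ShiftParseError(lineno, "torsion row needs >=4 columns")
        try:
            resid = int(parts[0])
        except ValueError:
            raise ShiftParseError(lineno, f"bad residue number {parts[0]!r}")
        try:
            phi = float(parts[2])
            psi = float(parts[3])
        except ValueError:
            raise ShiftParseError(
                lineno, f"non-numeric torsion angle in {parts[2]!r}/{parts[3]!r}"
            )
        label = parts[-1] if len(parts) > 4 and not _is_number(parts[-1]) else None
        if label is not None and label.lower() == "none":
            dropped += 1
            continue
        if abs(phi) > 360.0 or abs(psi) > 360.0:
            dropped += 1
            continue
        entries[resid] = TorsionEntry(normalize_angle(phi), normalize_angle(psi), label)
    return TorsionTable(entries=entries, dropped=dropped)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# writers


def _glycine_ha_columns(ds: ShiftDataset, i: int) -> float | None:
    ha2 = ds.get(i, "HA2")
    ha3 = ds.get(i, "HA3")
    if ha2 is not None and ha3 is not None:
        return 0.5 * (ha2 + ha3)
    if ha2 is not None:
        return ha2
    if ha3 is not None:
        return ha3
    return ds.get(i, "HA")


def write_shifty(ds: ShiftDataset) -> str:
    """Serialize to the SHIFTY columnar layout (HA2/HA3 collapse to HA)."""
    cols = ["HA", "CA", "CB", "CO", "N", "HN"]
    src = {"HA": "HA", "CA": "CA", "CB": "CB", "CO": "C", "N": "N", "HN": "H"}
    lines = ["#NUM AA " + " ".join(f"{c:>8s}" for c in cols)]
    for i in range(1, ds.n_residues + 1):
        aa = ds.residue_type(i)
        fields = [f"{i:>4d}", aa.rjust(2)]
        for c in cols:
            if c == "HA" and aa == "G":
                v = _glycine_ha_columns(ds, i)
            else:
                v = ds.get(i, src[c])
            fields.append(f"{v:8.3f}" if v is not None else f"{'.':>8s}")
        lines.append(" ".join(fields))
    return "\n".join(lines) + "\n"


def _residue_atom_rows(ds: ShiftDataset):
    for i in range(1, ds.n_residues + 1):
        for atom in ALLOWED_ATOMS:
            v = ds.get(i, atom)
            if v is not None:
                yield i, AA1_TO_3[ds.residue_type(i)], atom, v


def write_nmrstar3(ds: ShiftDataset) -> str:
    lines = [
        "data_shiftannot",
        "",
        "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category    assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.ID             1",
        "",
        "   loop_",
        "      _Atom_chem_shift.ID",
        "      _Atom_chem_shift.Entity_ID",
        "      _Atom_chem_shift.Comp_index_ID",
        "      _Atom_chem_shift.Comp_ID",
        "      _Atom_chem_shift.Atom_ID",
        "      _Atom_chem_shift.Val",
        "",
    ]
    for k, (i, res3, atom, v) in enumerate(_residue_atom_rows(ds), 1):
        lines.append(f"      {k:>5d} 1 {i:>4d} {res3} {atom:<4s} {v:10.3f}")
    lines += ["   stop_", "save_", ""]
    return "\n".join(lines)


def write_nmrstar2(ds: ShiftDataset) -> str:
    lines = [
        "data_shiftannot",
        "",
        "save_assigned_chemical_shifts",
        "   _Saveframe_category   assigned_chemical_shifts",
        "",
        "   loop_",
        "      _Atom_shift_assign_ID",
        "      _Residue_seq_code",
        "      _Residue_label",
        "      _Atom_name",
        "      _Chem_shift_value",
        "",
    ]
    for k, (i, res3, atom, v) in enumerate(_residue_atom_rows(ds), 1):
        lines.append(f"      {k:>5d} {i:>4d} {res3} {atom:<4s} {v:10.3f}")
    lines += ["   stop_", "save_", ""]
    return "\n".join(lines)


WRITERS = {
    "shifty": write_shifty,
    "nmrstar2": write_nmrstar2,
    "nmrstar3": write_nmrstar3,
}


def write_torsion_table(rows: list[tuple[int, str, float, float, str]]) -> str:
    """Serialize ``(resid, resname, phi, psi, class)`` rows TALOS-style."""
    lines = [
        "DATA FIRST_RESID 1",
        "",
        "VARS    RESID RESNAME PHI PSI CLASS",
        "FORMAT  %4d %s %9.3f %9.3f %s",
        "",
    ]
    for resid, resname, phi, psi, label in rows:
        lines.append(f"{resid:>5d} {resname} {phi:9.3f} {psi:9.3f} {label}")
    return "\n".join(lines) + "\n"
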