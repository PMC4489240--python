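"""Independent brute-force oracles kept free of the library's code paths."""

from __future__ import annotations

import itertools
import re

# Kyte-Doolittle > 0, written out independently of the shipped table.
HYDROPHOBIC = set("AVLIMFC")
CHARGED = set("DEKRH")


def sse_by_regex(consensus: list[int], min_helix: int = 4, min_strand: int = 3) -> str:
    """Run-length 3-state oracle implemented with a regex pass."""
    symbols = "".join("m" if v == -1 else "p" if v == 1 else "z" for v in consensus)
    out = list("C" * len(symbols))
    for m in re.finditer(r"m+", symbols):
        if m.end() - m.start() >= min_helix:
            out[m.start() : m.end()] = "H" * (m.end() - m.start())
    for m in re.finditer(r"p+", symbols):
        if m.end() - m.start() >= min_strand:
            out[m.start() : m.end()] = "B" * (m.end() - m.start())
    return "".join(out)


def edge_score_brute(
    span: tuple[int, int],
    ha_deltas: dict[int, float],
    s2: dict[int, float | None],
    fasa: dict[int, float],
    sequence: str,
) -> int:
    """Literal re-evaluation of the seven edge-strand criteria."""
    lo, hi = span
    idx = list(range(lo, hi + 1))
    length = len(idx)
    seg = sequence[lo - 1 : hi]
    score = 0

    # 1: alternating HA secondary-shift signs over >= 70% of available pairs
    pairs = alt = 0
    for a, b in zip(idx, idx[1:]):
        if a in ha_deltas and b in ha_deltas:
            pairs += 1
            if ha_deltas[a] * ha_deltas[b] < 0:
                alt += 1
    if pairs > 0 and alt / pairs >= 0.7:
        score += 1
    # 2: mean fasa strictly above 0.3
    if sum(fasa[i] for i in idx) / length > 0.3:
        score += 1
    # 3: strict majority of residues with fasa strictly above 0.25
    if sum(1 for i in idx if fasa[i] > 0.25) / length > 0.50:
        score += 1
    # 4: fraction of rigid residues (s2 strictly above 0.90) strictly below 0.40
    if sum(1 for i in idx if s2[i] is not None and s2[i] > 0.90) / length < 0.40:
        score += 1
    # 5: hydrophobic/hydrophilic alternation over >= 70% of pairs
    flips = sum(
        1
        for a, b in zip(seg, seg[1:])
        if (a in HYDROPHOBIC) != (b in HYDROPHOBIC)
    )
    if length > 1 and flips / (length - 1) >= 0.7:
        score += 1
    # 6: charged proportion >= 0.25 or a charge in the central third
    third = length // 3
    if (
        sum(1 for aa in seg if aa in CHARGED) / length >= 0.25
        or any(aa in CHARGED for aa in seg[third : length - third])
    ):
        score += 1
    # 7: short strand
    if length < 5:
        score += 1
    return score


def select_turns_exhaustive(candidates: list) -> list:
    """Oracle for the greedy non-overlapping turn selection.

    Enumerates every non-overlapping subset (candidates conflict iff
    their central pairs share a residue), keeps the maximal ones, and
    returns the subset whose sorted (total_deviation, start) key list is
    lexicographically smallest.
    """
    n = len(candidates)
    best_key = None
    best = []
    for mask in range(1 << n):
        subset = [candidates[i] for i in range(n) if mask >> i & 1]
        used = set()
        ok = True
        for c in subset:
            a, b = c.central
            if a in used or b in used:
                ok = False
                break
            used.update((a, b))
        if not ok:
            continue
        extendable = any(
            c.central[0] not in used and c.central[1] not in used
            for c in candidates
            if c not in subset
        )
        if extendable:
            continue
        key = sorted((c.total_deviation, c.start) for c in subset)
        if best_key is None or key < best_key:
            best_key = key
            best = subset
    return sorted(best, key=lambda c: c.start)
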