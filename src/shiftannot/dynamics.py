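"""Backbone flexibility (S2) and fractional accessible surface area.

Both estimators are deliberately simple, fully parameterized surrogates:
downstream logic consumes only their contracts (values in [0, 1],
monotone response to secondary-shift magnitude, fixed gate semantics),
and either profile can be supplied directly as a TSV to bypass
estimation entirely.

The order-parameter estimate maps the smoothed, normalized mean
secondary-shift magnitude m to ``s2 = clamp(1 - k / max(m, floor))``;
residues with no usable nuclei carry ``None``, which by convention fails
every "greater-than" gate and passes every "less-than" gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import _data
from .shift_profiles import SecondaryShiftProfile

DEFAULT_WEIGHTS = {"HA": 1.0, "CA": 1.0, "CB": 1.0, "C": 1.0}
#: Per-nucleus dynamic-range normalizers (ppm); 2x the ternary-filter cutoffs.
DEFAULT_NORMALIZERS = {"HA": 0.2, "CA": 1.4, "CB": 1.4, "C": 1.0}
DEFAULT_K = 0.1
DEFAULT_FLOOR = 0.02


@dataclass
class OrderProfile:
    s2: list[float | None]
    method_params: dict

    @property
    def n_residues(self) -> int:
        return len(self.s2)

    def get(self, index: int) -> float | None:
        return self.s2[index - 1]


@dataclass
class FasaProfile:
    fasa: list[float]

    @property
    def n_residues(self) -> int:
        return len(self.fasa)

    def get(self, index: int) -> float:
        return self.fasa[index - 1]


@dataclass
class FasaParams:
    a0: float = 0.0
    a1: float = 1.5   # flexibility term (1 - s2); >= 0 so lower s2 never lowers fasa
    a2: float = -1.2  # hydropathy term (Kyte-Doolittle, normalized to [-1, 1])
    a3: float = -1.0  # local normalized |delta| term


def _normalized_magnitudes(
    p: SecondaryShiftProfile,
    weights: dict[str, float],
    normalizers: dict[str, float],
) -> list[float | None]:
    out: list[float | None] = []
    for i in range(1, p.n_residues + 1):
        num = den = 0.0
        for nucleus, w in weights.items():
            if w <= 0:
                continue
            d = p.get(i, nucleus)
            if d is None:
                continue
            num += w * abs(d) / normalizers[nucleus]
            den += w
        out.append(num / den if den > 0 else None)
    return out


def _smooth(values: list[float | None], window: int) -> list[float | None]:
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd count")
    half = window // 2
    n = len(values)
    out: list[float | None] = []
    for i in range(n):
        if values[i] is None:
            out.append(None)
            continue
        neigh = [
            values[j]
            for j in range(max(0, i - half), min(n, i + half + 1))
            if values[j] is not None
        ]
        out.append(sum(neigh) / len(neigh))
    return out


def smoothed_shift_magnitude(
    p: SecondaryShiftProfile,
    weights: dict[str, float] | None = None,
    window: int = 3,
    normalizers: dict[str, float] | None = None,
) -> list[float | None]:
    """Centered moving average of the weighted normalized |delta| mean."""
    weights = weights or DEFAULT_WEIGHTS
    normalizers = normalizers or DEFAULT_NORMALIZERS
    return _smooth(_normalized_magnitudes(p, weights, normalizers), window)


def rci_s2(
    p: SecondaryShiftProfile,
    weights: dict[str, float] | None = None,
    window: int = 3,
    k: float = DEFAULT_K,
    floor: float = DEFAULT_FLOOR,
    normalizers: dict[str, float] | None = None,
) -> OrderProfile:
    """Shift-magnitude-based order-parameter estimate in [0, 1]."""
    weights = weights or DEFAULT_WEIGHTS
    normalizers = normalizers or DEFAULT_NORMALIZERS
    smoothed = smoothed_shift_magnitude(p, weights, window, normalizers)
    s2: list[float | None] = []
    for m in smoothed:
        if m is None:
            s2.append(None)
        else:
            s2.append(min(1.0, max(0.0, 1.0 - k / max(m, floor))))
    params = {
        "weights": dict(weights),
        "normalizers": dict(normalizers),
        "window": window,
        "k": k,
        "floor": floor,
    }
    return OrderProfile(s2=s2, method_params=params)


def fasa_estimate(
    p: SecondaryShiftProfile,
    o: OrderProfile,
    sequence: str,
    params: FasaParams | None = None,
    weights: dict[str, float] | None = None,
    window: int = 3,
    normalizers: dict[str, float] | None = None,
) -> FasaProfile:
    """Logistic exposure estimate from flexibility, hydropathy and |delta|.

    Exposed residues (hydrophilic, flexible, small secondary shifts)
    score high; buried ones (hydrophobic, rigid, large shifts) score low.
    Undefined s2 is treated as fully flexible (conservatively exposed).
    """
    import math

    params = params or FasaParams()
    scale = _data.hydropathy_scale()
    local = smoothed_shift_magnitude(p, weights, window, normalizers)
    fasa = []
    for i in range(1, o.n_residues + 1):
        s2 = o.get(i)
        flex = 1.0 if s2 is None else 1.0 - s2
        hydro = scale[sequence[i - 1]] / 4.5
        m = local[i - 1] or 0.0
        x = params.a0 + params.a1 * flex + params.a2 * hydro + params.a3 * m
        fasa.append(1.0 / (1.0 + math.exp(-x)))
    return FasaProfile(fasa=fasa)


# ---------------------------------------------------------------------------
# profile TSV interchange (lets real estimator outputs be plugged in)


def profiles_tsv(o: OrderProfile, f: FasaProfile) -> str:
    lines = ["residue_index\ts2\tfasa"]
    for i in range(1, o.n_residues + 1):
        s2 = o.get(i)
        lines.append(
            f"{i}\t{'NA' if s2 is None else f'{s2:.4f}'}\t{f.get(i):.4f}"
        )
    return "\n".join(lines) + "\n"


def parse_profiles_tsv(text: str) -> tuple[OrderProfile, FasaProfile]:
    s2: list[float | None] = []
    fasa: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        s = raw.strip()
        if not s or s.startswith("residue_index"):
            continue
        parts = s.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated columns")
        s2.append(None if parts[1] == "NA" else float(parts[1]))
        fasa.append(float(parts[2]))
    return (
        OrderProfile(s2=s2, method_params={"source": "tsv"}),
        FasaProfile(fasa=fasa),
    )
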