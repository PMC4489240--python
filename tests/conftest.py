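from __future__ import annotations

import numpy as np
import pytest

from shiftannot.context_assign import TURN_TYPES
from shiftannot.synth import Element, TopologySpec, generate


def random_topology(rng: np.random.Generator) -> TopologySpec:
    """A random, always-valid topology with at least one of each feature
    family available to the pipeline."""
    elements = [Element("coil", int(rng.integers(2, 5)))]
    roles: dict[int, str] = {}
    ordinal = 0
    for _ in range(int(rng.integers(2, 5))):
        kind = str(rng.choice(["helix", "strand", "hairpin", "turn"]))
        if kind == "helix":
            elements.append(Element("helix", int(rng.integers(4, 9))))
        elif kind == "strand":
            role = str(rng.choice(["edge", "interior"]))
            length = int(rng.integers(3, 6)) if role == "edge" else int(rng.integers(5, 8))
            roles[ordinal] = role
            ordinal += 1
            elements.append(Element("strand", length))
        elif kind == "hairpin":
            role = str(rng.choice(["edge", "interior"]))
            length = int(rng.integers(3, 6)) if role == "edge" else int(rng.integers(5, 7))
            roles[ordinal] = role
            roles[ordinal + 1] = role
            ordinal += 2
            elements.append(
                Element(
                    "hairpin",
                    length=length,
                    loop_len=int(rng.integers(2, 7)),
                    turn_type=str(rng.choice(list(TURN_TYPES))),
                )
            )
        else:
            elements.append(Element("turn", turn_type=str(rng.choice(list(TURN_TYPES)))))
        elements.append(Element("coil", int(rng.integers(2, 6))))
    disordered = []
    if rng.random() < 0.3:
        n = sum_length(elements)
        elements.append(Element("coil", 10))
        disordered.append((n + 2, n + 10))
    return TopologySpec(
        elements=elements,
        strand_roles=roles,
        disordered_spans=disordered,
        seed=int(rng.integers(0, 2**31)),
    )


def sum_length(elements: list[Element]) -> int:
    total = 0
    for el in elements:
        if el.kind == "turn":
            total += 2
        elif el.kind == "hairpin":
            total += 2 * el.length + el.loop_len
        else:
            total += el.length
    return total


@pytest.fixture
def hairpin_spec() -> TopologySpec:
    return TopologySpec(
        elements=[
            Element("coil", 3),
            Element("helix", 6),
            Element("coil", 3),
            Element("hairpin", length=5, loop_len=4, turn_type="I'"),
            Element("coil", 2),
            Element("strand", 6),
            Element("coil", 4),
        ],
        strand_roles={0: "edge", 1: "edge", 2: "interior"},
        seed=11,
    )


@pytest.fixture
def hairpin_result(hairpin_spec):
    return generate(hairpin_spec)
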