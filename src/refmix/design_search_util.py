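"""Small combinatorial helpers for the design grid."""

from __future__ import annotations

import itertools
from fractions import Fraction


def simplex_grid(n_components: int, step: Fraction | float) -> list[tuple[float, ...]]:
    """All points on the unit simplex whose coordinates are multiples of step.

    With step = 1/k this is the standard stars-and-bars lattice with
    C(k + n - 1, n - 1) points.
    """
    step = Fraction(step).limit_denominator(10**6)
    k = Fraction(1) / step
    if k.denominator != 1:
        raise ValueError("step must divide 1 exactly")
    k = int(k)
    pts = []
    for cuts in itertools.combinations(range(k + n_components - 1), n_components - 1):
        prev = -1
        counts = []
        for c in cuts:
            counts.append(c - prev - 1)
            prev = c
        counts.append(k + n_components - 2 - prev)
        pts.append(tuple(c / k for c in counts))
    return pts
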