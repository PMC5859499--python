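"""Grid search over mixture-design pairs with a Bland-Altman separation score.

A useful pair of reference mixtures spreads the target analytes across the
dynamic range (mean Cq axis) while building in fold-changes in both
directions that stay within a practical window (ΔCq axis).  The search
enumerates pairs of simplex points from a small grid of preparable ratios,
declares a pair feasible when every analyte's predicted |ΔCq| stays within a
bound and both ΔCq signs occur, and scores feasible pairs by the minimum
pairwise distance between analyte points in the (mean Cq, ΔCq) plane —
larger means the analytes are better separated and the design more
informative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from refmix.design_search_util import simplex_grid  # noqa: F401  (re-export)
from refmix.mixture import MixtureDesign, bland_altman, mean_profile, predict_pair_profiles

logger = logging.getLogger(__name__)


@dataclass
class DesignCandidate:
    """A candidate pair of mixture designs with its evaluation."""

    pair: tuple[MixtureDesign, MixtureDesign]
    points: pd.DataFrame | None = None
    score: float | None = None
    feasible: bool = False
    max_abs_dcq: float | None = None

    def __post_init__(self) -> None:
        d1, d2 = self.pair
        if d1.components != d2.components:
            raise ValueError("both designs must share the same component list")


def enumerate_designs(
    components: Sequence[str],
    fraction_grid: Iterable[Sequence[float]],
) -> list[tuple[MixtureDesign, MixtureDesign]]:
    """All unordered pairs of distinct simplex points from a fraction grid.

    Swapping the two designs of a pair only flips the sign of every ΔCq, so
    pairs are de-duplicated under that relabeling: each is emitted once, with
    the lexicographically smaller fraction vector as Mix1.
    """
    pts: list[tuple[float, ...]] = []
    seen = set()
    for fr in fraction_grid:
        arr = np.asarray(fr, dtype=float)
        if len(arr) != len(components):
            raise ValueError("grid point length must match component count")
        s = arr.sum()
        if s <= 0:
            raise ValueError("grid point must have positive sum")
        tup = tuple(np.round(arr / s, 12))
        if tup not in seen:
            seen.add(tup)
            pts.append(tup)
    pts.sort()
    pairs = []
    for f1, f2 in itertools.combinations(pts, 2):
        d1 = MixtureDesign("Mix1", tuple(components), f1)
        d2 = MixtureDesign("Mix2", tuple(components), f2)
        pairs.append((d1, d2))
    return pairs


def ratio_grid(n_components: int, values: Sequence[float] = (1, 3)) -> list[tuple[float, ...]]:
    """All mixing-ratio vectors with entries drawn from simple values."""
    return [
        tuple(p) for p in itertools.product(values, repeat=n_components)
    ]


def score_design_pair(
    candidate: DesignCandidate,
    profiles: pd.DataFrame,
    max_abs_dcq: float = 1.0,
    min_analyte_separation: float = 0.0,
    target_analytes: Sequence[str] | None = None,
    axis_scale: tuple[float, float] = (1.0, 1.0),
) -> DesignCandidate:
    """Evaluate a design pair against collapsed pure-component profiles.

    Feasibility requires every target analyte's mean predicted |ΔCq| to be at
    most ``max_abs_dcq`` and both ΔCq signs to occur among the targets.  The
    score of a feasible pair is the minimum pairwise Euclidean distance
    between analyte points in the (mean Cq, ΔCq) plane after dividing each
    axis by its scale constant (default 1 Cq on both axes).
    """
    d1, d2 = candidate.pair
    preds = predict_pair_profiles(profiles, [d1, d2], on_incomplete="error")
    prof1 = mean_profile(preds, d1.name)
    prof2 = mean_profile(preds, d2.name)
    if target_analytes is not None:
        targets = {a.upper() for a in target_analytes}
        prof1 = {a: v for a, v in prof1.items() if a in targets}
        prof2 = {a: v for a, v in prof2.items() if a in targets}
    points = bland_altman(prof1, prof2)
    candidate.points = points
    candidate.max_abs_dcq = float(points["delta_cq"].abs().max())

    within = bool((points["delta_cq"].abs() <= max_abs_dcq).all())
    signs = set(np.sign(points["delta_cq"]).astype(int)) - {0}
    candidate.feasible = within and signs == {-1, 1}

    if candidate.feasible:
        xy = points[["mean_cq", "delta_cq"]].to_numpy() / np.asarray(axis_scale)
        if len(xy) < 2:
            candidate.score = 0.0
        else:
            dists = [
                float(np.hypot(*(xy[i] - xy[j])))
                for i, j in itertools.combinations(range(len(xy)), 2)
            ]
            candidate.score = min(dists)
        if candidate.score < min_analyte_separation:
            candidate.feasible = False
            candidate.score = None
    else:
        candidate.score = None
    return candidate


def rank_designs(candidates: Iterable[DesignCandidate]) -> list[DesignCandidate]:
    """Feasible candidates by descending score; deterministic tie-breaks.

    Ties break toward the smaller maximum |ΔCq|, then lexicographic
    fractions, so the ranking is reproducible run to run.
    """
    feasible = [c for c in candidates if c.feasible]
    if not feasible:
        logger.warning("rank_designs: no feasible candidates")
        return []
    return sorted(
        feasible,
        key=lambda c: (
            -c.score,
            c.max_abs_dcq,
            c.pair[0].fractions,
            c.pair[1].fractions,
        ),
    )


def candidates_to_frame(candidates: Sequence[DesignCandidate]) -> pd.DataFrame:
    """Flatten ranked candidates into a table for CSV export."""
    rows = []
    for rank, c in enumerate(candidates, start=1):
        rows.append(
            {
                "rank": rank,
                "mix1_fractions": ":".join(f"{f:g}" for f in c.pair[0].fractions),
                "mix2_fractions": ":".join(f"{f:g}" for f in c.pair[1].fractions),
                "score": c.score,
                "max_abs_dcq": c.max_abs_dcq,
                "feasible": c.feasible,
            }
        )
    return pd.DataFrame(rows)
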