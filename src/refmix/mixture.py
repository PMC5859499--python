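"""In-silico prediction of mixture Cq values from component profiles.

Because one PCR cycle corresponds to a two-fold change in template, a Cq
value Y maps to a relative linear abundance of 2**(-Y).  Under the assumption
that abundance is additive and linear in the mixed components, a mixture with
component fractions phi has predicted Cq

    M = -log2( sum_c  2**(-Y_c) * phi_c )

evaluated per analyte within each measurement process (isolation lab x PCR
lab) and isolation replicate.  Mixture pairs are summarised as Bland-Altman
points (mean Cq vs. difference Mix1 - Mix2), the geometry used to judge a
design's spread of built-in abundance ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from refmix.data_model import CANONICAL_COLUMNS, IN_SILICO_MIXTURE, KEY_COLUMNS

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)

#: Cq at or above which a component is flagged as being at the detection
#: limit (single-molecule territory); its numeric contribution is kept.
DEFAULT_DETECTION_CEILING = 35.0


@dataclass(frozen=True)
class MixtureDesign:
    """A point on the component simplex: which components, in what fractions."""

    name: str
    components: tuple[str, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.fractions):
            raise ValueError("components and fractions must have equal length")
        object.__setattr__(self, "fractions", tuple(float(f) for f in self.fractions))
        fr = np.asarray(self.fractions, dtype=float)
        if (fr < 0).any():
            raise ValueError("fractions must be non-negative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {fr.sum()!r})")

    @classmethod
    def from_ratio(
        cls, name: str, components: Sequence[str], ratio: Sequence[float]
    ) -> "MixtureDesign":
        """Build a design from an integer mixing ratio such as 1:3:1."""
        total = Fraction(0)
        parts = [Fraction(r).limit_denominator(10**6) for r in ratio]
        total = sum(parts)
        if total == 0:
            raise ValueError("ratio must have a positive sum")
        fracs = tuple(float(p / total) for p in parts)
        return cls(name=name, components=tuple(components), fractions=fracs)

    def as_map(self) -> dict[str, float]:
        return dict(zip(self.components, self.fractions))


def predict_mixture_cq(
    component_cqs: Mapping[str, float], design: MixtureDesign
) -> float:
    """Predicted Cq of a designed mixture from its components' Cq values.

    Evaluated on the log scale (shifted log-sum-exp) so that faint
    components near the detection ceiling cannot underflow.  Components with
    zero fraction may be absent from ``component_cqs``.
    """
    ys, ws = [], []
    for comp, frac in zip(design.components, design.fractions):
        if frac == 0.0:
            continue
        if comp not in component_cqs:
            raise KeyError(f"no Cq provided for design component {comp!r}")
        ys.append(float(component_cqs[comp]))
        ws.append(float(frac))
    if not ys:
        raise ValueError("design has no component with positive fraction")
    ys_arr = np.asarray(ys)
    ws_arr = np.asarray(ws)
    # -log2 sum w*2^-y  ==  -logsumexp(-y*ln2, b=w)/ln2
    return float(-logsumexp(-ys_arr * LN2, b=ws_arr) / LN2)


@dataclass(frozen=True)
class PredictedMixtureProfile:
    """Per-analyte predicted mixture Cq under one measurement process."""

    design: MixtureDesign
    isolation_lab: str
    pcr_lab: str
    isolation_rep: int
    per_analyte_cq: Mapping[str, float]


def predict_pair_profiles(
    profiles: pd.DataFrame,
    designs: Sequence[MixtureDesign],
    detection_ceiling: float = DEFAULT_DETECTION_CEILING,
    on_incomplete: str = "warn",
) -> pd.DataFrame:
    """Predict mixture Cq for every design in every profiling stratum.

    ``profiles`` is collapsed pure-cell-line data in the canonical schema; a
    stratum is one (analyte, isolation_lab, isolation_rep, pcr_lab)
    combination and must contain a Cq for every design component.  Output is
    a canonical-schema frame with ``source`` set to the in-silico mixture
    label and ``sample`` set to the design name, plus an ``at_ceiling`` flag
    marking predictions that used a component at/above the detection ceiling.
    """
    if on_incomplete not in ("warn", "error"):
        raise ValueError("on_incomplete must be 'warn' or 'error'")
    strata = ["analyte", "isolation_lab", "isolation_rep", "pcr_lab"]
    needed = set()
    for d in designs:
        needed |= {c for c, f in zip(d.components, d.fractions) if f > 0}

    rows = []
    for key, grp in profiles.groupby(strata, sort=False):
        comp_cq = dict(zip(grp["sample"], grp["cq"]))
        missing = needed - set(comp_cq)
        if missing:
            msg = f"stratum {key}: missing components {sorted(missing)}"
            if on_incomplete == "error":
                raise ValueError(msg)
            logger.warning("skipping %s", msg)
            continue
        analyte, iso_lab, iso_rep, pcr_lab = key
        flagged = any(
            comp_cq[c] >= detection_ceiling for c in needed
        )
        for d in designs:
            rows.append(
                {
                    "analyte": analyte,
                    "source": IN_SILICO_MIXTURE,
                    "sample": d.name.upper(),
                    "isolation_lab": iso_lab,
                    "isolation_rep": iso_rep,
                    "pcr_lab": pcr_lab,
                    "plate": "insilico",
                    "well": "",
                    "cq": predict_mixture_cq(comp_cq, d),
                    "is_well_average": True,
                    "at_ceiling": flagged,
                }
            )
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS + ["at_ceiling"])


def bland_altman(
    mix1: Mapping[str, float], mix2: Mapping[str, float]
) -> pd.DataFrame:
    """Per-analyte (mean Cq, ΔCq = Mix1 − Mix2) difference-plot points.

    A negative ΔCq means the analyte is more abundant in Mix1 (lower Cq =
    more starting material).  Analytes present in only one map are excluded
    with a warning.
    """
    shared = [a for a in mix1 if a in mix2]
    dropped = (set(mix1) | set(mix2)) - set(shared)
    if dropped:
        logger.warning("bland_altman: analytes in only one profile: %s",
                       sorted(dropped))
    rows = [
        {
            "analyte": a,
            "mean_cq": 0.5 * (mix1[a] + mix2[a]),
            "delta_cq": mix1[a] - mix2[a],
        }
        for a in shared
    ]
    return pd.DataFrame(rows, columns=["analyte", "mean_cq", "delta_cq"])


def mean_profile(predictions: pd.DataFrame, sample: str) -> dict[str, float]:
    """Average a design's predicted per-analyte Cq over all strata."""
    sub = predictions[predictions["sample"] == sample.upper()]
    return sub.groupby("analyte")["cq"].mean().to_dict()
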