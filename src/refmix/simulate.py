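"""Synthetic Cq data with the structure of the two-phase crossover study.

The generator emulates the seven measurement scenarios: a profiling phase in
which three lung-cancer cell lines (H226, H358, H460) are each isolated at
two laboratories (3 replicate isolations per lab) and measured by RT-qPCR at
both labs, and a mixture phase in which a pair of designed mixtures (Mix1 =
1:3:1, Mix2 = 3:1:1 of H226:H358:H460) is prepared from four isolations and
measured in triplicate plates — at both PCR labs for RNA mixtures, at the
reference lab only for cell mixtures.

A well-level Cq is built additively:

    cq = cell-line mean
       + isolation-lab shift (analyte-specific)
       + PCR-lab shift (analyte x cell-line specific)
       + N(0, sigma_iso)   shared by one isolation occasion
       + N(0, sigma_plate) shared by one plate
       + N(0, sigma_well)  per well

Mixture true values are derived from the (shifted) component means through
the additive-abundance model, so the designed ΔCq per analyte is known
exactly and returned in a truth record.  Default cell-line means are chosen
so the qualitative geometry of real profiles holds: H358 most abundant for
miR-21 and miR-210, H226 for miR-126, H460 for miR-375, miR-375/486 near the
detection ceiling in H226, mixture abundance order
miR-486 < miR-375 < miR-126 < miR-210 < miR-21, and designed ΔCq within
±1 cycle with both signs represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from refmix.data_model import (
    CANONICAL_COLUMNS,
    CELL_MIXTURE,
    PURE_CELL_LINE,
    RNA_MIXTURE,
)
from refmix.mixture import MixtureDesign, predict_mixture_cq

CELL_LINES = ("H226", "H358", "H460")
ANALYTES = ("MIR-16", "MIR-21", "MIR-126", "MIR-210", "MIR-375", "MIR-486")
TARGET_ANALYTES = ("MIR-21", "MIR-126", "MIR-210", "MIR-375", "MIR-486")
CONTROL_ANALYTE = "MIR-16"

#: per-analyte true mean Cq in each cell line (H226, H358, H460)
DEFAULT_CELL_MEANS: dict[tuple[str, str], float] = {}
for _a, _vals in {
    "MIR-16": (22.0, 21.8, 22.1),
    "MIR-21": (25.5, 23.0, 25.0),
    "MIR-126": (27.0, 28.8, 29.3),
    "MIR-210": (28.7, 26.2, 28.0),
    "MIR-375": (35.0, 30.5, 29.0),
    "MIR-486": (35.0, 31.6, 31.7),
}.items():
    for _c, _v in zip(CELL_LINES, _vals):
        DEFAULT_CELL_MEANS[(_a, _c)] = _v

#: Cq added when the isolation lab is BRL (miR-21 looks more abundant there)
DEFAULT_ISOLATION_LAB_SHIFT = {"MIR-21": -0.4}

#: Cq added when the PCR lab is BRL; analyte x cell-line specific, producing
#: the analyte:cell-line:PCR-lab interaction seen for miR-126 and miR-486
DEFAULT_PCR_LAB_SHIFT = {
    ("MIR-126", "H226"): 0.5,
    ("MIR-126", "H358"): -0.1,
    ("MIR-126", "H460"): 0.1,
    ("MIR-486", "H358"): -0.15,
    ("MIR-486", "H460"): 0.15,
}


def default_designs() -> tuple[MixtureDesign, MixtureDesign]:
    return (
        MixtureDesign.from_ratio("Mix1", CELL_LINES, (1, 3, 1)),
        MixtureDesign.from_ratio("Mix2", CELL_LINES, (3, 1, 1)),
    )


@dataclass
class SimulationConfig:
    """True means, effect sizes and design counts for the generator."""

    cell_means: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_MEANS)
    )
    isolation_lab_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOLATION_LAB_SHIFT)
    )
    pcr_lab_shift: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PCR_LAB_SHIFT)
    )
    sigma_iso: float = 0.15
    sigma_plate: float = 0.10
    sigma_well: float = 0.10
    n_isolation_reps: int = 3      # profiling phase
    n_mixture_isolations: int = 4  # mixture phases
    n_plates: int = 3              # replicate plates per mixture measurement
    n_wells: int = 3
    designs: tuple[MixtureDesign, MixtureDesign] = field(default_factory=default_designs)
    detection_ceiling: float = 35.0
    expansion_drift_sd: float = 0.0  # per-isolation abundance drift in mixtures
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_iso", "sigma_plate", "sigma_well", "expansion_drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_isolation_reps", "n_mixture_isolations", "n_plates", "n_wells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for key, v in self.cell_means.items():
            if not (0.0 < v < 40.0):
                raise ValueError(f"cell mean {key} = {v} outside (0, 40)")

    @property
    def analytes(self) -> list[str]:
        return sorted({a for a, _ in self.cell_means})

    @property
    def cell_lines(self) -> list[str]:
        return sorted({c for _, c in self.cell_means})

    def true_component_cq(
        self, analyte: str, isolation_lab: str, pcr_lab: str
    ) -> dict[str, float]:
        """Noise-free component Cq under one measurement process."""
        iso = self.isolation_lab_shift.get(analyte, 0.0) if isolation_lab == "BRL" else 0.0
        out = {}
        for c in self.cell_lines:
            pcr = self.pcr_lab_shift.get((analyte, c), 0.0) if pcr_lab == "BRL" else 0.0
            out[c] = self.cell_means[(analyte, c)] + iso + pcr
        return out

    def true_mixture_cq(
        self, analyte: str, isolation_lab: str, pcr_lab: str
    ) -> dict[str, float]:
        """Noise-free Cq of each designed mixture under one process."""
        comp = self.true_component_cq(analyte, isolation_lab, pcr_lab)
        return {
            d.name.upper(): predict_mixture_cq(comp, d) for d in self.designs
        }

    def true_dcq(self, analyte: str, isolation_lab: str, pcr_lab: str) -> float:
        m = self.true_mixture_cq(analyte, isolation_lab, pcr_lab)
        d1, d2 = (d.name.upper() for d in self.designs)
        return m[d1] - m[d2]

    def truth_record(self) -> dict:
        """Machine-readable designed truth for test harnesses."""
        return {
            "cell_means": {f"{a}|{c}": v for (a, c), v in self.cell_means.items()},
            "isolation_lab_shift": dict(self.isolation_lab_shift),
            "pcr_lab_shift": {f"{a}|{c}": v for (a, c), v in self.pcr_lab_shift.items()},
            "sigma": {
                "iso": self.sigma_iso,
                "plate": self.sigma_plate,
                "well": self.sigma_well,
            },
            "true_dcq": {
                f"{a}|{iso}|{pcr}": self.true_dcq(a, iso, pcr)
                for a in self.analytes
                for iso in ("BDL", "BRL")
                for pcr in ("BDL", "BRL")
            },
        }


def _finish(rows: list[dict], ceiling: float) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS + ["at_ceiling"])
    df["at_ceiling"] = df["cq"] >= ceiling
    df["cq"] = df["cq"].clip(upper=ceiling)  # truncated and flagged, not dropped
    return df


def simulate_profiling_phase(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Well-level Cq data for the pure-cell-line crossover (scenarios 1-4)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for iso_lab in ("BDL", "BRL"):
        for rep in range(1, config.n_isolation_reps + 1):
            iso_dev = rng.normal(0.0, config.sigma_iso)
            for pcr_lab in ("BDL", "BRL"):
                plate = f"PROF-{iso_lab}{rep}-{pcr_lab}"
                plate_dev = rng.normal(0.0, config.sigma_plate)
                for analyte in config.analytes:
                    comp = config.true_component_cq(analyte, iso_lab, pcr_lab)
                    for cell, mean in comp.items():
                        wells = mean + iso_dev + plate_dev + rng.normal(
                            0.0, config.sigma_well, config.n_wells
                        )
                        for w, cq in enumerate(wells, start=1):
                            rows.append(
                                {
                                    "analyte": analyte,
                                    "source": PURE_CELL_LINE,
                                    "sample": cell,
                                    "isolation_lab": iso_lab,
                                    "isolation_rep": rep,
                                    "pcr_lab": pcr_lab,
                                    "plate": plate,
                                    "well": f"W{w}",
                                    "cq": float(cq),
                                    "is_well_average": False,
                                }
                            )
    return _finish(rows, config.detection_ceiling)


def simulate_mixture_phase(
    config: SimulationConfig, phase: str = "rna_mixture", seed: int | None = None
) -> pd.DataFrame:
    """Well-level Cq data for the mixture phase.

    ``phase='rna_mixture'`` produces scenarios 5-6 (isolated at BRL, measured
    at both PCR labs); ``phase='cell_mixture'`` produces scenario 7 (BRL
    only).  An optional per-isolation expansion drift perturbs each
    component's true abundance before mixing, emulating batch-to-batch
    culture differences.
    """
    if phase not in ("rna_mixture", "cell_mixture"):
        raise ValueError("phase must be 'rna_mixture' or 'cell_mixture'")
    source = RNA_MIXTURE if phase == "rna_mixture" else CELL_MIXTURE
    pcr_labs = ("BDL", "BRL") if phase == "rna_mixture" else ("BRL",)
    iso_lab = "BRL"
    rng = np.random.default_rng(config.seed if seed is None else seed)

    rows = []
    for rep in range(1, config.n_mixture_isolations + 1):
        iso_dev = rng.normal(0.0, config.sigma_iso)
        drift = {
            (a, c): rng.normal(0.0, config.expansion_drift_sd)
            for a in config.analytes
            for c in config.cell_lines
        } if config.expansion_drift_sd > 0 else {}
        for pcr_lab in pcr_labs:
            for plate_no in range(1, config.n_plates + 1):
                plate = f"{phase.upper()}-{rep}-{pcr_lab}-P{plate_no}"
                plate_dev = rng.normal(0.0, config.sigma_plate)
                for analyte in config.analytes:
                    comp = config.true_component_cq(analyte, iso_lab, pcr_lab)
                    if drift:
                        comp = {c: v + drift[(analyte, c)] for c, v in comp.items()}
                    for design in config.designs:
                        true_cq = predict_mixture_cq(comp, design)
                        wells = true_cq + iso_dev + plate_dev + rng.normal(
                            0.0, config.sigma_well, config.n_wells
                        )
                        for w, cq in enumerate(wells, start=1):
                            rows.append(
                                {
                                    "analyte": analyte,
                                    "source": source,
                                    "sample": design.name.upper(),
                                    "isolation_lab": iso_lab,
                                    "isolation_rep": rep,
                                    "pcr_lab": pcr_lab,
                                    "plate": plate,
                                    "well": f"W{w}",
                                    "cq": float(cq),
                                    "is_well_average": False,
                                }
                            )
    return _finish(rows, config.detection_ceiling)


def simulate_paired_mixtures(
    mix_means: Mapping[str, tuple[float, float]],
    source: str = RNA_MIXTURE,
    isolation_lab: str = "BRL",
    pcr_labs: Sequence[str] = ("BDL", "BRL"),
    n_isolations: int = 4,
    n_plates: int = 3,
    n_wells: int = 3,
    sigma_iso: float = 0.15,
    sigma_plate: float = 0.10,
    sigma_well: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mixture-pair data with directly specified true (Mix1, Mix2) Cq means.

    Useful for calibration studies where the designed ΔCq per analyte must
    be an exact, known quantity rather than derived from component profiles.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_isolations + 1):
        iso_dev = rng.normal(0.0, sigma_iso)
        for pcr_lab in pcr_labs:
            for plate_no in range(1, n_plates + 1):
                plate = f"PAIR-{rep}-{pcr_lab}-P{plate_no}"
                plate_dev = rng.normal(0.0, sigma_plate)
                for analyte, (m1, m2) in mix_means.items():
                    for sample, mean in (("MIX1", m1), ("MIX2", m2)):
                        wells = mean + iso_dev + plate_dev + rng.normal(
                            0.0, sigma_well, n_wells
                        )
                        for w, cq in enumerate(wells, start=1):
                            rows.append(
                                {
                                    "analyte": analyte.upper(),
                                    "source": source,
                                    "sample": sample,
                                    "isolation_lab": isolation_lab,
                                    "isolation_rep": rep,
                                    "pcr_lab": pcr_lab,
                                    "plate": plate,
                                    "well": f"W{w}",
                                    "cq": float(cq),
                                    "is_well_average": False,
                                }
                            )
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    df["at_ceiling"] = False
    return df
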