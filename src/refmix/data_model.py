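"""Domain types, CSV I/O and validation for Cq datasets.

A Cq observation is one quantification-cycle measurement with its full
experimental provenance: which analyte (miRNA assay), what kind of source
material (pure cell line, mixture of extracted RNA, or mixture of intact
cells), which sample (cell line or mixture label), which laboratory isolated
the RNA and on which replicate occasion, which laboratory ran the PCR, and on
which plate/well.  Collections of observations are carried as pandas
DataFrames in a canonical long-format schema; :class:`CqObservation` is the
validated record type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: canonical long-format column order
CANONICAL_COLUMNS = [
    "analyte",
    "source",
    "sample",
    "isolation_lab",
    "isolation_rep",
    "pcr_lab",
    "plate",
    "well",
    "cq",
    "is_well_average",
]

KEY_COLUMNS = [
    "analyte",
    "source",
    "sample",
    "isolation_lab",
    "isolation_rep",
    "pcr_lab",
    "plate",
]

PURE_CELL_LINE = "PURE_CELL_LINE"
RNA_MIXTURE = "RNA_MIXTURE"
CELL_MIXTURE = "CELL_MIXTURE"
IN_SILICO_MIXTURE = "IN_SILICO_MIXTURE"

SOURCES = (PURE_CELL_LINE, RNA_MIXTURE, CELL_MIXTURE, IN_SILICO_MIXTURE)
LABS = ("BDL", "BRL")

DEFAULT_CQ_MAX = 40.0


class SchemaError(ValueError):
    """A required column is missing or the dialect mapping is invalid."""


class ValidationError(ValueError):
    """Row-level content failed validation; message lists offending rows."""


@dataclass(frozen=True)
class CqObservation:
    """One Cq measurement (well level, or a within-plate well average)."""

    analyte: str
    source: str
    sample: str
    isolation_lab: str
    isolation_rep: int
    pcr_lab: str
    plate: str
    cq: float
    well: str = ""
    is_well_average: bool = False

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        for lab_field in ("isolation_lab", "pcr_lab"):
            lab = getattr(self, lab_field)
            if lab not in LABS:
                raise ValidationError(f"unknown {lab_field} {lab!r}")
        if self.isolation_rep < 1:
            raise ValidationError("isolation_rep must be a positive integer")
        if not (0.0 < self.cq <= DEFAULT_CQ_MAX):
            raise ValidationError(
                f"cq={self.cq} outside plausible range (0, {DEFAULT_CQ_MAX}]"
            )


@dataclass(frozen=True)
class ScenarioKey:
    """A measurement scenario: source material x isolation lab x PCR lab.

    Scenarios 1-4 form the pure-cell-line crossover (each lab's isolates
    measured at each lab); 5-6 are RNA mixtures isolated at the reference
    lab and measured at either PCR lab; 7 is the cell-mixture pathway run
    entirely at the reference lab.  The numbering is a convention and can be
    overridden via ``scenario_table``.
    """

    source: str
    isolation_lab: str
    pcr_lab: str
    scenario_id: int = field(default=0)

    #: default (source, isolation_lab, pcr_lab) -> scenario id
    DEFAULT_TABLE = {
        (PURE_CELL_LINE, "BDL", "BDL"): 1,
        (PURE_CELL_LINE, "BDL", "BRL"): 2,
        (PURE_CELL_LINE, "BRL", "BDL"): 3,
        (PURE_CELL_LINE, "BRL", "BRL"): 4,
        (RNA_MIXTURE, "BRL", "BDL"): 5,
        (RNA_MIXTURE, "BRL", "BRL"): 6,
        (CELL_MIXTURE, "BRL", "BRL"): 7,
    }

    @classmethod
    def from_fields(
        cls,
        source: str,
        isolation_lab: str,
        pcr_lab: str,
        scenario_table: Mapping[tuple, int] | None = None,
    ) -> "ScenarioKey":
        table = cls.DEFAULT_TABLE if scenario_table is None else scenario_table
        key = (source.upper(), isolation_lab.upper(), pcr_lab.upper())
        if key not in table:
            raise KeyError(f"no scenario defined for {key}")
        return cls(*key, scenario_id=table[key])


def observations_to_frame(observations: Iterable[CqObservation]) -> pd.DataFrame:
    """Convert validated records to the canonical DataFrame."""
    rows = [
        {c: getattr(obs, c) for c in CANONICAL_COLUMNS} for obs in observations
    ]
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def frame_to_observations(df: pd.DataFrame) -> list[CqObservation]:
    """Convert a canonical DataFrame to validated records."""
    return [
        CqObservation(
            analyte=str(r.analyte),
            source=str(r.source),
            sample=str(r.sample),
            isolation_lab=str(r.isolation_lab),
            isolation_rep=int(r.isolation_rep),
            pcr_lab=str(r.pcr_lab),
            plate=str(r.plate),
            well=str(r.well),
            cq=float(r.cq),
            is_well_average=bool(r.is_well_average),
        )
        for r in df.itertuples(index=False)
    ]


def _normalize_labels(df: pd.DataFrame) -> pd.DataFrame:
    # labels are case-insensitive, stored upper-case
    for col in ("analyte", "source", "sample", "isolation_lab", "pcr_lab"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    df["plate"] = df["plate"].astype(str).str.strip()
    df["well"] = df["well"].astype(str).str.strip()
    return df


def validate_frame(
    df: pd.DataFrame,
    cq_max: float = DEFAULT_CQ_MAX,
    missing_policy: str = "drop",
) -> pd.DataFrame:
    """Validate a canonical-schema DataFrame.

    Parameters
    ----------
    cq_max:
        Upper bound of the plausible Cq range (exclusive lower bound is 0).
    missing_policy:
        What to do with rows whose Cq is missing/non-numeric ("NA",
        "Undetermined", blank): ``drop`` removes them with a logged warning,
        ``ceiling`` imputes ``cq_max``, ``error`` raises.
    """
    missing_cols = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing canonical columns: {missing_cols}")
    df = df.copy()
    df = _normalize_labels(df)

    cq = pd.to_numeric(df["cq"], errors="coerce")
    missing = cq.isna()
    if missing.any():
        rows = [int(i) + 2 for i in df.index[missing]]  # 1-based incl. header
        if missing_policy == "error":
            raise ValidationError(f"non-numeric/missing Cq at file lines {rows}")
        if missing_policy == "ceiling":
            logger.warning(
                "imputed %d missing Cq values at ceiling %.1f (lines %s)",
                missing.sum(), cq_max, rows,
            )
            cq = cq.fillna(cq_max)
        elif missing_policy == "drop":
            logger.warning(
                "dropped %d rows with missing Cq (lines %s)", missing.sum(), rows
            )
            df = df.loc[~missing].reset_index(drop=True)
            cq = cq.loc[~missing].reset_index(drop=True)
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df["cq"] = cq.astype(float)

    out_of_range = ~((df["cq"] > 0) & (df["cq"] <= cq_max))
    if out_of_range.any():
        rows = [int(i) + 2 for i in df.index[out_of_range]]
        raise ValidationError(
            f"Cq outside (0, {cq_max}] at file lines {rows}: "
            f"{df.loc[out_of_range, 'cq'].tolist()}"
        )

    bad_source = ~df["source"].isin(SOURCES)
    if bad_source.any():
        raise ValidationError(
            f"unknown source values: {sorted(df.loc[bad_source, 'source'].unique())}"
        )
    for col in ("isolation_lab", "pcr_lab"):
        bad = ~df[col].isin(LABS)
        if bad.any():
            raise ValidationError(
                f"unknown {col} values: {sorted(df.loc[bad, col].unique())}"
            )
    df["isolation_rep"] = df["isolation_rep"].astype(int)
    if (df["isolation_rep"] < 1).any():
        raise ValidationError("isolation_rep must be >= 1")
    df["is_well_average"] = df["is_well_average"].astype(bool)

    dup_cols = KEY_COLUMNS + ["well"]
    dups = df.duplicated(subset=dup_cols, keep=False)
    if dups.any():
        raise ValidationError(
            "duplicate (analyte, source, sample, labs, rep, plate, well) keys:\n"
            + df.loc[dups, dup_cols].to_string()
        )
    return df[CANONICAL_COLUMNS]


def _load_dialect(dialect: str | Path | Mapping[str, str] | None) -> dict[str, str]:
    if dialect is None:
        return {}
    if isinstance(dialect, Mapping):
        return dict(dialect)
    with open(dialect) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise SchemaError("dialect config must be a flat mapping of column names")
    return {str(k): str(v) for k, v in loaded.items()}


def read_cq_table(
    path: str | Path,
    dialect: str | Path | Mapping[str, str] | None = None,
    missing_policy: str = "drop",
    cq_max: float = DEFAULT_CQ_MAX,
) -> pd.DataFrame:
    """Read a long-format Cq CSV into the canonical validated DataFrame.

    ``dialect`` maps canonical column names to the file's own headers, e.g.
    ``{"analyte": "miRNA", "cq": "Ct"}``; unmapped canonical names are taken
    verbatim.  Missing optional columns ``well`` and ``is_well_average``
    default to empty / False.
    """
    mapping = _load_dialect(dialect)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]

    df = pd.DataFrame(index=raw.index)
    for canonical in CANONICAL_COLUMNS:
        header = mapping.get(canonical, canonical)
        if header in raw.columns:
            df[canonical] = raw[header]
        elif canonical == "well":
            df[canonical] = ""
        elif canonical == "is_well_average":
            df[canonical] = False
        else:
            raise SchemaError(
                f"column {header!r} (for canonical {canonical!r}) not in {path}"
            )
    if df["is_well_average"].dtype == object:
        df["is_well_average"] = (
            df["is_well_average"].astype(str).str.lower().isin(["true", "1", "yes"])
        )
    df["cq"] = df["cq"].replace({"": None, "NA": None, "Undetermined": None})
    return validate_frame(df, cq_max=cq_max, missing_policy=missing_policy)


def write_cq_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical-schema DataFrame as UTF-8, RFC-4180 quoted CSV."""
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write: missing columns {missing}")
    df[CANONICAL_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def collapse_wells(df: pd.DataFrame) -> pd.DataFrame:
    """Average replicate wells within a plate into one Cq value per stratum.

    The Cq value used throughout downstream analysis is the within-plate mean
    over replicate wells for a given analyte and sample.
    """
    if df["is_well_average"].any():
        raise ValidationError(
            "collapse_wells expects well-level data (is_well_average False)"
        )
    grouped = (
        df.groupby(KEY_COLUMNS, sort=False, as_index=False)["cq"].mean()
    )
    grouped["well"] = ""
    grouped["is_well_average"] = True
    logger.info("collapsed %d wells into %d plate averages", len(df), len(grouped))
    return grouped[CANONICAL_COLUMNS]


def attach_scenarios(
    df: pd.DataFrame,
    scenario_table: Mapping[tuple, int] | None = None,
) -> pd.DataFrame:
    """Add a ``scenario`` column (integer pathway id) to a canonical frame."""
    table = ScenarioKey.DEFAULT_TABLE if scenario_table is None else scenario_table
    out = df.copy()
    keys = list(zip(out["source"], out["isolation_lab"], out["pcr_lab"]))
    out["scenario"] = [table.get(k, 0) for k in keys]
    return out
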