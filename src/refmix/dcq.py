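"""ΔCq and ΔΔCq difference statistics between a mixture pair.

ΔCq = Cq(Mix1) − Cq(Mix2) for the same analyte measured under the same
conditions; by the two-fold-per-cycle convention a ΔCq of −1 means the
analyte is two-fold more abundant in Mix1.  The ΔΔCq variant first
normalises each Cq to a control analyte (miR-16 here) measured on the same
plate and sample, cancelling any per-plate or per-sample loading shift, and
then differences the normalised values between mixtures.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAIR_KEYS_PLATE = ["analyte", "source", "isolation_lab", "isolation_rep", "pcr_lab", "plate"]
PAIR_KEYS_ISOLATION = ["analyte", "source", "isolation_lab", "isolation_rep", "pcr_lab"]


def _pivot_pair(
    df: pd.DataFrame, mix1: str, mix2: str, keys: Sequence[str]
) -> pd.DataFrame:
    sub = df[df["sample"].isin([mix1, mix2])]
    wide = (
        sub.groupby(list(keys) + ["sample"], sort=False)["cq"]
        .mean()
        .unstack("sample")
    )
    unpaired = wide[wide[[mix1, mix2]].isna().any(axis=1)] if {mix1, mix2} <= set(wide.columns) else wide
    if {mix1, mix2} - set(wide.columns):
        raise ValueError(f"no observations for {sorted({mix1, mix2} - set(wide.columns))}")
    if len(unpaired):
        logger.warning("delta_cq: %d unpaired units dropped", len(unpaired))
        wide = wide.dropna(subset=[mix1, mix2])
    if wide.empty:
        raise ValueError("no pairable Mix1/Mix2 units")
    return wide


def delta_cq(
    observations: pd.DataFrame,
    mix1: str = "MIX1",
    mix2: str = "MIX2",
    pairing: str = "plate",
) -> pd.DataFrame:
    """Per-replicate ΔCq = Cq(Mix1) − Cq(Mix2).

    ``pairing='plate'`` pairs the two mixtures within the same physical
    plate (the default when mixture pairs are co-plated);
    ``pairing='isolation'`` first averages plates within each
    (isolation replicate, PCR lab) unit and pairs those averages.
    """
    mix1, mix2 = mix1.upper(), mix2.upper()
    if pairing == "plate":
        keys = PAIR_KEYS_PLATE
    elif pairing == "isolation":
        keys = PAIR_KEYS_ISOLATION
    else:
        raise ValueError("pairing must be 'plate' or 'isolation'")
    wide = _pivot_pair(observations, mix1, mix2, keys)
    out = wide.reset_index()
    out["dcq"] = out[mix1] - out[mix2]
    return out.drop(columns=[mix1, mix2])


def delta_delta_cq(
    observations: pd.DataFrame,
    control_analyte: str = "MIR-16",
    mix1: str = "MIX1",
    mix2: str = "MIX2",
    pairing: str = "plate",
) -> pd.DataFrame:
    """Per-replicate ΔΔCq using a same-plate control analyte.

    ΔΔCq = [Cq_t(Mix1) − Cq_ctl(Mix1)] − [Cq_t(Mix2) − Cq_ctl(Mix2)], with
    the control taken from the same sample and plate as the target.  Units
    without a control measurement are excluded with a warning.
    """
    ctl = control_analyte.upper()
    sub = observations.copy()
    unit_keys = [k for k in PAIR_KEYS_PLATE if k != "analyte"] + ["sample"]
    ctl_cq = (
        sub[sub["analyte"] == ctl]
        .groupby(unit_keys, sort=False)["cq"]
        .mean()
        .rename("ctl_cq")
    )
    if ctl_cq.empty:
        raise ValueError(f"control analyte {ctl!r} not present in data")
    targets = sub[sub["analyte"] != ctl].merge(
        ctl_cq.reset_index(), on=unit_keys, how="left"
    )
    missing = targets["ctl_cq"].isna()
    if missing.all():
        raise ValueError("control analyte missing on every unit")
    if missing.any():
        logger.warning(
            "delta_delta_cq: %d units lacked a control measurement", missing.sum()
        )
        targets = targets.loc[~missing]
    targets = targets.assign(cq=targets["cq"] - targets["ctl_cq"]).drop(columns="ctl_cq")
    out = delta_cq(targets, mix1=mix1, mix2=mix2, pairing=pairing)
    return out.rename(columns={"dcq": "ddcq"})


def summarize_dcq(values: pd.DataFrame, grouping: str = "overall") -> pd.DataFrame:
    """Mean ± sample SD of ΔCq (or ΔΔCq) per group.

    ``by_isolation`` averages the replicate plates within each isolation;
    ``by_plate`` averages the isolations within each plate position;
    ``overall`` pools everything within an (analyte, labs) stratum.  SD uses
    the n−1 denominator and is NaN for singleton groups.
    """
    value_col = "ddcq" if "ddcq" in values.columns else "dcq"
    base = ["analyte", "source", "isolation_lab", "pcr_lab"]
    if grouping == "by_isolation":
        keys = base + ["isolation_rep"]
    elif grouping == "by_plate":
        keys = base + ["plate"]
    elif grouping == "overall":
        keys = base
    else:
        raise ValueError("grouping must be by_isolation, by_plate or overall")
    keys = [k for k in keys if k in values.columns]
    if values.empty:
        raise ValueError("no values to summarize")
    agg = values.groupby(keys, sort=False)[value_col].agg(
        mean_dcq="mean", sd_dcq=lambda s: s.std(ddof=1), n="count"
    )
    out = agg.reset_index()
    out["grouping"] = grouping
    return out
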