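"""Auxiliary quantification: corrected total cell fluorescence and ddCt.

CTCF corrects a cell ROI's integrated fluorescence for local
background: ``CTCF = integrated_density - cell_area * mean(background)``.

The comparative-Ct (ddCt) method converts qPCR threshold cycles to a
fold expression relative to a calibrator group, normalizing each
sample's target Ct to a reference gene (HPRT here):
``dCt = Ct_target - Ct_ref``; ``ddCt = dCt - mean dCt(calibrator)``;
``RQ = 2^(-ddCt)`` (amplification efficiency fixed at 2).  Technical
replicates are averaged at the Ct level before dCt is formed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class FluorMeasurement:
    integrated_density: float
    cell_area: float
    background_means: Sequence[float]

    def __post_init__(self) -> None:
        if self.cell_area <= 0:
            raise ValueError("cell_area must be > 0")
        if len(self.background_means) == 0:
            raise ValueError("need at least one background reading")


def ctcf(m: FluorMeasurement) -> float:
    """Corrected total cell fluorescence of one ROI measurement."""
    return float(m.integrated_density - m.cell_area * np.mean(m.background_means))


def ctcf_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized CTCF over a measurement table.

    Expects columns ``integrated_density``, ``cell_area`` and one or
    more ``background*`` columns (averaged per row); returns the input
    with a ``ctcf`` column appended.
    """
    bg_cols = [c for c in df.columns if c.startswith("background")]
    if not bg_cols:
        raise ValueError("no background* columns found")
    out = df.copy()
    out["ctcf"] = df["integrated_density"] - df["cell_area"] * df[bg_cols].mean(axis=1)
    return out


def ddct_rq(
    wells: pd.DataFrame,
    calibrator_group: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative quantification per sample by the comparative-Ct method.

    ``wells`` needs columns ``sample``, ``group``, ``ct_target``,
    ``ct_reference``; replicate rows per sample are averaged at the Ct
    level first.  Returns one row per sample with dct, ddct and rq
    columns; the calibrator group's mean dCt is the reference point, so
    its RQ values have geometric mean 1.
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = wells[wells["ct_reference"].isna() | wells["ct_target"].isna()]
    if len(bad):
        raise ValueError(f"missing Ct values for samples: {sorted(bad['sample'].unique())}")
    per_sample = (
        wells.groupby(["sample", "group"], as_index=False)[["ct_target", "ct_reference"]].mean()
    )
    if calibrator_group not in set(per_sample["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    per_sample["dct"] = per_sample["ct_target"] - per_sample["ct_reference"]
    cal_mean = per_sample.loc[per_sample["group"] == calibrator_group, "dct"].mean()
    per_sample["ddct"] = per_sample["dct"] - cal_mean
    per_sample["rq"] = efficiency ** (-per_sample["ddct"])
    return per_sample
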