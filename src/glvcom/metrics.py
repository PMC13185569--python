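"""Prediction-quality metrics: RMSE and squared Pearson correlation.

Predicted and measured fraction tables are joined on (community, species);
each species in each community contributes one point, matching the
per-species scatter used to validate co-culture predictions. The Pearson
coefficient is computed with ``scipy.stats.linregress``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = ["MetricResult", "compute_rmse_r2"]


@dataclass
class MetricResult:
    rmse: float
    r2: float | None       # None when undefined (zero variance on one side)
    n: int
    r2_defined: bool


def compute_rmse_r2(predicted: pd.DataFrame, measured: pd.DataFrame
                    ) -> MetricResult:
    """RMSE and r^2 between predicted and measured fraction tables.

    Both tables need columns ``community``, ``species``, ``fraction``.
    Raises on an empty join; with fewer than 2 joined points or zero
    variance on either side, r^2 is returned as None with
    ``r2_defined=False``.
    """
    for name, df in (("predicted", predicted), ("measured", measured)):
        missing = {"community", "species", "fraction"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns: {sorted(missing)}")
    joined = predicted.merge(measured, on=["community", "species"],
                             suffixes=("_pred", "_meas"))
    if joined.empty:
        raise ValueError("no (community, species) pairs join between tables")
    p = joined["fraction_pred"].to_numpy(dtype=float)
    m = joined["fraction_meas"].to_numpy(dtype=float)
    rmse = float(np.sqrt(np.mean((p - m) ** 2)))
    if joined.shape[0] < 2 or np.ptp(p) == 0 or np.ptp(m) == 0:
        return MetricResult(rmse=rmse, r2=None, n=len(joined), r2_defined=False)
    r = linregress(m, p).rvalue
    return MetricResult(rmse=rmse, r2=float(r * r), n=len(joined),
                        r2_defined=True)
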