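"""Growth-parameter extraction from OD time series.

The maximum specific growth rate is estimated by rolling-window log-linear
regression: the slope of ``ln(OD)`` against time over a sliding window, with
a carrying-capacity correction (each window slope is divided by
``1 - mean(OD)/K_hat``) applied when the curve has plateaued. The correction
removes the downward bias of the raw log-slope on saturating curves started
at a non-negligible fraction of capacity (OD 0.05 inocula), while leaving
non-saturating exponential traces untouched. The final population density is
the maximum of the median-of-3 smoothed trace, robust to a noisy final read
or end-of-run decline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import medfilt

__all__ = [
    "GrowthCurve",
    "SingleFit",
    "GrowthParams",
    "fit_growth_params",
    "call_growth",
    "fit_replicate",
    "aggregate_replicates",
    "fit_dataset",
]

logger = logging.getLogger(__name__)

#: fraction of the max log-slope below which the final window counts as plateau
_PLATEAU_SLOPE_FRACTION = 0.1
#: windows with mean OD above this fraction of K_hat are excluded from the
#: corrected-rate search (the correction denominator degenerates there)
_CORRECTION_OD_CUTOFF = 0.8


@dataclass
class GrowthCurve:
    """One OD(595 nm) time series for an (acceptor, medium, replicate) well.

    ``donor is None`` denotes a fresh-medium monoculture; otherwise the curve
    was recorded in medium conditioned by ``donor``.
    """

    acceptor: str
    donor: str | None
    replicate: str
    times: np.ndarray
    ods: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ods = np.asarray(self.ods, dtype=float)
        if self.times.size != self.ods.size:
            raise ValueError("times and ods must have equal length")
        if self.times.size < 4:
            raise ValueError("a growth curve needs >= 4 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.ods < 0):
            raise ValueError("ODs must be non-negative")


@dataclass
class SingleFit:
    """Per-replicate fit: max growth rate (1/h) and final density (OD)."""

    acceptor: str
    donor: str | None
    replicate: str
    max_growth_rate: float
    final_density: float
    grew: bool | None = None


@dataclass
class GrowthParams:
    """Replicate-aggregated growth parameters for one (acceptor, donor) condition.

    When ``grew`` is False the rate and density are carried as NaN (missing):
    a no-growth condition yields no usable parameter estimate.
    """

    acceptor: str
    donor: str | None
    max_growth_rate: float
    final_density: float
    rate_sd: float
    density_sd: float
    n_replicates: int
    grew: bool

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.rate_sd < 0 or self.density_sd < 0:
            raise ValueError("SDs must be >= 0")


def _smoothed(ods: np.ndarray) -> np.ndarray:
    if ods.size < 3:
        return ods.copy()
    return medfilt(ods, kernel_size=3)


def fit_growth_params(curve: GrowthCurve, window: int = 5,
                      od_floor: float = 1e-3,
                      capacity_correction: bool = True) -> SingleFit:
    """Fit one replicate's maximum growth rate and final density.

    Parameters
    ----------
    curve:
        The OD time series.
    window:
        Rolling-regression window size in points (>= 3, <= number of points).
    od_floor:
        Detection limit; non-positive ODs are floored here (with a warning)
        before the log transform. Windows in which at least half the points
        were floored are excluded from the rate search.
    capacity_correction:
        Apply the plateau-conditional capacity correction (see module notes).

    Returns
    -------
    SingleFit
        ``max_growth_rate`` (may be <= 0 for flat/declining traces) and
        ``final_density`` (max of median-3 smoothed trace), both finite.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    n = curve.times.size
    if window > n:
        raise ValueError(f"window ({window}) exceeds number of points ({n})")

    ods = curve.ods.copy()
    floored = ods < od_floor
    if np.any(floored):
        logger.warning(
            "%s in %s (rep %s): %d OD point(s) below detection floor %g",
            curve.acceptor, curve.donor or "fresh medium", curve.replicate,
            int(floored.sum()), od_floor)
        ods[floored] = od_floor

    smooth = _smoothed(ods)
    final_density = float(smooth.max())

    log_od = np.log(ods)
    t = curve.times
    slopes = np.full(n - window + 1, np.nan)
    mean_od = np.full(n - window + 1, np.nan)
    for k in range(n - window + 1):
        sl = slice(k, k + window)
        if floored[sl].sum() * 2 >= window:
            continue  # mostly at detection limit: slope meaningless
        tw = t[sl] - t[sl].mean()
        slopes[k] = float(tw @ log_od[sl] / (tw @ tw))
        mean_od[k] = float(ods[sl].mean())

    valid = np.isfinite(slopes)
    if not np.any(valid):
        # entire trace at the floor: no measurable growth
        return SingleFit(curve.acceptor, curve.donor, curve.replicate,
                         0.0, final_density)
    raw_max = float(np.nanmax(slopes))

    rate = raw_max
    if capacity_correction and raw_max > 0:
        last_valid = slopes[valid][-1]
        plateaued = last_valid < _PLATEAU_SLOPE_FRACTION * raw_max
        if plateaued:
            usable = valid & (mean_od <= _CORRECTION_OD_CUTOFF * final_density)
            if np.any(usable):
                corrected = slopes[usable] / (1.0 - mean_od[usable] / final_density)
                rate = float(np.max(corrected))
    return SingleFit(curve.acceptor, curve.donor, curve.replicate,
                     rate, final_density)


def call_growth(curve: GrowthCurve, fold_threshold: float = 2.0) -> bool:
    """Binary growth call: did the acceptor grow in this condition?

    True iff the final density (max of the median-3 smoothed trace) reached
    at least ``fold_threshold`` times the initial OD. The 2x default
    separates hard no-growth from weak growth without imposing an absolute
    OD cutoff.
    """
    if fold_threshold <= 1.0:
        raise ValueError("fold_threshold must be > 1")
    smooth = _smoothed(curve.ods)
    initial = curve.ods[0]
    if initial <= 0:
        return bool(smooth.max() > 0)
    return bool(smooth.max() >= fold_threshold * initial)


def fit_replicate(curve: GrowthCurve, window: int = 5, od_floor: float = 1e-3,
                  fold_threshold: float = 2.0) -> SingleFit:
    """Fit one replicate and attach its growth call."""
    fit = fit_growth_params(curve, window=window, od_floor=od_floor)
    fit.grew = call_growth(curve, fold_threshold=fold_threshold)
    return fit


def aggregate_replicates(fits: Sequence[SingleFit]) -> GrowthParams:
    """Aggregate single-replicate fits of one condition into GrowthParams.

    Mean and sample SD (ddof=1; zero for a single replicate) over replicates.
    The condition counts as grown iff a strict majority of replicates passed
    the growth call (a tie counts as no growth); a no-growth condition
    carries NaN parameters.
    """
    if not fits:
        raise ValueError("empty replicate list")
    acceptor, donor = fits[0].acceptor, fits[0].donor
    for f in fits[1:]:
        if f.acceptor != acceptor or f.donor != donor:
            raise ValueError("all replicates must share acceptor and donor")
    n = len(fits)
    grew_flags = [bool(f.grew) for f in fits]
    grew = sum(grew_flags) * 2 > n
    rates = np.array([f.max_growth_rate for f in fits], dtype=float)
    dens = np.array([f.final_density for f in fits], dtype=float)
    rate_sd = float(rates.std(ddof=1)) if n > 1 else 0.0
    dens_sd = float(dens.std(ddof=1)) if n > 1 else 0.0
    if not grew:
        return GrowthParams(acceptor, donor, float("nan"), float("nan"),
                            rate_sd, dens_sd, n, False)
    return GrowthParams(acceptor, donor, float(rates.mean()), float(dens.mean()),
                        rate_sd, dens_sd, n, True)


def fit_dataset(curves: Iterable[GrowthCurve], window: int = 5,
                od_floor: float = 1e-3,
                fold_threshold: float = 2.0) -> list[GrowthParams]:
    """Fit and aggregate a whole assay dataset, grouped by (acceptor, donor)."""
    groups: dict[tuple[str, str | None], list[SingleFit]] = {}
    for curve in curves:
        key = (curve.acceptor, curve.donor)
        groups.setdefault(key, []).append(
            fit_replicate(curve, window=window, od_floor=od_floor,
                          fold_threshold=fold_threshold))
    return [aggregate_replicates(fits)
            for _key, fits in sorted(groups.items(),
                                     key=lambda kv: (kv[0][0], kv[0][1] or ""))]
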