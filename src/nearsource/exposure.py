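"""Exposure aggregation: daily 1-hr maxima, annual means, and the
Concentration-to-Emission Ratio (CER).

The health-relevant exposure metric is the annual mean of daily 1-hr
maximum NO2 concentrations; the plain annual mean of all valid hours is
carried alongside it. Multi-year inputs are averaged with equal year
weights. Calm hours are missing by construction; a calendar day with no
valid hour contributes no daily maximum.

CER = modeled NO2 concentration / annual NOx emissions (ppb per ton), a
site-comparison heuristic: CER_avg uses the unweighted mean over block
groups of the exposure metric, CER_max the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import ppb_to_ugm3

#: default exposure basis for health and equity stages
DEFAULT_BASIS = "annual_mean_daily_max"


def daily_max_series(hourly: pd.DataFrame) -> pd.DataFrame:
    """Per-block-group daily 1-hr maxima over valid (non-calm) hours.

    Days on which every hour is missing are dropped.
    """
    if len(hourly) == 0:
        raise ValueError("hourly series is empty")
    daily = hourly.resample("D").max()
    return daily.dropna(how="all")


def summarize_exposure(hourly: pd.DataFrame,
                       daily: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate an hourly ppb field into per-block-group exposure metrics.

    Returns a DataFrame indexed by bg_id with columns
    ``annual_mean_daily_max`` (mean of daily maxima, equal year weights),
    ``annual_mean`` (mean of valid hours, equal year weights) and
    ``n_valid_days``.
    """
    if daily is None:
        daily = daily_max_series(hourly)
    if len(daily) == 0:
        raise ValueError("no valid days in exposure record")
    years_d = daily.index.year
    amdm = daily.groupby(years_d).mean().mean(axis=0)
    years_h = hourly.index.year
    amean = hourly.groupby(years_h).mean().mean(axis=0)
    out = pd.DataFrame({
        "annual_mean_daily_max": amdm,
        "annual_mean": amean,
        "n_valid_days": daily.notna().sum(axis=0),
    })
    out.index.name = "bg_id"
    return out


@dataclass(frozen=True)
class CERResult:
    cer_avg: float    # ppb per ton/yr
    cer_max: float
    basis: str

    def __post_init__(self):
        if not (self.cer_max >= self.cer_avg >= 0):
            raise ValueError("CER invariant violated: need cer_max >= cer_avg >= 0")


def _metric(summaries, basis: str) -> pd.Series:
    if isinstance(summaries, pd.DataFrame):
        return summaries[basis]
    return pd.Series(np.asarray(summaries, dtype=float))


def cer(summaries, annual_emissions: float, basis: str = DEFAULT_BASIS) -> CERResult:
    """Concentration-to-Emission Ratio over all block groups.

    ``summaries`` is the frame from :func:`summarize_exposure` (or a bare
    sequence of per-block-group concentrations, in which case ``basis`` is
    only a label). Block groups are unweighted.
    """
    if annual_emissions <= 0:
        raise ValueError("annual_emissions must be > 0 for CER")
    v = _metric(summaries, basis)
    return CERResult(cer_avg=float(v.mean() / annual_emissions),
                     cer_max=float(v.max() / annual_emissions),
                     basis=basis)


def max_min_ratio(summaries, basis: str = DEFAULT_BASIS) -> float:
    """Max/min of the exposure metric over block groups."""
    v = _metric(summaries, basis)
    lo = float(v.min())
    if lo <= 0:
        raise ValueError("max/min ratio undefined for non-positive minimum")
    return float(v.max()) / lo


def write_exposure_csv(summaries: pd.DataFrame, path) -> None:
    """Exposure summary CSV with both metrics in ppb and ug/m3."""
    out = summaries.copy()
    for col in ("annual_mean_daily_max", "annual_mean"):
        out[f"{col}_ugm3"] = ppb_to_ugm3(out[col].to_numpy())
    out.to_csv(path, float_format="%.10g")
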