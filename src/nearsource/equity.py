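"""Demographic-equity analyses: distance quintiles, POC% stratification,
intersectional race-income exposure groups, and spatial regression of
exposure on demographics.

All summaries are unweighted means over block groups (each block group
counts once regardless of population), matching the convention of the
quintile-table reports this module renders.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spatial import (SpatialWeights, build_weights, morans_i,  # noqa: F401
                      ols_fit, slm_fit, sem_fit, RegressionResult)

POC_BINS = ((0, 20), (20, 40), (40, 60), (60, 80), (80, 100))


def assign_distance_quintiles(block_groups) -> pd.Series:
    """Quintile label (1 = nearest) per block group.

    Block groups are ordered by increasing centroid distance (ties broken
    by bg_id) and split into five contiguous groups whose sizes differ by
    at most one; remainders go to the nearest-first quintiles.
    """
    n = len(block_groups)
    if n < 5:
        raise ValueError("need at least 5 block groups for quintiles")
    order = sorted(block_groups, key=lambda bg: (bg.distance_km, bg.bg_id))
    base, rem = divmod(n, 5)
    sizes = [base + (1 if q < rem else 0) for q in range(5)]
    labels = {}
    pos = 0
    for q, size in enumerate(sizes, start=1):
        for bg in order[pos:pos + size]:
            labels[bg.bg_id] = q
        pos += size
    out = pd.Series({bg.bg_id: labels[bg.bg_id] for bg in block_groups},
                    name="quintile")
    out.index.name = "bg_id"
    return out


def quintile_table(block_groups, exposure_ppb: pd.Series,
                   mortality_rate: pd.Series | None = None,
                   asthma_rate: pd.Series | None = None) -> pd.DataFrame:
    """Five-row summary table of exposure, demographics, and burden rates.

    Each cell is the unweighted mean over block groups in the quintile:
    distance (km), exposure (ppb), POC%, LI%, elderly% and, when supplied,
    the attributable mortality and pediatric asthma rates per 100,000.
    """
    q = assign_distance_quintiles(block_groups)
    df = pd.DataFrame({
        "bg_id": [bg.bg_id for bg in block_groups],
        "distance_km": [bg.distance_km for bg in block_groups],
        "poc_pct": [100.0 * bg.poc_frac for bg in block_groups],
        "li_pct": [100.0 * bg.li_frac for bg in block_groups],
        "elderly_pct": [100.0 * bg.elderly_frac for bg in block_groups],
    }).set_index("bg_id")
    df["quintile"] = q
    df["exposure_ppb"] = exposure_ppb
    if mortality_rate is not None:
        df["mortality_rate_per_100k"] = mortality_rate
    if asthma_rate is not None:
        df["asthma_rate_per_100k"] = asthma_rate
    tbl = df.groupby("quintile").mean().reset_index()
    tbl["n_blockgroups"] = df.groupby("quintile").size().to_numpy()
    return tbl


def stratify_by_poc(block_groups, values: pd.Series) -> pd.DataFrame:
    """Box-plot statistics of ``values`` within five POC% ranges.

    Bins are [0,20), [20,40), [40,60), [60,80), [80,100]. Outliers are
    points beyond 1.5 * IQR from the quartiles. Empty bins are emitted
    with null statistics.
    """
    poc = pd.Series({bg.bg_id: 100.0 * bg.poc_frac for bg in block_groups})
    rows = []
    for lo, hi in POC_BINS:
        if hi == 100:
            mask = (poc >= lo) & (poc <= hi)
        else:
            mask = (poc >= lo) & (poc < hi)
        v = values.loc[poc.index[mask]].dropna().to_numpy(dtype=float)
        row = {"poc_lo": lo, "poc_hi": hi, "n": len(v)}
        if len(v) == 0:
            row.update({k: float("nan") for k in
                        ("mean", "median", "q1", "q3", "n_outliers")})
        else:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            out = np.sum((v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr))
            row.update({"mean": float(v.mean()), "median": float(med),
                        "q1": float(q1), "q3": float(q3),
                        "n_outliers": int(out)})
        rows.append(row)
    return pd.DataFrame(rows)


def intersectional_groups(block_groups, exposure_ppb: pd.Series) -> pd.DataFrame:
    """Exposure by the four race-income groups split at the scenario means.

    Thresholds are the unweighted means of POC% and LI% over all block
    groups; groups are labelled HH (high POC, high LI), HL, LH, LL using
    >= mean vs < mean. Returns per-group n, mean, min, max exposure.
    """
    if len(block_groups) < 4:
        raise ValueError("need at least 4 block groups")
    poc = np.array([bg.poc_frac for bg in block_groups])
    li = np.array([bg.li_frac for bg in block_groups])
    ids = [bg.bg_id for bg in block_groups]
    poc_thr, li_thr = poc.mean(), li.mean()
    lab = np.where(poc >= poc_thr, "H", "L")
    lab = np.char.add(lab, np.where(li >= li_thr, "H", "L"))
    v = exposure_ppb.loc[ids].to_numpy(dtype=float)
    rows = []
    for g in ("HH", "HL", "LH", "LL"):
        m = lab == g
        row = {"group": g, "n": int(m.sum()),
               "poc_threshold_pct": 100.0 * poc_thr,
               "li_threshold_pct": 100.0 * li_thr}
        if m.any():
            row.update({"mean_ppb": float(v[m].mean()),
                        "min_ppb": float(v[m].min()),
                        "max_ppb": float(v[m].max())})
        else:
            row.update({"mean_ppb": float("nan"), "min_ppb": float("nan"),
                        "max_ppb": float("nan")})
        rows.append(row)
    return pd.DataFrame(rows)


def regression_table(block_groups, exposure_ppb: pd.Series, k: int = 8,
                     seed: int = 0) -> tuple:
    """OLS, SLM and SEM of exposure on POC% and LI%, plus the results frame.

    Returns ``(results, frame)`` where ``results`` maps model name to
    :class:`RegressionResult` and ``frame`` is a tidy CSV-ready summary
    (coefficients, SEs, spatial parameter, log-likelihood, residual
    Moran's I).
    """
    ids = [bg.bg_id for bg in block_groups]
    X = pd.DataFrame({
        "poc_pct": [100.0 * bg.poc_frac for bg in block_groups],
        "li_pct": [100.0 * bg.li_frac for bg in block_groups],
    }, index=ids)
    y = exposure_ppb.loc[ids].to_numpy(dtype=float)
    w = build_weights(block_groups, k=k)
    results = {
        "OLS": ols_fit(y, X, w, seed=seed),
        "SLM": slm_fit(y, X, w, seed=seed),
        "SEM": sem_fit(y, X, w, seed=seed),
    }
    rows = []
    for name, res in results.items():
        row = {"model": name,
               "spatial_param_name": res.spatial_param_name or "",
               "spatial_param": res.spatial_param,
               "log_likelihood": res.log_likelihood,
               "morans_i_residuals": res.morans_i_residuals,
               "morans_i_pvalue": res.morans_i_pvalue,
               "converged": res.converged}
        for nm in res.params.index:
            row[f"coef_{nm}"] = res.params[nm]
            row[f"se_{nm}"] = res.bse[nm]
        rows.append(row)
    return results, pd.DataFrame(rows)
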