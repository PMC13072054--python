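"""Steady-state Gaussian point-source plume model.

The regulatory model this emulates resolves hourly meteorology into
ground-level concentrations with similarity-theory dispersion, plume rise,
and terrain; here the same pipeline stage is provided by the classical
analytical machinery:

* Briggs final plume rise (buoyancy-driven, with a momentum fallback when
  the effluent is not buoyant),
* Briggs rural (open-country) dispersion coefficient curves per Pasquill
  stability class,
* the reflected Gaussian plume equation with mixing-lid image sources,
  switching to the well-mixed form once sigma_z outgrows the boundary layer.

Receptors are block-group centroids at ground level (flat terrain). Calm
hours are undefined for a steady-state plume and are reported as missing.
Concentrations leave this module as NOx in ppb (NO2-equivalent mass basis);
speciation to NO2 happens in the chemistry stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .met import CALM_THRESHOLD
from .region import PointSourceSpec, RegionScenario
from .units import G, UGM3_PER_PPB

log = logging.getLogger(__name__)

#: Briggs rural sigma_y: a * x * (1 + 0.0001 x)^(-1/2)
_SIGMA_Y_A = {"A": 0.22, "B": 0.16, "C": 0.11, "D": 0.08, "E": 0.06, "F": 0.04}

#: Briggs rural sigma_z: a * x * (1 + b x)^p
_SIGMA_Z = {
    "A": (0.20, 0.0, 0.0),
    "B": (0.12, 0.0, 0.0),
    "C": (0.08, 0.0002, -0.5),
    "D": (0.06, 0.0015, -0.5),
    "E": (0.03, 0.0003, -1.0),
    "F": (0.016, 0.0003, -1.0),
}


class CalmHourError(ValueError):
    """Raised when a steady-state plume is requested for a calm hour."""


@dataclass(frozen=True)
class PlumeParams:
    """Resolved inputs to the plume equation at one receptor distance."""

    effective_height: float   # m
    sigma_y: float            # m
    sigma_z: float            # m
    emission_rate: float      # g/s
    wind_speed: float         # m/s


def briggs_plume_rise(source: PointSourceSpec, wind_speed: float,
                      ambient_temperature: float, stability: str) -> float:
    """Final effective plume height (m) = stack height + Briggs rise.

    Buoyancy flux F = g * vs * (d/2)^2 * (Ts - Ta) / Ts. For unstable and
    neutral classes the final rise is 1.6 F^(1/3) (3.5 x*)^(2/3) / u with
    the distance-to-final-rise x* = 14 F^(5/8) (F < 55) or 34 F^(2/5).
    Stable classes use 2.6 (F / (u s))^(1/3) with the stability parameter
    s = 0.02 g/Ta (E) or 0.035 g/Ta (F). A non-buoyant effluent
    (Ts <= Ta) falls back to momentum rise 3 d vs / u.
    """
    u = float(wind_speed)
    if u < CALM_THRESHOLD:
        raise CalmHourError(f"plume rise undefined for calm hour (u={u} m/s)")
    Ts = source.exit_temperature
    Ta = float(ambient_temperature)
    d = source.stack_diameter
    vs = source.exit_velocity

    if Ts <= Ta:
        dh = 3.0 * d * vs / u
    else:
        F = G * vs * (d / 2.0) ** 2 * (Ts - Ta) / Ts
        if F <= 0:
            dh = 3.0 * d * vs / u
        elif stability in ("E", "F"):
            s = (0.02 if stability == "E" else 0.035) * G / Ta
            dh = 2.6 * (F / (u * s)) ** (1.0 / 3.0)
        else:
            xf = 14.0 * F ** 0.625 if F < 55.0 else 34.0 * F ** 0.4
            dh = 1.6 * F ** (1.0 / 3.0) * (3.5 * xf) ** (2.0 / 3.0) / u
    return source.stack_height + dh


def sigma_yz(stability: str, downwind_x):
    """Briggs rural dispersion coefficients (sigma_y, sigma_z) in m.

    ``downwind_x`` may be a scalar or array of distances in m; all entries
    must be > 0.
    """
    x = np.asarray(downwind_x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("downwind distance must be > 0")
    if stability not in _SIGMA_Y_A:
        raise ValueError(f"unknown stability class {stability!r}")
    sy = _SIGMA_Y_A[stability] * x * (1.0 + 0.0001 * x) ** -0.5
    a, b, p = _SIGMA_Z[stability]
    sz = a * x if b == 0.0 else a * x * (1.0 + b * x) ** p
    if np.isscalar(downwind_x):
        return float(sy), float(sz)
    return sy, sz


def plume_concentration(params: PlumeParams, crosswind_y, receptor_z=0.0,
                        mixing_height=np.inf, n_reflections: int = 4):
    """Ground-reflected Gaussian plume concentration in g/m3.

    Sums ``n_reflections`` pairs of mixing-lid image sources on each side.
    Where sigma_z exceeds 1.6 * mixing height the plume is treated as
    vertically well mixed through the boundary layer.
    """
    H = params.effective_height
    sy, sz = params.sigma_y, params.sigma_z
    Q, u = params.emission_rate, params.wind_speed
    if sy <= 0 or sz <= 0:
        raise ValueError("sigma values must be > 0")
    y = np.asarray(crosswind_y, dtype=float)
    z = float(receptor_z)
    zi = float(mixing_height)

    cross = np.exp(-y ** 2 / (2.0 * sy ** 2))
    if np.isfinite(zi) and sz > 1.6 * zi:
        c = Q / (np.sqrt(2.0 * np.pi) * sy * u * zi) * cross
    else:
        offsets = ([0.0] if not np.isfinite(zi)
                   else [2.0 * i * zi for i in range(-n_reflections, n_reflections + 1)])
        vert = 0.0
        for off in offsets:
            vert = vert + np.exp(-((z - H + off) ** 2) / (2.0 * sz ** 2))
            vert = vert + np.exp(-((z + H + off) ** 2) / (2.0 * sz ** 2))
        c = Q / (2.0 * np.pi * u * sy * sz) * cross * vert
    if np.ndim(crosswind_y) == 0:
        return float(c)
    return c


def simulate_hourly_field(source: PointSourceSpec, region: RegionScenario,
                          met: pd.DataFrame, n_reflections: int = 4) -> pd.DataFrame:
    """Hourly ground-level NOx (ppb, NO2-equivalent mass) per block group.

    For each non-calm hour the receptors are rotated into the downwind
    frame (transport bearing = wind_dir_from + 180 deg), the plume
    equation is evaluated at every centroid at z = 0, and the resulting
    mass concentration is expressed in ppb. Calm hours are emitted as NaN
    rows. Upwind receptors and the source location itself get 0.

    Returns a DataFrame indexed like ``met`` with one column per bg_id;
    ``df.attrs['calm_fraction']`` records the calm-hour share.
    """
    if len(met) == 0:
        raise ValueError("met series is empty")
    bgs = region.block_groups
    rx = np.array([bg.centroid_x - source.x for bg in bgs])
    ry = np.array([bg.centroid_y - source.y for bg in bgs])
    Q = source.emission_rate_gps
    cols = [bg.bg_id for bg in bgs]

    out = np.full((len(met), len(bgs)), np.nan)
    calm = met["calm"].to_numpy()
    u_arr = met["wind_speed"].to_numpy()
    dir_arr = met["wind_dir_from"].to_numpy()
    T_arr = met["temperature"].to_numpy()
    stab_arr = met["stability"].to_numpy()
    zi_arr = met["mixing_height"].to_numpy()

    for h in range(len(met)):
        if calm[h]:
            continue
        u = u_arr[h]
        stab = stab_arr[h]
        H = briggs_plume_rise(source, u, T_arr[h], stab)
        phi = np.deg2rad((dir_arr[h] + 180.0) % 360.0)  # transport bearing
        tx, ty = np.sin(phi), np.cos(phi)
        xd = rx * tx + ry * ty            # downwind distance, m
        yc = rx * ty - ry * tx            # signed crosswind offset, m
        row = np.zeros(len(bgs))
        down = xd > 0.0
        if np.any(down):
            sy, sz = sigma_yz(stab, xd[down])
            zi = zi_arr[h]
            cross = np.exp(-yc[down] ** 2 / (2.0 * sy ** 2))
            mixed = sz > 1.6 * zi
            vert = np.zeros_like(sy)
            for i in range(-n_reflections, n_reflections + 1):
                off = 2.0 * i * zi
                vert += np.exp(-((-H + off) ** 2) / (2.0 * sz ** 2))
                vert += np.exp(-((H + off) ** 2) / (2.0 * sz ** 2))
            c = Q / (2.0 * np.pi * u * sy * sz) * cross * vert
            c_mixed = Q / (np.sqrt(2.0 * np.pi) * sy * u * zi) * cross
            row[down] = np.where(mixed, c_mixed, c)
        out[h] = row

    # g/m3 -> ug/m3 -> ppb (NO2-equivalent mass basis)
    out_ppb = out * 1.0e6 / UGM3_PER_PPB
    df = pd.DataFrame(out_ppb, index=met.index, columns=cols)
    df.attrs["calm_fraction"] = float(calm.mean())
    if df.attrs["calm_fraction"] == 1.0:
        log.warning("all hours calm: concentration field entirely missing")
    return df
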