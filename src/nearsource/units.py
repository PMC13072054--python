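"""Physical constants and unit conversions shared across the pipeline.

Concentrations are carried internally in ppb; mass concentrations (g/m3)
appear only inside the dispersion kernel and are converted at the chemistry
boundary.
"""

#: grams per U.S. short ton (EPA emission-inventory convention)
GRAMS_PER_SHORT_TON = 907_184.74

#: seconds in a 365-day year, used to spread annual emissions uniformly
SECONDS_PER_YEAR = 365 * 24 * 3600

#: NO2 mass concentration per mixing ratio at 1 atm / 25 degC.
#: Derivable as MW(NO2) / molar volume = 46.0055 / 24.45 = 1.882 ug/m3 per
#: ppb; fixed at 1.88 to match the regulatory rounding used throughout.
UGM3_PER_PPB = 1.88

#: standard gravity, m/s2
G = 9.80665

#: NO2 1-hr National Ambient Air Quality Standard, ppb
NAAQS_NO2_1HR_PPB = 100.0


def emission_rate_gps(annual_emissions_tons: float) -> float:
    """Convert an annual NOx emission total (short tons/yr) to g/s.

    Emissions are assumed uniform in time, so the annual mass is spread
    over a 365-day year.
    """
    if annual_emissions_tons < 0:
        raise ValueError(f"annual_emissions must be >= 0, got {annual_emissions_tons}")
    return annual_emissions_tons * GRAMS_PER_SHORT_TON / SECONDS_PER_YEAR


def ppb_to_ugm3(no2_ppb):
    """NO2 ppb -> ug/m3 (exact factor 1.88)."""
    import numpy as np

    arr = np.asarray(no2_ppb, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("concentration must be >= 0")
    out = arr * UGM3_PER_PPB
    return float(out) if out.ndim == 0 else out


def ugm3_to_ppb(no2_ugm3):
    """NO2 ug/m3 -> ppb (exact factor 1.88)."""
    import numpy as np

    arr = np.asarray(no2_ugm3, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("concentration must be >= 0")
    out = arr / UGM3_PER_PPB
    return float(out) if out.ndim == 0 else out
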