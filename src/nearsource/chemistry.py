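"""In-plume NOx -> NO2 speciation and ppb/ug-m3 unit conversion.

Combustion sources emit NOx mostly as NO; ambient NO2 forms as background
ozone titrates the plume. Three selectable schemes span the range of
regulatory practice:

* ``FULL`` — complete conversion (conservative upper bound),
* ``ARM`` — a fixed ambient NO2/NOx ratio,
* ``OLM`` — the ozone-limiting method: the in-stack NO2 fraction converts
  immediately, the remainder converts only up to the available background
  ozone.

All concentrations here are ppb. The scheme obeys no2 <= nox always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import ppb_to_ugm3, ugm3_to_ppb, UGM3_PER_PPB  # noqa: F401  (re-export)

SCHEMES = ("FULL", "ARM", "OLM")


@dataclass(frozen=True)
class ChemistryConfig:
    scheme: str = "OLM"
    ambient_ratio: float = 0.80        # ARM only
    ozone_background: float = 36.8     # ppb, annual arithmetic mean
    in_stack_no2_fraction: float = 0.10

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if not 0.0 < self.ambient_ratio <= 1.0:
            raise ValueError("ambient_ratio must be in (0, 1]")
        if self.ozone_background < 0:
            raise ValueError("ozone_background must be >= 0")
        if not 0.0 <= self.in_stack_no2_fraction <= 1.0:
            raise ValueError("in_stack_no2_fraction must be in [0, 1]")


def convert_nox_to_no2(nox_ppb, cfg: ChemistryConfig):
    """NOx (ppb) -> NO2 (ppb) under the configured scheme.

    OLM: no2 = f * nox + min((1 - f) * nox, O3_background), f the in-stack
    NO2 fraction. NaNs (calm hours) pass through.
    """
    x = np.asarray(nox_ppb, dtype=float)
    if np.any(x[~np.isnan(x)] < 0):
        raise ValueError("nox must be >= 0")
    if cfg.scheme == "FULL":
        out = x.copy()
    elif cfg.scheme == "ARM":
        out = cfg.ambient_ratio * x
    else:  # OLM
        f = cfg.in_stack_no2_fraction
        out = f * x + np.minimum((1.0 - f) * x, cfg.ozone_background)
    if np.ndim(nox_ppb) == 0:
        return float(out)
    return out
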