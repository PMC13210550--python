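"""Forage-quality indices: DDM, DMI, RFV and crude protein.

Standard hay-evaluation formulas on the % of dry matter scale (numbers on
0-100, not fractions):

    DDM %          = 88.9 - 0.779 * ADF
    DMI (% of BW)  = 120 / NDF
    RFV            = DDM * DMI / 1.29
    CP %           = 6.25 * N

RFV ~ 100 corresponds to full-bloom reference hay; > 151 grades "Prime".
All functions accept scalars or numpy arrays / pandas Series and keep full
precision — round only when reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddm", "dmi", "rfv", "crude_protein", "add_quality_columns"]


def _check(cond, message: str) -> None:
    if not np.all(cond):
        raise ValueError(message)


def ddm(adf):
    """Digestible dry matter (%) from acid detergent fiber (% of DM)."""
    adf = np.asarray(adf, dtype=float)
    _check((adf >= 0) & (adf < 100), "ADF must be in [0, 100) % of DM")
    out = 88.9 - 0.779 * adf
    return out.item() if out.ndim == 0 else out


def dmi(ndf):
    """Dry matter intake (% of body weight) from neutral detergent fiber."""
    ndf = np.asarray(ndf, dtype=float)
    _check(ndf > 0, "NDF must be positive (it is a divisor)")
    out = 120.0 / ndf
    return out.item() if out.ndim == 0 else out


def rfv(adf, ndf):
    """Relative feed value (unitless index) from ADF and NDF (% of DM)."""
    out = np.asarray(ddm(adf)) * np.asarray(dmi(ndf)) / 1.29
    return out.item() if out.ndim == 0 else out


def crude_protein(nitrogen):
    """Crude protein (% of DM) from Kjeldahl nitrogen (% of DM)."""
    nitrogen = np.asarray(nitrogen, dtype=float)
    _check(nitrogen >= 0, "nitrogen content must be nonnegative")
    out = 6.25 * nitrogen
    return out.item() if out.ndim == 0 else out


def add_quality_columns(
    table: pd.DataFrame,
    adf_col: str = "adf",
    ndf_col: str = "ndf",
    rfv_col: str = "rfv",
) -> pd.DataFrame:
    """Return a copy of ``table`` with the RFV column (re)computed from ADF/NDF."""
    out = table.copy()
    out[rfv_col] = rfv(out[adf_col].to_numpy(), out[ndf_col].to_numpy())
    return out
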