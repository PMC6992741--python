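"""Recompute the derived cells of published benchmark metric tables.

The shipped fixture carries per-method metric rows (Sn, Sp, Acc, F1, MCC,
MCC', CHL) printed to 4 decimals by a published comparison of miRNA-target
prediction methods. Two identities tie the derived cells to the primary
ones within each row:

* MCC' = (MCC + 1) / 2
* CHL  = harmonic mean of (Acc, MCC', F1)

Recomputing from inputs already rounded to 4 decimals perturbs the result
by at most half an ULP of each input propagated through the formula, so
the checks use tolerances of 5.01e-5 (MCC') and 1.01e-4 (CHL) — i.e. the
recomputed value must round to the printed cell. A ``null`` CHL must
coincide with a ``null`` F1 (no positive call was made).
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .metrics import chl_index

__all__ = ["published_panels", "verify_panels", "MCCP_TOL", "CHL_TOL"]

MCCP_TOL = 5.01e-5
CHL_TOL = 1.01e-4


def published_panels() -> pd.DataFrame:
    """The shipped benchmark fixture as a DataFrame (``null`` -> NaN)."""
    with resources.files("mirmeta.data").joinpath("benchmark_panels.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", na_values=["null"])
    return df


def verify_panels(df: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Recompute MCC' and CHL for every fixture row.

    Returns the fixture plus ``mcc_prime_recomputed``, ``chl_recomputed``,
    and boolean ``mcc_prime_ok`` / ``chl_ok`` columns. Rows flagged
    ``mcc_consistent == 0`` (printed MCC/MCC' pair that disagrees in the
    source) are exempt from the MCC' identity but still checked for CHL,
    which is computed from the printed MCC'.
    """
    df = published_panels() if df is None else df.copy()
    mccp = (df["mcc"] + 1.0) / 2.0
    chl = []
    for acc, mp, f1 in zip(df["acc"], df["mcc_prime"], df["f1"]):
        if np.isnan(f1):
            chl.append(np.nan)
        else:
            chl.append(chl_index(float(acc), float(mp), float(f1)))
    df["mcc_prime_recomputed"] = mccp
    df["chl_recomputed"] = chl

    mccp_dev = (df["mcc_prime_recomputed"] - df["mcc_prime"]).abs()
    df["mcc_prime_ok"] = (mccp_dev <= MCCP_TOL) | (df["mcc_consistent"] == 0)

    printed_null = df["chl"].isna()
    recomputed_null = df["chl_recomputed"].isna()
    chl_dev = (df["chl_recomputed"] - df["chl"]).abs()
    df["chl_ok"] = (printed_null & recomputed_null & df["f1"].isna()) | (
        ~printed_null & ~recomputed_null & (chl_dev <= CHL_TOL)
    )
    return df
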