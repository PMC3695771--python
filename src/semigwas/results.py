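"""Per-SNP association results.

Both engines report one record per SNP: the effect estimate per dose
unit, its standard error, the Wald statistic, the base-10 log of the
two-sided p-value, and a status flag.  ``log10_p`` is the authoritative
significance measure: the linear-scale ``p = 10**log10_p`` column is
provided for convenience and is allowed to underflow to exactly 0 for
extreme statistics.  Logistic results add ``odds_ratio = exp(beta)``.

A full scan's results are assembled as a :class:`pandas.DataFrame` with
the columns of :data:`ASSOC_COLUMNS`; :class:`AssocResult` is the
single-row view of the same record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AssocResult", "ASSOC_COLUMNS", "STATUS_OK", "STATUS_MONOMORPHIC",
           "STATUS_FAILED", "assemble_results"]

STATUS_OK = "ok"
STATUS_MONOMORPHIC = "monomorphic"
STATUS_FAILED = "failed"

ASSOC_COLUMNS = ["snp_id", "n_used", "beta", "se", "stat", "log10_p", "p", "status"]


@dataclass
class AssocResult:
    """Association record for a single SNP."""

    snp_id: str
    n_used: int
    beta: float
    se: float
    stat: float
    log10_p: float
    p: float
    status: str
    odds_ratio: float | None = None


def assemble_results(
    snp_ids,
    n_used: int,
    beta: np.ndarray,
    se: np.ndarray,
    stat: np.ndarray,
    log10_p: np.ndarray,
    status: np.ndarray,
    odds_ratio: np.ndarray | None = None,
) -> pd.DataFrame:
    """Build the results frame, blanking estimates of non-ok SNPs to NaN."""
    bad = status != STATUS_OK
    for arr in (beta, se, stat, log10_p):
        arr[bad] = np.nan
    with np.errstate(over="ignore"):
        p = np.power(10.0, log10_p)  # may underflow to 0; log10_p is authoritative
    frame = pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "n_used": n_used,
            "beta": beta,
            "se": se,
            "stat": stat,
            "log10_p": log10_p,
            "p": p,
            "status": status,
        }
    )
    if odds_ratio is not None:
        odds_ratio[bad] = np.nan
        frame["odds_ratio"] = odds_ratio
    return frame
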