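"""Genotype and sample quality control.

The semi-parallel engines require complete data: a single missing value
in a phenotype or SNP column propagates through the block matrix
products.  Incomplete phenotypes or covariates are handled by dropping
those individuals from the whole analysis (complete cases).  Missing
genotypes are handled per SNP: variants with call rate below a
threshold (default 95%) are removed, and the surviving missing entries
are imputed with the sample mean of the observed doses — at typical
GWAS sample sizes and missingness this loses essentially no precision
relative to the complete-data analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .store import GenotypeBlock

__all__ = [
    "QcReport",
    "call_rate",
    "filter_by_call_rate",
    "mean_impute",
    "complete_cases",
]


@dataclass
class QcReport:
    """Per-SNP call rates and the keep decision at a given threshold."""

    snp_ids: list[str]
    call_rate: np.ndarray
    keep_mask: np.ndarray
    threshold: float

    @property
    def n_removed(self) -> int:
        return int((~self.keep_mask).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "call_rate": self.call_rate, "kept": self.keep_mask}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def call_rate(block: GenotypeBlock) -> np.ndarray:
    """Fraction of non-missing genotypes per SNP, in [0, 1]."""
    return 1.0 - block.missing_mask().mean(axis=0)


def filter_by_call_rate(rates: np.ndarray, threshold: float = 0.95) -> np.ndarray:
    """Keep mask: SNP kept iff its call rate is >= threshold.

    The boundary is kept: only SNPs with call rate strictly below the
    threshold are removed.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"call-rate threshold must lie in [0, 1], got {threshold}")
    rates = np.asarray(rates, dtype=float)
    if rates.size and (rates.min() < 0 or rates.max() > 1):
        raise ValueError("call rates must lie in [0, 1]")
    return rates >= threshold


def mean_impute(block: GenotypeBlock) -> GenotypeBlock:
    """Replace missing doses with the per-SNP mean of the observed doses.

    Observed entries are untouched; a block with no missing values is
    returned with its dose matrix bitwise unchanged.  All-missing SNPs
    must be removed beforehand (they have no observed mean).
    """
    missing = block.missing_mask()
    if not missing.any():
        return GenotypeBlock(
            doses=block.doses,
            snp_offset=block.snp_offset,
            snp_ids=list(block.snp_ids),
            missing_code=block.missing_code,
        )
    n_obs = (~missing).sum(axis=0)
    if (n_obs == 0).any():
        bad = [block.snp_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(
            f"SNPs with no observed genotypes cannot be mean-imputed: {bad[:5]}; "
            "filter by call rate first"
        )
    doses = block.doses.copy()
    doses[missing] = 0.0
    col_mean = doses.sum(axis=0) / n_obs
    rows, cols = np.nonzero(missing)
    doses[rows, cols] = col_mean[cols]
    return GenotypeBlock(
        doses=doses,
        snp_offset=block.snp_offset,
        snp_ids=list(block.snp_ids),
        missing_code=block.missing_code,
    )


def complete_cases(y: np.ndarray, X: np.ndarray | None = None) -> np.ndarray:
    """Indices of individuals with fully observed phenotype and covariates.

    Downstream analyses subset every input — phenotype, covariates and
    genotype blocks — by the returned index vector.
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"phenotype has {y.shape[0]} rows but covariates have {X.shape[0]}"
            )
        ok &= np.isfinite(X).all(axis=1)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError("no individuals with complete phenotype and covariates")
    return idx
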