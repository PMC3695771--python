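"""End-to-end association scans over a SNP-major genotype store.

The pipeline is the same for both models: restrict to complete cases on
the phenotype and covariates, build the null context once, then stream
SNP blocks from the container — call-rate filter, mean-impute,
residualize, associate — and concatenate the per-block results.
Results are invariant to the block size; it only bounds memory
(``block_size x n_individuals`` doses in core at a time).

Throughput is logged in Msips — millions of SNP-individual pairs
processed per second — purely informational, as it depends on the
hardware.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import linear, logistic, qc
from .store import GenotypeBlock, iterate_blocks, read_metadata

__all__ = ["ScanConfig", "run_scan", "run_scan_arrays"]

logger = logging.getLogger("semigwas")


@dataclass
class ScanConfig:
    """Options shared by the linear and logistic scan pipelines."""

    model: str = "linear"  # or "logistic"
    block_size: int = 1000
    call_rate_threshold: float = 0.95
    pvalue_reference: str = "normal"  # linear model only; "student" for small n
    refit_top_log10p: float | None = None  # logistic only
    irls_tol: float = 1e-8
    irls_max_iter: int = 25


@dataclass
class ScanOutcome:
    results: pd.DataFrame
    qc_report: qc.QcReport
    n_used: int
    elapsed_s: float
    msips: float
    extras: dict = field(default_factory=dict)


def _build_context(y: np.ndarray, X: np.ndarray | None, config: ScanConfig):
    if config.model == "linear":
        return linear.build_linear_context(y, X)
    if config.model == "logistic":
        return logistic.fit_null_logistic(
            y, X, tol=config.irls_tol, max_iter=config.irls_max_iter
        )
    raise ValueError(f"unknown model {config.model!r}")


def _assoc_block(ctx, block: GenotypeBlock, config: ScanConfig) -> pd.DataFrame:
    if config.model == "linear":
        return linear.scan_block(
            ctx, block, block.snp_ids, method=config.pvalue_reference
        )
    s_star = logistic.weighted_project_block(ctx, block)
    return logistic.assoc_logistic(ctx, s_star, block.snp_ids)


def run_scan_arrays(
    y: np.ndarray,
    X: np.ndarray | None,
    blocks,
    config: ScanConfig | None = None,
    case_idx: np.ndarray | None = None,
) -> ScanOutcome:
    """Scan an iterable of genotype blocks against in-memory phenotype data.

    ``case_idx`` (from :func:`semigwas.qc.complete_cases`) subsets the
    rows of every block; ``y`` and ``X`` must already be subset.  Each
    block is call-rate filtered, mean-imputed, residualized and
    associated; removed SNPs appear in the QC report but not in the
    results.
    """
    config = config or ScanConfig()
    t0 = time.perf_counter()
    ctx = _build_context(y, X, config)
    n = y.shape[0]
    frames: list[pd.DataFrame] = []
    qc_ids: list[str] = []
    qc_rates: list[np.ndarray] = []
    qc_keep: list[np.ndarray] = []
    kept_doses: list[np.ndarray] = []  # only retained when refitting top SNPs
    want_doses = config.model == "logistic" and config.refit_top_log10p is not None
    n_snps_seen = 0
    for block in blocks:
        if case_idx is not None:
            block = GenotypeBlock(
                doses=block.doses[case_idx],
                snp_offset=block.snp_offset,
                snp_ids=list(block.snp_ids),
                missing_code=block.missing_code,
            )
        rates = qc.call_rate(block)
        keep = qc.filter_by_call_rate(rates, config.call_rate_threshold)
        qc_ids.extend(block.snp_ids)
        qc_rates.append(rates)
        qc_keep.append(keep)
        n_snps_seen += block.n_snps
        if not keep.any():
            continue
        if not keep.all():
            block = GenotypeBlock(
                doses=block.doses[:, keep],
                snp_offset=block.snp_offset,
                snp_ids=[s for s, k in zip(block.snp_ids, keep) if k],
                missing_code=block.missing_code,
            )
        block = qc.mean_impute(block)
        frames.append(_assoc_block(ctx, block, config))
        if want_doses:
            kept_doses.append(block.doses)
        logger.info(
            "block at SNP %d: %d/%d SNPs pass call-rate QC",
            block.snp_offset,
            block.n_snps,
            len(keep),
        )
    report = qc.QcReport(
        snp_ids=qc_ids,
        call_rate=np.concatenate(qc_rates) if qc_rates else np.empty(0),
        keep_mask=np.concatenate(qc_keep) if qc_keep else np.empty(0, bool),
        threshold=config.call_rate_threshold,
    )
    if not frames:
        raise ValueError("no SNPs passed call-rate QC; nothing to analyze")
    results = pd.concat(frames, ignore_index=True)
    extras: dict = {}
    if want_doses:
        results, n_refit = logistic.refit_top_snps(
            results,
            y,
            ctx.X,
            np.concatenate(kept_doses, axis=1),
            config.refit_top_log10p,
        )
        extras["n_refit"] = n_refit
    elapsed = time.perf_counter() - t0
    msips = n * n_snps_seen / elapsed / 1e6
    logger.info(
        "scan done: %d SNPs x %d individuals in %.2f s (%.1f Msips, informational)",
        n_snps_seen,
        n,
        elapsed,
        msips,
    )
    return ScanOutcome(
        results=results,
        qc_report=report,
        n_used=n,
        elapsed_s=elapsed,
        msips=msips,
        extras=extras,
    )


def run_scan(
    store_path: str | Path,
    y: np.ndarray,
    X: np.ndarray | None = None,
    config: ScanConfig | None = None,
) -> ScanOutcome:
    """Scan a genotype store: complete cases, then block-streamed association.

    ``y`` (and ``X`` rows) must be aligned to the store's individual
    order; individuals with missing phenotype or covariates are dropped
    from the whole analysis and every genotype block is subset to the
    same cases.
    """
    config = config or ScanConfig()
    meta = read_metadata(store_path)
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != meta.n_individuals:
        raise ValueError(
            f"phenotype has {y.shape[0]} rows but store holds "
            f"{meta.n_individuals} individuals"
        )
    idx = qc.complete_cases(y, X)
    y_cc = y[idx]
    X_cc = None if X is None else np.asarray(X, float)[idx]
    blocks = iterate_blocks(store_path, config.block_size)
    return run_scan_arrays(y_cc, X_cc, blocks, config, case_idx=idx)
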