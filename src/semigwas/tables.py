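"""Phenotype/covariate tables and results files.

Phenotype input is a TSV with a header and one row per individual; an
ID column is matched against the genotype store's individual IDs so
that phenotype rows are re-ordered (never assumed aligned).  Results
and QC reports are written as TSV with a comment header recording the
package version, a configuration hash and the seed, so a results file
is self-describing and a rerun is byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["read_phenotype_table", "write_results_tsv", "config_hash"]


def read_phenotype_table(
    path: str | Path,
    individual_ids: list[str],
    phenotype: str,
    covariates: list[str] | None = None,
    id_column: str | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Load phenotype (and covariates) aligned to the store's individuals.

    ``id_column`` defaults to the first column.  Every store individual
    must appear exactly once in the table; unknown or missing IDs raise
    with examples, since silently mis-aligned phenotypes are the
    classic way to destroy a scan.
    """
    table = pd.read_csv(path, sep="\t", dtype={0: str} if id_column is None else None)
    if id_column is None:
        id_column = table.columns[0]
    table[id_column] = table[id_column].astype(str)
    if table[id_column].duplicated().any():
        dups = table[id_column][table[id_column].duplicated()].head(3).tolist()
        raise ValueError(f"duplicate individual IDs in phenotype table: {dups}")
    lookup = table.set_index(id_column)
    missing = [i for i in individual_ids if i not in lookup.index]
    if missing:
        raise ValueError(
            f"{len(missing)} store individuals absent from phenotype table, "
            f"e.g. {missing[:3]}"
        )
    aligned = lookup.loc[[str(i) for i in individual_ids]]
    if phenotype not in aligned.columns:
        raise ValueError(f"phenotype column {phenotype!r} not in table")
    y = aligned[phenotype].to_numpy(dtype=float)
    X = None
    if covariates:
        absent = [c for c in covariates if c not in aligned.columns]
        if absent:
            raise ValueError(f"covariate columns not in table: {absent}")
        X = aligned[list(covariates)].to_numpy(dtype=float)
    return y, X


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_results_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a results frame with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# semigwas {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config_hash(config)}\n")
        if seed is not None:
            fh.write(f"# seed {seed}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")
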