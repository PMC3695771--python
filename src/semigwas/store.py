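"""SNP-major chunked genotype storage and format decoders.

Genome-wide association scans read genotypes in blocks of SNPs spanning
all individuals.  Distribution formats are organised the other way
around: PLINK BED files pack observed genotypes two bits per call, and
MACH-style dosage text files hold one row per person.  This module
decodes both and maintains an HDF5 container whose single ``dosage``
dataset is laid out SNP-major (one row per SNP), chunked so that an
arbitrary block of SNPs for all individuals is a handful of contiguous
chunk reads.

Doses are real allele counts in [0, 2].  On disk each dose occupies one
unsigned byte as ``round(dose * 100)`` (0..200), with 255 as the missing
sentinel.  In memory, missing genotypes are marked with the code 3.0 —
outside the dose range, hence unambiguous.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterator, Sequence

import h5py
import numpy as np

__all__ = [
    "MISSING_CODE",
    "MISSING_SENTINEL",
    "DOSE_SCALE",
    "StoreMetadata",
    "GenotypeBlock",
    "BedFormatError",
    "decode_plink_bed",
    "read_plink_trio",
    "convert_plink_to_store",
    "convert_row_per_person_text",
    "write_store",
    "read_metadata",
    "read_block",
    "iterate_blocks",
]

#: In-memory marker for a missing genotype (outside the dose range [0, 2]).
MISSING_CODE = 3.0
#: On-disk byte sentinel for a missing genotype (outside 0..200).
MISSING_SENTINEL = 255
#: Doses are stored as round(dose * DOSE_SCALE) in one unsigned byte.
DOSE_SCALE = 100

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = 0x01
_BED_INDIV_MAJOR = 0x00


class BedFormatError(ValueError):
    """Raised for malformed or unsupported PLINK BED input."""


@dataclass
class StoreMetadata:
    """Descriptor of a SNP-major dosage container.

    ``chunk_snps`` and ``chunk_individuals`` are the chunk edge lengths
    of the on-disk dataset; the numbers of chunks along each axis follow
    as ``ceil(n_snps / chunk_snps)`` and
    ``ceil(n_individuals / chunk_individuals)``.
    """

    n_individuals: int
    n_snps: int
    snp_ids: list[str]
    individual_ids: list[str]
    chunk_snps: int
    chunk_individuals: int
    encoding: dict = field(
        default_factory=lambda: {"scale": DOSE_SCALE, "missing_sentinel": MISSING_SENTINEL}
    )
    layout: str = "snp-major"

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("store must hold at least one individual and one SNP")
        if len(self.snp_ids) != self.n_snps:
            raise ValueError(
                f"{len(self.snp_ids)} SNP ids for {self.n_snps} SNPs"
            )
        if len(self.individual_ids) != self.n_individuals:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for "
                f"{self.n_individuals} individuals"
            )
        self.chunk_snps = min(self.chunk_snps, self.n_snps)
        self.chunk_individuals = min(self.chunk_individuals, self.n_individuals)
        if self.chunk_snps < 1 or self.chunk_individuals < 1:
            raise ValueError("chunk sizes must be >= 1")


@dataclass
class GenotypeBlock:
    """Dense individuals x SNPs dose matrix for a contiguous SNP range.

    ``doses`` has shape (n_individuals, len(snp_ids)); missing entries
    hold ``missing_code``.  Non-missing entries lie in [0, 2].
    """

    doses: np.ndarray
    snp_offset: int
    snp_ids: list[str]
    missing_code: float = MISSING_CODE

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=np.float64)
        if self.doses.ndim != 2:
            raise ValueError("doses must be a 2-D matrix (individuals x SNPs)")
        if self.doses.shape[1] != len(self.snp_ids):
            raise ValueError(
                f"{self.doses.shape[1]} dose columns for {len(self.snp_ids)} SNP ids"
            )
        observed = self.doses[self.doses != self.missing_code]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("non-missing doses must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.doses.shape[0]

    @property
    def n_snps(self) -> int:
        return self.doses.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.doses == self.missing_code


# ---------------------------------------------------------------------------
# PLINK BED
# ---------------------------------------------------------------------------

def _bed_byte_table(allele_count: str) -> np.ndarray:
    """256 x 4 dose table for one packed BED byte.

    Bit-pairs are read least-significant first.  Counting the A1 allele:
    pair 0b00 -> 2 copies, 0b10 -> 1 (het), 0b11 -> 0, 0b01 -> missing.
    ``allele_count='a2'`` flips the orientation (dose counts A2).
    """
    if allele_count not in ("a1", "a2"):
        raise ValueError(f"allele_count must be 'a1' or 'a2', got {allele_count!r}")
    pair_dose = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: MISSING_CODE}
    table = np.empty((256, 4), dtype=np.float64)
    for byte in range(256):
        for pos in range(4):
            pair = (byte >> (2 * pos)) & 0b11
            d = pair_dose[pair]
            if allele_count == "a2" and d != MISSING_CODE:
                d = 2.0 - d
            table[byte, pos] = d
    return table


def decode_plink_bed(
    bed_stream: BinaryIO | bytes,
    n_individuals: int,
    n_snps: int,
    snp_ids: Sequence[str] | None = None,
    block_size: int = 1000,
    allele_count: str = "a1",
) -> Iterator[GenotypeBlock]:
    """Decode a PLINK v1 BED byte stream into blocks of dose columns.

    The stream must start with the magic bytes 0x6c 0x1b followed by the
    SNP-major mode byte 0x01; each SNP then occupies
    ``ceil(n_individuals / 4)`` bytes, two bits per individual.  Padding
    bits beyond ``n_individuals`` in the last byte of each SNP record
    are discarded.

    Yields :class:`GenotypeBlock` objects of at most ``block_size`` SNPs,
    with missing genotypes carrying :data:`MISSING_CODE`.
    """
    if isinstance(bed_stream, (bytes, bytearray)):
        bed_stream = io.BytesIO(bed_stream)
    header = bed_stream.read(3)
    if len(header) < 3 or header[:2] != _BED_MAGIC:
        raise BedFormatError("not a PLINK BED file (bad magic bytes)")
    if header[2] == _BED_INDIV_MAJOR:
        raise BedFormatError(
            "individual-major BED files are not supported; "
            "re-export in SNP-major mode"
        )
    if header[2] != _BED_SNP_MAJOR:
        raise BedFormatError(f"unknown BED mode byte 0x{header[2]:02x}")

    table = _bed_byte_table(allele_count)
    bytes_per_snp = (n_individuals + 3) // 4
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(n_snps)]
    for start in range(0, n_snps, block_size):
        b = min(block_size, n_snps - start)
        raw = bed_stream.read(b * bytes_per_snp)
        if len(raw) < b * bytes_per_snp:
            raise BedFormatError(
                f"truncated BED stream: expected {b * bytes_per_snp} bytes "
                f"for SNPs {start}..{start + b}, got {len(raw)}"
            )
        packed = np.frombuffer(raw, dtype=np.uint8).reshape(b, bytes_per_snp)
        # decode every byte to its 4 doses, then drop the padding tail
        doses = table[packed].reshape(b, bytes_per_snp * 4)[:, :n_individuals]
        yield GenotypeBlock(
            doses=np.ascontiguousarray(doses.T),
            snp_offset=start,
            snp_ids=list(snp_ids[start : start + b]),
        )
    trailing = bed_stream.read(1)
    if trailing:
        raise BedFormatError("BED stream longer than n_snps * ceil(n_individuals/4)")


def read_plink_trio(prefix: str | Path) -> tuple[Path, list[str], list[str]]:
    """Read the BIM/FAM side of a PLINK trio; return (bed path, snp ids, individual ids)."""
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file: {p}")
    snp_ids = [line.split()[1] for line in bim.read_text().splitlines() if line.strip()]
    individual_ids = [
        line.split()[1] for line in fam.read_text().splitlines() if line.strip()
    ]
    return bed, snp_ids, individual_ids


def convert_plink_to_store(
    prefix: str | Path,
    store_path: str | Path,
    chunk_snps: int = 1000,
    chunk_individuals: int = 10000,
    allele_count: str = "a1",
) -> StoreMetadata:
    """Convert a PLINK BED/BIM/FAM trio into the SNP-major dosage container."""
    bed, snp_ids, individual_ids = read_plink_trio(prefix)
    meta = StoreMetadata(
        n_individuals=len(individual_ids),
        n_snps=len(snp_ids),
        snp_ids=snp_ids,
        individual_ids=individual_ids,
        chunk_snps=chunk_snps,
        chunk_individuals=chunk_individuals,
    )
    with open(bed, "rb") as fh:
        blocks = decode_plink_bed(
            fh,
            meta.n_individuals,
            meta.n_snps,
            snp_ids=snp_ids,
            block_size=meta.chunk_snps,
            allele_count=allele_count,
        )
        write_store(store_path, meta, blocks)
    return meta


# ---------------------------------------------------------------------------
# Container read/write
# ---------------------------------------------------------------------------

def _create_store(h5: h5py.File, meta: StoreMetadata) -> h5py.Dataset:
    dset = h5.create_dataset(
        "dosage",
        shape=(meta.n_snps, meta.n_individuals),
        dtype=np.uint8,
        chunks=(meta.chunk_snps, meta.chunk_individuals),
        fillvalue=MISSING_SENTINEL,
    )
    str_dt = h5py.string_dtype(encoding="utf-8")
    h5.create_dataset("snp_ids", data=np.array(meta.snp_ids, dtype=object), dtype=str_dt)
    h5.create_dataset(
        "individual_ids", data=np.array(meta.individual_ids, dtype=object), dtype=str_dt
    )
    h5.attrs["scale"] = meta.encoding["scale"]
    h5.attrs["missing_sentinel"] = meta.encoding["missing_sentinel"]
    h5.attrs["layout"] = meta.layout
    return dset


def _encode_doses(doses: np.ndarray, missing_code: float) -> np.ndarray:
    """float doses (individuals x SNPs) -> uint8 bytes, missing -> sentinel."""
    out = np.rint(doses * DOSE_SCALE)
    out[doses == missing_code] = MISSING_SENTINEL
    return out.astype(np.uint8)


def write_store(
    store_path: str | Path,
    meta: StoreMetadata,
    blocks: Iterator[GenotypeBlock] | Sequence[GenotypeBlock],
) -> StoreMetadata:
    """Write consecutive genotype blocks into a new SNP-major container."""
    with h5py.File(store_path, "w") as h5:
        dset = _create_store(h5, meta)
        for block in blocks:
            lo, hi = block.snp_offset, block.snp_offset + block.n_snps
            dset[lo:hi, :] = _encode_doses(block.doses, block.missing_code).T
    return meta


def read_metadata(store_path: str | Path) -> StoreMetadata:
    """Load the container descriptor without touching dose data."""
    if not os.path.exists(store_path):
        raise FileNotFoundError(f"genotype store not found: {store_path}")
    with h5py.File(store_path, "r") as h5:
        dset = h5["dosage"]
        chunks = dset.chunks or dset.shape
        return StoreMetadata(
            n_individuals=dset.shape[1],
            n_snps=dset.shape[0],
            snp_ids=[s.decode() if isinstance(s, bytes) else s for s in h5["snp_ids"][:]],
            individual_ids=[
                s.decode() if isinstance(s, bytes) else s for s in h5["individual_ids"][:]
            ],
            chunk_snps=chunks[0],
            chunk_individuals=chunks[1],
            encoding={
                "scale": int(h5.attrs["scale"]),
                "missing_sentinel": int(h5.attrs["missing_sentinel"]),
            },
            layout=str(h5.attrs["layout"]),
        )


def read_block(
    store_path: str | Path, snp_start: int, snp_end: int
) -> GenotypeBlock:
    """Read doses for SNPs [snp_start, snp_end) across all individuals.

    Stored bytes are divided by the scale; sentinel entries come back as
    the block's missing code.  Indices are 0-based, half-open.
    """
    if not os.path.exists(store_path):
        raise FileNotFoundError(f"genotype store not found: {store_path}")
    with h5py.File(store_path, "r") as h5:
        dset = h5["dosage"]
        n_snps = dset.shape[0]
        if not (0 <= snp_start < snp_end <= n_snps):
            raise IndexError(
                f"SNP range [{snp_start}, {snp_end}) invalid for store with "
                f"{n_snps} SNPs (empty ranges are rejected)"
            )
        raw = dset[snp_start:snp_end, :]
        scale = int(h5.attrs["scale"])
        sentinel = int(h5.attrs["missing_sentinel"])
        snp_ids = [
            s.decode() if isinstance(s, bytes) else s
            for s in h5["snp_ids"][snp_start:snp_end]
        ]
    doses = raw.T.astype(np.float64) / scale
    doses[raw.T == sentinel] = MISSING_CODE
    return GenotypeBlock(doses=doses, snp_offset=snp_start, snp_ids=snp_ids)


def iterate_blocks(
    store_path: str | Path, block_size: int = 1000
) -> Iterator[GenotypeBlock]:
    """Yield consecutive non-overlapping blocks covering every SNP once."""
    if block_size < 1:
        raise ValueError(f"block_size must be >= 1, got {block_size}")
    n_snps = read_metadata(store_path).n_snps
    for start in range(0, n_snps, block_size):
        yield read_block(store_path, start, min(start + block_size, n_snps))


# ---------------------------------------------------------------------------
# Row-per-person dosage text
# ---------------------------------------------------------------------------

def convert_row_per_person_text(
    text_path: str | Path,
    store_path: str | Path,
    meta: StoreMetadata,
    skip_columns: int = 2,
    delimiter: str | None = None,
    missing_tokens: Sequence[str] = ("NA", "na", "NaN", "nan", "."),
    individual_block: int | None = None,
) -> StoreMetadata:
    """Transpose a row-per-person dosage text file into the SNP-major store.

    Each input record holds the doses of all SNPs for one individual
    (MACH mldose style: by default two leading identifier columns are
    skipped and fields are whitespace-delimited).  Transposition runs in
    bounded memory: individuals are read in blocks of ``individual_block``
    records and written into the container as transposed column slabs,
    so the largest in-core buffer is ``individual_block x n_snps`` bytes.
    """
    if individual_block is None:
        # ~64 MB buffer by default
        individual_block = max(1, (64 << 20) // max(meta.n_snps, 1))
    missing_set = set(missing_tokens)

    with h5py.File(store_path, "w") as h5:
        dset = _create_store(h5, meta)
        with open(text_path, "r") as fh:
            row = 0
            buf = np.empty((min(individual_block, meta.n_individuals), meta.n_snps), np.uint8)
            buf_fill = 0
            buf_start = 0
            for line in fh:
                if not line.strip():
                    continue
                if row >= meta.n_individuals:
                    raise ValueError(
                        f"more records than the declared {meta.n_individuals} individuals"
                    )
                fields = line.split(delimiter)[skip_columns:]
                if len(fields) != meta.n_snps:
                    raise ValueError(
                        f"record {row + 1}: expected {meta.n_snps} dose fields, "
                        f"got {len(fields)} (ragged input)"
                    )
                buf[buf_fill] = _parse_dose_row(fields, row, missing_set)
                buf_fill += 1
                row += 1
                if buf_fill == buf.shape[0]:
                    dset[:, buf_start : buf_start + buf_fill] = buf[:buf_fill].T
                    buf_start = row
                    buf_fill = 0
                    remaining = meta.n_individuals - row
                    if 0 < remaining < buf.shape[0]:
                        buf = np.empty((remaining, meta.n_snps), np.uint8)
            if buf_fill:
                dset[:, buf_start : buf_start + buf_fill] = buf[:buf_fill].T
            if row != meta.n_individuals:
                raise ValueError(
                    f"found {row} records for {meta.n_individuals} declared individuals"
                )
    return meta


def _parse_dose_row(fields: list[str], row: int, missing_set: set[str]) -> np.ndarray:
    out = np.empty(len(fields), dtype=np.uint8)
    for j, tok in enumerate(fields):
        if tok in missing_set:
            out[j] = MISSING_SENTINEL
            continue
        try:
            dose = float(tok)
        except ValueError as exc:
            raise ValueError(
                f"record {row + 1}, dose column {j + 1}: not a number: {tok!r}"
            ) from exc
        if not 0.0 <= dose <= 2.0:
            raise ValueError(
                f"record {row + 1}, dose column {j + 1}: dose {dose} outside [0, 2]"
            )
        out[j] = int(round(dose * DOSE_SCALE))
    return out
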