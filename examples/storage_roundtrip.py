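"""Genotype storage: BED decoding and dosage-text conversion.

Decodes a tiny PLINK BED byte stream (built here by hand) into dose
columns, then converts a MACH-style row-per-person dosage text file
into the SNP-major container and reads a block back.  The container
stores each dose as round(dose * 100) in one byte, so any value comes
back within 0.005 of what the text file said.
"""

import numpy as np

from semigwas import (
    StoreMetadata,
    convert_row_per_person_text,
    decode_plink_bed,
    read_block,
)

# --- PLINK BED: magic bytes, SNP-major mode, then 2 bits per genotype ---
# one SNP for 4 individuals; bit-pairs from least significant:
# 00 -> dose 2, 10 -> dose 1, 01 -> missing, 11 -> dose 0
payload = b"\x6c\x1b\x01" + bytes([0b11011000])
(block,) = decode_plink_bed(payload, n_individuals=4, n_snps=1)
print("decoded BED doses:", block.doses.ravel(), "(3.0 marks a missing call)")

# --- dosage text -> SNP-major container ---
lines = [
    "ind1 DOSE 1.000 0.239 1.731",
    "ind2 DOSE 0.004 2.000 NA",
    "ind3 DOSE 1.117 0.561 0.802",
]
with open("scratch_doses.txt", "w") as fh:
    fh.write("\n".join(lines) + "\n")

meta = StoreMetadata(
    n_individuals=3,
    n_snps=3,
    snp_ids=["rs1", "rs2", "rs3"],
    individual_ids=["ind1", "ind2", "ind3"],
    chunk_snps=2,
    chunk_individuals=3,
)
convert_row_per_person_text("scratch_doses.txt", "scratch_store.h5", meta)
back = read_block("scratch_store.h5", 0, 3)
print("doses read back from the container (individuals x SNPs):")
print(back.doses)
print(
    "0.239 came back as 0.24 (one-byte quantization at scale 100); "
    "the NA is the in-memory missing code 3.0."
)
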