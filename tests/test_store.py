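"""Storage layer: BED decoding, dosage text conversion, block reads."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import semigwas.store as store
from semigwas import (
    GenotypeBlock,
    MISSING_CODE,
    StoreMetadata,
    convert_row_per_person_text,
    decode_plink_bed,
    iterate_blocks,
    read_block,
    read_metadata,
)
from semigwas.store import BedFormatError

from conftest import make_store

BED_HEADER = b"\x6c\x1b\x01"


def reference_bed_table():
    """Exhaustive 256 x 4 dose table built directly from the published
    bit-pair convention, independently of the decoder's own table."""
    table = np.empty((256, 4))
    for byte in range(256):
        bits = [(byte >> k) & 1 for k in range(8)]
        for pos in range(4):
            lo, hi = bits[2 * pos], bits[2 * pos + 1]
            if (hi, lo) == (0, 0):
                table[byte, pos] = 2  # homozygous A1
            elif (hi, lo) == (1, 0):
                table[byte, pos] = 1  # heterozygous
            elif (hi, lo) == (1, 1):
                table[byte, pos] = 0  # homozygous A2
            else:  # (0, 1)
                table[byte, pos] = MISSING_CODE
    return table


def decode_all(payload, n_individuals, n_snps, **kw):
    blocks = list(decode_plink_bed(payload, n_individuals, n_snps, **kw))
    return np.concatenate([b.doses for b in blocks], axis=1)


class TestBedDecode:
    def test_exhaustive_byte_table(self):
        """Every byte value at every position decodes per the 2-bit convention."""
        expected = reference_bed_table()
        payload = BED_HEADER + bytes(range(256))
        doses = decode_all(payload, n_individuals=4, n_snps=256)
        np.testing.assert_array_equal(doses.T, expected)

    def test_examples_and_padding(self):
        # one byte of 00-pairs -> four doses of 2
        d = decode_all(BED_HEADER + b"\x00", 4, 1)
        np.testing.assert_array_equal(d.ravel(), [2, 2, 2, 2])
        # pairs (00, 10, 01, 11) from LSB: byte 0b11_01_10_00
        d = decode_all(BED_HEADER + bytes([0b11011000]), 4, 1)
        np.testing.assert_array_equal(d.ravel(), [2, 1, MISSING_CODE, 0])
        # padding bits beyond n_individuals are discarded
        d = decode_all(BED_HEADER + bytes([0b11011000]), 2, 1)
        np.testing.assert_array_equal(d.ravel(), [2, 1])

    def test_a2_orientation_flips_doses(self):
        d1 = decode_all(BED_HEADER + bytes([0b11011000]), 4, 1)
        d2 = decode_all(BED_HEADER + bytes([0b11011000]), 4, 1, allele_count="a2")
        keep = d1 != MISSING_CODE
        np.testing.assert_array_equal(d2[keep], 2 - d1[keep])
        assert d2[~keep] == MISSING_CODE

    @pytest.mark.parametrize(
        "payload, error_match",
        [
            (b"\x00\x00\x01\x00", "magic"),
            (b"\x6c\x1b\x00\x00", "individual-major"),
            (BED_HEADER + b"\x00", "truncated"),  # needs 2 bytes for n=5
            (BED_HEADER + b"\x00\x00\x00", "longer"),
        ],
    )
    def test_malformed_input(self, payload, error_match):
        with pytest.raises(BedFormatError, match=error_match):
            list(decode_plink_bed(payload, n_individuals=5, n_snps=1))

    @settings(derandomize=True, max_examples=25)
    @given(st.binary(min_size=1, max_size=64), st.integers(1, 4))
    def test_decode_agrees_with_reference_for_random_streams(self, body, n_ind):
        expected = reference_bed_table()
        doses = decode_all(BED_HEADER + body, n_ind, len(body))
        np.testing.assert_array_equal(
            doses, expected[np.frombuffer(body, np.uint8)][:, :n_ind].T
        )


class TestDosageText:
    def write_text(self, path, doses, ids=True):
        lines = []
        for i, row in enumerate(doses):
            prefix = f"ind{i} DOSE " if ids else ""
            lines.append(prefix + " ".join(f"{d:.3f}" for d in row))
        path.write_text("\n".join(lines) + "\n")

    def test_round_trip_within_quantization(self, tmp_path, rng):
        doses = rng.uniform(0, 2, size=(6, 10))
        text = tmp_path / "doses.txt"
        self.write_text(text, doses)
        meta = StoreMetadata(
            n_individuals=6, n_snps=10,
            snp_ids=[f"s{j}" for j in range(10)],
            individual_ids=[f"i{i}" for i in range(6)],
            chunk_snps=3, chunk_individuals=4,
        )
        out = tmp_path / "store.h5"
        convert_row_per_person_text(text, out, meta)
        got = read_block(out, 0, 10).doses
        # <= 0.005 (half of 1/scale) against the 3-decimal values in the
        # file, with float-representation slack at the exact boundary
        assert np.max(np.abs(got - np.round(doses, 3))) <= 0.005 + 1e-12

    def test_exact_scale_points_and_missing(self, tmp_path):
        text = tmp_path / "doses.txt"
        text.write_text("i0 D 1.000 0.239 NA\n")
        meta = StoreMetadata(
            n_individuals=1, n_snps=3, snp_ids=["a", "b", "c"],
            individual_ids=["i0"], chunk_snps=3, chunk_individuals=1,
        )
        out = tmp_path / "store.h5"
        convert_row_per_person_text(text, out, meta)
        got = read_block(out, 0, 3).doses.ravel()
        assert got[0] == 1.0
        assert got[1] == pytest.approx(0.24)
        assert got[2] == MISSING_CODE

    def test_bounded_memory_passes_match_single_pass(self, tmp_path, rng):
        doses = rng.uniform(0, 2, size=(9, 5))
        text = tmp_path / "doses.txt"
        self.write_text(text, doses)
        meta = dict(
            snp_ids=[f"s{j}" for j in range(5)],
            individual_ids=[f"i{i}" for i in range(9)],
            chunk_snps=2, chunk_individuals=3,
        )
        stores = []
        for ib in (1, 4, None):  # tiny blocks vs default single pass
            out = tmp_path / f"store_{ib}.h5"
            convert_row_per_person_text(
                text, out, StoreMetadata(n_individuals=9, n_snps=5, **meta),
                individual_block=ib,
            )
            stores.append(read_block(out, 0, 5).doses)
        np.testing.assert_array_equal(stores[0], stores[2])
        np.testing.assert_array_equal(stores[1], stores[2])

    @pytest.mark.parametrize(
        "bad_line, match",
        [
            ("i0 D 1.0 2.5 0.0", r"outside \[0, 2\]"),
            ("i0 D 1.0 0.5", "expected 3 dose fields"),
            ("i0 D 1.0 frog 0.0", "not a number"),
        ],
    )
    def test_bad_records_are_named(self, tmp_path, bad_line, match):
        text = tmp_path / "doses.txt"
        text.write_text(bad_line + "\n")
        meta = StoreMetadata(
            n_individuals=1, n_snps=3, snp_ids=list("abc"),
            individual_ids=["i0"], chunk_snps=3, chunk_individuals=1,
        )
        with pytest.raises(ValueError, match=match):
            convert_row_per_person_text(text, tmp_path / "s.h5", meta)


class TestBlockReads:
    def test_metadata_round_trip(self, small_store):
        path, _, meta = small_store
        got = read_metadata(path)
        assert (got.n_individuals, got.n_snps) == (6, 10)
        assert got.snp_ids == meta.snp_ids
        assert got.individual_ids == meta.individual_ids
        assert got.encoding == {"scale": 100, "missing_sentinel": 255}
        assert got.layout == "snp-major"

    def test_full_read_matches_source(self, small_store):
        path, doses, _ = small_store
        np.testing.assert_allclose(read_block(path, 0, 10).doses, doses, atol=0.005)

    def test_adjacent_blocks_concatenate_to_covering_block(self, small_store):
        path, _, _ = small_store
        whole = read_block(path, 0, 10)
        left, right = read_block(path, 0, 6), read_block(path, 6, 10)
        np.testing.assert_array_equal(
            np.concatenate([left.doses, right.doses], axis=1), whole.doses
        )
        assert left.snp_ids + right.snp_ids == whole.snp_ids

    def test_repeated_reads_identical(self, small_store):
        path, _, _ = small_store
        np.testing.assert_array_equal(
            read_block(path, 2, 7).doses, read_block(path, 2, 7).doses
        )

    @pytest.mark.parametrize("lo,hi", [(3, 3), (-1, 5), (0, 11), (9, 5)])
    def test_bad_ranges_rejected(self, small_store, lo, hi):
        with pytest.raises(IndexError):
            read_block(small_store[0], lo, hi)

    def test_missing_container(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_block(tmp_path / "nope.h5", 0, 1)

    @pytest.mark.parametrize("block_size,widths", [(4, [4, 4, 2]), (10, [10]), (99, [10])])
    def test_iterate_blocks_widths(self, small_store, block_size, widths):
        blocks = list(iterate_blocks(small_store[0], block_size))
        assert [b.n_snps for b in blocks] == widths
        assert [s for b in blocks for s in b.snp_ids] == small_store[2].snp_ids

    def test_iterate_blocks_rejects_bad_size(self, small_store):
        with pytest.raises(ValueError):
            list(iterate_blocks(small_store[0], 0))


class TestGenotypeBlockInvariants:
    def test_out_of_range_dose_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 2\]"):
            GenotypeBlock(doses=np.array([[2.5]]), snp_offset=0, snp_ids=["a"])

    def test_id_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            GenotypeBlock(doses=np.ones((2, 2)), snp_offset=0, snp_ids=["a"])
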