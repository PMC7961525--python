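import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wce3dct import entropy
from wce3dct.bayer import blocks_from_image
from wce3dct.entropy import (
    AC_CODE,
    DC_CODE,
    BitReader,
    BitWriter,
    ScanOrder,
    decode_ac,
    decode_dc,
    decode_image,
    default_scan_order,
    derive_zigzag,
    encode_ac,
    encode_dc,
    encode_image,
    payload_bit_length,
    zigzag_scan,
    zigzag_unscan,
)
from wce3dct.errors import (
    BadMagicError,
    ConfigurationError,
    InputShapeError,
    TruncatedStreamError,
)
from wce3dct.quantize import default_qtable
from wce3dct.synthetic import default_scan_corpus_params, generate_wce
from wce3dct.transform import dct3d_oracle_batch


class TestBitIO:
    @given(st.lists(st.tuples(st.integers(0, 2**16 - 1), st.integers(1, 17)), max_size=50))
    def test_roundtrip(self, fields):
        w = BitWriter()
        for value, nbits in fields:
            w.write(value & ((1 << nbits) - 1), nbits)
        r = BitReader(w.getvalue())
        for value, nbits in fields:
            assert r.read(nbits) == value & ((1 << nbits) - 1)

    def test_reading_past_end_raises(self):
        r = BitReader(b"\xff")
        r.read(8)
        with pytest.raises(TruncatedStreamError):
            r.read1()


class TestHuffmanTables:
    @pytest.mark.parametrize("table", [DC_CODE, AC_CODE])
    def test_prefix_free(self, table):
        codes = sorted(
            (f"{code:0{length}b}" for code, length in table.values()), key=len
        )
        for i, short in enumerate(codes):
            for long in codes[i + 1 :]:
                assert not long.startswith(short) or long == short
        assert len(set(codes)) == len(codes)

    @pytest.mark.parametrize("table", [DC_CODE, AC_CODE])
    def test_kraft_equality(self, table):
        # a Huffman code over all symbols is complete
        assert sum(2.0 ** -length for _, length in table.values()) == pytest.approx(1.0)


class TestScanOrder:
    def test_default_is_valid_permutation(self):
        order = default_scan_order()
        assert len(set(order.order)) == 60
        assert all(not (i == 0 and j == 0) for i, j, _ in order.order)

    def test_default_matches_regeneration_from_seeded_corpus(self):
        """Guard: the frozen fixture is exactly what its corpus derives."""
        spectra = []
        for p in default_scan_corpus_params():
            _, mosaic = generate_wce(p)
            blocks = blocks_from_image(mosaic).astype(np.float64) - 128.0
            spectra.append(dct3d_oracle_batch(blocks))
        derived = derive_zigzag(np.concatenate(spectra))
        assert derived.order == default_scan_order().order

    def test_dominant_position_scanned_first(self, rng):
        spectra = rng.normal(0, 1, (50, 4, 4, 4))
        spectra[:, 1, 0, 0] = 500.0
        assert derive_zigzag(spectra).order[0] == (1, 0, 0)

    def test_random_corpus_yields_valid_permutation(self, rng):
        order = derive_zigzag(rng.normal(0, 1, (30, 4, 4, 4)))
        assert sorted(order.order) == sorted(entropy.AC_POSITIONS)

    def test_low_frequency_positions_lead(self):
        """All 7 AC positions with i+j+k <= 2 sit in the first 10 slots."""
        low = {p for p in entropy.AC_POSITIONS if sum(p) <= 2}
        assert len(low) == 7
        assert low <= set(default_scan_order().order[:10])

    def test_empty_corpus_rejected(self):
        with pytest.raises(InputShapeError):
            derive_zigzag(np.zeros((0, 4, 4, 4)))

    def test_invalid_permutation_rejected(self):
        order = list(default_scan_order().order)
        order[0] = (0, 0, 1)  # a DC position
        with pytest.raises(ConfigurationError):
            ScanOrder(tuple(order))

    def test_byte_roundtrip(self):
        order = default_scan_order()
        assert ScanOrder.from_bytes(order.to_bytes()).order == order.order


class TestZigzag:
    def test_all_zero_block(self):
        dc, ac = zigzag_scan(np.zeros((4, 4, 4), dtype=np.int64), default_scan_order())
        assert (dc == 0).all() and (ac == 0).all() and ac.shape == (60,)

    def test_roundtrip(self, rng):
        order = default_scan_order()
        for _ in range(20):
            lv = rng.integers(-50, 50, (4, 4, 4))
            dc, ac = zigzag_scan(lv, order)
            assert np.array_equal(zigzag_unscan(dc, ac, order), lv)

    def test_first_scan_position(self):
        order = default_scan_order()
        lv = np.zeros((4, 4, 4), dtype=np.int64)
        lv[order.order[0]] = 9
        _, ac = zigzag_scan(lv, order)
        assert ac[0] == 9 and (ac[1:] == 0).all()

    def test_dc_taken_in_plane_order(self):
        lv = np.zeros((4, 4, 4), dtype=np.int64)
        lv[0, 0, :] = [1, 2, 3, 4]
        dc, _ = zigzag_scan(lv, default_scan_order())
        assert list(dc) == [1, 2, 3, 4]


class TestDcCoding:
    def test_zero_diff_uses_category_zero(self):
        w = BitWriter()
        encode_dc(w, np.array([5, 5, 5, 5]), np.array([5, 5, 5, 5]))
        assert w.bit_length == 4 * DC_CODE[0][1]

    def test_amplitude_sign_convention(self):
        # +1 -> category 1, amplitude bit 1; -1 -> category 1, amplitude bit 0
        for diff, bit in [(1, 1), (-1, 0)]:
            w = BitWriter()
            encode_dc(w, np.array([diff, 0, 0, 0]), np.zeros(4, dtype=np.int64))
            r = BitReader(w.getvalue())
            r.read(DC_CODE[1][1])
            assert r.read1() == bit

    def test_roundtrip_chain(self, rng):
        w = BitWriter()
        pred = np.zeros(4, dtype=np.int64)
        sequence = rng.integers(-200, 200, (30, 4))
        for dc in sequence:
            pred = encode_dc(w, dc, pred)
        r = BitReader(w.getvalue())
        pred = np.zeros(4, dtype=np.int64)
        for dc in sequence:
            got, pred = decode_dc(r, pred)
            assert np.array_equal(got, dc)


class TestAcCoding:
    def test_all_zeros_is_single_eob(self):
        w = BitWriter()
        encode_ac(w, np.zeros(60, dtype=np.int64))
        assert w.bit_length == AC_CODE[entropy.EOB][1]

    def test_single_leading_coefficient(self):
        ac = np.zeros(60, dtype=np.int64)
        ac[0] = 5  # size 3
        w = BitWriter()
        encode_ac(w, ac)
        expected = AC_CODE[(0, 3)][1] + 3 + AC_CODE[entropy.EOB][1]
        assert w.bit_length == expected

    @given(
        st.lists(
            st.tuples(st.integers(0, 59), st.integers(-2000, 2000)), max_size=12
        )
    )
    def test_roundtrip_sparse(self, entries):
        ac = np.zeros(60, dtype=np.int64)
        for pos, val in entries:
            ac[pos] = val
        w = BitWriter()
        encode_ac(w, ac)
        assert np.array_equal(decode_ac(BitReader(w.getvalue())), ac)

    def test_long_zero_runs_use_zrl(self, rng):
        ac = np.zeros(60, dtype=np.int64)
        ac[40] = 3  # run of 40 zeros -> 2 ZRL + (8, size)
        w = BitWriter()
        encode_ac(w, ac)
        assert np.array_equal(decode_ac(BitReader(w.getvalue())), ac)

    def test_sparser_never_costs_more(self):
        dense = np.zeros(60, dtype=np.int64)
        dense[:10] = 7
        sparse = dense.copy()
        sparse[5:] = 0
        wd, ws = BitWriter(), BitWriter()
        encode_ac(wd, dense)
        encode_ac(ws, sparse)
        assert ws.bit_length <= wd.bit_length


class TestImageContainer:
    def _random_levels(self, rng, n):
        levels = np.zeros((n, 4, 4, 4), dtype=np.int64)
        mask = rng.random((n, 4, 4, 4)) < 0.15
        levels[mask] = rng.integers(-400, 400, int(mask.sum()))
        return levels

    def test_roundtrip_identity(self, rng):
        levels = self._random_levels(rng, 24)
        q, order = default_qtable(), default_scan_order()
        stream = encode_image(levels, q, order, 32, 48)
        out = decode_image(stream)
        assert np.array_equal(out["levels"], levels)
        assert out["width"] == 32 and out["height"] == 48
        assert out["level_shift"] is True
        assert np.array_equal(out["qtable"].steps, q.steps)
        assert out["scan_order"].order == order.order

    def test_header_qtable_bytes_exact(self, rng):
        q, order = default_qtable(), default_scan_order()
        stream = encode_image(self._random_levels(rng, 1), q, order, 8, 8)
        assert stream[10:74] == q.to_bytes()

    def test_bad_magic(self):
        with pytest.raises(BadMagicError):
            decode_image(b"XXXX" + bytes(200))

    def test_truncated_stream(self, rng):
        q, order = default_qtable(), default_scan_order()
        stream = encode_image(self._random_levels(rng, 24), q, order, 32, 48)
        with pytest.raises(TruncatedStreamError):
            decode_image(stream[: len(stream) - 8])

    def test_bit_accounting(self, rng):
        """Stream size = header + payload bits (+ final byte padding)."""
        levels = self._random_levels(rng, 24)
        q, order = default_qtable(), default_scan_order()
        stream = encode_image(levels, q, order, 32, 48)
        payload = payload_bit_length(levels, order)
        assert 8 * len(stream) - 8 * entropy.HEADER_BYTES - payload in range(0, 8)

    def test_all_zero_image_collapses(self):
        """A zero-level 480x480 image compresses below 3% of raw size."""
        levels = np.zeros((3600, 4, 4, 4), dtype=np.int64)
        stream = encode_image(levels, default_qtable(), default_scan_order(), 480, 480)
        assert 8 * len(stream) < 0.03 * 480 * 480 * 8
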