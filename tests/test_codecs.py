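"""Generic codec selection and the acgt/domqual/hapmat specific codecs."""
import lzma
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcol import codecs


# -- selection ---------------------------------------------------------------


def test_select_random_bytes_store():
    rng = np.random.default_rng(0)
    sample = rng.integers(0, 256, 100 * 1024, dtype=np.uint8).tobytes()
    codec, ratio, _ = codecs.select_codec(sample)
    assert codec == codecs.STORE


def test_select_homopolymer_real_codec():
    sample = b"A" * (100 * 1024)
    codec, ratio, _ = codecs.select_codec(sample)
    assert codec != codecs.STORE
    assert ratio > 100


def test_select_empty_store():
    assert codecs.select_codec(b"")[0] == codecs.STORE


def test_selection_is_deterministic():
    sample = (b"the quick brown fox " * 3000)[:100 * 1024]
    first = codecs.select_codec(sample)[0]
    for _ in range(3):
        assert codecs.select_codec(sample)[0] == first


@pytest.mark.parametrize("codec", codecs.GENERIC)
def test_generic_roundtrip(codec):
    data = b"some not very random data " * 100
    assert codecs.generic_decode(codec, codecs.generic_encode(codec, data)) == data


# -- acgt --------------------------------------------------------------------


def test_acgt_hand_packed():
    packed, xcgt = codecs.acgt_encode(b"ACGT")
    assert packed == bytes([0b00011011])
    assert xcgt == b""


def test_acgt_exception_stream():
    packed, xcgt = codecs.acgt_encode(b"ACGN")
    assert packed == codecs.acgt_encode(b"ACGA")[0]
    assert codecs.acgt_decode(packed, xcgt, 4) == b"ACGN"


def test_acgt_empty():
    assert codecs.acgt_encode(b"") == (b"", b"")
    assert codecs.acgt_decode(b"", b"", 0) == b""


def test_acgt_packing_density():
    for n in (1, 4, 5, 403):
        seq = (b"ACGT" * (n // 4 + 1))[:n]
        packed, xcgt = codecs.acgt_encode(seq)
        assert len(packed) == math.ceil(n / 4)
        assert xcgt == b""


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.binary(max_size=200))
def test_acgt_bijective(seq):
    packed, xcgt = codecs.acgt_encode(seq)
    assert codecs.acgt_decode(packed, xcgt, len(seq)) == seq


# -- domqual -----------------------------------------------------------------


def test_domqual_hand_trace():
    payload = codecs.domqual_encode([b"FFAF"], ord("F"))
    assert codecs.domqual_decode(payload) == [b"FFAF"]
    import lzma as _l
    raw = _l.decompress(payload)
    d = raw[0]
    assert d == ord("F")
    # header: dominant, n_strings=1, runs_len; runs: strlen=4, run=2, run=1; exc 'A'
    assert raw[1] == 1
    assert raw[-1] == ord("A")


def test_domqual_uniform_tiny():
    quals = [b"F" * 100] * 1000
    payload = codecs.domqual_encode(quals, ord("F"))
    assert len(payload) < 0.03 * sum(len(q) for q in quals)
    assert codecs.domqual_decode(payload) == quals


def test_domqual_empty_list():
    assert codecs.domqual_decode(codecs.domqual_encode([], ord("F"))) == []


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.lists(st.binary(min_size=0, max_size=50).map(
    lambda b: bytes(33 + (x % 93) for x in b)), max_size=10))
def test_domqual_bijective(quals):
    dom = codecs.domqual_pick_dominant(quals)
    assert codecs.domqual_decode(codecs.domqual_encode(quals, dom)) == quals


def test_domqual_dominant_pick():
    assert codecs.domqual_pick_dominant([b"FFFFIIF", b"FF"]) == ord("F")


# -- hapmat ------------------------------------------------------------------


def test_hapmat_all_zeros():
    m = np.zeros((6, 9), dtype=np.uint8)
    out = codecs.hapmat_decode(codecs.hapmat_encode(m))
    assert np.array_equal(out, m)


def test_hapmat_greedy_places_identical_rows_adjacent():
    m = np.array([[0, 0, 1, 1],
                  [1, 1, 0, 0],
                  [0, 0, 1, 1],
                  [1, 1, 0, 0]], dtype=np.uint8)
    order = codecs.hapmat_order(m).tolist()
    # start at row 0; row 2 is identical (distance 0) so it must come next,
    # then rows 1 and 3 pair up
    assert order == [0, 2, 1, 3]


def test_hapmat_beats_unpermuted_lzma_text():
    rng = np.random.default_rng(7)
    m = (rng.random((100, 500)) < 0.05).astype(np.uint8)
    encoded = codecs.hapmat_encode(m)
    text = b"\n".join(b"".join(b"%d" % v for v in row) for row in m)
    assert len(encoded) < len(lzma.compress(text, preset=6))


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.integers(1, 12), st.integers(1, 20), st.integers(0, 2**31 - 1))
def test_hapmat_bijective(n_hap, n_var, seed):
    rng = np.random.default_rng(seed)
    m = rng.choice(np.array([0, 1, 2, 255], dtype=np.uint8),
                   size=(n_hap, n_var))
    assert np.array_equal(codecs.hapmat_decode(codecs.hapmat_encode(m)), m)
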