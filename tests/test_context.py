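"""Context/dictionary/b250 machinery and the clone/merge lifecycle."""
import pytest

from gcol.container import Container, item
from gcol.context import (Context, VBlock, ZState, clone_contexts,
                          merge_contexts, seg_delta_vs, seg_id, seg_pos,
                          seg_snip)
from gcol.snips import decode_snip


def test_seg_snip_dedup():
    c = Context("FILTER")
    assert seg_snip(c, b"PASS") == 0
    assert seg_snip(c, b"PASS") == 0
    assert len(c.dict_list) == 1
    assert c.b250 == [0, 0]


def test_seg_snip_order():
    c = Context("X")
    for payload in (b"A", b"B", b"A"):
        seg_snip(c, payload)
    assert [decode_snip(s)[1] for s in c.dict_list] == [b"A", b"B"]
    assert c.b250 == [0, 1, 0]


def test_seg_snip_many_distinct():
    c = Context("X")
    payloads = [b"v%d" % i for i in range(10_000)]
    for p in payloads:
        seg_snip(c, p)
    assert len(c.dict_list) == 10_000
    assert len(set(c.b250)) == 10_000
    # brute-force comparison against an independent set
    assert {decode_snip(s)[1] for s in c.dict_list} == set(payloads)


def test_seg_pos_deltas():
    c = Context("POS")
    anchor = 0
    for p in (b"100", b"105", b"105"):
        anchor = seg_pos(c, p, anchor)
    payloads = [decode_snip(c.dict_list[i])[1] for i in c.b250]
    assert payloads == [b"\x00100", b"\x005", b"\x000"]


def test_seg_pos_descending_and_large():
    c = Context("POS")
    anchor = seg_pos(c, b"200", 0)
    anchor = seg_pos(c, b"150", anchor)
    assert decode_snip(c.dict_list[c.b250[-1]])[1] == b"\x00-50"
    anchor = seg_pos(c, b"1000000000", anchor)
    anchor = seg_pos(c, b"1000000001", anchor)
    assert decode_snip(c.dict_list[c.b250[-1]])[1] == b"\x001"


def test_seg_id_forms():
    c = Context("ID")
    seg_id(c, b"rs23424")
    assert c.local == [(23424, 5)]
    seg_id(c, b"rs007")
    assert c.local[-1] == (7, 3)
    seg_id(c, b".")
    assert decode_snip(c.dict_list[c.b250[-1]]) == (0, b".")
    seg_id(c, b"rs99999999999")  # >= 2**32 -> verbatim
    assert decode_snip(c.dict_list[c.b250[-1]])[1] == b"rs99999999999"


def test_seg_delta_vs_other_context():
    c = Context("PNEXT")
    seg_delta_vs(c, b"1150", "POS", 1000)
    assert decode_snip(c.dict_list[0])[1] == b"POS\x00150"


def _merge_one(zstate, payload_lists, name="X"):
    """Segment payload lists into consecutive vblocks and merge each."""
    for i, payloads in enumerate(payload_lists, start=zstate.merged_vblocks + 1):
        vb = VBlock(i)
        clone_contexts(zstate, vb)
        c = vb.ctx(name)
        for p in payloads:
            c.seg_snip(p)
        merge_contexts(zstate, vb)
        yield vb


def test_clone_preserves_indices():
    z = ZState()
    # duplicated within their vblock so the singleton rule does not divert them
    vbs = list(_merge_one(z, [[b"alpha", b"alpha", b"beta", b"beta"],
                              [b"beta"], [b"alpha"]]))
    # snip added in vblock 1 keeps its global index when used in vblock 3
    assert vbs[0].contexts["X"].b250 == [0, 0, 1, 1]
    assert vbs[1].contexts["X"].b250 == [1]
    assert vbs[2].contexts["X"].b250 == [0]


def test_merge_no_new_entries_for_reused_snips():
    z = ZState()
    list(_merge_one(z, [[b"a", b"a", b"b", b"b"]]))
    size1 = len(z.contexts["X"].dict_list)
    list(_merge_one(z, [[b"a", b"b", b"a"]]))
    assert len(z.contexts["X"].dict_list) == size1


def test_merge_disjoint_union_in_vblock_order():
    z = ZState()
    list(_merge_one(z, [[b"a", b"a"], [b"b", b"b"]]))
    stored = [decode_snip(s)[1] for s in z.contexts["X"].dict_list]
    assert stored == [b"a", b"b"]


def test_singleton_moved_to_local():
    z = ZState()
    (vb,) = _merge_one(z, [[b"unique1", b"twice", b"twice", b"unique2"]])
    zc = z.contexts["X"]
    payloads = [decode_snip(s) for s in zc.dict_list]
    # dictionary holds only the repeated snip and the LOOKUP escape entry
    assert (0, b"twice") in payloads
    assert (1, b"") in payloads          # LOOKUP_LOCAL
    assert all(p not in (b"unique1", b"unique2") for _, p in payloads)
    assert vb.contexts["X"].local == [b"unique1", b"unique2"]


def test_singleton_not_applied_when_seen_twice():
    z = ZState()
    list(_merge_one(z, [[b"solo"]]))            # singleton in vblock 1
    list(_merge_one(z, [[b"solo"]]))            # still absent globally -> again
    # a snip seen twice within one vblock merges normally
    list(_merge_one(z, [[b"pair", b"pair"]]))
    stored = [decode_snip(s)[1] for s in z.contexts["X"].dict_list]
    assert b"pair" in stored
    assert b"solo" not in stored


def test_empty_global_clone():
    z = ZState()
    vb = VBlock(1)
    clone_contexts(z, vb)
    assert vb.contexts == {}


def test_alias_context_stores_nothing():
    vb = VBlock(1)
    target = vb.ctx("@CIGAR")
    alias = vb.ctx("MC:Z", alias_of="@CIGAR")
    assert alias is target
    vb.ctx("MC:Z").seg_snip(b"100M")
    assert vb.contexts.keys() == {"@CIGAR"}
    assert vb.aliases == {"MC:Z": "@CIGAR"}


def test_container_item_bound():
    with pytest.raises(ValueError):
        Container(tuple(item(f"C{i}") for i in range(256)))
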