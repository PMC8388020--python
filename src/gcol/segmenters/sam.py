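"""SAM (text dialect) segmenter.

Aligned records (RNAME, POS and CIGAR all present) encode their sequence
against the reference via the CIGAR-driven bitmap; other records go through
the aligner.  CIGAR strings live in a context named ``@CIGAR``; the optional
tags MC:Z and OC:Z carry CIGAR-shaped data and are declared aliases of that
context so all three share one dictionary.  An alternate toplevel container
(``TOP2FQ``) carrying translator tags reconstructs the archive as FASTQ:
sequence/quality are reverse-complemented/reversed for reverse-strand
records and secondary/supplementary records are dropped.
"""
from __future__ import annotations

from .. import codecs
from .. import context as ctxmod
from ..container import Container, item
from ..context import seg_delta_vs, seg_pos
from ..errors import FormatError
from ..reconstruct import register_repeat_filter, register_translator
from ..reference import (encode_seq_aligned, encode_seq_missing,
                         encode_seq_unaligned, encode_seq_verbatim, revcomp)
from .base import Segmenter, register, seg_tokenized

_FIELD_ITEMS = ("QNAME", "FLAG", "RNAME", "POS", "MAPQ", "@CIGAR",
                "RNEXT", "PNEXT", "TLEN")

_CIGAR_ALIASES = ("MC:Z", "OC:Z")

FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@register
class SamSegmenter(Segmenter):
    name = "SAM"
    extensions = (".sam",)
    ra_ctxs = ("RNAME", "POS")

    @classmethod
    def sniff(cls, head: bytes) -> bool:
        if head[:4] in (b"@HD\t", b"@SQ\t", b"@RG\t", b"@PG\t", b"@CO\t"):
            return True
        first = head.split(b"\n", 1)[0]
        f = first.split(b"\t")
        return len(f) >= 11 and f[1].isdigit() and f[3].isdigit()

    @classmethod
    def split_header(cls, data: bytes) -> tuple[bytes, bytes]:
        pos = 0
        while pos < len(data) and data[pos:pos + 1] == b"@":
            nl = data.find(b"\n", pos)
            if nl < 0:
                return data, b""
            pos = nl + 1
        return data[:pos], data[pos:]

    def seg_record(self, vb, record: bytes, line_index: int) -> None:
        f = record[:-1].split(b"\t")
        if len(f) < 11:
            raise FormatError(
                f"SAM: fewer than 11 fields at alignment line {line_index + 1}")
        qname, flag, rname, pos, mapq, cigar, rnext, pnext, tlen, seq, qual = f[:11]

        seg_tokenized(vb, "QNAME", qname, self.anchors)
        vb.ctx("FLAG").seg_snip(flag)
        vb.ctx("RNAME").seg_snip(rname)
        self.anchors["POS"] = seg_pos(vb.ctx("POS"), pos, self.anchors.get("POS", 0))
        vb.ctx("MAPQ").seg_snip(mapq)
        vb.ctx("@CIGAR").seg_snip(cigar)
        vb.ctx("RNEXT").seg_snip(rnext)
        if pos.isdigit():
            seg_delta_vs(vb.ctx("PNEXT"), pnext, "POS", int(pos))
        else:
            vb.ctx("PNEXT").seg_snip(pnext)
        vb.ctx("TLEN").seg_snip(tlen)

        aligned = rname != b"*" and pos.isdigit() and int(pos) > 0 and cigar != b"*"
        if seq == b"*":
            encode_seq_missing(vb)
        elif aligned and self.ref is not None:
            encode_seq_aligned(vb, seq, cigar, rname, int(pos), self.ref)
        elif self.ref is not None:
            encode_seq_unaligned(vb, seq, self.ref)
        else:
            encode_seq_verbatim(vb, seq)
        if seq != b"*" and qual != b"*" and len(qual) != len(seq):
            raise FormatError(
                f"SAM: SEQ/QUAL length mismatch at line {line_index + 1}")

        vb.ctx("QUAL", ctxmod.LT_TEXT, forced_codec=codecs.DOMQUAL).add_local(qual)

        tag_items = []
        for tagf in f[11:]:
            if len(tagf) < 6 or tagf[2:3] != b":" or tagf[4:5] != b":":
                raise FormatError(
                    f"SAM: malformed optional tag at line {line_index + 1}")
            key = tagf[:4].decode("latin-1")
            if key in _CIGAR_ALIASES:
                tctx = vb.ctx(key, alias_of="@CIGAR")
            else:
                tctx = vb.ctx(key)
            tctx.seg_snip(tagf[5:])
            tag_items.append(item(key, prefix=b"\t" + tagf[:5]))
        tags = vb.ctx("TAGS")
        if tag_items:
            tags.seg_container(Container(tuple(tag_items)))
        else:
            tags.seg_snip(b"")

        if aligned:
            vb.note_position(rname, int(pos))

    def end_vblock(self, vb) -> None:
        items = [item(n, sep=b"\t") for n in _FIELD_ITEMS]
        items.append(item("SQBITMAP", sep=b"\t"))
        items.append(item("QUAL"))
        items.append(item("TAGS", sep=b"\n"))
        vb.ctx("TOPLEVEL").seg_container(
            Container(tuple(items), repeats=vb.line_count))
        # alternate toplevel: SAM -> FASTQ translation
        fq_items = [item("QNAME", prefix=b"@", sep=b"\n")]
        fq_items += [item(n, translator="drop")
                     for n in _FIELD_ITEMS if n != "QNAME"]
        fq_items.append(item("SQBITMAP", translator="sam2fq_seq", sep=b"\n+\n"))
        fq_items.append(item("QUAL", translator="sam2fq_qual", sep=b"\n"))
        fq_items.append(item("TAGS", translator="drop"))
        vb.ctx("TOP2FQ").seg_container(
            Container(tuple(fq_items), repeats=vb.line_count,
                      repeat_filter="sam_primary"))


# -- translators -------------------------------------------------------------


def _t_drop(recon, val: bytes) -> bytes:
    return b""


def _t_seq_fq(recon, val: bytes) -> bytes:
    return revcomp(val) if recon.last_int.get("FLAG", 0) & FLAG_REVERSE else val


def _t_qual_fq(recon, val: bytes) -> bytes:
    return val[::-1] if recon.last_int.get("FLAG", 0) & FLAG_REVERSE else val


def _f_primary(recon) -> bool:
    return not recon.last_int.get("FLAG", 0) & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)


register_translator("drop", _t_drop)
register_translator("sam2fq_seq", _t_seq_fq)
register_translator("sam2fq_qual", _t_qual_fq)
register_repeat_filter("sam_primary", _f_primary)
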