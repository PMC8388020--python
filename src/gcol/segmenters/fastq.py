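"""FASTQ segmenter.

A logical line is four textual lines: title, sequence, '+', quality.  The
title splits into a tokenised read name (QNAME) and an optional description;
the sequence goes through the reference module's unaligned path (aligner +
SQBITMAP/NONREF/GPOS/STRAND) or, without a reference, to NONREF via the acgt
codec; qualities are stored for the domqual codec.  In paired mode, mate-2
read names identical to mate-1 become a copy snip and mate-2 gpos values are
stored as signed deltas vs. the mate-1 placement of the same record.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .. import codecs
from .. import context as ctxmod
from ..container import Container, item
from ..errors import FormatError
from ..reconstruct import register_special
from ..reference import (encode_seq_unaligned, encode_seq_verbatim)
from ..snips import OP_SPECIAL
from .base import Segmenter, register, seg_tokenized


@dataclass
class PairState:
    """Mate-1 per-record state replayed while handling mate-2."""
    qnames: list = field(default_factory=list)
    gpos: dict = field(default_factory=dict)


@register
class FastqSegmenter(Segmenter):
    name = "FASTQ"
    extensions = (".fastq", ".fq")
    record_lines = 4

    def __init__(self, zstate, opts):
        super().__init__(zstate, opts)
        self.pair_in: PairState | None = opts.pair_in
        self.pair_out: PairState | None = PairState() if opts.collect_pair else None

    @classmethod
    def sniff(cls, head: bytes) -> bool:
        if not head.startswith(b"@"):
            return False
        lines = head.split(b"\n", 4)
        return len(lines) >= 3 and lines[2][:1] == b"+"

    def seg_record(self, vb, record: bytes, line_index: int) -> None:
        lines = record[:-1].split(b"\n")
        if len(lines) != 4 or not lines[0].startswith(b"@") \
                or not lines[2].startswith(b"+"):
            raise FormatError(f"FASTQ: malformed record at read {line_index + 1}")
        title, seq, plus, qual = lines
        if len(seq) != len(qual):
            raise FormatError(
                f"FASTQ: SEQ/QUAL length mismatch at read {line_index + 1}")
        body = title[1:]
        sp = body.find(b" ")
        if sp >= 0:
            qname, desc = body[:sp], body[sp:]
        else:
            qname, desc = body, b""

        qctx = vb.ctx("QNAME")
        mate_q = None
        if self.pair_in is not None and line_index < len(self.pair_in.qnames):
            mate_q = self.pair_in.qnames[line_index]
        if mate_q is not None and mate_q == qname:
            qctx.seg_snip(b"P", OP_SPECIAL)
        else:
            seg_tokenized(vb, "QNAME", qname, self.anchors)
        vb.ctx("DESC").seg_snip(desc)

        pair_gpos = self.pair_in.gpos.get(line_index) if self.pair_in else None
        if self.ref is not None:
            gpos, _ = encode_seq_unaligned(
                vb, seq, self.ref,
                pair_gpos=pair_gpos, pair_has=self.pair_in is not None)
        else:
            encode_seq_verbatim(vb, seq)
            gpos = None
        if self.pair_out is not None:
            self.pair_out.qnames.append(qname)
            if gpos is not None:
                self.pair_out.gpos[line_index] = gpos

        pctx = vb.ctx("PLUS")
        if plus == b"+":
            pctx.seg_snip(b"+")
        elif plus[1:] == body:
            pctx.seg_snip(b"C", OP_SPECIAL)
        else:
            pctx.seg_snip(plus)

        qualctx = vb.ctx("QUAL", ctxmod.LT_TEXT, forced_codec=codecs.DOMQUAL)
        qualctx.add_local(qual)

    def end_vblock(self, vb) -> None:
        top = Container(
            (
                item("QNAME", prefix=b"@"),
                item("DESC", sep=b"\n"),
                item("SQBITMAP", sep=b"\n"),
                item("PLUS", sep=b"\n"),
                item("QUAL", sep=b"\n"),
            ),
            repeats=vb.line_count,
        )
        vb.ctx("TOPLEVEL").seg_container(top)


def _special_pair_qname(recon, ctx, payload):
    if recon.pair_state is None or recon.line_index >= len(recon.pair_state.qnames):
        from ..errors import CorruptArchive
        raise CorruptArchive("paired archive: mate-1 state unavailable")
    return recon.pair_state.qnames[recon.line_index]


def _special_plus_copy(recon, ctx, payload):
    return b"+" + recon.last_text.get("QNAME", b"") + recon.last_text.get("DESC", b"")


register_special(b"P", _special_pair_qname)
register_special(b"C", _special_plus_copy)
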