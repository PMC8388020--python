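"""VCF segmenter.

Fixed columns go to per-field contexts (CHROM dictionary, POS deltas, ID via
the prefix+number algorithm); INFO splits on ';' into per-key contexts under
a per-line container; when a reference genome is supplied and REF matches it
at POS, the bases are replaced by a lookup snip.  FORMAT/GT genotypes across
samples accumulate into the vblock haplotype matrix (hapmat codec), with
per-genotype ploidy and phase separators recorded exactly; other FORMAT keys
get per-key contexts inside a per-sample container.
"""
from __future__ import annotations

import numpy as np

from .. import codecs
from .. import context as ctxmod
from ..container import Container, item
from ..context import seg_id, seg_pos
from ..errors import CorruptArchive, FormatError
from ..reconstruct import register_special
from ..snips import OP_SPECIAL
from .base import Segmenter, register

MISSING = 255  # sentinel: missing allele '.' and padding beyond ploidy


@register
class VcfSegmenter(Segmenter):
    name = "VCF"
    extensions = (".vcf",)
    ra_ctxs = ("CHROM", "POS")

    def __init__(self, zstate, opts):
        super().__init__(zstate, opts)
        self.samples: list[str] = []
        self.gt_lines: list | None = None

    @classmethod
    def sniff(cls, head: bytes) -> bool:
        return head.startswith(b"##fileformat=VCF")

    @classmethod
    def split_header(cls, data: bytes) -> tuple[bytes, bytes]:
        pos = 0
        while pos < len(data) and data[pos:pos + 1] == b"#":
            nl = data.find(b"\n", pos)
            if nl < 0:
                return data, b""
            pos = nl + 1
        return data[:pos], data[pos:]

    def parse_header(self, header: bytes) -> None:
        for line in header.splitlines():
            if line.startswith(b"#CHROM"):
                cols = line.split(b"\t")
                self.samples = [c.decode() for c in cols[9:]]

    def begin_vblock(self, vb) -> None:
        super().begin_vblock(vb)
        self.gt_lines = []

    def seg_record(self, vb, record: bytes, line_index: int) -> None:
        f = record[:-1].split(b"\t")
        if len(f) < 8:
            raise FormatError(f"VCF: fewer than 8 columns at line {line_index + 1}")
        n_samples = len(self.samples)
        if n_samples and len(f) != 9 + n_samples:
            raise FormatError(
                f"VCF: expected {9 + n_samples} columns, found {len(f)} "
                f"at line {line_index + 1}")
        chrom, pos, vid, ref_a, alt, qual, filt, info = f[:8]

        vb.ctx("CHROM").seg_snip(chrom)
        self.anchors["POS"] = seg_pos(vb.ctx("POS"), pos,
                                      self.anchors.get("POS", 0))
        seg_id(vb.ctx("ID"), vid)
        self._seg_ref(vb, chrom, pos, ref_a)
        vb.ctx("ALT").seg_snip(alt)
        vb.ctx("QUAL").seg_snip(qual)
        vb.ctx("FILTER").seg_snip(filt)
        self._seg_info(vb, info)
        if n_samples:
            self._seg_samples(vb, f[8], f[9:], line_index)
        if pos.isdigit():
            vb.note_position(chrom, int(pos))

    # -- REF vs. reference genome -------------------------------------------

    def _seg_ref(self, vb, chrom: bytes, pos: bytes, ref_a: bytes) -> None:
        ctx = vb.ctx("REF")
        if self.ref is not None and pos.isdigit():
            try:
                g = self.ref.gpos_of(chrom.decode("latin-1"), int(pos) - 1)
                if self.ref.window(g, len(ref_a)) == ref_a:
                    ctx.seg_snip(b"R%d" % len(ref_a), OP_SPECIAL)
                    return
            except FormatError:
                pass
        ctx.seg_snip(ref_a)

    # -- INFO ----------------------------------------------------------------

    def _seg_info(self, vb, info: bytes) -> None:
        ctx = vb.ctx("INFO")
        if info in (b".", b""):
            ctx.seg_snip(info)
            return
        items = []
        for i, entry in enumerate(info.split(b";")):
            key, eq, value = entry.partition(b"=")
            cname = "I_" + key.decode("latin-1")
            if len(cname.encode()) > 16 or not key:
                ctx.seg_snip(info)
                return
            lead = b";" if i else b""
            vb.ctx(cname).seg_snip(value)
            items.append(item(cname, prefix=lead + key + eq))
        ctx.seg_container(Container(tuple(items)))

    # -- FORMAT + samples ----------------------------------------------------

    def _seg_samples(self, vb, fmt: bytes, sample_fields: list[bytes],
                     line_index: int) -> None:
        vb.ctx("FORMAT").seg_snip(fmt)
        keys = fmt.split(b":")
        parsed = []
        regular = True
        for sf in sample_fields:
            parts = sf.split(b":")
            if len(parts) != len(keys):
                regular = False
                break
            parsed.append(parts)
        gt_ok = regular and self._gt_parse(parsed, keys)
        samples_ctx = vb.ctx("SAMPLES")
        if not regular:
            for sf in sample_fields:
                vb.ctx("SMPRAW").seg_snip(sf)
            samples_ctx.seg_container(Container(
                (item("SMPRAW"),), repeats=len(sample_fields), repeat_sep=b"\t"))
            return
        items = []
        for ki, key in enumerate(keys):
            lead = b":" if ki else b""
            use_gt = key == b"GT" and gt_ok is not None
            cname = "GT" if use_gt else "F_" + key.decode("latin-1")
            if len(cname.encode()) > 16:
                cname = "F_X%d" % ki
            cctx = vb.ctx(cname)
            for parts in parsed:
                if use_gt:
                    cctx.seg_snip(b"G", OP_SPECIAL)
                else:
                    cctx.seg_snip(parts[ki])
            if use_gt:
                vb.ctx("GT", ctxmod.LT_BYTES, forced_codec=codecs.HAPMAT)
            items.append(item(cname, prefix=lead))
        samples_ctx.seg_container(Container(
            tuple(items), repeats=len(parsed), repeat_sep=b"\t"))
        if gt_ok is not None:
            self.gt_lines.append(gt_ok)
            pl = vb.ctx("GT_PLOIDY", ctxmod.LT_U8)
            ph = vb.ctx("GT_PHASE", ctxmod.LT_BYTES)
            for alleles, seps in gt_ok:
                pl.add_local(len(alleles))
                ph.add_local(seps)

    def _gt_parse(self, parsed, keys):
        """Parse all GT values of a line; None if hapmat cannot apply."""
        if b"GT" not in keys:
            return None
        ki = keys.index(b"GT")
        out = []
        for parts in parsed:
            gt = parts[ki]
            alleles: list[int] = []
            seps = bytearray()
            tok = bytearray()
            for b in gt:
                if b in (0x2F, 0x7C):  # '/' or '|'
                    a = self._allele(bytes(tok))
                    if a is None:
                        return None
                    alleles.append(a)
                    seps.append(b)
                    tok.clear()
                else:
                    tok.append(b)
            a = self._allele(bytes(tok))
            if a is None or not alleles and not tok:
                return None
            alleles.append(a)
            out.append((alleles, bytes(seps)))
        return out

    @staticmethod
    def _allele(tok: bytes):
        if tok == b".":
            return MISSING
        if tok.isdigit() and (tok == b"0" or not tok.startswith(b"0")):
            v = int(tok)
            if v < MISSING:
                return v
        return None

    # -- vblock finalisation --------------------------------------------------

    def end_vblock(self, vb) -> None:
        if self.gt_lines:
            n_samples = len(self.samples)
            max_ploidy = max(len(a) for line in self.gt_lines for a, _ in line)
            matrix = np.full((n_samples * max_ploidy, len(self.gt_lines)),
                             MISSING, dtype=np.uint8)
            for col, line in enumerate(self.gt_lines):
                for s, (alleles, _) in enumerate(line):
                    matrix[s * max_ploidy:s * max_ploidy + len(alleles), col] = alleles
            vb.ctx("GT").local = [matrix]
        fixed = [item(n, sep=b"\t") for n in
                 ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER")]
        if self.samples:
            fixed.append(item("INFO", sep=b"\t"))
            fixed.append(item("FORMAT", sep=b"\t"))
            fixed.append(item("SAMPLES", sep=b"\n"))
        else:
            fixed.append(item("INFO", sep=b"\n"))
        vb.ctx("TOPLEVEL").seg_container(
            Container(tuple(fixed), repeats=vb.line_count))


# -- special handlers --------------------------------------------------------


def _special_vcf_ref(recon, ctx, payload):
    if recon.reference is None:
        raise CorruptArchive("archive requires a reference genome for decompression")
    n = int(payload)
    chrom = recon.last_text.get("CHROM", b"").decode("latin-1")
    pos = recon.last_int.get("POS", 0)
    return recon.reference.window(recon.reference.gpos_of(chrom, pos - 1), n)


def _special_gt(recon, ctx, payload):
    if ctx.local is None or ctx.local.matrix is None:
        raise CorruptArchive("GT matrix missing")
    st = recon.scratch.setdefault("gt", {"i": 0})
    matrix = ctx.local.matrix
    n_samples = recon.n_samples
    if n_samples <= 0 or matrix.shape[0] % n_samples:
        raise CorruptArchive("GT matrix shape inconsistent with sample count")
    max_ploidy = matrix.shape[0] // n_samples
    i = st["i"]
    st["i"] += 1
    var, smp = divmod(i, n_samples)
    if var >= matrix.shape[1]:
        raise CorruptArchive("GT matrix exhausted")
    pl = recon.ctxs.get("GT_PLOIDY")
    ph = recon.ctxs.get("GT_PHASE")
    if pl is None or ph is None or pl.local is None or ph.local is None:
        raise CorruptArchive("GT ploidy/phase streams missing")
    ploidy = pl.local.next_int()
    seps = ph.local.next_bytes(ploidy - 1)
    alleles = matrix[smp * max_ploidy: smp * max_ploidy + ploidy, var]
    out = bytearray()
    for j, a in enumerate(alleles):
        if j:
            out.append(seps[j - 1])
        out += b"." if a == MISSING else b"%d" % a
    return bytes(out)


register_special(b"R", _special_vcf_ref)
register_special(b"G", _special_gt)
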