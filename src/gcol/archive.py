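"""High-level operations: compress, decompress, subset, list, stats.

This layer drives the vblock lifecycle (clone -> segment -> merge -> write),
owns file binding/unbinding, MD5 integrity, the random-access index, region
and sample subsetting, downsampling and SAM->FASTQ translation.  It reads
gzip-compressed inputs transparently; decompression always emits plain text.
"""
from __future__ import annotations

import gzip
import hashlib
import io
import json
import struct
import sys
import zlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import codecs
from . import segmenters
from .context import VBlock, ZState, clone_contexts, merge_contexts
from .errors import CorruptArchive, FormatError, Md5Mismatch, UsageError
from .reconstruct import Reconstructor
from .reference import ReferenceGenome, reference_from_fasta
from .segmenters import PairState
from .zfile import (SEC_FILE_HEADER, SEC_RANDOM_ACCESS, SEC_REFERENCE,
                    SEC_TXT_HEADER, ArchiveReader, ArchiveWriter,
                    write_dict_sections, write_vblock_sections)

DEFAULT_VBLOCK = 1 << 20          # desk-scale default; the tool this design
                                  # follows defaults to 16 MB
ARCHIVE_EXT = ".gcol"


@dataclass
class SegOpts:
    reference: ReferenceGenome | None = None
    vblock_size: int = DEFAULT_VBLOCK
    pair_in: PairState | None = None
    collect_pair: bool = False
    mode: str = "best"


def read_input(path: str) -> tuple[str, bytes]:
    """Read a (possibly gzip-compressed) input file or '-' for stdin."""
    if path == "-":
        data = sys.stdin.buffer.read()
        name = "stdin"
    else:
        with open(path, "rb") as fh:
            data = fh.read()
        name = path
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
        if name.endswith(".gz"):
            name = name[:-3]
    return name, data


# ---------------------------------------------------------------------------
# compression


def compress(inputs, out=None, *, reference=None, embed_reference=False,
             vblock_size: int = DEFAULT_VBLOCK, pair: bool = False,
             mode: str = "best", parallel: bool = False,
             data_type: str | None = None) -> dict:
    """Compress one or more files (bound into a single archive).

    ``inputs`` is a list of paths or (name, bytes) pairs; ``out`` a path or
    binary file object.  Returns the archive metadata dict.
    """
    if not inputs:
        raise UsageError("no input files")
    loaded = []
    for inp in inputs:
        if isinstance(inp, tuple):
            loaded.append(inp)
        else:
            loaded.append(read_input(inp))
    if pair:
        if len(loaded) != 2:
            raise UsageError("--pair requires exactly two FASTQ files")
        parallel = False

    ref = _as_reference(reference)
    seg_classes = [
        segmenters.by_name(data_type) if data_type
        else segmenters.detect(name, data)
        for name, data in loaded
    ]
    names = {c.name for c in seg_classes}
    if len(names) > 1:
        raise UsageError(f"cannot bind mixed formats: {sorted(names)}")
    seg_cls = seg_classes[0]
    if pair and seg_cls.name != "FASTQ":
        raise UsageError("--pair applies to FASTQ files only")

    close_out = False
    if out is None or isinstance(out, str):
        out_path = out if out is not None else loaded[0][0] + ARCHIVE_EXT
        fh = open(out_path, "wb")
        close_out = True
    else:
        fh = out
        out_path = None
    try:
        meta = _compress_to(fh, loaded, seg_cls, ref, embed_reference,
                            vblock_size, pair, mode, parallel)
    except BaseException:
        if close_out:
            fh.close()
            import os
            try:
                os.unlink(out_path)
            except OSError:
                pass
        raise
    if close_out:
        fh.close()
    meta["out_path"] = out_path
    return meta


def _compress_to(fh, loaded, seg_cls, ref, embed_reference, vblock_size,
                 pair, mode, parallel) -> dict:
    writer = ArchiveWriter(fh)
    writer.add_section(SEC_FILE_HEADER, 0, "GCOL", codecs.STORE, 0, 0,
                       json.dumps({"data_type": seg_cls.name}).encode())
    zstate = ZState(mode=mode)
    files_meta = []
    ra: list[list] = []
    vbid = 0
    pair_state: PairState | None = None
    prev_counts: list[int] | None = None

    for file_idx, (name, data) in enumerate(loaded):
        opts = SegOpts(reference=ref, vblock_size=vblock_size, mode=mode,
                       pair_in=pair_state if (pair and file_idx == 1) else None,
                       collect_pair=pair and file_idx == 0)
        seg = seg_cls(zstate, opts)
        header, body = seg.split_header(data)
        seg.parse_header(header)
        writer.add_section(SEC_TXT_HEADER, 0, f"TXT{file_idx}", codecs.LZMA, 0,
                           len(header), codecs.generic_encode(codecs.LZMA, header))
        no_nl = False
        if seg.text_based and body and not body.endswith(b"\n"):
            body += b"\n"
            no_nl = True
        records = list(seg.iter_records(body))
        if pair and file_idx == 1 and prev_counts is not None:
            if sum(prev_counts) != len(records):
                raise UsageError("--pair: mate files have different read counts")
            groups = _group_by_counts(records, prev_counts)
        else:
            groups = _group_by_size(records, vblock_size)
        counts = [len(g) for g in groups]

        file_vblocks = []
        line_base = 0
        if parallel:
            work = []
            for g in groups:
                vbid += 1
                vb = VBlock(vbid)
                clone_contexts(zstate, vb)
                vseg = seg_cls(zstate, opts)
                vseg.samples = getattr(seg, "samples", None) or []
                work.append((vb, vseg, g, line_base))
                line_base += len(g)
                file_vblocks.append(vbid)
            with ThreadPoolExecutor(max_workers=4) as pool:
                futures = [pool.submit(_segment_group, vb, vseg, g, base)
                           for vb, vseg, g, base in work]
                for f in futures:
                    f.result()
            for vb, _, _, _ in work:
                merge_contexts(zstate, vb)
                write_vblock_sections(writer, vb, zstate)
                _collect_ra(ra, vb)
        else:
            for g in groups:
                vbid += 1
                vb = VBlock(vbid)
                clone_contexts(zstate, vb)
                _segment_group(vb, seg, g, line_base)
                line_base += len(g)
                merge_contexts(zstate, vb)
                write_vblock_sections(writer, vb, zstate)
                _collect_ra(ra, vb)
                file_vblocks.append(vbid)

        fmeta = {
            "name": name,
            "size": len(data),
            "md5": hashlib.md5(data).hexdigest(),
            "lines": len(records),
            "vblocks": file_vblocks,
            "header_name": f"TXT{file_idx}",
            "no_final_newline": no_nl,
        }
        if seg_cls.name == "VCF":
            samples = getattr(seg, "samples", [])
            fmeta["n_samples"] = len(samples)
            fmeta["sample_names"] = samples
        files_meta.append(fmeta)
        if pair and file_idx == 0:
            pair_state = seg.pair_out
            prev_counts = counts

    write_dict_sections(writer, zstate)
    if ra:
        writer.add_section(SEC_RANDOM_ACCESS, 0, "RA", codecs.ZLIB, 0, 0,
                           codecs.generic_encode(
                               codecs.ZLIB, json.dumps(ra).encode()))
    if embed_reference and ref is not None:
        write_reference_sections(writer, ref)
    meta = {
        "version": 1,
        "data_type": seg_cls.name,
        "mode": mode,
        "vblock_size": vblock_size,
        "aliases": zstate.aliases,
        "files": files_meta,
        "pair": pair,
        "requires_reference": ref is not None and _uses_reference(zstate),
        "ref_embedded": embed_reference and ref is not None,
        "ra_ctxs": list(seg_cls.ra_ctxs) if seg_cls.ra_ctxs else None,
        "codec_choices": [c.as_dict() for c in zstate.codec_choices.values()],
    }
    writer.finish(meta)
    return meta


def _segment_group(vb: VBlock, seg, records, line_base: int) -> None:
    seg.begin_vblock(vb)
    for i, rec in enumerate(records):
        seg.seg_record(vb, rec, line_base + i)
        vb.line_count += 1
        vb.txt_len += len(rec)
    seg.end_vblock(vb)


def _group_by_size(records, vblock_size):
    groups = []
    cur: list[bytes] = []
    size = 0
    for rec in records:
        cur.append(rec)
        size += len(rec)
        if size >= vblock_size:
            groups.append(cur)
            cur = []
            size = 0
    if cur:
        groups.append(cur)
    return groups


def _group_by_counts(records, counts):
    groups = []
    pos = 0
    for c in counts:
        groups.append(records[pos:pos + c])
        pos += c
    return groups


def _collect_ra(ra: list, vb: VBlock) -> None:
    for chrom, (lo, hi) in vb.ra.items():
        ra.append([vb.vblock_id, chrom, lo, hi])


def _uses_reference(zstate: ZState) -> bool:
    """True if any stored snip needs reference bases at reconstruction."""
    if "GPOS" in zstate.contexts:
        return True
    sq = zstate.contexts.get("SQBITMAP")
    if sq is not None and any(s.startswith(b"\x04SA") for s in sq.dict_list):
        return True
    ref = zstate.contexts.get("REF")
    return ref is not None and any(s.startswith(b"\x04R") for s in ref.dict_list)


def _as_reference(reference) -> ReferenceGenome | None:
    if reference is None or isinstance(reference, ReferenceGenome):
        return reference
    return load_reference(reference)


# ---------------------------------------------------------------------------
# reference archives


def make_reference(fasta_path, out_path: str) -> ReferenceGenome:
    """Preprocess a reference FASTA into a reference archive."""
    if isinstance(fasta_path, tuple):
        _, data = fasta_path
    else:
        _, data = read_input(fasta_path)
    genome = reference_from_fasta(data)
    genome.build_index()
    with open(out_path, "wb") as fh:
        writer = ArchiveWriter(fh)
        writer.add_section(SEC_FILE_HEADER, 0, "GCOL", codecs.STORE, 0, 0,
                           json.dumps({"data_type": "REF"}).encode())
        write_reference_sections(writer, genome)
        writer.finish({"version": 1, "data_type": "REF", "files": [],
                       "aliases": {}, "pair": False,
                       "requires_reference": False, "ref_embedded": False})
    return genome


def write_reference_sections(writer: ArchiveWriter, genome: ReferenceGenome) -> None:
    contigs_json = json.dumps(
        [[n, l, o] for n, l, o in genome.contigs]).encode()
    writer.add_section(SEC_REFERENCE, 0, "REF_META", codecs.ZLIB, 0,
                       len(contigs_json),
                       codecs.generic_encode(codecs.ZLIB, contigs_json))
    packed, xcgt = codecs.acgt_encode(genome.seq)
    writer.add_section(SEC_REFERENCE, 0, "REF_SEQ", codecs.ACGT, 0,
                       len(genome.seq),
                       codecs.generic_encode(codecs.LZMA, packed))
    writer.add_section(SEC_REFERENCE, 0, "REF_SEQ_X", codecs.LZMA, 0,
                       len(xcgt), codecs.generic_encode(codecs.LZMA, xcgt))
    ic, ip = genome.index_arrays()
    raw = struct.pack("<Q", ic.size) + ic.astype("<u4").tobytes() \
        + ip.astype("<u4").tobytes()
    writer.add_section(SEC_REFERENCE, 0, "REF_KIDX", codecs.LZMA, 0,
                       len(raw), codecs.generic_encode(codecs.LZMA, raw))


def reference_from_reader(reader: ArchiveReader) -> ReferenceGenome:
    def _payload(name):
        infos = reader.find(SEC_REFERENCE, name=name)
        if not infos:
            raise CorruptArchive(f"reference section {name} missing")
        return infos[0], reader.payload(infos[0])

    minfo, mpayload = _payload("REF_META")
    contigs = [tuple(c) for c in
               json.loads(codecs.generic_decode(minfo.codec, mpayload))]
    sinfo, spayload = _payload("REF_SEQ")
    packed = codecs.generic_decode(codecs.LZMA, spayload)
    xinfo, xpayload = _payload("REF_SEQ_X")
    xcgt = codecs.generic_decode(xinfo.codec, xpayload)
    seq = codecs.acgt_decode(packed, xcgt, sinfo.unc_len)
    genome = ReferenceGenome(contigs, seq)
    kinfo, kpayload = _payload("REF_KIDX")
    raw = codecs.generic_decode(kinfo.codec, kpayload)
    (count,) = struct.unpack_from("<Q", raw, 0)
    codes = np.frombuffer(raw, dtype="<u4", count=count, offset=8)
    pos = np.frombuffer(raw, dtype="<u4", count=count, offset=8 + 4 * count)
    genome.set_index(codes, pos)
    return genome


def load_reference(path: str) -> ReferenceGenome:
    with open(path, "rb") as fh:
        reader = ArchiveReader(fh)
        return reference_from_reader(reader)


# ---------------------------------------------------------------------------
# decompression / subsetting


@dataclass
class FileResult:
    name: str
    data: bytes
    md5_ok: bool | None = None


@dataclass
class CatStats:
    vblocks_decompressed: int = 0
    vblocks_skipped: int = 0
    results: list = field(default_factory=list)


class Archive:
    """Read-side handle over one archive."""

    def __init__(self, path_or_fh):
        if isinstance(path_or_fh, (str, bytes)):
            self.fh = open(path_or_fh, "rb")
            self._close = True
        else:
            self.fh = path_or_fh
            self._close = False
        self.reader = ArchiveReader(self.fh)
        self.meta = self.reader.meta

    def close(self):
        if self._close:
            self.fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- reference ----------------------------------------------------------

    def reference(self, reference_path: str | None = None,
                  reference: ReferenceGenome | None = None) -> ReferenceGenome | None:
        if reference is not None:
            return reference
        if self.meta.get("ref_embedded"):
            return reference_from_reader(self.reader)
        if reference_path:
            return load_reference(reference_path)
        return None

    def header_bytes(self, fmeta: dict) -> bytes:
        infos = self.reader.find(SEC_TXT_HEADER, name=fmeta["header_name"])
        if not infos:
            raise CorruptArchive("missing TXT_HEADER section")
        return codecs.generic_decode(infos[0].codec, self.reader.payload(infos[0]))

    # -- core reconstruction -------------------------------------------------

    def reconstruct_file(self, file_idx: int, *, ref=None, toplevel="TOPLEVEL",
                         line_filter=None, sample_select=None,
                         emit_header=True, header_override=None,
                         skip_vblocks=None, stats: CatStats | None = None,
                         pair_state=None, collect_pair=False):
        fmeta = self.meta["files"][file_idx]
        recon = Reconstructor(
            aliases=self.meta.get("aliases") or {},
            reference=ref,
            n_samples=fmeta.get("n_samples", 0),
            pair_state=pair_state,
        )
        collected = None
        if collect_pair:
            collected = PairState()
            recon.collecting_pair = collected
            recon.line_hook = lambda r: collected.qnames.append(
                r.last_text.get("QNAME", b""))
        recon.sample_select = sample_select
        recon.line_filter = line_filter
        chunks = []
        if emit_header:
            chunks.append(header_override if header_override is not None
                          else self.header_bytes(fmeta))
        for vb_id in fmeta["vblocks"]:
            if skip_vblocks and vb_id in skip_vblocks:
                if stats:
                    stats.vblocks_skipped += 1
                continue
            ctxs = self.reader.vblock_contexts(vb_id)
            recon.start_vblock(ctxs)
            chunks.append(recon.reconstruct_vblock(toplevel))
            if stats:
                stats.vblocks_decompressed += 1
        data = b"".join(chunks)
        no_filters = (line_filter is None and sample_select is None
                      and toplevel == "TOPLEVEL" and not skip_vblocks)
        if fmeta.get("no_final_newline") and no_filters and data.endswith(b"\n"):
            data = data[:-1]
        return data, collected


def decompress(archive_path, *, reference=None, reference_path=None) -> list[FileResult]:
    """Full decompression of every bound file, with MD5 verification."""
    with Archive(archive_path) as ar:
        ref = ar.reference(reference_path, reference)
        _check_reference_needed(ar, ref)
        results = []
        pair_state = None
        for i, fmeta in enumerate(ar.meta["files"]):
            collect = ar.meta.get("pair") and i == 0
            data, collected = ar.reconstruct_file(
                i, ref=ref, pair_state=pair_state, collect_pair=collect)
            if collect:
                pair_state = collected
            digest = hashlib.md5(data).hexdigest()
            ok = digest == fmeta["md5"]
            if not ok:
                raise Md5Mismatch(
                    f"{fmeta['name']}: MD5 mismatch "
                    f"(stored {fmeta['md5']}, computed {digest})")
            results.append(FileResult(fmeta["name"], data, ok))
        return results


def _check_reference_needed(ar: Archive, ref) -> None:
    if ar.meta.get("requires_reference") and ref is None \
            and not ar.meta.get("ref_embedded"):
        raise UsageError(
            "archive was compressed against a reference genome; "
            "supply it with --reference")


# -- region / sample / downsample subsetting ---------------------------------


def parse_regions(region_strs) -> list[tuple[str, int, int | None]]:
    out = []
    for rs in region_strs:
        chrom, sep, rng = rs.partition(":")
        if not chrom:
            raise UsageError(f"malformed region {rs!r}")
        if not sep:
            out.append((chrom, 1, None))
            continue
        start_s, dash, end_s = rng.partition("-")
        try:
            start = int(start_s)
            if dash:
                end = int(end_s) if end_s else None
            else:
                end = start
        except ValueError:
            raise UsageError(f"malformed region {rs!r}") from None
        if start < 1 or (end is not None and end < start):
            raise UsageError(f"malformed region {rs!r}")
        out.append((chrom, start, end))
    return out


def _region_match(regions, chrom: str, pos: int) -> bool:
    for rchrom, start, end in regions:
        if rchrom == chrom and pos >= start and (end is None or pos <= end):
            return True
    return False


def cat(archive_path, *, regions=None, samples=None, downsample=None,
        translate=None, reference=None, reference_path=None) -> CatStats:
    """genocat: display or subset an archive.

    Returns CatStats whose ``results`` hold the emitted text per bound file;
    the vblock counters make the index-skipping behaviour observable.
    """
    stats = CatStats()
    with Archive(archive_path) as ar:
        meta = ar.meta
        ref = ar.reference(reference_path, reference)
        _check_reference_needed(ar, ref)
        data_type = meta.get("data_type")

        toplevel = "TOPLEVEL"
        if translate:
            if translate != "fastq" or data_type != "SAM":
                raise UsageError("translation supported: SAM -> FASTQ (--fastq)")
            toplevel = "TOP2FQ"

        region_list = None
        skip: set[int] | None = None
        if regions:
            if not meta.get("ra_ctxs"):
                raise UsageError(f"--regions not supported for {data_type}")
            region_list = parse_regions(regions)
            ra = ar.reader.random_access()
            known_chroms = {chrom for _, chrom, _, _ in ra}
            for chrom, _, _ in region_list:
                if chrom not in known_chroms:
                    print(f"gcol: warning: chromosome {chrom!r} not in archive",
                          file=sys.stderr)
            skip = _vblocks_to_skip(meta, ra, region_list)

        if downsample is not None and downsample < 1:
            raise UsageError("--downsample requires n >= 1")

        pair_state = None
        for i, fmeta in enumerate(meta["files"]):
            sample_select = None
            header_override = None
            if samples is not None:
                if data_type != "VCF":
                    raise UsageError("--samples applies to VCF archives only")
                sample_select, header_override = _sample_selection(
                    fmeta, ar.header_bytes(fmeta), samples)

            line_filter = _build_line_filter(meta, region_list, downsample)
            collect = meta.get("pair") and i == 0
            data, collected = ar.reconstruct_file(
                i, ref=ref, toplevel=toplevel, line_filter=line_filter,
                sample_select=sample_select, emit_header=(toplevel == "TOPLEVEL"),
                header_override=header_override, skip_vblocks=skip,
                stats=stats, pair_state=pair_state, collect_pair=collect)
            if collect:
                pair_state = collected
            stats.results.append(FileResult(fmeta["name"], data))
    return stats


def _build_line_filter(meta, region_list, downsample):
    ra_ctxs = meta.get("ra_ctxs")
    fns = []
    if region_list:
        c_chrom, c_pos = ra_ctxs

        def _rf(recon):
            chrom = recon.last_text.get(c_chrom, b"").decode("latin-1")
            return _region_match(region_list, chrom, recon.last_int.get(c_pos, 0))
        fns.append(_rf)
    if downsample is not None and downsample > 1:
        fns.append(lambda recon: recon.line_index % downsample == 0)
    if not fns:
        return None
    if len(fns) == 1:
        return fns[0]
    return lambda recon: all(fn(recon) for fn in fns)


def _vblocks_to_skip(meta, ra, region_list) -> set[int]:
    covered: dict[int, bool] = {}
    for vb, chrom, lo, hi in ra:
        hit = any(rchrom == chrom and (end is None or lo <= end) and hi >= start
                  for rchrom, start, end in region_list)
        covered[vb] = covered.get(vb, False) or hit
    all_vblocks = {vb for f in meta["files"] for vb in f["vblocks"]}
    return {vb for vb in all_vblocks if not covered.get(vb, False)}


def _sample_selection(fmeta, header: bytes, wanted: list[str]):
    names = fmeta.get("sample_names") or []
    sel = []
    for w in wanted:
        if w not in names:
            raise UsageError(
                f"unknown sample {w!r}; available: {', '.join(names) or '(none)'}")
        sel.append(names.index(w))
    lines = header.split(b"\n")
    for i, line in enumerate(lines):
        if line.startswith(b"#CHROM"):
            cols = line.split(b"\t")
            lines[i] = b"\t".join(cols[:9] + [w.encode() for w in wanted])
    return sel, b"\n".join(lines)


def downsample_stream(archive_path, n: int, **kw) -> CatStats:
    return cat(archive_path, downsample=n, **kw)


# ---------------------------------------------------------------------------
# genols / show-stats


def list_metadata(paths) -> list[dict]:
    rows = []
    for path in paths:
        try:
            with Archive(path) as ar:
                import os
                comp = os.path.getsize(path) if isinstance(path, str) else 0
                total = sum(f["size"] for f in ar.meta["files"])
                for f in ar.meta["files"]:
                    rows.append({
                        "archive": path if isinstance(path, str) else "-",
                        "name": f["name"],
                        "size": f["size"],
                        "compressed": comp,
                        "ratio": round(total / comp, 2) if comp else 0.0,
                        "md5": f["md5"],
                        "bound_files": len(ar.meta["files"]),
                    })
        except (OSError, CorruptArchive) as exc:
            rows.append({"archive": path, "error": str(exc)})
    return rows


_STREAM_BY_TYPE = {3: "b250", 4: "local", 5: "dict", 2: "header",
                   6: "index", 7: "reference", 1: "header"}


def show_stats(archive_path) -> list[dict]:
    with Archive(archive_path) as ar:
        groups: dict[tuple[str, str], dict] = {}
        for s in ar.reader.sections:
            stream = _STREAM_BY_TYPE.get(s.type)
            if stream is None:
                continue
            key = (s.name, stream)
            g = groups.setdefault(key, {
                "context": s.name, "stream": stream,
                "codec": codecs.CODEC_NAMES.get(s.codec, str(s.codec)),
                "uncompressed": 0, "compressed": 0,
            })
            g["uncompressed"] += s.unc_len
            g["compressed"] += s.comp_len
        rows = sorted(groups.values(),
                      key=lambda g: (-g["compressed"], g["context"]))
        total_c = sum(g["compressed"] for g in rows) or 1
        total_u = sum(g["uncompressed"] for g in rows)
        for g in rows:
            g["ratio"] = round(g["uncompressed"] / g["compressed"], 2) \
                if g["compressed"] else 0.0
            g["pct"] = round(100.0 * g["compressed"] / total_c, 2)
        rows.append({
            "context": "TOTAL", "stream": "", "codec": "",
            "uncompressed": total_u, "compressed": total_c,
            "ratio": round(total_u / total_c, 2), "pct": 100.0,
        })
        return rows
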