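"""The generic, Container-driven reconstructor.

Decompression walks the TOPLEVEL container of each vblock and pulls one
value per container item per repeat from the named contexts.  The only
format-specific logic permitted here is codec inversion (handled upstream),
registered *special* snip handlers and registered *translators* — record
layout comes solely from Container data, so a new segmenter round-trips with
zero changes to this module.
"""
from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

from .container import Container
from .errors import CorruptArchive
from . import context as ctxmod
from .snips import (
    OP_CONTAINER,
    OP_DELTA,
    OP_LOOKUP_LOCAL,
    OP_SPECIAL,
    OP_VERBATIM,
    decode_snip,
)

# registries -----------------------------------------------------------------

SPECIALS: dict[bytes, Callable] = {}
TRANSLATORS: dict[str, Callable] = {}
REPEAT_FILTERS: dict[str, Callable] = {}


def register_special(key: bytes, fn: Callable) -> None:
    SPECIALS[key] = fn


def register_translator(name: str, fn: Callable) -> None:
    TRANSLATORS[name] = fn


def register_repeat_filter(name: str, fn: Callable) -> None:
    REPEAT_FILTERS[name] = fn


# local streams --------------------------------------------------------------


class LocalStream:
    """Typed cursor over a context's decoded local buffer."""

    def __init__(self, ltype: int, *, items: list | None = None,
                 ints: np.ndarray | None = None, bits: np.ndarray | None = None,
                 data: bytes = b"", matrix: np.ndarray | None = None):
        self.ltype = ltype
        self.items = items if items is not None else []
        self.ints = ints if ints is not None else np.zeros(0, dtype=np.int64)
        self.bits = bits if bits is not None else np.zeros(0, dtype=bool)
        self.data = data
        self.matrix = matrix
        self.pos = 0

    def next_text(self) -> bytes:
        if self.pos >= len(self.items):
            raise CorruptArchive("local text stream exhausted")
        v = self.items[self.pos]
        self.pos += 1
        return v

    def next_item(self):
        return self.next_text()

    def next_int(self) -> int:
        if self.pos >= len(self.ints):
            raise CorruptArchive("local integer stream exhausted")
        v = int(self.ints[self.pos])
        self.pos += 1
        return v

    def next_bits(self, n: int) -> np.ndarray:
        if self.pos + n > len(self.bits):
            raise CorruptArchive("local bitmap exhausted")
        v = self.bits[self.pos:self.pos + n]
        self.pos += n
        return v

    def next_bit(self) -> int:
        return int(self.next_bits(1)[0])

    def next_bytes(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise CorruptArchive("local byte stream exhausted")
        v = self.data[self.pos:self.pos + n]
        self.pos += n
        return v

    def rest(self) -> bytes:
        v = self.data[self.pos:]
        self.pos = len(self.data)
        return v


class ReconContext:
    """Read-side view of one context within one vblock."""

    __slots__ = ("name", "dict_list", "b250", "b250_pos", "local", "ltype")

    def __init__(self, name: str, dict_list: list[bytes], b250: list[int],
                 local: LocalStream | None, ltype: int):
        self.name = name
        self.dict_list = dict_list
        self.b250 = b250
        self.b250_pos = 0
        self.local = local
        self.ltype = ltype


class Reconstructor:
    """Rebuilds vblock text by traversing containers from a toplevel context."""

    def __init__(self, aliases: dict[str, str] | None = None, *,
                 reference=None, n_samples: int = 0,
                 pair_state=None):
        self.aliases = aliases or {}
        self.reference = reference
        self.n_samples = n_samples
        self.pair_state = pair_state          # mate-1 replay for paired FASTQ
        self.collecting_pair = None           # PairState being recorded
        self.line_index = 0                   # per-file logical line counter
        self.last_text: dict[str, bytes] = {}
        self.last_int: dict[str, int] = {}
        self.scratch: dict = {}               # handler scratch, reset per vblock
        self.ctxs: dict[str, ReconContext] = {}
        self.samples_ctx = "SAMPLES"
        self.sample_select: list[int] | None = None
        self.line_filter: Callable | None = None
        self.line_hook: Callable | None = None
        self._container_cache: dict[tuple[str, int], Container] = {}

    # ------------------------------------------------------------------

    def start_vblock(self, contexts: dict[str, ReconContext]) -> None:
        self.ctxs = contexts
        self.last_text.clear()
        self.last_int.clear()
        self.scratch.clear()
        self._container_cache.clear()

    def reconstruct_vblock(self, toplevel: str = "TOPLEVEL") -> bytes:
        """Emit the vblock's txt data byte-exactly (modulo active filters)."""
        top = self.ctxs.get(toplevel)
        if top is None:
            raise CorruptArchive(f"missing toplevel context {toplevel!r}")
        out = []
        while top.b250_pos < len(top.b250):
            out.append(self._consume(toplevel, is_top=True))
        return b"".join(out)

    # ------------------------------------------------------------------

    def _resolve(self, name: str) -> ReconContext:
        name = self.aliases.get(name, name)
        c = self.ctxs.get(name)
        if c is None:
            raise CorruptArchive(f"container references missing context {name!r}")
        return c

    def _consume(self, name: str, is_top: bool = False) -> bytes:
        c = self._resolve(name)
        if c.b250_pos < len(c.b250):
            idx = c.b250[c.b250_pos]
            c.b250_pos += 1
            if idx >= len(c.dict_list):
                raise CorruptArchive(
                    f"context {c.name}: b250 index {idx} out of dictionary range")
            opcode, payload = decode_snip(c.dict_list[idx])
            if opcode == OP_VERBATIM:
                val = payload
                self._note(c.name, val)
            elif opcode == OP_LOOKUP_LOCAL:
                if c.local is None:
                    raise CorruptArchive(f"context {c.name}: lookup without local data")
                val = c.local.next_text()
                self._note(c.name, val)
            elif opcode == OP_DELTA:
                val = self._eval_delta(c.name, payload)
            elif opcode == OP_CONTAINER:
                key = (c.name, idx)
                cont = self._container_cache.get(key)
                if cont is None:
                    cont = Container.from_payload(payload)
                    self._container_cache[key] = cont
                val = self._render_container(cont, origin=c.name, is_top=is_top)
                if not is_top:
                    self.last_text[c.name] = val
            elif opcode == OP_SPECIAL:
                handler = SPECIALS.get(payload[:1])
                if handler is None:
                    raise CorruptArchive(
                        f"context {c.name}: unknown special snip {payload[:1]!r}")
                val = handler(self, c, payload[1:])
                self._note(c.name, val)
            else:
                raise CorruptArchive(f"context {c.name}: reserved opcode in archive")
            return val
        # no dictionary entry: value comes from the local buffer
        if c.local is None:
            raise CorruptArchive(f"context {c.name}: stream exhausted")
        lt = c.ltype
        if lt == ctxmod.LT_TEXT:
            val = c.local.next_text()
        elif lt in (ctxmod.LT_U8, ctxmod.LT_U32, ctxmod.LT_I64):
            v = c.local.next_int()
            self.last_int[c.name] = v
            val = b"%d" % v
            self.last_text[c.name] = val
            return val
        elif lt == ctxmod.LT_BYTES:
            val = c.local.rest()
        else:
            raise CorruptArchive(f"context {c.name}: not directly reconstructable")
        self._note(c.name, val)
        return val

    def _note(self, name: str, val: bytes) -> None:
        self.last_text[name] = val
        if val.isdigit() or (val[:1] == b"-" and val[1:].isdigit()):
            self.last_int[name] = int(val)

    def _eval_delta(self, name: str, payload: bytes) -> bytes:
        try:
            base, delta_text = payload.split(b"\x00", 1)
            delta = int(delta_text)
        except ValueError as exc:
            raise CorruptArchive(f"context {name}: malformed delta snip") from exc
        anchor_name = base.decode("latin-1") if base else name
        anchor = self.last_int.get(anchor_name, 0)
        value = anchor + delta
        self.last_int[name] = value
        val = b"%d" % value
        self.last_text[name] = val
        return val

    # ------------------------------------------------------------------

    def _render_container(self, cont: Container, origin: str, is_top: bool) -> bytes:
        select = (self.sample_select is not None and origin == self.samples_ctx)
        reps: list[bytes] = []
        for _ in range(cont.repeats):
            chunks: list[bytes] = []
            for it in cont.items:
                if it.prefix:
                    chunks.append(it.prefix)
                val = self._consume(it.ctx)
                if it.translator is not None:
                    fn = TRANSLATORS.get(it.translator)
                    if fn is None:
                        raise CorruptArchive(f"unknown translator {it.translator!r}")
                    val = fn(self, val)
                chunks.append(val)
                if it.sep:
                    chunks.append(it.sep)
            rep = b"".join(chunks)
            if is_top:
                if self.line_hook is not None:
                    self.line_hook(self)
                keep = True
                if cont.repeat_filter is not None:
                    keep = REPEAT_FILTERS[cont.repeat_filter](self)
                if keep and self.line_filter is not None:
                    keep = self.line_filter(self)
                self.line_index += 1
                if not keep:
                    continue
            reps.append(rep)
        if select:
            try:
                reps = [reps[i] for i in self.sample_select]
            except IndexError as exc:
                raise CorruptArchive("sample index out of range") from exc
        return cont.repeat_sep.join(reps)


# builtin special handler: seg_id numeric suffix ('I' + prefix)


def _special_id(recon: Reconstructor, ctx: ReconContext, payload: bytes) -> bytes:
    if ctx.local is None:
        raise CorruptArchive(f"context {ctx.name}: id snip without local data")
    number, width = ctx.local.next_item()
    return payload + b"%0*d" % (width, number)


register_special(b"I", _special_id)
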