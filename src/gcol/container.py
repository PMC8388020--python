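"""Containers: structural snips that encode record layout.

A Container names the contexts a record draws its values from, together with
per-item separators, optional prefixes and optional translator tags.  The
whole-vblock layout is itself a Container stored in the TOPLEVEL context, so
the reconstructor needs no built-in knowledge of any file format: it simply
walks the TOPLEVEL container, pulling one value per item per repeat from the
named contexts.

Containers serialize canonically (compact JSON, latin-1 byte mapping) so that
identical layouts on different lines deduplicate to a single dictionary entry.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

from .snips import OP_CONTAINER, encode_snip

MAX_ITEMS = 255
MAX_REPEATS = 2**32


@dataclass(frozen=True)
class ContainerItem:
    ctx: str
    sep: bytes = b""
    prefix: bytes = b""
    translator: str | None = None


@dataclass(frozen=True)
class Container:
    items: tuple[ContainerItem, ...]
    repeats: int = 1
    repeat_sep: bytes = b""
    #: name of a registered per-repeat filter (used by format translation)
    repeat_filter: str | None = None

    def __post_init__(self) -> None:
        if len(self.items) > MAX_ITEMS:
            raise ValueError(f"container exceeds {MAX_ITEMS} items")
        if not 0 <= self.repeats < MAX_REPEATS:
            raise ValueError("container repeats out of range")

    def to_payload(self) -> bytes:
        doc: dict = {
            "r": self.repeats,
            "rs": self.repeat_sep.decode("latin-1"),
            "it": [
                [
                    it.ctx,
                    it.sep.decode("latin-1"),
                    it.prefix.decode("latin-1"),
                    it.translator,
                ]
                for it in self.items
            ],
        }
        if self.repeat_filter:
            doc["rf"] = self.repeat_filter
        return json.dumps(doc, separators=(",", ":")).encode("latin-1")

    def to_snip(self) -> bytes:
        """Stored dictionary form (opcode CONTAINER)."""
        return encode_snip(self.to_payload(), OP_CONTAINER)

    @staticmethod
    def from_payload(payload: bytes) -> "Container":
        try:
            doc = json.loads(payload.decode("latin-1"))
            items = tuple(
                ContainerItem(
                    ctx=c,
                    sep=s.encode("latin-1"),
                    prefix=p.encode("latin-1"),
                    translator=t,
                )
                for c, s, p, t in doc["it"]
            )
            return Container(
                items=items,
                repeats=doc["r"],
                repeat_sep=doc["rs"].encode("latin-1"),
                repeat_filter=doc.get("rf"),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise CorruptContainer(str(exc)) from exc


class CorruptContainer(ValueError):
    pass


def item(ctx: str, sep: bytes = b"", prefix: bytes = b"", translator: str | None = None) -> ContainerItem:
    return ContainerItem(ctx=ctx, sep=sep, prefix=prefix, translator=translator)
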