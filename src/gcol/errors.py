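"""Error taxonomy.  Each class maps to a distinct CLI exit code."""
from __future__ import annotations


class GcolError(Exception):
    exit_code = 1


class UsageError(GcolError):
    exit_code = 2


class FormatError(GcolError):
    """The input file violates its declared format."""
    exit_code = 3


class CorruptArchive(GcolError):
    exit_code = 4


class Md5Mismatch(GcolError):
    exit_code = 5
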