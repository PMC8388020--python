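# Methods

This note documents the model behind `gcol`, the parameters that matter,
the numerical and design choices made where the design was open, and what
the synthetic-data generators do and do not emulate.

## Data model

An archive is a set of *contexts*, one per data component. A context stores
each distinct value (*snip*) once in a dictionary; occurrences are a stream
of dictionary indices (*b250*, LEB128 varints); bulk non-dictionary data
(numbers, sequence bytes, bitmaps) lives in a typed *local* buffer. Record
layout is data, not code: every vblock's structure is a Container snip in
the TOPLEVEL context naming the member contexts, their separators, prefixes
and repeat count, and reconstruction is a traversal of that container.
Translators (e.g. SAM→FASTQ) are alternate toplevel containers whose items
carry transformation tags; the reconstructor itself stays format-agnostic.

Snip opcodes occupy one reserved leading byte: 0x01 LOOKUP_LOCAL, 0x02
DELTA, 0x03 CONTAINER, 0x04 SPECIAL, 0x05 reserved, 0x06 escape. Verbatim
values beginning with a reserved byte are escaped, and dictionary
serialization joins escaped snips with 0x00 terminators, so any byte string
round-trips.

## Vblock lifecycle and determinism

Input is chunked into vblocks of whole logical lines (default 1 MB,
`--vblock`; chosen for responsiveness on desk-scale data — 16 MB is the
conventional value for production-scale archives and remains available).
Each vblock is segmented against a private context set cloned from the
global state, then merged back in vblock-id order. Merging assigns global
dictionary indices by remapping the vblock-local indices, so segmentation
of distinct vblocks may run in any order (or concurrently) while the merged
result — and therefore the archive bytes — depends only on the input and
settings. Two further choices support this reproducibility contract:

- **Delta anchors reset at vblock boundaries.** Position deltas (and
  numeric read-name tokens) are computed against the previous line *within
  the vblock*, with the first line anchored at 0. This costs one absolute
  value per vblock and makes each vblock self-contained.
- **Codec selection uses nominal speeds.** The selection rule keeps the
  best-ratio codec unless the top two ratios are within 5% relative (15% in
  `--fast` mode) and the runner-up is ≥2× faster. "Faster" is evaluated
  against a fixed nominal throughput table (STORE ≫ zlib ≫ bz2 ≫ lzma)
  rather than wall-clock timing, because measured times vary run-to-run and
  would leak nondeterminism into the archive. The measured sample time is
  still recorded in the in-memory choice record for diagnostics. Ties break
  by fixed codec order (lzma > bz2 > zlib > store).

**Singletons.** A verbatim snip occurring exactly once in the merging
vblock and absent from the global dictionary is not merged; its payload
moves to the context's local buffer behind a LOOKUP_LOCAL snip. Counting is
per-vblock: a value that is unique in every vblock stays out of the
dictionary forever, which is the intended behaviour for read names. The rule
applies only to dictionary-style contexts (never to containers, deltas, or
contexts whose local buffer carries typed data).

## Codecs

- **acgt**: 2 bits per base, four bases per byte, first base in the high
  bits; a partial final byte is zero-padded. Non-ACGT bytes pack as A and
  are recorded as (position-delta varint, original byte) pairs in a
  companion exception context (`NONREF_X`, `SEQ_X`, …). The packed stream
  then takes an lzma pass. On pure-ACGT input the transform alone achieves
  exactly ⌈n/4⌉ bytes.
- **domqual**: the dominant score is the most frequent byte in a ≤100 KB
  sample of the first vblock's quality strings and is fixed for the rest of
  the context's lifetime. Each string is coded as its length followed by
  alternating run-lengths of the dominant byte and single literal
  exceptions; runs and exceptions are separate streams inside one
  lzma-compressed payload.
- **hapmat**: haplotype rows (n_samples × max ploidy; allele codes 0–254,
  255 for both missing alleles and padding beyond a genotype's ploidy) are
  reordered by a greedy nearest-neighbour walk on Hamming distance starting
  from row 0, ties to the lowest row index. The permutation and the
  column-major matrix are lzma-compressed together. Per-genotype ploidy and
  phase separators are stored in side contexts, so mixed-ploidy and
  mixed-phasing files round-trip exactly. Genotypes that cannot be coded
  (allele > 254, non-numeric) fall back to verbatim snips line-by-line.

## Reference model and aligner

Contigs are concatenated and addressed by *gpos*, an unsigned 32-bit 0-based
global coordinate (SAM/VCF positions stay 1-based at the format boundary).
`make-reference` stores the acgt-coded bases, the contig table and the
k-mer index in a reference archive; `--REFERENCE` embeds those sections in
the output so decompression needs no external file.

Index parameters: k = 14, every 4th reference position sampled, candidate
lists capped at 8 (smallest gpos kept), k-mers containing non-ACGT skipped.
Queries sample every 3rd position of the read — a stride coprime to the
reference stride, so every sampling phase is covered — on both strands.
Each index hit implies a start position; the (gpos, strand) with the most
votes wins, ties preferring forward strand then smaller gpos. Alignment is
gapless by design: a vote minimum of 2 and a contig-span check reject
placements that would not compress well, and rejected reads store their
sequence verbatim through acgt. Reference bases outside ACGT never match
(their bitmap bit is 0 and the read base goes to NONREF), keeping bitmap
semantics byte-exact. The aligner makes no claim of biological correctness.

With ~25,000 sampled 14-mers per 100 kb and ~46 query k-mers per 150-bp
read, an exact read accrues ≈11 votes at its true position, which is why
recall on exact reads is effectively 100% and the no-alignment path is
reserved for genuinely foreign sequence.

## Subsetting and integrity

During segmentation the SAM and VCF segmenters report (chromosome,
position) per line; the framework keeps one (vblock, chrom, min, max) entry
per chromosome per vblock and writes them as the random-access section.
`--regions` skips vblocks whose extents miss every requested region
(observable through the skipped/decompressed counters) and filters lines
exactly within the vblocks it does decode. Region strings are 1-based
inclusive (`chrom`, `chrom:start`, `chrom:start-end`, `chrom:start-`).
Every section carries a CRC32 — decode failures surface as corrupt-archive
errors — while source integrity is an MD5 over the uncompressed input
stream, verified on every decompression (`--test` decompresses to a null
sink). Trailing-newline-less text inputs are flagged in the footer and
trimmed on emission.

## Synthetic data

The generators produce: uniform-random ACGT references (60-column wrap,
optional N islands); reads sampled uniformly with reverse-complementation
probability 0.5, per-base mutation (default 0.5%), a dominant quality score
at 85% frequency, and a truth sidecar of true gpos/strand per read; VCFs
with sorted unique positions, REF taken from the reference, genotypes drawn
at 2% minor-allele frequency with a configurable phased fraction; SAM files
mixing exact, mutated, soft-clipped, inserted, reverse-strand, secondary
and unmapped records with MC:Z tags mirroring CIGARs. All are pure
functions of (parameters, seed).

They deliberately do not model platform error profiles, quality-score
correlation along the read, duplication, indel-rich alignment, or real
population LD structure. Passing tests therefore demonstrate structural
correctness (losslessness, determinism, index behaviour, codec advantage on
the stated distributions), not field-calibrated compression ratios; ratios
on real data will differ, most visibly in the quality channel.

## Known limitations

- SAM is handled in its text dialect; BAM/CRAM, BCF and encrypted archives
  are out of scope, and `.gz` inputs are decompressed on read (decompression
  emits plain text, not a byte-identical `.gz`).
- The aligner is gapless; indel-heavy reads fall back to mismatch-dense
  bitmaps or verbatim storage rather than gapped placement.
- VCF ALT alleles are not checked against the reference (REF is); sample
  columns whose field count disagrees with FORMAT are stored verbatim and
  cannot be sample-subset.
- Paired-mate state is replayed from mate 1 during decompression, so pair
  mode forces serial segmentation and unbinding processes files in order.
- Memory scales with the archive (inputs are processed in RAM); this is a
  desk-scale tool, not a streaming server.
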