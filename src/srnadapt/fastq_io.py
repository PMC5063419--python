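"""FASTQ reading, writing, sampling and quality trimming.

Input may be plain or gzip-compressed FASTQ (detected by magic bytes, not
file extension).  Reads are sampled in file order: adapter prediction looks
at the first N reads of a library, which is what the 50,000-read default of
the predictor expects.  Quality trimming uses the Mott algorithm (the
3'-end trimmer of BWA and cutadapt).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO, Iterable, Sequence

_VALID_BASES = frozenset("ACGTN")

GZIP_MAGIC = b"\x1f\x8b"


class FastqParseError(ValueError):
    """Malformed FASTQ record; the message names the offending line."""


class PhredDetectionError(ValueError):
    """Phred offset could not be inferred from the quality strings."""


class QualityEncodingError(ValueError):
    """A quality character decodes to a negative score under the declared offset."""


@dataclass(frozen=True, slots=True)
class SequenceRead:
    """One FASTQ record.

    ``bases`` is uppercase over {A, C, G, T, N} and ``quals`` is the raw
    quality string of equal length (the Phred offset is carried separately
    by the caller, because it is a property of the file, not the read).
    """

    read_id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: bases ({len(self.bases)}) and "
                f"qualities ({len(self.quals)}) differ in length"
            )

    def __len__(self) -> int:
        return len(self.bases)


def _open_maybe_gzip(source: str | Path | BinaryIO) -> io.BufferedReader:
    """Open ``source`` for binary reading, transparently ungzipping."""
    if isinstance(source, (str, Path)):
        raw: BinaryIO = open(source, "rb")
    else:
        raw = source
    buffered = raw if isinstance(raw, io.BufferedReader) else io.BufferedReader(raw)  # type: ignore[arg-type]
    if buffered.peek(2)[:2] == GZIP_MAGIC:
        return io.BufferedReader(gzip.GzipFile(fileobj=buffered))  # type: ignore[arg-type]
    return buffered


def read_fastq(
    source: str | Path | BinaryIO,
    limit: int | None = None,
) -> list[SequenceRead]:
    """Read at most ``limit`` records from a FASTQ file in file order.

    Parameters
    ----------
    source
        Path or binary stream; plain or gzip-compressed (magic-byte
        detection).
    limit
        Stop after this many records; ``None`` reads the whole file.
        Sampling "the first N reads" is deliberate -- adapter signal is
        position-independent, and file order keeps the sample reproducible.

    Returns
    -------
    list of SequenceRead with uppercased bases.  An empty file yields an
    empty list; a truncated or malformed record raises
    :class:`FastqParseError` naming the line number.
    """
    if limit is not None and limit <= 0:
        raise ValueError("limit must be positive (or None for unlimited)")
    reads: list[SequenceRead] = []
    stream = _open_maybe_gzip(source)
    line_no = 0
    while limit is None or len(reads) < limit:
        header = stream.readline()
        if not header:
            break
        line_no += 1
        header_s = header.decode("ascii").rstrip("\r\n")
        if not header_s.startswith("@"):
            raise FastqParseError(
                f"line {line_no}: expected '@' header, got {header_s[:30]!r}"
            )
        seq_line = stream.readline()
        plus_line = stream.readline()
        qual_line = stream.readline()
        if not qual_line:
            raise FastqParseError(
                f"line {line_no}: record starting here is truncated "
                "(FASTQ records are 4 lines)"
            )
        bases = seq_line.decode("ascii").rstrip("\r\n").upper()
        if not set(bases) <= _VALID_BASES:
            bad = sorted(set(bases) - _VALID_BASES)
            raise FastqParseError(
                f"line {line_no + 1}: sequence contains non-ACGTN characters {bad}"
            )
        if not plus_line.decode("ascii").startswith("+"):
            raise FastqParseError(f"line {line_no + 2}: expected '+' separator")
        quals = qual_line.decode("ascii").rstrip("\r\n")
        if len(quals) != len(bases):
            raise FastqParseError(
                f"line {line_no + 3}: quality length {len(quals)} != "
                f"sequence length {len(bases)}"
            )
        line_no += 3
        reads.append(SequenceRead(header_s[1:], bases, quals))
    return reads


def write_fastq(
    reads: Iterable[SequenceRead],
    sink: str | Path | BinaryIO,
    gzip_out: bool = False,
) -> int:
    """Write records as 4-line FASTQ; returns the record count.

    Round-trips bit-exact through :func:`read_fastq` for valid records.
    """
    own = isinstance(sink, (str, Path))
    raw: BinaryIO = open(sink, "wb") if own else sink  # type: ignore[assignment]
    stream: BinaryIO = gzip.GzipFile(fileobj=raw, mode="wb") if gzip_out else raw  # type: ignore[assignment]
    n = 0
    try:
        for read in reads:
            stream.write(
                f"@{read.read_id}\n{read.bases}\n+\n{read.quals}\n".encode("ascii")
            )
            n += 1
    finally:
        if gzip_out:
            stream.close()
        if own:
            raw.close()
    return n


def detect_phred_offset(reads: Sequence[SequenceRead]) -> int:
    """Infer the Phred offset (33 or 64) from quality characters.

    Any character code below 64 is impossible under the offset-64 encoding,
    so the minimum code over the sample decides: ``min < 64`` -> 33, else 64.
    Raises :class:`PhredDetectionError` when no read carries a quality
    string, in which case the caller must supply the offset explicitly.
    """
    lo = None
    for read in reads:
        if read.quals:
            m = min(read.quals)
            if lo is None or m < lo:
                lo = m
    if lo is None:
        raise PhredDetectionError(
            "no quality strings present; pass the Phred offset explicitly "
            "(33 or 64)"
        )
    return 33 if ord(lo) < 64 else 64


def mott_trim(read: SequenceRead, cutoff: int, offset: int = 33) -> SequenceRead:
    """Trim the 3' end of a read by the Mott algorithm.

    Walking from the 3' end toward the 5' end, accumulate
    ``sum(cutoff - q_i)`` over the suffix considered so far and remember the
    position where this running sum is maximal.  If that maximum is
    positive, the suffix starting there is removed; otherwise the read is
    returned unchanged.  Equivalently: remove the suffix whose summed
    quality shortfall below ``cutoff`` is largest.  Ties are broken toward
    the 3' end (retain more bases), which preserves adapter signal.

    The result is always a (possibly empty) prefix of the input and the
    operation is idempotent at a fixed cutoff.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    quals = [ord(c) - offset for c in read.quals]
    if quals and min(quals) < 0:
        raise QualityEncodingError(
            f"read {read.read_id!r}: quality score below zero under "
            f"offset {offset}; wrong Phred offset?"
        )
    best = 0
    cut = len(quals)
    running = 0
    for i in range(len(quals) - 1, -1, -1):
        running += cutoff - quals[i]
        if running > best:  # strict: ties keep the cut closest to the 3' end
            best = running
            cut = i
    if cut == len(quals):
        return read
    return SequenceRead(read.read_id, read.bases[:cut], read.quals[:cut])
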