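"""Raw-read preprocessing: adapter, terminal-base and UMI removal.

The library construction leaves every raw read with the layout

    [7-nt UMI] [insert] [1 untemplated base] [3' adapter ...]

and preprocessing inverts it in three fixed steps, in this order:

1. cut the 3' adapter at its first (leftmost) occurrence, allowing a
   configurable mismatch fraction and a 3'-anchored partial match at the
   read end;
2. drop the final untemplated base(s) of what remains;
3. drop the leading UMI bases, recording them in the read id.

Reads too short to survive all three steps become discarded records
with a reason, never exceptions.  Reads without any adapter occurrence
are kept whole (inserts longer than the sequencing cycle count
legitimately lack adapter).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

DEFAULT_ADAPTER = "GATCGGAAGAGCACACGTCT"
DEFAULT_UMI_LEN = 7
DEFAULT_TRAILING = 1
#: reads below this insert length are dropped unless classified as tRNA
DEFAULT_MIN_NON_TRNA_LEN = 16
#: absolute floor for tRNA-classified reads (one below the non-tRNA minimum)
DEFAULT_MIN_TRNA_LEN = 15


@dataclass(frozen=True)
class RawRead:
    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.read_id}: seq/qual length mismatch")


@dataclass
class ProcessedRead:
    read_id: str
    insert_seq: str = ""
    umi: str = ""
    discarded: bool = False
    reason: str = ""
    #: set by length_filter; consumed after classification
    short: bool = False


def find_adapter(
    seq: str,
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> int:
    """Position of the first adapter occurrence, or -1.

    A full-length match may start anywhere; a partial match (>=
    ``min_overlap``) is only accepted when anchored at the read's 3'
    end.  ``max_error_rate`` mismatches per matched base are tolerated.
    """
    exact = seq.find(adapter)
    n = len(seq)
    a = len(adapter)
    for i in range(n - min_overlap + 1):
        if exact != -1 and i > exact:
            break
        overlap = min(a, n - i)
        if overlap < a and i + overlap != n:
            continue
        budget = int(max_error_rate * overlap)
        mism = 0
        for x, y in zip(seq[i : i + overlap], adapter):
            if x != y:
                mism += 1
                if mism > budget:
                    break
        else:
            return i
    return exact


def trim_read(
    raw: RawRead,
    adapter: str = DEFAULT_ADAPTER,
    umi_len: int = DEFAULT_UMI_LEN,
    trailing: int = DEFAULT_TRAILING,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> ProcessedRead:
    """Apply the three trimming steps in their stated order."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if umi_len < 0 or trailing < 0:
        raise ValueError("umi_len and trailing must be >= 0")
    pos = find_adapter(raw.seq, adapter, max_error_rate, min_overlap)
    remainder = raw.seq[:pos] if pos != -1 else raw.seq
    if len(remainder) < umi_len + trailing + 1:
        return ProcessedRead(
            raw.read_id, discarded=True, reason="too_short_after_trimming"
        )
    remainder = remainder[: len(remainder) - trailing]
    umi = remainder[:umi_len]
    insert = remainder[umi_len:]
    return ProcessedRead(raw.read_id, insert_seq=insert, umi=umi)


def length_filter(
    reads: Iterable[ProcessedRead],
    min_non_trna: int = DEFAULT_MIN_NON_TRNA_LEN,
) -> list[ProcessedRead]:
    """Flag inserts below the non-tRNA minimum length.

    The flag is deferred: flagged reads survive preprocessing and are
    dropped after classification unless they resolve to the tRNA
    category (the minimum applies to non-tRNA reads only).
    """
    out = []
    for read in reads:
        if not read.discarded and len(read.insert_seq) < min_non_trna:
            read.short = True
        out.append(read)
    return out


# ---------------------------------------------------------------------------
# FASTQ I/O


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield RawRead(entry.name, entry.sequence, entry.quality or "")


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write (read_id, seq, qual) triples; gzip when the name ends .gz.

    The gzip mtime field is pinned to zero so identical content yields
    identical bytes (reproducible reruns).
    """
    import contextlib
    import io

    n = 0
    with contextlib.ExitStack() as stack:
        if str(path).endswith(".gz"):
            # fileobj form: neither mtime nor filename enters the header
            raw = stack.enter_context(open(path, "wb"))
            gz = stack.enter_context(
                gzip.GzipFile(fileobj=raw, mode="wb", mtime=0, filename="")
            )
            fh = stack.enter_context(io.TextIOWrapper(gz))
        else:
            fh = stack.enter_context(open(path, "wt"))
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


@dataclass
class TrimStats:
    total: int = 0
    kept: int = 0
    discarded: int = 0
    flagged_short: int = 0
    reasons: dict = field(default_factory=dict)


def trim_fastq(
    in_path: str | Path,
    out_path: str | Path | None = None,
    discard_path: str | Path | None = None,
    adapter: str = DEFAULT_ADAPTER,
    umi_len: int = DEFAULT_UMI_LEN,
    trailing: int = DEFAULT_TRAILING,
    min_non_trna: int = DEFAULT_MIN_NON_TRNA_LEN,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> tuple[list[ProcessedRead], TrimStats]:
    """Trim a whole FASTQ; optionally write inserts (UMI moved into the
    header as ``read_id#UMI``) and a discard-reason TSV."""
    processed = []
    stats = TrimStats()
    for raw in read_fastq(in_path):
        read = trim_read(raw, adapter, umi_len, trailing, max_error_rate, min_overlap)
        processed.append(read)
        stats.total += 1
        if read.discarded:
            stats.discarded += 1
            stats.reasons[read.reason] = stats.reasons.get(read.reason, 0) + 1
        else:
            stats.kept += 1
    processed = length_filter(processed, min_non_trna)
    stats.flagged_short = sum(r.short for r in processed)
    if out_path is not None:
        write_fastq(
            (
                (f"{r.read_id}#{r.umi}", r.insert_seq, "I" * len(r.insert_seq))
                for r in processed
                if not r.discarded
            ),
            out_path,
        )
    if discard_path is not None:
        with open(discard_path, "w") as fh:
            fh.write("read_id\treason\n")
            for r in processed:
                if r.discarded:
                    fh.write(f"{r.read_id}\t{r.reason}\n")
    return processed, stats
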