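"""FASTQ grooming: adaptor trimming, quality filtering, barcode dedup.

The library structure is 5'-adaptor (ending in a 5-nt random barcode) +
insert + 3'-adaptor. After sequencing, a read is barcode + insert, with
the 3' adaptor visible whenever the insert is shorter than the read.
Processing order: trim the 3' adaptor (discarding reads that contain the
5' adaptor, or that are too short after clipping), split off the barcode,
filter on length and quality, then collapse PCR duplicates on the
(barcode, insert) key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .synth import ADAPTOR_3P, ADAPTOR_5P


class FastqParseError(ValueError):
    pass


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FastqParseError(
                f"{self.read_id}: sequence/quality length mismatch"
            )


@dataclass(frozen=True)
class TaggedRead:
    """A trimmed read split into its random barcode and insert."""

    read_id: str
    barcode: str
    insert: str
    quality: str  # quality of the insert only

    def __post_init__(self) -> None:
        if len(self.insert) < 1 or len(self.quality) != len(self.insert):
            raise ValueError(f"{self.read_id}: malformed tagged read")


@dataclass
class FilterReport:
    """Exact read accounting through the preprocessing stages."""

    input: int = 0
    adaptor_discarded: int = 0  # contained the 5' adaptor
    too_short: int = 0
    low_quality: int = 0
    duplicates_removed: int = 0
    surviving: int = 0

    def check(self) -> None:
        total = (
            self.adaptor_discarded
            + self.too_short
            + self.low_quality
            + self.duplicates_removed
            + self.surviving
        )
        if total != self.input:
            raise AssertionError(
                f"read accounting broken: {total} accounted vs {self.input} input"
            )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            for k, v in vars(self).items():
                fh.write(f"{k}\t{v}\n")


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4:
        raise FastqParseError(f"{path}: truncated FASTQ (line count not divisible by 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise FastqParseError(f"malformed FASTQ record at line {i + 1}")
        yield FastqRead(head[1:].split()[0], seq, qual)


def write_fastq(reads: Iterable[TaggedRead], path: str | Path) -> None:
    """Write tagged reads; the barcode is kept in the header for traceability."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} BC:{r.barcode}\n{r.insert}\n+\n{r.quality}\n")


def _find_adaptor_3p(seq: str, adaptor: str, min_overlap: int) -> int:
    """Leftmost trim point: full adaptor inside the read, or an adaptor
    prefix of >= min_overlap nt at the read's 3' end. -1 if absent."""
    n = len(seq)
    for i in range(n):
        tail = seq[i:]
        if len(tail) >= len(adaptor):
            if tail.startswith(adaptor):
                return i
        elif len(tail) >= min_overlap and adaptor.startswith(tail):
            return i
    return -1


def trim_adaptor(
    read: FastqRead,
    adaptor_3p: str = ADAPTOR_3P,
    adaptor_5p: str = ADAPTOR_5P,
    min_post_trim_len: int = 1,
    min_overlap: int = 5,
) -> tuple[FastqRead | None, str | None]:
    """Clip the 3' adaptor; returns ``(read, None)`` or ``(None, reason)``.

    Reads containing the 5' adaptor anywhere are discarded (they indicate
    adaptor-dimer or missing insert). Reads with no adaptor overlap pass
    through unchanged.
    """
    if not adaptor_3p or not adaptor_5p:
        raise ValueError("adaptor sequences must be non-empty")
    if adaptor_5p in read.sequence:
        return None, "5p_adaptor"
    cut = _find_adaptor_3p(read.sequence, adaptor_3p, min_overlap)
    if cut == -1:
        return read, None
    if cut < min_post_trim_len:
        return None, "too_short"
    return FastqRead(read.read_id, read.sequence[:cut], read.quality[:cut]), None


def extract_barcode(read: FastqRead, barcode_length: int = 5) -> TaggedRead | None:
    """Split off the 5' random barcode; None if the read is too short."""
    if len(read.sequence) <= barcode_length:
        return None
    return TaggedRead(
        read_id=read.read_id,
        barcode=read.sequence[:barcode_length],
        insert=read.sequence[barcode_length:],
        quality=read.quality[barcode_length:],
    )


def mean_phred(quality: str) -> float:
    vals = [ord(c) - 33 for c in quality]
    if any(v < 0 or v > 93 for v in vals):
        raise FastqParseError("quality string is not Phred+33")
    return sum(vals) / len(vals)


def quality_filter(
    read: TaggedRead,
    min_len: int = 15,
    min_q: float = 20.0,
    per_base: bool = False,
) -> str | None:
    """Return a drop reason ('too_short' | 'low_quality') or None to keep.

    The quality criterion is mean Phred >= min_q over the insert by
    default; ``per_base=True`` requires every base to pass instead.
    Boundaries are inclusive: a 15-nt insert at exactly Q20 is kept.
    """
    if len(read.insert) < min_len:
        return "too_short"
    if per_base:
        ok = all(ord(c) - 33 >= min_q for c in read.quality)
    else:
        ok = mean_phred(read.quality) >= min_q
    return None if ok else "low_quality"


def dedup(
    reads: Iterable[TaggedRead], drop_all: bool = False
) -> tuple[list[TaggedRead], int]:
    """Collapse PCR duplicates on the (barcode, insert) key.

    The first occurrence of each key is kept; ``drop_all=True`` instead
    removes every read whose key occurs more than once. Returns the
    surviving reads and the number removed.
    """
    reads = list(reads)
    if drop_all:
        from collections import Counter

        counts = Counter((r.barcode, r.insert) for r in reads)
        kept = [r for r in reads if counts[(r.barcode, r.insert)] == 1]
        return kept, len(reads) - len(kept)
    seen: set[tuple[str, str]] = set()
    kept = []
    for r in reads:
        key = (r.barcode, r.insert)
        if key not in seen:
            seen.add(key)
            kept.append(r)
    return kept, len(reads) - len(kept)


def preprocess_fastq(
    reads: Iterable[FastqRead],
    adaptor_3p: str = ADAPTOR_3P,
    adaptor_5p: str = ADAPTOR_5P,
    barcode_length: int = 5,
    min_len: int = 15,
    min_q: float = 20.0,
    per_base: bool = False,
    drop_all_duplicates: bool = False,
) -> tuple[list[TaggedRead], FilterReport]:
    """Full grooming pipeline: trim, barcode, filter, dedup, with accounting."""
    report = FilterReport()
    tagged: list[TaggedRead] = []
    for read in reads:
        report.input += 1
        trimmed, reason = trim_adaptor(read, adaptor_3p, adaptor_5p)
        if trimmed is None:
            if reason == "5p_adaptor":
                report.adaptor_discarded += 1
            else:
                report.too_short += 1
            continue
        tr = extract_barcode(trimmed, barcode_length)
        if tr is None:
            report.too_short += 1
            continue
        drop = quality_filter(tr, min_len=min_len, min_q=min_q, per_base=per_base)
        if drop == "too_short":
            report.too_short += 1
            continue
        if drop == "low_quality":
            report.low_quality += 1
            continue
        tagged.append(tr)
    unique, removed = dedup(tagged, drop_all=drop_all_duplicates)
    report.duplicates_removed = removed
    report.surviving = len(unique)
    report.check()
    return unique, report
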