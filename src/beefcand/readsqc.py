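"""Whole-read quality filtering and base-level quality summaries for FASTQ.

Clean reads are obtained by removing (in this priority order) reads that
contain an adapter, reads with more than 10% ambiguous bases (N), and reads
in which more than half of the bases have a Phred quality of 20 or below.
Reads are removed whole — no trimming. Q20/Q30 are the percentages of bases
with Phred quality strictly above 20 and 30; GC content is computed over
non-N bases.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

# Illumina TruSeq read-1 / read-2 adapter sequences, the default contaminant
# set; exact-substring matching (no mismatches).
TRUSEQ_ADAPTERS: tuple[str, ...] = (
    "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA",
    "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT",
)


@dataclass
class ReadRecord:
    id: str
    bases: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id}: negative Phred score")


@dataclass
class QCSummary:
    """Read-removal tally and clean-data base-quality statistics."""

    n_raw: int
    n_clean: int
    n_adapter: int
    n_highn: int
    n_lowq: int
    q20: float
    q30: float
    gc: float

    def __post_init__(self) -> None:
        removed = self.n_adapter + self.n_highn + self.n_lowq
        if self.n_clean + removed != self.n_raw:
            raise ValueError("QC counts do not add up to n_raw")
        if not (0.0 <= self.q30 <= self.q20 <= 100.0):
            raise ValueError("expected 0 <= q30 <= q20 <= 100")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_tsv(self) -> str:
        d = asdict(self)
        return (
            "\t".join(d.keys())
            + "\n"
            + "\t".join(f"{v:.4f}" if isinstance(v, float) else str(v) for v in d.values())
            + "\n"
        )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Parse a (possibly gzipped) Phred+33 FASTQ file into ReadRecords.

    A malformed record raises a ValueError naming the record index.
    """
    index = 0
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                yield ReadRecord(
                    id=rec.id,
                    bases=str(rec.seq).upper(),
                    qualities=rec.letter_annotations["phred_quality"],
                )
                index += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write Phred+33 FASTQ; returns the number of records written."""
    n = 0
    with _open_text(path, "wt") as out:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            out.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")
            n += 1
    return n


def is_low_quality(read: ReadRecord, phred_cutoff: int = 20, max_fraction: float = 0.5) -> bool:
    """True iff strictly more than half the bases have Phred <= 20."""
    if len(read.bases) == 0:
        raise ValueError(f"read {read.id}: empty read")
    n_low = sum(1 for q in read.qualities if q <= phred_cutoff)
    return n_low / len(read.qualities) > max_fraction


def has_excess_n(read: ReadRecord, max_fraction: float = 0.10) -> bool:
    """True iff the fraction of N bases is strictly greater than 10%."""
    if len(read.bases) == 0:
        raise ValueError(f"read {read.id}: empty read")
    return read.bases.count("N") / len(read.bases) > max_fraction


def has_adapter(read: ReadRecord, adapters: Sequence[str] = TRUSEQ_ADAPTERS) -> bool:
    """True iff any adapter occurs as an exact substring of the read."""
    if not adapters:
        raise ValueError("adapter set must be non-empty")
    return any(a in read.bases for a in adapters)


def filter_reads(
    reads: Iterable[ReadRecord],
    adapters: Sequence[str] = TRUSEQ_ADAPTERS,
) -> tuple[list[ReadRecord], QCSummary]:
    """Apply the three whole-read filters and summarize the clean output.

    Each removed read is attributed to exactly one reason, by priority
    adapter > excess N > low quality. Quality percentages in the returned
    summary are computed on the clean reads.
    """
    clean: list[ReadRecord] = []
    n_raw = n_adapter = n_highn = n_lowq = 0
    for read in reads:
        n_raw += 1
        if has_adapter(read, adapters):
            n_adapter += 1
        elif has_excess_n(read):
            n_highn += 1
        elif is_low_quality(read):
            n_lowq += 1
        else:
            clean.append(read)
    if clean:
        q20, q30, gc = summarize_quality(clean)
    else:
        q20 = q30 = gc = 0.0
    summary = QCSummary(
        n_raw=n_raw,
        n_clean=len(clean),
        n_adapter=n_adapter,
        n_highn=n_highn,
        n_lowq=n_lowq,
        q20=q20,
        q30=q30,
        gc=gc,
    )
    return clean, summary


def summarize_quality(reads: Iterable[ReadRecord]) -> tuple[float, float, float]:
    """Return (Q20, Q30, GC) percentages over all bases of all reads.

    Q20/Q30 count bases with Phred strictly above 20/30; the GC denominator
    excludes N bases.
    """
    n_bases = n_q20 = n_q30 = n_gc = n_acgt = 0
    for read in reads:
        n_bases += len(read.bases)
        for q in read.qualities:
            if q > 20:
                n_q20 += 1
                if q > 30:
                    n_q30 += 1
        for b in read.bases:
            if b in "GC":
                n_gc += 1
                n_acgt += 1
            elif b in "AT":
                n_acgt += 1
    if n_bases == 0:
        raise ValueError("cannot summarize an empty read stream")
    gc = 100.0 * n_gc / n_acgt if n_acgt else 0.0
    return 100.0 * n_q20 / n_bases, 100.0 * n_q30 / n_bases, gc
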