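"""Shared domain types for the candidate-gene pipeline.

Coordinates are 1-based inclusive throughout (gene tables and QTL spans are
printed that way in cattle genetics resources on UMD3.1.x assemblies); BED
export converts to 0-based half-open at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


def normalize_chrom(name: str | int) -> str:
    """Normalize a chromosome label: strip a leading ``chr`` and uppercase.

    ``chr4`` and ``4`` map to the same key; ``x`` maps to ``X``.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper()


@dataclass(frozen=True)
class GeneModel:
    """A gene as a genomic span plus the length used for FPKM."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    symbol: Optional[str] = None
    length: Optional[int] = None
    annotation_status: str = "annotated"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: 1-based start must be >= 1")
        if self.effective_length <= 0:
            raise ValueError(f"{self.gene_id}: non-positive length")
        if self.annotation_status not in ("annotated", "pseudogene", "novel"):
            raise ValueError(
                f"{self.gene_id}: unknown annotation status "
                f"{self.annotation_status!r}"
            )

    @property
    def effective_length(self) -> int:
        """Length used for FPKM: explicit exonic length if supplied, else span."""
        if self.length is not None:
            return self.length
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class QTLRecord:
    """A trait-associated genomic region with a peak position."""

    qtl_id: str
    chromosome: str
    span_start: int
    span_end: int
    peak: int
    trait_code: str
    trait_class: str
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.span_start > self.span_end:
            raise ValueError(f"{self.qtl_id}: span_start > span_end")
        if not (self.span_start <= self.peak <= self.span_end):
            raise ValueError(f"{self.qtl_id}: peak outside span")


@dataclass(frozen=True)
class SNPRecord:
    """A trait-associated point variant from a GWAS catalog."""

    snp_name: str
    chromosome: str
    position: int
    trait_code: str
    trait_class: str
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.snp_name}: position must be >= 1")


@dataclass
class QTLMatch:
    """Evidence that a gene overlaps a QTL, with signed peak distance."""

    qtl: QTLRecord
    distance_cm: float


@dataclass
class SNPMatch:
    """Evidence that a gene lies near a SNP, with nearest-edge distance."""

    snp: SNPRecord
    distance_mb: float


@dataclass
class CandidateEvidence:
    """Per-gene screen evidence collected for the candidate report."""

    gene: GeneModel
    qtl_matches: list[QTLMatch] = field(default_factory=list)
    snp_matches: list[SNPMatch] = field(default_factory=list)

    @property
    def passes_qtl(self) -> bool:
        return len(self.qtl_matches) > 0

    @property
    def passes_snp(self) -> bool:
        return len(self.snp_matches) > 0
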