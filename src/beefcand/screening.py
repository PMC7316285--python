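"""QTL-SNP positional screening of DEGs for candidate genes.

The screening procedure is purely positional, run over a trait-filtered QTL
catalog and a trait-filtered GWAS SNP pool:

1. QTL screen — a DEG passes when its genomic span lies within (by default,
   overlaps) the span of at least one trait-associated QTL; the signed
   genetic distance from the gene midpoint to the QTL peak is reported as
   annotation (never used as a filter).
2. SNP screen — a DEG passes when its distance to at least one
   trait-associated SNP is strictly less than 5 Mb (nearest gene edge;
   zero if the SNP falls inside the gene).
3. Candidates — the intersection of the two pass sets.

Distances to QTL peaks are converted from physical distance with a uniform
(or per-chromosome) cM-per-Mb factor. Gene and catalog chromosomes are
normalized (leading "chr" stripped) before comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .models import (
    CandidateEvidence,
    GeneModel,
    QTLMatch,
    QTLRecord,
    SNPMatch,
    SNPRecord,
    normalize_chrom,
)

MEAT_QUALITY = "meat_quality"
REPRODUCTION = "reproduction"

#: Controlled trait vocabulary: code -> (trait class, description).
TRAIT_VOCABULARY: dict[str, tuple[str, str]] = {
    "CW": (MEAT_QUALITY, "carcass weight"),
    "IMF": (MEAT_QUALITY, "intramuscular fat"),
    "FT12R": (MEAT_QUALITY, "fat thickness at the 12th rib"),
    "LMY": (MEAT_QUALITY, "lean meat yield"),
    "SF": (MEAT_QUALITY, "shear force"),
    "CC": (MEAT_QUALITY, "carcass conformation"),
    "IMFP": (MEAT_QUALITY, "intramuscular fat percentage"),
    "LDMA": (MEAT_QUALITY, "loin muscle area"),
    "MS": (MEAT_QUALITY, "marbling score"),
    "SC": (REPRODUCTION, "scrotal circumference"),
    "GL": (REPRODUCTION, "gestation length"),
    "SM": (REPRODUCTION, "sperm motility"),
    "CCR": (REPRODUCTION, "cow conception rate"),
}

DEFAULT_MAX_SNP_DISTANCE_MB = 5.0
DEFAULT_CM_PER_MB = 1.0

OVERLAP_MODES = ("any", "containment", "midpoint")


@dataclass
class ScreenResult:
    """Pass sets with per-gene evidence and the screening parameters used."""

    qtl_pass: dict[str, CandidateEvidence]
    snp_pass: dict[str, CandidateEvidence]
    parameters: dict = field(default_factory=dict)

    @property
    def candidates(self) -> set[str]:
        return set(self.qtl_pass) & set(self.snp_pass)

    def report(self) -> pd.DataFrame:
        """Candidate-report rows: one row per (gene, evidence) pairing."""
        rows = []
        for gid in sorted(self.candidates):
            gene = self.qtl_pass[gid].gene
            qtl_matches = self.qtl_pass[gid].qtl_matches
            snp_matches = self.snp_pass[gid].snp_matches
            for i in range(max(len(qtl_matches), len(snp_matches))):
                q = qtl_matches[i] if i < len(qtl_matches) else None
                s = snp_matches[i] if i < len(snp_matches) else None
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "symbol": gene.symbol or gene.gene_id,
                        "chromosome": gene.chromosome,
                        "start": gene.start,
                        "end": gene.end,
                        "qtl_id": q.qtl.qtl_id if q else "",
                        "qtl_peak_distance_cm": round(q.distance_cm, 1) if q else float("nan"),
                        "qtl_trait": q.qtl.trait_code if q else "",
                        "snp_name": s.snp.snp_name if s else "",
                        "snp_distance_mb": round(s.distance_mb, 2) if s else float("nan"),
                        "snp_trait": s.snp.trait_code if s else "",
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "symbol", "chromosome", "start", "end",
                "qtl_id", "qtl_peak_distance_cm", "qtl_trait",
                "snp_name", "snp_distance_mb", "snp_trait",
            ],
        )


def filter_by_trait_class(
    records: Sequence[QTLRecord] | Sequence[SNPRecord],
    trait_class: str,
    vocabulary: Mapping[str, tuple[str, str]] = TRAIT_VOCABULARY,
) -> list:
    """Keep records whose trait code belongs to ``trait_class``.

    Unknown trait codes are rejected (all offenders listed) rather than
    silently dropped, so vocabulary drift in a catalog surfaces early.
    """
    unknown = sorted({r.trait_code for r in records if r.trait_code not in vocabulary})
    if unknown:
        raise ValueError(f"unknown trait codes in catalog: {unknown}")
    classes = {r[0] for r in vocabulary.values()}
    if trait_class not in classes:
        raise ValueError(f"unknown trait class {trait_class!r}; known: {sorted(classes)}")
    return [r for r in records if vocabulary[r.trait_code][0] == trait_class]


def gene_qtl_overlap(gene: GeneModel, qtl: QTLRecord, mode: str = "any") -> bool:
    """Does a gene lie within a QTL region, under the given convention?

    Modes (1-based inclusive coordinates): ``any`` — the spans share at
    least one base; ``containment`` — the gene lies entirely inside the QTL
    span; ``midpoint`` — the gene midpoint lies inside the QTL span.
    """
    if mode not in OVERLAP_MODES:
        raise ValueError(f"overlap mode must be one of {OVERLAP_MODES}")
    if normalize_chrom(gene.chromosome) != normalize_chrom(qtl.chromosome):
        return False
    if mode == "any":
        return gene.start <= qtl.span_end and qtl.span_start <= gene.end
    if mode == "containment":
        return qtl.span_start <= gene.start and gene.end <= qtl.span_end
    return qtl.span_start <= gene.midpoint <= qtl.span_end


def distance_to_peak_cm(
    gene: GeneModel,
    qtl: QTLRecord,
    cm_per_mb: float | Mapping[str, float] = DEFAULT_CM_PER_MB,
) -> float:
    """Signed genetic distance from gene midpoint to QTL peak.

    Negative means the gene lies to the left of (before) the peak. The
    physical distance is scaled by a uniform or per-chromosome cM/Mb
    factor; this is annotation only and never filters genes.
    """
    chrom = normalize_chrom(gene.chromosome)
    if isinstance(cm_per_mb, Mapping):
        norm = {normalize_chrom(k): v for k, v in cm_per_mb.items()}
        if chrom not in norm:
            raise KeyError(f"no cM/Mb conversion for chromosome {chrom}")
        factor = norm[chrom]
    else:
        factor = float(cm_per_mb)
    return (gene.midpoint - qtl.peak) / 1.0e6 * factor


def gene_snp_distance_mb(gene: GeneModel, snp: SNPRecord) -> float:
    """Distance (Mb) from a SNP to the nearest gene edge; 0 inside the gene.

    Different chromosomes give +inf so the SNP can never satisfy a distance
    threshold.
    """
    if normalize_chrom(gene.chromosome) != normalize_chrom(snp.chromosome):
        return math.inf
    if gene.start <= snp.position <= gene.end:
        return 0.0
    return min(abs(snp.position - gene.start), abs(snp.position - gene.end)) / 1.0e6


def _check_chrom_compat(genes: Sequence[GeneModel], catalog_chroms: set[str], what: str) -> None:
    gene_chroms = {normalize_chrom(g.chromosome) for g in genes}
    if genes and catalog_chroms and not (gene_chroms & catalog_chroms):
        raise ValueError(
            f"no chromosome shared between DEGs ({sorted(gene_chroms)[:5]}...) and the "
            f"{what} catalog ({sorted(catalog_chroms)[:5]}...); check that both use the "
            "same naming scheme (a leading 'chr' is stripped automatically)"
        )


def qtl_screen(
    degs: Sequence[GeneModel],
    qtl_catalog: Sequence[QTLRecord],
    mode: str = "any",
    cm_per_mb: float | Mapping[str, float] = DEFAULT_CM_PER_MB,
) -> dict[str, CandidateEvidence]:
    """Genes overlapping at least one QTL, with all matches as evidence.

    Lookup uses a per-chromosome interval tree over QTL spans; the signed
    peak distance of every matched QTL is attached.
    """
    if mode not in OVERLAP_MODES:
        raise ValueError(f"overlap mode must be one of {OVERLAP_MODES}")
    _check_chrom_compat(degs, {normalize_chrom(q.chromosome) for q in qtl_catalog}, "QTL")
    trees: dict[str, IntervalTree] = {}
    for q in qtl_catalog:
        # half-open tree interval; +1 keeps 1-based inclusive span ends
        trees.setdefault(normalize_chrom(q.chromosome), IntervalTree()).addi(
            q.span_start, q.span_end + 1, q
        )
    result: dict[str, CandidateEvidence] = {}
    for gene in degs:
        tree = trees.get(normalize_chrom(gene.chromosome))
        if tree is None:
            continue
        hits = [iv.data for iv in sorted(tree.overlap(gene.start, gene.end + 1))]
        matches = [
            QTLMatch(q, distance_to_peak_cm(gene, q, cm_per_mb))
            for q in hits
            if gene_qtl_overlap(gene, q, mode)
        ]
        if matches:
            result[gene.gene_id] = CandidateEvidence(gene, qtl_matches=matches)
    return result


def snp_screen(
    degs: Sequence[GeneModel],
    snp_catalog: Sequence[SNPRecord],
    max_mb: float = DEFAULT_MAX_SNP_DISTANCE_MB,
) -> dict[str, CandidateEvidence]:
    """Genes with at least one SNP strictly closer than ``max_mb``."""
    if max_mb <= 0:
        raise ValueError("max_mb must be positive")
    _check_chrom_compat(degs, {normalize_chrom(s.chromosome) for s in snp_catalog}, "SNP")
    by_chrom: dict[str, list[SNPRecord]] = {}
    for s in snp_catalog:
        by_chrom.setdefault(normalize_chrom(s.chromosome), []).append(s)
    result: dict[str, CandidateEvidence] = {}
    for gene in degs:
        snps = by_chrom.get(normalize_chrom(gene.chromosome), [])
        matches = []
        for s in snps:
            d = gene_snp_distance_mb(gene, s)
            if d < max_mb:
                matches.append(SNPMatch(s, d))
        if matches:
            matches.sort(key=lambda m: m.distance_mb)
            result[gene.gene_id] = CandidateEvidence(gene, snp_matches=matches)
    return result


def intersect_candidates(
    qtl_pass: dict[str, CandidateEvidence],
    snp_pass: dict[str, CandidateEvidence],
    parameters: dict | None = None,
) -> ScreenResult:
    """Combine the two screens; candidates are the set intersection."""
    return ScreenResult(
        qtl_pass=qtl_pass, snp_pass=snp_pass, parameters=parameters or {}
    )


def screen(
    degs: Sequence[GeneModel],
    qtl_catalog: Sequence[QTLRecord],
    snp_catalog: Sequence[SNPRecord],
    trait_class: str = MEAT_QUALITY,
    max_snp_distance_mb: float = DEFAULT_MAX_SNP_DISTANCE_MB,
    overlap_mode: str = "any",
    cm_per_mb: float | Mapping[str, float] = DEFAULT_CM_PER_MB,
    vocabulary: Mapping[str, tuple[str, str]] = TRAIT_VOCABULARY,
) -> ScreenResult:
    """Trait-filter both catalogs, run both screens, and intersect."""
    qtls = filter_by_trait_class(qtl_catalog, trait_class, vocabulary)
    snps = filter_by_trait_class(snp_catalog, trait_class, vocabulary)
    qp = qtl_screen(degs, qtls, mode=overlap_mode, cm_per_mb=cm_per_mb)
    sp = snp_screen(degs, snps, max_mb=max_snp_distance_mb)
    return intersect_candidates(
        qp,
        sp,
        parameters={
            "trait_class": trait_class,
            "max_snp_distance_mb": max_snp_distance_mb,
            "overlap_mode": overlap_mode,
            "cm_per_mb": cm_per_mb if not isinstance(cm_per_mb, Mapping) else dict(cm_per_mb),
        },
    )


# ---------------------------------------------------------------------------
# catalog / gene-table (de)serialization


def genes_from_frame(df: pd.DataFrame) -> list[GeneModel]:
    """Build GeneModels from a table with gene_id, chromosome, start, end
    and optional symbol/length/annotation_status columns."""
    genes = []
    for r in df.itertuples():
        genes.append(
            GeneModel(
                gene_id=str(r.gene_id),
                chromosome=normalize_chrom(r.chromosome),
                start=int(r.start),
                end=int(r.end),
                symbol=str(r.symbol) if hasattr(r, "symbol") else None,
                length=int(r.length) if hasattr(r, "length") and pd.notna(r.length) else None,
                annotation_status=(
                    str(r.annotation_status) if hasattr(r, "annotation_status") else "annotated"
                ),
            )
        )
    return genes


def qtls_from_frame(df: pd.DataFrame) -> list[QTLRecord]:
    return [
        QTLRecord(
            qtl_id=str(r.qtl_id),
            chromosome=normalize_chrom(r.chromosome),
            span_start=int(r.span_start),
            span_end=int(r.span_end),
            peak=int(r.peak),
            trait_code=str(r.trait_code),
            trait_class=str(r.trait_class),
            source_ref=str(getattr(r, "source_ref", "")),
        )
        for r in df.itertuples()
    ]


def snps_from_frame(df: pd.DataFrame) -> list[SNPRecord]:
    return [
        SNPRecord(
            snp_name=str(r.snp_name),
            chromosome=normalize_chrom(r.chromosome),
            position=int(r.position),
            trait_code=str(r.trait_code),
            trait_class=str(r.trait_class),
            source_ref=str(getattr(r, "source_ref", "")),
        )
        for r in df.itertuples()
    ]


def genes_to_bed(genes: Iterable[GeneModel]) -> str:
    """BED (0-based half-open) export of gene spans."""
    lines = [
        f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.symbol or g.gene_id}"
        for g in genes
    ]
    return "\n".join(lines) + ("\n" if lines else "")
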