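"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: a gene annotation,
a two-group negative-binomial fragment-count matrix with planted fold
changes, QTL and SNP catalogs constructed so that a known subset of the
planted DEGs passes each positional screen, phenotype tables, triplicate
qPCR Ct plates, and FASTQ files with planted contamination. All generators
are pure functions of (config, seed); sub-seeds are derived per generator
so each table can be regenerated independently.

The default configuration mirrors a bull-vs-steer muscle RNA-seq design:
~11,500 expressed genes on 29 cattle-sized autosomes, 56 planted DEGs
(41 annotated, 4 pseudogenes, 11 novel) with |log2FC| between 1.2 and 4,
3 sequenced animals per group, and catalogs planted so that 9 annotated
DEGs pass the QTL screen, 39 pass the SNP screen, and 7 pass both.

Placement guarantees (enforced, with bounded retries, else an error):

* QTL-pass genes are chosen among genes that overlap no other gene, and
  their planted QTL spans are clipped so they overlap no other gene either;
  decoy QTLs are placed wholly in intergenic space. Hence *no* gene outside
  the planted QTL-pass set can ever pass the QTL screen — the planted
  candidate set is recoverable even when differential-expression calling
  admits a few false positives.
* SNPs are kept at least ``max_snp_distance_mb + placement_margin_mb`` away
  from every annotated DEG that must fail the SNP screen, and planted SNPs
  sit at least 1 Mb inside the distance threshold, so floating-point
  conventions cannot flip a truth label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .readsqc import ReadRecord, TRUSEQ_ADAPTERS, write_fastq
from .screening import MEAT_QUALITY, REPRODUCTION, TRAIT_VOCABULARY


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


class PlacementError(RuntimeError):
    """Feature placement failed within the retry budget."""


#: Approximate cattle autosome lengths (bp), chromosomes 1..29.
CATTLE_CHROM_LENGTHS: dict[str, int] = {
    "1": 158_300_000, "2": 137_100_000, "3": 121_400_000, "4": 120_800_000,
    "5": 121_200_000, "6": 119_500_000, "7": 112_600_000, "8": 113_400_000,
    "9": 105_700_000, "10": 104_300_000, "11": 107_300_000, "12": 91_200_000,
    "13": 84_200_000, "14": 84_600_000, "15": 85_300_000, "16": 81_700_000,
    "17": 75_200_000, "18": 66_000_000, "19": 64_100_000, "20": 72_000_000,
    "21": 71_600_000, "22": 61_400_000, "23": 52_500_000, "24": 62_700_000,
    "25": 42_900_000, "26": 51_700_000, "27": 45_400_000, "28": 46_300_000,
    "29": 51_500_000,
}

_MEAT_CODES = [c for c, (cls, _) in TRAIT_VOCABULARY.items() if cls == MEAT_QUALITY]
_REPRO_CODES = [c for c, (cls, _) in TRAIT_VOCABULARY.items() if cls == REPRODUCTION]

# fixed sub-seed tags so generators can be re-run independently
_STAGE = {"annotation": 11, "counts": 23, "qtl": 37, "snp": 41, "phenotype": 53,
          "qpcr": 61, "fastq": 71}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with bull-vs-steer defaults."""

    seed: int = 0
    n_genes: int = 11_500
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(CATTLE_CHROM_LENGTHS)
    )
    gene_length_range: tuple[int, int] = (2_000, 200_000)
    transcript_length_range: tuple[int, int] = (500, 10_000)
    n_samples_per_group: int = 3
    group_names: tuple[str, str] = ("bull", "steer")  # (calibrator, case)
    n_planted_degs: int = 56
    n_annotated_degs: int = 41
    n_pseudogene_degs: int = 4
    log2fc_range: tuple[float, float] = (1.2, 4.0)
    up_fraction: float = 37 / 56
    nb_dispersion: float = 0.05
    base_mean_range: tuple[float, float] = (5.0, 5_000.0)
    deg_base_mean_min: float = 50.0
    library_size_range: tuple[float, float] = (18e6, 25e6)
    n_qtls: int = 60
    n_snps: int = 48
    n_qtl_pass: int = 9
    planted_candidate_fraction: float = 7 / 9
    max_snp_distance_mb: float = 5.0
    placement_margin_mb: float = 1.0
    qtl_pad_bp: int = 500_000
    decoy_qtl_width_range: tuple[int, int] = (50_000, 300_000)
    reproduction_decoy_fraction: float = 0.2
    trait_vocabulary: list[str] = field(default_factory=lambda: list(_MEAT_CODES))
    max_retries: int = 5_000

    # -- derived truth sizes ------------------------------------------------
    @property
    def n_candidates(self) -> int:
        return int(round(self.n_qtl_pass * self.planted_candidate_fraction))

    @property
    def n_snp_fail(self) -> int:
        """Annotated DEGs that must fail the SNP screen (QTL-only genes)."""
        return self.n_qtl_pass - self.n_candidates

    @property
    def n_snp_pass(self) -> int:
        """Annotated DEGs passing the SNP screen: everything except the
        QTL-only genes, capped by the number of SNPs in the catalog."""
        return min(self.n_annotated_degs - self.n_snp_fail, self.n_snps)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be >= 1")
        if not self.chrom_lengths:
            raise SimConfigError("chrom_lengths must be non-empty")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise SimConfigError("chromosome lengths must be positive")
        if self.gene_length_range[1] > min(self.chrom_lengths.values()):
            raise SimConfigError(
                "maximum gene length exceeds the shortest chromosome"
            )
        if self.nb_dispersion <= 0:
            raise SimConfigError("nb_dispersion must be > 0")
        if self.n_planted_degs > self.n_genes:
            raise SimConfigError("cannot plant more DEGs than genes")
        if self.n_annotated_degs + self.n_pseudogene_degs > self.n_planted_degs:
            raise SimConfigError("annotation partition exceeds planted DEG count")
        if not (0 <= self.planted_candidate_fraction <= 1):
            raise SimConfigError("planted_candidate_fraction must lie in [0, 1]")
        if self.n_qtl_pass > self.n_annotated_degs:
            raise SimConfigError("n_qtl_pass exceeds annotated DEG count")
        if self.n_qtl_pass > self.n_qtls:
            raise SimConfigError("n_qtl_pass exceeds catalog size n_qtls")
        if self.n_snp_pass < self.n_candidates:
            raise SimConfigError(
                "n_snps is too small to let every planted candidate pass "
                "the SNP screen"
            )
        if self.max_snp_distance_mb <= self.placement_margin_mb:
            raise SimConfigError("max_snp_distance_mb must exceed the margin")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-generator stream derived from the root seed."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STAGE[stage]])
        )


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``candidate_gene_ids`` is the intersection of the two pass sets by
    construction; every planted candidate is a planted (annotated) DEG.
    """

    deg_log2fc: dict[str, float]
    deg_status: dict[str, str]
    base_means: dict[str, float]
    qtl_pass_ids: set[str]
    snp_pass_ids: set[str]
    sample_groups: dict[str, str]
    case_group: str = "steer"

    def __post_init__(self) -> None:
        annotated = self.annotated_deg_ids
        if not self.qtl_pass_ids <= annotated or not self.snp_pass_ids <= annotated:
            raise ValueError("pass sets must be subsets of the annotated DEGs")

    @property
    def deg_gene_ids(self) -> set[str]:
        return set(self.deg_log2fc)

    @property
    def annotated_deg_ids(self) -> set[str]:
        return {g for g, s in self.deg_status.items() if s == "annotated"}

    @property
    def candidate_gene_ids(self) -> set[str]:
        return self.qtl_pass_ids & self.snp_pass_ids

    def to_json(self) -> str:
        return json.dumps(
            {
                "deg_log2fc": self.deg_log2fc,
                "deg_status": self.deg_status,
                "base_means": self.base_means,
                "qtl_pass_ids": sorted(self.qtl_pass_ids),
                "snp_pass_ids": sorted(self.snp_pass_ids),
                "candidate_gene_ids": sorted(self.candidate_gene_ids),
                "sample_groups": self.sample_groups,
                "case_group": self.case_group,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            deg_log2fc=d["deg_log2fc"],
            deg_status=d["deg_status"],
            base_means=d["base_means"],
            qtl_pass_ids=set(d["qtl_pass_ids"]),
            snp_pass_ids=set(d["snp_pass_ids"]),
            sample_groups=d["sample_groups"],
            case_group=d.get("case_group", "steer"),
        )


# ---------------------------------------------------------------------------
# gene annotation


def gen_annotation(config: SimConfig) -> pd.DataFrame:
    """Place genes uniformly on the configured chromosomes.

    Returns a table with gene_id, symbol, chromosome, start, end (1-based
    inclusive genomic spans) and length; overlap between genes is allowed.
    Genomic span lengths are log-uniform over ``gene_length_range``; the
    ``length`` column is a log-uniform *transcript* (exonic) length over
    ``transcript_length_range``, capped at the span, and is the length used
    for FPKM — introns do not attract fragments.
    """
    config.validate()
    rng = config.rng("annotation")
    chroms = sorted(config.chrom_lengths, key=lambda c: (len(c), c))
    lens = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    lo, hi = config.gene_length_range
    lengths = np.floor(
        10 ** rng.uniform(np.log10(lo), np.log10(hi), size=config.n_genes)
    ).astype(int)
    chrom_idx = rng.choice(len(chroms), size=config.n_genes, p=probs)
    chrom_len_per_gene = lens[chrom_idx].astype(int)
    too_long = lengths > chrom_len_per_gene
    if too_long.any():
        i = int(np.argmax(too_long))
        raise SimConfigError(
            f"gene of length {lengths[i]} exceeds chromosome "
            f"{chroms[chrom_idx[i]]} ({chrom_len_per_gene[i]} bp)"
        )
    starts = rng.integers(1, chrom_len_per_gene - lengths + 2)
    t_lo, t_hi = config.transcript_length_range
    tx_lengths = np.minimum(
        np.floor(
            10 ** rng.uniform(np.log10(t_lo), np.log10(t_hi), size=config.n_genes)
        ).astype(int),
        lengths,
    )
    df = pd.DataFrame(
        {
            "gene_id": [f"SIMG{i + 1:06d}" for i in range(config.n_genes)],
            "symbol": [f"GENE{i + 1}" for i in range(config.n_genes)],
            "chromosome": [chroms[i] for i in chrom_idx],
            "start": starts,
            "end": starts + lengths - 1,
            "length": tx_lengths,
        }
    )
    return df.set_index("gene_id", drop=False)


def annotation_to_gff3(genes: pd.DataFrame) -> str:
    """GFF3 rendering of the gene table (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for r in genes.itertuples():
        lines.append(
            f"{r.chromosome}\tbeefcand_sim\tgene\t{r.start}\t{r.end}\t.\t+\t."
            f"\tID={r.gene_id};Name={r.symbol}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# structural helpers for placement guarantees


def _per_chrom(genes: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {
        str(c): sub.sort_values("start")
        for c, sub in genes.groupby("chromosome", sort=False)
    }


def _overlap_isolated_ids(genes: pd.DataFrame) -> set[str]:
    """Genes whose span intersects no other gene span."""
    isolated: set[str] = set()
    for _, sub in _per_chrom(genes).items():
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["gene_id"].to_numpy()
        running_max_end = np.maximum.accumulate(ends)
        for i in range(len(sub)):
            left_clear = i == 0 or running_max_end[i - 1] < starts[i]
            right_clear = i == len(sub) - 1 or starts[i + 1] > ends[i]
            # right_clear via next start is sufficient because later genes
            # start at or after starts[i+1]
            if left_clear and right_clear:
                isolated.add(ids[i])
    return isolated


def _merged_intervals(genes: pd.DataFrame) -> dict[str, np.ndarray]:
    """Merged gene intervals per chromosome, as an (n, 2) array."""
    merged: dict[str, np.ndarray] = {}
    for chrom, sub in _per_chrom(genes).items():
        out: list[list[int]] = []
        for s, e in zip(sub["start"], sub["end"]):
            if out and s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=np.int64).reshape(-1, 2)
    return merged


def _intersects_any(merged: np.ndarray, start: int, end: int) -> bool:
    if merged.size == 0:
        return False
    i = np.searchsorted(merged[:, 0], end, side="right")
    return bool(i > 0 and merged[i - 1, 1] >= start) or bool(
        i < len(merged) and merged[i, 0] <= end
    )


def _min_distance_to_spans(
    spans: Sequence[tuple[str, int, int]], chrom: str, pos: int
) -> float:
    """Distance in bp from a position to the nearest of the given spans."""
    best = np.inf
    for c, s, e in spans:
        if c != chrom:
            continue
        if s <= pos <= e:
            return 0.0
        best = min(best, abs(pos - s), abs(pos - e))
    return best


# ---------------------------------------------------------------------------
# counts with planted fold changes


def gen_counts(
    genes: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Two-group negative-binomial count matrix with planted DEGs.

    Counts for gene g in sample j are NB with mean ``s_j * mu_g * fc`` and
    variance ``mu + dispersion * mu^2``; ``fc = 2^log2fc`` applies to the
    case (steer) group for planted genes only. Per-sample scale factors
    ``s_j`` are set so the expected library size falls in
    ``library_size_range``. Base means are log-uniform over
    ``base_mean_range``; planted DEGs are drawn from genes with base mean at
    least ``deg_base_mean_min`` (DEGs detectable with a handful of animals
    per group are necessarily not at the noise floor).

    Returns (counts matrix, planted truth). The structural choices behind
    ``qtl_pass_ids``/``snp_pass_ids`` are described in the module docstring.
    """
    config.validate()
    rng = config.rng("counts")
    gene_ids = genes["gene_id"].to_numpy()
    n = len(gene_ids)
    if config.n_planted_degs > n:
        raise SimConfigError("cannot plant more DEGs than genes in annotation")
    lo, hi = config.base_mean_range
    base = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
    base_by_id = dict(zip(gene_ids, base))

    eligible = [g for g, m in zip(gene_ids, base) if m >= config.deg_base_mean_min]
    if len(eligible) < config.n_planted_degs:
        raise SimConfigError(
            "not enough genes above deg_base_mean_min to plant DEGs"
        )
    isolated = _overlap_isolated_ids(genes) & set(eligible)

    # pick the screen-structural genes first (see module docstring)
    margin_bp = int(
        (2 * config.max_snp_distance_mb + config.placement_margin_mb) * 1e6
    )
    iso_sorted = sorted(isolated)
    if len(iso_sorted) < config.n_qtl_pass:
        raise PlacementError(
            "too few overlap-isolated genes to plant the QTL-pass set; "
            "reduce gene density or n_qtl_pass"
        )
    snp_fail = list(
        rng.choice(iso_sorted, size=config.n_snp_fail, replace=False)
    )
    fail_spans = [
        (genes.loc[g, "chromosome"], genes.loc[g, "start"], genes.loc[g, "end"])
        for g in snp_fail
    ]

    def far_from_fail(gid: str) -> bool:
        row = genes.loc[gid]
        d1 = _min_distance_to_spans(fail_spans, row["chromosome"], int(row["start"]))
        d2 = _min_distance_to_spans(fail_spans, row["chromosome"], int(row["end"]))
        return min(d1, d2) > margin_bp

    cand_pool = [g for g in iso_sorted if g not in snp_fail and far_from_fail(g)]
    if len(cand_pool) < config.n_candidates:
        raise PlacementError("too few isolated genes clear of the SNP-fail genes")
    candidates = list(rng.choice(cand_pool, size=config.n_candidates, replace=False))
    qtl_pass = set(snp_fail) | set(candidates)

    fill_pool = [
        g for g in eligible if g not in qtl_pass and far_from_fail(g)
    ]
    n_fill_annotated = config.n_annotated_degs - config.n_qtl_pass
    n_other = config.n_planted_degs - config.n_annotated_degs
    if len(fill_pool) < n_fill_annotated + n_other:
        raise PlacementError("too few eligible genes to fill the planted DEG set")
    fill = list(
        rng.choice(fill_pool, size=n_fill_annotated + n_other, replace=False)
    )
    annotated_degs = sorted(qtl_pass) + fill[:n_fill_annotated]
    other_degs = fill[n_fill_annotated:]
    deg_ids = annotated_degs + other_degs
    status = {g: "annotated" for g in annotated_degs}
    for g in other_degs[: config.n_pseudogene_degs]:
        status[g] = "pseudogene"
    for g in other_degs[config.n_pseudogene_degs:]:
        status[g] = "novel"
    snp_pool = sorted(set(annotated_degs) - set(snp_fail) - set(candidates))
    n_extra = config.n_snp_pass - config.n_candidates
    snp_pass = set(candidates) | set(
        rng.choice(snp_pool, size=n_extra, replace=False) if n_extra else []
    )

    # planted effects: magnitude uniform over log2fc_range, sign by up_fraction
    mags = rng.uniform(*config.log2fc_range, size=len(deg_ids))
    signs = np.where(rng.random(len(deg_ids)) < config.up_fraction, 1.0, -1.0)
    deg_log2fc = {g: float(m * s) for g, m, s in zip(deg_ids, mags, signs)}

    fc_case = np.ones(n)
    id_to_idx = {g: i for i, g in enumerate(gene_ids)}
    for g, lfc in deg_log2fc.items():
        fc_case[id_to_idx[g]] = 2.0**lfc

    calibrator, case = config.group_names
    samples: list[str] = []
    groups: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}
    r_nb = 1.0 / config.nb_dispersion
    for group, fc in ((calibrator, np.ones(n)), (case, fc_case)):
        mu_group = base * fc
        for k in range(config.n_samples_per_group):
            name = f"{group}_{k + 1}"
            target = rng.uniform(*config.library_size_range)
            mu = mu_group * (target / mu_group.sum())
            p = r_nb / (r_nb + mu)
            columns[name] = rng.negative_binomial(r_nb, p)
            samples.append(name)
            groups[name] = group
    counts = pd.DataFrame(columns, index=genes.index)
    counts.index.name = "gene_id"
    truth = PlantedTruth(
        deg_log2fc=deg_log2fc,
        deg_status=status,
        base_means={g: float(base_by_id[g]) for g in deg_ids},
        qtl_pass_ids=set(qtl_pass),
        snp_pass_ids=snp_pass,
        sample_groups=groups,
        case_group=case,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# QTL and SNP catalogs planted around the truth


def _decoy_trait(rng: np.random.Generator, config: SimConfig) -> tuple[str, str]:
    if _REPRO_CODES and rng.random() < config.reproduction_decoy_fraction:
        code = str(rng.choice(_REPRO_CODES))
        return code, REPRODUCTION
    code = str(rng.choice(config.trait_vocabulary))
    return code, MEAT_QUALITY


def gen_qtl_catalog(
    genes: pd.DataFrame, truth: PlantedTruth, config: SimConfig
) -> pd.DataFrame:
    """QTL catalog in which exactly the planted QTL-pass genes have overlaps.

    Each QTL-pass gene gets one meat-quality QTL whose span covers the gene
    (padded by up to ``qtl_pad_bp`` but clipped so it touches no other
    gene); decoy QTLs are placed wholly between genes.
    """
    config.validate()
    rng = config.rng("qtl")
    per_chrom = _per_chrom(genes)
    merged = _merged_intervals(genes)
    rows = []
    k = 0
    for gid in sorted(truth.qtl_pass_ids):
        row = genes.loc[gid]
        chrom = str(row["chromosome"])
        sub = per_chrom[chrom]
        chrom_len = config.chrom_lengths[chrom]
        left = sub[sub["end"] < row["start"]]["end"]
        right = sub[sub["start"] > row["end"]]["start"]
        span_start = int(
            max(row["start"] - config.qtl_pad_bp, (left.max() + 1) if len(left) else 1, 1)
        )
        span_end = int(
            min(
                row["end"] + config.qtl_pad_bp,
                (right.min() - 1) if len(right) else chrom_len,
                chrom_len,
            )
        )
        k += 1
        rows.append(
            {
                "qtl_id": f"SIMQTL{k:04d}",
                "chromosome": chrom,
                "span_start": span_start,
                "span_end": span_end,
                "peak": int(rng.integers(span_start, span_end + 1)),
                "trait_code": str(rng.choice(config.trait_vocabulary)),
                "trait_class": MEAT_QUALITY,
                "source_ref": f"planted:{gid}",
            }
        )
    chroms = sorted(config.chrom_lengths, key=lambda c: (len(c), c))
    lens = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    w_lo, w_hi = config.decoy_qtl_width_range
    for _ in range(config.n_qtls - len(rows)):
        for attempt in range(config.max_retries):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            width = int(rng.integers(w_lo, w_hi + 1))
            chrom_len = config.chrom_lengths[chrom]
            if width >= chrom_len:
                continue
            start = int(rng.integers(1, chrom_len - width + 1))
            end = start + width - 1
            if not _intersects_any(merged.get(chrom, np.empty((0, 2))), start, end):
                break
        else:
            raise PlacementError(
                "could not place a decoy QTL in intergenic space within the "
                "retry budget; chromosomes are too crowded"
            )
        code, klass = _decoy_trait(rng, config)
        k += 1
        rows.append(
            {
                "qtl_id": f"SIMQTL{k:04d}",
                "chromosome": chrom,
                "span_start": start,
                "span_end": end,
                "peak": int(rng.integers(start, end + 1)),
                "trait_code": code,
                "trait_class": klass,
                "source_ref": "decoy",
            }
        )
    return pd.DataFrame(rows)


def gen_snp_catalog(
    genes: pd.DataFrame, truth: PlantedTruth, config: SimConfig
) -> pd.DataFrame:
    """SNP catalog in which exactly the planted SNP-pass genes are hit.

    Every SNP-pass gene gets one meat-quality SNP strictly inside the
    distance threshold (at most ``max_snp_distance_mb - placement_margin_mb``
    from the gene edge); all SNPs, planted and decoy, stay at least
    ``max_snp_distance_mb + placement_margin_mb`` away from annotated DEGs
    that must fail the screen.
    """
    config.validate()
    rng = config.rng("snp")
    fail_ids = truth.annotated_deg_ids - truth.snp_pass_ids
    fail_spans = [
        (
            str(genes.loc[g, "chromosome"]),
            int(genes.loc[g, "start"]),
            int(genes.loc[g, "end"]),
        )
        for g in sorted(fail_ids)
    ]
    keepout_bp = (config.max_snp_distance_mb + config.placement_margin_mb) * 1e6
    rows = []
    k = 0
    for gid in sorted(truth.snp_pass_ids):
        row = genes.loc[gid]
        chrom = str(row["chromosome"])
        chrom_len = config.chrom_lengths[chrom]
        for attempt in range(config.max_retries):
            dist = rng.uniform(
                0.05e6, (config.max_snp_distance_mb - config.placement_margin_mb) * 1e6
            )
            pos = (
                int(row["start"] - dist)
                if rng.random() < 0.5
                else int(row["end"] + dist)
            )
            if not (1 <= pos <= chrom_len):
                continue
            if _min_distance_to_spans(fail_spans, chrom, pos) > keepout_bp:
                break
        else:
            raise PlacementError(
                f"could not place a SNP near {gid} clear of the SNP-fail genes"
            )
        k += 1
        rows.append(
            {
                "snp_name": f"SIMSNP{k:04d}",
                "chromosome": chrom,
                "position": pos,
                "trait_code": str(rng.choice(config.trait_vocabulary)),
                "trait_class": MEAT_QUALITY,
                "source_ref": f"planted:{gid}",
            }
        )
    chroms = sorted(config.chrom_lengths, key=lambda c: (len(c), c))
    lens = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    for _ in range(config.n_snps - len(rows)):
        for attempt in range(config.max_retries):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            pos = int(rng.integers(1, config.chrom_lengths[chrom] + 1))
            if _min_distance_to_spans(fail_spans, chrom, pos) > keepout_bp:
                break
        else:
            raise PlacementError("could not place a decoy SNP within the retry budget")
        code, klass = _decoy_trait(rng, config)
        k += 1
        rows.append(
            {
                "snp_name": f"SIMSNP{k:04d}",
                "chromosome": chrom,
                "position": pos,
                "trait_code": code,
                "trait_class": klass,
                "source_ref": "decoy",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phenotypes, qPCR plates, FASTQ


def gen_phenotypes(
    trait_specs: pd.DataFrame, n_per_group: int, seed: int
) -> pd.DataFrame:
    """Draw i.i.d. normal per-animal trait values from group means and SDs.

    ``trait_specs`` needs columns trait, group, mean, sd. Returns a long
    table (trait, group, animal_id, value). SD = 0 yields constant values.
    """
    required = {"trait", "group", "mean", "sd"}
    if not required.issubset(trait_specs.columns):
        raise KeyError(f"trait_specs must have columns {sorted(required)}")
    if (trait_specs["sd"] < 0).any():
        raise ValueError("trait SDs must be >= 0")
    if n_per_group < 2:
        raise ValueError("need at least 2 animals per group")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE["phenotype"]]))
    rows = []
    for r in trait_specs.itertuples():
        values = rng.normal(float(r.mean), float(r.sd), size=n_per_group)
        for i, v in enumerate(values):
            rows.append(
                {
                    "trait": r.trait,
                    "group": r.group,
                    "animal_id": f"{r.group}_{i + 1}",
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


def trait_specs_from_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Convert a (trait, group, mean, se, n) summary into sampling specs
    with SD = SE * sqrt(n)."""
    out = summary.copy()
    out["sd"] = out["se"] * np.sqrt(out["n"])
    return out[["trait", "group", "mean", "sd"]]


def gen_qpcr(
    truth: PlantedTruth,
    reference_genes: Sequence[str] = ("ACTB", "GAPDH"),
    noise_sd: float = 0.2,
    seed: int = 0,
    n_targets: int = 9,
    n_replicates: int = 3,
    target_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Triplicate Ct plate consistent with the planted fold changes.

    The case-group Ct of a target gene is shifted by -log2FC (one extra
    fold of expression removes one cycle); reference genes are stable
    between groups. A per-sample plate shift (drawn once per sample,
    applied to every well of that sample) models pipetting/input
    differences and cancels exactly in dCt; replicate noise is
    N(0, noise_sd).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE["qpcr"]]))
    if target_genes is None:
        annotated = sorted(truth.annotated_deg_ids)
        if n_targets > len(annotated):
            raise ValueError("n_targets exceeds the number of annotated DEGs")
        target_genes = list(rng.choice(annotated, size=n_targets, replace=False))
    base_ct = {g: float(rng.uniform(20.0, 28.0)) for g in target_genes}
    for ref in reference_genes:
        base_ct[ref] = float(rng.uniform(16.0, 20.0))
    samples = sorted(truth.sample_groups)
    shifts = {s: float(rng.normal(0.0, 0.5)) for s in samples}
    groups = truth.sample_groups
    case_group = truth.case_group
    rows = []
    for gene in list(target_genes) + list(reference_genes):
        for sample in samples:
            ct = base_ct[gene] + shifts[sample]
            if gene in truth.deg_log2fc and groups[sample] == case_group:
                ct -= truth.deg_log2fc[gene]
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "sample": sample,
                        "group": groups[sample],
                        "replicate": rep,
                        "ct": ct + float(rng.normal(0.0, noise_sd)) if noise_sd else ct,
                    }
                )
    return pd.DataFrame(rows)


def gen_fastq(
    n_reads: int,
    read_length: int = 100,
    frac_adapter: float = 0.0,
    frac_lowq: float = 0.0,
    frac_highn: float = 0.0,
    seed: int = 0,
    adapters: Sequence[str] = TRUSEQ_ADAPTERS,
    path: str | Path | None = None,
) -> list[ReadRecord]:
    """Reads with planted contamination classes labelled in read names.

    Names end in ``|adapter``, ``|highN``, ``|lowq`` or ``|clean`` so QC
    results can be checked against planted truth exactly. Class counts are
    ``round(frac * n_reads)``. Phred+33; written to ``path`` if given.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    fracs = (frac_adapter, frac_lowq, frac_highn)
    if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
        raise ValueError("contamination fractions must be >= 0 and sum to <= 1")
    if adapters and read_length < max(len(a) for a in adapters):
        raise ValueError("read_length is shorter than the adapter sequence")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE["fastq"]]))
    n_ad = int(round(frac_adapter * n_reads))
    n_lq = int(round(frac_lowq * n_reads))
    n_nn = int(round(frac_highn * n_reads))
    labels = ["adapter"] * n_ad + ["lowq"] * n_lq + ["highN"] * n_nn
    labels += ["clean"] * (n_reads - len(labels))
    rng.shuffle(labels)

    bases = np.array(list("ACGT"))
    reads: list[ReadRecord] = []
    for i, label in enumerate(labels):
        seq = rng.choice(bases, size=read_length)
        qual = rng.integers(25, 41, size=read_length)
        if label == "adapter":
            a = adapters[int(rng.integers(len(adapters)))]
            pos = int(rng.integers(0, read_length - len(a) + 1))
            seq[pos : pos + len(a)] = list(a)
        elif label == "lowq":
            # 60% of bases at Phred <= 20: strictly over the 50% removal bar
            n_low = int(np.ceil(0.6 * read_length))
            idx = rng.choice(read_length, size=n_low, replace=False)
            qual[idx] = rng.integers(2, 21, size=n_low)
        elif label == "highN":
            # 15% N: strictly over the 10% removal bar
            n_n = int(np.ceil(0.15 * read_length))
            idx = rng.choice(read_length, size=n_n, replace=False)
            seq[idx] = "N"
            qual[idx] = 2
        reads.append(
            ReadRecord(
                id=f"simread_{i + 1:07d}|{label}",
                bases="".join(seq),
                qualities=[int(q) for q in qual],
            )
        )
    if path is not None:
        write_fastq(reads, path)
    return reads
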