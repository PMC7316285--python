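"""Pipeline orchestration: config, logging, stage running, manifest, report.

Stages run in the order of the underlying experiment — read QC, FPKM
quantification, differential expression, trait statistics, QTL-SNP
screening, qPCR validation — each standalone with TSV/JSON files as the
only interface. ``run_all`` on a synthetic configuration generates every
input with planted truth first and then runs the full chain.

Configuration comes from a YAML file with CLI overrides (precedence
CLI > file > defaults). All TSV outputs are plain headered tables without
comment lines, so every artifact re-parses cleanly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import expression, fixtures, qpcr, readsqc, screening, simulate, traits
from .simulate import PlantedTruth, SimConfig

logger = logging.getLogger("beefcand")


def setup_logging(level: str = "INFO") -> None:
    """Stage-tagged logging to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for a full run."""

    seed: int = 0
    outdir: str = "beefcand_out"
    log_level: str = "INFO"
    # stage toggles
    run_qc: bool = True
    run_quantify: bool = True
    run_de: bool = True
    run_traits: bool = True
    run_screen: bool = True
    run_qpcr: bool = True
    # stage parameters
    alpha: float = 0.05
    pseudocount: float = expression.DEFAULT_PSEUDOCOUNT
    expressed_threshold: float = expression.DEFAULT_EXPRESSED_THRESHOLD
    level_boundaries: tuple[float, ...] = expression.DEFAULT_LEVEL_BOUNDARIES
    trait_class: str = screening.MEAT_QUALITY
    max_snp_distance_mb: float = screening.DEFAULT_MAX_SNP_DISTANCE_MB
    overlap_mode: str = "any"
    cm_per_mb: float = screening.DEFAULT_CM_PER_MB
    reference_genes: tuple[str, ...] = ("ACTB", "GAPDH")
    qpcr_noise_sd: float = 0.2
    n_phenotype_per_group: int = 10
    n_fastq_reads: int = 2000
    fastq_frac_adapter: float = 0.05
    fastq_frac_lowq: float = 0.05
    fastq_frac_highn: float = 0.05
    # simulation knobs forwarded to SimConfig (empty -> defaults)
    sim: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def sim_config(self) -> SimConfig:
        cfg = SimConfig(seed=self.seed, **self.sim)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, config: PipelineConfig, row_counts: dict[str, int]) -> Path:
    """Record config hash, per-file checksums and stage row counts."""
    from . import __version__

    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    manifest = {
        "tool_version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "row_counts": row_counts,
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.suffix in (".tsv", ".json", ".fastq", ".gff3", ".md")
            and p.name != "manifest.json"
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def simulate_inputs(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    """Generate all synthetic inputs (with truth) into ``outdir``."""
    sim = config.sim_config()
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("simulate: generating annotation (%d genes)", sim.n_genes)
    genes = simulate.gen_annotation(sim)
    counts, truth = simulate.gen_counts(genes, sim)
    qtl = simulate.gen_qtl_catalog(genes, truth, sim)
    snp = simulate.gen_snp_catalog(genes, truth, sim)
    specs = simulate.trait_specs_from_summary(fixtures.load_fixture("table1"))
    phenotypes = simulate.gen_phenotypes(specs, config.n_phenotype_per_group, sim.seed)
    plate = simulate.gen_qpcr(truth, config.reference_genes, config.qpcr_noise_sd, sim.seed)
    reads = simulate.gen_fastq(
        config.n_fastq_reads,
        frac_adapter=config.fastq_frac_adapter,
        frac_lowq=config.fastq_frac_lowq,
        frac_highn=config.fastq_frac_highn,
        seed=sim.seed,
        path=outdir / "reads.fastq",
    )
    paths = {
        "genes": outdir / "genes.tsv",
        "genes_gff3": outdir / "genes.gff3",
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.json",
        "qtl_catalog": outdir / "qtl_catalog.tsv",
        "snp_catalog": outdir / "snp_catalog.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "ct_plate": outdir / "ct_plate.tsv",
        "fastq": outdir / "reads.fastq",
    }
    genes.to_csv(paths["genes"], sep="\t", index=False)
    paths["genes_gff3"].write_text(simulate.annotation_to_gff3(genes))
    counts.to_csv(paths["counts"], sep="\t")
    paths["truth"].write_text(truth.to_json())
    qtl.to_csv(paths["qtl_catalog"], sep="\t", index=False)
    snp.to_csv(paths["snp_catalog"], sep="\t", index=False)
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    plate.to_csv(paths["ct_plate"], sep="\t", index=False)
    logger.info("simulate: %d reads, %d planted DEGs, %d planted candidates",
                len(reads), len(truth.deg_log2fc), len(truth.candidate_gene_ids))
    return paths


@dataclass
class RunResult:
    outdir: Path
    qc_summary: readsqc.QCSummary | None = None
    de_table: pd.DataFrame | None = None
    degs: pd.DataFrame | None = None
    deg_partition: dict | None = None
    trait_table: pd.DataFrame | None = None
    screen_result: screening.ScreenResult | None = None
    fold_changes: pd.DataFrame | None = None
    correlation: dict | None = None
    truth: PlantedTruth | None = None


def run_all(config: PipelineConfig) -> RunResult:
    """Simulate inputs and run every enabled stage; write all artifacts."""
    setup_logging(config.log_level)
    outdir = Path(config.outdir)
    paths = simulate_inputs(config, outdir)
    truth = PlantedTruth.from_json(paths["truth"].read_text())
    sim = config.sim_config()
    result = RunResult(outdir=outdir, truth=truth)
    row_counts: dict[str, int] = {}

    if config.run_qc:
        reads = list(readsqc.parse_fastq(paths["fastq"]))
        clean, summary = readsqc.filter_reads(reads)
        readsqc.write_fastq(clean, outdir / "reads.clean.fastq")
        (outdir / "qc_summary.json").write_text(summary.to_json())
        (outdir / "qc_summary.tsv").write_text(summary.to_tsv())
        logger.info("qc: %d raw -> %d clean reads", summary.n_raw, summary.n_clean)
        result.qc_summary = summary
        row_counts["qc_clean_reads"] = summary.n_clean

    genes = pd.read_csv(paths["genes"], sep="\t", dtype={"chromosome": str})
    genes = genes.set_index("gene_id", drop=False)
    counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
    lengths = genes["length"]
    groups = truth.sample_groups
    calibrator = next(g for g in groups.values() if g != truth.case_group)

    if config.run_quantify:
        fpkm_df = expression.fpkm_matrix(counts, lengths)
        fpkm_df.to_csv(outdir / "fpkm.tsv", sep="\t")
        sets, common = expression.expressed_sets(
            fpkm_df, groups, config.expressed_threshold
        )
        mean_fpkm = fpkm_df.mean(axis=1)
        expressed = mean_fpkm[mean_fpkm > config.expressed_threshold]
        _, level_counts = expression.bin_expression_levels(
            expressed, config.level_boundaries
        )
        summary = {
            "expressed_per_group": {g: len(s) for g, s in sets.items()},
            "expressed_common": len(common),
            "level_counts": {int(k): int(v) for k, v in level_counts.items()},
        }
        (outdir / "expression_summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("quantify: expressed per group %s, common %d",
                    summary["expressed_per_group"], summary["expressed_common"])
        row_counts["expressed_common"] = len(common)

    if config.run_de:
        de = expression.de_test(
            counts, groups, lengths, truth.case_group, calibrator,
            pseudocount=config.pseudocount,
        )
        degs, partition = expression.call_degs(
            de, alpha=config.alpha, annotation_status=truth.deg_status
        )
        de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
        degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
        logger.info("de: %d DEGs (%d up / %d down)",
                    partition["n_degs"], partition["n_up"], partition["n_down"])
        result.de_table, result.degs, result.deg_partition = de, degs, partition
        row_counts["degs"] = partition["n_degs"]

    if config.run_traits:
        phen = pd.read_csv(paths["phenotypes"], sep="\t")
        table = traits.compare_raw_table(phen)
        table.to_csv(outdir / "trait_comparisons.tsv", sep="\t", index=False)
        logger.info("traits: %d traits compared", len(table))
        result.trait_table = table
        row_counts["traits"] = len(table)

    if config.run_screen and result.degs is not None:
        deg_genes = screening.genes_from_frame(
            genes.loc[[g for g in result.degs["gene_id"]
                       if truth.deg_status.get(g) == "annotated"
                       or g not in truth.deg_status]]
        )
        qtl_cat = screening.qtls_from_frame(
            pd.read_csv(paths["qtl_catalog"], sep="\t", dtype={"chromosome": str})
        )
        snp_cat = screening.snps_from_frame(
            pd.read_csv(paths["snp_catalog"], sep="\t", dtype={"chromosome": str})
        )
        sres = screening.screen(
            deg_genes, qtl_cat, snp_cat,
            trait_class=config.trait_class,
            max_snp_distance_mb=config.max_snp_distance_mb,
            overlap_mode=config.overlap_mode,
            cm_per_mb=config.cm_per_mb,
        )
        sres.report().to_csv(outdir / "candidate_report.tsv", sep="\t", index=False)
        logger.info("screen: qtl_pass=%d snp_pass=%d candidates=%d",
                    len(sres.qtl_pass), len(sres.snp_pass), len(sres.candidates))
        result.screen_result = sres
        row_counts["candidates"] = len(sres.candidates)

    if config.run_qpcr and result.de_table is not None:
        plate = pd.read_csv(paths["ct_plate"], sep="\t")
        targets = [
            g for g in plate["gene"].unique() if g not in config.reference_genes
        ]
        fc = qpcr.fold_changes(
            plate, targets, config.reference_genes, truth.case_group, calibrator
        )
        rnaseq = result.de_table.set_index("gene_id")["log2fc"]
        corr = qpcr.correlate_with_rnaseq(fc, rnaseq)
        fc.to_csv(outdir / "qpcr_fold_changes.tsv", sep="\t", index=False)
        (outdir / "qpcr_correlation.json").write_text(
            json.dumps({k: v for k, v in corr.items() if k != "points"}, indent=2)
        )
        logger.info("qpcr: %d targets, Pearson r=%.3f vs RNA-seq",
                    len(fc), corr["pearson_r"])
        result.fold_changes = fc
        result.correlation = corr
        row_counts["qpcr_targets"] = len(fc)

    render_report(result, outdir / "report.md")
    write_manifest(outdir, config, row_counts)
    return result


def render_report(result: RunResult, path: Path | None = None) -> str:
    """Deterministic markdown report over whatever results are present."""
    lines = ["# beefcand run report", ""]
    if result.qc_summary is not None:
        s = result.qc_summary
        lines += [
            "## Read QC",
            f"- raw reads: {s.n_raw}; clean: {s.n_clean} "
            f"(adapter {s.n_adapter}, high-N {s.n_highn}, low-quality {s.n_lowq})",
            f"- clean-data Q20 {s.q20:.2f}%, Q30 {s.q30:.2f}%, GC {s.gc:.2f}%",
            "",
        ]
    if result.deg_partition is not None:
        p = result.deg_partition
        lines += [
            "## Differential expression",
            f"- DEGs: {p['n_degs']} ({p['n_up']} up, {p['n_down']} down)",
            "",
        ]
    if result.trait_table is not None:
        lines += ["## Trait comparisons", ""]
        for r in result.trait_table.itertuples():
            lines.append(
                f"- {r.trait}: diff {r.mean_diff:+.2f}, SED {r.sed_3dp}, "
                f"p {r.pvalue_3dp} ({r.tier})"
            )
        lines.append("")
    if result.screen_result is not None:
        sr = result.screen_result
        lines += [
            "## QTL-SNP screening",
            f"- QTL screen pass: {len(sr.qtl_pass)}",
            f"- SNP screen pass: {len(sr.snp_pass)}",
            f"- candidate genes ({len(sr.candidates)}): "
            + ", ".join(sorted(sr.candidates)),
            "",
        ]
    if result.correlation is not None:
        lines += [
            "## qPCR validation",
            f"- Pearson r (qPCR vs RNA-seq log2 ratios): "
            f"{result.correlation['pearson_r']:.3f} over "
            f"{result.correlation['n_genes']} genes",
            "",
        ]
    text = "\n".join(lines)
    if path is not None:
        path.write_text(text)
    return text


def volcano_plot(de_table: pd.DataFrame, path: str | Path, alpha: float = 0.05) -> None:
    """Optional volcano scatter (log2FC vs -log10 p) of the DE table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    padj = (
        de_table["padj"]
        if "padj" in de_table.columns
        else expression.bh_adjust(de_table["pvalue"])
    )
    sig = padj < alpha
    up = sig & (de_table["log2fc"] > 0)
    down = sig & (de_table["log2fc"] < 0)
    fig, ax = plt.subplots(figsize=(5, 4))
    logp = -np.log10(de_table["pvalue"])
    ax.scatter(de_table["log2fc"][~sig], logp[~sig], s=4, c="tab:blue", alpha=0.4)
    ax.scatter(de_table["log2fc"][up], logp[up], s=6, c="tab:red")
    ax.scatter(de_table["log2fc"][down], logp[down], s=6, c="tab:green")
    ax.set_xlabel("log2 fold change (case/calibrator)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
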