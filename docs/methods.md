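# Methods

## Scope and model of the data

The package implements the analysis chain of a two-group cattle muscle
transcriptome design: bulls vs steers, phenotyped for growth and carcass
traits (n = 10 animals per group), RNA-sequenced on a small subset of
animals, and screened for candidate genes by position against QTL and
GWAS-SNP catalogs. Alignment and fragment counting are out of scope;
fragment counts are either supplied or simulated directly.

## Trait statistics

Printed carcass-trait tables report per-group mean ± SE and a column
(often labelled "SEM") that is in fact the standard error of the
difference, SED = √(SE₁² + SE₂²). `traits.ttest_from_summary` reproduces
the comparison from summaries alone: t = Δx̄/SED with pooled df
(n₁ + n₂ − 2), two-sided p. The pooled-df Student form is the default
because it reproduces the verifiable printed p-values (initial weight
0.306, carcass weight 0.047, rib eye area 0.002, marbling 0.008 at 3 dp
with n = 10 per group); a Welch option is available behind a flag. Three
printed rows (water 0.024, IMF 0.048, protein 0.102) are *not*
reproducible from their printed summaries under either flavor at
n = 10 — most plausibly the per-trait n differed — so they are excluded
from acceptance checks rather than force-fitted. Marbling's printed SED
(0.269) also differs from √(0.15² + 0.22²) = 0.266 at the last digit
(SE rounding); SED checks use rows where the identity holds at print
precision.

Normality: `ks_normality` tests against a normal with mean and SD fitted
from the sample and therefore uses the Lilliefors correction (plain KS
p-values would be anticonservative with estimated parameters). This
mirrors what common statistics suites do under the "Kolmogorov–Smirnov"
label and is documented as an approximation.

Reported p-values and SEDs are rounded to 3 dp in report columns;
unrounded values are always retained alongside.

## Expression quantification and DEG calling

FPKM uses the fragments assigned to genes in the supplied matrix as the
per-sample denominator by default (configurable to externally determined
totals); gene length is the `length` column when present, else the
genomic span end − start + 1. Five expression levels are cut at FPKM
(0.1, 1, 10, 100) — the actual published level boundaries are not
printed, so these are stand-in defaults and a config parameter. A gene is
"expressed" in a group when its mean FPKM exceeds 0.1 (same caveat).

The differential-expression route is deliberately plain plumbing: Welch
t-test on log₂(FPKM + c), pseudo-count c = 0.25 FPKM (configurable), BH
step-up correction (via statsmodels), DEG iff corrected p < 0.05
(strict, per the source wording). It does not shrink dispersions or share
information across genes, so its power at 3 samples per group is far
below that of a negative-binomial DE package — with the default
simulation parameters and n = 3 it calls few or no DEGs. That is a
faithful property of the simple test, not a defect; the pipeline
therefore also accepts an externally produced DE table
(gene_id, log2fc, pvalue [, padj]) as an entry point, which is how the
packaged published DEG table is screened. The packaged DEG table's
printed "P-Value" column is treated as the corrected p-value: all 40
entries sit below 0.05, which raw p-values from an ~11,500-gene scan
could not all do after correction.

## QTL–SNP screening conventions

All coordinates are 1-based inclusive; chromosome labels are normalized
by stripping a leading `chr` and uppercasing, and a complete namespace
mismatch between DEGs and a catalog is a hard error with guidance, never
a silent non-match.

* **QTL overlap.** Default mode `any`: gene span and QTL span share at
  least one base. "Located within" is ambiguous between containment and
  overlap; any-overlap is the default because gene spans of ~100 kb can
  straddle narrow QTL boundaries. `containment` and `midpoint` modes are
  config flags.
* **Peak distance.** Signed (gene midpoint − peak), converted at
  1 cM/Mb by default with a per-chromosome override map. Published cM
  distances cannot be reproduced without the (unstated) genetic map, so
  the cM value is annotation only and never filters genes — matching the
  source procedure, which filters on region membership only.
* **SNP distance.** Nearest gene edge, 0 inside the gene, +∞ across
  chromosomes; a gene passes iff distance < 5 Mb *strictly*. The anchor
  (start/midpoint/edge) is unstated in the source; nearest-edge is the
  most inclusive convention consistent with "distance to the SNP".
* **Candidates** are the plain intersection of the two pass sets. Trait
  agreement between a gene's QTL evidence and SNP evidence is *not*
  required (the published evidence table itself pairs carcass-weight QTLs
  with a carcass-conformation SNP).

Screening uses a per-chromosome interval tree; tests verify equivalence
with an all-pairs brute-force scan on catalogs up to 10⁴ features.

The packaged evidence table prints SNP distances without SNP coordinates
and QTL ids without spans, so `fixtures.synthetic_catalogs_from_table4`
reconstructs *synthetic* catalogs: each SNP is placed at its printed
distance downstream of its gene's end, each QTL span is the gene span
padded by 50 kb with the peak displaced by the printed signed distance at
1 cM/Mb. Positions are stand-ins (the same SNP name can receive slightly
different reconstructed positions from different rows); the screening
*outcome* — which of the 40 packaged DEGs pass and the seven-gene
candidate set — matches the published table and is what the fixture is
for.

## qPCR quantification

ΔCt(sample) = Ct(target) − mean Ct(reference genes); ΔΔCt = mean
ΔCt(case) − mean ΔCt(calibrator); fold change = 2^−ΔΔCt with
amplification efficiency fixed at 2. Dual references are combined by the
arithmetic mean of their Cts, which equals normalizing to the geometric
mean of their linear quantities (asserted numerically in tests). Group
ΔΔCt averages per-sample ΔCt within group without pairing, because
samples are unpaired animals. ΔΔCt is invariant to adding a constant to
every Ct on a plate; this plate-shift invariance is tested.

## Read QC

Whole reads are removed (never trimmed), attributed to exactly one reason
by priority adapter → excess N → low quality. Boundary rules are kept
verbatim from their definitions even where they differ: the low-quality
*filter* removes reads with strictly more than 50% of bases at
Phred ≤ 20, while the Q20 *summary* counts bases with Phred > 20 — a
base at exactly Q20 counts against a read in the filter but not toward
Q20. Excess N is strictly > 10%. Adapter matching is exact substring
against a configurable set (default: Illumina TruSeq read-1/read-2);
mismatch-tolerant matching is out of scope. GC content excludes N bases
from the denominator. Filtering is per single read; when pairs are
supplied, the conservative convention is to drop a pair if either mate is
dropped.

## Synthetic-data generator

Every generator is a pure function of (config, seed); sub-seeds are
derived per generator, so any table can be regenerated independently.
The default `SimConfig` mirrors the study scale: 29 cattle-sized
autosomes (~2.5 Gb), 11,500 expressed genes, 56 planted DEGs
(41 annotated, 4 pseudogenes, 11 novel) with |log₂FC| uniform in
[1.2, 4] and sign up with probability 37/56, three animals per group,
and catalogs planted so that of the annotated DEGs 9 pass the QTL
screen, 39 pass the SNP screen, and 7 pass both. (With a 40-gene
universe a 9-gene and a 39-gene subset must share at least 8 members, so
the published 9/39/7 shape forces a 41-gene annotated universe; the
generator uses 41.)

**Counts.** Negative binomial with mean μ and variance μ + φμ²
(dispersion φ = 0.05 by default, a typical bulk-RNA-seq biological
dispersion); base means log-uniform on [5, 5000]; case-group means scaled
by 2^log2FC for planted genes; per-sample totals drawn uniformly from the
library-size range (18–25 M fragments, the scale of uniquely mapped
fragments in a ~50 M-read library). Planted DEGs are drawn from genes
with base mean ≥ 50 — DEGs detectable with a handful of animals are
necessarily not at the noise floor. Gene spans are placed uniformly
(overlap allowed) with span lengths log-uniform on [2, 200] kb; the
FPKM length is a separate transcript length log-uniform on [0.5, 10] kb,
capped at the span, because introns do not attract fragments.

**Placement guarantees.** Planted "non-pass" labels are protected by
margins of ≥ 1 Mb beyond the 5 Mb SNP threshold so floating-point
conventions cannot flip a truth label. Stronger, QTL-pass genes are
chosen among genes overlapping no other gene, planted QTL spans are
clipped to touch no other gene, and decoy QTLs are placed wholly in
intergenic space. Consequently *no* gene outside the planted QTL-pass
set can pass the QTL screen, which makes the planted candidate set
recoverable end-to-end even when BH-calling admits a few false-positive
DEGs. All placements use bounded rejection sampling and raise a
`PlacementError` when a chromosome is too crowded. This is also the
generator's main departure from real catalogs, where QTL regions are
broad and overlap many genes; passing the planted-truth tests therefore
demonstrates correctness of the screening logic, not that real catalogs
admit unambiguous candidates.

**Phenotypes.** I.i.d. normal within group (matching the normality
premise of the trait tests), specified by per-trait group means and SDs;
the packaged group summaries with SD = SE·√10 are the default
specification.

**qPCR plates.** Triplicate wells; target Ct shifted by −log₂FC in the
case group; reference genes group-stable; a per-sample N(0, 0.5) plate
shift applied to every well of a sample (cancels exactly in ΔCt);
replicate noise N(0, σ) with σ = 0.2 cycles by default. With σ = 0 the
planted fold change is recovered to machine precision.

**FASTQ.** Planted contamination classes are labelled in read names
(`|adapter`, `|lowq`, `|highN`, `|clean`) so filter output can be checked
exactly. Low-quality reads carry 60% of bases at Phred ≤ 20 and N-rich
reads 15% N — strictly past the removal bars. Read sequences are random
and do not align to any genome; isoforms, GC bias and batch effects are
not simulated. All distributional parameters of the generator are
stand-ins chosen for realism, since the original raw data were not
deposited and give no distributional detail.

## Problem sizes used in checks

Unit tests run on a scaled-down study (800 genes on six 60-Mb
chromosomes, 4–5 animals per group) chosen so the screen-placement
geometry stays feasible while each simulation costs milliseconds.
Study-scale checks (11,500 genes) run the end-to-end chain across tens
of seeds with a "margin-respecting" configuration — six animals per
group, dispersion 0.01, |log₂FC| in [2, 4] — under which the plain
t-test route detects every planted DEG comfortably; the recall/FDR check
uses dispersion 0.05 and |log₂FC| in [2, 3]. The brute-force screening
cross-check uses random catalogs of 10⁴ features.

## Known limitations

* The DE route is a stand-in; at the original design's n = 3 it is far
  less powerful than dispersion-sharing NB models, and results at that
  depth should come through the external-DE-table entry point.
* cM distances are linear-interpolation annotations (default 1 cM/Mb),
  not map-based.
* Adapter matching is exact; heavily error-laden adapters will not be
  flagged.
* The expression-level boundaries and expressed-gene threshold are
  configurable stand-ins.
* Reconstructed fixture catalogs are positionally synthetic (see above);
  they validate screening outcomes, not catalog coordinates.
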