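"""Positional screening: overlap/distance conventions, trait filtering,
planted-truth and brute-force equivalence, published-table reproduction."""

import numpy as np
import pandas as pd
import pytest

from beefcand import fixtures
from beefcand.models import GeneModel, QTLRecord, SNPRecord
from beefcand.screening import (
    MEAT_QUALITY,
    REPRODUCTION,
    distance_to_peak_cm,
    filter_by_trait_class,
    gene_qtl_overlap,
    gene_snp_distance_mb,
    genes_from_frame,
    intersect_candidates,
    qtl_screen,
    qtls_from_frame,
    screen,
    snp_screen,
    snps_from_frame,
)
from beefcand.simulate import gen_qtl_catalog, gen_snp_catalog
from conftest import small_config
from oracles import qtl_pass_genes, snp_pass_genes


def gene(gid="g1", chrom="1", start=100, end=200):
    return GeneModel(gene_id=gid, chromosome=chrom, start=start, end=end)


def qtl(qid="q1", chrom="1", start=50, end=500, peak=None, trait="CW"):
    return QTLRecord(qtl_id=qid, chromosome=chrom, span_start=start, span_end=end,
                     peak=peak if peak is not None else (start + end) // 2,
                     trait_code=trait, trait_class=MEAT_QUALITY)


def snp(name="s1", chrom="1", pos=150, trait="CW"):
    return SNPRecord(snp_name=name, chromosome=chrom, position=pos, trait_code=trait,
                     trait_class=MEAT_QUALITY)


class TestTraitFilter:
    CATALOG = [qtl("q1", trait="CW"), qtl("q2", trait="IMF"),
               qtl("q3", trait="SC"), qtl("q4", trait="GL")]

    def test_meat_quality_subset(self):
        out = filter_by_trait_class(self.CATALOG, MEAT_QUALITY)
        assert [q.qtl_id for q in out] == ["q1", "q2"]

    def test_reproduction_on_meat_only_catalog_is_empty(self):
        assert filter_by_trait_class(self.CATALOG[:2], REPRODUCTION) == []

    def test_idempotent(self):
        once = filter_by_trait_class(self.CATALOG, MEAT_QUALITY)
        assert filter_by_trait_class(once, MEAT_QUALITY) == once

    def test_unknown_code_rejected_with_offenders(self):
        bad = [qtl("qx", trait="NOT_A_CODE")]
        with pytest.raises(ValueError, match="NOT_A_CODE"):
            filter_by_trait_class(bad, MEAT_QUALITY)


class TestOverlap:
    def test_gene_inside_qtl(self):
        assert gene_qtl_overlap(gene(start=100, end=200), qtl(start=50, end=500))

    def test_disjoint(self):
        assert not gene_qtl_overlap(gene(start=100, end=200), qtl(start=300, end=400))

    def test_single_base_touch_counts(self):
        assert gene_qtl_overlap(gene(start=100, end=200), qtl(start=200, end=400))

    def test_different_chromosomes_false_not_error(self):
        assert not gene_qtl_overlap(gene(chrom="1"), qtl(chrom="2"))

    def test_chr_prefix_normalized(self):
        assert gene_qtl_overlap(gene(chrom="chr1"), qtl(chrom="1"))

    def test_containment_mode_stricter(self):
        g = gene(start=100, end=600)
        q = qtl(start=50, end=500)
        assert gene_qtl_overlap(g, q, mode="any")
        assert not gene_qtl_overlap(g, q, mode="containment")

    def test_midpoint_mode(self):
        g = gene(start=100, end=600)  # midpoint 350
        assert gene_qtl_overlap(g, qtl(start=300, end=400), mode="midpoint")
        assert not gene_qtl_overlap(g, qtl(start=500, end=700, peak=600), mode="midpoint")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            gene_qtl_overlap(gene(), qtl(), mode="nope")


class TestPeakDistance:
    def test_midpoint_at_peak_is_zero(self):
        g = gene(start=100, end=200)  # midpoint 150
        assert distance_to_peak_cm(g, qtl(start=50, end=500, peak=150)) == 0.0

    def test_two_mb_right_at_one_cm_per_mb(self):
        g = gene(start=2_999_000, end=3_001_000)  # midpoint 3,000,000
        q = qtl(start=1, end=5_000_000, peak=1_000_000)
        assert distance_to_peak_cm(g, q) == pytest.approx(2.0)

    def test_sign_negative_left_of_peak(self):
        g = gene(start=999_000, end=1_001_000)
        q = qtl(start=1, end=5_000_000, peak=3_000_000)
        assert distance_to_peak_cm(g, q) == pytest.approx(-2.0)

    def test_per_chromosome_map_and_missing_conversion(self, rng):
        g = gene(chrom="2", start=999_000, end=1_001_000)
        q = qtl(chrom="2", start=1, end=5_000_000, peak=2_000_000)
        assert distance_to_peak_cm(g, q, {"2": 0.5}) == pytest.approx(-0.5)
        with pytest.raises(KeyError):
            distance_to_peak_cm(g, q, {"1": 1.0})

    def test_scalar_recomputation_oracle(self, rng):
        for _ in range(50):
            s = int(rng.integers(1, 10**7))
            e = s + int(rng.integers(1, 10**6))
            peak = int(rng.integers(1, 2 * 10**7))
            factor = float(rng.uniform(0.2, 3))
            g = gene(start=s, end=e)
            q = qtl(start=min(s, peak), end=max(e, peak), peak=peak)
            expected = ((s + e) / 2 - peak) / 1e6 * factor
            assert distance_to_peak_cm(g, q, factor) == pytest.approx(expected)


class TestSnpDistance:
    def test_inside_gene_is_zero(self):
        assert gene_snp_distance_mb(gene(start=100, end=200), snp(pos=150)) == 0.0

    def test_published_gadl1_style_distance(self):
        g = gene(chrom="22", start=5_258_463, end=5_452_369)
        s = snp(chrom="22", pos=5_512_369)
        assert gene_snp_distance_mb(g, s) == pytest.approx(0.06)

    def test_symmetric_in_edges(self):
        g = gene(start=100, end=10_000)
        assert gene_snp_distance_mb(g, snp(pos=50)) == pytest.approx(50 / 1e6)
        assert gene_snp_distance_mb(g, snp(pos=10_050)) == pytest.approx(50 / 1e6)

    def test_other_chromosome_is_infinite(self):
        assert gene_snp_distance_mb(gene(chrom="1"), snp(chrom="2")) == np.inf


class TestScreens:
    def test_empty_catalog_empty_pass(self):
        assert qtl_screen([gene()], []) == {}
        assert snp_screen([gene()], []) == {}

    def test_snp_exactly_at_threshold_excluded(self):
        g = gene(start=1_000_000, end=2_000_000)
        at_limit = snp(pos=7_000_000)      # exactly 5.0 Mb from gene end
        just_in = snp("s2", pos=6_999_999)  # 4.999999 Mb
        assert snp_screen([g], [at_limit]) == {}
        passed = snp_screen([g], [just_in])
        assert set(passed) == {"g1"}
        assert passed["g1"].snp_matches[0].distance_mb == pytest.approx(4.999999)

    def test_decoy_on_degfree_chromosome_changes_nothing(self):
        g = gene(chrom="1", start=100, end=200)
        base = [qtl("q1", chrom="1", start=50, end=500)]
        with_decoy = base + [qtl("q2", chrom="5", start=1, end=10**6)]
        assert set(qtl_screen([g], base)) == set(qtl_screen([g], with_decoy)) == {"g1"}

    def test_chromosome_namespace_mismatch_raises_guidance(self):
        g = gene(chrom="NC_037331")
        with pytest.raises(ValueError, match="naming scheme"):
            qtl_screen([g], [qtl(chrom="4")])

    def test_evidence_lists_every_matching_qtl(self):
        g = gene(start=100, end=200)
        hits = qtl_screen([g], [qtl("q1"), qtl("q2", start=150, end=160)])
        assert [m.qtl.qtl_id for m in hits["g1"].qtl_matches] == ["q1", "q2"]

    def test_monotone_in_max_mb(self):
        g = gene(start=1_000_000, end=2_000_000)
        catalog = [snp(f"s{i}", pos=2_000_000 + i * 10**6) for i in range(8)]
        sizes = [len(snp_screen([g], catalog, max_mb=m)) for m in (1, 3, 5, 9)]
        assert sizes == sorted(sizes)

    def test_catalog_order_irrelevant(self, sim_small):
        cfg, genes, _, truth = sim_small
        qtl_df = gen_qtl_catalog(genes, truth, cfg)
        degs = genes_from_frame(genes.loc[sorted(truth.annotated_deg_ids)])
        fwd = qtl_screen(degs, qtls_from_frame(qtl_df))
        rev = qtl_screen(degs, qtls_from_frame(qtl_df.iloc[::-1]))
        assert set(fwd) == set(rev)
        for g in fwd:
            assert {m.qtl.qtl_id for m in fwd[g].qtl_matches} == {
                m.qtl.qtl_id for m in rev[g].qtl_matches
            }


class TestIntersection:
    def _evidence(self, gid):
        from beefcand.models import CandidateEvidence

        return CandidateEvidence(gene(gid))

    def test_plain_set_intersection(self):
        qp = {g: self._evidence(g) for g in "ABC"}
        sp = {g: self._evidence(g) for g in "BCD"}
        assert intersect_candidates(qp, sp).candidates == {"B", "C"}

    def test_disjoint_inputs_yield_wellformed_empty_report(self):
        qp = {"A": self._evidence("A")}
        sp = {"B": self._evidence("B")}
        result = intersect_candidates(qp, sp)
        report = result.report()
        assert result.candidates == set() and len(report) == 0
        assert "snp_distance_mb" in report.columns


class TestPlantedTruthRecovery:
    def test_screen_returns_exactly_planted_candidates(self, sim_small):
        cfg, genes, _, truth = sim_small
        qtl_df = gen_qtl_catalog(genes, truth, cfg)
        snp_df = gen_snp_catalog(genes, truth, cfg)
        degs = genes_from_frame(genes.loc[sorted(truth.annotated_deg_ids)])
        result = screen(degs, qtls_from_frame(qtl_df), snps_from_frame(snp_df))
        assert set(result.qtl_pass) == truth.qtl_pass_ids
        assert set(result.snp_pass) == truth.snp_pass_ids
        assert result.candidates == truth.candidate_gene_ids

    def test_trait_class_separation(self, sim_small):
        cfg, genes, _, truth = sim_small
        qtl_df = gen_qtl_catalog(genes, truth, cfg)
        snp_df = gen_snp_catalog(genes, truth, cfg)
        degs = genes_from_frame(genes.loc[sorted(truth.annotated_deg_ids)])
        meat = screen(degs, qtls_from_frame(qtl_df), snps_from_frame(snp_df),
                      trait_class=MEAT_QUALITY)
        repro = screen(degs, qtls_from_frame(qtl_df), snps_from_frame(snp_df),
                       trait_class=REPRODUCTION)
        meat_ids = {m.qtl.qtl_id for ev in meat.qtl_pass.values() for m in ev.qtl_matches}
        repro_ids = {m.qtl.qtl_id for ev in repro.qtl_pass.values() for m in ev.qtl_matches}
        assert meat_ids.isdisjoint(repro_ids)


class TestBruteForceEquivalence:
    def test_random_catalogs_match_oracle(self, rng):
        for trial in range(5):
            n_genes, n_qtl, n_snp = 40, 120, 120
            chroms = [str(c) for c in rng.integers(1, 6, size=n_genes)]
            starts = rng.integers(1, 5 * 10**7, size=n_genes)
            lengths = rng.integers(1000, 3 * 10**6, size=n_genes)
            gene_rows = [
                {"gene_id": f"g{i}", "chromosome": chroms[i],
                 "start": int(starts[i]), "end": int(starts[i] + lengths[i])}
                for i in range(n_genes)
            ]
            qtl_rows = [
                {"qtl_id": f"q{i}", "chromosome": str(rng.integers(1, 6)),
                 "span_start": (s := int(rng.integers(1, 5 * 10**7))),
                 "span_end": s + int(rng.integers(10**4, 10**7)),
                 "trait_code": "CW", "trait_class": MEAT_QUALITY, "source_ref": ""}
                for i in range(n_qtl)
            ]
            for q in qtl_rows:
                q["peak"] = (q["span_start"] + q["span_end"]) // 2
            snp_rows = [
                {"snp_name": f"s{i}", "chromosome": str(rng.integers(1, 6)),
                 "position": int(rng.integers(1, 6 * 10**7)),
                 "trait_code": "IMF", "trait_class": MEAT_QUALITY, "source_ref": ""}
                for i in range(n_snp)
            ]
            degs = genes_from_frame(pd.DataFrame(gene_rows))
            qp = qtl_screen(degs, qtls_from_frame(pd.DataFrame(qtl_rows)))
            sp = snp_screen(degs, snps_from_frame(pd.DataFrame(snp_rows)))
            assert set(qp) == qtl_pass_genes(gene_rows, qtl_rows)
            assert set(sp) == snp_pass_genes(gene_rows, snp_rows)


class TestPublishedTables:
    def test_reconstructed_catalogs_reproduce_seven_candidates(self):
        qtls, snps = fixtures.synthetic_catalogs_from_table4()
        result = screen(fixtures.table2_genes(), qtls, snps)
        id2sym = {g.gene_id: g.symbol for g in fixtures.table2_genes()}
        assert sorted(id2sym[g] for g in result.candidates) == sorted(
            fixtures.table4_candidate_symbols()
        )

    def test_report_has_table_shape(self):
        qtls, snps = fixtures.synthetic_catalogs_from_table4()
        report = screen(fixtures.table2_genes(), qtls, snps).report()
        assert {"symbol", "qtl_id", "qtl_peak_distance_cm",
                "snp_name", "snp_distance_mb"} <= set(report.columns)
        assert report["symbol"].nunique() == 7
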