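"""Peak annotation: location classes, distance categories, promoter enrichment."""

import numpy as np
import pandas as pd
import pytest

from podomot.cistrome import (
    annotate_peaks,
    cistrome_summary,
    classify_location,
    gene_distance_category,
    load_intervals,
    promoter_enrichment,
    read_bed,
    read_gtf_genes,
)
from podomot.synthetic import GenomeSimConfig, simulate_genome_peaks


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def genes_df(rows):
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "responsive"]
    )
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


# ---------------------------------------------------------------------------
# loading

class TestLoading:
    def test_bed_passthrough(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t100\t200\tp1\n")
        df = read_bed(p)
        assert tuple(df.iloc[0][["chrom", "start", "end", "name"]]) == ("chr1", 100, 200, "p1")

    def test_gtf_coordinate_conversion(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "gp";\n'
            'chr1\tsrc\tgene\t101\t200\t.\t-\t.\tgene_id "gm";\n'
        )
        genes = read_gtf_genes(gtf, responsive_genes={"gp"})
        plus = genes[genes["gene_id"] == "gp"].iloc[0]
        minus = genes[genes["gene_id"] == "gm"].iloc[0]
        assert (plus["start"], plus["end"], plus["tss"]) == (100, 200, 100)
        assert minus["tss"] == 199  # 0-based position of the - strand 5' end
        assert bool(plus["responsive"]) and not bool(minus["responsive"])

    def test_unknown_chromosome_rejected(self, tmp_path):
        (tmp_path / "p.bed").write_text("chrUn\t0\t10\tp1\n")
        (tmp_path / "g.tsv").write_text(
            "gene_id\tchrom\tstart\tend\tstrand\tresponsive\ng1\tchr1\t0\t10\t+\tTrue\n"
        )
        (tmp_path / "c.tsv").write_text("chr1\t1000\n")
        with pytest.raises(ValueError, match="unknown chromosome"):
            load_intervals(tmp_path / "p.bed", tmp_path / "g.tsv", tmp_path / "c.tsv")

    def test_malformed_strand_rejected(self, tmp_path):
        (tmp_path / "g.tsv").write_text(
            "gene_id\tchrom\tstart\tend\tstrand\tresponsive\ng1\tchr1\t0\t10\t*\tTrue\n"
        )
        with pytest.raises(ValueError, match="strand"):
            from podomot.cistrome import read_gene_table

            read_gene_table(tmp_path / "g.tsv")


# ---------------------------------------------------------------------------
# classification

class TestClassifyLocation:
    GENES = genes_df([("g1", "chr1", 100_000, 110_000, "+", True)])

    def test_intragenic_containment(self):
        ann = classify_location(peaks_df([("chr1", 104_000, 104_300, "p")]), self.GENES)
        assert ann["location_class"].iloc[0] == "intragenic"

    def test_promoter_upstream_of_plus_strand(self):
        ann = classify_location(peaks_df([("chr1", 98_900, 99_100, "p")]), self.GENES)
        assert ann["location_class"].iloc[0] == "promoter_2_5kb"
        assert ann["distance_to_nearest_tss"].iloc[0] == -1000  # upstream negative

    def test_promoter_upstream_of_minus_strand(self):
        genes = genes_df([("g1", "chr1", 100_000, 110_000, "-", True)])
        # upstream of a - strand gene is to the right of tss = 109_999
        ann = classify_location(peaks_df([("chr1", 110_900, 111_100, "p")]), genes)
        assert ann["location_class"].iloc[0] == "promoter_2_5kb"

    def test_downstream_is_not_promoter(self):
        ann = classify_location(peaks_df([("chr1", 110_900, 111_100, "p")]), self.GENES)
        assert ann["location_class"].iloc[0] == "distal"

    def test_distal_distance_single_gene(self):
        ann = classify_location(peaks_df([("chr1", 199_850, 200_150, "p")]), self.GENES)
        assert ann["location_class"].iloc[0] == "distal"
        assert ann["distance_to_nearest_tss"].iloc[0] == 100_000

    def test_intragenic_precedence_over_promoter(self):
        # two genes: peak inside g2 but within g1's upstream window
        genes = genes_df(
            [
                ("g1", "chr1", 100_000, 110_000, "+", True),
                ("g2", "chr1", 97_000, 99_500, "+", False),
            ]
        )
        ann = classify_location(peaks_df([("chr1", 98_900, 99_100, "p")]), genes)
        assert ann["location_class"].iloc[0] == "intragenic"


class TestGeneDistanceCategory:
    def test_overlap_with_responsive_gene(self):
        genes = genes_df([("g1", "chr1", 1000, 2000, "+", True)])
        cat = gene_distance_category(peaks_df([("chr1", 1500, 1600, "p")]), genes)
        assert cat["gene_distance_category"].iloc[0] == "le50kb_responsive"
        assert cat["gene_distance_bp"].iloc[0] == 0

    def test_beyond_threshold(self):
        genes = genes_df([("g1", "chr1", 0, 1000, "+", True)])
        cat = gene_distance_category(peaks_df([("chr1", 61_100, 61_200, "p")]), genes)
        assert cat["gene_distance_category"].iloc[0] == "gt50kb_any_gene"

    def test_nearest_gene_rule(self):
        genes = genes_df(
            [
                ("resp", "chr1", 100_000, 110_000, "+", True),
                ("unresp", "chr1", 200_000, 210_000, "+", False),
            ]
        )
        # 10 kb from unresp, 80 kb from resp
        cat = gene_distance_category(peaks_df([("chr1", 189_900, 190_100, "p")]), genes)
        assert cat["gene_distance_category"].iloc[0] == "le50kb_unresponsive"

    def test_exact_tie_goes_to_responsive(self):
        genes = genes_df(
            [
                ("unresp", "chr1", 0, 1000, "+", False),
                ("resp", "chr1", 3000, 4000, "+", True),
            ]
        )
        # peak [1900, 2100): gap to unresp = 900, gap to resp = 900
        cat = gene_distance_category(peaks_df([("chr1", 1900, 2100, "p")]), genes)
        assert cat["gene_distance_category"].iloc[0] == "le50kb_responsive"
        assert cat["nearest_gene"].iloc[0] == "resp"


# ---------------------------------------------------------------------------
# brute-force oracle equivalence

def brute_force_annotation(peaks, genes, promoter_bp=2500, max_bp=50_000):
    """Pure-python per-pair oracle for location class + distance category."""
    out = []
    for _, p in peaks.iterrows():
        mid = (p["start"] + p["end"]) // 2
        cls = "distal"
        overlaps = False
        in_prom = False
        best_gap, best_resp = float("inf"), False
        for _, g in genes.iterrows():
            if g["chrom"] != p["chrom"]:
                continue
            if p["start"] < g["end"] and g["start"] < p["end"]:
                overlaps = True
            if g["strand"] == "+":
                if g["tss"] - promoter_bp <= mid < g["tss"]:
                    in_prom = True
            else:
                if g["tss"] < mid <= g["tss"] + promoter_bp:
                    in_prom = True
            gap = max(0, g["start"] - p["end"], p["start"] - g["end"])
            if gap < best_gap:
                best_gap, best_resp = gap, bool(g["responsive"])
            elif gap == best_gap and g["responsive"]:
                best_resp = True
        cls = "intragenic" if overlaps else ("promoter_2_5kb" if in_prom else "distal")
        if best_gap > max_bp:
            cat = "gt50kb_any_gene"
        else:
            cat = "le50kb_responsive" if best_resp else "le50kb_unresponsive"
        out.append((cls, cat, best_gap))
    return out


class TestOracleEquivalence:
    def test_random_small_genomes_match_brute_force(self, rng):
        for trial in range(50):
            n_genes = int(rng.integers(1, 11))
            n_peaks = int(rng.integers(1, 51))
            L = 300_000
            genes = genes_df(
                [
                    (
                        f"g{i}",
                        f"chr{int(rng.integers(1, 3))}",
                        s := int(rng.integers(0, L - 5000)),
                        s + int(rng.integers(500, 5000)),
                        "+" if rng.random() < 0.5 else "-",
                        bool(rng.random() < 0.4),
                    )
                    for i in range(n_genes)
                ]
            )
            peaks = peaks_df(
                [
                    (
                        f"chr{int(rng.integers(1, 3))}",
                        s := int(rng.integers(0, L - 400)),
                        s + int(rng.integers(100, 400)),
                        f"p{i}",
                    )
                    for i in range(n_peaks)
                ]
            )
            # some peaks land on chromosomes without genes: restrict to chroms
            # carrying at least one gene so a nearest gene always exists
            peaks = peaks[peaks["chrom"].isin(set(genes["chrom"]))].reset_index(drop=True)
            if peaks.empty:
                continue
            ann = annotate_peaks(peaks, genes)
            expected = brute_force_annotation(peaks, genes)
            for row, (cls, cat, gap) in zip(ann.itertuples(), expected):
                assert row.location_class == cls, trial
                assert row.gene_distance_category == cat, trial
                assert row.gene_distance_bp == gap, trial


# ---------------------------------------------------------------------------
# enrichment

class TestPromoterEnrichment:
    def test_arithmetic_example(self):
        # genome 1 Mb; 20 genes with non-overlapping 2.5 kb promoters = 50 kb
        genes = genes_df(
            [("g%d" % i, "chr1", 10_000 + 40_000 * i, 12_000 + 40_000 * i, "+", True)
             for i in range(20)]
        )
        sizes = {"chr1": 1_000_000}
        rows = []
        for i in range(20):  # 20 peaks in promoters
            tss = 10_000 + 40_000 * i
            rows.append(("chr1", tss - 1200, tss - 1000, f"in{i}"))
        for i in range(80):  # 80 peaks far away
            rows.append(("chr1", 20_000 + 10_000 * i, 20_100 + 10_000 * i, f"out{i}"))
        res = promoter_enrichment(peaks_df(rows), genes, sizes)
        assert res.observed_fraction == pytest.approx(0.20)
        assert res.background_fraction == pytest.approx(0.05)
        assert res.enrichment == pytest.approx(4.0)

    def test_uniform_peaks_give_unit_enrichment(self, rng):
        genes = genes_df(
            [("g%d" % i, "chr1", 20_000 + 45_000 * i, 25_000 + 45_000 * i,
              "+" if i % 2 else "-", True)
             for i in range(20)]
        )
        sizes = {"chr1": 1_000_000}
        mids = rng.integers(200, 999_800, size=10_000)
        rows = [("chr1", int(m) - 100, int(m) + 100, f"p{i}") for i, m in enumerate(mids)]
        res = promoter_enrichment(peaks_df(rows), genes, sizes)
        assert res.enrichment == pytest.approx(1.0, abs=0.1)

    def test_no_promoter_hits_gives_zero(self):
        genes = genes_df([("g1", "chr1", 500_000, 510_000, "+", True)])
        res = promoter_enrichment(
            peaks_df([("chr1", 0, 200, "p1")]), genes, {"chr1": 1_000_000}
        )
        assert res.enrichment == 0.0

    def test_duplicated_gene_records_are_merged(self):
        base = genes_df([("g1", "chr1", 500_000, 510_000, "+", True)])
        doubled = pd.concat([base, base.assign(gene_id="g1b")], ignore_index=True)
        pk = peaks_df([("chr1", 498_800, 499_000, "p1"), ("chr1", 0, 200, "p2")])
        sizes = {"chr1": 1_000_000}
        a = promoter_enrichment(pk, base, sizes)
        b = promoter_enrichment(pk, doubled, sizes)
        assert a.enrichment == pytest.approx(b.enrichment)

    def test_empty_peaks_rejected(self):
        genes = genes_df([("g1", "chr1", 500_000, 510_000, "+", True)])
        with pytest.raises(ValueError, match="empty"):
            promoter_enrichment(peaks_df([]), genes, {"chr1": 1_000_000})


# ---------------------------------------------------------------------------
# summary + invariances

class TestSummary:
    def test_fraction_counting_and_partition(self):
        genes = genes_df([("g1", "chr1", 100_000, 110_000, "+", True)])
        rows = [("chr1", 102_000 + i, 102_300 + i, f"in{i}") for i in range(4)]
        rows += [("chr1", 200_000 + 1000 * i, 200_300 + 1000 * i, f"out{i}") for i in range(6)]
        ann = annotate_peaks(peaks_df(rows), genes)
        s = cistrome_summary(ann)
        assert s["location_class_fraction"]["intragenic"] == pytest.approx(0.4)
        assert sum(s["location_class_fraction"].values()) == pytest.approx(1.0)
        assert sum(s["gene_distance_category_fraction"].values()) == pytest.approx(1.0)

    def test_each_peak_classified_exactly_once(self):
        peaks, genes, sizes, truth = simulate_genome_peaks(
            GenomeSimConfig(n_peaks=100, seed=5)
        )
        ann = annotate_peaks(peaks, genes)
        assert len(ann) == 100
        assert ann["location_class"].isin(
            ["intragenic", "promoter_2_5kb", "distal"]
        ).all()
        assert ann["gene_distance_category"].notna().all()

    def test_invariance_to_chrom_renaming_and_peak_order(self):
        peaks, genes, sizes, _ = simulate_genome_peaks(GenomeSimConfig(n_peaks=60, seed=2))
        ann = annotate_peaks(peaks, genes).sort_values("name").reset_index(drop=True)
        rename = {"chr1": "scaffold_A", "chr2": "scaffold_B"}
        p2 = peaks.assign(chrom=peaks["chrom"].map(rename)).iloc[::-1].reset_index(drop=True)
        g2 = genes.assign(chrom=genes["chrom"].map(rename))
        ann2 = annotate_peaks(p2, g2).sort_values("name").reset_index(drop=True)
        pd.testing.assert_series_equal(ann["location_class"], ann2["location_class"])
        pd.testing.assert_series_equal(
            ann["gene_distance_category"], ann2["gene_distance_category"]
        )

    def test_responsive_gene_coverage_counts_each_gene_once(self):
        genes = genes_df(
            [
                ("near", "chr1", 100_000, 110_000, "+", True),
                ("far", "chr1", 500_000, 510_000, "+", True),
            ]
        )
        # two peaks near the same gene: numerator must still be 1
        pk = peaks_df(
            [("chr1", 90_000, 90_300, "p1"), ("chr1", 95_000, 95_300, "p2")]
        )
        ann = annotate_peaks(pk, genes)
        s = cistrome_summary(ann, pk, genes)
        cov = s["responsive_genes_near_peak"]
        assert (cov["numerator"], cov["denominator"]) == (1, 2)
        assert cov["percent"] == pytest.approx(50.0)
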