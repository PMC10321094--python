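"""SNP-to-gene mapping on a hand-built fixture with boundary cases.

The fixture has 10 SNPs and 8 genes (one non-coding) and exercises: the 60 kb
positional boundary (inclusive at exactly 60,000, exclusive at 60,001),
co-nearest ties, containment in overlapping gene bodies, the nearest-vs-all
positional modes, eQTL open-chromatin gating, Hi-C anchor-side selection, the
strand-aware -250/+500 promoter window, and the +/-2 kb promoter annotation
boundary. Expected maps were derived by hand from the coordinates below.
"""

import numpy as np
import pandas as pd
import pytest

from cogsys.intervals import merge_intervals, points_in_intervals
from cogsys.snp2gene import (
    AnnotationBundle,
    annotate_hic_promoters,
    build_snp_gene_map,
    derive_regions,
    integrate,
    map_eqtl,
    map_hic,
    map_positional,
    validate_map,
)

GENES = pd.DataFrame(
    [
        # gene_id, symbol, biotype, chrom, strand, start, end
        ("GA", "GA", "protein_coding", "chr1", "+", 100_000, 110_000),
        ("GB", "GB", "protein_coding", "chr1", "+", 190_000, 200_000),
        ("GC", "GC", "protein_coding", "chr1", "-", 500_000, 510_000),
        ("GD", "GD", "protein_coding", "chr1", "+", 505_000, 515_000),
        ("GE", "GE", "protein_coding", "chr2", "+", 100_000, 120_000),
        ("GF", "GF", "protein_coding", "chr2", "-", 200_000, 210_000),
        ("GG", "GG", "lncRNA", "chr2", "+", 400_000, 410_000),
        ("GH", "GH", "protein_coding", "chr2", "+", 700_000, 705_000),
    ],
    columns=["gene_id", "symbol", "biotype", "chrom", "strand", "start", "end"],
)

SNPS = pd.DataFrame(
    [
        ("s01", "chr1", 40_000),   # exactly 60 kb from GA TSS -> mapped
        ("s02", "chr1", 39_999),   # 60,001 bp -> unmapped
        ("s03", "chr1", 150_000),  # equidistant (40 kb) from GA TES and GB TSS
        ("s04", "chr1", 507_000),  # inside both GC and GD bodies
        ("s05", "chr1", 512_000),  # inside GD only; GC at 2 kb (all-mode extra)
        ("s06", "chr2", 105_000),  # eQTL to GF, inside open chromatin
        ("s07", "chr2", 150_000),  # eQTL to GE but outside open chromatin
        ("s08", "chr2", 209_900),  # inside the Hi-C promoter anchor (GF)
        ("s09", "chr2", 260_500),  # inside the Hi-C enhancer anchor
        ("s10", "chr2", 702_000),  # inside GH body
    ],
    columns=["snp_id", "chrom", "pos"],
)

OPEN_CHROMATIN = pd.DataFrame(
    [("chr2", 104_900, 105_100)], columns=["chrom", "start", "end"]
)
ENHANCERS = pd.DataFrame(
    [("chr2", 260_000, 261_000)], columns=["chrom", "start", "end"]
)
EQTLS = pd.DataFrame(
    [("s06", "GF", "brain"), ("s07", "GE", "brain")],
    columns=["snp_id", "gene_id", "tissue"],
)
# interaction 1: enhancer anchor [260000,261000) <-> promoter anchor covering
# s08 and GF's strand-aware promoter window [209500, 210250] (minus strand)
# interaction 2: "enhancer" side overlaps no known enhancer -> contributes nothing
HIC = pd.DataFrame(
    [
        ("chr2", 260_000, 261_000, "chr2", 209_400, 210_300, "enh_prom"),
        ("chr2", 600_000, 601_000, "chr2", 209_400, 210_300, "enh_prom"),
    ],
    columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
             "orientation"],
)


def bundle() -> AnnotationBundle:
    return AnnotationBundle(
        genes=GENES.copy(), open_chromatin=OPEN_CHROMATIN.copy(),
        enhancers=ENHANCERS.copy(), eqtls=EQTLS.copy(), hic=HIC.copy(),
    )


def as_set(df: pd.DataFrame) -> set:
    return set(map(tuple, df[["snp_id", "gene_id", "evidence"]].to_numpy()))


# hand-derived expected maps -------------------------------------------------

EXPECTED_PROMOTER_NEAREST = {
    ("s01", "GA", "positional"),
    ("s03", "GA", "positional"), ("s03", "GB", "positional"),
    ("s04", "GC", "positional"), ("s04", "GD", "positional"),
    ("s05", "GD", "positional"),
    ("s06", "GF", "eQTL"),
    ("s07", "GE", "positional"),
    ("s08", "GF", "HiC"),
    ("s09", "GF", "positional"),
    ("s10", "GH", "positional"),
}
EXPECTED_ENHANCER_NEAREST = (
    EXPECTED_PROMOTER_NEAREST
    - {("s08", "GF", "HiC"), ("s09", "GF", "positional")}
) | {("s08", "GF", "positional"), ("s09", "GF", "HiC")}
EXPECTED_PROMOTER_ALL = EXPECTED_PROMOTER_NEAREST | {
    ("s05", "GC", "positional"), ("s07", "GF", "positional"),
}
EXPECTED_ENHANCER_ALL = (
    EXPECTED_ENHANCER_NEAREST
    | {("s05", "GC", "positional"), ("s07", "GF", "positional")}
)


class TestHandFixture:
    @pytest.mark.parametrize(
        "hic_side,mode,expected",
        [
            ("promoter", "nearest", EXPECTED_PROMOTER_NEAREST),
            ("enhancer", "nearest", EXPECTED_ENHANCER_NEAREST),
            ("promoter", "all", EXPECTED_PROMOTER_ALL),
            ("enhancer", "all", EXPECTED_ENHANCER_ALL),
        ],
    )
    def test_full_map_matches_hand_derivation(self, hic_side, mode, expected):
        out = build_snp_gene_map(
            SNPS, bundle(), positional_mode=mode, hic_snp_side=hic_side
        )
        assert as_set(out) == expected

    def test_no_snp_mixes_positional_and_functional(self):
        out = build_snp_gene_map(SNPS, bundle())
        validate_map(out)  # must not raise

    def test_noncoding_gene_never_mapped(self):
        for mode in ("nearest", "all"):
            out = build_snp_gene_map(SNPS, bundle(), positional_mode=mode)
            assert "GG" not in set(out["gene_id"])


class TestPositional:
    def test_60kb_boundary_inclusive(self):
        out = map_positional(SNPS, GENES[GENES["biotype"] == "protein_coding"])
        got = out.groupby("snp_id")["gene_id"].agg(set).to_dict()
        assert got.get("s01") == {"GA"}
        assert "s02" not in got

    def test_growing_max_dist_never_drops_mappings(self):
        coding = GENES[GENES["biotype"] == "protein_coding"]
        small = as_set(map_positional(SNPS, coding, max_dist=30_000))
        large = as_set(map_positional(SNPS, coding, max_dist=90_000))
        assert small <= large

    def test_overlapping_gene_bodies_both_retained(self):
        coding = GENES[GENES["biotype"] == "protein_coding"]
        out = map_positional(SNPS, coding)
        got = out[out["snp_id"] == "s04"]["gene_id"].tolist()
        assert sorted(got) == ["GC", "GD"]

    def test_strand_reflection_mirrors_the_map(self):
        L = 1_000_000
        coding = GENES[GENES["biotype"] == "protein_coding"].copy()
        reflected = coding.copy()
        reflected["start"] = L - coding["end"]
        reflected["end"] = L - coding["start"]
        reflected["strand"] = coding["strand"].map({"+": "-", "-": "+"})
        rsnps = SNPS.copy()
        rsnps["pos"] = L - SNPS["pos"]
        rsnps = rsnps.sort_values(["chrom", "pos"]).reset_index(drop=True)
        orig = as_set(map_positional(SNPS, coding))
        mirror = as_set(map_positional(rsnps, reflected))
        assert orig == mirror


class TestEqtl:
    def test_open_chromatin_gates_eqtl_evidence(self):
        out = map_eqtl(SNPS, EQTLS, OPEN_CHROMATIN)
        assert as_set(out) == {("s06", "GF", "eQTL")}

    def test_empty_open_chromatin_kills_all_eqtls(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        assert map_eqtl(SNPS, EQTLS, empty).empty

    def test_unknown_snp_records_skipped(self):
        eqtls = pd.concat(
            [EQTLS, pd.DataFrame([("sXX", "GA", "brain")], columns=EQTLS.columns)]
        )
        out = map_eqtl(SNPS, eqtls, OPEN_CHROMATIN)
        assert as_set(out) == {("s06", "GF", "eQTL")}

    def test_five_record_fixture_survivors(self):
        oc = pd.DataFrame(
            [("chr1", 39_000, 41_000), ("chr2", 104_000, 106_000)],
            columns=["chrom", "start", "end"],
        )
        eqtls = pd.DataFrame(
            [
                ("s01", "GA", "brain"),  # in oc
                ("s02", "GA", "brain"),  # in oc
                ("s06", "GE", "brain"),  # in oc
                ("s07", "GE", "brain"),  # not in oc
                ("s10", "GH", "brain"),  # not in oc
            ],
            columns=["snp_id", "gene_id", "tissue"],
        )
        out = map_eqtl(SNPS, eqtls, oc)
        assert len(out) == 3
        assert set(out["snp_id"]) == {"s01", "s02", "s06"}


class TestHic:
    def test_promoter_window_is_strand_aware(self):
        # GF is minus-strand: genomic window [tss-500, tss+250] = [209500,210250]
        hic = pd.DataFrame(
            [("chr2", 260_000, 261_000, "chr2", 209_400, 209_501, "enh_prom")],
            columns=HIC.columns,
        )
        out = map_hic(SNPS, hic, ENHANCERS, GENES, snp_side="promoter")
        # promoter anchor [209400,209501) overlaps [209500,210250] at base 209501
        assert ("s08", "GF", "HiC") not in as_set(out)  # s08 not inside anchor
        hic2 = hic.copy()
        hic2.loc[0, "end_b"] = 210_300
        out2 = map_hic(SNPS, hic2, ENHANCERS, GENES, snp_side="promoter")
        assert as_set(out2) == {("s08", "GF", "HiC")}

    def test_non_enhancer_side_contributes_nothing(self):
        hic = HIC.iloc[[1]]
        out = map_hic(SNPS, hic, ENHANCERS, GENES)
        assert out.empty

    def test_orientation_inferred_when_missing(self):
        hic = HIC.iloc[[0]].copy()
        hic["orientation"] = ""
        out = map_hic(SNPS, hic, ENHANCERS, GENES, snp_side="promoter")
        assert as_set(out) == {("s08", "GF", "HiC")}


class TestPromoterAnnotation:
    def test_two_kb_boundary(self):
        # GH TSS = 700,000; +/-2 kb window covers 1-based [698000, 702000]
        hic = pd.DataFrame(
            [
                ("chr2", 697_999, 698_000, "chr2", 1, 2, ""),   # exactly 2 kb
                ("chr2", 697_998, 697_999, "chr2", 1, 2, ""),   # 2,001 bp away
            ],
            columns=HIC.columns,
        )
        out = annotate_hic_promoters(hic, GENES)
        hits = set(zip(out["interaction"], out["anchor"], out["gene_id"]))
        assert (0, "A", "GH") in hits
        assert not any(i == 1 for i, _, _ in hits)

    def test_four_interaction_fixture(self):
        hic = pd.DataFrame(
            [
                ("chr1", 99_000, 99_500, "chr1", 1, 2, ""),       # GA upstream
                ("chr1", 108_500, 109_000, "chr1", 1, 2, ""),     # GA interior/TES side (no)
                ("chr2", 209_000, 212_500, "chr2", 1, 2, ""),     # GF TSS (minus strand, tss=210000)
                ("chr1", 1, 2, "chr1", 189_000, 190_500, ""),     # GB via anchor B
            ],
            columns=HIC.columns,
        )
        out = annotate_hic_promoters(hic, GENES)
        hits = set(zip(out["interaction"], out["anchor"], out["gene_id"]))
        assert hits == {(0, "A", "GA"), (2, "A", "GF"), (3, "B", "GB")}


class TestRegions:
    def test_state_value_boundary_at_seven(self):
        table = pd.DataFrame(
            [
                ("chr1", 0, 100, 7, "Enh"),
                ("chr1", 200, 300, 8, "ZNF/Rpts"),
            ],
            columns=["chrom", "start", "end", "state_value", "state_label"],
        )
        oc, enh = derive_regions(table)
        assert oc.to_numpy().tolist() == [["chr1", 0, 100]]

    def test_adjacent_intervals_merge(self):
        table = pd.DataFrame(
            [
                ("chr1", 0, 100, 4, "Tx"),
                ("chr1", 100, 180, 5, "TxWk"),
            ],
            columns=["chrom", "start", "end", "state_value", "state_label"],
        )
        oc, _ = derive_regions(table)
        assert oc.to_numpy().tolist() == [["chr1", 0, 180]]

    def test_six_interval_fixture_hand_merge(self):
        table = pd.DataFrame(
            [
                ("chr1", 0, 50, 7, "Enh"),
                ("chr1", 40, 120, 6, "EnhG"),
                ("chr1", 300, 400, 15, "Quies"),
                ("chr2", 10, 20, 1, "TssA"),
                ("chr2", 20, 30, 9, "Het"),
                ("chr2", 25, 60, 7, "Enh"),
            ],
            columns=["chrom", "start", "end", "state_value", "state_label"],
        )
        oc, enh = derive_regions(table)
        assert oc.to_numpy().tolist() == [
            ["chr1", 0, 120], ["chr2", 10, 20], ["chr2", 25, 60]
        ]
        assert enh.to_numpy().tolist() == [["chr1", 0, 120], ["chr2", 25, 60]]

    def test_unknown_labels_warn_and_are_ignored(self):
        table = pd.DataFrame(
            [("chr1", 0, 10, 7, "Mystery")],
            columns=["chrom", "start", "end", "state_value", "state_label"],
        )
        with pytest.warns(UserWarning, match="unknown"):
            oc, enh = derive_regions(table)
        assert enh.empty  # label rule ignores the unknown state
        assert not oc.empty  # value rule still applies


class TestIntegrate:
    def test_functional_evidence_suppresses_positional(self):
        e = pd.DataFrame([("s1", "GA", "eQTL")],
                         columns=["snp_id", "gene_id", "evidence"])
        h = pd.DataFrame(columns=["snp_id", "gene_id", "evidence"])
        p = pd.DataFrame([("s1", "GB", "positional"), ("s2", "GB", "positional")],
                         columns=["snp_id", "gene_id", "evidence"])
        out = integrate(e, h, p)
        assert as_set(out) == {("s1", "GA", "eQTL"), ("s2", "GB", "positional")}

    def test_eqtl_and_hic_coexist_for_one_snp(self):
        e = pd.DataFrame([("s1", "GA", "eQTL")],
                         columns=["snp_id", "gene_id", "evidence"])
        h = pd.DataFrame([("s1", "GB", "HiC")],
                         columns=["snp_id", "gene_id", "evidence"])
        p = pd.DataFrame(columns=["snp_id", "gene_id", "evidence"])
        out = integrate(e, h, p)
        assert as_set(out) == {("s1", "GA", "eQTL"), ("s1", "GB", "HiC")}

    def test_mixed_evidence_map_rejected_by_validator(self):
        bad = pd.DataFrame(
            [("s1", "GA", "eQTL"), ("s1", "GB", "positional")],
            columns=["snp_id", "gene_id", "evidence"],
        )
        with pytest.raises(AssertionError):
            validate_map(bad)


class TestIntervalHelpers:
    def test_point_membership_half_open(self):
        iv = pd.DataFrame([("chr1", 0, 100)], columns=["chrom", "start", "end"])
        inside = points_in_intervals(
            ["chr1", "chr1", "chr1"], [1, 100, 101], iv
        )
        assert inside.tolist() == [True, True, False]

    def test_merge_coalesces_overlaps(self):
        iv = pd.DataFrame(
            [("chr1", 0, 10), ("chr1", 5, 20), ("chr1", 30, 40)],
            columns=["chrom", "start", "end"],
        )
        assert merge_intervals(iv).to_numpy().tolist() == [
            ["chr1", 0, 20], ["chr1", 30, 40]
        ]
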