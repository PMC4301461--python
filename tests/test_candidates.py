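"""Candidate tiers, genotype-specific sets, and QTL-window co-localization."""

import pandas as pd
import pytest

from conftest import make_count_matrix
from vitiseq.candidates import (
    genotype_specific_sets,
    qtl_overlap_genes,
    qtl_window_proportion,
    read_bed_loci,
    read_gff3_loci,
    select_tier1,
    select_tier2_tier3,
)
from vitiseq.core import COMPARISON_LABELS
from vitiseq.expression_matrix import ExpressionProfile
from vitiseq.synthetic_data import write_bed, write_gff3


def _profile(wt_counts, mt_counts, genes):
    libs = {f"WT_{s}": wt_counts[i] for i, s in enumerate(("EL15", "EL27", "EL38"))}
    libs |= {f"MT_{s}": mt_counts[i] for i, s in enumerate(("EL15", "EL27", "EL38"))}
    return ExpressionProfile.from_counts(make_count_matrix(libs, genes=genes))


def test_genotype_specific_definition():
    # g0 expressed at WT EL15 only; g1 expressed in both; g2 MT only; g3 nowhere
    profile = _profile(
        wt_counts=[[900, 800, 0, 0], [0, 900, 0, 0], [0, 700, 0, 0]],
        mt_counts=[[0, 900, 600, 0], [0, 800, 0, 0], [0, 600, 900, 0]],
        genes=["g0", "g1", "g2", "g3"],
    )
    wt_only, mt_only = genotype_specific_sets(profile)
    assert wt_only == {"g0"}
    assert mt_only == {"g2"}
    assert not wt_only & mt_only


def _groups(rows):
    return pd.DataFrame(rows, columns=["gene_id", "genotype", "a", "b", "c", "group"])


def test_tier1_requires_flat_triplet_detection_and_enrichment():
    profile = _profile(
        wt_counts=[[700, 600, 400], [900, 800, 0], [300, 200, 100]],
        mt_counts=[[0, 0, 0], [0, 0, 0], [0, 0, 0]],
        genes=["g_keep", "g_de", "g_noterm"],
    )
    wt_only, mt_only = genotype_specific_sets(profile)
    groups = _groups(
        [
            ["g_keep", "WT", 0, 0, 0, "not_de"],
            ["g_de", "WT", 1, 0, 1, "2"],
            ["g_noterm", "WT", 0, 0, 0, "not_de"],
        ]
    )
    ann = pd.DataFrame(
        {"gene_id": ["g_keep", "g_de"], "term_id": ["GOOD", "GOOD"]}
    )
    out = select_tier1(wt_only, mt_only, groups, profile, ann, {"GOOD"})
    assert list(out["gene_id"]) == ["g_keep"]
    assert out["tier"].iloc[0] == "specific_nonDE"
    assert out["max_rpm"].iloc[0] >= 0.5


def test_tier1_excludes_undetected_specific_gene():
    # RPM 0.4 with no 5-read rescue is not detected anywhere -> cannot be
    # genotype-specific in the first place
    cm = make_count_matrix(
        {f"{g}_{s}": [4] if g == "WT" else [0] for g in ("WT", "MT")
         for s in ("EL15", "EL27", "EL38")},
        genes=["g_low"],
        totals={f"{g}_{s}": 10_000_000 for g in ("WT", "MT")
                for s in ("EL15", "EL27", "EL38")},
    )
    profile = ExpressionProfile.from_counts(cm)
    wt_only, mt_only = genotype_specific_sets(profile)
    assert "g_low" not in wt_only  # RPM 0.4, 4 reads: below both branches


def _de(rows):
    return pd.DataFrame(rows, columns=["gene_id", "comparison", "log2fc", "call"])


def test_tier2_and_tier3_rules():
    groups = _groups(
        [
            ["g_wtonly", "WT", 1, 0, 1, "2"], ["g_wtonly", "MT", 0, 0, 0, "not_de"],
            ["g_diff", "WT", 1, 0, 0, "3"], ["g_diff", "MT", 1, 0, 1, "2"],
            ["g_div", "WT", 1, 0, 0, "3"], ["g_div", "MT", 1, 0, 0, "3"],
            ["g_same", "WT", 1, 0, 1, "2"], ["g_same", "MT", 1, 0, 1, "2"],
        ]
    )
    def de_table(lfc_by_gene):
        rows = []
        for g, lfcs in lfc_by_gene.items():
            for label, v in zip(COMPARISON_LABELS, lfcs):
                rows.append([g, label, v, 0])
        return _de(rows)

    de_wt = de_table({"g_wtonly": (2, 0, 2), "g_diff": (2, 0, 0),
                      "g_div": (4.23, 0, 0), "g_same": (2, 0, 2)})
    de_mt = de_table({"g_wtonly": (0, 0, 0), "g_diff": (2, 0, 2),
                      "g_div": (1.0, 0, 0), "g_same": (2.1, 0, 2)})
    out = select_tier2_tier3(groups, de_wt, de_mt).set_index("gene_id")
    assert out.loc["g_wtonly", "tier"] == "specific_DE"
    assert out.loc["g_wtonly", "genotype"] == "WT"
    assert out.loc["g_diff", "tier"] == "common_DE_divergent"  # different group
    assert out.loc["g_div", "tier"] == "common_DE_divergent"   # ratio 2**3.23 > 2
    assert "g_same" not in out.index  # same group, fold ratio 2**0.1 < 2


def _loci(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def test_qtl_boundary_inclusive():
    peak = 10_000_000
    loci = _loci(
        [
            ["g_at_peak", "chr1", peak, peak + 100],
            ["g_edge_in", "chr1", peak + 5_000_000, peak + 5_000_100],
            ["g_edge_out", "chr1", peak + 5_000_001, peak + 5_000_100],
            ["g_far", "chr1", peak + 9_000_000, peak + 9_000_100],
        ]
    )
    peaks = pd.DataFrame({"trait": ["t"], "chrom": ["chr1"], "position_bp": [peak]})
    out = qtl_window_proportion(loci, peaks, set(loci["gene_id"]))
    assert out["n_in_window"].iloc[0] == 2  # at-peak and edge-in
    assert out["proportion"].iloc[0] == pytest.approx(2 / 4)
    hits = qtl_overlap_genes(loci, peaks, set(loci["gene_id"]))
    assert set(hits["gene_id"]) == {"g_at_peak", "g_edge_in"}


def test_qtl_proportion_half_planted():
    peak = 15_000_000
    rows = [[f"p{i}", "chr1", peak + i * 1000, peak + i * 1000 + 99] for i in range(10)]
    rows += [[f"d{i}", "chr1", peak + 8_000_000 + i * 1000, peak + 8_000_000 + i * 1000 + 99]
             for i in range(10)]
    loci = _loci(rows)
    peaks = pd.DataFrame({"trait": ["seed"], "chrom": ["chr1"], "position_bp": [peak]})
    out = qtl_window_proportion(loci, peaks, set(loci["gene_id"]))
    assert out["proportion"].iloc[0] == 0.5


def test_widening_halfwidth_is_monotone():
    peak = 15_000_000
    loci = _loci([[f"g{i}", "chr1", peak + i * 1_000_000, peak + i * 1_000_000 + 99]
                  for i in range(10)])
    peaks = pd.DataFrame({"trait": ["t"], "chrom": ["chr1"], "position_bp": [peak]})
    genes = set(loci["gene_id"])
    prev = 0.0
    for hw in (1_000_000, 3_000_000, 5_000_000, 10_000_000):
        prop = qtl_window_proportion(loci, peaks, genes, halfwidth=hw)["proportion"].iloc[0]
        assert prop >= prev
        prev = prop


def test_unknown_peak_chromosome_rejected():
    loci = _loci([["g", "chr1", 1, 100]])
    peaks = pd.DataFrame({"trait": ["t"], "chrom": ["chrX"], "position_bp": [5]})
    with pytest.raises(ValueError, match="chrX"):
        qtl_window_proportion(loci, peaks, {"g"})


def test_gff3_bed_roundtrip(tmp_path):
    loci = _loci([["gA", "chr1", 101, 1600], ["gB", "chr2", 1, 900]])
    write_gff3(loci, tmp_path / "x.gff3")
    write_bed(loci, tmp_path / "x.bed")
    from_gff = read_gff3_loci(tmp_path / "x.gff3").sort_values("gene_id").reset_index(drop=True)
    from_bed = read_bed_loci(tmp_path / "x.bed").sort_values("gene_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(from_gff, from_bed)
    assert from_gff.loc[0, "start"] == 101 and from_gff.loc[0, "end"] == 1600
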