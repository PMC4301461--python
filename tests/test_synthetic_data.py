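"""Generator determinism, distributional structure, and planted truth."""

import numpy as np
import pandas as pd
import pytest

from vitiseq.synthetic_data import (
    ConfigurationError,
    EnrichedTermSpec,
    PlantedPattern,
    SimConfig,
    generate_annotation,
    generate_counts,
    generate_loci_and_qtls,
    solve_multipliers,
)


def small_config(**kw):
    defaults = dict(
        n_genes=400,
        planted_patterns=(PlantedPattern((1, 0, 1), 50, 8.0),),
        frac_genotype_specific=0.0,
        n_low_expression=0,
        n_qtl_proximal=10,
        seed=11,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_determinism_byte_identical():
    c = small_config()
    cm1, t1 = generate_counts(c)
    cm2, t2 = generate_counts(c)
    pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
    pd.testing.assert_frame_equal(t1, t2)
    a1 = generate_annotation(c, t1)
    a2 = generate_annotation(c, t2)
    pd.testing.assert_frame_equal(a1, a2)


def test_null_config_equal_means():
    c = small_config(planted_patterns=(), dispersion=1e-9, n_genes=2000, seed=3)
    cm, truth = generate_counts(c)
    col_means = cm.counts.mean(axis=0)
    assert col_means.std() / col_means.mean() < 0.05
    assert (truth["triplet_WT"] == "0,0,0").all()


def test_planted_fold_recovered():
    """Mean EL27/EL15 count ratio of (1,0,1)-planted genes approximates the fold."""
    c = small_config(planted_patterns=(PlantedPattern((1, 0, 1), 50, 8.0),), seed=5)
    cm, truth = generate_counts(c)
    planted = truth.index[truth["role"] == "pattern"]
    ratio = (cm.counts.loc[planted, "WT_EL27"] / cm.counts.loc[planted, "WT_EL15"]).mean()
    assert abs(ratio - 8) / 8 < 0.25


def test_nb_mean_variance_relation():
    """Flat genes follow var = mu + alpha mu^2 across replicate draws."""
    alpha = 0.1
    c = SimConfig(n_genes=2000, planted_patterns=(), frac_genotype_specific=0.0,
                  n_low_expression=0, dispersion=alpha,
                  baseline_mean_log_range=(1.5, 1.6), seed=9)
    cm, _ = generate_counts(c)
    arr = cm.counts.to_numpy(float)  # 6 iid draws per gene (flat genes)
    mu = arr.mean()
    var = arr.var(axis=1, ddof=1).mean()
    assert abs(var / mu - (1 + alpha * mu)) / (1 + alpha * mu) < 0.2


def test_genotype_specific_hard_zero():
    c = small_config(frac_genotype_specific=0.1, n_genes=500)
    cm, truth = generate_counts(c)
    wt_only = truth.index[truth["role"] == "wt_only"]
    assert (cm.counts.loc[wt_only, ["MT_EL15", "MT_EL27", "MT_EL38"]] == 0).all().all()
    assert (cm.counts.loc[wt_only, ["WT_EL15", "WT_EL27", "WT_EL38"]].sum(axis=1) > 0).all()


def test_overplanting_rejected():
    with pytest.raises(ConfigurationError, match="exceed"):
        small_config(n_genes=40)


def test_threshold_only_triplet_rejected():
    with pytest.raises(ConfigurationError, match="not exactly realizable"):
        PlantedPattern((1, 0, 0), 10, 8.0)


def test_multipliers_realize_triplets():
    m = solve_multipliers((1, 0, 1), 8.0)
    assert m[1] / m[0] == pytest.approx(8) and m[2] / m[1] == pytest.approx(1)
    m = solve_multipliers((-1, -1, -1), 8.0)
    assert min(m) == pytest.approx(1.0)  # baseline anchors the lowest stage
    assert m[0] / m[1] == pytest.approx(8) and m[1] / m[2] == pytest.approx(8)


class TestAnnotation:
    def test_no_enrichment_at_strength_one(self):
        c = small_config(
            n_genes=1000, n_terms=50, term_base_rate=0.1,
            planted_patterns=(PlantedPattern((1, 0, 1), 200, 8.0),),
            enriched_terms=(EnrichedTermSpec("TERM_0001", 100, 1.0),),
        )
        cm, truth = generate_counts(c)
        ann = generate_annotation(c, truth)
        targets = truth.index[truth["member_terms"].str.contains("TERM_0001")]
        hit = ann[(ann["term_id"] == "TERM_0001") & (ann["gene_id"].isin(targets))]
        # at strength 1 the target subset carries the term at the base rate
        assert abs(len(hit) / len(targets) - 0.1) < 0.1

    def test_saturating_strength_marks_all_targets(self):
        c = small_config(
            enriched_terms=(EnrichedTermSpec("TERM_0002", 30, 1e9),),
            n_terms=10, term_base_rate=0.05,
        )
        cm, truth = generate_counts(c)
        ann = generate_annotation(c, truth)
        targets = set(truth.index[truth["member_terms"].str.contains("TERM_0002")])
        carried = set(ann.loc[ann["term_id"] == "TERM_0002", "gene_id"])
        assert targets <= carried and len(targets) == 30

    def test_total_annotations_binomial_expectation(self):
        c = small_config(n_genes=1000, n_terms=40, term_base_rate=0.05,
                         enriched_terms=())
        cm, truth = generate_counts(c)
        ann = generate_annotation(c, truth)
        expected = 0.05 * 1000 * 40
        assert abs(len(ann) - expected) < 4 * np.sqrt(expected * 0.95)


class TestLoci:
    def test_planted_window_membership(self):
        c = small_config(n_qtl=1, n_qtl_proximal=10,
                         chrom_lengths={"chr1": 40_000_000})
        cm, truth = generate_counts(c)
        loci, peaks = generate_loci_and_qtls(c, truth)
        assert len(peaks) == 1
        peak = int(peaks["position_bp"].iloc[0])
        prox = truth[truth["qtl_proximal"]]
        assert len(prox) == 10
        assert (prox["start"] >= peak - 5_000_000).all()
        assert (prox["end"] <= peak + 5_000_000).all()
        distal = truth[~truth["qtl_proximal"]]
        outside = (distal["end"] < peak - 5_000_000) | (distal["start"] > peak + 5_000_000)
        assert outside.all()

    def test_no_qtls(self):
        c = small_config(n_qtl=0, n_qtl_proximal=0)
        cm, truth = generate_counts(c)
        loci, peaks = generate_loci_and_qtls(c, truth)
        assert peaks.empty
        assert not truth["qtl_proximal"].any()

    def test_two_peaks_disjoint_windows(self):
        c = small_config(n_qtl=2, n_qtl_proximal=20,
                         chrom_lengths={"chr1": 45_000_000})
        cm, truth = generate_counts(c)
        loci, peaks = generate_loci_and_qtls(c, truth)
        p1, p2 = sorted(peaks["position_bp"])
        assert p2 - p1 == 15_000_000  # even spacing on one chromosome
        # windows [p-5Mb, p+5Mb] are disjoint; every proximal gene is in exactly one
        prox = truth[truth["qtl_proximal"]]
        in1 = (prox["start"] >= p1 - 5e6) & (prox["end"] <= p1 + 5e6)
        in2 = (prox["start"] >= p2 - 5e6) & (prox["end"] <= p2 + 5e6)
        assert ((in1.astype(int) + in2.astype(int)) == 1).all()

    def test_short_chromosome_rejected(self):
        c = small_config(chrom_lengths={"chr1": 9_000_000})
        cm, truth = generate_counts(c)
        with pytest.raises(ConfigurationError, match="must exceed"):
            generate_loci_and_qtls(c, truth)
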