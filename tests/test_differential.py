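"""Size factors, blind dispersion, the NB exact test, BH, and DE calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitiseq.count_rank import binomial_pair_pvalue
from vitiseq.differential import (
    bh_adjust,
    call_de,
    de_genotype,
    estimate_dispersion_blind,
    nb_exact_test,
    size_factors,
)


def _df(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestSizeFactors:
    def test_identical_libraries(self):
        counts = _df({"a": [10, 20, 40], "b": [10, 20, 40]})
        f = size_factors(counts)
        assert np.allclose(f, [1.0, 1.0])

    def test_scale_equivariance(self):
        counts = _df({"a": [10, 20, 40], "b": [20, 40, 80]})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)
        # normalized to geometric mean 1
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_hand_computed_median_of_ratios(self):
        # geomeans: sqrt(200), sqrt(800), sqrt(3200); ratios col a all 1/sqrt2,
        # col b all sqrt2 -> factor ratio 1:2
        counts = _df({"a": [10, 20, 40], "b": [20, 40, 80]})
        f = size_factors(counts)
        assert f["a"] == pytest.approx(1 / np.sqrt(2))
        assert f["b"] == pytest.approx(np.sqrt(2))

    def test_no_common_positive_gene(self):
        counts = _df({"a": [5, 0], "b": [0, 5]})
        with pytest.raises(ValueError, match="positive count"):
            size_factors(counts)


class TestDispersion:
    def test_identical_columns_zero_raw(self):
        counts = pd.DataFrame({"a": np.arange(20, 40), "b": np.arange(20, 40)})
        f = pd.Series([1.0, 1.0], index=["a", "b"])
        with pytest.warns(UserWarning):
            model = estimate_dispersion_blind(counts, f)
        assert (model.raw == 0).all()

    def test_poisson_data_fit_near_zero(self):
        rng = np.random.default_rng(42)
        mu = 10 ** rng.uniform(0.5, 3, size=5000)
        counts = pd.DataFrame({"a": rng.poisson(mu), "b": rng.poisson(mu)})
        f = pd.Series([1.0, 1.0], index=["a", "b"])
        model = estimate_dispersion_blind(counts, f)
        assert model.a0 <= 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(7)
        alpha = 0.2
        mu = 10 ** rng.uniform(1.0, 3, size=5000)
        r = 1 / alpha
        counts = pd.DataFrame(
            {c: rng.negative_binomial(r, r / (r + mu)) for c in ("a", "b")}
        )
        f = pd.Series([1.0, 1.0], index=["a", "b"])
        model = estimate_dispersion_blind(counts, f)
        assert 0.1 <= model.final.median() <= 0.4

    def test_maximum_mode_dominates_fit_only(self):
        rng = np.random.default_rng(3)
        mu = 10 ** rng.uniform(1, 2.5, size=500)
        counts = pd.DataFrame({"a": rng.poisson(mu), "b": rng.poisson(mu * 3)})
        f = pd.Series([1.0, 1.0], index=["a", "b"])
        fit_only = estimate_dispersion_blind(counts, f, sharing_mode="fit-only")
        maximum = estimate_dispersion_blind(counts, f, sharing_mode="maximum")
        assert (maximum.final >= fit_only.final - 1e-12).all()


class TestExactTest:
    def test_symmetric_split_is_one(self):
        for alpha in (0.0, 0.1, 1.0):
            assert nb_exact_test(9, 9, 1.0, 1.0, alpha) == pytest.approx(1.0)

    def test_zero_total_is_one(self):
        assert nb_exact_test(0, 0, 1.0, 1.0, 0.5) == 1.0

    def test_extreme_split_poisson_limit(self):
        assert nb_exact_test(0, 16, 1.0, 1.0, 0.0) == pytest.approx(2 * 0.5**16, rel=1e-9)

    def test_poisson_limit_equals_binomial_oracle(self):
        """Cross-module: at alpha = 0 and equal size factors the conditional
        NB test is the exact binomial pair test."""
        for total in range(1, 31):
            for kA in range(total + 1):
                expected = binomial_pair_pvalue(kA, total - kA, 1, 1)
                got = nb_exact_test(kA, total - kA, 1.0, 1.0, 0.0)
                assert got == pytest.approx(expected, abs=1e-10), (kA, total)

    def test_dispersion_widens_pvalue(self):
        p0 = nb_exact_test(30, 5, 1.0, 1.0, 0.0)
        p1 = nb_exact_test(30, 5, 1.0, 1.0, 0.5)
        assert p1 > p0


class TestBH:
    def test_hand_applied_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, ps, rnd):
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        base = bh_adjust(ps)
        shuffled = bh_adjust([ps[i] for i in perm])
        assert np.allclose([base[i] for i in perm], shuffled)


@pytest.mark.parametrize(
    "p_adj,log2fc,expected",
    [(0.04, 1.5, 1), (0.04, 0.9, 0), (0.06, 5.0, 0), (0.05, -1.01, -1), (0.04, -0.5, 0)],
)
def test_call_thresholds(p_adj, log2fc, expected):
    assert call_de(p_adj, log2fc) == expected


def test_de_genotype_planted_sign_power(planted_dataset):
    """Planted fold-8 steps at high base mean carry the planted sign."""
    truth = planted_dataset["truth"]
    de = planted_dataset["de_wt"]
    # genes planted as monotone up in WT: first comparison must be +1
    up = truth.index[(truth["triplet_WT"] == "1,1,1")]
    sub = de[(de["gene_id"].isin(up)) & (de["comparison"] == "EL27vsEL15")]
    assert (sub["call"] == 1).mean() >= 0.9


def test_de_requires_three_libraries(planted_dataset):
    cm = planted_dataset["cm"]
    with pytest.raises(ValueError, match="3 libraries"):
        de_genotype(cm.subset(["WT_EL15", "WT_EL27"]), "WT")
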