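"""Replicate-free two-condition differential expression on raw counts.

The study design has a single library per genotype x stage, so the test
must work without replicates.  The engine follows the classic
negative-binomial exact-test scheme for unreplicated count data:

1. *Size factors* by the median-of-ratios method: each library is scaled by
   the median, over genes, of its counts divided by the per-gene geometric
   mean across libraries.
2. *Blind dispersion estimation*: the two libraries being compared are
   treated as pseudo-replicates.  A method-of-moments estimate
   ``alpha_hat = max(0, (s^2 - mu) / mu^2)`` is computed per gene on
   size-factor-normalized counts, and the mean-dispersion trend
   ``alpha(mu) = a0 + a1 / mu`` is fitted across genes by least squares
   with one outlier-trimming pass (genes carrying real condition
   differences inflate their own alpha_hat and would otherwise bias the
   trend).
3. *NB exact test*: conditional on the count sum of a gene, the probability
   of a split as extreme or more extreme than observed, under independent
   NB laws with matched means and the gene's dispersion.  At alpha = 0 this
   reduces to the conditional binomial (Poisson) test.
4. *Benjamini-Hochberg* FDR adjustment, then calls at the study thresholds
   FDR <= 5% and |log2 fold change| > 1.

Because the per-gene raw dispersion of an unreplicated comparison contains
the very signal under test, the default sharing mode is ``"fit-only"``
(use the fitted trend value); ``"maximum"`` (``max(raw, fitted)``) is
available and is strictly more conservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from vitiseq.core import COMPARISONS, CountMatrix

FDR_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0

# relative slack when comparing point masses to the observed one; guards
# against ties lost to floating-point rounding
_MASS_TIE_REL = 1e-7


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Only genes with a positive count in every library contribute (their
    geometric mean is positive).  Raises if no such gene exists.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors require >= 2 libraries")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has a positive count in every library; size factors are "
            "undefined — check that the libraries share a common expressed core"
        )
    logs = np.log(arr[positive])
    log_geomean = logs.mean(axis=1)
    log_ratios = logs - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class DispersionModel:
    """Per-gene dispersions plus the fitted mean-dispersion trend.

    ``final`` is the dispersion the exact test uses: the fitted trend value
    under ``sharing_mode="fit-only"`` (default for unreplicated designs) or
    ``max(raw, fitted)`` under ``"maximum"``.
    """

    raw: pd.Series
    fitted: pd.Series
    a0: float
    a1: float
    sharing_mode: str

    @property
    def final(self) -> pd.Series:
        if self.sharing_mode == "fit-only":
            return self.fitted
        return pd.concat([self.raw, self.fitted], axis=1).max(axis=1)


# median of the chi-square distribution with one degree of freedom: with two
# pseudo-replicates the sample variance is (approximately) var * chi2_1, so
# the conditional median of the unclipped moment estimate is biased by this
# factor and can be corrected analytically
_CHI2_1_MEDIAN = 0.45493642311957174

# below this normalized mean the moment estimate is dominated by count
# discreteness and is excluded from the trend fit
_FIT_MEAN_FLOOR = 10.0


def _fit_trend(mu: np.ndarray, alpha_hat: np.ndarray) -> tuple[float, float]:
    """Robust fit of ``alpha(mu) = a0 + a1/mu`` from unclipped moment estimates.

    Median (quantile 0.5) regression keeps genes carrying real condition
    differences — whose own estimates are inflated by the signal under
    test — from dragging the trend up.  Under the null the sample variance
    of two pseudo-replicates is roughly ``var * chi2_1``, so the fitted
    conditional median is rescaled by the chi2_1 median to make the trend
    unbiased for the true dispersion.
    """
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    res = sm.QuantReg(alpha_hat, X).fit(q=0.5)
    b0, b1 = res.params
    a0 = max(float(b0) / _CHI2_1_MEDIAN, 0.0)
    a1 = max((float(b1) + 1 - _CHI2_1_MEDIAN) / _CHI2_1_MEDIAN, 0.0)
    return a0, a1


def estimate_dispersion_blind(
    counts: pd.DataFrame,
    factors: pd.Series,
    sharing_mode: str = "fit-only",
) -> DispersionModel:
    """Blind dispersion from two libraries treated as pseudo-replicates.

    ``counts`` holds the two libraries of one comparison.  Per-gene
    method-of-moments estimates feed a robust ``a0 + a1/mu`` trend fit over
    genes with normalized mean >= 10; with fewer than 10 genes carrying
    positive raw dispersion the trend degenerates to the mean of whatever
    positive estimates exist (warned).
    """
    if sharing_mode not in ("fit-only", "maximum"):
        raise ValueError(f"unknown sharing_mode: {sharing_mode!r}")
    if counts.shape[1] != 2:
        raise ValueError("blind estimation expects exactly the two libraries of a comparison")
    norm = counts.to_numpy(dtype=float) / factors.loc[counts.columns].to_numpy(dtype=float)
    mu = norm.mean(axis=1)
    s2 = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
    raw_unclipped = raw.copy()
    raw = np.clip(raw, 0.0, None)
    pos = (raw > 0) & (mu > 0)
    eligible = mu >= _FIT_MEAN_FLOOR
    if pos.sum() < 10 or eligible.sum() < 10:
        warnings.warn(
            "fewer than 10 genes usable for the dispersion trend; "
            "falling back to a constant fitted trend",
            stacklevel=2,
        )
        a0 = float(raw[pos].mean()) if pos.any() else 0.0
        a1 = 0.0
    else:
        a0, a1 = _fit_trend(mu[eligible], raw_unclipped[eligible])
    with np.errstate(divide="ignore", invalid="ignore"):
        fitted = np.where(mu > 0, a0 + a1 / mu, a0)
    fitted = np.clip(fitted, 0.0, None)
    idx = counts.index
    return DispersionModel(
        raw=pd.Series(raw, index=idx, name="raw_dispersion"),
        fitted=pd.Series(fitted, index=idx, name="fitted_dispersion"),
        a0=a0, a1=a1, sharing_mode=sharing_mode,
    )


def _log_pmf(ks: np.ndarray, mean: float, alpha: float) -> np.ndarray:
    if mean <= 0:
        out = np.full(ks.shape, -np.inf)
        out[ks == 0] = 0.0
        return out
    if alpha <= 0:
        return stats.poisson.logpmf(ks, mean)
    r = 1.0 / alpha
    return stats.nbinom.logpmf(ks, r, r / (r + mean))


def nb_exact_test(kA: int, kB: int, sA: float, sB: float, alpha: float) -> float:
    """Exact conditional NB test for one gene's count pair.

    Conditional on the total ``kA + kB``, sums the probabilities of all
    splits whose joint probability does not exceed the observed one, under
    independent NB laws with common normalized mean
    ``q = (kA/sA + kB/sB) / 2`` scaled back by each size factor, and
    dispersion ``alpha`` (variance ``mu + alpha*mu^2``).  ``alpha = 0`` is
    the Poisson / conditional-binomial limit; a zero total gives p = 1.
    """
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    if kA < 0 or kB < 0:
        raise ValueError("counts must be non-negative")
    total = kA + kB
    if total == 0:
        return 1.0
    q = (kA / sA + kB / sB) / 2.0
    muA, muB = q * sA, q * sB
    ks = np.arange(total + 1)
    logp = _log_pmf(ks, muA, alpha) + _log_pmf(total - ks, muB, alpha)
    norm = logsumexp(logp)
    obs = logp[kA]
    keep = logp <= obs + np.log1p(_MASS_TIE_REL)
    p = float(np.exp(logsumexp(logp[keep]) - norm))
    return min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de(p_adj: float, log2fc: float,
            fdr: float = FDR_THRESHOLD, lfc: float = LFC_THRESHOLD) -> int:
    """Three-level significance call at the study thresholds.

    +1 for significant up-regulation (FDR <= 5% and log2FC > 1), -1 for
    significant down-regulation (log2FC < -1), 0 otherwise.
    """
    if p_adj <= fdr:
        if log2fc > lfc:
            return 1
        if log2fc < -lfc:
            return -1
    return 0


def de_comparison(
    cm: CountMatrix,
    genotype: str,
    label: str,
    stage_a: str,
    stage_b: str,
    factors: pd.Series,
    fdr: float = FDR_THRESHOLD,
    lfc: float = LFC_THRESHOLD,
    sharing_mode: str = "fit-only",
) -> pd.DataFrame:
    """DE table for one later-vs-earlier stage comparison within a genotype."""
    lib_a = cm.libraries_for(genotype, stage_a)
    lib_b = cm.libraries_for(genotype, stage_b)
    if len(lib_a) != 1 or len(lib_b) != 1:
        raise ValueError(f"expected one library for {genotype}/{stage_a} and {genotype}/{stage_b}")
    lib_a, lib_b = lib_a[0], lib_b[0]
    pair = cm.counts[[lib_a, lib_b]]
    sA = float(factors.loc[lib_a])
    sB = float(factors.loc[lib_b])
    disp = estimate_dispersion_blind(pair, factors, sharing_mode=sharing_mode)
    alphas = disp.final.to_numpy()
    ka = pair[lib_a].to_numpy(dtype=int)
    kb = pair[lib_b].to_numpy(dtype=int)
    mean_a = ka / sA
    mean_b = kb / sB
    # log2fc oriented later/earlier; 0.5 pseudocount only on zero means
    num = np.where(mean_b > 0, mean_b, 0.5)
    den = np.where(mean_a > 0, mean_a, 0.5)
    log2fc = np.log2(num / den)

    testable = (ka + kb) > 0
    p_raw = np.full(len(pair), np.nan)
    for i in np.flatnonzero(testable):
        p_raw[i] = nb_exact_test(int(ka[i]), int(kb[i]), sA, sB, float(alphas[i]))
    p_adj = np.full(len(pair), np.nan)
    p_adj[testable] = bh_adjust(p_raw[testable])
    calls = np.zeros(len(pair), dtype=int)
    for i in np.flatnonzero(testable):
        calls[i] = call_de(p_adj[i], log2fc[i], fdr=fdr, lfc=lfc)
    return pd.DataFrame(
        {
            "gene_id": pair.index,
            "genotype": genotype,
            "comparison": label,
            "baseMeanA": mean_a,
            "baseMeanB": mean_b,
            "log2fc": np.where(testable, log2fc, np.nan),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "call": calls,
        }
    ).reset_index(drop=True)


def de_genotype(
    cm: CountMatrix,
    genotype: str,
    fdr: float = FDR_THRESHOLD,
    lfc: float = LFC_THRESHOLD,
    sharing_mode: str = "fit-only",
) -> pd.DataFrame:
    """All three stage comparisons for one genotype, concatenated.

    Size factors are estimated once over the genotype's three libraries.
    """
    libs = cm.libraries_for(genotype)
    if len(libs) != 3:
        raise ValueError(f"expected 3 libraries for genotype {genotype}, got {len(libs)}")
    factors = size_factors(cm.counts[libs])
    frames = [
        de_comparison(cm, genotype, label, a, b, factors, fdr=fdr, lfc=lfc,
                      sharing_mode=sharing_mode)
        for label, a, b in COMPARISONS
    ]
    return pd.concat(frames, ignore_index=True)
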