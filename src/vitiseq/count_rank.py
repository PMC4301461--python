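"""Signed exact-binomial ranking of transcripts between two libraries.

For a gene with counts ``n1``, ``n2`` in two libraries of total depths
``N1``, ``N2``, the significance of the count difference is assessed with
an exact two-sided binomial test: conditional on ``n = n1 + n2``, the count
``n1`` is Binomial(n, pi) under the null of equal per-read rates, with
``pi = N1 / (N1 + N2)``.  The p-value is log-transformed for numerical
stability and signed by the direction of the library-size-corrected
difference, then combined with the (pseudocount-stabilized) log2 expression
ratio into a single ranking value.  The ranking applies to any pair of the
six libraries, independently of genotype; the p-values are used only for
ordering, never corrected for multiple testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from vitiseq.core import CountMatrix

_P_FLOOR = 5e-324  # smallest subnormal double: keeps log10 finite


def binomial_pair_pvalue(n1: int, n2: int, N1: int, N2: int) -> float:
    """Two-sided exact binomial p-value for a count pair.

    Tests ``n1`` successes in ``n1 + n2`` trials against success probability
    ``N1 / (N1 + N2)``; two-sidedness is the minimum-likelihood convention
    (the sum of all outcome probabilities not exceeding the observed
    outcome's probability).  No trials (``n1 = n2 = 0``) gives 1.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    n = n1 + n2
    if n == 0:
        return 1.0
    pi = N1 / (N1 + N2)
    p = stats.binomtest(n1, n, pi, alternative="two-sided").pvalue
    return float(min(max(p, _P_FLOOR), 1.0))


def signed_log_score(n1: int, n2: int, N1: int, N2: int) -> float:
    """``-log10`` of the pair p-value, signed by the rate difference.

    Positive when ``n1/N1 > n2/N2``, negative for the reverse, and exactly 0
    when the library-size-corrected rates are equal.
    """
    if n1 / N1 == n2 / N2:
        return 0.0
    p = binomial_pair_pvalue(n1, n2, N1, N2)
    sign = 1.0 if n1 / N1 > n2 / N2 else -1.0
    return float(sign * -np.log10(p))


@dataclass
class PairScore:
    """Per-gene score for one library pair."""

    gene_id: str
    n1: int
    n2: int
    N1: int
    N2: int
    p_two_sided: float
    signed_log_p: float
    log2_ratio: float
    ranking_value: float


def pair_score(gene_id: str, n1: int, n2: int, N1: int, N2: int) -> PairScore:
    """Score one gene: p-value, signed log score, stabilized ratio, ranking value.

    The log2 ratio uses a depth-tied pseudocount ``eps = 0.5 / min(N1, N2)``
    on the per-read rates so zero counts stay finite and the stabilization
    is scale-free; the ranking value is ``signed_log_p * |log2_ratio|``.
    """
    p = binomial_pair_pvalue(n1, n2, N1, N2)
    slp = signed_log_score(n1, n2, N1, N2)
    eps = 0.5 / min(N1, N2)
    log2_ratio = float(np.log2((n1 / N1 + eps) / (n2 / N2 + eps)))
    return PairScore(
        gene_id=gene_id, n1=n1, n2=n2, N1=N1, N2=N2,
        p_two_sided=p, signed_log_p=slp, log2_ratio=log2_ratio,
        ranking_value=float(slp * abs(log2_ratio)),
    )


def ranking_value(score: PairScore) -> float:
    return score.ranking_value


def rank_transcripts(scores: list[PairScore]) -> pd.DataFrame:
    """Order scores by descending |ranking value|; ties by |signed log p|, then gene id.

    All scores must come from the same library pair (same ``N1``, ``N2``).
    """
    if not scores:
        return pd.DataFrame(
            columns=["gene_id", "n1", "n2", "p", "signed_log_p", "log2_ratio", "ranking_value", "rank"]
        )
    pairs = {(s.N1, s.N2) for s in scores}
    if len(pairs) > 1:
        raise ValueError(f"mixed library pairs in one ranking: {sorted(pairs)}")
    df = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "n1": [s.n1 for s in scores],
            "n2": [s.n2 for s in scores],
            "p": [s.p_two_sided for s in scores],
            "signed_log_p": [s.signed_log_p for s in scores],
            "log2_ratio": [s.log2_ratio for s in scores],
            "ranking_value": [s.ranking_value for s in scores],
        }
    )
    df["_abs_rv"] = df["ranking_value"].abs()
    df["_abs_slp"] = df["signed_log_p"].abs()
    df = df.sort_values(
        ["_abs_rv", "_abs_slp", "gene_id"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns=["_abs_rv", "_abs_slp"])
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def rank_pair(cm: CountMatrix, lib_a: str, lib_b: str) -> pd.DataFrame:
    """Rank every gene of a count matrix between two of its libraries."""
    for lib in (lib_a, lib_b):
        if lib not in cm.counts.columns:
            raise ValueError(f"unknown library id: {lib}")
    N1 = int(cm.libraries.loc[lib_a, "total_reads"])
    N2 = int(cm.libraries.loc[lib_b, "total_reads"])
    scores = [
        pair_score(g, int(cm.counts.at[g, lib_a]), int(cm.counts.at[g, lib_b]), N1, N2)
        for g in cm.gene_ids
    ]
    return rank_transcripts(scores)
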