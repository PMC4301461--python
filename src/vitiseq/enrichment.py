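"""Hypergeometric over-representation analysis of annotation terms.

For a study gene set of size ``n`` drawn from an annotated background of
``N`` genes, a term carried by ``K`` background genes and ``k`` study genes
is scored with the upper tail of the hypergeometric distribution,
``P(X >= k)``.  P-values over the tested term family are BH-adjusted, and a
term is called significantly enriched under the dual rule FDR < 0.05 *and*
raw p < 0.01 — both conditions must hold.

The background defaults to all annotated genes (the reference-genome
convention); only over-representation is tested, and only terms actually
present in the study set (k >= 1) enter the family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from vitiseq.differential import bh_adjust

ENRICH_FDR = 0.05
ENRICH_P = 0.01


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """``P(X >= k)`` for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} out of range [0, min(K={K}, n={n})]")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if K < 0 or n < 0 or N < 0:
        raise ValueError("all arguments must be non-negative")
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


@dataclass
class EnrichmentResult:
    term_id: str
    N: int
    K: int
    n: int
    k: int
    p_hyper: float
    fdr: float
    significant: bool


def enrich(
    study_set,
    annotation: pd.DataFrame,
    background=None,
    fdr_threshold: float = ENRICH_FDR,
    p_threshold: float = ENRICH_P,
) -> pd.DataFrame:
    """Test every term present in the study set for over-representation.

    Parameters
    ----------
    study_set
        Iterable of gene ids; must be a subset of the background.
    annotation
        Long-format table with columns ``gene_id`` and ``term_id``.
    background
        Background gene universe; defaults to all genes in the annotation
        table.  Restricting it (e.g. to expressed genes) is the caller's
        choice.

    Returns a DataFrame sorted by p with columns
    term_id, k, n, K, N, p_hyper, fdr, significant.
    """
    if background is None:
        background = set(annotation["gene_id"])
    else:
        background = set(background)
    study = set(study_set)
    if not study <= background:
        extra = sorted(study - background)[:5]
        raise ValueError(f"study set contains genes outside the background, e.g. {extra}")
    cols = ["term_id", "k", "n", "K", "N", "p_hyper", "fdr", "significant"]
    if not study:
        warnings.warn("empty study set: nothing to test", stacklevel=2)
        return pd.DataFrame(columns=cols)

    ann = annotation[annotation["gene_id"].isin(background)].drop_duplicates(
        ["gene_id", "term_id"]
    )
    N = len(background)
    n = len(study)
    K_by_term = ann.groupby("term_id")["gene_id"].nunique()
    in_study = ann[ann["gene_id"].isin(study)]
    k_by_term = in_study.groupby("term_id")["gene_id"].nunique()
    if k_by_term.empty:
        return pd.DataFrame(columns=cols)

    rows = []
    for term, k in k_by_term.items():
        K = int(K_by_term.loc[term])
        rows.append(
            {"term_id": term, "k": int(k), "n": n, "K": K, "N": N,
             "p_hyper": hypergeom_upper_tail(int(k), K, n, N)}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_hyper"])
    out["significant"] = (out["fdr"] < fdr_threshold) & (out["p_hyper"] < p_threshold)
    return out.sort_values(["p_hyper", "term_id"], kind="mergesort").reset_index(drop=True)[cols]
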