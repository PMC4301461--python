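"""Sign-triplet classification of stage-course differential expression.

Each gene's three significance calls — (a, b, c) for the comparisons
EL15->EL27, EL27->EL38 and EL15->EL38, each in {-1, 0, +1} — form a sign
triplet.  Of the 27 possible triplets, 18 describe logically consistent
("relevant") expression patterns; the rest are contradictory, e.g.
(1, 1, -1): two successive significant increases cannot produce an overall
significant decrease.  The all-zero triplet is a non-DE gene, not a
pattern.

Relevance rule (an explicit formalization of the pattern catalogue):

(i)   (0, 0, 0) is not a pattern;
(ii)  if a = b != 0 the overall call c must repeat the common sign;
(iii) if exactly one of a, b is nonzero with sign s, c must be s or 0;
(iv)  if a = -b != 0 (rise then fall or fall then rise), any c is possible;
(v)   if a = b = 0, only a nonzero c (a change visible only end-to-end)
      makes the gene DE.

Exactly 18 triplets satisfy the rule; they are numbered 1-18, group 1 being
monotone up-regulation (1,1,1) and group 18 monotone down-regulation
(-1,-1,-1).  Observed-but-irrelevant triplets (possible on thresholded real
data) are retained in an explicit ``inconsistent`` bin so the partition of
DE genes stays exact.
"""

from __future__ import annotations

from itertools import product

import pandas as pd

Triplet = tuple[int, int, int]

#: Group numbering of the 18 relevant triplets.  Within narrative pairs the
#: variant that remains significant end-to-end comes first (group 2 = (1,0,1)
#: before group 3 = (1,0,0), and so on down the catalogue).
GROUP_OF_TRIPLET: dict[Triplet, int] = {
    (1, 1, 1): 1,
    (1, 0, 1): 2,
    (1, 0, 0): 3,
    (1, -1, 1): 4,
    (1, -1, 0): 5,
    (1, -1, -1): 6,
    (0, 1, 1): 7,
    (0, 1, 0): 8,
    (0, 0, 1): 9,
    (0, -1, -1): 10,
    (0, -1, 0): 11,
    (0, 0, -1): 12,
    (-1, 1, 1): 13,
    (-1, 1, 0): 14,
    (-1, 1, -1): 15,
    (-1, 0, -1): 16,
    (-1, 0, 0): 17,
    (-1, -1, -1): 18,
}

TRIPLET_OF_GROUP: dict[int, Triplet] = {g: t for t, g in GROUP_OF_TRIPLET.items()}


def is_relevant(triplet: Triplet) -> bool:
    """Whether a sign triplet is a logically consistent DE pattern."""
    a, b, c = triplet
    if (a, b, c) == (0, 0, 0):
        return False
    if a != 0 and a == b:
        return c == a
    if a != 0 and b != 0 and a == -b:
        return True
    if a == 0 and b == 0:
        return c != 0
    s = a if a != 0 else b
    return c in (s, 0)


def assign_group(triplet: Triplet) -> int | None:
    """Group id 1-18 of a relevant triplet, ``None`` for irrelevant ones."""
    for v in triplet:
        if v not in (-1, 0, 1):
            raise ValueError(f"triplet entries must be in {{-1,0,1}}, got {triplet}")
    return GROUP_OF_TRIPLET.get(tuple(triplet))


def enumerate_patterns() -> pd.DataFrame:
    """All 27 sign triplets with relevance flags and group ids."""
    rows = []
    for t in product((-1, 0, 1), repeat=3):
        rows.append(
            {"a": t[0], "b": t[1], "c": t[2],
             "relevant": is_relevant(t), "group_id": assign_group(t)}
        )
    df = pd.DataFrame(rows)
    df["group_id"] = df["group_id"].astype("Int64")
    return df


def _triplets_from_calls(de: pd.DataFrame) -> pd.DataFrame:
    from vitiseq.core import COMPARISON_LABELS

    wide = de.pivot_table(index="gene_id", columns="comparison", values="call", aggfunc="first")
    missing_cols = [c for c in COMPARISON_LABELS if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"missing comparisons: {missing_cols}")
    incomplete = wide[list(COMPARISON_LABELS)].isna().any(axis=1)
    if incomplete.any():
        raise ValueError(
            f"genes missing a comparison call: {wide.index[incomplete][:5].tolist()}"
        )
    out = wide[list(COMPARISON_LABELS)].astype(int)
    out.columns = ["a", "b", "c"]
    return out


def classify_genes(de_wt: pd.DataFrame, de_mt: pd.DataFrame) -> dict:
    """Per-gene triplets and the WT-vs-MT group-count table.

    Takes the per-genotype DE tables (one row per gene per comparison with a
    ``call`` column).  Genes whose triplet is all-zero in a genotype are not
    DE there and are excluded from that genotype's counts; genes with an
    observed irrelevant triplet are tallied in an ``inconsistent`` bin.

    Returns a dict with ``genes`` (per gene, per genotype: a, b, c,
    group label) and ``group_counts`` (group_id, pattern, n_WT, n_MT).
    """
    per_gene_frames = []
    counts: dict[str, pd.Series] = {}
    for genotype, de in (("WT", de_wt), ("MT", de_mt)):
        trip = _triplets_from_calls(de)
        labels = []
        for a, b, c in trip.itertuples(index=False):
            t = (int(a), int(b), int(c))
            if t == (0, 0, 0):
                labels.append("not_de")
            elif is_relevant(t):
                labels.append(str(GROUP_OF_TRIPLET[t]))
            else:
                labels.append("inconsistent")
        trip = trip.assign(genotype=genotype, group=labels)
        per_gene_frames.append(trip.reset_index())
        de_only = trip[trip["group"] != "not_de"]
        counts[genotype] = de_only["group"].value_counts()

    order = [str(g) for g in range(1, 19)] + ["inconsistent"]
    table = pd.DataFrame(
        {
            "group_id": order,
            "pattern": [
                ",".join(map(str, TRIPLET_OF_GROUP[int(g)])) if g != "inconsistent" else ""
                for g in order
            ],
            "n_WT": [int(counts["WT"].get(g, 0)) for g in order],
            "n_MT": [int(counts["MT"].get(g, 0)) for g in order],
        }
    )
    return {"genes": pd.concat(per_gene_frames, ignore_index=True), "group_counts": table}
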