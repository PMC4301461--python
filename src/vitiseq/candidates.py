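"""Candidate-gene selection funnel and QTL-window co-localization.

Three automatable tiers narrow the gene lists toward candidates for the
seedless phenotype:

* ``specific_nonDE`` — genes detected in exactly one genotype, with no
  significant change across stages there, carrying at least one
  significantly enriched annotation term;
* ``specific_DE`` — genes differentially expressed in exactly one genotype;
* ``common_DE_divergent`` — genes DE in both genotypes but with a different
  expression-pattern group, or the same group with fold changes diverging
  by at least a configurable factor (default 2 on the fold scale).

The expert "function relevant to seed development" criterion is an optional
keyword filter over annotation descriptions and is never applied by
default.  Separately, genes are co-localized with previously mapped
seed-content QTLs: a gene counts as QTL-proximal when its locus intersects
the 10-Mb window (inclusive +/- 5 Mb) centered on a QTL peak.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from vitiseq.expression_matrix import ExpressionProfile

QTL_HALFWIDTH = 5_000_000
DIVERGENCE_FACTOR = 2.0

LOCUS_COLUMNS = ["gene_id", "chrom", "start", "end"]


def read_gff3_loci(path: str | Path) -> pd.DataFrame:
    """Gene loci from a GFF3 file (1-based inclusive, kept as-is).

    Uses ``gene`` features; the gene id comes from the ``ID`` attribute.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = [
        {"gene_id": f.id, "chrom": f.seqid, "start": f.start, "end": f.end}
        for f in db.features_of_type("gene")
    ]
    return pd.DataFrame(rows, columns=LOCUS_COLUMNS)


def read_bed_loci(path: str | Path) -> pd.DataFrame:
    """Gene loci from BED (0-based half-open), converted to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    out = pd.DataFrame(
        {"gene_id": df[3], "chrom": df[0], "start": df[1] + 1, "end": df[2]}
    )
    return out[LOCUS_COLUMNS]


def genotype_specific_sets(profile: ExpressionProfile) -> tuple[set[str], set[str]]:
    """Genes detected only in WT and only in MT.

    WT-only: detected in at least one WT stage and in no MT stage;
    symmetric for MT-only.  The two sets are disjoint by construction.
    """
    wt = profile.expressed_set(genotype="WT")
    mt = profile.expressed_set(genotype="MT")
    return wt - mt, mt - wt


def _max_rpm(profile: ExpressionProfile, gene: str, genotype: str) -> float:
    libs = profile.libraries.index[profile.libraries["genotype"] == genotype]
    return float(profile.rpm.loc[gene, libs].max())


def select_tier1(
    wt_only: set[str],
    mt_only: set[str],
    gene_groups: pd.DataFrame,
    profile: ExpressionProfile,
    annotation: pd.DataFrame,
    enriched_terms: set[str],
    keywords: list[str] | None = None,
    descriptions: pd.Series | None = None,
) -> pd.DataFrame:
    """Genotype-specific, non-DE candidates.

    Keeps genotype-specific genes whose triplet in their genotype is
    all-zero, which are detected (the low-expression rescue counts), and
    which belong to at least one significantly enriched term.  ``keywords``,
    matched case-insensitively against ``descriptions`` (gene id -> free
    text), optionally narrows the list further.
    """
    gene_terms = annotation.groupby("gene_id")["term_id"].agg(set)
    rows = []
    for genotype, specific in (("WT", wt_only), ("MT", mt_only)):
        sub = gene_groups[(gene_groups["genotype"] == genotype)
                          & (gene_groups["gene_id"].isin(specific))]
        for rec in sub.itertuples(index=False):
            if rec.group != "not_de":
                continue
            detected = bool(
                profile.expressed.loc[
                    rec.gene_id,
                    profile.libraries.index[profile.libraries["genotype"] == genotype],
                ].any()
            )
            if not detected:
                continue
            terms = gene_terms.get(rec.gene_id, set())
            hit_terms = terms & enriched_terms
            if not hit_terms:
                continue
            if keywords:
                text = "" if descriptions is None else str(descriptions.get(rec.gene_id, ""))
                if not any(kw.lower() in text.lower() for kw in keywords):
                    continue
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "tier": "specific_nonDE",
                    "genotype": genotype,
                    "max_rpm": _max_rpm(profile, rec.gene_id, genotype),
                    "enriched_terms": ";".join(sorted(hit_terms)),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "tier", "genotype", "max_rpm", "enriched_terms"])


def select_tier2_tier3(
    gene_groups: pd.DataFrame,
    de_wt: pd.DataFrame,
    de_mt: pd.DataFrame,
    divergence: float = DIVERGENCE_FACTOR,
) -> pd.DataFrame:
    """Background-specific DE genes (tier 2) and divergent common DE genes (tier 3).

    A gene is DE in a genotype when its triplet there has at least one
    nonzero call (relevant or not).  Tier 3 requires DE in both genotypes
    and either a different pattern group or, within the same group, a
    fold-change ratio of at least ``divergence`` (on the fold scale, i.e.
    ``2**|log2fc_WT - log2fc_MT|``) in some comparison.
    """
    groups = gene_groups.pivot_table(index="gene_id", columns="genotype", values="group",
                                     aggfunc="first")
    lfc = {}
    for genotype, de in (("WT", de_wt), ("MT", de_mt)):
        lfc[genotype] = de.pivot_table(index="gene_id", columns="comparison",
                                       values="log2fc", aggfunc="first")
    rows = []
    for gene in groups.index:
        g_wt = groups.at[gene, "WT"] if "WT" in groups.columns else "not_de"
        g_mt = groups.at[gene, "MT"] if "MT" in groups.columns else "not_de"
        de_in_wt = g_wt != "not_de"
        de_in_mt = g_mt != "not_de"
        if de_in_wt != de_in_mt:
            rows.append(
                {"gene_id": gene, "tier": "specific_DE",
                 "genotype": "WT" if de_in_wt else "MT",
                 "group_WT": g_wt, "group_MT": g_mt, "max_fold_ratio": np.nan}
            )
        elif de_in_wt and de_in_mt:
            diff = (lfc["WT"].loc[gene] - lfc["MT"].loc[gene]).abs()
            max_ratio = float(2 ** diff.max()) if diff.notna().any() else np.nan
            if g_wt != g_mt:
                rows.append(
                    {"gene_id": gene, "tier": "common_DE_divergent", "genotype": "both",
                     "group_WT": g_wt, "group_MT": g_mt, "max_fold_ratio": max_ratio}
                )
            elif np.isfinite(max_ratio) and max_ratio >= divergence:
                rows.append(
                    {"gene_id": gene, "tier": "common_DE_divergent", "genotype": "both",
                     "group_WT": g_wt, "group_MT": g_mt, "max_fold_ratio": max_ratio}
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "tier", "genotype", "group_WT", "group_MT", "max_fold_ratio"]
    )


def _window_overlap(loci: pd.DataFrame, peak_chrom: str, peak_pos: int,
                    halfwidth: int) -> pd.Series:
    lo, hi = peak_pos - halfwidth, peak_pos + halfwidth
    return (loci["chrom"] == peak_chrom) & (loci["start"] <= hi) & (loci["end"] >= lo)


def qtl_window_proportion(
    loci: pd.DataFrame,
    peaks: pd.DataFrame,
    candidate_genes,
    halfwidth: int = QTL_HALFWIDTH,
) -> pd.DataFrame:
    """Per-peak proportion of candidate genes inside the QTL window.

    A gene overlaps a window when its 1-based inclusive interval intersects
    ``[peak - halfwidth, peak + halfwidth]`` (both ends inclusive).  The
    denominator is the number of candidate genes located on the peak's
    chromosome; chromosomes without peaks contribute to no window.
    """
    candidates = set(candidate_genes)
    sub = loci[loci["gene_id"].isin(candidates)]
    known = set(loci["chrom"])
    unknown = set(peaks["chrom"]) - known
    if unknown:
        raise ValueError(
            f"peak chromosomes absent from loci: {sorted(unknown)}; known: {sorted(known)}"
        )
    rows = []
    for peak in peaks.itertuples(index=False):
        on_chrom = sub[sub["chrom"] == peak.chrom]
        inside = _window_overlap(on_chrom, peak.chrom, int(peak.position_bp), halfwidth)
        n_chrom = len(on_chrom)
        rows.append(
            {
                "trait": peak.trait,
                "chrom": peak.chrom,
                "position_bp": int(peak.position_bp),
                "n_in_window": int(inside.sum()),
                "n_on_chromosome": n_chrom,
                "proportion": float(inside.sum() / n_chrom) if n_chrom else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["trait", "chrom", "position_bp", "n_in_window", "n_on_chromosome", "proportion"],
    )


def qtl_overlap_genes(
    loci: pd.DataFrame,
    peaks: pd.DataFrame,
    genes,
    halfwidth: int = QTL_HALFWIDTH,
) -> pd.DataFrame:
    """Genes among ``genes`` whose locus intersects any QTL window, with traits."""
    sub = loci[loci["gene_id"].isin(set(genes))]
    rows = []
    for rec in sub.itertuples(index=False):
        traits = [
            str(p.trait)
            for p in peaks.itertuples(index=False)
            if p.chrom == rec.chrom
            and rec.start <= int(p.position_bp) + halfwidth
            and rec.end >= int(p.position_bp) - halfwidth
        ]
        if traits:
            rows.append({"gene_id": rec.gene_id, "tier": "qtl_overlap",
                         "qtl_traits": ";".join(sorted(set(traits)))})
    return pd.DataFrame(rows, columns=["gene_id", "tier", "qtl_traits"])
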