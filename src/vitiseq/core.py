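"""Shared containers and TSV I/O for the six-library study design.

The study design is fixed: two genotypes (``WT`` seeded wild-type, ``MT``
seedless mutant) sampled at three berry developmental stages (``EL15``,
``EL27``, ``EL38``), one sequencing library per genotype x stage, no
replicates.  Counts are uniquely mapped reads per annotated gene model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

GENOTYPES = ("WT", "MT")
STAGES = ("EL15", "EL27", "EL38")

#: Pairwise stage comparisons, oriented later-vs-earlier so that a positive
#: log2 fold change means up-regulation along development.
COMPARISONS = (
    ("EL27vsEL15", "EL15", "EL27"),
    ("EL38vsEL27", "EL27", "EL38"),
    ("EL38vsEL15", "EL15", "EL38"),
)
COMPARISON_LABELS = tuple(c[0] for c in COMPARISONS)


class InvalidLibraryError(ValueError):
    """A library total is missing or non-positive."""


def library_id(genotype: str, stage: str) -> str:
    return f"{genotype}_{stage}"


@dataclass
class CountMatrix:
    """Raw uniquely mapped read counts per gene per library.

    Parameters
    ----------
    counts
        Integer DataFrame, genes as rows (index = unique gene ids),
        libraries as columns.
    libraries
        Metadata DataFrame indexed by library id with columns
        ``genotype`` (WT|MT), ``stage`` (EL15|EL27|EL38) and
        ``total_reads`` (the library's total uniquely mapped reads; it may
        exceed the column sum because reads can map outside the gene set,
        but it must be positive).
    high_confidence
        Optional DataFrame of the same shape as ``counts`` holding the
        subset of reads passing the high-stringency mapping filter
        (identity > 98% over 100 bp), used by the detection rule's
        low-expression rescue branch.  When absent the raw counts stand in.
    """

    counts: pd.DataFrame
    libraries: pd.DataFrame
    high_confidence: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.libraries.index)
        if missing:
            raise ValueError(f"libraries missing metadata: {sorted(missing)}")
        totals = self.libraries.loc[list(self.counts.columns), "total_reads"]
        if (totals <= 0).any():
            bad = totals[totals <= 0].index.tolist()
            raise InvalidLibraryError(f"non-positive total_reads for {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def libraries_for(self, genotype: str | None = None, stage: str | None = None) -> list[str]:
        """Library ids matching a genotype and/or stage selection."""
        meta = self.libraries.loc[list(self.counts.columns)]
        mask = pd.Series(True, index=meta.index)
        if genotype is not None:
            mask &= meta["genotype"] == genotype
        if stage is not None:
            mask &= meta["stage"] == stage
        return meta.index[mask].tolist()

    def subset(self, library_ids: list[str]) -> "CountMatrix":
        hc = None if self.high_confidence is None else self.high_confidence[library_ids]
        return CountMatrix(self.counts[library_ids], self.libraries.loc[library_ids], hc)


# ---------------------------------------------------------------------------
# TSV dialect: tab-separated, '#'-prefixed comment lines ignored, first
# column gene_id.  Writers prepend provenance comments (seed, config hash).


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_count_matrix(
    counts_path: str | Path,
    metadata_path: str | Path,
    high_confidence_path: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix TSV plus its library-metadata TSV.

    The metadata file needs columns ``library_id``, ``genotype``, ``stage``,
    ``total_reads``.
    """
    counts = _read_tsv(counts_path, index_col=0)
    meta = _read_tsv(metadata_path).set_index("library_id")
    hc = None
    if high_confidence_path is not None:
        hc = _read_tsv(high_confidence_path, index_col=0)
    return CountMatrix(counts, meta, hc)


def write_tsv(df: pd.DataFrame, path: str | Path, header_comments: list[str] | None = None,
              index: bool = True, index_label: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a two-column gene -> term annotation TSV (gene_id, term_id)."""
    df = _read_tsv(path)
    cols = list(df.columns[:2])
    return df[cols].rename(columns=dict(zip(cols, ["gene_id", "term_id"])))


def read_gaf(path: str | Path) -> pd.DataFrame:
    """Read a GAF 2.x association file (object id from column 2, GO id from column 5)."""
    df = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str)
    return pd.DataFrame({"gene_id": df[1], "term_id": df[4]})


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a QTL peak table TSV with columns trait, chrom, position_bp."""
    df = _read_tsv(path)
    need = {"trait", "chrom", "position_bp"}
    if not need.issubset(df.columns):
        raise ValueError(f"peak table must have columns {sorted(need)}")
    return df
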