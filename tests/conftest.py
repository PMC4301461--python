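import numpy as np
import pandas as pd
import pytest

from vitiseq.core import CountMatrix, GENOTYPES, STAGES, library_id
from vitiseq.differential import de_genotype
from vitiseq.pattern_groups import classify_genes
from vitiseq.synthetic_data import SimConfig, generate_counts


def make_count_matrix(counts: dict[str, list[int]], genes: list[str] | None = None,
                      totals: dict[str, int] | None = None,
                      high_confidence: dict[str, list[int]] | None = None) -> CountMatrix:
    """Hand-built count matrix over the standard six-library layout.

    ``counts`` maps library ids (subset of the 6 standard ones) to count
    columns; totals default to 10^6 per library.
    """
    lib_ids = list(counts)
    n = len(next(iter(counts.values())))
    genes = genes or [f"g{i}" for i in range(n)]
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    meta_rows = []
    for g in GENOTYPES:
        for s in STAGES:
            lid = library_id(g, s)
            if lid in lib_ids:
                meta_rows.append(
                    {"library_id": lid, "genotype": g, "stage": s,
                     "total_reads": (totals or {}).get(lid, 1_000_000)}
                )
    meta = pd.DataFrame(meta_rows).set_index("library_id")
    hc = None
    if high_confidence is not None:
        hc = pd.DataFrame(high_confidence, index=df.index)
    return CountMatrix(df, meta, hc)


@pytest.fixture(scope="session")
def planted_dataset():
    """The default study conditions: 5000 genes, 8 planted pattern blocks at
    fold 8, alpha = 0.05, one-million-read libraries (seed 1)."""
    config = SimConfig(n_genes=5000, seed=1)
    cm, truth = generate_counts(config)
    de_wt = de_genotype(cm, "WT")
    de_mt = de_genotype(cm, "MT")
    patterns = classify_genes(de_wt, de_mt)
    return {"config": config, "cm": cm, "truth": truth,
            "de_wt": de_wt, "de_mt": de_mt, "patterns": patterns}


@pytest.fixture(scope="session")
def null_dataset():
    """No planted signal, dispersion 0.1: every nonzero call is a false positive."""
    config = SimConfig(
        n_genes=3000, seed=2, dispersion=0.1, planted_patterns=(),
        frac_genotype_specific=0.0, n_low_expression=0,
    )
    cm, truth = generate_counts(config)
    de_wt = de_genotype(cm, "WT")
    de_mt = de_genotype(cm, "MT")
    return {"config": config, "cm": cm, "truth": truth, "de_wt": de_wt, "de_mt": de_mt}
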