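"""RPM normalization, the expression detection rule, and expressed-gene set algebra.

A gene's expression level in a library is reported as RPM (reads per
million): the uniquely mapped read count scaled by the library's total
uniquely mapped reads over 10^6.  A gene is *detected* (expressed) in a
library when its RPM reaches 0.5, or — for genes just under that limit —
when at least five high-stringency uniquely mapped reads support it.

Set algebra over the per-stage detected-gene sets produces the Venn region
cardinalities used to compare expression signatures across stages and
between the two genotypes, plus the count of constitutively non-expressed
genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from vitiseq.core import CountMatrix, InvalidLibraryError, STAGES

RPM_DETECTION_LIMIT = 0.5
MIN_RESCUE_READS = 5


def compute_rpm(count, library_total):
    """Reads-per-million: ``count * 1e6 / library_total``.

    Accepts scalars or arrays; ``library_total`` must be positive.
    """
    total = np.asarray(library_total, dtype=float)
    if (total <= 0).any():
        raise InvalidLibraryError("library total must be positive")
    out = np.asarray(count, dtype=float) * 1e6 / total
    if np.ndim(count) == 0 and np.ndim(library_total) == 0:
        return float(out)
    return out


def is_expressed(rpm, high_confidence_reads=0):
    """Detection rule: RPM >= 0.5, or >= 5 high-stringency reads below that.

    ``high_confidence_reads`` is the count of uniquely mapped reads with
    identity > 98% over 100 bp; when that column is unavailable callers pass
    the raw count (documented dialect switch) or omit it (treated as 0).
    """
    rpm_arr = np.asarray(rpm, dtype=float)
    hc = np.asarray(high_confidence_reads)
    out = (rpm_arr >= RPM_DETECTION_LIMIT) | (hc >= MIN_RESCUE_READS)
    if np.ndim(rpm) == 0 and np.ndim(high_confidence_reads) == 0:
        return bool(out)
    return out


@dataclass
class ExpressionProfile:
    """Per-gene per-library RPM values and detection flags."""

    rpm: pd.DataFrame
    expressed: pd.DataFrame
    libraries: pd.DataFrame

    @classmethod
    def from_counts(cls, cm: CountMatrix) -> "ExpressionProfile":
        totals = cm.libraries.loc[list(cm.counts.columns), "total_reads"].to_numpy(float)
        rpm = cm.counts.astype(float) * 1e6 / totals
        hc = cm.high_confidence if cm.high_confidence is not None else cm.counts
        expressed = (rpm >= RPM_DETECTION_LIMIT) | (hc >= MIN_RESCUE_READS)
        return cls(rpm=rpm, expressed=expressed, libraries=cm.libraries.loc[list(cm.counts.columns)])

    def expressed_set(self, genotype: str | None = None, stage: str | None = None) -> set[str]:
        """Genes detected in >= 1 library of the selection."""
        mask = pd.Series(True, index=self.libraries.index)
        if genotype is not None:
            mask &= self.libraries["genotype"] == genotype
        if stage is not None:
            mask &= self.libraries["stage"] == stage
        libs = self.libraries.index[mask].tolist()
        if not libs:
            raise ValueError(f"no libraries match genotype={genotype}, stage={stage}")
        any_expressed = self.expressed[libs].any(axis=1)
        return set(self.expressed.index[any_expressed])


def venn_counts(sets: dict[str, set]) -> dict[str, int]:
    """Cardinality of every region of the Venn decomposition of named sets.

    Region labels are membership bitstrings in the order of ``sets`` keys,
    e.g. for sets A,B,C the label ``"101"`` is (in A) & (not in B) & (in C).
    The all-zero region is omitted (its complement is unbounded).
    """
    if not sets:
        raise ValueError("empty scope: at least one set required")
    names = list(sets)
    regions: dict[str, int] = {}
    universe = set().union(*sets.values())
    for bits in product((0, 1), repeat=len(names)):
        if not any(bits):
            continue
        region = set(universe)
        for name, bit in zip(names, bits):
            region &= sets[name] if bit else (universe - sets[name])
        regions["".join(map(str, bits))] = len(region)
    return regions


def expression_sets(profile: ExpressionProfile, genotype: str | None = None) -> dict:
    """Expressed-gene set report for one genotype across stages, or WT vs MT.

    With ``genotype`` given, returns the three per-stage detected sets of
    that genotype and their 3-set Venn regions; with ``genotype=None``,
    returns the two whole-genotype sets and their 2-set Venn regions.
    Always includes ``never_expressed``: genes detected in no library at all.
    """
    if genotype is not None:
        sets = {stage: profile.expressed_set(genotype=genotype, stage=stage) for stage in STAGES}
    else:
        sets = {g: profile.expressed_set(genotype=g) for g in ("WT", "MT")}
    never = int((~profile.expressed.any(axis=1)).sum())
    return {
        "sets": {k: sorted(v) for k, v in sets.items()},
        "cardinalities": {k: len(v) for k, v in sets.items()},
        "venn": venn_counts(sets),
        "union": len(set().union(*sets.values())),
        "never_expressed": never,
    }
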