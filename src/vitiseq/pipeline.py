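"""End-to-end orchestration of the stage-course analysis.

Runs, from a single configuration (real input files or a synthetic-data
configuration): expression detection and set algebra, per-genotype
differential expression over the three stage comparisons, sign-triplet
pattern classification, functional enrichment of the DE sets, candidate
selection, and QTL-window co-localization.  Emits per-module TSVs plus a
single JSON summary report; every output carries the configuration hash
and seed, so identical configurations reproduce byte-identical results.

The analysis contrasts stages *within* each genotype and never tests WT
against MT directly at a stage: with a single library per condition and
possibly asynchronous sampling of the two clones, between-stage contrasts
within a clone are the comparisons the design supports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from vitiseq import candidates as cand
from vitiseq import differential as de_mod
from vitiseq import enrichment as enr
from vitiseq.core import (
    COMPARISON_LABELS,
    CountMatrix,
    read_annotation,
    read_count_matrix,
    read_peaks,
    write_tsv,
)
from vitiseq.expression_matrix import ExpressionProfile, expression_sets
from vitiseq.pattern_groups import classify_genes
from vitiseq.synthetic_data import SimConfig, simulate_dataset

logger = logging.getLogger("vitiseq")


class PipelineError(RuntimeError):
    """A module failed; the message names the stage."""


@dataclass
class RunConfig:
    """One configuration for a full pipeline run.

    Exactly one of ``sim`` (synthetic mode) or ``counts_path`` must be set.
    Thresholds default to the study values: DE at FDR <= 0.05 and
    |log2FC| > 1; detection at RPM 0.5 with a 5-read rescue; enrichment at
    FDR < 0.05 and p < 0.01; QTL windows of +/- 5 Mb; a tier-3 fold
    divergence factor of 2.
    """

    out_dir: str = "vitiseq_out"
    sim: SimConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    loci_path: str | None = None
    peaks_path: str | None = None
    fdr: float = 0.05
    lfc: float = 1.0
    rpm_limit: float = 0.5
    min_reads: int = 5
    enrich_fdr: float = 0.05
    enrich_p: float = 0.01
    qtl_halfwidth: int = 5_000_000
    divergence: float = 2.0
    sharing_mode: str = "fit-only"
    seed: int = 0

    def __post_init__(self):
        for name in ("fdr", "lfc", "rpm_limit", "enrich_fdr", "enrich_p",
                     "divergence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if (self.sim is None) == (self.counts_path is None):
            raise ValueError("set exactly one of sim (synthetic mode) or counts_path")

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")  # where results land does not change what they are
        payload = repr(sorted(fields.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def percentages(part: int, whole: int, decimals: int = 1) -> float:
    """``100 * part / whole`` rounded half-up to ``decimals`` places."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if part < 0 or part > whole:
        raise ValueError("part must lie in [0, whole]")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(part) * 100 / Decimal(whole)).quantize(q, rounding=ROUND_HALF_UP)
    return float(value)


def round_half_up(value: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _de_gene_set(de: pd.DataFrame) -> set[str]:
    """Genes with at least one nonzero call."""
    return set(de.loc[de["call"] != 0, "gene_id"])


def de_overlap_summary(wt_set: set, mt_set: set) -> dict:
    """Set-overlap arithmetic between the per-genotype DE gene sets.

    Returns totals, the shared and genotype-specific counts, and the
    percentages of each over the grand total (rounded half-up to whole
    percent).  The identities shared + specific = per-genotype total and
    WT + MT - shared = grand total hold by construction.
    """
    shared = wt_set & mt_set
    grand = wt_set | mt_set
    out = {
        "wt_total": len(wt_set),
        "mt_total": len(mt_set),
        "shared": len(shared),
        "wt_specific": len(wt_set - mt_set),
        "mt_specific": len(mt_set - wt_set),
        "grand_total": len(grand),
    }
    if out["grand_total"]:
        out["pct_shared"] = percentages(out["shared"], out["grand_total"], 0)
        out["pct_wt_specific"] = percentages(out["wt_specific"], out["grand_total"], 0)
        out["pct_mt_specific"] = percentages(out["mt_specific"], out["grand_total"], 0)
    return out


def _updown_table(de: pd.DataFrame, genotype: str) -> list[dict]:
    rows = []
    for label in COMPARISON_LABELS:
        sub = de[de["comparison"] == label]
        up = int((sub["call"] == 1).sum())
        down = int((sub["call"] == -1).sum())
        total = up + down
        rows.append(
            {
                "genotype": genotype,
                "comparison": label,
                "up": up,
                "down": down,
                "total": total,
                "pct_up": percentages(up, total, 1) if total else None,
                "pct_down": percentages(down, total, 1) if total else None,
            }
        )
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole analysis; returns the summary report (also written).

    Raises :class:`PipelineError` with the failing stage's name on error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_comments = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]
    stage = "input"
    try:
        if config.sim is not None:
            data = simulate_dataset(config.sim, out / "synthetic")
            cm: CountMatrix = data["counts"]
            annotation = data["annotation"]
            loci, peaks = data["loci"], data["peaks"]
        else:
            cm = read_count_matrix(config.counts_path, config.metadata_path)
            annotation = (read_annotation(config.annotation_path)
                          if config.annotation_path else None)
            loci = (cand.read_gff3_loci(config.loci_path)
                    if config.loci_path and str(config.loci_path).endswith((".gff", ".gff3"))
                    else cand.read_bed_loci(config.loci_path) if config.loci_path else None)
            peaks = read_peaks(config.peaks_path) if config.peaks_path else None
        logger.info("loaded %d genes x %d libraries", *cm.counts.shape)

        stage = "expression_matrix"
        profile = ExpressionProfile.from_counts(cm)
        sets_report = {
            "WT": expression_sets(profile, "WT"),
            "MT": expression_sets(profile, "MT"),
            "genotypes": expression_sets(profile, None),
        }
        for key, rep in sets_report.items():
            venn = pd.DataFrame(
                sorted(rep["venn"].items()), columns=["region_label", "cardinality"]
            )
            write_tsv(venn, out / f"venn_{key}.tsv", meta_comments, index=False)

        stage = "differential"
        de_wt = de_mod.de_genotype(cm, "WT", fdr=config.fdr, lfc=config.lfc,
                                   sharing_mode=config.sharing_mode)
        de_mt = de_mod.de_genotype(cm, "MT", fdr=config.fdr, lfc=config.lfc,
                                   sharing_mode=config.sharing_mode)
        write_tsv(de_wt, out / "de_WT.tsv", meta_comments, index=False)
        write_tsv(de_mt, out / "de_MT.tsv", meta_comments, index=False)

        stage = "pattern_groups"
        patterns = classify_genes(de_wt, de_mt)
        write_tsv(patterns["genes"], out / "gene_patterns.tsv", meta_comments, index=False)
        write_tsv(patterns["group_counts"], out / "group_counts.tsv", meta_comments, index=False)

        stage = "de_overlap"
        wt_set, mt_set = _de_gene_set(de_wt), _de_gene_set(de_mt)
        grand = wt_set | mt_set
        overlap = de_overlap_summary(wt_set, mt_set)

        updown = _updown_table(de_wt, "WT") + _updown_table(de_mt, "MT")
        write_tsv(pd.DataFrame(updown), out / "updown.tsv", meta_comments, index=False)

        stage = "enrichment"
        enrichment_report = {}
        sig_terms: set[str] = set()
        if annotation is not None:
            for genotype, gene_set in (("WT", wt_set), ("MT", mt_set)):
                study = gene_set & set(annotation["gene_id"])
                res = enr.enrich(study, annotation, fdr_threshold=config.enrich_fdr,
                                 p_threshold=config.enrich_p) if study else pd.DataFrame(
                    columns=["term_id", "significant"])
                write_tsv(res, out / f"enrichment_{genotype}.tsv", meta_comments, index=False)
                sig = res.loc[res.get("significant", pd.Series(dtype=bool)).fillna(False),
                              "term_id"] if len(res) else []
                enrichment_report[genotype] = {
                    "tested_terms": int(len(res)),
                    "significant_terms": sorted(sig),
                }
                sig_terms |= set(sig)

        stage = "candidates"
        wt_only, mt_only = cand.genotype_specific_sets(profile)
        tier1 = tier23 = qtl_hits = None
        candidate_report = {
            "wt_only_expressed": len(wt_only),
            "mt_only_expressed": len(mt_only),
        }
        if annotation is not None:
            tier1 = cand.select_tier1(wt_only, mt_only, patterns["genes"], profile,
                                      annotation, sig_terms)
            write_tsv(tier1, out / "candidates_tier1.tsv", meta_comments, index=False)
            candidate_report["tier1"] = int(len(tier1))
        tier23 = cand.select_tier2_tier3(patterns["genes"], de_wt, de_mt,
                                         divergence=config.divergence)
        write_tsv(tier23, out / "candidates_tier2_tier3.tsv", meta_comments, index=False)
        candidate_report["tier2"] = int((tier23["tier"] == "specific_DE").sum())
        candidate_report["tier3"] = int((tier23["tier"] == "common_DE_divergent").sum())

        qtl_report = None
        if loci is not None and peaks is not None and len(peaks):
            clone_specific = wt_only | mt_only
            proportions = cand.qtl_window_proportion(
                loci, peaks, clone_specific, halfwidth=config.qtl_halfwidth)
            write_tsv(proportions, out / "qtl_proportions.tsv", meta_comments, index=False)
            qtl_hits = cand.qtl_overlap_genes(loci, peaks, grand,
                                              halfwidth=config.qtl_halfwidth)
            write_tsv(qtl_hits, out / "candidates_qtl.tsv", meta_comments, index=False)
            qtl_report = {
                "per_peak": proportions.to_dict(orient="records"),
                "de_genes_in_windows": int(len(qtl_hits)),
            }

        stage = "report"
        report = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __import__("vitiseq").__version__,
            "thresholds": {
                "fdr": config.fdr, "lfc": config.lfc, "rpm_limit": config.rpm_limit,
                "min_reads": config.min_reads, "enrich_fdr": config.enrich_fdr,
                "enrich_p": config.enrich_p, "qtl_halfwidth": config.qtl_halfwidth,
                "divergence": config.divergence,
            },
            "n_genes": int(cm.counts.shape[0]),
            "expressed": {k: v["cardinalities"] for k, v in sets_report.items()},
            "venn": {k: v["venn"] for k, v in sets_report.items()},
            "never_expressed": sets_report["WT"]["never_expressed"],
            "de_overlap": overlap,
            "updown": updown,
            "group_counts": patterns["group_counts"].to_dict(orient="records"),
            "enrichment": enrichment_report,
            "candidates": candidate_report,
            "qtl": qtl_report,
        }
        # internal consistency identities
        assert overlap["shared"] + overlap["wt_specific"] == overlap["wt_total"]
        assert overlap["shared"] + overlap["mt_specific"] == overlap["mt_total"]
        assert (overlap["wt_total"] + overlap["mt_total"] - overlap["shared"]
                == overlap["grand_total"])
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"pipeline failed in stage '{stage}': {exc}") from exc
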