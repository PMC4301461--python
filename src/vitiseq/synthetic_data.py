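"""Synthetic six-library count data with known ground truth.

The generator emulates the statistical structure the analysis assumes: two
genotypes (WT, MT) x three developmental stages (EL15, EL27, EL38), one
library each, negative-binomial counts (variance = mu + alpha*mu^2), a
majority of genes flat across stages, planted differentially expressed
genes realizing chosen sign-triplet patterns at chosen fold changes,
genotype-specific genes (hard-zero mean in the other genotype), a
low-expression class straddling the RPM 0.5 detection limit, planted
enriched annotation terms, and gene coordinates placed inside or outside
10-Mb QTL windows.  Every generated object is deterministic under the
configured seed, and a per-gene truth table records what was planted.

A sign triplet is *exactly realizable* when per-stage mean multipliers
exist that make each nonzero call a fold change of at least the configured
magnitude and each zero call an exactly equal mean.  Twelve of the 18
relevant patterns are exactly realizable; the other six (e.g. (1,0,0),
where the overall change equals a significant step yet must test
non-significant) exist only through threshold effects and are rejected by
the generator with a configuration error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vitiseq.core import (
    CountMatrix,
    GENOTYPES,
    STAGES,
    library_id,
    write_tsv,
)
from vitiseq.pattern_groups import Triplet, is_relevant

GENE_LENGTH = 1_500


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class PlantedPattern:
    """A block of genes planted with one sign-triplet archetype.

    ``fold`` is the fold-change magnitude applied per significant step
    (must be > 1); ``genotypes`` selects where the pattern is active — in
    the other genotype the genes stay flat.
    """

    triplet: Triplet
    n_genes: int
    fold: float = 8.0
    genotypes: tuple[str, ...] = GENOTYPES

    def __post_init__(self):
        if self.fold <= 1:
            raise ConfigurationError(f"fold must be > 1, got {self.fold}")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if not is_relevant(self.triplet):
            raise ConfigurationError(f"triplet {self.triplet} is not a relevant pattern")
        solve_multipliers(self.triplet, self.fold)  # raises if not realizable


@dataclass(frozen=True)
class EnrichedTermSpec:
    """A term over-assigned to a target gene subset.

    ``strength`` multiplies the base annotation rate inside the target
    subset (capped at probability 1); strength 1 means no enrichment.
    """

    term_id: str
    n_target: int
    strength: float


def _default_patterns() -> tuple[PlantedPattern, ...]:
    archetypes = [
        (1, 1, 1), (1, 0, 1), (0, 1, 1), (1, -1, 0),
        (-1, -1, -1), (-1, 0, -1), (0, -1, -1), (-1, 1, 0),
    ]
    return tuple(PlantedPattern(t, 50, 8.0) for t in archetypes)


def _default_enriched_terms() -> tuple[EnrichedTermSpec, ...]:
    return (
        EnrichedTermSpec("TERM_0001", 30, 18.0),
        EnrichedTermSpec("TERM_0002", 30, 20.0),
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the study design: six libraries of a million uniquely
    mapped reads each, gene baselines log-uniform between 1 and ~300 RPM,
    mild overdispersion (alpha = 0.05), eight planted pattern blocks of 50
    genes at fold 8 drawn from moderately-to-highly expressed genes, 5% of
    genes expressed in only one genotype, and two planted enriched terms.
    """

    n_genes: int = 5_000
    library_sizes: tuple[int, ...] = (1_000_000,) * 6
    baseline_mean_log_range: tuple[float, float] = (0.0, 2.5)  # log10 RPM
    planted_baseline_log_range: tuple[float, float] = (2.0, 2.5)
    dispersion: float = 0.05
    planted_patterns: tuple[PlantedPattern, ...] = field(default_factory=_default_patterns)
    frac_genotype_specific: float = 0.05
    n_low_expression: int = 50
    low_expression_rpm_range: tuple[float, float] = (0.3, 0.6)
    n_terms: int = 200
    term_base_rate: float = 0.05
    enriched_terms: tuple[EnrichedTermSpec, ...] = field(default_factory=_default_enriched_terms)
    n_qtl: int = 2
    n_qtl_proximal: int = 100
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 30_000_000, "chr2": 30_000_000})
    qtl_halfwidth: int = 5_000_000
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if len(self.library_sizes) != 6 or any(s <= 0 for s in self.library_sizes):
            raise ConfigurationError("need 6 positive library sizes (2 genotypes x 3 stages)")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if not 0 <= self.frac_genotype_specific < 1:
            raise ConfigurationError("frac_genotype_specific must be in [0, 1)")
        if self.n_terms < 1:
            raise ConfigurationError("n_terms must be >= 1")
        n_planted = sum(p.n_genes for p in self.planted_patterns)
        n_specific = int(round(self.frac_genotype_specific * self.n_genes))
        if n_planted + n_specific + self.n_low_expression > self.n_genes:
            raise ConfigurationError(
                f"planted genes ({n_planted} pattern + {n_specific} specific + "
                f"{self.n_low_expression} low-expression) exceed n_genes={self.n_genes}"
            )

    @property
    def library_ids(self) -> list[str]:
        return [library_id(g, s) for g in GENOTYPES for s in STAGES]

    def library_metadata(self) -> pd.DataFrame:
        rows = []
        for i, (g, s) in enumerate(itertools.product(GENOTYPES, STAGES)):
            rows.append({"library_id": library_id(g, s), "genotype": g, "stage": s,
                         "total_reads": int(self.library_sizes[i])})
        return pd.DataFrame(rows).set_index("library_id")


def solve_multipliers(triplet: Triplet, fold: float) -> tuple[float, float, float]:
    """Per-stage mean multipliers (m15, m27, m38) realizing a sign triplet.

    Searches log2 multipliers over multiples of L = log2(fold), requiring
    each nonzero call to reach magnitude >= L in its comparison and each
    zero call to be an exact equality.  The smallest-magnitude solution is
    normalized so its minimum is 1: the planted baseline is a gene's
    *lowest* stage mean and fold steps rise above it, keeping every
    significant comparison of a planted gene in the well-powered count
    regime.  Raises for the six threshold-only patterns.
    """
    a, b, c = triplet
    L = np.log2(fold)
    grid = [-2 * L, -L, 0.0, L, 2 * L]

    def ok(call: int, delta: float) -> bool:
        if call == 0:
            return abs(delta) < 1e-12
        return delta >= L - 1e-12 if call > 0 else delta <= -L + 1e-12

    best = None
    for x in grid:  # log2 m27
        for y in grid:  # log2 m38
            if ok(a, x) and ok(b, y - x) and ok(c, y):
                cost = abs(x) + abs(y)
                if best is None or cost < best[0]:
                    best = (cost, x, y)
    if best is None:
        raise ConfigurationError(
            f"triplet {triplet} is not exactly realizable by stage-mean fold "
            "changes (it arises only through threshold effects)"
        )
    m = (1.0, float(2 ** best[1]), float(2 ** best[2]))
    low = min(m)
    return tuple(v / low for v in m)


def _assign_roles(config: SimConfig) -> pd.DataFrame:
    """Gene ids plus their planted role, in a fixed deterministic layout."""
    gene_ids = [f"gene_{i:05d}" for i in range(config.n_genes)]
    roles = ["flat"] * config.n_genes
    pattern_idx = [-1] * config.n_genes
    pos = 0
    for pi, pat in enumerate(config.planted_patterns):
        for _ in range(pat.n_genes):
            roles[pos] = "pattern"
            pattern_idx[pos] = pi
            pos += 1
    for _ in range(config.n_low_expression):
        roles[pos] = "low_expression"
        pos += 1
    n_specific = int(round(config.frac_genotype_specific * config.n_genes))
    n_wt_only = n_specific // 2
    for i in range(n_specific):
        roles[pos] = "wt_only" if i < n_wt_only else "mt_only"
        pos += 1
    return pd.DataFrame({"gene_id": gene_ids, "role": roles, "pattern_idx": pattern_idx})


def generate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the 6-library count matrix and its ground-truth table.

    Each count is NB(mean = baseline_rpm x library-size scale x planted
    stage multiplier, dispersion alpha); flat genes keep one mean across
    stages, genotype-specific genes have mean zero in the other genotype.
    """
    rng = np.random.default_rng([config.seed, 0])
    layout = _assign_roles(config)
    n = config.n_genes

    lo, hi = config.baseline_mean_log_range
    baseline = 10 ** rng.uniform(lo, hi, size=n)
    plo, phi = config.planted_baseline_log_range
    is_pattern = (layout["role"] == "pattern").to_numpy()
    baseline[is_pattern] = 10 ** rng.uniform(plo, phi, size=int(is_pattern.sum()))
    low = (layout["role"] == "low_expression").to_numpy()
    baseline[low] = rng.uniform(*config.low_expression_rpm_range, size=int(low.sum()))
    # genotype-specific genes stay comfortably above the detection limit
    spec = layout["role"].isin(["wt_only", "mt_only"]).to_numpy()
    baseline[spec] = 10 ** rng.uniform(max(lo, np.log10(2.0)), hi, size=int(spec.sum()))

    # stage multipliers per genotype
    mult = {g: np.ones((n, 3)) for g in GENOTYPES}
    triplets = {g: [(0, 0, 0)] * n for g in GENOTYPES}
    for i, (role, pi) in enumerate(zip(layout["role"], layout["pattern_idx"])):
        if role == "pattern":
            pat = config.planted_patterns[pi]
            m = solve_multipliers(pat.triplet, pat.fold)
            for g in pat.genotypes:
                mult[g][i, :] = m
                triplets[g][i] = pat.triplet
        elif role == "wt_only":
            mult["MT"][i, :] = 0.0
        elif role == "mt_only":
            mult["WT"][i, :] = 0.0

    counts = {}
    meta = config.library_metadata()
    for lib in config.library_ids:
        g = meta.loc[lib, "genotype"]
        s_idx = STAGES.index(meta.loc[lib, "stage"])
        depth_scale = meta.loc[lib, "total_reads"] / 1e6
        mu = baseline * mult[g][:, s_idx] * depth_scale
        if config.dispersion > 0:
            r = 1.0 / config.dispersion
            p = r / (r + mu)
            counts[lib] = rng.negative_binomial(r, p)
        else:
            counts[lib] = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=layout["gene_id"])
    counts_df.index.name = "gene_id"
    cm = CountMatrix(counts_df, meta)

    folds = [
        config.planted_patterns[pi].fold if pi >= 0 else np.nan
        for pi in layout["pattern_idx"]
    ]
    truth = pd.DataFrame(
        {
            "gene_id": layout["gene_id"],
            "role": layout["role"],
            "triplet_WT": [",".join(map(str, t)) for t in triplets["WT"]],
            "triplet_MT": [",".join(map(str, t)) for t in triplets["MT"]],
            "fold": folds,
            "baseline_rpm": baseline,
            "expressed_WT": (mult["WT"].max(axis=1) > 0),
            "expressed_MT": (mult["MT"].max(axis=1) > 0),
            "member_terms": "",
            "chrom": "",
            "start": -1,
            "end": -1,
            "qtl_proximal": False,
        }
    ).set_index("gene_id")
    return cm, truth


def generate_annotation(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Gene -> term annotation with planted enriched terms.

    Background gene-term pairs occur at ``term_base_rate``; each enriched
    term's target subset (sampled from planted-pattern genes when
    available) carries the term with probability
    ``min(1, strength x base_rate)``.  Updates ``truth.member_terms`` with
    the enriched terms targeted at each gene and returns the long-format
    annotation table.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = truth.index.to_numpy()
    terms = [f"TERM_{i + 1:04d}" for i in range(config.n_terms)]
    member = rng.random((len(genes), config.n_terms)) < config.term_base_rate

    term_pos = {t: i for i, t in enumerate(terms)}
    pattern_genes = truth.index[truth["role"] == "pattern"].to_numpy()
    pool = pattern_genes if len(pattern_genes) else genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    targeted: dict[str, list[str]] = {}
    for spec in config.enriched_terms:
        if spec.n_target > len(pool):
            raise ConfigurationError(
                f"enriched term {spec.term_id}: n_target={spec.n_target} exceeds "
                f"the {len(pool)}-gene target pool"
            )
        target = rng.choice(pool, size=spec.n_target, replace=False)
        p_in = min(1.0, spec.strength * config.term_base_rate)
        col = term_pos.get(spec.term_id)
        if col is None:
            raise ConfigurationError(f"enriched term {spec.term_id} not among the {config.n_terms} terms")
        rows = np.array([gene_pos[g] for g in target])
        member[rows, col] = rng.random(len(rows)) < p_in
        targeted[spec.term_id] = list(target)

    for term, tgt in targeted.items():
        for g in tgt:
            cur = truth.at[g, "member_terms"]
            truth.at[g, "member_terms"] = f"{cur};{term}" if cur else term

    gi, ti = np.nonzero(member)
    return pd.DataFrame({"gene_id": genes[gi], "term_id": np.array(terms)[ti]})


def generate_loci_and_qtls(
    config: SimConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene loci and QTL peaks with planted window membership.

    QTL-proximal genes are placed entirely inside the +/- halfwidth window
    of some peak; all other genes are placed outside every window.  Updates
    ``truth`` coordinates and ``qtl_proximal`` flags; returns
    (loci, peaks) tables.
    """
    rng = np.random.default_rng([config.seed, 2])
    hw = config.qtl_halfwidth
    chroms = list(config.chrom_lengths)
    for name, length in config.chrom_lengths.items():
        if length <= 2 * hw:
            raise ConfigurationError(
                f"chromosome {name} (length {length}) must exceed the "
                f"{2 * hw} bp QTL window"
            )

    peaks_rows = []
    per_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for qi in range(config.n_qtl):
        chrom = chroms[qi % len(chroms)]
        per_chrom[chrom].append(qi)
    for chrom, qids in per_chrom.items():
        length = config.chrom_lengths[chrom]
        for j, qi in enumerate(qids):
            pos = int((j + 1) * length / (len(qids) + 1))
            peaks_rows.append({"trait": f"seed_trait_{qi + 1}", "chrom": chrom,
                               "position_bp": pos})
    peaks = pd.DataFrame(peaks_rows, columns=["trait", "chrom", "position_bp"])

    n_prox = min(config.n_qtl_proximal, len(truth)) if config.n_qtl else 0
    prox_genes = rng.choice(truth.index.to_numpy(), size=n_prox, replace=False) if n_prox else []
    prox_set = set(prox_genes)

    # allowed distal segments per chromosome: [1, length - gene_len] minus
    # the windows, expanded by gene length so intervals cannot touch them
    segments: list[tuple[str, int, int]] = []
    for chrom in chroms:
        length = config.chrom_lengths[chrom]
        blocked = sorted(
            (max(1, int(p.position_bp) - hw - GENE_LENGTH), int(p.position_bp) + hw)
            for p in peaks.itertuples(index=False) if p.chrom == chrom
        )
        cursor = 1
        for lo, hi in blocked:
            if lo - 1 - GENE_LENGTH > cursor:
                segments.append((chrom, cursor, lo - 1 - GENE_LENGTH))
            cursor = max(cursor, hi + 1)
        if length - GENE_LENGTH > cursor:
            segments.append((chrom, cursor, length - GENE_LENGTH))
    if not segments and len(prox_set) < len(truth):
        raise ConfigurationError("chromosomes too short to place any gene outside the QTL windows")
    seg_weights = np.array([hi - lo + 1 for _, lo, hi in segments], dtype=float)
    seg_weights /= seg_weights.sum()

    rows = []
    for gene in truth.index:
        if gene in prox_set:
            peak = peaks.iloc[int(rng.integers(len(peaks)))]
            lo = max(1, int(peak.position_bp) - hw)
            hi = int(peak.position_bp) + hw - GENE_LENGTH
            start = int(rng.integers(lo, hi + 1))
            chrom = peak.chrom
        else:
            si = int(rng.choice(len(segments), p=seg_weights))
            chrom, lo, hi = segments[si]
            start = int(rng.integers(lo, hi + 1))
        rows.append({"gene_id": gene, "chrom": chrom, "start": start,
                     "end": start + GENE_LENGTH - 1})
    loci = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    truth.loc[:, "chrom"] = loci.set_index("gene_id")["chrom"]
    truth.loc[:, "start"] = loci.set_index("gene_id")["start"]
    truth.loc[:, "end"] = loci.set_index("gene_id")["end"]
    truth.loc[:, "qtl_proximal"] = truth.index.isin(prox_set)
    return loci, peaks


# ---------------------------------------------------------------------------
# writers


def write_counts_tsv(cm: CountMatrix, path: str | Path, seed: int | None = None) -> None:
    comments = [f"seed={seed}"] if seed is not None else []
    write_tsv(cm.counts, path, header_comments=comments, index_label="gene_id")


def write_metadata_tsv(cm: CountMatrix, path: str | Path, seed: int | None = None) -> None:
    comments = [f"seed={seed}"] if seed is not None else []
    write_tsv(cm.libraries, path, header_comments=comments, index_label="library_id")


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path,
                         seed: int | None = None) -> None:
    comments = [f"seed={seed}"] if seed is not None else []
    write_tsv(annotation, path, header_comments=comments, index=False)


def write_truth_tsv(truth: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    comments = [f"seed={seed}"] if seed is not None else []
    write_tsv(truth, path, header_comments=comments, index_label="gene_id")


def write_peaks_tsv(peaks: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    comments = [f"seed={seed}"] if seed is not None else []
    write_tsv(peaks, path, header_comments=comments, index=False)


def write_gff3(loci: pd.DataFrame, path: str | Path) -> None:
    """Write loci as GFF3 gene features (1-based inclusive)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in loci.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\tvitiseq\tgene\t{rec.start}\t{rec.end}\t.\t+\t.\t"
                f"ID={rec.gene_id}\n"
            )


def write_bed(loci: pd.DataFrame, path: str | Path) -> None:
    """Write loci as BED (0-based half-open)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in loci.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start - 1}\t{rec.end}\t{rec.gene_id}\n")


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> dict:
    """Generate counts, annotation, loci and peaks and write all TSVs."""
    out = Path(out_dir)
    cm, truth = generate_counts(config)
    annotation = generate_annotation(config, truth)
    loci, peaks = generate_loci_and_qtls(config, truth)
    write_counts_tsv(cm, out / "counts.tsv", seed=config.seed)
    write_metadata_tsv(cm, out / "metadata.tsv", seed=config.seed)
    write_annotation_tsv(annotation, out / "annotation.tsv", seed=config.seed)
    write_truth_tsv(truth, out / "truth.tsv", seed=config.seed)
    write_peaks_tsv(peaks, out / "qtl_peaks.tsv", seed=config.seed)
    write_gff3(loci, out / "loci.gff3")
    write_bed(loci, out / "loci.bed")
    return {"counts": cm, "truth": truth, "annotation": annotation,
            "loci": loci, "peaks": peaks}
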