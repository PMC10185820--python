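"""Instrument selection: significance filtering, LD clumping, confounder
exclusion, and instrument-strength (F-statistic) gating.

Selection follows the usual two-sample MR recipe for microbiome exposures:
a locus-wide p < 1e-5 screen (genome-wide 5e-8 available), greedy clumping at
r2 < 0.001 within a 10,000-kb window, removal of SNPs tied to known
confounders via a static exclusion list, and exclusion of whole taxa whose
instrument set has F < 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .summary_io import GwasSummaryRecord, LdMatrix, SummaryDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection.

    Defaults follow the locus-wide convention for microbiome GWAS: abundance
    traits rarely yield genome-wide hits, so p < 1e-5 is used to avoid losing
    signal; disease exposures in the reverse direction should switch to 5e-8.
    """

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    proxy_r2: float = 0.8
    f_min: float = 10.0
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in [0, 1]")
        if self.clump_kb <= 0:
            raise ValueError("clump_kb must be positive")
        if not (0 < self.proxy_r2 <= 1):
            raise ValueError("proxy_r2 must be in (0, 1]")
        if self.f_min < 0:
            raise ValueError("f_min must be non-negative")


GENOME_WIDE = 5e-8
LOCUS_WIDE = 1e-5


@dataclass(frozen=True)
class InstrumentStrength:
    """Aggregate strength of a taxon's instrument set."""

    r2_total: float
    n: int
    k: int
    f_stat: float


@dataclass
class AttritionLog:
    """Ordered per-stage SNP accounting: (stage, n_in, n_out, reason)."""

    stages: list[tuple[str, int, int, str]] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, reason: str) -> None:
        if self.stages and n_in != self.stages[-1][2]:
            raise ValueError(
                f"attrition stages must telescope: stage {stage!r} starts at "
                f"{n_in}, previous ended at {self.stages[-1][2]}"
            )
        if n_out > n_in:
            raise ValueError("SNP count cannot increase through a stage")
        self.stages.append((stage, n_in, n_out, reason))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["stage\tn_in\tn_out\treason"]
        lines += [f"{s}\t{i}\t{o}\t{r}" for s, i, o, r in self.stages]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def select_by_pvalue(
    dataset: SummaryDataset,
    config: SelectionConfig,
    log: AttritionLog | None = None,
) -> SummaryDataset:
    """Retain records with ``pval < p_threshold`` (strict inequality)."""
    keep = [r.rsid for r in dataset if r.pval < config.p_threshold]
    out = dataset.subset(keep)
    if log is not None:
        log.record("p_threshold", len(dataset), len(out),
                   f"pval >= {config.p_threshold:g}")
    if not out.records:
        logger.warning(
            "no SNPs pass p < %g for %s", config.p_threshold, dataset.trait_label
        )
    return out


def clump(
    candidates: SummaryDataset,
    ld: LdMatrix,
    config: SelectionConfig,
    log: AttritionLog | None = None,
) -> SummaryDataset:
    """Greedy LD clumping: keep the most significant SNP, discard its LD
    partners, repeat.

    A SNP is discarded when its r2 to an already-kept index SNP is at least
    ``clump_r2`` *and* it lies within ``clump_kb`` of the index on the same
    chromosome (if positions are unknown, the window is ignored and LD alone
    decides). Candidates absent from the LD matrix are dropped with a logged
    reason. Ties on p-value break by lexicographic rsid, so output is
    invariant to input row order.
    """
    n_in = len(candidates)
    present = [r for r in candidates if r.rsid in ld]
    n_absent = n_in - len(present)
    if n_absent:
        logger.info("clump: %d candidate SNP(s) absent from LD matrix, dropped",
                    n_absent)

    remaining = sorted(present, key=lambda r: (r.pval, r.rsid))
    kept: list[GwasSummaryRecord] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for r in remaining:
            in_ld = ld.r2_between(index.rsid, r.rsid) >= config.clump_r2
            in_window = (
                index.chrom == r.chrom
                and abs(index.pos - r.pos) <= config.clump_kb * 1000.0
            )
            if in_ld and in_window:
                continue
            survivors.append(r)
        remaining = survivors

    out = candidates.subset([r.rsid for r in kept])
    if log is not None:
        log.record("clump", n_in, len(out),
                   f"r2 >= {config.clump_r2:g} within {config.clump_kb:g} kb"
                   + (f"; {n_absent} absent from LD" if n_absent else ""))
    return out


def exclude_confounder_snps(
    dataset: SummaryDataset,
    config: SelectionConfig,
    log: AttritionLog | None = None,
) -> SummaryDataset:
    """Remove instruments tied to known confounders (static exclusion list)."""
    removed = [r.rsid for r in dataset if r.rsid in config.exclusion_list]
    for rsid in removed:
        logger.info("excluding %s: on confounder list", rsid)
    out = dataset.subset([r.rsid for r in dataset if r.rsid not in config.exclusion_list])
    if log is not None:
        log.record("confounder_exclusion", len(dataset), len(out),
                   "rsid on confounder exclusion list")
    return out


def read_exclusion_list(path: str | Path) -> frozenset[str]:
    """Read an rsid-per-line exclusion file; '#' starts a comment."""
    rsids = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            rsids.add(token)
    return frozenset(rsids)


def snp_r2(record: GwasSummaryRecord) -> float:
    """Variance in a standardized exposure explained by one SNP.

    Uses 2·p(1−p)·β² with p the effect-allele frequency, appropriate for
    rank-normalized abundance traits whose betas are in SD units. When eaf is
    missing, use :func:`snp_r2_from_se` instead.
    """
    if record.eaf is None:
        raise ValueError(
            f"{record.rsid}: eaf missing; use snp_r2_from_se for the "
            "se-based approximation"
        )
    return 2.0 * record.eaf * (1.0 - record.eaf) * record.beta**2


def snp_r2_from_se(record: GwasSummaryRecord) -> float:
    """se-based fallback R² = β² / (β² + n·se²); requires sample size."""
    if record.n is None:
        raise ValueError(f"{record.rsid}: sample size missing for se-based R²")
    return record.beta**2 / (record.beta**2 + record.n * record.se**2)


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Instrument-set F-statistic: F = R²(n−k−1) / (k(1−R²))."""
    if not (0 <= r2_total < 1):
        raise ValueError("r2_total must be in [0, 1)")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    return r2_total * (n - k - 1) / (k * (1.0 - r2_total))


def taxon_strength(dataset: SummaryDataset) -> InstrumentStrength:
    """Summed variance explained and F-statistic over a taxon's instruments.

    Falls back to the se-based per-SNP R² when eaf is absent from a record.
    """
    if not dataset.records:
        raise ValueError("no instruments")
    r2_total = 0.0
    for rec in dataset:
        r2_total += snp_r2(rec) if rec.eaf is not None else snp_r2_from_se(rec)
    ns = [rec.n for rec in dataset if rec.n is not None]
    if not ns:
        raise ValueError("sample size required for the F-statistic")
    n = int(max(ns))
    k = len(dataset)
    return InstrumentStrength(
        r2_total=r2_total, n=n, k=k, f_stat=f_statistic(r2_total, n, k)
    )


def filter_weak(
    exposure_sets: dict[str, SummaryDataset],
    config: SelectionConfig,
) -> tuple[dict[str, SummaryDataset], dict[str, InstrumentStrength]]:
    """Drop taxa whose instrument set is weak (F < f_min, strict).

    Returns the retained sets and the strength computed for every input taxon
    (dropped ones included, for the attrition report).
    """
    strengths: dict[str, InstrumentStrength] = {}
    kept: dict[str, SummaryDataset] = {}
    for label, ds in exposure_sets.items():
        strength = taxon_strength(ds)
        strengths[label] = strength
        if strength.f_stat < config.f_min:
            logger.info("dropping %s: F = %.3f < %.3g", label, strength.f_stat,
                        config.f_min)
        else:
            kept[label] = ds
    return kept, strengths
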