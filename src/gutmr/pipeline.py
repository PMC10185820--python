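"""End-to-end orchestration of the bidirectional MR workflow.

Forward direction: each bacterial taxon is the exposure and the disease the
outcome — select instruments (p-threshold, clumping, confounder exclusion,
per-taxon F gate), harmonize, estimate (IVW primary; MR-Egger and weighted
median as additional methods), run the sensitivity suite, and grade the
evidence. Taxa reaching at least nominal significance feed the MR-BMA
ranking when two or more survive. Reverse direction: the disease GWAS
becomes the exposure (genome-wide 5e-8 instrument threshold — disease GWAS
are well powered, so the locus-wide relaxation used for microbiome exposures
is not carried over) and each taxon the outcome.

All randomness flows from one master seed; re-running a config reproduces
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bma import BmaConfig, BmaSummary, build_exposure_matrix, run_bma_iterative
from .estimators import (
    MrEstimate,
    SignificanceCall,
    classify_significance,
    egger,
    ivw,
    weighted_median,
)
from .harmonize import HarmonizedSet, harmonize
from .instruments import (
    AttritionLog,
    SelectionConfig,
    clump,
    exclude_confounder_snps,
    read_exclusion_list,
    select_by_pvalue,
    taxon_strength,
)
from .sensitivity import SensitivityReport, sensitivity_suite, write_sensitivity_tsv
from .summary_io import LdMatrix, SummaryDataset, read_ld_matrix, read_summary_tsv

logger = logging.getLogger(__name__)

REVERSE_P_THRESHOLD = 5e-8


@dataclass
class PipelineConfig:
    """Inputs and options for a full bidirectional run.

    Datasets may be given in memory (``exposures``/``outcome``/``ld``) or as
    paths; paths are loaded lazily by :meth:`load`. ``selection`` governs the
    forward direction; the reverse direction reuses it with the genome-wide
    p-threshold unless ``reverse_selection`` overrides it entirely.
    """

    exposures: dict[str, SummaryDataset] = field(default_factory=dict)
    outcome: SummaryDataset | None = None
    ld: LdMatrix | None = None
    exposure_paths: dict[str, str] = field(default_factory=dict)
    outcome_path: str | None = None
    ld_path: str | None = None
    exclusion_path: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    reverse_selection: SelectionConfig | None = None
    ivw_mode: str = "auto"
    n_boot: int = 1000
    n_sim: int = 1000
    cooks_threshold: float = 0.5
    bma: BmaConfig = field(default_factory=BmaConfig)
    direction: str = "both"  # forward | reverse | both
    out_dir: str | None = None
    seed: int = 0

    def load(self) -> "PipelineConfig":
        """Materialize any path-specified inputs."""
        if self.exposure_paths and not self.exposures:
            self.exposures = {}
            for label, path in self.exposure_paths.items():
                ds, rej = read_summary_tsv(path, trait_label=label, role="exposure")
                if rej:
                    logger.info("%s: %d rows rejected at read", label, len(rej))
                self.exposures[label] = ds
        if self.outcome_path and self.outcome is None:
            self.outcome, _ = read_summary_tsv(
                self.outcome_path, trait_label="outcome", role="outcome"
            )
        if self.ld_path and self.ld is None:
            self.ld = read_ld_matrix(self.ld_path)
        if self.exclusion_path:
            self.selection = dataclasses.replace(
                self.selection,
                exclusion_list=read_exclusion_list(self.exclusion_path),
            )
        return self

    def reverse_config(self) -> SelectionConfig:
        if self.reverse_selection is not None:
            return self.reverse_selection
        return dataclasses.replace(self.selection, p_threshold=REVERSE_P_THRESHOLD)


@dataclass
class PairResult:
    """Everything computed for one exposure-outcome pair."""

    exposure_label: str
    outcome_label: str
    harmonized: HarmonizedSet
    estimates: dict[str, MrEstimate]
    sensitivity: SensitivityReport
    call: SignificanceCall
    attrition: AttritionLog


@dataclass
class PipelineResult:
    direction: str
    pairs: dict[str, PairResult]
    dropped: dict[str, str]  # label -> reason (failed QC before estimation)
    bma_iterations: list[BmaSummary] | None = None


def _seed_for(master: int, label: str, salt: int) -> int:
    import zlib

    return (master * 1_000_003 + zlib.crc32(label.encode()) + salt) % (2**31 - 1)


def analyse_pair(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LdMatrix,
    selection: SelectionConfig,
    seed: int = 0,
    ivw_mode: str = "auto",
    n_boot: int = 1000,
    n_sim: int = 1000,
    cooks_threshold: float = 0.5,
) -> PairResult | tuple[None, str]:
    """Run the single-pair workflow; returns (None, reason) when a QC gate
    empties the instrument set."""
    log = AttritionLog()
    label = exposure.trait_label
    selected = select_by_pvalue(exposure, selection, log)
    if not selected.records:
        return None, "no SNP passes the p-value threshold"
    clumped = clump(selected, ld, selection, log)
    if not clumped.records:
        return None, "no SNP survives clumping"
    screened = exclude_confounder_snps(clumped, selection, log)
    if not screened.records:
        return None, "all instruments on the confounder exclusion list"
    strength = taxon_strength(screened)
    if strength.f_stat < selection.f_min:
        return None, f"weak instruments (F = {strength.f_stat:.2f})"
    try:
        hset = harmonize(screened, outcome, ld, selection)
    except ValueError:
        return None, "no usable instruments after harmonization"
    log.record("harmonize", len(screened), len(hset),
               "palindromic / missing from outcome / incompatible alleles")

    estimates: dict[str, MrEstimate] = {"ivw": ivw(hset, mode=ivw_mode)}
    additional: list[MrEstimate] = []
    if len(hset) >= 3:
        estimates["egger"] = egger(hset)
        estimates["weighted_median"] = weighted_median(
            hset, n_boot=n_boot, seed=_seed_for(seed, label, 1)
        )
        additional = [estimates["egger"], estimates["weighted_median"]]
    sens = sensitivity_suite(
        hset,
        n_sim=n_sim,
        seed=_seed_for(seed, label, 2),
        cooks_threshold=cooks_threshold,
    )
    call = classify_significance(estimates["ivw"], additional, sens)
    return PairResult(
        exposure_label=label,
        outcome_label=outcome.trait_label,
        harmonized=hset,
        estimates=estimates,
        sensitivity=sens,
        call=call,
        attrition=log,
    )


def run_forward(config: PipelineConfig) -> PipelineResult:
    """Forward MR (taxa -> disease) plus MR-BMA over nominal taxa."""
    config.load()
    if not config.exposures or config.outcome is None or config.ld is None:
        raise ValueError("config must provide exposures, outcome and LD matrix")
    pairs: dict[str, PairResult] = {}
    dropped: dict[str, str] = {}
    for label in sorted(config.exposures):
        result = analyse_pair(
            config.exposures[label], config.outcome, config.ld,
            config.selection, seed=config.seed, ivw_mode=config.ivw_mode,
            n_boot=config.n_boot, n_sim=config.n_sim,
            cooks_threshold=config.cooks_threshold,
        )
        if isinstance(result, tuple):
            dropped[label] = result[1]
            logger.info("forward: %s dropped (%s)", label, result[1])
        else:
            pairs[label] = result
    if not pairs:
        raise ValueError("no exposure survives QC")

    nominal = {
        label: res.harmonized
        for label, res in pairs.items()
        if res.call.level in ("nominal", "significant")
    }
    bma_iters: list[BmaSummary] | None = None
    if len(nominal) >= 2:
        mat = build_exposure_matrix(nominal)
        bma_cfg = dataclasses.replace(config.bma, seed=config.seed)
        bma_iters = run_bma_iterative(mat, bma_cfg)
    return PipelineResult("forward", pairs, dropped, bma_iters)


def run_reverse(config: PipelineConfig) -> PipelineResult:
    """Reverse MR (disease -> each taxon); no BMA (single exposure)."""
    config.load()
    if not config.exposures or config.outcome is None or config.ld is None:
        raise ValueError("config must provide exposures, outcome and LD matrix")
    disease = config.outcome.with_role("exposure")
    selection = config.reverse_config()
    pairs: dict[str, PairResult] = {}
    dropped: dict[str, str] = {}
    for label in sorted(config.exposures):
        taxon_outcome = config.exposures[label].with_role("outcome")
        result = analyse_pair(
            disease, taxon_outcome, config.ld, selection,
            seed=config.seed + 1, ivw_mode=config.ivw_mode,
            n_boot=config.n_boot, n_sim=config.n_sim,
            cooks_threshold=config.cooks_threshold,
        )
        if isinstance(result, tuple):
            dropped[label] = result[1]
        else:
            pairs[label] = result
    if not pairs and dropped:
        # a disease with no genome-wide instruments is an empty, reported result
        logger.warning("reverse: no pair could be analysed")
    return PipelineResult("reverse", pairs, dropped, None)


def _fmt_p(p: float) -> str:
    return f"{p:.3g}"


def format_estimate_row(exposure: str, outcome: str, est: MrEstimate) -> dict:
    lo, hi = est.ci95
    return {
        "exposure": exposure,
        "n_snps": est.n_snps,
        "outcome": outcome,
        "method": est.method,
        "OR": f"{est.or_value:.3f}",
        "OR_95CI": f"{lo:.3f}-{hi:.3f}",
        "beta": f"{est.beta:.3f}",
        "p": _fmt_p(est.pval),
    }


def report_tables(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the results bundle as TSV reports; returns the paths written.

    ``mr_results`` mirrors the classic MR results table (exposure, n SNPs,
    outcome, method, OR, 95% CI, beta, p, significance); ``sensitivity`` and
    per-exposure ``attrition`` files carry the diagnostics; ``bma`` (when
    present) lists MIP/MACE/PP ranks per iteration with its SNP count and
    excluded instruments in block headers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    cols = ["exposure", "n_snps", "outcome", "method", "OR", "OR_95CI",
            "beta", "p", "significance"]
    lines = ["\t".join(cols)]
    for label in sorted(result.pairs):
        res = result.pairs[label]
        for method in ("ivw", "egger", "weighted_median"):
            if method not in res.estimates:
                continue
            row = format_estimate_row(label, res.outcome_label,
                                      res.estimates[method])
            row["significance"] = res.call.level if method == "ivw" else ""
            lines.append("\t".join(str(row[c]) for c in cols))
    path = out_dir / f"mr_results_{result.direction}.tsv"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written["mr_results"] = path

    sens_path = out_dir / f"sensitivity_{result.direction}.tsv"
    write_sensitivity_tsv(
        [result.pairs[k].sensitivity for k in sorted(result.pairs)], sens_path
    )
    written["sensitivity"] = sens_path

    att_lines = ["exposure\tstage\tn_in\tn_out\treason"]
    for label in sorted(result.pairs):
        for stage, n_in, n_out, reason in result.pairs[label].attrition.stages:
            att_lines.append(f"{label}\t{stage}\t{n_in}\t{n_out}\t{reason}")
    for label in sorted(result.dropped):
        att_lines.append(f"{label}\tdropped\t.\t.\t{result.dropped[label]}")
    att_path = out_dir / f"attrition_{result.direction}.tsv"
    att_path.write_text("\n".join(att_lines) + "\n", encoding="utf-8")
    written["attrition"] = att_path

    if result.bma_iterations:
        bma_lines = []
        for it, summary in enumerate(result.bma_iterations, start=1):
            header = f"# iteration {it}: model averaging employing {summary.n_snps} SNPs"
            if summary.excluded_snps:
                header += (
                    "; excluding " + ",".join(summary.excluded_snps)
                    + " before the next iteration"
                )
            bma_lines.append(header)
            bma_lines.append(
                "exposure\tMIP\trank_by_MIP\tMACE\tPP\trank_by_PP\tcausal_estimate\tp"
            )
            pp_rank = np.argsort(np.argsort(-summary.best_model_pp)) + 1
            for k, label in enumerate(summary.exposure_labels):
                p_str = (
                    f"{summary.perm_pval[k]:.8f}"
                    if summary.perm_pval is not None else "."
                )
                bma_lines.append(
                    f"{label}\t{summary.mip[k]:.3f}\t{summary.rank_by_mip[k]}\t"
                    f"{summary.mace[k]:.3f}\t{summary.best_model_pp[k]:.3f}\t"
                    f"{pp_rank[k]}\t{summary.causal_estimate[k]:.3f}\t{p_str}"
                )
        bma_path = out_dir / "bma_ranking.tsv"
        bma_path.write_text("\n".join(bma_lines) + "\n", encoding="utf-8")
        written["bma"] = bma_path
    return written


def run(config: PipelineConfig) -> dict[str, PipelineResult]:
    """Run the configured direction(s) and write reports if out_dir is set."""
    results: dict[str, PipelineResult] = {}
    if config.direction in ("forward", "both"):
        results["forward"] = run_forward(config)
    if config.direction in ("reverse", "both"):
        results["reverse"] = run_reverse(config)
    if config.out_dir:
        for res in results.values():
            report_tables(res, config.out_dir)
    return results
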