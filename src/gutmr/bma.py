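"""Multivariable MR Bayesian model averaging (MR-BMA).

Candidate exposures (bacterial taxa) often share instruments, so univariable
MR cannot tell which of several correlated taxa drives a disease signal.
MR-BMA treats each subset S of the K exposures as a linear model for the
instrument-level outcome effects,

    y_j = sum_{k in S} theta_k X_jk + eps_j,   eps_j ~ N(0, se_y_j^2),

puts a normal shrinkage prior N(0, sigma^2) on each included effect and an
independent-inclusion prior p_incl on each exposure, and scores every
non-empty subset by its posterior probability (PP). Per-exposure evidence is
summarized by the marginal inclusion probability (MIP, the summed PP of
models containing the exposure) and the model-averaged causal effect (MACE).
Instrument outliers are flagged per best model by the per-SNP heterogeneity
statistic q_j and Cook's distance, removed, and the analysis repeated until
none remain. Empirical per-exposure p-values come from permuting the outcome
effects across instruments.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet
from .summary_io import SummaryDataset

logger = logging.getLogger(__name__)


@dataclass
class ExposureMatrix:
    """Instrument-level design for multivariable MR.

    Rows are the union of instruments across exposures (harmonized to the
    outcome's allele orientation); a SNP absent from one exposure's GWAS
    contributes a zero entry in that column.
    """

    snp_ids: list[str]
    exposure_labels: list[str]
    X: np.ndarray  # (J, K) SNP-exposure betas
    y: np.ndarray  # (J,) SNP-outcome betas
    se_y: np.ndarray  # (J,) SNP-outcome SEs

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        j, k = self.X.shape
        if len(self.snp_ids) != j or len(self.exposure_labels) != k:
            raise ValueError("inconsistent ExposureMatrix dimensions")
        if self.y.shape != (j,) or self.se_y.shape != (j,):
            raise ValueError("inconsistent outcome vector length")
        if (self.se_y <= 0).any():
            raise ValueError("outcome SEs must be positive")

    @property
    def n_snps(self) -> int:
        return self.X.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.X.shape[1]

    def drop_snps(self, rsids: set[str]) -> "ExposureMatrix":
        keep = [i for i, s in enumerate(self.snp_ids) if s not in rsids]
        return ExposureMatrix(
            snp_ids=[self.snp_ids[i] for i in keep],
            exposure_labels=list(self.exposure_labels),
            X=self.X[keep],
            y=self.y[keep],
            se_y=self.se_y[keep],
        )


@dataclass(frozen=True)
class BmaConfig:
    """Priors, thresholds and permutation settings for MR-BMA.

    ``prior_inclusion`` defaults to 0.25 (one of four candidate exposures
    expected causal a priori) and ``prior_sd`` to 0.5 on the log-odds scale;
    the ranking properties are insensitive to both within a broad range.
    """

    prior_inclusion: float = 0.25
    prior_sd: float = 0.5
    pp_threshold: float = 0.02
    q_threshold: float = 10.0
    cooks_threshold: float | None = None  # None -> F-distribution median rule
    n_perm: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prior_inclusion < 1):
            raise ValueError("prior_inclusion must be in (0, 1)")
        if not (0 < self.pp_threshold < 1):
            raise ValueError("pp_threshold must be in (0, 1)")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass(frozen=True)
class ModelPosterior:
    subset: tuple[int, ...]
    pp: float
    estimates: tuple[float, ...]  # posterior-mean effects of included exposures


@dataclass
class BmaSummary:
    """Per-exposure MR-BMA evidence for one iteration."""

    exposure_labels: list[str]
    mip: np.ndarray
    rank_by_mip: np.ndarray
    mace: np.ndarray
    best_model_pp: np.ndarray
    causal_estimate: np.ndarray  # from the top-PP model containing each exposure
    perm_pval: np.ndarray | None
    models: list[ModelPosterior]
    n_snps: int
    excluded_snps: list[str] = field(default_factory=list)


def build_exposure_matrix(
    sets: dict[str, HarmonizedSet],
    outcome: SummaryDataset | None = None,
) -> ExposureMatrix:
    """Assemble the union-of-instruments design from per-exposure sets.

    Each harmonized set already carries outcome effects on aligned alleles;
    outcome values are taken from the first set providing each SNP (they
    agree across sets by construction). Missing SNP-exposure entries are set
    to zero and counted in the log.
    """
    if len(sets) < 2:
        raise ValueError("multivariable MR needs at least 2 exposures")
    labels = sorted(sets)
    union: dict[str, tuple[float, float]] = {}
    per_exp: dict[str, dict[str, float]] = {}
    for label in labels:
        hset = sets[label]
        per_exp[label] = {}
        for inst in hset:
            per_exp[label][inst.rsid] = inst.gamma
            if inst.rsid not in union:
                union[inst.rsid] = (inst.Gamma_out, inst.se_Gamma)
    if not union:
        raise ValueError("empty instrument union")
    snp_ids = sorted(union)
    X = np.zeros((len(snp_ids), len(labels)))
    n_missing = 0
    for kk, label in enumerate(labels):
        for jj, rsid in enumerate(snp_ids):
            if rsid in per_exp[label]:
                X[jj, kk] = per_exp[label][rsid]
            else:
                n_missing += 1
    if n_missing:
        logger.info("exposure matrix: %d missing SNP-exposure entries set to 0",
                    n_missing)
    y = np.array([union[r][0] for r in snp_ids])
    se_y = np.array([union[r][1] for r in snp_ids])
    return ExposureMatrix(snp_ids, labels, X, y, se_y)


def enumerate_models(K: int, config: BmaConfig) -> list[tuple[tuple[int, ...], float]]:
    """All non-empty exposure subsets with normalized prior probabilities.

    prior(S) is proportional to p^|S| (1-p)^(K-|S|), renormalized over the
    non-empty subsets. Exhaustive enumeration only; K is capped at 20.
    """
    if K > 20:
        raise ValueError("exhaustive enumeration is limited to K <= 20 exposures")
    if K < 1:
        raise ValueError("need at least one exposure")
    p = config.prior_inclusion
    models = []
    for size in range(1, K + 1):
        for subset in itertools.combinations(range(K), size):
            models.append((subset, p**size * (1 - p) ** (K - size)))
    total = sum(w for _, w in models)
    return [(s, w / total) for s, w in models]


def model_posterior(
    mat: ExposureMatrix,
    subset: tuple[int, ...],
    config: BmaConfig,
    prior: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Unnormalized posterior mass and shrunken effect estimates of one model.

    After scaling rows by 1/se_y the errors are standard normal, so the
    marginal likelihood of y ~ N(0, sigma^2 X_S X_S' + I) has the closed
    form; log det and the quadratic form are evaluated through the
    |S| x |S| matrix A = X_S' X_S + I/sigma^2. The returned estimates are
    the posterior means A^{-1} X_S' y (ridge-shrunken least squares).
    """
    if not subset:
        raise ValueError("empty model subset")
    Xs = mat.X[:, list(subset)] / mat.se_y[:, None]
    ys = mat.y / mat.se_y
    s2 = config.prior_sd**2
    A = Xs.T @ Xs + np.eye(len(subset)) / s2
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular weighted design")
    # det(I_J + s2 Xs Xs') = det(A) * s2^|S|
    logdet = logdet_A + len(subset) * math.log(s2)
    Xty = Xs.T @ ys
    theta = np.linalg.solve(A, Xty)
    quad = float(ys @ ys - Xty @ theta)
    j = mat.n_snps
    log_ml = -0.5 * (j * math.log(2 * math.pi) + logdet + quad)
    log_pp = math.log(prior) + log_ml
    return log_pp, theta


def _posteriors(
    mat: ExposureMatrix, config: BmaConfig
) -> list[ModelPosterior]:
    models = enumerate_models(mat.n_exposures, config)
    log_pps = np.empty(len(models))
    thetas: list[np.ndarray] = []
    for i, (subset, prior) in enumerate(models):
        log_pps[i], theta = model_posterior(mat, subset, config, prior)
        thetas.append(theta)
    log_pps -= log_pps.max()
    pps = np.exp(log_pps)
    pps /= pps.sum()
    return [
        ModelPosterior(subset=s, pp=float(pp), estimates=tuple(map(float, th)))
        for (s, _), pp, th in zip(models, pps, thetas)
    ]


def mip_mace(
    models: list[ModelPosterior], K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Marginal inclusion probabilities, MACE, and MIP ranks.

    mip_k sums the PPs of all models containing exposure k; mace_k averages
    its effect over models (zero when excluded). Ranks order by descending
    MIP with ties broken by descending |MACE|.
    """
    mip = np.zeros(K)
    mace = np.zeros(K)
    for m in models:
        for pos, k in enumerate(m.subset):
            mip[k] += m.pp
            mace[k] += m.pp * m.estimates[pos]
    order = sorted(range(K), key=lambda k: (-mip[k], -abs(mace[k]), k))
    rank = np.empty(K, dtype=int)
    for r, k in enumerate(order, start=1):
        rank[k] = r
    return mip, mace, rank


def snp_diagnostics(
    mat: ExposureMatrix,
    best_models: list[ModelPosterior],
    config: BmaConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP heterogeneity q_j and Cook's distance, maximized over the
    best models (those with PP at or above the threshold).

    q_j is the squared standardized residual of SNP j under a model's fitted
    values; Cook's distance uses the ridge-regression hat matrix on the
    weighted design. The Cook's flag threshold defaults to the median of the
    F(|S|, J-|S|) distribution.
    """
    if not best_models:
        raise ValueError("no best models supplied")
    j = mat.n_snps
    q_max = np.zeros(j)
    d_max = np.zeros(j)
    ys = mat.y / mat.se_y
    for m in best_models:
        Xs = mat.X[:, list(m.subset)] / mat.se_y[:, None]
        p = len(m.subset)
        A = Xs.T @ Xs + np.eye(p) / config.prior_sd**2
        theta = np.array(m.estimates)
        resid = ys - Xs @ theta
        q = resid**2
        H = Xs @ np.linalg.solve(A, Xs.T)
        h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
        dof = max(j - p, 1)
        s2 = float(resid @ resid / dof)
        if s2 > 0:
            d = resid**2 / (p * s2) * h / (1 - h) ** 2
        else:
            d = np.zeros(j)
        q_max = np.maximum(q_max, q)
        d_max = np.maximum(d_max, d)
    return q_max, d_max


def cooks_rule_threshold(mat: ExposureMatrix, best_models: list[ModelPosterior],
                         config: BmaConfig) -> float:
    """Cook's-distance flag threshold: fixed override or the F-median rule
    (median of F(|S|, J-|S|)), taken over the best models (smallest wins)."""
    if config.cooks_threshold is not None:
        return config.cooks_threshold
    j = mat.n_snps
    return min(
        float(stats.f.median(len(m.subset), max(j - len(m.subset), 1)))
        for m in best_models
    )


def _diagnose(
    mat: ExposureMatrix, models: list[ModelPosterior], config: BmaConfig
) -> list[str]:
    """rsids flagged as outliers across the best models."""
    best = [m for m in models if m.pp >= config.pp_threshold]
    if not best:
        best = [max(models, key=lambda m: m.pp)]
    q, d = snp_diagnostics(mat, best, config)
    thr = cooks_rule_threshold(mat, best, config)
    return sorted(
        mat.snp_ids[idx]
        for idx in range(mat.n_snps)
        if q[idx] > config.q_threshold or d[idx] > thr
    )


def _mip_only(mat: ExposureMatrix, config: BmaConfig) -> np.ndarray:
    models = _posteriors(mat, config)
    mip, _, _ = mip_mace(models, mat.n_exposures)
    return mip


def permutation_pvalues(
    mat: ExposureMatrix,
    observed_mip: np.ndarray,
    config: BmaConfig,
) -> np.ndarray:
    """Empirical per-exposure p-values by permuting outcome effects.

    (y, se_y) rows are permuted jointly across SNPs; each exposure's MIP is
    recomputed and p = (1 + #{MIP_perm >= MIP_obs}) / (n_perm + 1), so every
    achievable p is a multiple of 1/(n_perm+1).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0xBA])
    )
    count = np.zeros(mat.n_exposures)
    for _ in range(config.n_perm):
        perm = rng.permutation(mat.n_snps)
        pmat = ExposureMatrix(
            snp_ids=list(mat.snp_ids),
            exposure_labels=list(mat.exposure_labels),
            X=mat.X,
            y=mat.y[perm],
            se_y=mat.se_y[perm],
        )
        count += _mip_only(pmat, config) >= observed_mip
    return (1.0 + count) / (config.n_perm + 1.0)


def run_bma(
    mat: ExposureMatrix,
    config: BmaConfig,
    with_permutation: bool = True,
) -> BmaSummary:
    """One MR-BMA fit: model posteriors, MIP/MACE ranking, permutation p."""
    models = _posteriors(mat, config)
    K = mat.n_exposures
    mip, mace, rank = mip_mace(models, K)
    best_pp = np.zeros(K)
    causal = np.full(K, np.nan)
    for m in sorted(models, key=lambda m: -m.pp):
        for pos, k in enumerate(m.subset):
            if m.pp > best_pp[k]:
                best_pp[k] = m.pp
                causal[k] = m.estimates[pos]
    perm = permutation_pvalues(mat, mip, config) if with_permutation else None
    return BmaSummary(
        exposure_labels=list(mat.exposure_labels),
        mip=mip,
        rank_by_mip=rank,
        mace=mace,
        best_model_pp=best_pp,
        causal_estimate=causal,
        perm_pval=perm,
        models=models,
        n_snps=mat.n_snps,
    )


def run_bma_iterative(
    mat: ExposureMatrix,
    config: BmaConfig,
    with_permutation: bool = True,
    max_iter: int = 20,
) -> list[BmaSummary]:
    """Fit, flag instrument outliers, remove, refit — until a fixpoint.

    Stops when no SNP is flagged, when fewer than 3*K instruments would
    remain, or after ``max_iter`` rounds. Each iteration's summary records
    the SNPs removed *going into the next* iteration.
    """
    summaries: list[BmaSummary] = []
    current = mat
    for _ in range(max_iter):
        summary = run_bma(current, config, with_permutation=with_permutation)
        summaries.append(summary)
        flagged = _diagnose(current, summary.models, config)
        if not flagged:
            break
        remaining = current.n_snps - len(flagged)
        if remaining < 3 * current.n_exposures:
            logger.warning(
                "stopping outlier iteration: %d instruments would remain", remaining
            )
            break
        summary.excluded_snps = flagged
        current = current.drop_snps(set(flagged))
    else:
        raise RuntimeError("outlier removal did not converge")
    return summaries
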