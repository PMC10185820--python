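"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

The validity checks that accompany any IVW estimate:

* Cochran's Q — heterogeneity of the per-SNP Wald ratios about the
  fixed-effect estimate, chi-square with J-1 df. Significant Q triggers the
  IVW random-effects fallback upstream.
* Egger intercept — directional-pleiotropy test; intercept p < 0.05 flags a
  violated exclusion restriction.
* MR-PRESSO — parametric-simulation test on the residual sum of squares with
  global, per-SNP outlier, and distortion components.
* Leave-one-out — per-instrument re-estimation plus Cook's distance from the
  zero-intercept weighted regression; flags single IVs driving the result.

Per-SNP simulation streams are derived by hashing the rsid into the master
seed, so PRESSO results are invariant to instrument order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .estimators import egger
from .harmonize import HarmonizedSet

COOKS_THRESHOLD_DEFAULT = 0.5


@dataclass(frozen=True)
class HeterogeneityResult:
    q_stat: float
    df: int
    pval: float


@dataclass(frozen=True)
class PressoResult:
    global_pval: float
    outlier_rsids: tuple[str, ...]
    per_snp_pvals: dict
    distortion_pval: float | None
    n_sim: int
    seed: int


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out estimates and Cook's distances, one row per instrument."""

    rsids: tuple[str, ...]
    betas: tuple[float, ...]
    ses: tuple[float, ...]
    cooks_d: tuple[float, ...]
    flagged: tuple[str, ...]
    threshold: float


@dataclass
class SensitivityReport:
    """Bundle of diagnostics for one exposure-outcome pair."""

    exposure_label: str
    outcome_label: str
    heterogeneity: HeterogeneityResult
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    presso: PressoResult | None
    loo: LooResult | None

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure_label,
            "outcome": self.outcome_label,
            "Q": self.heterogeneity.q_stat,
            "df": self.heterogeneity.df,
            "Q_p": self.heterogeneity.pval,
            "egger_intercept": self.egger_intercept,
            "intercept_p": self.egger_intercept_pval,
            "presso_global_p": self.presso.global_pval if self.presso else float("nan"),
            "n_outliers": len(self.presso.outlier_rsids) if self.presso else 0,
            "max_cooks_d": max(self.loo.cooks_d) if self.loo else float("nan"),
        }


def _arrays(instrument_set: HarmonizedSet):
    g = np.array([i.gamma for i in instrument_set])
    sg = np.array([i.se_gamma for i in instrument_set])
    G = np.array([i.Gamma_out for i in instrument_set])
    sG = np.array([i.se_Gamma for i in instrument_set])
    return g, sg, G, sG


def cochran_q(instrument_set: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q about the fixed-effect IVW estimate, chi2 with J-1 df."""
    j = len(instrument_set)
    if j < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    g, _, G, sG = _arrays(instrument_set)
    w = g**2 / sG**2
    ratios = G / g
    beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta) ** 2))
    return HeterogeneityResult(q_stat=q, df=j - 1, pval=float(stats.chi2.sf(q, j - 1)))


def egger_intercept_test(instrument_set: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, SE, two-sided p) from the MR-Egger fit."""
    est = egger(instrument_set)
    return (
        est.extra["intercept"],
        est.extra["intercept_se"],
        est.extra["intercept_pval"],
    )


def _snp_seed(master_seed: int, rsid: str) -> np.random.Generator:
    # rsid-keyed stream: PRESSO draws do not depend on instrument order
    return np.random.default_rng(
        np.random.SeedSequence([master_seed & 0x7FFFFFFF, zlib.crc32(rsid.encode())])
    )


def _loo_betas(g: np.ndarray, G: np.ndarray, w_inv_var: np.ndarray) -> np.ndarray:
    """IVW slope excluding each instrument in turn (vectorized).

    Weights are 1/sigma_Gamma^2 on the Gamma-scale regression, identical to
    the ratio-scale IVW weights gamma^2/sigma_Gamma^2.
    """
    sxy = np.sum(w_inv_var * g * G)
    sxx = np.sum(w_inv_var * g * g)
    return (sxy - w_inv_var * g * G) / (sxx - w_inv_var * g * g)


def mr_presso(
    instrument_set: HarmonizedSet,
    n_sim: int = 1000,
    sig_level: float | None = None,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    The observed statistic is the leave-one-out weighted residual sum of
    squares RSS = sum_j (Gamma_j - b_(-j) gamma_j)^2 / sigma_Gamma_j^2. Its
    null distribution comes from parametric simulation: draw
    gamma*_j ~ N(gamma_j, sigma_gamma_j) and
    Gamma*_j ~ N(b_(-j) gamma_j, sigma_Gamma_j), recompute the full
    leave-one-out RSS on the simulated data. Empirical p-values use the
    add-one rule, so the minimum achievable p is 1/(n_sim+1). Per-SNP
    outlier tests compare each observed RSS term with its simulated
    distribution at a Bonferroni-adjusted level (default 0.05/J). The
    distortion test compares the outlier-free estimate against estimates
    obtained by removing equally many random instruments.
    """
    insts = list(instrument_set)
    j = len(insts)
    if j < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    if sig_level is None:
        sig_level = 0.05 / j
    g, sg, G, sG = _arrays(instrument_set)
    w = 1.0 / sG**2

    beta_loo = _loo_betas(g, G, w)
    obs_terms = w * (G - beta_loo * g) ** 2
    rss_obs = float(np.sum(obs_terms))

    # per-SNP rsid-keyed streams -> (n_sim, J) draws, order-invariant
    g_star = np.empty((n_sim, j))
    G_star = np.empty((n_sim, j))
    for k, inst in enumerate(insts):
        rng = _snp_seed(seed, inst.rsid)
        g_star[:, k] = rng.normal(g[k], sg[k], size=n_sim)
        G_star[:, k] = rng.normal(beta_loo[k] * g[k], sG[k], size=n_sim)

    sxy = np.sum(w * g_star * G_star, axis=1, keepdims=True)
    sxx = np.sum(w * g_star**2, axis=1, keepdims=True)
    beta_loo_star = (sxy - w * g_star * G_star) / (sxx - w * g_star**2)
    sim_terms = w * (G_star - beta_loo_star * g_star) ** 2
    rss_star = np.sum(sim_terms, axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_snp = {
        inst.rsid: float((1 + np.sum(sim_terms[:, k] >= obs_terms[k])) / (n_sim + 1))
        for k, inst in enumerate(insts)
    }
    outliers = tuple(sorted(r for r, p in per_snp.items() if p < sig_level))

    distortion_p: float | None = None
    if outliers:
        out_idx = np.array([inst.rsid in outliers for inst in insts])
        keep = ~out_idx
        if keep.sum() >= 2:
            def _ivw_slope(mask: np.ndarray) -> float:
                return float(
                    np.sum(w[mask] * g[mask] * G[mask]) / np.sum(w[mask] * g[mask] ** 2)
                )

            beta_full = _ivw_slope(np.ones(j, dtype=bool))
            d_obs = _ivw_slope(keep) - beta_full
            rng = np.random.default_rng(
                np.random.SeedSequence([seed & 0x7FFFFFFF, 0xD157])
            )
            n_out = int(out_idx.sum())
            d_null = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(j, size=n_out, replace=False)
                mask = np.ones(j, dtype=bool)
                mask[drop] = False
                d_null[s] = _ivw_slope(mask) - beta_full
            distortion_p = float(
                (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1)
            )
    return PressoResult(
        global_pval=global_p,
        outlier_rsids=outliers,
        per_snp_pvals=per_snp,
        distortion_pval=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(
    instrument_set: HarmonizedSet,
    cooks_threshold: float = COOKS_THRESHOLD_DEFAULT,
) -> LooResult:
    """Leave-one-out IVW estimates and Cook's distances per instrument.

    Cook's distance comes from the zero-intercept weighted regression of
    Gamma on gamma (the IVW model): D_j = (e_j^2 / s^2) * h_j / (1-h_j)^2
    with weighted residuals e_j, hat values h_j and p = 1 parameter.
    """
    insts = list(instrument_set)
    j = len(insts)
    if j < 3:
        raise ValueError("leave-one-out needs at least 3 instruments")
    g, _, G, sG = _arrays(instrument_set)
    w = 1.0 / sG**2

    beta_loo = _loo_betas(g, G, w)
    ses = np.array(
        [
            float(np.sum(np.delete(w * g * g, k)) ** -0.5)
            for k in range(j)
        ]
    )

    sxx = float(np.sum(w * g * g))
    beta_full = float(np.sum(w * g * G) / sxx)
    h = w * g * g / sxx
    e = np.sqrt(w) * (G - beta_full * g)
    dof = j - 1
    s2 = float(np.sum(e**2) / dof) if dof else 0.0
    # a numerically perfect fit has residuals at machine precision relative to
    # the data scale; Cook's d is residual-scale-invariant, so floor it to 0
    scale = float(np.sum(w * G**2)) or 1.0
    if s2 < 1e-20 * scale:
        s2 = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cooks = np.where(
            (s2 > 0) & (h < 1), e**2 / s2 * h / (1 - h) ** 2, 0.0
        )
    rsids = tuple(i.rsid for i in insts)
    flagged = tuple(r for r, d in zip(rsids, cooks) if d > cooks_threshold)
    return LooResult(
        rsids=rsids,
        betas=tuple(float(b) for b in beta_loo),
        ses=tuple(float(s) for s in ses),
        cooks_d=tuple(float(d) for d in cooks),
        flagged=flagged,
        threshold=cooks_threshold,
    )


def sensitivity_suite(
    instrument_set: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    cooks_threshold: float = COOKS_THRESHOLD_DEFAULT,
) -> SensitivityReport:
    """Run every diagnostic that the instrument count permits."""
    j = len(instrument_set)
    if j >= 2:
        het = cochran_q(instrument_set)
    else:
        het = HeterogeneityResult(q_stat=0.0, df=0, pval=1.0)
    if j >= 3:
        intercept, i_se, i_p = egger_intercept_test(instrument_set)
        loo = leave_one_out(instrument_set, cooks_threshold)
    else:
        intercept, i_se, i_p = float("nan"), float("nan"), 1.0
        loo = None
    presso = mr_presso(instrument_set, n_sim=n_sim, seed=seed) if j >= 4 else None
    return SensitivityReport(
        exposure_label=instrument_set.exposure_label,
        outcome_label=instrument_set.outcome_label,
        heterogeneity=het,
        egger_intercept=intercept,
        egger_intercept_se=i_se,
        egger_intercept_pval=i_p,
        presso=presso,
        loo=loo,
    )


def write_sensitivity_tsv(reports: list[SensitivityReport], path: str | Path) -> None:
    cols = [
        "exposure", "outcome", "Q", "df", "Q_p", "egger_intercept",
        "intercept_p", "presso_global_p", "n_outliers", "max_cooks_d",
    ]
    lines = ["\t".join(cols)]
    for rep in reports:
        row = rep.to_row()
        lines.append("\t".join(str(row[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
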