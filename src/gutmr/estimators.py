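"""Causal-effect estimators for two-sample summary-data MR.

Given J harmonized instruments with SNP-exposure effects gamma_j (SE
sigma_gamma_j) and SNP-outcome effects Gamma_j (SE sigma_Gamma_j), each
instrument yields a Wald ratio beta_j = Gamma_j / gamma_j. The estimators
combine these ratios under different identifying assumptions:

* IVW — precision-weighted mean with weights w_j = gamma_j^2 / sigma_Gamma_j^2
  (first-order Wald-ratio precisions); equivalent to a zero-intercept weighted
  regression of Gamma on gamma. Fixed-effect SE is (sum w_j)^{-1/2};
  the multiplicative random-effects SE inflates it by
  sqrt(max(1, Q/(J-1))) and never shrinks below the fixed-effect SE.
* MR-Egger — weighted regression with a free intercept after orienting all
  gamma_j positive; the intercept estimates directional pleiotropy, the slope
  remains consistent when the InSIDE assumption holds.
* Weighted median — consistent when instruments carrying at least half of the
  total weight are valid; SE by seeded parametric bootstrap.

All p-values use the standard normal, the usual summary-data MR convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument, HarmonizedSet

if TYPE_CHECKING:  # pragma: no cover
    from .sensitivity import SensitivityReport  # noqa: F401 (docstring/type use)

Z_95 = 1.96  # conventional 95% multiplier, also used when rebuilding SEs from CIs


@dataclass(frozen=True)
class MrEstimate:
    """One method's causal estimate on the log-odds scale."""

    method: str  # wald | ivw_fixed | ivw_random | egger | weighted_median
    beta: float
    se: float
    n_snps: int
    extra: dict = field(default_factory=dict)

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.beta - Z_95 * self.se),
            math.exp(self.beta + Z_95 * self.se),
        )

    @property
    def pval(self) -> float:
        if self.se == 0:
            return 0.0 if self.beta != 0 else 1.0
        return float(2.0 * stats.norm.sf(abs(self.beta) / self.se))


@dataclass(frozen=True)
class SignificanceCall:
    """Evidence grade for one exposure-outcome pair.

    ``nominal`` requires IVW p < 0.05; ``significant`` additionally requires
    direction-concordant support from at least one additional method and a
    clean sensitivity profile.
    """

    level: str  # none | nominal | significant
    rationale: str


def _arrays(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    g = np.array([i.gamma for i in instruments])
    sg = np.array([i.se_gamma for i in instruments])
    G = np.array([i.Gamma_out for i in instruments])
    sG = np.array([i.se_Gamma for i in instruments])
    return g, sg, G, sG


def wald_ratio(inst: HarmonizedInstrument) -> MrEstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order SE."""
    if inst.gamma == 0:
        raise ZeroDivisionError(f"{inst.rsid}: zero exposure effect")
    return MrEstimate(
        method="wald",
        beta=inst.Gamma_out / inst.gamma,
        se=inst.se_Gamma / abs(inst.gamma),
        n_snps=1,
    )


def _ivw_core(g: np.ndarray, G: np.ndarray, sG: np.ndarray) -> tuple[float, float, float]:
    """Return (beta, fixed se, Cochran's Q) for the IVW estimator."""
    w = g**2 / sG**2
    ratios = G / g
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratios - beta) ** 2))
    return beta, se_fixed, q


def ivw(instrument_set: HarmonizedSet, mode: str = "auto") -> MrEstimate:
    """Inverse-variance-weighted causal estimate.

    ``mode`` is ``fixed``, ``random`` (multiplicative overdispersion, floored
    at the fixed-effect SE), or ``auto`` (random iff Cochran's Q p < 0.05).
    A single instrument degenerates to the Wald ratio.
    """
    if mode not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    insts = list(instrument_set)
    if not insts:
        raise ValueError("no instruments")
    if len(insts) == 1:
        est = wald_ratio(insts[0])
        return MrEstimate("ivw_fixed", est.beta, est.se, 1)
    g, _, G, sG = _arrays(insts)
    if np.any(g == 0):
        raise ZeroDivisionError("zero exposure effect among instruments")
    beta, se_fixed, q = _ivw_core(g, G, sG)
    j = len(insts)
    q_p = float(stats.chi2.sf(q, j - 1))
    use_random = mode == "random" or (mode == "auto" and q_p < 0.05)
    inflation = math.sqrt(max(1.0, q / (j - 1))) if use_random else 1.0
    return MrEstimate(
        method="ivw_random" if use_random else "ivw_fixed",
        beta=beta,
        se=se_fixed * inflation,
        n_snps=j,
        extra={"q_stat": q, "q_pval": q_p},
    )


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: bool):
    """Weighted least squares via the normal equations.

    Returns (coef, cov) where coef is [slope] or [intercept, slope].
    """
    if intercept:
        X = np.column_stack([np.ones_like(x), x])
    else:
        X = x[:, None]
    WX = X * w[:, None]
    A = X.T @ WX
    b = WX.T @ y
    coef = np.linalg.solve(A, b)
    resid = y - X @ coef
    dof = len(x) - X.shape[1]
    sigma2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
    cov = np.linalg.inv(A) * sigma2
    return coef, cov


def egger(instrument_set: HarmonizedSet) -> MrEstimate:
    """MR-Egger regression: slope = causal effect, intercept = pleiotropy.

    Instruments are oriented so every gamma_j is positive (both betas negated
    where needed) before the weighted fit with weights 1/sigma_Gamma_j^2.
    The residual variance multiplier is floored at 1 so the SE never
    undercuts the homoscedastic weighted fit.
    """
    insts = list(instrument_set)
    if len(insts) < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    g, _, G, sG = _arrays(insts)
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    w = 1.0 / sG**2
    coef, cov = _wls(g, G, w, intercept=True)
    # multiplicative residual inflation, floored at 1 (matches IVW-random spirit)
    X = np.column_stack([np.ones_like(g), g])
    A_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    resid = G - X @ coef
    dof = len(g) - 2
    phi = max(1.0, float(np.sum(w * resid**2) / dof)) if dof > 0 else 1.0
    cov = A_inv * phi
    intercept_se = math.sqrt(cov[0, 0])
    slope_se = math.sqrt(cov[1, 1])
    intercept = float(coef[0])
    intercept_p = (
        float(2.0 * stats.norm.sf(abs(intercept) / intercept_se))
        if intercept_se > 0 else (1.0 if intercept == 0 else 0.0)
    )
    return MrEstimate(
        method="egger",
        beta=float(coef[1]),
        se=slope_se,
        n_snps=len(insts),
        extra={
            "intercept": intercept,
            "intercept_se": intercept_se,
            "intercept_pval": intercept_p,
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    Sorts ratios ascending; with normalized weights p_j the cumulative
    midpoints s_j = cum(p)_j - p_j/2 bracket probability 0.5, and the
    estimate interpolates linearly between the bracketing ratios.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    p = weights[order] / np.sum(weights)
    s = np.cumsum(p) - p / 2.0
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    hi = int(np.searchsorted(s, 0.5))
    lo = hi - 1
    frac = (0.5 - s[lo]) / (s[hi] - s[lo])
    return float(r[lo] + frac * (r[hi] - r[lo]))


def weighted_median(
    instrument_set: HarmonizedSet,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Valid when instruments carrying at least 50% of the inverse-variance
    weight satisfy the exclusion restriction. Each bootstrap replicate
    resamples (gamma_j, Gamma_j) from their sampling normals and recomputes
    the weighted median; the SE is the SD over replicates.
    """
    insts = list(instrument_set)
    if len(insts) < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    g, sg, G, sG = _arrays(insts)
    w = g**2 / sG**2
    point = _weighted_median_point(G / g, w)
    rng = np.random.default_rng(seed)
    g_star = rng.normal(g, sg, size=(n_boot, len(insts)))
    G_star = rng.normal(G, sG, size=(n_boot, len(insts)))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        gb = g_star[b]
        gb = np.where(gb == 0, 1e-300, gb)
        boot[b] = _weighted_median_point(G_star[b] / gb, gb**2 / sG**2)
    return MrEstimate(
        method="weighted_median",
        beta=point,
        se=float(np.std(boot, ddof=1)),
        n_snps=len(insts),
        extra={"n_boot": n_boot, "seed": seed},
    )


def classify_significance(
    ivw_est: MrEstimate,
    additional: Sequence[MrEstimate],
    sensitivity: "SensitivityReport | None" = None,
) -> SignificanceCall:
    """Grade the evidence for a causal relationship.

    No call below IVW p < 0.05; nominal at IVW p < 0.05; significant when at
    least one additional method (MR-Egger or weighted median) is itself
    p < 0.05 with the same effect direction as IVW, and the sensitivity
    report (when supplied) shows no directional pleiotropy (Egger intercept
    p >= 0.05) and no MR-PRESSO outliers.
    """
    if ivw_est.pval >= 0.05:
        return SignificanceCall("none", f"IVW p = {ivw_est.pval:.3g} >= 0.05")
    supporters = [
        est.method
        for est in additional
        if est.pval < 0.05 and np.sign(est.beta) == np.sign(ivw_est.beta)
    ]
    if not supporters:
        return SignificanceCall(
            "nominal", "IVW p < 0.05; no additional method concordant at p < 0.05"
        )
    if sensitivity is not None:
        if sensitivity.egger_intercept_pval < 0.05:
            return SignificanceCall(
                "nominal", "directional pleiotropy (Egger intercept p < 0.05)"
            )
        if sensitivity.presso is not None and sensitivity.presso.outlier_rsids:
            return SignificanceCall("nominal", "MR-PRESSO flagged outliers")
    return SignificanceCall(
        "significant", f"IVW p < 0.05 supported by {', '.join(supporters)}"
    )


def wald_p_from_ci(or_value: float, ci_lo: float, ci_hi: float) -> float:
    """Two-sided Wald p reconstructed from an odds ratio's 95% CI.

    The log-scale midpoint of the CI gives the point estimate and the CI
    width gives the SE (b = (ln lo + ln hi)/2, se = (ln hi - ln lo)/3.92);
    useful for checking reported tables for internal consistency.
    """
    if not (0 < ci_lo < ci_hi):
        raise ValueError("require 0 < ci_lo < ci_hi")
    b = (math.log(ci_lo) + math.log(ci_hi)) / 2.0
    se = (math.log(ci_hi) - math.log(ci_lo)) / (2.0 * 1.96)
    if se == 0:
        return 1.0 if b == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(b) / se))
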