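"""Published reference estimates used as internal-consistency fixtures.

The univariable MR results reported for the four gut-microbiota taxa with at
least nominal evidence on IgA nephropathy, exactly as printed (OR, 95% CI,
beta, p; Cochran's Q with its p for the IVW rows; Egger intercept with its
p). These numbers cannot be recomputed without the consortium SNP-level
data, but they are internally redundant — the OR is the geometric mean of
its CI bounds, the Wald p follows from the CI, and the heterogeneity p
follows from Q and the instrument count — which makes them useful fixtures
for the reporting and consistency utilities.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReportedMrRow:
    exposure: str
    n_snps: int
    method: str  # ivw | egger | wm
    or_value: float
    ci_lo: float
    ci_hi: float
    beta: float
    pval: float
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    cochran_q: float | None = None
    cochran_q_p: float | None = None


#: Univariable MR results for taxa with nominal evidence on IgA nephropathy.
REPORTED_MR_RESULTS: tuple[ReportedMrRow, ...] = (
    ReportedMrRow("Genus Butyricicoccus", 8, "egger", 3.209, 0.766, 13.455,
                  1.166, 0.162, egger_intercept=0.008, egger_intercept_p=0.905,
                  cochran_q=3.836, cochran_q_p=0.798),
    ReportedMrRow("Genus Butyricicoccus", 8, "wm", 3.075, 1.193, 7.927,
                  1.123, 0.020),
    ReportedMrRow("Genus Butyricicoccus", 8, "ivw", 3.471, 1.671, 7.209,
                  1.244, 0.001),
    ReportedMrRow("Genus Enterorhabdus", 6, "egger", 0.307, 0.055, 1.713,
                  -1.181, 0.249, egger_intercept=0.056, egger_intercept_p=0.652,
                  cochran_q=2.358, cochran_q_p=0.798),
    ReportedMrRow("Genus Enterorhabdus", 6, "wm", 0.377, 0.162, 0.875,
                  -0.976, 0.023),
    ReportedMrRow("Genus Enterorhabdus", 6, "ivw", 0.456, 0.238, 0.875,
                  -0.785, 0.018),
    ReportedMrRow("Family Peptococcaceae", 9, "egger", 1.480, 0.300, 7.296,
                  0.392, 0.645, egger_intercept=-0.097, egger_intercept_p=0.229,
                  cochran_q=6.180, cochran_q_p=0.627),
    ReportedMrRow("Family Peptococcaceae", 9, "wm", 0.569, 0.261, 1.238,
                  -0.565, 0.155),
    ReportedMrRow("Family Peptococcaceae", 9, "ivw", 0.545, 0.307, 0.967,
                  -0.608, 0.038),
    ReportedMrRow("Family Prevotellaceae", 16, "egger", 0.242, 0.034, 1.709,
                  -1.420, 0.177, egger_intercept=0.052, egger_intercept_p=0.462,
                  cochran_q=8.230, cochran_q_p=0.914),
    ReportedMrRow("Family Prevotellaceae", 16, "wm", 0.559, 0.276, 1.130,
                  -0.582, 0.105),
    ReportedMrRow("Family Prevotellaceae", 16, "ivw", 0.499, 0.291, 0.855,
                  -0.695, 0.011),
)

#: The abstract-level headline p for the risk taxon, printed to 4 dp.
BUTYRICICOCCUS_ABSTRACT_P = 0.0008

#: Empirical permutation p-values printed by the multivariable ranking are
#: all exact multiples of 1/101 (100 permutations, add-one rule).
BMA_PERMUTATION_GRANULARITY = 1.0 / 101.0


def ivw_rows() -> list[ReportedMrRow]:
    return [r for r in REPORTED_MR_RESULTS if r.method == "ivw"]
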