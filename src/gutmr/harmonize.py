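"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR needs the SNP-exposure effect (gamma) and SNP-outcome effect
(Gamma) expressed on the same effect allele. Outcome records may report the
swapped allele pair (sign flip), the opposite strand (complement both
alleles), or both. Palindromic SNPs (A/T, C/G) are excluded outright — with
only summary data their strand cannot be resolved — and instruments missing
from the outcome GWAS may be replaced by a high-LD proxy (r2 > 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from .instruments import SelectionConfig
from .summary_io import VALID_ALLELES, GwasSummaryRecord, LdMatrix, SummaryDataset

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP with exposure and outcome effects aligned to one effect allele."""

    rsid: str
    gamma: float
    se_gamma: float
    Gamma_out: float
    se_Gamma: float
    effect_allele: str
    other_allele: str
    eaf: float | None = None
    n_exposure: int | None = None
    is_proxy: bool = False
    proxy_source: str | None = None

    def __post_init__(self) -> None:
        if self.se_gamma <= 0 or self.se_Gamma <= 0:
            raise ValueError(f"{self.rsid}: standard errors must be positive")
        if is_palindromic(self.effect_allele, self.other_allele):
            raise ValueError(f"{self.rsid}: palindromic allele pair")


@dataclass
class HarmonizedSet:
    """Instruments harmonized for one exposure-outcome pair, with a drop log."""

    exposure_label: str
    outcome_label: str
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    drop_log: list[tuple[str, str, str]] = field(default_factory=list)  # rsid, stage, reason

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    def rsids(self) -> list[str]:
        return [inst.rsid for inst in self.instruments]

    def write_drop_log(self, path: str | Path) -> None:
        lines = ["rsid\tstage\treason"]
        lines += [f"{r}\t{s}\t{why}" for r, s, why in self.drop_log]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise ValueError(f"invalid allele pair ({a1!r}, {a2!r})")
    return _COMPLEMENT[a1] == a2


def align_alleles(
    exp_rec: GwasSummaryRecord, out_rec: GwasSummaryRecord
) -> HarmonizedInstrument | str:
    """Align an outcome record to the exposure's effect allele.

    Returns the harmonized instrument, or a reason string on rejection.
    Same orientation keeps the outcome beta; swapped alleles negate it; a
    strand-complemented pair is complemented first and then the same rule
    applies. Any other allele combination is incompatible.
    """
    e1, e2 = exp_rec.effect_allele, exp_rec.other_allele
    o1, o2 = out_rec.effect_allele, out_rec.other_allele
    if is_palindromic(e1, e2) or is_palindromic(o1, o2):
        return "palindromic"

    if (o1, o2) == (e1, e2):
        flip = False
    elif (o1, o2) == (e2, e1):
        flip = True
    else:
        c1, c2 = _COMPLEMENT[o1], _COMPLEMENT[o2]
        if (c1, c2) == (e1, e2):
            flip = False
        elif (c1, c2) == (e2, e1):
            flip = True
        else:
            return "incompatible_alleles"

    return HarmonizedInstrument(
        rsid=exp_rec.rsid,
        gamma=exp_rec.beta,
        se_gamma=exp_rec.se,
        Gamma_out=-out_rec.beta if flip else out_rec.beta,
        se_Gamma=out_rec.se,
        effect_allele=e1,
        other_allele=e2,
        eaf=exp_rec.eaf,
        n_exposure=exp_rec.n,
    )


def find_proxy(
    rsid: str,
    outcome: SummaryDataset,
    ld: LdMatrix,
    config: SelectionConfig,
) -> str | None:
    """Best outcome-present proxy for an instrument absent from the outcome.

    Returns the outcome SNP with maximal r2 to ``rsid`` provided it exceeds
    ``proxy_r2`` (strict); ties break lexicographically. None when no
    candidate qualifies or the SNP is missing from the LD matrix.
    """
    if rsid not in ld:
        logger.info("find_proxy: %s absent from LD matrix", rsid)
        return None
    candidates = [
        (ld.r2_between(rsid, other), other)
        for other in ld.snp_ids
        if other != rsid and other in outcome
    ]
    if not candidates:
        return None
    best_r2 = max(r2 for r2, _ in candidates)
    if best_r2 <= config.proxy_r2:
        return None
    return min(other for r2, other in candidates if r2 == best_r2)


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LdMatrix | None = None,
    config: SelectionConfig | None = None,
) -> HarmonizedSet:
    """Harmonize a selected exposure instrument set against an outcome GWAS.

    For each instrument: substitute a proxy when the SNP is absent from the
    outcome (requires an LD matrix), reject palindromes, align alleles. Every
    drop is recorded as (rsid, stage, reason). Raises when no instrument
    survives.
    """
    config = config or SelectionConfig()
    out = HarmonizedSet(exposure.trait_label, outcome.trait_label)
    for exp_rec in exposure:
        rsid = exp_rec.rsid
        if is_palindromic(exp_rec.effect_allele, exp_rec.other_allele):
            out.drop_log.append((rsid, "palindrome", "palindromic"))
            continue
        proxy_of: str | None = None
        out_rec: GwasSummaryRecord | None = outcome.records.get(rsid)
        if out_rec is None:
            proxy = find_proxy(rsid, outcome, ld, config) if ld is not None else None
            if proxy is None:
                out.drop_log.append((rsid, "proxy", "absent_from_outcome_no_proxy"))
                continue
            # The proxy's own outcome record stands in; its alleles must still
            # harmonize with the exposure record *of the proxy SNP itself* —
            # with an r2-only matrix no phase information exists, so the
            # exposure effect is kept and the proxy's outcome effect is used
            # only when the allele pairs are compatible.
            out_rec = outcome.records[proxy]
            proxy_of = rsid
            if is_palindromic(out_rec.effect_allele, out_rec.other_allele):
                out.drop_log.append((rsid, "proxy", "proxy_palindromic"))
                continue
            aligned = align_alleles(exp_rec, out_rec)
            if isinstance(aligned, str):
                out.drop_log.append((rsid, "proxy", f"proxy_{aligned}"))
                continue
            aligned = replace(aligned, is_proxy=True, proxy_source=rsid,
                              rsid=out_rec.rsid)
            out.instruments.append(aligned)
            continue
        aligned = align_alleles(exp_rec, out_rec)
        if isinstance(aligned, str):
            out.drop_log.append((rsid, "align", aligned))
            continue
        out.instruments.append(aligned)
    if not out.instruments:
        raise ValueError(
            f"no usable instruments for {exposure.trait_label} -> "
            f"{outcome.trait_label}"
        )
    return out
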