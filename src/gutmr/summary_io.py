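"""Reading, validation and writing of GWAS summary statistics and LD matrices.

File dialect: tab-separated UTF-8 with one header line; missing optional fields
are written as ``.``. Positions are 1-based; alleles are stored upper-case.
Only biallelic SNVs are accepted — indels and multi-allelic records are rejected
at read time because allele-complement logic downstream is defined on single
nucleotides only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order of the summary-statistic TSV.
CANONICAL_COLUMNS = (
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval", "eaf", "n",
)

MISSING = "."


class SummaryIOError(ValueError):
    """Raised for malformed summary-statistic or LD-matrix files."""


@dataclass(frozen=True)
class GwasSummaryRecord:
    """One SNP's association summary for one trait.

    ``beta`` is the per-effect-allele effect: log-odds for binary traits,
    SD units for (rank-normalized) abundance traits.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def validate(self) -> str | None:
        """Return a machine-readable reason code if invalid, else None."""
        if self.effect_allele not in VALID_ALLELES:
            return "invalid_effect_allele"
        if self.other_allele not in VALID_ALLELES:
            return "invalid_other_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not math.isfinite(self.beta):
            return "non_finite_beta"
        if not (math.isfinite(self.se) and self.se > 0):
            return "non_positive_se"
        if not (0 < self.pval <= 1):
            return "pval_out_of_range"
        if self.eaf is not None and not (0 < self.eaf < 1):
            return "eaf_out_of_range"
        if self.n is not None and self.n <= 0:
            return "non_positive_n"
        if self.pos <= 0:
            return "non_positive_pos"
        return None

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class SummaryDataset:
    """A labelled collection of per-SNP summary records for one trait.

    rsids are unique within a dataset; duplicates are a hard error at
    construction because downstream stages key instruments by rsid.
    """

    trait_label: str
    role: str  # "exposure" | "outcome"
    records: dict[str, GwasSummaryRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("exposure", "outcome"):
            raise ValueError(f"role must be 'exposure' or 'outcome', got {self.role!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __getitem__(self, rsid: str) -> GwasSummaryRecord:
        return self.records[rsid]

    def __iter__(self):
        return iter(self.records.values())

    def add(self, rec: GwasSummaryRecord) -> None:
        if rec.rsid in self.records:
            raise SummaryIOError(f"duplicate rsid {rec.rsid!r} in {self.trait_label!r}")
        self.records[rec.rsid] = rec

    def subset(self, rsids: Iterable[str]) -> "SummaryDataset":
        keep = [r for r in rsids if r in self.records]
        return SummaryDataset(
            self.trait_label, self.role, {r: self.records[r] for r in keep}
        )

    def with_role(self, role: str) -> "SummaryDataset":
        return SummaryDataset(self.trait_label, role, dict(self.records))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": r.rsid, "chrom": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "beta": r.beta, "se": r.se, "pval": r.pval,
                "eaf": r.eaf, "n": r.n,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass
class LdMatrix:
    """Pairwise LD (r-squared) over an ordered set of SNPs.

    Symmetric with unit diagonal; entries in [0, 1]. ``positions`` optionally
    carries (chrom, pos) per SNP so clumping can apply a physical window.
    """

    snp_ids: list[str]
    r2: np.ndarray
    positions: dict[str, tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise SummaryIOError(
                f"LD matrix shape {self.r2.shape} does not match {k} SNP ids"
            )
        if k and not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise SummaryIOError("LD matrix diagonal must be exactly 1")
        if k and not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise SummaryIOError("LD matrix must be symmetric")
        if k and ((self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-8).any()):
            raise SummaryIOError("LD r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != k:
            raise SummaryIOError("duplicate SNP ids in LD matrix")

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


def _parse_float(value: str, col: str) -> float | None:
    if value == MISSING or value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise SummaryIOError(f"cannot parse {col}={value!r} as float") from exc


def read_summary_tsv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
    role: str = "exposure",
) -> tuple[SummaryDataset, list[tuple[str, str]]]:
    """Read a GWAS summary-statistic TSV into a validated :class:`SummaryDataset`.

    Parameters
    ----------
    column_map
        Mapping from canonical field name to the source file's column name;
        ``None`` assumes the canonical header. ``eaf`` and ``n`` are optional.
    trait_label, role
        Attached to the returned dataset.

    Returns
    -------
    (dataset, rejections)
        ``rejections`` lists ``(rsid_or_line, reason_code)`` for every row
        failing a record invariant; duplicate rsids raise instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cmap = dict(column_map) if column_map else {c: c for c in CANONICAL_COLUMNS}
    required = [f for f in CANONICAL_COLUMNS if f not in ("eaf", "n")]
    for fld in required:
        src = cmap.get(fld, fld)
        if src not in df.columns:
            raise SummaryIOError(f"mapped column {src!r} for field {fld!r} missing")

    dataset = SummaryDataset(trait_label or path.stem, role)
    rejections: list[tuple[str, str]] = []
    for idx, row in df.iterrows():
        rsid = row[cmap.get("rsid", "rsid")].strip()
        a1 = row[cmap.get("effect_allele", "effect_allele")].strip().upper()
        a2 = row[cmap.get("other_allele", "other_allele")].strip().upper()
        if len(a1) != 1 or len(a2) != 1:
            rejections.append((rsid or f"line{idx + 2}", "not_a_snv"))
            continue
        try:
            pos = int(row[cmap.get("pos", "pos")])
        except ValueError:
            rejections.append((rsid or f"line{idx + 2}", "invalid_pos"))
            continue
        eaf_col = cmap.get("eaf", "eaf")
        n_col = cmap.get("n", "n")
        eaf = _parse_float(row[eaf_col], "eaf") if eaf_col in df.columns else None
        n_raw = _parse_float(row[n_col], "n") if n_col in df.columns else None
        rec = GwasSummaryRecord(
            rsid=rsid,
            chrom=str(row[cmap.get("chrom", "chrom")]).strip(),
            pos=pos,
            effect_allele=a1,
            other_allele=a2,
            beta=_parse_float(row[cmap.get("beta", "beta")], "beta"),
            se=_parse_float(row[cmap.get("se", "se")], "se"),
            pval=_parse_float(row[cmap.get("pval", "pval")], "pval"),
            eaf=eaf,
            n=int(n_raw) if n_raw is not None else None,
        )
        reason = rec.validate()
        if reason is not None:
            rejections.append((rsid or f"line{idx + 2}", reason))
            continue
        dataset.add(rec)  # raises on duplicate rsid
    return dataset, rejections


def write_summary_tsv(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset as canonical TSV; :func:`read_summary_tsv` inverts it."""
    path = Path(path)
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for rec in dataset:
        lines.append(
            "\t".join(
                [
                    rec.rsid, rec.chrom, str(rec.pos),
                    rec.effect_allele, rec.other_allele,
                    repr(rec.beta), repr(rec.se), repr(rec.pval),
                    MISSING if rec.eaf is None else repr(rec.eaf),
                    MISSING if rec.n is None else str(rec.n),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read a labelled square r-squared table (TSV, row and column labels)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise SummaryIOError("LD table row labels differ from column labels")
    return LdMatrix(snp_ids=[str(s) for s in df.index], r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    """Write an :class:`LdMatrix` as a labelled square TSV."""
    df = pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids)
    df.to_csv(path, sep="\t")
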