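"""Read, validate and write tab-delimited GWAS summary statistics and result tables.

The canonical on-disk dialect is tab-separated text with header
``rsid effect_allele other_allele eaf beta se pval n`` and ``NA`` for missing
values. Files in other column layouts are read through a :class:`ColumnDialect`
that remaps headers onto the canonical field names.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Smallest p-value admitted; input zeros are clamped here (downstream code
#: takes -log p).
P_FLOOR = 1e-300

CANONICAL_FIELDS = ("rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")
MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass(frozen=True, slots=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (log odds ratio for
    binary traits), ``se`` its standard error, ``eaf`` the effect-allele
    frequency and ``n`` the study sample size (both optional).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def validate(self) -> str | None:
        """Return a reason string if any invariant is violated, else None."""
        if not self.rsid:
            return "empty rsid"
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "non-SNP allele"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not math.isfinite(self.beta):
            return "non-finite beta"
        if not (math.isfinite(self.se) and self.se > 0):
            return "non-positive se"
        if not (0 < self.pval <= 1):
            return "p-value outside (0, 1]"
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return "eaf outside [0, 1]"
        if self.n is not None and self.n <= 0:
            return "non-positive n"
        return None


@dataclass(frozen=True)
class ColumnDialect:
    """Mapping from canonical field names to the column headers of a source file.

    Every mandatory canonical field must be mapped; ``eaf`` and ``n`` may be
    absent. ``na_values`` is the missing-value sentinel.
    """

    columns: dict[str, str] = field(
        default_factory=lambda: {f: f for f in CANONICAL_FIELDS}
    )
    na_values: str = "NA"

    def __post_init__(self) -> None:
        missing = [f for f in MANDATORY_FIELDS if f not in self.columns]
        if missing:
            raise ValueError(f"dialect leaves mandatory fields unmapped: {missing}")


CANONICAL_DIALECT = ColumnDialect()


class SummaryStatError(Exception):
    """Fatal condition while reading or writing summary statistics."""


class RecordList(list):
    """A list of records that also carries the read report.

    Attributes ``n_input``, ``n_dropped`` and ``dropped`` (list of
    ``(rsid, reason)``) satisfy ``n_input == len(self) + n_dropped``.
    """

    def __init__(self, records: Iterable[SummaryStatRecord], dropped: list[tuple[str, str]], n_input: int):
        super().__init__(records)
        self.dropped = dropped
        self.n_dropped = len(dropped)
        self.n_input = n_input


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_summary_stats(path: str | Path, dialect: ColumnDialect | None = None) -> RecordList:
    """Read one trait's summary statistics, validating every row.

    Rows violating record invariants (bad alleles, se <= 0, out-of-range eaf or
    p, duplicate rsid) are dropped, counted and logged rather than fatal;
    an unreadable file, an unmapped mandatory column or zero surviving rows is
    fatal. Alleles are upper-cased; p-values of exactly 0 are clamped to
    ``P_FLOOR`` with a warning.
    """
    dialect = dialect or CANONICAL_DIALECT
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=[dialect.na_values], keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SummaryStatError(f"cannot read summary statistics from {path}: {exc}") from exc

    missing_cols = [dialect.columns[f] for f in MANDATORY_FIELDS if dialect.columns[f] not in df.columns]
    if missing_cols:
        raise SummaryStatError(f"{path}: mandatory columns absent from header: {missing_cols}")

    records: list[SummaryStatRecord] = []
    dropped: list[tuple[str, str]] = []
    seen: set[str] = set()
    n_clamped = 0

    def col(f: str):
        name = dialect.columns.get(f)
        return name if name is not None and name in df.columns else None

    for _, row in df.iterrows():
        rsid = str(row[col("rsid")]).strip() if not pd.isna(row[col("rsid")]) else ""
        try:
            eaf_col, n_col = col("eaf"), col("n")
            eaf = _parse_optional_float(row[eaf_col]) if eaf_col and not pd.isna(row[eaf_col]) else None
            n_raw = _parse_optional_float(row[n_col]) if n_col and not pd.isna(row[n_col]) else None
            pval = float(row[col("pval")])
            if pval == 0.0:
                pval = P_FLOOR
                n_clamped += 1
            rec = SummaryStatRecord(
                rsid=rsid,
                effect_allele=str(row[col("effect_allele")]).strip().upper(),
                other_allele=str(row[col("other_allele")]).strip().upper(),
                beta=float(row[col("beta")]),
                se=float(row[col("se")]),
                pval=pval,
                eaf=eaf,
                n=int(n_raw) if n_raw is not None else None,
            )
        except (TypeError, ValueError):
            dropped.append((rsid, "unparsable numeric field"))
            continue
        reason = rec.validate()
        if reason is None and rec.rsid in seen:
            reason = "duplicate rsid"
        if reason is not None:
            dropped.append((rsid, reason))
            continue
        seen.add(rec.rsid)
        records.append(rec)

    if n_clamped:
        logger.warning("%s: clamped %d zero p-values to %g", path, n_clamped, P_FLOOR)
    if dropped:
        logger.warning("%s: dropped %d of %d rows failing validation", path, len(dropped), len(df))
    if not records:
        raise SummaryStatError(f"{path}: no valid summary-statistic rows")
    return RecordList(records, dropped, n_input=len(df))


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.12g}"
    return str(value)


def write_summary_stats(records: Sequence[SummaryStatRecord], path: str | Path) -> Path:
    """Write records in the canonical dialect (12 significant digits, NA for missing)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_FIELDS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in (r.rsid, r.effect_allele, r.other_allele, r.eaf, r.beta, r.se, r.pval, r.n)
                )
                + "\n"
            )
    return path


def _write_table(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")
    return path


def write_results_tables(bundle, out_dir: str | Path) -> list[Path]:
    """Write the full result-table set of an analysis bundle.

    Emits tab-delimited ``estimates.tsv`` (one row per method),
    ``heterogeneity.tsv`` (Cochran's Q per method), ``pleiotropy.tsv`` (Egger
    intercept), ``single_snp.tsv`` (per-SNP Wald ratios) and
    ``leave_one_out.tsv``. Returns the written paths.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise SummaryStatError(f"cannot write to {out_dir}: {exc}") from exc

    paths: list[Path] = []

    est_rows = [
        {
            "method": e.method, "nsnp": e.n_snps, "beta": e.beta, "se": e.se,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "or": e.or_,
            "or_ci_low": e.or_ci_low, "or_ci_high": e.or_ci_high, "pval": e.pval,
        }
        for e in bundle.estimates
    ]
    paths.append(_write_table(pd.DataFrame(est_rows), out_dir / "estimates.tsv"))

    het_rows = [
        {"method": h.method, "Q": h.q, "Q_df": h.q_df, "Q_pval": h.q_pval}
        for h in bundle.heterogeneity
    ]
    paths.append(_write_table(pd.DataFrame(het_rows), out_dir / "heterogeneity.tsv"))

    p = bundle.pleiotropy
    pleio_rows = [] if p is None else [{
        "intercept": p.intercept, "se": p.se, "ci_low": p.ci_low,
        "ci_high": p.ci_high, "pval": p.pval,
    }]
    paths.append(_write_table(
        pd.DataFrame(pleio_rows, columns=["intercept", "se", "ci_low", "ci_high", "pval"]),
        out_dir / "pleiotropy.tsv"))

    snp_rows = [
        {"rsid": rsid, "ratio": ratio, "se": se}
        for rsid, ratio, se in bundle.wald_table
    ]
    paths.append(_write_table(
        pd.DataFrame(snp_rows, columns=["rsid", "ratio", "se"]), out_dir / "single_snp.tsv"))

    loo = bundle.leave_one_out
    loo_rows = []
    if loo is not None:
        loo_rows = [
            {"omitted": rsid, "beta": e.beta, "se": e.se, "ci_low": e.ci_low,
             "ci_high": e.ci_high, "pval": e.pval, "nsnp": e.n_snps}
            for rsid, e in loo.estimates
        ]
        a = loo.full
        loo_rows.append({"omitted": "none (all SNPs)", "beta": a.beta, "se": a.se,
                         "ci_low": a.ci_low, "ci_high": a.ci_high, "pval": a.pval,
                         "nsnp": a.n_snps})
    paths.append(_write_table(
        pd.DataFrame(loo_rows, columns=["omitted", "beta", "se", "ci_low", "ci_high", "pval", "nsnp"]),
        out_dir / "leave_one_out.tsv"))
    return paths
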