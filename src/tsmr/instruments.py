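"""Select independent, strong, confounder-free instruments from exposure GWAS.

The selection pipeline runs in a fixed order: genome-wide significance filter
(p < 5e-8) → confounder-blacklist exclusion → greedy LD clumping (r² < 0.001,
lowest p first). Instruments missing from the outcome study may be replaced by
high-LD proxies (r² > 0.8). Instrument strength is summarised by per-SNP F
statistics (β/se)² and, when effect-allele frequencies are available, by the
variance explained R² = Σ 2·eaf(1−eaf)·β² and the aggregate
F = ((n−k−1)/k)·R²/(1−R²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .summary_io import SummaryStatRecord

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8


class SelectionError(Exception):
    pass


@dataclass(frozen=True)
class SelectionConfig:
    p_threshold: float = GENOME_WIDE_P
    clump_r2: float = 0.001
    proxy_r2_min: float = 0.8
    palindrome_maf_threshold: float = 0.3
    confounder_blacklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0 <= self.clump_r2 < self.proxy_r2_min <= 1):
            raise ValueError("need 0 <= clump_r2 < proxy_r2_min <= 1")


class LDTable:
    """Symmetric pairwise r² lookup; absent pairs are treated as unlinked (r² = 0)."""

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[frozenset[str], float] = {}
        for a, b, r2 in pairs:
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValueError(f"r² must lie in [0, 1], got {r2}")
        if a != b:
            self._r2[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_file(cls, path: str | Path) -> "LDTable":
        """Read a tab-delimited ``rsid_a rsid_b r2`` table."""
        df = pd.read_csv(path, sep="\t")
        return cls(zip(df["rsid_a"], df["rsid_b"], df["r2"].astype(float)))


@dataclass(frozen=True, slots=True)
class InstrumentStrength:
    per_snp_f: tuple[float, ...]
    mean_f: float
    r2_explained: float | None
    aggregate_f: float | None


def filter_genome_wide(
    records: Sequence[SummaryStatRecord], p_threshold: float = GENOME_WIDE_P
) -> list[SummaryStatRecord]:
    """Keep records with p strictly below the genome-wide threshold, order preserved."""
    kept = [r for r in records if r.pval < p_threshold]
    if not kept:
        raise SelectionError(f"no SNP passes the significance threshold p < {p_threshold:g}")
    return kept


def ld_clump(
    records: Sequence[SummaryStatRecord],
    ld: LDTable,
    clump_r2: float = 0.001,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping: lowest-p index SNPs claim and discard their r² > threshold neighbours.

    Repeatedly takes the smallest-p unclaimed SNP as an index (equal p broken
    lexicographically by rsid, for determinism) and discards every remaining
    SNP with r² strictly greater than ``clump_r2`` to any retained index.
    Retained SNPs are returned in their original input order.
    """
    order = sorted(records, key=lambda r: (r.pval, r.rsid))
    retained: list[SummaryStatRecord] = []
    for cand in order:
        if all(ld.r2(cand.rsid, kept.rsid) <= clump_r2 for kept in retained):
            retained.append(cand)
    retained_ids = {r.rsid for r in retained}
    return [r for r in records if r.rsid in retained_ids]


def exclude_confounders(
    records: Sequence[SummaryStatRecord], blacklist: Iterable[str]
) -> list[SummaryStatRecord]:
    """Drop records whose rsid appears on the confounder blacklist (idempotent)."""
    blacklist = set(blacklist)
    removed = [r.rsid for r in records if r.rsid in blacklist]
    if removed:
        logger.info("excluded %d blacklisted confounder SNPs: %s", len(removed), removed)
    return [r for r in records if r.rsid not in blacklist]


def substitute_proxies(
    requested: Iterable[str],
    available: Iterable[str],
    proxies: Sequence[tuple[str, str, float]],
    proxy_r2_min: float = 0.8,
) -> tuple[dict[str, str], list[str]]:
    """Map each requested rsid to itself or its best admissible proxy.

    A requested SNP absent from ``available`` is replaced by its highest-r²
    proxy with r² strictly greater than ``proxy_r2_min`` that is itself
    available; SNPs with no admissible proxy are returned as dropped.
    """
    available = set(available)
    best: dict[str, tuple[float, str]] = {}
    for missing_rsid, proxy_rsid, r2 in proxies:
        if r2 > proxy_r2_min and proxy_rsid in available:
            cur = best.get(missing_rsid)
            if cur is None or r2 > cur[0]:
                best[missing_rsid] = (r2, proxy_rsid)
    mapping: dict[str, str] = {}
    dropped: list[str] = []
    for rsid in requested:
        if rsid in available:
            mapping[rsid] = rsid
        elif rsid in best:
            mapping[rsid] = best[rsid][1]
        else:
            dropped.append(rsid)
    if dropped:
        logger.info("no admissible proxy for %d SNPs: %s", len(dropped), dropped)
    return mapping, dropped


def instrument_strength(
    records: Sequence[SummaryStatRecord],
    n_exposure: int | None = None,
    k: int | None = None,
) -> InstrumentStrength:
    """Instrument-strength summary: per-SNP F = (β/se)², R² explained, aggregate F.

    The aggregate F uses ((n−k−1)/k)·R²/(1−R²) with k instruments and exposure
    sample size n; it is reported as unavailable when any eaf or n is missing.
    """
    if not records:
        raise SelectionError("instrument strength of an empty set is undefined")
    per_f = tuple((r.beta / r.se) ** 2 for r in records)
    mean_f = sum(per_f) / len(per_f)
    k = k if k is not None else len(records)
    if any(r.eaf is None for r in records):
        return InstrumentStrength(per_f, mean_f, None, None)
    r2 = sum(2.0 * r.eaf * (1.0 - r.eaf) * r.beta**2 for r in records)
    if n_exposure is None:
        n_candidates = {r.n for r in records if r.n is not None}
        n_exposure = max(n_candidates) if n_candidates else None
    if n_exposure is None or r2 >= 1:
        return InstrumentStrength(per_f, mean_f, r2, None)
    agg = ((n_exposure - k - 1) / k) * r2 / (1.0 - r2)
    return InstrumentStrength(per_f, mean_f, r2, agg)


def read_blacklist(path: str | Path) -> frozenset[str]:
    """Read a confounder blacklist: one rsid per line, '#' comments allowed."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line)
    return frozenset(out)
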