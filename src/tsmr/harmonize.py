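"""Align exposure and outcome summary statistics to a shared effect allele.

Two-sample MR needs each SNP's exposure effect γ and outcome effect α to refer
to the same allele. Outcome records whose alleles are swapped relative to the
exposure are sign-flipped; records reported on the opposite strand are
complemented first. Palindromic SNPs (A/T or C/G) cannot be strand-resolved
from alleles alone and are dropped when their minor-allele frequency exceeds a
threshold (default 0.3), where the frequency no longer identifies the allele.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .summary_io import SummaryStatRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class HarmonizationError(Exception):
    pass


@dataclass(frozen=True, slots=True)
class HarmonizedInstrument:
    """A SNP's aligned exposure effect γ ± σ_γ and outcome effect α ± σ_α."""

    rsid: str
    effect_allele: str
    other_allele: str
    gamma: float
    se_gamma: float
    alpha: float
    se_alpha: float
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    pval_exposure: float | None = None
    pval_outcome: float | None = None
    flipped: bool = False
    palindromic: bool = False


def is_palindromic(a1: str, a2: str) -> bool:
    return (a1, a2) in PALINDROMIC_PAIRS


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
) -> tuple[list[HarmonizedInstrument], list[tuple[str, str]]]:
    """Join exposure and outcome records on rsid and align outcome effects.

    For each shared SNP: identical allele pairs pass through unchanged; swapped
    pairs get the outcome beta negated and eaf mirrored (``flipped``); pairs
    matching only after strand complement are complemented and then treated the
    same; anything else is excluded with a reason. Returns the instruments in
    exposure order plus the exclusion report ``(rsid, reason)``.
    """
    out_by_rsid = {r.rsid: r for r in outcome}
    instruments: list[HarmonizedInstrument] = []
    exclusions: list[tuple[str, str]] = []
    for exp in exposure:
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            continue  # not part of the rsid intersection
        e1, e2 = exp.effect_allele, exp.other_allele
        o1, o2 = out.effect_allele, out.other_allele
        palindromic = is_palindromic(e1, e2)

        if not palindromic and (o1, o2) not in {(e1, e2), (e2, e1)}:
            c1, c2 = COMPLEMENT[o1], COMPLEMENT[o2]
            if (c1, c2) in {(e1, e2), (e2, e1)}:
                o1, o2 = c1, c2
        if (o1, o2) == (e1, e2):
            alpha, eaf_out, flipped = out.beta, out.eaf, False
        elif (o1, o2) == (e2, e1):
            alpha = -out.beta
            eaf_out = None if out.eaf is None else 1.0 - out.eaf
            flipped = True
        else:
            exclusions.append((exp.rsid, f"irreconcilable alleles {e1}/{e2} vs {out.effect_allele}/{out.other_allele}"))
            continue
        instruments.append(
            HarmonizedInstrument(
                rsid=exp.rsid, effect_allele=e1, other_allele=e2,
                gamma=exp.beta, se_gamma=exp.se,
                alpha=alpha, se_alpha=out.se,
                eaf_exposure=exp.eaf, eaf_outcome=eaf_out,
                pval_exposure=exp.pval, pval_outcome=out.pval,
                flipped=flipped, palindromic=palindromic,
            )
        )
    if not instruments:
        raise HarmonizationError("no instruments could be harmonized")
    return instruments, exclusions


def drop_palindromic(
    instruments: Sequence[HarmonizedInstrument],
    maf_threshold: float = 0.3,
) -> tuple[list[HarmonizedInstrument], list[tuple[str, str]]]:
    """Remove palindromic instruments whose exposure-side MAF exceeds the threshold.

    Near-0.5 frequencies cannot tell the two strands apart, so A/T and C/G
    SNPs with min(eaf, 1−eaf) > ``maf_threshold`` are excluded; a palindromic
    SNP with no eaf at all is excluded as strand-indeterminate. Non-palindromic
    instruments always pass.
    """
    kept: list[HarmonizedInstrument] = []
    excluded: list[tuple[str, str]] = []
    for inst in instruments:
        if not inst.palindromic:
            kept.append(inst)
            continue
        if inst.eaf_exposure is None:
            excluded.append((inst.rsid, "indeterminate strand"))
            continue
        maf = min(inst.eaf_exposure, 1.0 - inst.eaf_exposure)
        if maf > maf_threshold:
            excluded.append((inst.rsid, f"palindromic with MAF {maf:.3g} > {maf_threshold:g}"))
        else:
            kept.append(inst)
    return kept, excluded
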