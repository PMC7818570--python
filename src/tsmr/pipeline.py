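"""End-to-end orchestration: selection → harmonization → estimation → sensitivity.

`run_full_analysis` executes the fixed stage order (significance filter,
confounder exclusion, LD clumping, proxy substitution, allele harmonization,
palindromic-SNP removal, estimator battery) with a per-stage exclusion ledger,
writes all result tables plus a machine-readable run log, and is bit-for-bit
reproducible given the seed.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import estimators as est
from .harmonize import HarmonizedInstrument, drop_palindromic, harmonize
from .instruments import (
    LDTable,
    InstrumentStrength,
    SelectionConfig,
    exclude_confounders,
    filter_genome_wide,
    instrument_strength,
    ld_clump,
    read_blacklist,
    substitute_proxies,
)
from .summary_io import (
    SummaryStatRecord,
    read_summary_stats,
    write_results_tables,
)

logger = logging.getLogger(__name__)

#: estimator registry: name -> (callable signature kind, minimum J)
STOCHASTIC_ESTIMATORS = frozenset(
    {"weighted_median", "penalized_weighted_median", "simple_mode", "weighted_mode"}
)
DEFAULT_ESTIMATORS = (
    "ivw",
    "ivw_fixed",
    "mr_egger",
    "maximum_likelihood",
    "weighted_median",
    "penalized_weighted_median",
    "simple_mode",
    "weighted_mode",
    "raps",
)


class PipelineError(Exception):
    """Fatal stage failure; carries the stage name and the ledger so far."""

    def __init__(self, stage: str, message: str, ledger: list | None = None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.ledger = ledger or []


@dataclass(frozen=True)
class RunConfig:
    exposure: str
    outcome: str
    out_dir: str = "tsmr_out"
    ld: str | None = None
    proxies: str | None = None
    blacklist: str | None = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    proxy_r2_min: float = 0.8
    palindrome_maf_threshold: float = 0.3
    estimators: tuple[str, ...] = DEFAULT_ESTIMATORS
    effects_model: str = "random_multiplicative"
    n_boot: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.estimators) - set(DEFAULT_ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")
        needs_seed = STOCHASTIC_ESTIMATORS & set(self.estimators)
        if needs_seed and self.n_boot > 0 and self.seed is None:
            raise ValueError(
                f"a seed is required for stochastic estimators {sorted(needs_seed)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "estimators" in raw:
            raw["estimators"] = tuple(raw["estimators"])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["estimators"] = list(self.estimators)
        return d


@dataclass
class AnalysisBundle:
    """Everything one run produces, ready for `summary_io.write_results_tables`."""

    estimates: list[est.MREstimate]
    pleiotropy: est.PleiotropyResult | None
    heterogeneity: list[est.HeterogeneityResult]
    wald_table: list[tuple[str, float, float]]
    leave_one_out: est.LeaveOneOutResult | None
    strength: InstrumentStrength | None
    instruments: list[HarmonizedInstrument]
    ledger: list[dict]
    config: RunConfig | None = None

    @property
    def n_instruments(self) -> int:
        return len(self.instruments)


def _stage(ledger: list[dict], name: str, n_in: int, n_out: int, exclusions=()) -> None:
    ledger.append({
        "stage": name, "n_in": n_in, "n_out": n_out,
        "exclusions": [list(x) for x in exclusions],
    })
    logger.info("stage %-22s %4d -> %4d", name, n_in, n_out)


def select_instruments(
    exposure: list[SummaryStatRecord],
    outcome_rsids: set[str],
    selection: SelectionConfig,
    ld: LDTable,
    proxies: list[tuple[str, str, float]],
    ledger: list[dict],
) -> tuple[list[SummaryStatRecord], dict[str, str]]:
    """Fixed-order selection: p-filter → confounder exclusion → clumping → proxies."""
    try:
        sig = filter_genome_wide(exposure, selection.p_threshold)
    except Exception as exc:
        raise PipelineError("significance_filter", str(exc), ledger) from exc
    _stage(ledger, "significance_filter", len(exposure), len(sig),
           [(r.rsid, "p >= threshold") for r in exposure if r.pval >= selection.p_threshold])

    no_conf = exclude_confounders(sig, selection.confounder_blacklist)
    _stage(ledger, "confounder_exclusion", len(sig), len(no_conf),
           [(r.rsid, "blacklisted confounder") for r in sig
            if r.rsid in selection.confounder_blacklist])

    clumped = ld_clump(no_conf, ld, selection.clump_r2)
    kept = {r.rsid for r in clumped}
    _stage(ledger, "ld_clumping", len(no_conf), len(clumped),
           [(r.rsid, "clumped (r2 above threshold)") for r in no_conf if r.rsid not in kept])

    mapping, dropped = substitute_proxies(
        [r.rsid for r in clumped], outcome_rsids, proxies, selection.proxy_r2_min
    )
    by_rsid = {r.rsid: r for r in exposure}
    selected: list[SummaryStatRecord] = []
    exclusions = [(r, "absent from outcome, no admissible proxy") for r in dropped]
    taken: set[str] = set()
    for r in clumped:
        used = mapping.get(r.rsid)
        if used is None:
            continue
        if used in taken:
            exclusions.append((r.rsid, f"proxy {used} already used as an instrument"))
            continue
        if used == r.rsid:
            selected.append(r)
            taken.add(used)
        elif used in by_rsid:
            selected.append(by_rsid[used])
            taken.add(used)
        else:
            exclusions.append((r.rsid, f"proxy {used} absent from exposure data"))
    _stage(ledger, "proxy_substitution", len(clumped), len(selected), exclusions)
    if not selected:
        raise PipelineError("proxy_substitution", "no instruments survive selection", ledger)
    return selected, mapping


def estimate_all(
    instruments: list[HarmonizedInstrument],
    which: tuple[str, ...] = DEFAULT_ESTIMATORS,
    effects_model: str = "random_multiplicative",
    n_boot: int = 1000,
    seed: int | None = None,
) -> AnalysisBundle:
    """Run the estimator battery on harmonized instruments.

    Estimators whose preconditions fail (too few SNPs, no root) are skipped
    with a log line rather than aborting the run. Bootstrap seeds are spawned
    deterministically from ``seed``.
    """
    seeds = {}
    if seed is not None:
        children = np.random.SeedSequence(seed).spawn(len(STOCHASTIC_ESTIMATORS))
        seeds = dict(zip(sorted(STOCHASTIC_ESTIMATORS), children))

    def boot_seed(name: str) -> int | None:
        ss = seeds.get(name)
        return int(ss.generate_state(1)[0] % (2**31)) if ss is not None else None

    estimates: list[est.MREstimate] = []
    pleio = None
    het: list[est.HeterogeneityResult] = []
    calls = {
        "ivw": lambda: est.ivw(instruments, effects_model=effects_model),
        "ivw_fixed": lambda: est.ivw(instruments, effects_model="fixed"),
        "maximum_likelihood": lambda: est.maximum_likelihood(instruments),
        "weighted_median": lambda: est.weighted_median(
            instruments, penalized=False, n_boot=n_boot, seed=boot_seed("weighted_median")),
        "penalized_weighted_median": lambda: est.weighted_median(
            instruments, penalized=True, n_boot=n_boot,
            seed=boot_seed("penalized_weighted_median")),
        "simple_mode": lambda: est.mode_estimator(
            instruments, weighted=False, n_boot=n_boot, seed=boot_seed("simple_mode")),
        "weighted_mode": lambda: est.mode_estimator(
            instruments, weighted=True, n_boot=n_boot, seed=boot_seed("weighted_mode")),
        "raps": lambda: est.raps(instruments),
    }
    for name in which:
        if name == "mr_egger":
            try:
                slope, pleio = est.mr_egger(instruments)
                estimates.append(slope)
                het.append(est.cochrans_q(
                    instruments, slope.beta, n_params=2, intercept=pleio.intercept))
            except est.EstimatorError as exc:
                logger.warning("MR-Egger unavailable: %s", exc)
            continue
        try:
            estimates.append(calls[name]())
        except est.EstimatorError as exc:
            logger.warning("%s unavailable: %s", name, exc)

    ivw_est = next((e for e in estimates if e.method.startswith(("IVW", "Wald"))), None)
    if ivw_est is not None and len(instruments) >= 2:
        try:
            het.insert(0, est.cochrans_q(instruments, ivw_est.beta, n_params=1))
        except est.EstimatorError as exc:
            logger.warning("IVW heterogeneity unavailable: %s", exc)

    wald = est.wald_ratios(instruments)
    loo = None
    if len(instruments) >= 3 and ivw_est is not None:
        loo = est.leave_one_out(instruments, est.ivw, effects_model=effects_model)

    return AnalysisBundle(
        estimates=estimates, pleiotropy=pleio, heterogeneity=het,
        wald_table=wald, leave_one_out=loo, strength=None,
        instruments=list(instruments), ledger=[],
    )


def run_full_analysis(config: RunConfig) -> AnalysisBundle:
    """Execute the whole pipeline from summary-statistic files to result tables."""
    ledger: list[dict] = []
    try:
        exposure = read_summary_stats(config.exposure)
        outcome = read_summary_stats(config.outcome)
    except Exception as exc:
        raise PipelineError("input", str(exc), ledger) from exc
    _stage(ledger, "read_exposure", exposure.n_input, len(exposure), exposure.dropped)
    _stage(ledger, "read_outcome", outcome.n_input, len(outcome), outcome.dropped)

    blacklist = read_blacklist(config.blacklist) if config.blacklist else frozenset()
    selection = SelectionConfig(
        p_threshold=config.p_threshold, clump_r2=config.clump_r2,
        proxy_r2_min=config.proxy_r2_min,
        palindrome_maf_threshold=config.palindrome_maf_threshold,
        confounder_blacklist=blacklist,
    )
    ld = LDTable.from_file(config.ld) if config.ld else LDTable()
    proxies: list[tuple[str, str, float]] = []
    if config.proxies:
        import pandas as pd

        pdf = pd.read_csv(config.proxies, sep="\t")
        proxies = list(zip(pdf["rsid"], pdf["proxy_rsid"], pdf["r2"].astype(float)))

    selected, _ = select_instruments(
        exposure, {r.rsid for r in outcome}, selection, ld, proxies, ledger)

    try:
        harmonized, excl = harmonize(selected, outcome)
    except Exception as exc:
        raise PipelineError("harmonization", str(exc), ledger) from exc
    _stage(ledger, "harmonization", len(selected), len(harmonized), excl)

    instruments, pal_excl = drop_palindromic(harmonized, selection.palindrome_maf_threshold)
    _stage(ledger, "palindromic_filter", len(harmonized), len(instruments), pal_excl)
    if not instruments:
        raise PipelineError("palindromic_filter", "no instruments remain", ledger)

    bundle = estimate_all(
        instruments, which=config.estimators, effects_model=config.effects_model,
        n_boot=config.n_boot, seed=config.seed,
    )
    final_ids = {i.rsid for i in instruments}
    strength_records = [r for r in selected if r.rsid in final_ids]
    bundle.strength = instrument_strength(strength_records)
    bundle.ledger = ledger
    bundle.config = config

    out_dir = Path(config.out_dir)
    write_results_tables(bundle, out_dir)
    _write_strength_table(bundle.strength, strength_records, out_dir / "instrument_strength.tsv")
    _write_run_log(bundle, out_dir / "run_log.yaml")
    return bundle


def _write_strength_table(strength: InstrumentStrength, records, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tf_stat\n")
        for r, f in zip(records, strength.per_snp_f):
            fh.write(f"{r.rsid}\t{f:.12g}\n")
        fh.write(f"# mean_f={strength.mean_f:.12g}\n")
        if strength.r2_explained is not None:
            fh.write(f"# r2_explained={strength.r2_explained:.12g}\n")
        if strength.aggregate_f is not None:
            fh.write(f"# aggregate_f={strength.aggregate_f:.12g}\n")


def _write_run_log(bundle: AnalysisBundle, path: Path) -> None:
    log = {
        "tsmr_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": bundle.config.to_dict() if bundle.config else None,
        "seed": bundle.config.seed if bundle.config else None,
        "n_instruments": bundle.n_instruments,
        "stages": bundle.ledger,
    }
    path.write_text(yaml.safe_dump(log, sort_keys=False))
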