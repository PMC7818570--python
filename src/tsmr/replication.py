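"""Replicate simulation studies: calibration, coverage and parameter recovery.

These drive the package's own quality checks: under the null scenario the IVW
test should reject at its nominal level and its confidence interval should
cover zero at its nominal rate; under the causal scenario every estimator
should recover the planted slope on average; under directional pleiotropy the
MR-Egger intercept should recover the planted mean direct effect while IVW is
biased. Estimates are point-only (no bootstrap) since only their replicate
means and rejection rates are consumed.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Iterator

import numpy as np

from . import estimators as est
from .harmonize import HarmonizedInstrument, drop_palindromic, harmonize
from .simulate import SimulationConfig, scenario_preset, simulate_pair


def _iter_instruments(
    config: SimulationConfig, n_reps: int, seed: int
) -> Iterator[tuple[list[HarmonizedInstrument], float]]:
    """Yield harmonized instrument sets from independent replicate simulations."""
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    for s in rep_seeds:
        cfg = replace(config, seed=int(s))
        exposure, outcome, truth = simulate_pair(cfg)
        instruments, _ = harmonize(exposure, outcome)
        instruments, _ = drop_palindromic(instruments)
        yield instruments, truth.beta_true


def ivw_calibration(n_reps: int = 500, seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error and 95% CI coverage of the IVW test under the null scenario.

    Returns the empirical rejection rate at level ``alpha``, the coverage of
    the nominal 95% interval, and the Monte-Carlo standard error of each.
    """
    cfg = scenario_preset("null")
    reject = 0
    cover = 0
    for instruments, beta_true in _iter_instruments(cfg, n_reps, seed):
        e = est.ivw(instruments)
        reject += e.pval < alpha
        cover += e.ci_low <= beta_true <= e.ci_high
    t1 = reject / n_reps
    cov = cover / n_reps
    return {
        "type1_error": t1,
        "type1_mc_se": float(np.sqrt(t1 * (1 - t1) / n_reps)),
        "coverage": cov,
        "coverage_mc_se": float(np.sqrt(cov * (1 - cov) / n_reps)),
        "n_reps": n_reps,
    }


#: point-estimate battery used by the recovery study
RECOVERY_ESTIMATORS: dict[str, Callable] = {
    "ivw": lambda inst: est.ivw(inst),
    "mr_egger": lambda inst: est.mr_egger(inst)[0],
    "maximum_likelihood": est.maximum_likelihood,
    "weighted_median": lambda inst: est.weighted_median(inst, n_boot=0),
    "penalized_weighted_median": lambda inst: est.weighted_median(
        inst, penalized=True, n_boot=0),
    "simple_mode": lambda inst: est.mode_estimator(inst, n_boot=0),
    "weighted_mode": lambda inst: est.mode_estimator(inst, weighted=True, n_boot=0),
    "raps": est.raps,
}


def estimator_recovery(
    n_reps: int = 500, seed: int = 0, preset: str = "causal"
) -> dict[str, dict]:
    """Replicate means of every estimator against the planted causal slope.

    For each estimator returns its mean and Monte-Carlo SE of the mean over
    ``n_reps`` independent replicates, plus the true slope and the z-score of
    the mean bias.
    """
    cfg = scenario_preset(preset)
    draws: dict[str, list[float]] = {name: [] for name in RECOVERY_ESTIMATORS}
    beta_true = cfg.beta_true
    for instruments, _ in _iter_instruments(cfg, n_reps, seed):
        for name, fn in RECOVERY_ESTIMATORS.items():
            draws[name].append(fn(instruments).beta)
    out: dict[str, dict] = {}
    for name, vals in draws.items():
        arr = np.asarray(vals)
        mc_se = float(arr.std(ddof=1) / np.sqrt(len(arr)))
        out[name] = {
            "mean": float(arr.mean()),
            "mc_se": mc_se,
            "beta_true": beta_true,
            "bias_z": float((arr.mean() - beta_true) / mc_se),
            "n_reps": len(arr),
        }
    return out


def egger_intercept_recovery(n_reps: int = 500, seed: int = 0) -> dict:
    """Mean MR-Egger intercept and mean IVW slope under planted directional pleiotropy.

    With InSIDE holding the intercept should center on the planted mean direct
    effect while the unadjusted IVW slope is pulled away from the true β.
    """
    cfg = scenario_preset("directional_pleiotropy")
    intercepts: list[float] = []
    ivw_betas: list[float] = []
    for instruments, _ in _iter_instruments(cfg, n_reps, seed):
        _, pleio = est.mr_egger(instruments)
        intercepts.append(pleio.intercept)
        ivw_betas.append(est.ivw(instruments).beta)
    arr = np.asarray(intercepts)
    ivw_arr = np.asarray(ivw_betas)
    mc_se = float(arr.std(ddof=1) / np.sqrt(n_reps))
    return {
        "intercept_mean": float(arr.mean()),
        "intercept_mc_se": mc_se,
        "pleio_mean_true": cfg.pleio_mean,
        "intercept_bias_z": float((arr.mean() - cfg.pleio_mean) / mc_se),
        "ivw_mean": float(ivw_arr.mean()),
        "ivw_mc_se": float(ivw_arr.std(ddof=1) / np.sqrt(n_reps)),
        "beta_true": cfg.beta_true,
        "n_reps": n_reps,
    }
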