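"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the summary-level data a two-sample MR study consumes:
per-SNP exposure effects γ_j with a chosen strength distribution, outcome
effects α_j = β·γ_j + δ_j where δ_j is a per-SNP direct (pleiotropic) effect,
standard errors from the per-allele variance approximation
1/sqrt(2·maf(1−maf)·n), palindromic and non-palindromic allele pairs, randomly
swapped or strand-complemented outcome coding (so harmonization has real work
to do), and a pairwise LD / proxy table for clumping and substitution tests.

Binary-outcome effects are generated directly on the log-odds scale; exposure
and outcome samples are independent, matching the two-sample design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_io import P_FLOOR, SummaryStatRecord

#: Slope of the planted linear dependence of δ_j on γ_j when the InSIDE
#: assumption is deliberately violated.
INSIDE_VIOLATION_SLOPE = 0.5

_NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one two-sample scenario.

    ``beta_true`` is the causal effect on the log-odds scale; γ_j magnitudes
    are N(gamma_mean, gamma_sd) (random sign when ``sign_random``); direct
    effects δ_j are N(pleio_mean, pleio_sd), independent of γ_j unless
    ``inside_violation`` adds a linear γ dependence. ``randomize_outcome_coding``
    swaps or strand-complements outcome allele coding at random so the
    harmonization step is exercised.
    """

    n_snps: int = 30
    beta_true: float = 0.0
    gamma_mean: float = 0.08
    gamma_sd: float = 0.05
    maf_low: float = 0.1
    maf_high: float = 0.4
    n_exposure: int = 187_365
    n_outcome: int = 117_165
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    inside_violation: bool = False
    n_palindromic: int = 0
    sign_random: bool = True
    randomize_outcome_coding: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.gamma_sd < 0 or self.pleio_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not (0 < self.maf_low <= self.maf_high < 1):
            raise ValueError("need 0 < maf_low <= maf_high < 1")
        if self.n_palindromic > self.n_snps:
            raise ValueError("n_palindromic cannot exceed n_snps")
        if self.n_exposure < 1 or self.n_outcome < 1:
            raise ValueError("sample sizes must be positive")


@dataclass(frozen=True)
class SimulationTruth:
    """The generating parameters behind one simulated pair, for recovery tests."""

    config: SimulationConfig
    rsids: tuple[str, ...]
    maf: tuple[float, ...]
    gamma: tuple[float, ...]
    delta: tuple[float, ...]

    @property
    def beta_true(self) -> float:
        return self.config.beta_true

    @property
    def seed(self) -> int:
        return self.config.seed


def _se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pval(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, P_FLOOR)


def _rsids(j: int) -> list[str]:
    return [f"rs{k + 1:05d}" for k in range(j)]


def simulate_pair(
    config: SimulationConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], SimulationTruth]:
    """Generate matched exposure and outcome summary statistics plus the truth.

    Identical configs (including seed) produce identical output. The first
    ``n_palindromic`` SNPs receive A/T or C/G allele pairs; the outcome study's
    allele coding is randomly swapped and, for non-palindromic SNPs, randomly
    reported on the opposite strand when ``randomize_outcome_coding`` is set.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps
    rsids = _rsids(J)

    maf = rng.uniform(config.maf_low, config.maf_high, J)
    gamma = rng.normal(config.gamma_mean, config.gamma_sd, J)
    if config.sign_random:
        gamma = gamma * rng.choice([-1.0, 1.0], J)
    delta = rng.normal(config.pleio_mean, config.pleio_sd, J)
    if config.inside_violation:
        delta = delta + INSIDE_VIOLATION_SLOPE * gamma
    alpha = config.beta_true * gamma + delta

    se_g = _se(maf, config.n_exposure)
    se_a = _se(maf, config.n_outcome)
    gamma_hat = rng.normal(gamma, se_g)
    alpha_hat = rng.normal(alpha, se_a)
    p_g = _pval(gamma_hat, se_g)
    p_a = _pval(alpha_hat, se_a)

    # effect allele is the minor or major allele at random
    eaf = np.where(rng.random(J) < 0.5, maf, 1.0 - maf)

    exposure: list[SummaryStatRecord] = []
    outcome: list[SummaryStatRecord] = []
    for j in range(J):
        if j < config.n_palindromic:
            a1, a2 = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        else:
            a1, a2 = _NON_PALINDROMIC_PAIRS[rng.integers(len(_NON_PALINDROMIC_PAIRS))]
        exposure.append(SummaryStatRecord(
            rsid=rsids[j], effect_allele=a1, other_allele=a2,
            beta=float(gamma_hat[j]), se=float(se_g[j]), pval=float(p_g[j]),
            eaf=float(eaf[j]), n=config.n_exposure,
        ))
        o1, o2, ob, oeaf = a1, a2, float(alpha_hat[j]), float(eaf[j])
        if config.randomize_outcome_coding:
            if rng.random() < 0.5:  # swapped allele order
                o1, o2, ob, oeaf = o2, o1, -ob, 1.0 - oeaf
            if j >= config.n_palindromic and rng.random() < 0.25:
                o1, o2 = _COMPLEMENT[o1], _COMPLEMENT[o2]  # opposite strand
        outcome.append(SummaryStatRecord(
            rsid=rsids[j], effect_allele=o1, other_allele=o2,
            beta=ob, se=float(se_a[j]), pval=float(p_a[j]),
            eaf=oeaf, n=config.n_outcome,
        ))

    truth = SimulationTruth(
        config=config, rsids=tuple(rsids), maf=tuple(map(float, maf)),
        gamma=tuple(map(float, gamma)), delta=tuple(map(float, delta)),
    )
    return exposure, outcome, truth


def simulate_ld_tables(
    config: SimulationConfig,
    n_pairs_linked: int = 0,
    r2_linked: float = 0.5,
) -> tuple[list[tuple[str, str, float]], list[tuple[str, str, float]]]:
    """Pairwise LD and proxy tables consistent with :func:`simulate_pair` rsids.

    The LD table holds ``n_pairs_linked`` disjoint SNP pairs at ``r2_linked``
    plus background pairs below the clumping threshold; the proxy table offers,
    for each of the first two SNPs, a high-LD stand-in (r² = 0.9) with an rsid
    outside the simulated panel.
    """
    J = config.n_snps
    if n_pairs_linked > J // 2:
        raise ValueError("n_pairs_linked must not exceed n_snps/2")
    rsids = _rsids(J)
    ld: list[tuple[str, str, float]] = []
    for k in range(n_pairs_linked):
        ld.append((rsids[2 * k], rsids[2 * k + 1], r2_linked))
    for k in range(2 * n_pairs_linked, J - 1, 2):
        ld.append((rsids[k], rsids[k + 1], 0.0005))
    proxies = [
        (rsids[k], f"rs{90_000 + k + 1:05d}", 0.9) for k in range(min(2, J))
    ]
    return ld, proxies


def write_ld_table(pairs: Sequence[tuple[str, str, float]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("rsid_a\trsid_b\tr2\n")
        for a, b, r2 in pairs:
            fh.write(f"{a}\t{b}\t{r2:.12g}\n")
    return path


def write_proxy_table(rows: Sequence[tuple[str, str, float]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("rsid\tproxy_rsid\tr2\n")
        for a, b, r2 in rows:
            fh.write(f"{a}\t{b}\t{r2:.12g}\n")
    return path


def write_truth(truth: SimulationTruth, path: str | Path) -> Path:
    """Write the per-SNP truth as TSV with the config echoed in '#' header lines."""
    path = Path(path)
    cfg = truth.config
    with open(path, "w") as fh:
        for key, val in vars(cfg).items():
            fh.write(f"# {key}={val}\n")
        fh.write("rsid\tmaf\tgamma\tdelta\n")
        for rsid, m, g, d in zip(truth.rsids, truth.maf, truth.gamma, truth.delta):
            fh.write(f"{rsid}\t{m:.12g}\t{g:.12g}\t{d:.12g}\n")
    return path


#: Fixed scenario presets. `causal` plants β = −0.28, the protective
#: total-cholesterol log odds ratio scale effect the pipeline should recover;
#: `null` switches the causal effect off under otherwise identical balanced
#: pleiotropy; `directional_pleiotropy` plants a nonzero mean direct effect on
#: a null causal background, with γ positive and bounded well away from zero —
#: otherwise the Egger orientation step folds part of the planted direction
#: away and the intercept no longer targets the planted mean;
#: `heterogeneous` widens the direct-effect spread until Cochran's Q far
#: exceeds its degrees of freedom.
_PRESETS: dict[str, SimulationConfig] = {
    "null": SimulationConfig(
        n_snps=50, beta_true=0.0, pleio_mean=0.0, pleio_sd=0.002,
    ),
    "causal": SimulationConfig(
        n_snps=30, beta_true=-0.28, pleio_mean=0.0, pleio_sd=0.002,
    ),
    "directional_pleiotropy": SimulationConfig(
        n_snps=30, beta_true=0.0, pleio_mean=0.01, pleio_sd=0.005,
        gamma_sd=0.02, sign_random=False,
    ),
    "heterogeneous": SimulationConfig(
        n_snps=30, beta_true=-0.28, pleio_mean=0.0, pleio_sd=0.01,
    ),
}


def scenario_preset(name: str, seed: int | None = None) -> SimulationConfig:
    """Return a documented fixed scenario config, optionally re-seeded."""
    try:
        cfg = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg
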