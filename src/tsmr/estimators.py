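"""Causal-effect estimators for two-sample Mendelian randomization.

Given J harmonized instruments with exposure effects γ_i ± σ_γi and outcome
effects α_i ± σ_αi on a shared effect allele, this module computes the
inverse-variance-weighted (IVW) estimate, MR-Egger regression with its
pleiotropy intercept, Cochran's Q heterogeneity statistics, and the
sensitivity battery: profile maximum likelihood, (penalized) weighted median,
simple/weighted mode, the robust adjusted profile score (RAPS), and
leave-one-out re-estimation.

All slope estimates are reported on the log-odds scale with two-sided normal
p-values; odds ratios and their confidence limits are obtained by
exponentiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import optimize, special, stats

from .harmonize import HarmonizedInstrument

Z95 = stats.norm.ppf(0.975)

__all__ = [
    "MREstimate", "PleiotropyResult", "HeterogeneityResult", "LeaveOneOutResult",
    "EstimatorError", "wald_ratios", "ivw", "mr_egger", "cochrans_q",
    "chi2_upper_tail", "maximum_likelihood", "weighted_median", "mode_estimator",
    "raps", "leave_one_out",
]


class EstimatorError(Exception):
    """An estimator could not produce a result (too few SNPs, no root, ...)."""


@dataclass(frozen=True, slots=True)
class MREstimate:
    """One method's causal estimate: slope β on the log-odds scale plus OR form."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)


@dataclass(frozen=True, slots=True)
class PleiotropyResult:
    """MR-Egger intercept β₀: the estimated average directional pleiotropy."""

    intercept: float
    se: float
    ci_low: float
    ci_high: float
    pval: float


@dataclass(frozen=True, slots=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity statistic for the IVW or Egger fit."""

    method: Literal["IVW", "MR Egger"]
    q: float
    q_df: int
    q_pval: float


@dataclass(frozen=True, slots=True)
class LeaveOneOutResult:
    estimates: tuple[tuple[str, MREstimate], ...]
    full: MREstimate


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    g = np.array([i.gamma for i in instruments], dtype=float)
    sg = np.array([i.se_gamma for i in instruments], dtype=float)
    a = np.array([i.alpha for i in instruments], dtype=float)
    sa = np.array([i.se_alpha for i in instruments], dtype=float)
    return g, sg, a, sa


def _estimate_from(method: str, beta: float, se: float, n: int) -> MREstimate:
    z = beta / se if se > 0 else math.inf
    pval = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    return MREstimate(
        method=method, beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pval=pval, n_snps=n,
    )


def wald_ratios(instruments: Sequence[HarmonizedInstrument]) -> list[tuple[str, float, float]]:
    """Per-SNP causal ratios α_i/γ_i with first-order SEs σ_αi/|γ_i|.

    SNPs with γ_i = 0 are excluded (their ratio is undefined).
    """
    out = []
    for i in instruments:
        if i.gamma == 0:
            continue
        out.append((i.rsid, i.alpha / i.gamma, i.se_alpha / abs(i.gamma)))
    return out


def chi2_upper_tail(q: float, df: int) -> float:
    """Upper-tail probability of chi-square(df) at q.

    Computed as the regularized upper incomplete gamma Q(df/2, q/2); at df = 2
    it reduces to exp(−q/2).
    """
    if q < 0:
        raise ValueError("q must be nonnegative")
    if df <= 0:
        raise ValueError("df must be positive")
    return float(special.gammaincc(df / 2.0, q / 2.0))


def cochrans_q(
    instruments: Sequence[HarmonizedInstrument],
    beta_ref: float,
    n_params: int = 1,
    intercept: float = 0.0,
) -> HeterogeneityResult:
    """Cochran's Q about a reference slope (IVW, n_params=1) or Egger fit (n_params=2).

    IVW form: Q = Σ w_i (ratio_i − β_ref)², w_i = (σ_αi/|γ_i|)⁻².
    Egger form: Q = Σ σ_αi⁻² (α_i − β₀ − β·γ_i)² on γ-oriented instruments.
    """
    if not instruments:
        raise EstimatorError("Cochran's Q needs at least one instrument")
    g, sg, a, sa = _arrays(instruments)
    if n_params == 1:
        ratio = a / g
        w = (g / sa) ** 2
        q = float(np.sum(w * (ratio - beta_ref) ** 2))
        method = "IVW"
    else:
        g, a = np.where(g < 0, -g, g), np.where(g < 0, -a, a)
        resid = a - intercept - beta_ref * g
        q = float(np.sum((resid / sa) ** 2))
        method = "MR Egger"
    df = len(instruments) - n_params
    if df <= 0:
        raise EstimatorError(f"Q has df={df} <= 0 with {len(instruments)} instruments")
    return HeterogeneityResult(method=method, q=q, q_df=df, q_pval=chi2_upper_tail(q, df))


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    effects_model: Literal["fixed", "random_multiplicative"] = "random_multiplicative",
) -> MREstimate:
    """Inverse-variance-weighted estimate: weighted regression of α on γ through the origin.

    β̂ = Σ γ_i α_i σ_αi⁻² / Σ γ_i² σ_αi⁻². The fixed-effects SE is
    (Σ γ_i² σ_αi⁻²)^(−1/2); the multiplicative random-effects model scales it
    by max(1, sqrt(Q/(J−1))), never deflating below the fixed value.

    With a single instrument the estimate degenerates to that SNP's Wald ratio.
    """
    if not instruments:
        raise EstimatorError("IVW needs at least one instrument")
    g, sg, a, sa = _arrays(instruments)
    if np.all(g == 0):
        raise EstimatorError("all exposure effects are zero; IVW undefined")
    denom = float(np.sum(g**2 / sa**2))
    beta = float(np.sum(g * a / sa**2)) / denom
    se = denom ** -0.5
    J = len(instruments)
    method = "IVW"
    if J == 1:
        method = "Wald ratio"
    elif effects_model == "random_multiplicative":
        q = float(np.sum(((a - beta * g) / sa) ** 2))
        se *= max(1.0, math.sqrt(q / (J - 1)))
    elif effects_model != "fixed":
        raise ValueError(f"unknown effects model: {effects_model}")
    if effects_model == "fixed" and J > 1:
        method = "IVW (fixed effects)"
    return _estimate_from(method, beta, se, J)


def _orient(g: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip (γ_i, α_i) sign pairs so that every γ_i >= 0 (Egger convention)."""
    flip = g < 0
    return np.where(flip, -g, g), np.where(flip, -a, a)


def mr_egger(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[MREstimate, PleiotropyResult]:
    """MR-Egger regression: weighted least squares of α on γ with a free intercept.

    The slope is the pleiotropy-corrected causal effect; the intercept β₀
    estimates the average directional pleiotropy (consistent under InSIDE).
    Instruments are oriented so every γ_i >= 0 before fitting; weights are
    σ_αi⁻²; SEs carry a residual scale floored at 1, max(1, sqrt(Q/(J−2))).
    """
    J = len(instruments)
    if J < 3:
        raise EstimatorError(f"MR-Egger needs >= 3 instruments, got {J}")
    g, sg, a, sa = _arrays(instruments)
    g, a = _orient(g, a)
    w = sa**-2.0
    # Weighted normal equations for [intercept, slope]
    sw, swx = float(np.sum(w)), float(np.sum(w * g))
    swxx, swy, swxy = float(np.sum(w * g * g)), float(np.sum(w * a)), float(np.sum(w * g * a))
    det = sw * swxx - swx**2
    if det <= 0:
        raise EstimatorError("degenerate design: exposure effects carry no spread")
    b0 = (swxx * swy - swx * swxy) / det
    b1 = (sw * swxy - swx * swy) / det
    resid = a - b0 - b1 * g
    q = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(q / (J - 2)))
    se_b0 = math.sqrt(swxx / det) * scale
    se_b1 = math.sqrt(sw / det) * scale
    slope = _estimate_from("MR Egger", b1, se_b1, J)
    p0 = 2.0 * stats.norm.sf(abs(b0 / se_b0))
    intercept = PleiotropyResult(
        intercept=b0, se=se_b0,
        ci_low=b0 - Z95 * se_b0, ci_high=b0 + Z95 * se_b0, pval=p0,
    )
    return slope, intercept


def _profile_neg2ll(beta: float, g: np.ndarray, sg: np.ndarray, a: np.ndarray, sa: np.ndarray) -> float:
    # g_i profiled out analytically: residual variance σ_α² + β²σ_γ²
    return float(np.sum((a - beta * g) ** 2 / (sa**2 + beta**2 * sg**2)))


def maximum_likelihood(instruments: Sequence[HarmonizedInstrument]) -> MREstimate:
    """Profile maximum-likelihood estimate of the causal slope.

    Each (γ̂_i, α̂_i) is modelled as independent normals around (g_i, β g_i)
    with known SEs; the nuisance means g_i are profiled out in closed form,
    leaving −2ℓ(β) = Σ (α̂_i − βγ̂_i)²/(σ_αi² + β²σ_γi²). The SE comes from
    the observed information (numerical curvature at the optimum). As
    σ_γ → 0 the estimate converges to fixed-effects IVW.
    """
    if len(instruments) < 2:
        raise EstimatorError("maximum likelihood needs >= 2 instruments")
    g, sg, a, sa = _arrays(instruments)
    start = ivw(instruments, effects_model="fixed").beta
    width = 1.0 + abs(start)
    res = optimize.minimize_scalar(
        _profile_neg2ll, args=(g, sg, a, sa),
        bracket=(start - width, start, start + width),
        method="brent", options={"xtol": 1e-12},
    )
    if not res.success or not math.isfinite(res.x):
        raise EstimatorError(f"likelihood optimisation failed: {res}")
    beta = float(res.x)
    h = 1e-5 * (1.0 + abs(beta))
    f = lambda b: _profile_neg2ll(b, g, sg, a, sa)
    curv = (f(beta + h) - 2.0 * f(beta) + f(beta - h)) / h**2
    if curv <= 0:
        raise EstimatorError("non-positive curvature at the likelihood optimum")
    se = math.sqrt(2.0 / curv)  # -2ll curvature = 2 * information
    return _estimate_from("Maximum likelihood", beta, se, len(instruments))


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation at standardized cumulative weight 0.5."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    penalized: bool = False,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimate of the causal slope (consistent if >50% of weight is valid).

    Wald ratios are ordered and the estimate interpolates the ratio at
    standardized cumulative inverse-variance weight 0.5. The penalized variant
    down-weights outlying SNPs by min(1, 20·p_i), where p_i is the upper-tail
    chi-square(1) probability of that SNP's Q contribution about the unpenalized
    estimate. The SE comes from a parametric bootstrap over the ratio errors
    (``n_boot`` draws; ``n_boot=0`` skips it and reports NaN se/CI/p).
    """
    J = len(instruments)
    if J < 3:
        raise EstimatorError(f"weighted median needs >= 3 instruments, got {J}")
    g, sg, a, sa = _arrays(instruments)
    ratios = a / g
    ratio_se = sa / np.abs(g)
    weights = ratio_se**-2.0

    def point(r: np.ndarray) -> float:
        w = weights
        if penalized:
            b = _weighted_median_point(r, w)
            q_contrib = w * (r - b) ** 2
            pen = np.minimum(1.0, 20.0 * stats.chi2.sf(q_contrib, df=1))
            w = w * pen
        return _weighted_median_point(r, w)

    beta = point(ratios)
    method = "Penalized weighted median" if penalized else "Weighted median"
    if n_boot == 0:
        return MREstimate(method=method, beta=beta, se=math.nan, ci_low=math.nan,
                          ci_high=math.nan, pval=math.nan, n_snps=J)
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, ratio_se, size=(n_boot, J))
    boot = np.array([point(d) for d in draws])
    se = float(boot.std(ddof=1))
    if se == 0:
        se = math.sqrt(np.finfo(float).eps)
    return _estimate_from(method, beta, se, J)


def _silverman_bandwidth(r: np.ndarray, phi: float) -> float:
    s = float(np.std(r, ddof=1))
    m = float(stats.median_abs_deviation(r, scale="normal"))
    spread = min(x for x in (s, m) if x > 0) if (s > 0 or m > 0) else 0.0
    if spread == 0:
        return 0.0
    return phi * 0.9 * spread * len(r) ** (-1 / 5)


def _kde_argmax(r: np.ndarray, w: np.ndarray, h: float) -> float:
    """Argmax of the weighted normal-kernel density over ratios r."""
    if h == 0:  # all ratios (numerically) identical
        return float(r[0])
    wn = w / w.sum()

    def negdens(x: float) -> float:
        return -float(np.sum(wn * np.exp(-0.5 * ((x - r) / h) ** 2)))

    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
    dens = (wn[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2)).sum(axis=1)
    k = int(np.argmax(dens))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(negdens, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def mode_estimator(
    instruments: Sequence[HarmonizedInstrument],
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimate: the argmax of a kernel-smoothed density of Wald ratios.

    Uses a normal kernel with bandwidth φ × 0.9·min(sd, MAD)·J^(−1/5) (modified
    Silverman rule on the ratios). The weighted variant weights each kernel by
    the ratio's inverse variance. SE by seeded parametric bootstrap
    (``n_boot=0`` skips it).
    """
    J = len(instruments)
    if J < 3:
        raise EstimatorError(f"mode estimator needs >= 3 instruments, got {J}")
    g, sg, a, sa = _arrays(instruments)
    ratios = a / g
    ratio_se = sa / np.abs(g)
    w = ratio_se**-2.0 if weighted else np.ones(J)

    def point(r: np.ndarray) -> float:
        return _kde_argmax(r, w, _silverman_bandwidth(r, bandwidth_factor))

    beta = point(ratios)
    method = "Weighted mode" if weighted else "Simple mode"
    if n_boot == 0:
        return MREstimate(method=method, beta=beta, se=math.nan, ci_low=math.nan,
                          ci_high=math.nan, pval=math.nan, n_snps=J)
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, ratio_se, size=(n_boot, J))
    boot = np.array([point(d) for d in draws])
    se = float(boot.std(ddof=1))
    if se == 0:
        se = math.sqrt(np.finfo(float).eps)
    return _estimate_from(method, beta, se, J)


def _raps_score(beta: float, tau2: float, g, sg, a, sa) -> float:
    v = sa**2 + beta**2 * sg**2 + tau2
    return float(np.sum((a - beta * g) * g / v))


def raps(instruments: Sequence[HarmonizedInstrument], overdispersion: bool = False) -> MREstimate:
    """Robust adjusted profile score (RAPS) estimate.

    Solves Σ_i ψ_i(β, τ²) = 0 with ψ_i = (α_i − βγ_i)γ_i /
    (σ_αi² + β²σ_γi² + τ²); the profile-score variance accounts for measurement
    error in the exposure effects. With ``overdispersion`` a systematic
    pleiotropy variance τ² >= 0 is estimated jointly by moment matching of the
    standardized residuals. The SE is the sandwich estimate from the score and
    its numerical derivative. As σ_γ → 0 (and τ² = 0) the root coincides with
    fixed-effects IVW.
    """
    J = len(instruments)
    if J < 3:
        raise EstimatorError(f"RAPS needs >= 3 instruments, got {J}")
    g, sg, a, sa = _arrays(instruments)
    start = ivw(instruments, effects_model="fixed").beta

    def solve_beta(tau2: float) -> float:
        f = lambda b: _raps_score(b, tau2, g, sg, a, sa)
        width = 1.0 + abs(start)
        lo, hi = start - width, start + width
        for _ in range(60):
            if f(lo) * f(hi) < 0:
                return float(optimize.brentq(f, lo, hi, xtol=1e-12))
            width *= 2.0
            lo, hi = start - width, start + width
        raise EstimatorError("no sign change of the RAPS score in any bracket")

    tau2 = 0.0
    beta = solve_beta(tau2)
    if overdispersion:
        for _ in range(200):
            v = sa**2 + beta**2 * sg**2 + tau2
            # moment condition: mean standardized squared residual = 1
            excess = float(np.mean((a - beta * g) ** 2 - (sa**2 + beta**2 * sg**2)))
            new_tau2 = max(0.0, excess)
            new_beta = solve_beta(new_tau2)
            if abs(new_beta - beta) < 1e-12 and abs(new_tau2 - tau2) < 1e-14:
                beta, tau2 = new_beta, new_tau2
                break
            beta, tau2 = new_beta, new_tau2
    h = 1e-6 * (1.0 + abs(beta))
    dpsi = (_raps_score(beta + h, tau2, g, sg, a, sa) - _raps_score(beta - h, tau2, g, sg, a, sa)) / (2 * h)
    v = sa**2 + beta**2 * sg**2 + tau2
    psi_i = (a - beta * g) * g / v
    bread = abs(dpsi)
    meat = float(np.sum(psi_i**2))
    if bread == 0:
        raise EstimatorError("flat RAPS score at the root")
    # under correct specification E[psi_i^2] = g_i^2 / v_i; use the model-based
    # meat when residual spread collapses (exact fixtures), sandwich otherwise
    model_meat = float(np.sum(g**2 / v))
    se = math.sqrt(max(meat, 1e-12 * model_meat)) / bread
    method = "RAPS (overdispersed)" if overdispersion else "RAPS"
    return _estimate_from(method, beta, se, J)


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    estimator: Callable[..., MREstimate] = ivw,
    **kwargs,
) -> LeaveOneOutResult:
    """Re-estimate J times, omitting each SNP in turn, plus the all-SNP estimate."""
    if len(instruments) < 3:
        raise EstimatorError("leave-one-out needs >= 3 instruments")
    full = estimator(instruments, **kwargs)
    outs = []
    for k, inst in enumerate(instruments):
        subset = [x for j, x in enumerate(instruments) if j != k]
        outs.append((inst.rsid, estimator(subset, **kwargs)))
    return LeaveOneOutResult(estimates=tuple(outs), full=full)
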