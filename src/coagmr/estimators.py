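"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume harmonized per-variant effect pairs (exposure beta in SD
units, outcome beta in log-odds) and return the causal effect ``theta`` as the
log-odds of the outcome per 1 SD *higher* exposure. Because drug-target analyses
are framed as inhibition, every estimate also exposes the odds ratio per 1 SD
*lower* exposure, exp(−theta).

Primary estimator: the inverse-variance-weighted (IVW) mean of per-variant Wald
ratios under multiplicative random effects, with the dispersion floored at 1 so
underdispersion never shrinks the standard error below its fixed-effect value.

Robust estimators (consistent under progressively weaker assumptions about
horizontal pleiotropy): MR-Egger (regression with a pleiotropy intercept), the
weighted median (valid when >50% of weight is on valid instruments), the
contamination mixture (profile likelihood with an explicit invalid-instrument
component), and an outlier-removal procedure in the MR-PRESSO style (parametric
bootstrap of the leave-one-out residual sum of squares; the distortion test is
out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import normal_ci, two_sided_p
from .sumstats import HarmonizedPair

__all__ = [
    "EstimatorError",
    "SingleInstrumentError",
    "GridError",
    "RatioEstimate",
    "MREstimate",
    "CMConfig",
    "PressoConfig",
    "ratio_estimates",
    "wald_ratio",
    "ivw_mre",
    "egger",
    "weighted_median",
    "contamination_mixture",
    "mr_presso",
    "cochran_q",
]

Z95 = stats.norm.ppf(0.975)


class EstimatorError(RuntimeError):
    """An estimator's preconditions are not met."""


class SingleInstrumentError(EstimatorError):
    """Too few instruments for a multi-SNP estimator; use the Wald ratio."""


class GridError(EstimatorError):
    """The profile-likelihood grid does not bracket the maximum."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio with first-order standard error."""

    variant_id: str
    theta_j: float
    se_j: float

    def __post_init__(self):
        if self.se_j <= 0:
            raise ValueError("ratio SE must be positive")


@dataclass
class MREstimate:
    """One estimator's result: theta = log-OR of outcome per 1 SD higher exposure."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    q_stat: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    outliers: list[str] | None = None
    global_p: float | None = None
    multimodal: bool | None = None

    @property
    def or_per_sd_lower(self) -> float:
        """Odds ratio per 1 SD decrease in the exposure (inhibition framing)."""
        return math.exp(-self.theta)

    @property
    def or_per_sd_lower_ci(self) -> tuple[float, float]:
        return math.exp(-self.ci_high), math.exp(-self.ci_low)

    @property
    def or_per_sd_higher(self) -> float:
        return math.exp(self.theta)


@dataclass
class CMConfig:
    """Contamination-mixture tuning: psi is the SD of invalid-instrument effects;
    the default profile grid covers the IVW estimate ± 5 SE and the full span of
    the ratio estimates, widened on demand."""

    psi: float | None = None  # default: 1.5 x SD of ratio estimates
    grid_lo: float | None = None
    grid_hi: float | None = None
    grid_points: int = 5001
    max_widenings: int = 8

    def __post_init__(self):
        if self.psi is not None and self.psi <= 0:
            raise ValueError("psi must be positive")
        if self.grid_points < 3:
            raise ValueError("grid_points must be >= 3")


@dataclass
class PressoConfig:
    n_sim: int = 1000
    seed: int = 0
    outlier_alpha: float = 0.05  # Bonferroni-corrected by n_snps

    def __post_init__(self):
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")


def ratio_estimates(pairs: Sequence[HarmonizedPair]) -> list[RatioEstimate]:
    """Per-variant Wald ratios theta_j = beta_out/beta_exp, se_j = se_out/|beta_exp|."""
    out = []
    for p in pairs:
        if p.beta_exp == 0:
            raise EstimatorError(f"degenerate instrument {p.variant_id}: beta_exp = 0")
        out.append(
            RatioEstimate(p.variant_id, p.beta_out / p.beta_exp, p.se_out / abs(p.beta_exp))
        )
    return out


def _finish(method, theta, se, n_snps, **extra) -> MREstimate:
    lo, hi = normal_ci(theta, se)
    p = float(two_sided_p(theta / se))
    return MREstimate(method, float(theta), float(se), float(lo), float(hi), p, n_snps, **extra)


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-instrument causal estimate (first-order delta-method SE)."""
    if pair.beta_exp == 0:
        raise EstimatorError(f"degenerate instrument {pair.variant_id}: beta_exp = 0")
    theta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return _finish("wald", theta, se, 1)


def cochran_q(theta_j: np.ndarray, se_j: np.ndarray, theta: float) -> tuple[float, float, int]:
    """Weighted heterogeneity statistic and its chi-square p-value (df = n − 1)."""
    w = 1.0 / se_j ** 2
    q = float(np.sum(w * (theta_j - theta) ** 2))
    df = len(theta_j) - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, q_p, df


def ivw_mre(ratios: Sequence[RatioEstimate]) -> MREstimate:
    """Inverse-variance-weighted mean of Wald ratios, multiplicative random
    effects with the dispersion floored at 1 (underdispersion correction).

    theta = Σ w_j θ_j / Σ w_j with w_j = 1/se_j²; fixed-effect SE = (Σ w_j)^−1/2;
    reported SE = fixed-effect SE × sqrt(max(1, Q/(n−1))).
    """
    if len(ratios) < 2:
        raise SingleInstrumentError(
            "IVW requires >= 2 instruments; use wald_ratio for a single instrument"
        )
    theta_j = np.array([r.theta_j for r in ratios])
    se_j = np.array([r.se_j for r in ratios])
    w = 1.0 / se_j ** 2
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se_fe = float(1.0 / math.sqrt(np.sum(w)))
    q, q_p, df = cochran_q(theta_j, se_j, theta)
    phi = q / df
    se = se_fe * math.sqrt(max(1.0, phi))
    return _finish("ivw_mre", theta, se, len(ratios), q_stat=q, q_pval=q_p)


def _oriented(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, ...]:
    bx = np.array([p.beta_exp for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    return bx * flip, sx, by * flip, sy


def egger(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure effects with a free
    intercept (the average directional-pleiotropy term), exposure effects
    oriented positive first. Multiplicative random effects with the dispersion
    floored at 1, as for IVW.
    """
    if len(pairs) < 3:
        raise EstimatorError("MR-Egger requires >= 3 instruments")
    bx, _, by, sy = _oriented(pairs)
    if np.ptp(bx) == 0:
        raise EstimatorError("singular design: all exposure effects equal after orientation")
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    n = len(pairs)
    rss = float(np.sum(w * resid ** 2))
    phi = max(1.0, rss / (n - 2))
    cov = np.linalg.inv(xtwx) * phi
    intercept, theta = coef
    se_int = math.sqrt(cov[0, 0])
    se_theta = math.sqrt(cov[1, 1])
    est = _finish(
        "egger", theta, se_theta, n,
        q_stat=rss, q_pval=float(stats.chi2.sf(rss, n - 2)),
        egger_intercept=float(intercept),
        egger_intercept_p=float(two_sided_p(intercept / se_int)),
    )
    return est


def weighted_median(
    ratios: Sequence[RatioEstimate], n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of Wald ratios; SE by seeded parametric bootstrap.

    Consistent as long as valid instruments carry more than half of the total
    inverse-variance weight.
    """
    if len(ratios) < 3:
        raise EstimatorError("weighted median requires >= 3 instruments")
    theta_j = np.array([r.theta_j for r in ratios])
    se_j = np.array([r.se_j for r in ratios])
    theta = _weighted_median(theta_j, 1.0 / se_j ** 2)
    rng = np.random.default_rng(seed)
    draws = theta_j[None, :] + se_j[None, :] * rng.standard_normal((n_boot, len(ratios)))
    boot = np.array([_weighted_median(d, 1.0 / se_j ** 2) for d in draws])
    se = float(np.std(boot, ddof=1))
    return _finish("weighted_median", theta, se, len(ratios))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, v))


def contamination_mixture(
    ratios: Sequence[RatioEstimate], config: CMConfig | None = None
) -> MREstimate:
    """Profile-likelihood mixture of valid and invalid instruments.

    At each candidate theta, each ratio contributes the larger of a valid-
    component log-likelihood Normal(θ_j; θ, se_j²) and an invalid-component
    Normal(θ_j; 0, se_j² + ψ²); the estimate is the grid argmax and the 95% CI
    is the set within 1.92 log-likelihood units of the maximum (the connected
    component containing the maximum is reported, with a multimodality flag
    when the set is disconnected). The grid is widened automatically while the
    maximum or the CI touches a boundary.
    """
    if len(ratios) < 1:
        raise EstimatorError("contamination mixture requires >= 1 instrument")
    config = config or CMConfig()
    theta_j = np.array([r.theta_j for r in ratios])
    se_j = np.array([r.se_j for r in ratios])
    w = 1.0 / se_j ** 2
    center = float(np.sum(w * theta_j) / np.sum(w))
    se_fe = float(1.0 / math.sqrt(np.sum(w)))

    psi = config.psi
    if psi is None:
        psi = 1.5 * float(np.std(theta_j, ddof=1)) if len(theta_j) > 1 else 0.0
        if psi <= 0:
            psi = 1.5 * float(np.mean(se_j))

    invalid_ll = stats.norm.logpdf(theta_j, 0.0, np.sqrt(se_j ** 2 + psi ** 2))
    if config.grid_lo is not None and config.grid_hi is not None:
        lo, hi = float(config.grid_lo), float(config.grid_hi)
    else:
        # the grid must bracket every candidate mode, not just the IVW point:
        # under contamination the IVW centre can sit far from the profile maximum
        lo = min(center - 5.0 * se_fe, float(np.min(theta_j - 4.0 * se_j)))
        hi = max(center + 5.0 * se_fe, float(np.max(theta_j + 4.0 * se_j)))

    # profile level when every instrument is absorbed by the invalid component;
    # the profile tends to this constant far from the data, so when it lies
    # within 1.92 of the maximum the confidence set is unbounded and no amount
    # of widening closes it — the CI is then clamped to the evaluated grid
    tail_level = float(invalid_ll.sum())
    for _ in range(config.max_widenings + 1):
        grid = np.linspace(lo, hi, config.grid_points)
        # profile log-likelihood, vectorized over the grid
        dev = (theta_j[None, :] - grid[:, None]) / se_j[None, :]
        valid_ll = -0.5 * dev ** 2 - np.log(se_j)[None, :] - 0.5 * math.log(2 * math.pi)
        profile = np.maximum(valid_ll, invalid_ll[None, :]).sum(axis=1)
        k = int(np.argmax(profile))
        in_ci = profile >= profile[k] - 1.92
        unbounded_ci = profile[k] - tail_level <= 1.92
        if (k in (0, len(grid) - 1) or in_ci[0] or in_ci[-1]) and not unbounded_ci:
            span = hi - lo
            lo, hi = lo - span / 2.0, hi + span / 2.0
            continue
        break
    else:
        raise GridError("profile-likelihood grid does not bracket the maximum; widen the grid")

    theta = float(grid[k])
    # connected component of the CI containing the maximum
    i_lo = k
    while i_lo > 0 and in_ci[i_lo - 1]:
        i_lo -= 1
    i_hi = k
    while i_hi < len(grid) - 1 and in_ci[i_hi + 1]:
        i_hi += 1
    ci_low, ci_high = float(grid[i_lo]), float(grid[i_hi])
    runs = int(np.sum(np.diff(in_ci.astype(int)) == 1) + (1 if in_ci[0] else 0))
    se = (ci_high - ci_low) / (2.0 * Z95)
    if se <= 0:
        se = (grid[1] - grid[0]) / Z95  # degenerate single-point CI: one grid step
    p = float(two_sided_p(theta / se))
    return MREstimate(
        "contamination_mixture", theta, float(se), ci_low, ci_high, p, len(ratios),
        multimodal=runs > 1,
    )


def mr_presso(
    pairs: Sequence[HarmonizedPair], config: PressoConfig | None = None
) -> MREstimate:
    """Outlier detection via parametric bootstrap of leave-one-out residuals.

    The observed residual sum of squares uses leave-one-out IVW fits (weights
    1/se_out²); its null distribution is simulated by redrawing effect pairs
    from their sampling distributions around the leave-one-out fit. The global
    p is the exceedance fraction; per-variant outlier p-values come from each
    variant's simulated residual distribution, Bonferroni-corrected. The
    reported estimate is IVW-MRE after removing detected outliers. The
    distortion test is not implemented.
    """
    if len(pairs) < 4:
        raise EstimatorError("MR-PRESSO requires >= 4 instruments")
    config = config or PressoConfig()
    n = len(pairs)
    bx = np.array([p.beta_exp for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    w = 1.0 / sy ** 2

    def loo_theta(bxa, bya):
        num = np.sum(w * bxa * bya, axis=-1, keepdims=True) - w * bxa * bya
        den = np.sum(w * bxa ** 2, axis=-1, keepdims=True) - w * bxa ** 2
        return num / den

    loo = loo_theta(bx, by)
    resid_obs = w * (by - loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(config.seed)
    bx_sim = bx[None, :] + sx[None, :] * rng.standard_normal((config.n_sim, n))
    expected = loo * bx  # expected outcome effect under the leave-one-out fit
    by_sim = expected[None, :] + sy[None, :] * rng.standard_normal((config.n_sim, n))
    loo_sim = loo_theta(bx_sim, by_sim)
    resid_sim = w[None, :] * (by_sim - loo_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + config.n_sim))

    # stepwise outlier detection: a single gross outlier contaminates every
    # leave-one-out fit, so flag the most extreme significant residual, refit
    # without it, and repeat until the remaining set is clean
    active = np.arange(n)
    outlier_idx: list[int] = []
    rng_outlier = np.random.default_rng(config.seed + 1)
    while len(active) >= 3:
        bxa, bya = bx[active], by[active]
        sxa, sya = sx[active], sy[active]
        wa = 1.0 / sya ** 2
        num = np.sum(wa * bxa * bya) - wa * bxa * bya
        den = np.sum(wa * bxa ** 2) - wa * bxa ** 2
        loo_a = num / den
        resid_a = wa * (bya - loo_a * bxa) ** 2
        bx_s = bxa[None, :] + sxa[None, :] * rng_outlier.standard_normal((config.n_sim, len(active)))
        by_s = (loo_a * bxa)[None, :] + sya[None, :] * rng_outlier.standard_normal((config.n_sim, len(active)))
        num_s = np.sum(wa * bx_s * by_s, axis=1, keepdims=True) - wa * bx_s * by_s
        den_s = np.sum(wa * bx_s ** 2, axis=1, keepdims=True) - wa * bx_s ** 2
        resid_s = wa[None, :] * (by_s - (num_s / den_s) * bx_s) ** 2
        p_a = (1 + np.sum(resid_s >= resid_a[None, :], axis=0)) / (1 + config.n_sim)
        sig = p_a < config.outlier_alpha / n
        if not sig.any():
            break
        worst = int(np.argmax(np.where(sig, resid_a, -np.inf)))
        outlier_idx.append(int(active[worst]))
        active = np.delete(active, worst)
    outliers = [pairs[i].variant_id for i in sorted(outlier_idx)]

    outlier_mask = np.zeros(n, bool)
    outlier_mask[outlier_idx] = True
    kept = [p for p, o in zip(pairs, outlier_mask) if not o]
    if len(kept) >= 2:
        base = ivw_mre(ratio_estimates(kept))
    elif len(kept) == 1:
        base = wald_ratio(kept[0])
    else:
        raise EstimatorError("MR-PRESSO flagged every instrument as an outlier")
    return MREstimate(
        "presso", base.theta, base.se, base.ci_low, base.ci_high, base.pval,
        len(kept), q_stat=base.q_stat, q_pval=base.q_pval,
        outliers=outliers, global_p=global_p,
    )
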