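"""Two-sample MR causal estimators and diagnostics.

Every estimator consumes harmonized instruments carrying
(beta_X, se_X, beta_Y, se_Y) and returns an MRResult with a point
estimate theta (the effect on the outcome per unit exposure), its
standard error, 95% CI, p-value and method-specific extras.

The suite mirrors standard practice in proteome-wide MR studies:

* Wald ratio — single-instrument estimate beta_Y / beta_X.
* IVW (delta) — inverse-variance-weighted mean of Wald ratios with
  delta-method ratio variances; the primary estimator.  Optional
  multiplicative random-effects inflation by sqrt(Q/(J-1)), floored at 1.
* Robust IVW — Tukey-biweight M-estimation of the through-origin
  weighted regression, resistant to outlying ratios.
* MR-Egger — weighted regression with an intercept; the intercept is a
  test for directional pleiotropy, valid under InSIDE.
* Weighted median — consistent when >50% of weight is on valid
  instruments; bootstrap SE.
* Weighted mode — consistent when the largest group of instruments
  shares the true effect (ZEMPA); kernel-density argmax, bootstrap SE.
* Contamination mixture — two-component likelihood (valid around theta,
  invalid around 0 with inflated variance) maximized over a theta grid.
* MR-PRESSO — RSS-based global pleiotropy test with simulated null,
  per-instrument outlier flagging and outlier-corrected re-estimate.
* cML — constrained maximum likelihood treating K instruments as
  invalid, K selected by BIC.
* Cochran's Q — heterogeneity among ratio estimates.
* Steiger — causal-direction test comparing variance explained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._utils import Z95, ratio_and_variance, two_sided_p
from .errors import (
    ConfigurationError,
    ConvergenceError,
    InsufficientDataError,
    PreconditionError,
    UndefinedRatioError,
)
from .summary_io import HarmonizedInstrument

logger = logging.getLogger(__name__)


@dataclass
class MRResult:
    """One estimator's output for one protein-phenotype pair."""

    method: str
    theta_hat: float
    se_theta: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    extras: dict = field(default_factory=dict)


@dataclass
class SteigerResult:
    """Directionality verdict from variance explained on each side."""

    r2_exposure: float
    r2_outcome: float
    direction: str  # exposure_to_outcome | outcome_to_exposure
    z: float
    pvalue: float
    approximate_binary: bool = False


def usable(instruments: Sequence[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """Instruments without a drop_reason and with nonzero exposure effect."""
    return [
        i for i in instruments if i.drop_reason is None and i.beta_exposure != 0.0
    ]


def _arrays(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    inst = usable(instruments)
    bx = np.array([i.beta_exposure for i in inst], dtype=float)
    sx = np.array([i.se_exposure for i in inst], dtype=float)
    by = np.array([i.beta_outcome for i in inst], dtype=float)
    sy = np.array([i.se_outcome for i in inst], dtype=float)
    return bx, sx, by, sy


def _normal_result(
    method: str, theta: float, se: float, n_snps: int, extras: dict | None = None
) -> MRResult:
    if se > 0:
        z = theta / se
        p = float(two_sided_p(z))
    else:
        p = 1.0 if theta == 0.0 else 0.0
    return MRResult(
        method=method,
        theta_hat=float(theta),
        se_theta=float(se),
        ci_low=float(theta - Z95 * se),
        ci_high=float(theta + Z95 * se),
        pvalue=p,
        n_snps=n_snps,
        extras=extras or {},
    )


# ---------------------------------------------------------------------------
# Wald ratio and IVW


def wald_ratio(inst: HarmonizedInstrument, order: str = "second") -> MRResult:
    """Single-instrument causal estimate beta_Y / beta_X.

    order="first" ignores uncertainty in beta_X (se = |se_Y/beta_X|);
    order="second" adds the delta-method term beta_Y^2 se_X^2 / beta_X^4.
    """
    if inst.beta_exposure == 0.0:
        raise UndefinedRatioError(f"beta_exposure is 0 for {inst.variant_id}")
    theta, var = ratio_and_variance(
        inst.beta_exposure,
        inst.se_exposure,
        inst.beta_outcome,
        inst.se_outcome,
        order=order,
    )
    return _normal_result("wald", float(theta), math.sqrt(float(var)), 1)


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    random_effects: str = "multiplicative",
    weights: str = "second",
) -> MRResult:
    """Inverse-variance-weighted combination of per-instrument Wald ratios.

    theta_hat = sum(w_j theta_j) / sum(w_j) with w_j the reciprocal
    delta-method ratio variance (second-order by default).  Under
    ``random_effects="multiplicative"`` the SE is inflated by
    max(1, sqrt(Q/(J-1))) — never deflated — to absorb heterogeneity.
    Extras carry Cochran's Q, its p-value, and the inflation applied.
    """
    if random_effects not in ("fixed", "multiplicative"):
        raise ConfigurationError(f"unknown random_effects {random_effects!r}")
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 2:
        raise InsufficientDataError(f"ivw requires >= 2 instruments, got {j}")
    theta_j, var_j = ratio_and_variance(bx, sx, by, sy, order=weights)
    w = 1.0 / var_j
    # fsum: exactly rounded sums, so instrument order cannot perturb bits
    sw = math.fsum(w)
    theta = math.fsum(w * theta_j) / sw
    se = math.sqrt(1.0 / sw)
    q = math.fsum(w * (theta_j - theta) ** 2)
    p_q = float(stats.chi2.sf(q, j - 1))
    inflation = 1.0
    if random_effects == "multiplicative":
        inflation = max(1.0, math.sqrt(q / (j - 1)))
        se *= inflation
    return _normal_result(
        "ivw",
        theta,
        se,
        j,
        extras={
            "Q": q,
            "p_Q": p_q,
            "re_inflation": inflation,
            "random_effects": random_effects,
            "weights": weights,
        },
    )


def ivw_robust(
    instruments: Sequence[HarmonizedInstrument],
    tuning: float = 4.685,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> MRResult:
    """Through-origin weighted regression of beta_Y on beta_X fitted by
    iteratively reweighted Tukey-biweight M-estimation.

    Works on the precision-standardized scale (beta_Y/se_Y on beta_X/se_Y)
    so the base weights match first-order IVW; the biweight then
    downweights instruments with large standardized residuals.  SE by the
    sandwich formula.  Residual scale is the rescaled MAD; when residuals
    vanish the fit coincides with fixed-effect first-order IVW.
    """
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientDataError(f"ivw_robust requires >= 3 instruments, got {j}")
    x = bx / sy
    y = by / sy
    # OLS through origin on the standardized scale == first-order IVW
    beta = float(np.sum(x * y) / np.sum(x * x))
    resid = y - beta * x
    scale = 1.4826 * float(np.median(np.abs(resid)))
    if scale < 1e-12:
        res = ivw(instruments, random_effects="fixed", weights="first")
        res.method = "ivw_robust"
        res.extras["degenerate_zero_residuals"] = True
        return res

    converged = False
    rw = np.ones(j)
    for it in range(max_iter):
        u = resid / (tuning * scale)
        rw = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        denom = float(np.sum(rw * x * x))
        if denom <= 0.0:
            raise ConvergenceError(
                "all instruments downweighted to zero",
                {"iteration": it, "scale": scale},
            )
        new_beta = float(np.sum(rw * x * y) / denom)
        resid = y - new_beta * x
        scale = 1.4826 * float(np.median(np.abs(resid)))
        if scale < 1e-12:
            scale = 1e-12
        if abs(new_beta - beta) <= tol * max(1.0, abs(beta)):
            beta = new_beta
            converged = True
            break
        beta = new_beta
    if not converged:
        raise ConvergenceError(
            f"robust IVW did not converge in {max_iter} iterations",
            {"last_beta": beta, "scale": scale},
        )
    # sandwich SE: (sum w x^2)^-1 * sum (w r x)^2 * (sum w x^2)^-1
    bread = 1.0 / float(np.sum(rw * x * x))
    meat = float(np.sum((rw * resid * x) ** 2))
    se = math.sqrt(bread * meat * bread) * math.sqrt(j / max(j - 1, 1))
    return _normal_result(
        "ivw_robust",
        beta,
        se,
        j,
        extras={"tuning": tuning, "robust_weights_min": float(np.min(rw))},
    )


# ---------------------------------------------------------------------------
# MR-Egger


def egger(instruments: Sequence[HarmonizedInstrument]) -> MRResult:
    """MR-Egger: weighted regression of beta_Y on beta_X with intercept.

    Instruments are first oriented so beta_X >= 0 (the estimator is
    defined on that orientation); weights are 1/se_Y^2.  The slope is the
    causal estimate (consistent under InSIDE even with directional
    pleiotropy); the intercept alpha_0 estimates the average pleiotropic
    effect, and its two-sided test is the pleiotropy diagnostic.  SEs use
    multiplicative inflation max(1, sqrt(RSS_w/(J-2))) and t(J-2)
    reference distributions.
    """
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientDataError(f"egger requires >= 3 instruments, got {j}")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    w = 1.0 / sy**2

    sw = float(np.sum(w))
    swx = float(np.sum(w * x))
    swy = float(np.sum(w * y))
    swxx = float(np.sum(w * x * x))
    swxy = float(np.sum(w * x * y))
    denom = sw * swxx - swx**2
    if denom <= 0.0:
        raise InsufficientDataError("degenerate design: no spread in beta_X")
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw
    resid = y - intercept - slope * x
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / (j - 2))  # multiplicative overdispersion, floored
    var_slope = phi * sw / denom
    var_intercept = phi * swxx / denom
    se_slope = math.sqrt(var_slope)
    se_intercept = math.sqrt(var_intercept)
    df = j - 2

    def t_p(est: float, se: float) -> float:
        if se <= 0.0:
            return 1.0 if est == 0.0 else 0.0
        return float(2.0 * stats.t.sf(abs(est / se), df))

    tcrit = float(stats.t.ppf(0.975, df))
    return MRResult(
        method="egger",
        theta_hat=float(slope),
        se_theta=float(se_slope),
        ci_low=float(slope - tcrit * se_slope),
        ci_high=float(slope + tcrit * se_slope),
        pvalue=t_p(slope, se_slope),
        n_snps=j,
        extras={
            "intercept": float(intercept),
            "se_intercept": float(se_intercept),
            "p_intercept": t_p(intercept, se_intercept),
            "overdispersion": phi,
        },
    )


# ---------------------------------------------------------------------------
# Weighted median / mode


def _weighted_median_rows(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with the standardized-cumulative-weight
    interpolation rule; theta and w are (R, J)."""
    order = np.argsort(theta, axis=1)
    ts = np.take_along_axis(theta, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    cw = np.cumsum(ws, axis=1)
    total = cw[:, -1:]
    s = (cw - ws / 2.0) / total
    # index of first s >= 0.5 per row
    ge = s >= 0.5
    k = np.argmax(ge, axis=1)
    rows = np.arange(theta.shape[0])
    out = np.empty(theta.shape[0])
    at_left = k == 0
    out[at_left] = ts[rows[at_left], 0]
    r = rows[~at_left]
    kk = k[~at_left]
    s_lo = s[r, kk - 1]
    s_hi = s[r, kk]
    t_lo = ts[r, kk - 1]
    t_hi = ts[r, kk]
    frac = (0.5 - s_lo) / (s_hi - s_lo)
    out[~at_left] = t_lo + frac * (t_hi - t_lo)
    return out


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
    weights: str = "second",
) -> MRResult:
    """Weighted median of the ratio estimates (consistent when valid
    instruments carry a majority of the weight).

    The estimate interpolates the ordered ratios at standardized
    cumulative weight 0.5; the SE comes from a parametric bootstrap that
    resamples (beta_X, beta_Y) from their normal sampling distributions.
    """
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientDataError(
            f"weighted_median requires >= 3 instruments, got {j}"
        )
    theta_j, var_j = ratio_and_variance(bx, sx, by, sy, order=weights)
    theta = float(
        _weighted_median_rows(theta_j[None, :], (1.0 / var_j)[None, :])[0]
    )
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, j))
    bys = rng.normal(by, sy, size=(n_boot, j))
    bxs = np.where(bxs == 0.0, 1e-300, bxs)
    t_b, v_b = ratio_and_variance(bxs, sx, bys, sy, order=weights)
    boots = _weighted_median_rows(t_b, 1.0 / v_b)
    se = float(np.std(boots, ddof=1))
    return _normal_result(
        "weighted_median", theta, se, j, extras={"n_boot": n_boot, "seed": seed}
    )


def _mode_argmax(
    theta_j: np.ndarray, w: np.ndarray, h: float, fine_step: float = 1e-4
) -> float:
    """Argmax of the weighted normal-kernel density: coarse grid (step h/50,
    capped at 20000 points) then a fine local grid at ``fine_step``."""
    lo = float(np.min(theta_j)) - 3.0 * h
    hi = float(np.max(theta_j)) + 3.0 * h
    step = max((hi - lo) / 20000.0, h / 50.0)
    grid = np.arange(lo, hi + step, step)
    dens = np.exp(-0.5 * ((grid[:, None] - theta_j[None, :]) / h) ** 2) @ w
    best = float(grid[int(np.argmax(dens))])
    fg = np.arange(best - 2.0 * step, best + 2.0 * step, fine_step)
    dens = np.exp(-0.5 * ((fg[:, None] - theta_j[None, :]) / h) ** 2) @ w
    return float(fg[int(np.argmax(dens))])


def weighted_mode(
    instruments: Sequence[HarmonizedInstrument],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    weights: str = "second",
) -> MRResult:
    """Weighted mode: argmax of a weighted normal-kernel density over the
    ratio estimates.

    Bandwidth = bandwidth_factor x the modified Silverman rule
    0.9 min(sd, 1.4826 mad) J^(-1/5) on the ratio estimates.  SE by
    parametric bootstrap (the mode is re-estimated on each resample,
    coarse grid only for speed).
    """
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientDataError(f"weighted_mode requires >= 3 instruments, got {j}")
    if bandwidth_factor <= 0:
        raise ConfigurationError("bandwidth_factor must be > 0")
    theta_j, var_j = ratio_and_variance(bx, sx, by, sy, order=weights)
    w = 1.0 / var_j
    w = w / np.sum(w)

    def bandwidth(t: np.ndarray) -> float:
        sd = float(np.std(t, ddof=1))
        mad = 1.4826 * float(np.median(np.abs(t - np.median(t))))
        s = min(sd, mad) if mad > 0 else sd
        if s <= 0:
            s = max(abs(float(np.mean(t))), 1.0) * 1e-6
        return bandwidth_factor * 0.9 * s * len(t) ** (-0.2)

    h = bandwidth(theta_j)
    theta = _mode_argmax(theta_j, w, h)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs = np.where(bxs == 0.0, 1e-300, bxs)
        t_b, v_b = ratio_and_variance(bxs, sx, bys, sy, order=weights)
        w_b = 1.0 / v_b
        w_b = w_b / np.sum(w_b)
        h_b = bandwidth(t_b)
        lo = float(np.min(t_b)) - 3.0 * h_b
        hi = float(np.max(t_b)) + 3.0 * h_b
        step = max((hi - lo) / 2000.0, h_b / 20.0)
        grid = np.arange(lo, hi + step, step)
        dens = np.exp(-0.5 * ((grid[:, None] - t_b[None, :]) / h_b) ** 2) @ w_b
        boots[b] = grid[int(np.argmax(dens))]
    se = float(np.std(boots, ddof=1))
    return _normal_result(
        "weighted_mode",
        theta,
        se,
        j,
        extras={"bandwidth": h, "n_boot": n_boot, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Contamination mixture


def conmix(
    instruments: Sequence[HarmonizedInstrument],
    psi: float | None = None,
    theta_grid: tuple[float, float, float] | None = None,
    weights: str = "second",
) -> MRResult:
    """Contamination-mixture estimator.

    For each candidate theta on a grid, each instrument's log-likelihood
    is the better of a valid component N(theta_j; theta, se_j^2) and an
    invalid component N(theta_j; 0, se_j^2 + psi^2); theta_hat maximizes
    the profile log-likelihood and the 95% CI collects grid points within
    chi2_1(0.95)/2 of the maximum (it may be a union of intervals).

    psi defaults to 1.5 x SD of the ratio estimates; the grid defaults to
    the ratio range widened by 25% (at least [-2, 2]) at step 0.001 x its
    half-width scale.  A maximum on the grid boundary is logged.
    """
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientDataError(f"conmix requires >= 3 instruments, got {j}")
    theta_j, var_j = ratio_and_variance(bx, sx, by, sy, order=weights)
    se_j = np.sqrt(var_j)
    if psi is None:
        psi = 1.5 * float(np.std(theta_j, ddof=1))
        if psi <= 0.0:
            psi = 1.0
    if psi <= 0.0:
        raise ConfigurationError("psi must be > 0")
    if theta_grid is None:
        span = float(np.max(theta_j) - np.min(theta_j))
        lo = min(-2.0, float(np.min(theta_j)) - 0.25 * span)
        hi = max(2.0, float(np.max(theta_j)) + 0.25 * span)
        step = max((hi - lo) * 2.5e-4, 1e-4)
    else:
        lo, hi, step = theta_grid
    grid = np.arange(lo, hi + step, step)

    inv_ll = stats.norm.logpdf(theta_j, loc=0.0, scale=np.sqrt(var_j + psi**2))
    # (G, J) valid-component loglik, chunked to bound memory
    ll = np.empty(grid.shape[0])
    chunk = max(1, int(4_000_000 / max(j, 1)))
    for s in range(0, grid.shape[0], chunk):
        g = grid[s : s + chunk, None]
        val = -0.5 * ((theta_j[None, :] - g) / se_j[None, :]) ** 2 - np.log(
            se_j[None, :] * math.sqrt(2 * math.pi)
        )
        ll[s : s + chunk] = np.sum(np.maximum(val, inv_ll[None, :]), axis=1)
    k = int(np.argmax(ll))
    theta = float(grid[k])
    if k == 0 or k == len(grid) - 1:
        logger.warning("conmix maximum on grid boundary (theta=%.4g)", theta)
    cut = ll[k] - stats.chi2.ppf(0.95, 1) / 2.0
    in_ci = ll >= cut
    ci_low = float(grid[in_ci][0])
    ci_high = float(grid[in_ci][-1])
    # contiguous segments of the CI (multimodality diagnostic)
    edges = np.flatnonzero(np.diff(in_ci.astype(int)) != 0)
    n_segments = int((len(edges) + (1 if in_ci[0] else 0) + (1 if in_ci[-1] else 0)) // 2)

    val_at = -0.5 * ((theta_j - theta) / se_j) ** 2 - np.log(
        se_j * math.sqrt(2 * math.pi)
    )
    valid_mask = val_at >= inv_ll
    inst = usable(instruments)
    valid_ids = [inst[i].variant_id for i in np.flatnonzero(valid_mask)]

    se = (ci_high - ci_low) / (2.0 * Z95)
    if se <= 0.0:
        se = step / Z95
    z = theta / se
    return MRResult(
        method="conmix",
        theta_hat=theta,
        se_theta=float(se),
        ci_low=ci_low,
        ci_high=ci_high,
        pvalue=float(two_sided_p(z)),
        n_snps=j,
        extras={
            "psi": float(psi),
            "valid_set": valid_ids,
            "n_valid": int(valid_mask.sum()),
            "ci_segments": n_segments,
            "boundary": k in (0, len(grid) - 1),
        },
    )


# ---------------------------------------------------------------------------
# MR-PRESSO


def _loo_ivw_rows(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out first-order IVW estimates, row-wise; (R, J) -> (R, J)."""
    sw = np.sum(w, axis=1, keepdims=True)
    swt = np.sum(w * theta, axis=1, keepdims=True)
    return (swt - w * theta) / (sw - w)


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> MRResult:
    """MR-PRESSO global pleiotropy test, outlier flagging, and corrected
    estimate.

    The observed statistic is the weighted RSS of each instrument's
    outcome effect against its leave-one-out IVW prediction.  The null
    distribution resimulates beta_Y_j ~ N(theta_loo_j beta_X_j, se_Y_j^2)
    n_sim times, recomputing the leave-one-out fits on each simulated
    dataset.  Instruments whose observed squared residual is extreme
    against its simulated distribution (Bonferroni across J) are flagged
    as outliers; the corrected estimate is IVW on the remainder, and the
    distortion test compares the raw-vs-corrected shift against removals
    of random same-sized instrument subsets.
    """
    if n_sim < 100:
        raise ConfigurationError("mr_presso requires n_sim >= 100")
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 4:
        raise InsufficientDataError(f"mr_presso requires >= 4 instruments, got {j}")
    inst = usable(instruments)
    rng = np.random.default_rng(seed)

    theta_j = by / bx
    w = bx**2 / sy**2  # first-order weights: fixed under beta_Y resampling
    loo = _loo_ivw_rows(theta_j[None, :], w[None, :])[0]
    resid2_obs = ((by - loo * bx) / sy) ** 2
    rss_obs = float(np.sum(resid2_obs))

    by_sim = rng.normal(loo * bx, sy, size=(n_sim, j))
    theta_sim = by_sim / bx
    loo_sim = _loo_ivw_rows(theta_sim, np.broadcast_to(w, (n_sim, j)))
    resid2_sim = ((by_sim - loo_sim * bx) / sy) ** 2
    rss_sim = np.sum(resid2_sim, axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))

    p_out = (1 + np.sum(resid2_sim >= resid2_obs[None, :], axis=0)) / (1 + n_sim)
    p_out_bonf = np.minimum(1.0, p_out * j)
    outlier_mask = p_out_bonf < outlier_alpha
    outlier_ids = [inst[i].variant_id for i in np.flatnonzero(outlier_mask)]

    raw = ivw(inst, random_effects="fixed")
    raw.extras = {k: raw.extras[k] for k in ("Q", "p_Q")}
    distortion_p = math.nan
    if outlier_mask.any() and (~outlier_mask).sum() >= 2:
        kept = [inst[i] for i in np.flatnonzero(~outlier_mask)]
        corrected = ivw(kept, random_effects="fixed")
        n_out = int(outlier_mask.sum())
        # distortion null: remove random subsets of the same size
        n_draws = min(n_sim, 1000)
        d_null = np.empty(n_draws)
        theta2, var2 = ratio_and_variance(bx, sx, by, sy, order="second")
        w2 = 1.0 / var2
        for b in range(n_draws):
            drop = rng.choice(j, size=n_out, replace=False)
            keep = np.setdiff1d(np.arange(j), drop, assume_unique=True)
            th_b = float(np.sum(w2[keep] * theta2[keep]) / np.sum(w2[keep]))
            d_null[b] = raw.theta_hat - th_b
        d_obs = raw.theta_hat - corrected.theta_hat
        distortion_p = float(
            (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (1 + n_draws)
        )
        result = corrected
    else:
        result = raw

    return MRResult(
        method="presso",
        theta_hat=result.theta_hat,
        se_theta=result.se_theta,
        ci_low=result.ci_low,
        ci_high=result.ci_high,
        pvalue=result.pvalue,
        n_snps=j,
        extras={
            "global_p": global_p,
            "rss_obs": rss_obs,
            "outliers": outlier_ids,
            "distortion_p": distortion_p,
            "raw_theta": raw.theta_hat,
            "raw_se": raw.se_theta,
            "raw_p": raw.pvalue,
            "n_sim": n_sim,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Constrained maximum likelihood (cML) with BIC model selection


def _cml_fit_k_from(
    bx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    k: int,
    theta0: float,
    max_iter: int = 200,
) -> tuple[float, np.ndarray, float]:
    """Coordinate ascent at fixed invalid-set size K from one start.

    Alternates: given theta, the K instruments with the largest
    standardized residuals |beta_Y - theta beta_X| / se_Y are invalid
    (their pleiotropy parameters absorb the residual exactly); given the
    invalid set, theta is the weighted-least-squares slope on the valid
    set.  Returns (theta, invalid_mask, negloglik) where negloglik is
    sum of valid squared standardized residuals / 2 (constants dropped).
    """
    w = 1.0 / sy**2
    theta = theta0
    invalid = np.zeros(len(bx), dtype=bool)
    for _ in range(max_iter):
        r2 = ((by - theta * bx) / sy) ** 2
        new_invalid = np.zeros_like(invalid)
        if k > 0:
            new_invalid[np.argsort(-r2, kind="stable")[:k]] = True
        valid = ~new_invalid
        denom = float(np.sum(w[valid] * bx[valid] ** 2))
        if denom <= 0.0:
            raise ConvergenceError("cML: valid set has no exposure signal")
        new_theta = float(np.sum(w[valid] * bx[valid] * by[valid]) / denom)
        if np.array_equal(new_invalid, invalid) and abs(new_theta - theta) < 1e-12:
            theta, invalid = new_theta, new_invalid
            break
        theta, invalid = new_theta, new_invalid
    valid = ~invalid
    nll = 0.5 * float(np.sum(((by[valid] - theta * bx[valid]) / sy[valid]) ** 2))
    return theta, invalid, nll


def _cml_fit_k(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray, k: int, max_iter: int = 200
) -> tuple[float, np.ndarray, float]:
    """Best of several deterministic coordinate-ascent starts.

    The alternation can stall in local optima when the full-data slope is
    badly contaminated, so each K is fitted from the full-data WLS slope,
    the median ratio, and every individual ratio estimate; the fit with
    the smallest negative log-likelihood wins.
    """
    w = 1.0 / sy**2
    ratios = by / bx
    starts = [
        float(np.sum(w * bx * by) / np.sum(w * bx * bx)),
        float(np.median(ratios)),
        *(float(r) for r in ratios),
    ]
    best: tuple[float, np.ndarray, float] | None = None
    for theta0 in starts:
        fit = _cml_fit_k_from(bx, by, sy, k, theta0, max_iter)
        if best is None or fit[2] < best[2] - 1e-12:
            best = fit
    return best


def mr_cml(
    instruments: Sequence[HarmonizedInstrument],
    k_max: int | None = None,
    seed: int = 0,
    n: float | None = None,
) -> MRResult:
    """Constrained-ML estimator with BIC selection of the invalid count.

    Fits the Gaussian model beta_Y_j ~ N(theta beta_X_j + alpha_j, se_Y_j^2)
    where exactly K instruments have free pleiotropy parameters alpha_j,
    for K = 0..min(k_max, J-2); BIC = 2 negloglik + K log(n) selects K,
    with n the (smaller) GWAS sample size when supplied and the instrument
    count J otherwise.  The estimate and SE come from the selected model's
    valid set.  This is the BIC-selection variant (no model averaging or
    data perturbation); ``seed`` is accepted for API uniformity and unused.
    """
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientDataError(f"mr_cml requires >= 3 instruments, got {j}")
    if k_max is None:
        k_max = j - 2
    k_max = min(k_max, j - 2)
    penalty = math.log(n) if n is not None else math.log(j)

    best = None
    for k in range(0, k_max + 1):
        theta, invalid, nll = _cml_fit_k(bx, by, sy, k)
        bic = 2.0 * nll + k * penalty
        if best is None or bic < best[0] - 1e-12:
            best = (bic, k, theta, invalid, nll)
    bic, k_sel, theta, invalid, nll = best
    valid = ~invalid
    w = 1.0 / sy**2
    se = math.sqrt(1.0 / float(np.sum(w[valid] * bx[valid] ** 2)))
    inst = usable(instruments)
    invalid_ids = [inst[i].variant_id for i in np.flatnonzero(invalid)]
    res = _normal_result(
        "cml",
        theta,
        se,
        j,
        extras={
            "K_selected": int(k_sel),
            "BIC": float(bic),
            "invalid_set": invalid_ids,
            "negloglik": float(nll),
            "bic_penalty": penalty,
        },
    )
    return res


# ---------------------------------------------------------------------------
# Heterogeneity and directionality


def cochran_q(
    instruments: Sequence[HarmonizedInstrument],
    theta_ref: float,
    weights: str = "second",
) -> tuple[float, int, float]:
    """Cochran's Q = sum w_j (theta_j - theta_ref)^2 with df = J - 1."""
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 2:
        raise InsufficientDataError(f"cochran_q requires >= 2 instruments, got {j}")
    theta_j, var_j = ratio_and_variance(bx, sx, by, sy, order=weights)
    q = float(np.sum((theta_j - theta_ref) ** 2 / var_j))
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


def steiger_direction(
    instruments: Sequence[HarmonizedInstrument],
    n_exposure: float,
    n_outcome: float,
    outcome_type: str = "quantitative",
) -> SteigerResult:
    """Steiger directionality test on summed variance explained.

    Per instrument and side, r^2 = 2 p q beta^2 / (2 p q beta^2 +
    2 p q se^2 n); the side explaining more variance is inferred to be
    causally upstream.  The z statistic compares the two multiple
    correlations sqrt(r^2) via Fisher's z with the two (independent)
    sample sizes.  For binary outcomes the observed-scale approximation
    is used and flagged.
    """
    inst = usable(instruments)
    if not inst:
        raise InsufficientDataError("steiger requires >= 1 usable instrument")
    for i in inst:
        if i.eaf is None:
            raise PreconditionError(f"missing eaf for variant {i.variant_id}")

    def r2_sum(betas, ses, n):
        total = 0.0
        for i, b, s in betas:
            pq2 = 2.0 * i.eaf * (1.0 - i.eaf)
            total += (pq2 * b**2) / (pq2 * b**2 + pq2 * s**2 * n)
        return total

    r2_exp = r2_sum(
        [(i, i.beta_exposure, i.se_exposure) for i in inst], None, n_exposure
    )
    r2_out = r2_sum([(i, i.beta_outcome, i.se_outcome) for i in inst], None, n_outcome)
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    z_exp = math.atanh(math.sqrt(r2_exp))
    z_out = math.atanh(math.sqrt(r2_out))
    se = math.sqrt(1.0 / (n_exposure - 3.0) + 1.0 / (n_outcome - 3.0))
    z = (z_exp - z_out) / se
    direction = "exposure_to_outcome" if r2_exp > r2_out else "outcome_to_exposure"
    return SteigerResult(
        r2_exposure=float(r2_exp),
        r2_outcome=float(r2_out),
        direction=direction,
        z=float(z),
        pvalue=float(two_sided_p(z)),
        approximate_binary=(outcome_type == "binary"),
    )
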