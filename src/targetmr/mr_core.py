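"""Two-sample MR estimators over a harmonized exposure/outcome set.

All estimators consume per-variant effect pairs (beta_x, se_x, beta_y,
se_y) aligned to a common effect allele and return an ``MRResult`` on the
outcome scale per unit of exposure. The battery:

* ``ivw`` — inverse-variance weighted (primary); fixed-effect for small k,
  multiplicative random effects otherwise.
* ``egger`` — weighted regression with intercept; the intercept estimates
  average directional pleiotropy.
* ``weighted_median`` — consistent when >= 50% of weight is on valid
  instruments.
* ``weighted_mode`` — consistent when the largest cluster of instruments
  is valid.
* ``robust_ivw`` — IVW through the origin fitted by IRLS with Huber loss.
* ``raps`` — robust adjusted profile score with additive overdispersion.
* ``presso`` — residual-sum-of-squares global pleiotropy test, per-variant
  outlier detection, distortion test and outlier-corrected re-estimate.

Stochastic procedures (bootstrap SEs, PRESSO null simulations) are
reproducible bit for bit given (inputs, seed, rep count); passing
``n_boot=0`` returns a point estimate with NaN uncertainty, which the
Monte-Carlo harnesses use when only the point estimate is under study.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import HarmonizedSet, MRResult

__all__ = [
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "robust_ivw",
    "raps",
    "presso",
    "scale_to_unit_decrease",
    "all_estimators",
    "MMOL_PER_L",
]

#: mmol/l expressed in mg/dl for the two lipid exposures
MMOL_PER_L = {"ldl_c_mg_dl": 38.7, "tg_mg_dl": 88.9}

_Z975 = stats.norm.ppf(0.975)
_HUBER_C = 1.345


def _check_k(hset: HarmonizedSet, minimum: int, method: str) -> None:
    if hset.n_snps < minimum:
        raise ValueError(f"{method} requires at least {minimum} SNPs, got {hset.n_snps}")


def _normal_result(method, est, se, k, extras=None) -> MRResult:
    if np.isfinite(se) and se > 0:
        p = 2.0 * stats.norm.sf(abs(est) / se)
        lo, hi = est - _Z975 * se, est + _Z975 * se
    else:
        p, lo, hi = np.nan, np.nan, np.nan
    return MRResult(method, float(est), float(se), float(lo), float(hi), float(p), k, extras or {})


def _ivw_point(bx, by, sy) -> tuple[float, float, float]:
    """(estimate, fixed-effect SE, Cochran Q) for weights 1/se_y^2."""
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    est = np.sum(w * bx * by) / denom
    se_fe = np.sqrt(1.0 / denom)
    q = float(np.sum(w * (by - est * bx) ** 2))
    return float(est), float(se_fe), q


def ivw(hset: HarmonizedSet, model: str = "auto") -> MRResult:
    """Inverse-variance weighted estimate.

    ``model``: "fixed", "random" (multiplicative random effects, SE scaled
    by sqrt(max(1, Q/(k-1)))), or "auto" (fixed when k <= 3, random
    otherwise). A single instrument falls back to the Wald ratio, reported
    as method "wald_ratio".
    """
    if model not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    _check_k(hset, 1, "ivw")
    bx, sx, by, sy = hset.arrays()
    k = len(bx)
    if k == 1:
        est = by[0] / bx[0]
        se = sy[0] / abs(bx[0])
        return _normal_result("wald_ratio", est, se, 1, {"model": "wald"})
    est, se_fe, q = _ivw_point(bx, by, sy)
    q_df = k - 1
    q_p = float(stats.chi2.sf(q, q_df))
    use_random = model == "random" or (model == "auto" and k > 3)
    scale = np.sqrt(max(1.0, q / q_df)) if use_random else 1.0
    se = se_fe * scale
    extras = {
        "q": q,
        "q_df": q_df,
        "q_p": q_p,
        "model": "random" if use_random else "fixed",
        "se_fixed": se_fe,
    }
    return _normal_result("ivw", est, se, k, extras)


def egger(hset: HarmonizedSet) -> MRResult:
    """MR-Egger: weighted regression of beta_y on beta_x with intercept.

    Inputs are re-oriented so every beta_x >= 0 before fitting; SEs carry
    a residual overdispersion factor floored at 1; inference uses the t
    distribution with k - 2 df.
    """
    _check_k(hset, 3, "egger")
    bx, sx, by, sy = hset.arrays()
    k = len(bx)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.allclose(bx, bx[0]):
        raise ValueError("egger: constant beta_x across SNPs, slope unidentified")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], by * sw, rcond=None)
    resid = by - X @ coef
    dof = k - 2
    sigma2 = float(np.sum(w * resid**2) / dof)
    cov = np.linalg.inv(X.T @ (X * w[:, None])) * max(1.0, sigma2)
    inter, slope = coef
    se_inter, se_slope = np.sqrt(np.diag(cov))
    tq = stats.t.ppf(0.975, dof)
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, dof)
    p_inter = 2.0 * stats.t.sf(abs(inter) / se_inter, dof)
    extras = {
        "egger_intercept": float(inter),
        "intercept_se": float(se_inter),
        "intercept_p": float(p_inter),
        "residual_sigma2": sigma2,
    }
    return MRResult(
        "egger",
        float(slope),
        float(se_slope),
        float(slope - tq * se_slope),
        float(slope + tq * se_slope),
        float(p_slope),
        k,
        extras,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    b, w = ratios[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(b[0])
    j = int(np.searchsorted(s, 0.5))
    if j >= len(b):
        return float(b[-1])
    if s[j] == s[j - 1]:
        return float(b[j])
    return float(b[j - 1] + (b[j] - b[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1]))


def _parametric_boot(hset, point_fn, n_boot, seed):
    bx, sx, by, sy = hset.arrays()
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ests[i] = point_fn(bxs, sx, bys, sy)
    return float(np.std(ests, ddof=1))


def weighted_median(hset: HarmonizedSet, n_boot: int = 2000, seed: int = 0) -> MRResult:
    """Weighted median of Wald ratios; SE by parametric bootstrap."""
    _check_k(hset, 3, "weighted_median")
    bx, sx, by, sy = hset.arrays()
    k = len(bx)

    def point(bx_, sx_, by_, sy_):
        r = by_ / bx_
        w = (bx_ / sy_) ** 2  # inverse first-order ratio variance
        return _weighted_median_point(r, w)

    est = point(bx, sx, by, sy)
    se = _parametric_boot(hset, point, n_boot, seed) if n_boot > 0 else np.nan
    return _normal_result("weighted_median", est, se, k, {"n_boot": n_boot, "seed": seed})


def _weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float
) -> tuple[float, bool]:
    w = weights / weights.sum()
    k = len(ratios)
    mean = np.sum(w * ratios)
    sd = np.sqrt(np.sum(w * (ratios - mean) ** 2))
    mad = 1.4826 * _weighted_median_point(np.abs(ratios - _weighted_median_point(ratios, w)), w)
    spread = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    if spread == 0.0:
        return float(ratios[0]), False
    h = bandwidth_factor * 0.9 * spread * k ** (-1 / 5)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2048)
    dens = np.sum(w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2), axis=0)
    peak = dens.max()
    at_peak = np.flatnonzero(np.isclose(dens, peak, rtol=0, atol=peak * 1e-12))
    tie = bool(len(at_peak) > 1 and grid[at_peak[-1]] - grid[at_peak[0]] > 2 * h)
    return float(grid[at_peak[0]]), tie  # exact tie broken toward the smaller estimate


def weighted_mode(
    hset: HarmonizedSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 2000,
    seed: int = 0,
) -> MRResult:
    """Mode of the weighted kernel density over Wald ratios.

    Bandwidth is ``bandwidth_factor`` times a Silverman-type rule (0.9 x
    min(weighted SD, scaled weighted MAD) x k^(-1/5)). Exact density ties
    are broken toward the smaller estimate and flagged in ``extras``.
    """
    _check_k(hset, 3, "weighted_mode")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    bx, sx, by, sy = hset.arrays()
    k = len(bx)

    tie_flag = False

    def point(bx_, sx_, by_, sy_):
        nonlocal tie_flag
        r = by_ / bx_
        w = (bx_ / sy_) ** 2
        est, tie = _weighted_mode_point(r, w, bandwidth_factor)
        tie_flag = tie_flag or tie
        return est

    est = point(bx, sx, by, sy)
    obs_tie = tie_flag
    se = _parametric_boot(hset, point, n_boot, seed) if n_boot > 0 else np.nan
    extras = {"n_boot": n_boot, "seed": seed, "mode_tie": obs_tie, "bandwidth_factor": bandwidth_factor}
    return _normal_result("weighted_mode", est, se, k, extras)


def robust_ivw(
    hset: HarmonizedSet,
    tuning: float = _HUBER_C,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> MRResult:
    """IVW through the origin fitted by IRLS with Huber loss.

    Residuals are standardized by se_y and by a MAD scale re-estimated at
    each iteration; convergence when the estimate moves < ``tol``.
    """
    _check_k(hset, 2, "robust_ivw")
    bx, sx, by, sy = hset.arrays()
    x, y = bx / sy, by / sy
    theta = float(np.sum(x * y) / np.sum(x**2))
    trace = [theta]
    hw = np.ones_like(x)
    for _ in range(max_iter):
        resid = y - theta * x
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if scale <= 0:
            hw = np.ones_like(x)
            break
        u = np.abs(resid) / scale
        with np.errstate(divide="ignore"):
            hw = np.where(u <= tuning, 1.0, tuning / np.where(u > 0, u, np.inf))
        theta_new = float(np.sum(hw * x * y) / np.sum(hw * x**2))
        trace.append(theta_new)
        if abs(theta_new - theta) < tol:
            theta = theta_new
            break
        theta = theta_new
    else:
        raise RuntimeError(
            f"robust_ivw failed to converge in {max_iter} iterations; "
            f"last estimates: {trace[-5:]}"
        )
    resid = y - theta * x
    denom = np.sum(hw * x**2)
    se = float(np.sqrt(np.sum((hw * x * resid) ** 2)) / denom)
    se = max(se, float(np.sqrt(1.0 / denom)))  # never report below the IVW floor
    return _normal_result(
        "robust_ivw", theta, se, len(x), {"iterations": len(trace) - 1, "tuning": tuning}
    )


def _huber_psi(t: np.ndarray, c: float) -> np.ndarray:
    return np.clip(t, -c, c)


def raps(
    hset: HarmonizedSet,
    tuning: float = _HUBER_C,
    overdispersion: bool = True,
    psi: str = "huber",
) -> MRResult:
    """Robust adjusted profile score.

    Solves the profile estimating equation in theta with standardized
    residuals t_j = (beta_y - theta beta_x) / sqrt(se_y^2 + theta^2 se_x^2
    + tau^2), Huber psi, and additive overdispersion tau^2 >= 0 estimated
    jointly; tau^2 absorbs systematic (balanced) pleiotropy. SE comes from
    the sandwich form with tau^2 held at its estimate.
    """
    _check_k(hset, 3, "raps")
    if psi not in ("huber", "identity"):
        raise ValueError(f"unknown psi {psi!r}")
    bx, sx, by, sy = hset.arrays()
    k = len(bx)
    c = tuning

    def apply_psi(t):
        return _huber_psi(t, c) if psi == "huber" else t

    delta = 2 * stats.norm.cdf(c) - 1 if psi == "huber" else 1.0

    def t_resid(theta, tau2):
        s = np.sqrt(sy**2 + theta**2 * sx**2 + tau2)
        return (by - theta * bx) / s, s

    def score_theta(theta, tau2):
        t, s = t_resid(theta, tau2)
        dt = -(bx + t * theta * sx**2 / s) / s
        return float(np.sum(apply_psi(t) * dt))

    def score_tau2(theta, tau2):
        t, s = t_resid(theta, tau2)
        return float(np.sum((apply_psi(t) * t - delta) / s**2))

    from scipy.optimize import brentq

    theta = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    tau2 = 0.0
    for _ in range(100):
        theta_old, tau2_old = theta, tau2
        if overdispersion:
            if score_tau2(theta, 0.0) <= 0:
                tau2 = 0.0
            else:
                hi = max(np.var(by), 1e-6)
                for _ in range(60):
                    if score_tau2(theta, hi) < 0:
                        break
                    hi *= 4.0
                else:
                    raise RuntimeError("raps: failed to bracket tau^2")
                tau2 = brentq(lambda t2: score_tau2(theta, t2), 0.0, hi, xtol=1e-14)
        width = max(10.0 * abs(theta), 1.0)
        lo, hi_b = theta - width, theta + width
        for _ in range(60):
            if score_theta(lo, tau2) * score_theta(hi_b, tau2) < 0:
                break
            lo -= width
            hi_b += width
            width *= 2.0
        else:
            raise RuntimeError("raps: failed to bracket a root for theta")
        theta = brentq(lambda th: score_theta(th, tau2), lo, hi_b, xtol=1e-12)
        if abs(theta - theta_old) < 1e-10 and abs(tau2 - tau2_old) < 1e-12:
            break

    # sandwich SE with tau^2 fixed at its estimate
    t, s = t_resid(theta, tau2)
    dt = -(bx + t * theta * sx**2 / s) / s
    g = apply_psi(t) * dt
    eps = 1e-6 * max(abs(theta), 1.0)
    a = (score_theta(theta + eps, tau2) - score_theta(theta - eps, tau2)) / (2 * eps)
    se = float(np.sqrt(np.sum(g**2)) / abs(a))
    return _normal_result(
        "raps", theta, se, k, {"tau2": float(tau2), "psi": psi, "overdispersion": overdispersion}
    )


def _loo_ivw_estimates(bx, by, w):
    """theta_hat_(-j) for every j, from fixed-effect IVW sums."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def presso(
    hset: HarmonizedSet,
    n_sim: int = 2000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> MRResult:
    """Pleiotropy residual sum and outlier test (global + outlier +
    distortion), with outlier-corrected IVW when outliers are found.

    The observed RSS uses leave-one-out IVW predictions; its null
    distribution comes from ``n_sim`` parametric simulations under the
    fitted no-pleiotropy model. Per-variant outliers are declared at
    Bonferroni-corrected ``outlier_alpha``.
    """
    _check_k(hset, 4, "presso")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    bx, sx, by, sy = hset.arrays()
    k = len(bx)
    w = 1.0 / sy**2
    rng = np.random.default_rng(seed)

    theta_loo = _loo_ivw_estimates(bx, by, w)
    rss_obs_j = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(rss_obs_j))

    # parametric null: beta_y centred on the LOO no-pleiotropy predictions
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    s_xy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    theta_loo_sim = (s_xy - w * bx_sim * by_sim) / (s_xx - w * bx_sim**2)
    rss_sim_j = w * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(rss_sim_j, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    p_j = (1 + np.sum(rss_sim_j >= rss_obs_j[None, :], axis=0)) / (1 + n_sim)
    outlier_mask = p_j * k < outlier_alpha
    outlier_ids = hset.df.loc[outlier_mask, "snp_id"].tolist()

    est_raw, se_raw, _ = _ivw_point(bx, by, sy)
    extras = {
        "presso_global_p": global_p,
        "outlier_ids": outlier_ids,
        "raw_estimate": est_raw,
        "n_sim": n_sim,
        "seed": seed,
    }
    if outlier_ids and (~outlier_mask).sum() < 2:
        # a gross outlier can contaminate every leave-one-out prediction,
        # flagging nearly all variants; report flags but skip correction
        extras.update(
            {
                "correction_skipped": True,
                "distortion_coefficient": np.nan,
                "distortion_p": np.nan,
            }
        )
        return _normal_result("presso", est_raw, se_raw, k, extras)
    if outlier_ids:
        keep = ~outlier_mask
        est, se_fe, q = _ivw_point(bx[keep], by[keep], sy[keep])
        n_out = int(outlier_mask.sum())
        d_obs = (est - est_raw) / abs(est) if est != 0 else np.inf
        d_sim = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(k, size=n_out, replace=False)
            m = np.ones(k, bool)
            m[drop] = False
            e_i, _, _ = _ivw_point(bx[m], by[m], sy[m])
            d_sim[i] = (e_i - est_raw) / abs(e_i) if e_i != 0 else np.inf
        distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (1 + n_sim))
        extras.update(
            {"distortion_coefficient": float(d_obs) * 100.0, "distortion_p": distortion_p}
        )
        res = _normal_result("presso", est, se_fe, int(keep.sum()), extras)
    else:
        extras.update({"distortion_coefficient": np.nan, "distortion_p": np.nan})
        res = _normal_result("presso", est_raw, se_raw, k, extras)
    return res


def scale_to_unit_decrease(result: MRResult, conversion: float = 1.0) -> MRResult:
    """Re-express an estimate per 1 mmol/l *decrease* in the exposure.

    ``conversion`` is 1 mmol/l expressed in the exposure GWAS's units
    (38.7 for LDL-C in mg/dl, 88.9 for TG in mg/dl, 1.0 if the GWAS is
    already in mmol/l). The sign flips (drug action lowers the lipid) and
    CI endpoints are re-ordered after the transform.
    """
    if conversion <= 0:
        raise ValueError(f"conversion must be positive, got {conversion}")
    factor = -conversion
    lo, hi = sorted((result.ci_low * factor, result.ci_high * factor))
    extras = dict(result.extras)
    extras["scaled_per_mmol_decrease"] = True
    extras["conversion"] = conversion
    return MRResult(
        result.method,
        result.estimate * factor,
        result.se * conversion,
        lo,
        hi,
        result.pval,
        result.n_snps,
        extras,
    )


def all_estimators(
    hset: HarmonizedSet,
    seed: int = 0,
    n_boot: int = 2000,
    n_sim: int = 2000,
) -> dict[str, MRResult]:
    """Run the full battery; estimators whose preconditions fail (too few
    SNPs, degenerate design) are skipped with the error message recorded
    under ``_skipped``."""
    out: dict[str, MRResult] = {}
    skipped: dict[str, str] = {}
    runs = [
        ("ivw", lambda: ivw(hset)),
        ("weighted_median", lambda: weighted_median(hset, n_boot=n_boot, seed=seed)),
        ("weighted_mode", lambda: weighted_mode(hset, n_boot=n_boot, seed=seed + 1)),
        ("robust_ivw", lambda: robust_ivw(hset)),
        ("egger", lambda: egger(hset)),
        ("raps", lambda: raps(hset)),
        ("presso", lambda: presso(hset, n_sim=n_sim, seed=seed + 2)),
    ]
    for name, fn in runs:
        try:
            out[name] = fn()
        except (ValueError, RuntimeError) as exc:
            skipped[name] = str(exc)
    if skipped:
        out["_skipped"] = skipped  # type: ignore[assignment]
    return out
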