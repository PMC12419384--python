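"""Two-sample MR estimators and sensitivity analyses.

All estimators operate on a harmonized-instrument table (see
:mod:`lipidmr.summary_stats`) restricted to retained rows. With per-SNP
exposure effects beta_exp (standard error se_exp) and outcome effects
beta_out (se_out) aligned to a shared effect allele, the per-SNP Wald ratio
is beta_out / beta_exp and the inverse-variance weight is
beta_exp² / se_out² (first-order weights; outcome uncertainty only).

Implemented: Wald ratio, fixed- and multiplicative random-effects IVW,
Cochran Q, MR-Egger (slope + pleiotropy intercept), weighted median,
mode-based estimate, MR-PRESSO global/outlier tests, and leave-one-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: 97.5% normal quantile used for every confidence interval
Z95 = 1.959964

_MIN_INSTRUMENTS = {"egger": 3, "weighted_median": 3, "weighted_mode": 3, "mr_presso": 4}


class EstimationError(ValueError):
    """Estimation cannot proceed (empty set, zero exposure effect, ...)."""


@dataclass
class MRResult:
    """One estimator's causal-effect estimate.

    ``beta`` is the effect of a 1-SD change in the exposure on the outcome
    (SD units for continuous outcomes, log-odds for binary ones). CI bounds
    are beta ± 1.959964·se.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    q_stat: float | None = None
    q_pvalue: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    seed: int | None = None


@dataclass
class PressoReport:
    """MR-PRESSO global heterogeneity and per-SNP outlier test report."""

    global_rss_observed: float
    global_p: float
    per_snp_outlier_p: dict[str, float]
    outliers_flagged: set[str] = field(default_factory=set)
    n_simulations: int = 1000
    seed: int = 0


def _arrays(insts: pd.DataFrame):
    be = insts["beta_exp"].to_numpy(dtype=float)
    se_e = insts["se_exp"].to_numpy(dtype=float)
    bo = insts["beta_out"].to_numpy(dtype=float)
    se_o = insts["se_out"].to_numpy(dtype=float)
    return be, se_e, bo, se_o


def _normal_p(z) -> float:
    return float(2.0 * stats.norm.sf(np.abs(z)))


def _result(method: str, beta: float, se: float, n_snp: int, pvalue: float | None = None,
            **extra) -> MRResult:
    if pvalue is None:
        pvalue = _normal_p(beta / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MRResult(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        pvalue=float(pvalue), n_snp=int(n_snp), **extra,
    )


def wald_ratio(beta_exp: float, beta_out: float, se_out: float,
               se_exp: float | None = None, second_order: bool = False) -> MRResult:
    """Single-SNP causal estimate beta_out / beta_exp.

    The default standard error is the first-order delta method
    se_out / |beta_exp|; with ``second_order=True`` (requires ``se_exp``)
    the exposure uncertainty term is added:
    sqrt(se_out²/beta_exp² + beta_out²·se_exp²/beta_exp⁴).
    """
    if beta_exp == 0:
        raise EstimationError("Wald ratio undefined: beta_exp = 0")
    beta = beta_out / beta_exp
    var = (se_out / beta_exp) ** 2
    if second_order:
        if se_exp is None:
            raise EstimationError("second-order Wald SE requires se_exp")
        var += beta_out**2 * se_exp**2 / beta_exp**4
    return _result("wald_ratio", beta, np.sqrt(var), 1)


def ivw(insts: pd.DataFrame, random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted estimate.

    Equivalent to weighted least squares of beta_out on beta_exp through the
    origin with weights 1/se_out². Fixed-effect SE is 1/sqrt(sum of IVW
    weights); the multiplicative random-effects SE inflates it by
    max(1, sqrt(Q/(n-1))). A single instrument reduces to the Wald ratio
    (reported as ivw_fixed).
    """
    if insts.empty:
        raise EstimationError("IVW on empty instrument set")
    be, _, bo, se_o = _arrays(insts)
    if np.any(be == 0):
        raise EstimationError("IVW undefined: some beta_exp = 0")
    if len(insts) == 1:
        r = wald_ratio(be[0], bo[0], se_o[0])
        r.method = "ivw_fixed"
        return r

    ratio = bo / be
    w = be**2 / se_o**2
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q, q_p = cochran_q(insts, beta)
    if random_effects:
        se = se_fixed * max(1.0, np.sqrt(q / (len(insts) - 1)))
        method = "ivw_random"
    else:
        se = se_fixed
        method = "ivw_fixed"
    return _result(method, beta, se, len(insts), q_stat=q, q_pvalue=q_p)


def cochran_q(insts: pd.DataFrame, beta_ivw: float) -> tuple[float, float]:
    """Cochran heterogeneity Q across per-SNP ratios and its chi-square
    p-value (n-1 df). Returns (nan, nan) for fewer than two instruments."""
    if len(insts) < 2:
        return (float("nan"), float("nan"))
    be, _, bo, se_o = _arrays(insts)
    ratio = bo / be
    w = be**2 / se_o**2
    q = float(np.sum(w * (ratio - beta_ivw) ** 2))
    return q, float(stats.chi2.sf(q, len(insts) - 1))


def egger(insts: pd.DataFrame) -> tuple[MRResult, MRResult] | None:
    """MR-Egger regression: pleiotropy-adjusted slope plus average-pleiotropy
    intercept.

    Instruments are first oriented so every beta_exp >= 0 (both betas negated
    where needed; required for intercept identifiability). Weighted least
    squares of beta_out on beta_exp with intercept and weights 1/se_out²;
    standard errors carry the multiplicative overdispersion factor
    max(1, sqrt(RSS_w/(n-2))) and p-values come from the t distribution with
    n-2 df. Returns None for fewer than three instruments.
    """
    n = len(insts)
    if n < _MIN_INSTRUMENTS["egger"]:
        return None
    be, _, bo, se_o = _arrays(insts)
    flip = np.sign(be)
    flip[flip == 0] = 1.0
    x = be * flip
    y = bo * flip
    w = 1.0 / se_o**2

    # closed-form weighted normal equations for y = a + b x
    sw = np.sum(w)
    sx = np.sum(w * x)
    sy = np.sum(w * y)
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    det = sw * sxx - sx * sx
    if det <= 0:
        raise EstimationError("Egger design is singular (no spread in beta_exp)")
    slope = (sw * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det

    resid = y - intercept - slope * x
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, np.sqrt(rss_w / (n - 2)))
    se_slope = np.sqrt(sw / det) * phi
    se_int = np.sqrt(sxx / det) * phi

    p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), df=n - 2))
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), df=n - 2))

    slope_res = _result("egger", slope, se_slope, n, pvalue=p_slope,
                        intercept=float(intercept), intercept_se=float(se_int),
                        intercept_p=p_int)
    int_res = _result("egger_intercept", intercept, se_int, n, pvalue=p_int)
    return slope_res, int_res


def _weighted_median_point(ratio: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratio, kind="mergesort")
    r = ratio[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, r))


def _boot_draws(insts, n_boot, seed):
    be, se_e, bo, se_o = _arrays(insts)
    rng = np.random.default_rng(seed)
    be_star = rng.normal(be, se_e, size=(n_boot, len(insts)))
    bo_star = rng.normal(bo, se_o, size=(n_boot, len(insts)))
    return be_star, bo_star, se_o


def weighted_median(insts: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MRResult | None:
    """Weighted-median estimator, consistent when instruments carrying >50%
    of the weight are valid.

    Ratios are sorted with normalized IVW weights; the estimate interpolates
    the ratio at cumulative weight 0.5. The SE is a parametric bootstrap:
    beta_exp and beta_out are redrawn from normals at their SEs, the estimate
    recomputed, and the SD over ``n_boot`` draws taken. Returns None below
    three instruments.
    """
    if len(insts) < _MIN_INSTRUMENTS["weighted_median"]:
        return None
    be, _, bo, se_o = _arrays(insts)
    w = be**2 / se_o**2
    beta = _weighted_median_point(bo / be, w)

    be_star, bo_star, se_o = _boot_draws(insts, n_boot, seed)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        wk = be_star[k] ** 2 / se_o**2
        boots[k] = _weighted_median_point(bo_star[k] / be_star[k], wk)
    se = float(np.std(boots, ddof=1))
    return _result("weighted_median", beta, se, len(insts), seed=seed)


def _weighted_mode_point(ratio: np.ndarray, w: np.ndarray,
                         bandwidth_factor: float, n_grid: int = 512) -> float:
    wn = w / np.sum(w)
    center = _weighted_median_point(ratio, wn)
    mad = _weighted_median_point(np.abs(ratio - center), wn)
    h = bandwidth_factor * 1.4826 * mad
    if h <= 0:
        # >50% of the weight sits on a single ratio value: that is the mode
        return center
    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, n_grid)
    dens = np.sum(wn * np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / h) ** 2), axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(insts: pd.DataFrame, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MRResult | None:
    """Mode-based estimate: the argmax of a normal-kernel-smoothed, weighted
    density of the per-SNP ratios, consistent when the largest homogeneous
    cluster of instruments is valid.

    Bandwidth is ``bandwidth_factor × 1.4826 × weighted MAD`` of the ratios;
    the density is evaluated on a 512-point grid spanning
    [min - 3h, max + 3h]. Bootstrap SE as in :func:`weighted_median`.
    """
    if len(insts) < _MIN_INSTRUMENTS["weighted_mode"]:
        return None
    be, _, bo, se_o = _arrays(insts)
    w = be**2 / se_o**2
    beta = _weighted_mode_point(bo / be, w, bandwidth_factor)

    be_star, bo_star, se_o = _boot_draws(insts, n_boot, seed)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        wk = be_star[k] ** 2 / se_o**2
        boots[k] = _weighted_mode_point(bo_star[k] / be_star[k], wk, bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    return _result("weighted_mode", beta, se, len(insts), seed=seed)


def _loo_ivw_betas(be: np.ndarray, bo: np.ndarray, se_o: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates for every SNP, via weight-sum updates."""
    wx = be / se_o**2
    s_xy = np.sum(wx * bo)
    s_xx = np.sum(wx * be)
    return (s_xy - wx * bo) / (s_xx - wx * be)


def mr_presso(insts: pd.DataFrame, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> tuple[PressoReport, MRResult] | None:
    """MR-PRESSO: simulation-based global pleiotropy test and per-SNP outlier
    detection on IVW residual sums of squares.

    The observed global RSS is sum_j w_j (beta_out_j - b(-j)·beta_exp_j)²
    with b(-j) the IVW estimate excluding SNP j. The null distribution is
    built by redrawing beta_out_j* ~ Normal(b(-j)·beta_exp_j, se_out_j²) and
    recomputing the RSS (with leave-one-out estimates refit on the redrawn
    data) for each of ``n_sim`` replicates; the global p is the empirical
    rank (1 + #{RSS* >= RSS_obs})/(n_sim + 1). Per-SNP outlier p-values are
    the analogous ranks of each SNP's weighted squared residual,
    Bonferroni-corrected by the number of SNPs; SNPs with corrected
    p < ``outlier_alpha`` are flagged and the corrected estimate is the IVW
    on the unflagged set. Returns None below four instruments.
    """
    n = len(insts)
    if n < _MIN_INSTRUMENTS["mr_presso"]:
        return None
    be, _, bo, se_o = _arrays(insts)
    snps = insts["snp"].tolist()
    w = be**2 / se_o**2

    b_loo = _loo_ivw_betas(be, bo, se_o)
    resid_obs = bo - b_loo * be
    rss_j_obs = w * resid_obs**2
    rss_obs = float(np.sum(rss_j_obs))

    rng = np.random.default_rng(seed)
    bo_star = rng.normal(b_loo * be, se_o, size=(n_sim, n))

    wx = be / se_o**2
    s_xx = np.sum(wx * be)
    s_xy_star = bo_star @ wx
    b_loo_star = (s_xy_star[:, None] - wx[None, :] * bo_star) / (s_xx - wx * be)[None, :]
    resid_star = bo_star - b_loo_star * be[None, :]
    rss_j_star = w[None, :] * resid_star**2
    rss_star = np.sum(rss_j_star, axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_snp_p = (1 + np.sum(rss_j_star >= rss_j_obs[None, :], axis=0)) / (n_sim + 1)
    corrected = np.minimum(1.0, per_snp_p * n)
    flagged = {snps[j] for j in range(n) if corrected[j] < outlier_alpha}

    report = PressoReport(
        global_rss_observed=rss_obs, global_p=global_p,
        per_snp_outlier_p={snps[j]: float(per_snp_p[j]) for j in range(n)},
        outliers_flagged=flagged, n_simulations=n_sim, seed=seed,
    )
    keep = insts.loc[~insts["snp"].isin(flagged)]
    if keep.empty:
        raise EstimationError("no instruments survive outlier removal")
    corrected_res = ivw(keep)
    corrected_res.method = "presso_outlier_corrected"
    corrected_res.seed = seed
    return report, corrected_res


def leave_one_out(insts: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    """IVW re-estimated with each SNP removed in turn.

    Returns a table keyed by the dropped SNP (forest-plot-ready) and a
    boolean that is True when all leave-one-out CIs exclude zero on the same
    side — the usual visual check that no single SNP drives the result.
    """
    if len(insts) < 2:
        raise EstimationError("leave-one-out needs at least 2 instruments")
    rows = []
    for j in range(len(insts)):
        rest = insts.drop(insts.index[j])
        res = ivw(rest)
        rows.append({
            "snp_dropped": insts.iloc[j]["snp"],
            "beta": res.beta, "se": res.se,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "pvalue": res.pvalue, "n_snp": res.n_snp,
        })
    table = pd.DataFrame(rows)
    same_side = bool((table["ci_low"] > 0).all() or (table["ci_high"] < 0).all())
    return table, same_side


def pvalue_from_estimate(beta: float, ci_low: float, ci_high: float) -> float:
    """Two-sided normal p-value implied by a point estimate and its 95% CI
    (se recovered as CI width / (2 × 1.959964)). Used to sanity-check
    published rows reported only as beta with CI."""
    if not ci_low < ci_high:
        raise EstimationError("degenerate confidence interval")
    se = (ci_high - ci_low) / (2.0 * Z95)
    return _normal_p(beta / se)


def results_table(results: dict[str, MRResult | None], drug_class: str = "",
                  gene: str = "") -> pd.DataFrame:
    """Flatten a method -> MRResult mapping into the standard output table
    (drug_class, gene, method, beta, ci_low, ci_high, pvalue, q_pvalue, n_snp)."""
    rows = []
    for method, res in results.items():
        if res is None:
            continue
        rows.append({
            "drug_class": drug_class, "gene": gene, "method": method,
            "beta": res.beta, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "pvalue": res.pvalue, "q_pvalue": res.q_pvalue, "n_snp": res.n_snp,
        })
    return pd.DataFrame(rows)
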