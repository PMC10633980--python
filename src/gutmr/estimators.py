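"""Causal-effect estimators and diagnostics for harmonized instrument tables.

Notation: for instrument j, (beta_Xj, se_Xj) is the exposure association and
(beta_Yj, se_Yj) the outcome association, aligned to a common effect allele.
Under the instrumental-variable assumptions each Wald ratio
theta_j = beta_Yj / beta_Xj estimates the causal effect theta.

* IVW combines ratios by inverse-variance weighting, equivalent to a weighted
  regression of beta_Y on beta_X through the origin with weights 1/se_Yj^2.
  The default multiplicative random-effects model inflates the fixed-effect
  SE by max(1, sqrt(Q/(J-1))) where Q is Cochran's heterogeneity statistic.
* MR-Egger adds an intercept; a non-zero intercept indicates directional
  pleiotropy (under InSIDE), and the slope remains a causal estimate.
* The weighted median is consistent when instruments carrying >= 50% of the
  weight are valid; the mode-based estimators when the largest group of
  instruments with equal ratios is valid (ZEMPA).
* MR-PRESSO detects outlying instruments by comparing observed residual sums
  of squares against a parametric simulation under the no-pleiotropy model,
  and re-estimates after outlier removal (with a distortion test for the
  raw-vs-corrected difference).

Wald-type 95% CIs (beta +- 1.96 se) throughout; odds-ratio columns are the
exponentiated fields for binary outcomes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats as sps

from .exceptions import EstimationError, InputError
from .harmonize import retained as _retained
from .sumstats import HarmonizedInstrument

log = logging.getLogger(__name__)

Z95 = 1.959963984540054

METHOD_WALD = "wald"
METHOD_IVW = "ivw"
METHOD_EGGER = "egger"
METHOD_WMEDIAN = "weighted_median"
METHOD_SIMPLE_MODE = "simple_mode"
METHOD_WEIGHTED_MODE = "weighted_mode"
METHOD_PRESSO_RAW = "presso_raw"
METHOD_PRESSO_CORRECTED = "presso_corrected"


@dataclass
class MREstimate:
    """One method's causal estimate with Wald CI and optional diagnostics."""

    method: str
    beta: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float
    nsnp: int
    or_: Optional[float] = None
    or_low: Optional[float] = None
    or_high: Optional[float] = None
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_pvalue: Optional[float] = None
    exposure: str = ""
    outcome: str = ""
    binary_outcome: bool = False
    seed: Optional[int] = None


@dataclass
class HeterogeneityResult:
    """Cochran's Q with its degrees of freedom and upper-tail chi-square p."""

    q_stat: float
    df: int
    pvalue: float


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_obs: float
    global_p: float
    outlier_ids: list[str]
    outlier_p: dict
    distortion_p: float
    corrected: MREstimate
    raw: MREstimate
    n_sim: int
    seed: Optional[int] = None


def _finalize(est: MREstimate, binary: bool = False,
              exposure: str = "", outcome: str = "") -> MREstimate:
    est.ci_low = est.beta - Z95 * est.se
    est.ci_high = est.beta + Z95 * est.se
    est.exposure = exposure or est.exposure
    est.outcome = outcome or est.outcome
    est.binary_outcome = binary or est.binary_outcome
    if est.binary_outcome:
        est.or_ = math.exp(est.beta)
        est.or_low = math.exp(est.ci_low)
        est.or_high = math.exp(est.ci_high)
    return est


def _norm_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


def _arrays(insts):
    ins = _retained(insts)
    bx = np.array([h.beta_exp for h in ins])
    sx = np.array([h.se_exp for h in ins])
    by = np.array([h.beta_out for h in ins])
    sy = np.array([h.se_out for h in ins])
    ids = [h.variant_id for h in ins]
    return bx, sx, by, sy, ids


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False,
               binary: bool = False) -> MREstimate:
    """Single-instrument ratio estimate beta_Y/beta_X.

    The default SE is first order (se_Y/|beta_X|), matching the weighting the
    IVW regression uses; ``second_order`` adds the exposure-noise term.
    """
    if inst.beta_exp == 0:
        raise EstimationError(f"{inst.variant_id}: Wald ratio undefined for beta_exp = 0")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    if second_order:
        se = math.sqrt(inst.se_out ** 2 / inst.beta_exp ** 2
                       + inst.beta_out ** 2 * inst.se_exp ** 2 / inst.beta_exp ** 4)
    est = MREstimate(METHOD_WALD, beta, se, _norm_p(beta / se), 0, 0, nsnp=1)
    return _finalize(est, binary)


def ivw(insts, model: str = "multiplicative_random",
        binary: bool = False) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate: regression of beta_Y on beta_X
    through the origin with weights 1/se_Yj^2, plus Cochran's Q."""
    bx, sx, by, sy, _ = _arrays(insts)
    j = len(bx)
    if j < 2:
        raise EstimationError("ivw needs >= 2 instruments; use wald_ratio for one")
    if model not in ("fixed", "multiplicative_random"):
        raise InputError(f"unknown IVW model {model!r}")
    w = 1.0 / sy ** 2
    sxx = float(np.sum(w * bx ** 2))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx ** -0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = j - 1
    q_p = float(sps.chi2.sf(q, df))
    se = se_fixed
    if model == "multiplicative_random":
        se = se_fixed * max(1.0, math.sqrt(q / df))
    est = MREstimate(METHOD_IVW, beta, se, _norm_p(beta / se), 0, 0, nsnp=j,
                     q_stat=q, q_df=df, q_pvalue=q_p)
    return _finalize(est, binary), HeterogeneityResult(q, df, q_p)


def egger(insts, binary: bool = False) -> tuple[MREstimate, HeterogeneityResult]:
    """MR-Egger: weighted regression of beta_Y on beta_X with an intercept.

    Exposure effects are oriented non-negative first (the Egger model is not
    invariant to allele re-coding). The intercept estimates the average
    directional pleiotropy; its SE shares the multiplicative random-effects
    inflation used for the slope.
    """
    bx, sx, by, sy, _ = _arrays(insts)
    j = len(bx)
    if j < 3:
        raise EstimationError("egger needs >= 3 instruments")
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(j), bx])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    coef = cov @ (XtW @ by)
    resid = by - X @ coef
    q = float(np.sum(w * resid ** 2))
    df = j - 2
    q_p = float(sps.chi2.sf(q, df))
    infl = max(1.0, math.sqrt(q / df))
    se_int, se_slope = np.sqrt(np.diag(cov)) * infl
    slope, intercept = float(coef[1]), float(coef[0])
    est = MREstimate(METHOD_EGGER, slope, float(se_slope),
                     _norm_p(slope / se_slope), 0, 0, nsnp=j,
                     intercept=intercept, intercept_se=float(se_int),
                     intercept_p=_norm_p(intercept / se_int),
                     q_stat=q, q_df=df, q_pvalue=q_p)
    return _finalize(est, binary), HeterogeneityResult(q, df, q_p)


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with the p_j = (S_j - w_j/2)/S_J interpolation
    convention. ``ratios`` and ``weights`` are (B, J)."""
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    s = np.cumsum(w, axis=1)
    total = s[:, -1:]
    p = (s - w / 2.0) / total
    out = np.empty(ratios.shape[0])
    for b in range(ratios.shape[0]):
        pb, rb = p[b], r[b]
        if pb[0] >= 0.5:
            out[b] = rb[0]
        elif pb[-1] <= 0.5:
            out[b] = rb[-1]
        else:
            k = int(np.searchsorted(pb, 0.5, side="right")) - 1
            out[b] = rb[k] + (rb[k + 1] - rb[k]) * (0.5 - pb[k]) / (pb[k + 1] - pb[k])
    return out


def weighted_median(insts, n_boot: int = 1000, seed: int = 0,
                    binary: bool = False) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP ratios are weighted by beta_Xj^2/se_Yj^2 (the inverse of the
    first-order ratio variance); the estimate is the value at cumulative
    weight 0.5 with linear interpolation.
    """
    bx, sx, by, sy, _ = _arrays(insts)
    j = len(bx)
    if j < 3:
        raise EstimationError("weighted_median needs >= 3 instruments")
    if n_boot < 100:
        log.warning("weighted_median: n_boot=%d is small; SEs will be noisy", n_boot)
    ratios = by / bx
    weights = bx ** 2 / sy ** 2
    beta = float(_weighted_median_rows(ratios[None, :], weights[None, :])[0])
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, j))
    bys = rng.normal(by, sy, size=(n_boot, j))
    boots = _weighted_median_rows(bys / bxs, bxs ** 2 / sy ** 2)
    se = float(np.std(boots, ddof=1))
    est = MREstimate(METHOD_WMEDIAN, beta, se, _norm_p(beta / se), 0, 0,
                     nsnp=j, seed=seed)
    return _finalize(est, binary)


def _silverman_bw(x: np.ndarray, factor: float) -> float:
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    s = min(sd, iqr / 1.349) if iqr > 0 else sd
    if s <= 0:
        return 0.0
    return factor * 0.9 * s * len(x) ** (-1.0 / 5.0)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, h: float,
                grid: np.ndarray) -> float:
    # normal-kernel weighted density, argmax on a fixed grid
    z = (grid[:, None] - ratios[None, :]) / h
    dens = (np.exp(-0.5 * z ** 2) * weights[None, :]).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(insts, weighted: bool = True, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0, binary: bool = False,
                  grid_size: int = 512) -> MREstimate:
    """Mode-based estimator: argmax of a normal-kernel density of the per-SNP
    ratios (weights 1/se_ratio^2 when ``weighted``), bandwidth from a modified
    Silverman rule scaled by ``bandwidth_factor``; SE by parametric bootstrap.
    """
    bx, sx, by, sy, _ = _arrays(insts)
    j = len(bx)
    if j < 3:
        raise EstimationError("mode_estimate needs >= 3 instruments")
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    weights = 1.0 / se_ratio ** 2 if weighted else np.ones(j)
    weights = weights / weights.sum()
    h = _silverman_bw(ratios, bandwidth_factor)
    rng = np.random.default_rng(seed)
    method = METHOD_WEIGHTED_MODE if weighted else METHOD_SIMPLE_MODE

    bxs = rng.normal(bx, sx, size=(n_boot, j))
    bys = rng.normal(by, sy, size=(n_boot, j))
    rats = bys / bxs
    if weighted:
        wts = np.abs(bxs) ** 2 / sy[None, :] ** 2
    else:
        wts = np.ones_like(rats)
    wts = wts / wts.sum(axis=1, keepdims=True)

    if h == 0.0:
        # all ratios identical: the mode is that common value
        beta = float(ratios[0])
        boots = np.median(rats, axis=1)
    else:
        lo = ratios.min() - 3 * h
        hi = ratios.max() + 3 * h
        grid = np.linspace(lo, hi, grid_size)
        beta = _mode_point(ratios, weights, h, grid)
        boots = np.empty(n_boot)
        sds = np.std(rats, axis=1, ddof=1)
        q75, q25 = np.percentile(rats, [75, 25], axis=1)
        iqrs = q75 - q25
        s = np.where(iqrs > 0, np.minimum(sds, iqrs / 1.349), sds)
        hs = np.maximum(bandwidth_factor * 0.9 * s * j ** (-0.2), 1e-12)
        glo = rats.min() - 3 * hs.max()
        ghi = rats.max() + 3 * hs.max()
        bgrid = np.linspace(glo, ghi, grid_size)
        chunk = max(1, int(2e6 // (grid_size * j)))
        for start in range(0, n_boot, chunk):
            end = min(start + chunk, n_boot)
            z = (bgrid[None, :, None] - rats[start:end, None, :]) / hs[start:end, None, None]
            dens = (np.exp(-0.5 * z ** 2) * wts[start:end, None, :]).sum(axis=2)
            boots[start:end] = bgrid[np.argmax(dens, axis=1)]
    se = float(np.std(boots, ddof=1))
    est = MREstimate(method, beta, se, _norm_p(beta / se), 0, 0, nsnp=j, seed=seed)
    return _finalize(est, binary)


def _loo_ivw_theta(bx, by, w):
    """Leave-one-out IVW estimates theta_(-j), vectorized."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx ** 2)
    return (sxy - w * bx * by) / (sxx - w * bx ** 2)


def mr_presso(insts, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int = 0, n_distortion: int = 1000,
              binary: bool = False) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    The observed residual sum of squares uses leave-one-out IVW predictions
    weighted by 1/se_Yj^2; the null distribution comes from ``n_sim``
    parametric simulations of (beta_X*, beta_Y*) under the no-pleiotropy
    model. Per-SNP outlier p-values are Bonferroni-corrected by instrument
    count at ``outlier_alpha``; the distortion test compares the raw-vs-
    corrected estimate difference against random removals of the same size.
    """
    bx, sx, by, sy, ids = _arrays(insts)
    j = len(bx)
    if j < 4:
        raise EstimationError("mr_presso needs >= 4 instruments")
    if n_sim < 1000:
        raise InputError("mr_presso needs n_sim >= 1000")
    w = 1.0 / sy ** 2
    theta_loo = _loo_ivw_theta(bx, by, w)
    res_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_sim, j))
    bys = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    sxy = (w * bxs * bys).sum(axis=1, keepdims=True)
    sxx = (w * bxs ** 2).sum(axis=1, keepdims=True)
    theta_loo_sim = (sxy - w * bxs * bys) / (sxx - w * bxs ** 2)
    res_sim = w * (bys - theta_loo_sim * bxs) ** 2
    rss_sim = res_sim.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_per = (1 + (res_sim >= res_obs[None, :]).sum(axis=0)) / (n_sim + 1)
    outlier_p = {ids[k]: float(p_per[k]) for k in range(j)}
    flags = p_per * j < outlier_alpha
    outlier_ids = [ids[k] for k in range(j) if flags[k]]

    raw_est, _ = ivw(insts, binary=binary)
    raw_est = replace(raw_est, method=METHOD_PRESSO_RAW)
    keep = [h for h in _retained(insts) if h.variant_id not in set(outlier_ids)]
    distortion_p = float("nan")
    if outlier_ids and len(keep) >= 2:
        corr_est, _ = ivw(keep, binary=binary)
        corr_est = replace(corr_est, method=METHOD_PRESSO_CORRECTED)
        d_obs = abs(raw_est.beta - corr_est.beta)
        k = len(outlier_ids)
        d_null = np.empty(n_distortion)
        for b in range(n_distortion):
            drop = rng.choice(j, size=k, replace=False)
            mask = np.ones(j, dtype=bool)
            mask[drop] = False
            bxm, bym, wm = bx[mask], by[mask], w[mask]
            theta_b = float(np.sum(wm * bxm * bym) / np.sum(wm * bxm ** 2))
            d_null[b] = abs(raw_est.beta - theta_b)
        distortion_p = float((1 + np.sum(d_null >= d_obs)) / (n_distortion + 1))
    elif outlier_ids and len(keep) == 1:
        corr_est = wald_ratio(keep[0], binary=binary)
        corr_est = replace(corr_est, method=METHOD_PRESSO_CORRECTED)
    else:
        corr_est = replace(raw_est, method=METHOD_PRESSO_CORRECTED)
    return PressoResult(global_rss_obs=rss_obs, global_p=global_p,
                        outlier_ids=outlier_ids, outlier_p=outlier_p,
                        distortion_p=distortion_p, corrected=corr_est,
                        raw=raw_est, n_sim=n_sim, seed=seed)


@dataclass
class EstimatorConfig:
    """Knobs for the method battery; every stochastic step takes an explicit seed."""

    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    n_sim: int = 1000
    outlier_alpha: float = 0.05
    bandwidth_factor: float = 1.0
    seed: int = 0


def estimate_all(insts, binary: bool = False,
                 config: Optional[EstimatorConfig] = None) -> list[MREstimate]:
    """Run the method battery appropriate to the instrument count.

    1 instrument: Wald ratio only. 2: IVW only. >= 3: adds Egger, weighted
    median and both mode estimators. >= 4: adds MR-PRESSO (raw + corrected).
    """
    cfg = config or EstimatorConfig()
    ins = _retained(insts)
    j = len(ins)
    if j == 0:
        raise InputError("estimate_all: no retained instruments")
    if j == 1:
        return [wald_ratio(ins[0], binary=binary)]
    out = [ivw(ins, model=cfg.ivw_model, binary=binary)[0]]
    if j >= 3:
        out.append(egger(ins, binary=binary)[0])
        out.append(weighted_median(ins, n_boot=cfg.n_boot, seed=cfg.seed, binary=binary))
        out.append(mode_estimate(ins, weighted=False, bandwidth_factor=cfg.bandwidth_factor,
                                 n_boot=cfg.n_boot, seed=cfg.seed + 1, binary=binary))
        out.append(mode_estimate(ins, weighted=True, bandwidth_factor=cfg.bandwidth_factor,
                                 n_boot=cfg.n_boot, seed=cfg.seed + 2, binary=binary))
    if j >= 4:
        presso = mr_presso(ins, n_sim=cfg.n_sim, outlier_alpha=cfg.outlier_alpha,
                           seed=cfg.seed + 3, binary=binary)
        out.append(presso.corrected)
    return out
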