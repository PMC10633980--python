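"""Two-step MR mediation and multivariable MR.

The mediation triangle is taxon (X) -> risk factor (M) -> outcome (Y):
beta1 is the effect of the taxon on the risk factor, beta2 the effect of the
risk factor on the outcome, beta3 the total effect of the taxon on the
outcome. The indirect effect is the product beta1*beta2 and the proportion
mediated is beta1*beta2/beta3, with uncertainty from a parametric bootstrap
that treats the three coefficients as independent normals (they come from
non-overlapping two-sample fits).

Multivariable MR regresses the outcome effects of the pooled instrument set
on the matrix of exposure effects (no intercept, weights 1/se_out^2); each
coefficient is an exposure's direct effect conditional on the others, used to
validate that a mediator carries part of the taxon's total effect.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .estimators import MREstimate, ivw, wald_ratio
from .exceptions import EstimationError, InputError
from .harmonize import retained as _retained

log = logging.getLogger(__name__)


@dataclass
class TwoStepEffects:
    """The three coefficients of the mediation triangle, with SEs."""

    beta1: float
    se1: float
    beta2: float
    se2: float
    beta3: float
    se3: float


@dataclass
class MVMRResult:
    """Direct effects of each exposure conditional on the others."""

    exposures: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvalues: np.ndarray
    nsnp: int


@dataclass
class MediationResult:
    """Product-of-coefficients mediation estimate with bootstrap CI."""

    beta1: float
    beta2: float
    beta3: float
    indirect: float
    proportion: float
    se_prop: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_boot: int
    seed: int
    unstable: bool = False


def _primary(insts) -> MREstimate:
    ins = _retained(insts)
    if len(ins) == 0:
        raise EstimationError("no retained instruments")
    if len(ins) == 1:
        return wald_ratio(ins[0])
    return ivw(ins)[0]


def two_step_mr(taxon_mediator_insts, mediator_outcome_insts,
                taxon_outcome: MREstimate) -> TwoStepEffects:
    """Estimate the triangle's coefficients.

    beta1 = IVW (or Wald) of the taxon on the mediator, beta2 = IVW of the
    mediator on the outcome, beta3 = the taxon's total effect on the outcome
    (from the screening stage).
    """
    e1 = _primary(taxon_mediator_insts)
    e2 = _primary(mediator_outcome_insts)
    return TwoStepEffects(beta1=e1.beta, se1=e1.se,
                          beta2=e2.beta, se2=e2.se,
                          beta3=taxon_outcome.beta, se3=taxon_outcome.se)


def mvmr_fit(outcome_betas: Sequence[float], exposure_beta_matrix,
             outcome_ses: Sequence[float],
             exposure_ids: Optional[Sequence[str]] = None) -> MVMRResult:
    """Weighted least squares of outcome betas on the exposure-beta matrix
    without intercept, weights 1/se_out^2. SEs carry the same multiplicative
    random-effects floor as IVW (of which this is the multi-exposure
    generalization; with k=1 it reduces to IVW exactly).
    """
    y = np.asarray(outcome_betas, dtype=float)
    X = np.atleast_2d(np.asarray(exposure_beta_matrix, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, k = X.shape
    ids = list(exposure_ids) if exposure_ids is not None else [f"exposure_{i}" for i in range(k)]
    if n <= k:
        raise InputError(f"mvmr_fit needs more instruments ({n}) than exposures ({k})")
    sy = np.asarray(outcome_ses, dtype=float)
    w = 1.0 / sy ** 2
    XtW = X.T * w
    gram = XtW @ X
    if np.linalg.matrix_rank(gram) < k:
        raise EstimationError(f"rank-deficient design: collinear exposures among {ids}")
    cov = np.linalg.inv(gram)
    coef = cov @ (XtW @ y)
    resid = y - X @ coef
    q = float(np.sum(w * resid ** 2))
    infl = max(1.0, np.sqrt(q / (n - k)))
    ses = np.sqrt(np.diag(cov)) * infl
    p = 2.0 * sps.norm.sf(np.abs(coef / ses))
    return MVMRResult(exposures=ids, betas=coef, ses=ses, pvalues=p, nsnp=n)


def mediation_proportion(beta1: float, se1: float, beta2: float, se2: float,
                         beta3: float, se3: float, n_boot: int = 2000,
                         seed: int = 0) -> MediationResult:
    """Proportion mediated beta1*beta2/beta3 with bootstrap percentile CI.

    Draws (beta1*, beta2*, beta3*) independently from Normal(beta_i, se_i^2);
    se_prop is the SD of the draws and the p-value comes from the normal
    approximation |proportion|/se_prop. Draws in which beta3* crosses zero
    make the ratio unstable; they are retained but flagged when more than 1%.
    """
    if beta3 == 0:
        raise EstimationError("mediation proportion undefined: total effect beta3 = 0")
    if n_boot < 1000:
        raise InputError("mediation_proportion needs n_boot >= 1000")
    indirect = beta1 * beta2
    proportion = indirect / beta3
    rng = np.random.default_rng(seed)
    b1 = rng.normal(beta1, se1, n_boot)
    b2 = rng.normal(beta2, se2, n_boot)
    b3 = rng.normal(beta3, se3, n_boot)
    draws = b1 * b2 / b3
    crossing = float(np.mean(np.sign(b3) != np.sign(beta3)))
    unstable = crossing > 0.01
    if unstable:
        log.warning("mediation bootstrap: %.1f%% of beta3 draws cross zero; "
                    "proportion CI is unstable", 100 * crossing)
    ci_low, ci_high = np.percentile(draws, [2.5, 97.5])
    se_prop = float(np.std(draws, ddof=1))
    pvalue = float(2.0 * sps.norm.sf(abs(proportion) / se_prop))
    return MediationResult(beta1=beta1, beta2=beta2, beta3=beta3,
                           indirect=indirect, proportion=proportion,
                           se_prop=se_prop, ci_low=float(ci_low),
                           ci_high=float(ci_high), pvalue=pvalue,
                           n_boot=n_boot, seed=seed, unstable=unstable)
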