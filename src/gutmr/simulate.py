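"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the data the pipeline consumes in the field:

* ``simulate_sumstats`` — a two-sample MR dataset. Per SNP j the minor-allele
  frequency is uniform on ``maf_range``, the true exposure effect gamma_j is
  Normal(0, gamma_sd^2), and GWAS standard errors follow the standard
  per-allele approximation se = 1/sqrt(2 f (1-f) n) where n is the (effective)
  sample size. Instruments are drawn conditional on passing the discovery
  p-value threshold, emulating how suggestive instruments are ascertained
  (real instrument sets are by construction strong, F > ~19). Outcome effects
  are Gamma_j = theta * gamma_j + alpha_j with alpha_j the pleiotropic effect
  (none / balanced mean-zero / directional).
* ``simulate_triangle`` — three summary-statistic pairs for a mediation
  triangle X -> M -> Y with known beta1, beta2 and direct effect delta, so
  the total effect is beta3 = delta + beta1*beta2. Instrument sets for X and
  M are disjoint.
* ``simulate_cohort`` — an individual-level cohort: binomial genotype
  dosages, age/sex/batch/centre/PC covariates, exponential event times whose
  log-hazard is linear in the wt-GRS and covariates, independent exponential
  censoring plus an administrative end of follow-up, a competing-death
  process, and a configurable prevalent fraction.

All generators are pure functions of their config (seed mandatory).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable
from .exceptions import InputError
from .sumstats import SNPAssociation, SummaryStats

DAYS_PER_YEAR = 365.25

# Non-palindromic allele pairs; palindrome handling is exercised by
# dedicated harmonization fixtures rather than the bulk generators.
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass
class TriangleParams:
    """Ground-truth mediation triangle: X->M (beta1), M->Y (beta2), direct X->Y (delta)."""

    beta1: float = 0.05
    beta2: float = 0.336
    delta: float = 0.123

    @property
    def beta3(self) -> float:
        return self.delta + self.beta1 * self.beta2

    @property
    def proportion(self) -> float:
        return self.beta1 * self.beta2 / self.beta3


@dataclass
class SimulationConfig:
    """Study conditions for the generators.

    Defaults mirror the motivating study design: a gut-microbiome exposure
    GWAS of 7,738 individuals yielding a handful of suggestive instruments,
    and a large binary outcome GWAS whose ``n_out`` is an effective sample
    size (~the case count when cases are heavily outnumbered). ``theta`` is
    the true causal effect on the outcome scale (log-odds for binary).
    """

    n_snps: int = 10
    n_exp: float = 7738.0
    n_out: float = 60620.0
    theta: float = 0.0
    pleiotropy_mode: str = "none"      # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    maf_range: tuple = (0.05, 0.5)
    gamma_sd: float = 0.15
    instrument_p_threshold: Optional[float] = 1e-5  # None disables ascertainment
    triangle: Optional[TriangleParams] = None
    mediator_n_snps: int = 50
    n_mediator: float = 300000.0
    cohort_n: int = 50000
    true_hr: float = 1.14              # hazard ratio per wt-GRS unit
    baseline_hazard: float = 0.005     # events per person-year
    censor_rate: float = 0.02          # loss-to-follow-up per person-year
    death_rate: float = 0.004          # competing death per person-year
    followup_years: float = 13.0       # administrative end of follow-up
    prevalent_frac: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise InputError("SimulationConfig.seed is mandatory")
        if self.pleiotropy_sd < 0 or self.gamma_sd < 0:
            raise InputError("standard deviations must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InputError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise InputError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")


def _se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def _draw_instruments(rng: np.random.Generator, n_snps: int, cfg: SimulationConfig,
                      n_sample: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (maf, gamma, observed beta_x) conditional on discovery ascertainment."""
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, n_snps)
    se_x = _se(maf, n_sample)
    gamma = rng.normal(0.0, cfg.gamma_sd, n_snps)
    bx = rng.normal(gamma, se_x)
    if cfg.instrument_p_threshold is not None:
        zcrit = sps.norm.isf(cfg.instrument_p_threshold / 2.0)
        for _ in range(10_000):
            fail = np.abs(bx / se_x) <= zcrit
            if not fail.any():
                break
            k = int(fail.sum())
            gamma[fail] = rng.normal(0.0, cfg.gamma_sd, k)
            bx[fail] = rng.normal(gamma[fail], se_x[fail])
        else:
            raise InputError("instrument ascertainment failed to converge; "
                             "gamma_sd too small for the discovery threshold")
    return maf, gamma, bx


def _records(prefix: str, rng: np.random.Generator, maf, beta, se,
             n_sample: float, id_offset: int = 0) -> list[SNPAssociation]:
    pvals = _pvals(beta, se)
    recs = []
    for j in range(len(maf)):
        k = j + id_offset
        ea, oa = _ALLELE_PAIRS[k % len(_ALLELE_PAIRS)]
        recs.append(SNPAssociation(
            variant_id=f"{prefix}{k + 1}",
            chromosome=str(k % 22 + 1),
            position=int(1_000_000 + (k // 22) * 25_000_000),
            effect_allele=ea, other_allele=oa,
            eaf=float(maf[j]), beta=float(beta[j]), se=float(se[j]),
            pvalue=float(pvals[j]), n=n_sample))
    return recs


def simulate_sumstats(config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None,
                      variant_prefix: str = "rs",
                      outcome_binary: bool = True):
    """Generate an (exposure, outcome) summary-statistics pair plus the truth.

    Returns ``(SummaryStats, SummaryStats, truth_dict)`` where the truth dict
    retains per-SNP gamma and alpha and the causal effect theta.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    maf, gamma, bx = _draw_instruments(rng, config.n_snps, config, config.n_exp)
    se_x = _se(maf, config.n_exp)
    if config.pleiotropy_mode == "none":
        alpha = np.zeros(config.n_snps)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, config.n_snps)
    else:
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, config.n_snps)
    big_gamma = config.theta * gamma + alpha
    se_y = _se(maf, config.n_out)
    by = rng.normal(big_gamma, se_y)
    exposure = SummaryStats(
        trait_id="exposure", trait_type="continuous",
        records=_records(variant_prefix, rng, maf, bx, se_x, config.n_exp))
    outcome = SummaryStats(
        trait_id="outcome", trait_type="binary" if outcome_binary else "continuous",
        records=_records(variant_prefix, rng, maf, by, se_y, config.n_out))
    truth = {"theta": config.theta, "gamma": gamma, "alpha": alpha, "maf": maf}
    return exposure, outcome, truth


@dataclass
class TriangleData:
    """Three summary-statistics pairs plus ground truth for a mediation triangle."""

    taxon_mediator: tuple     # (exposure SummaryStats, outcome SummaryStats)
    mediator_outcome: tuple
    taxon_outcome: tuple
    truth: dict


def simulate_triangle(config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None) -> TriangleData:
    """Generate the three GWAS pairs of a mediation triangle.

    The taxon's instruments (``n_snps``, discovered at ``n_exp``) appear in
    the mediator GWAS with effect beta1*gamma and in the outcome GWAS with
    effect beta3*gamma (total effect); the mediator's own instruments
    (``mediator_n_snps``, discovered at ``n_mediator``) appear in the outcome
    GWAS with effect beta2*delta_m. Instrument sets are disjoint.
    """
    if config.triangle is None:
        raise InputError("simulate_triangle requires config.triangle")
    tri = config.triangle
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    maf_t, gamma_t, bx_t = _draw_instruments(rng, config.n_snps, config, config.n_exp)
    se_xt = _se(maf_t, config.n_exp)
    taxon_exp = SummaryStats("taxon", "continuous",
                             _records("rsX", rng, maf_t, bx_t, se_xt, config.n_exp))

    se_m_at_t = _se(maf_t, config.n_mediator)
    bm = rng.normal(tri.beta1 * gamma_t, se_m_at_t)
    mediator_out = SummaryStats("mediator", "continuous",
                                _records("rsX", rng, maf_t, bm, se_m_at_t, config.n_mediator))

    se_y_at_t = _se(maf_t, config.n_out)
    by_t = rng.normal(tri.beta3 * gamma_t, se_y_at_t)
    outcome_at_t = SummaryStats("outcome", "binary",
                                _records("rsX", rng, maf_t, by_t, se_y_at_t, config.n_out))

    med_cfg = replace(config, n_snps=config.mediator_n_snps, n_exp=config.n_mediator)
    maf_m, delta_m, bx_m = _draw_instruments(rng, med_cfg.n_snps, med_cfg, med_cfg.n_exp)
    se_xm = _se(maf_m, config.n_mediator)
    mediator_exp = SummaryStats("mediator", "continuous",
                                _records("rsM", rng, maf_m, bx_m, se_xm, config.n_mediator))
    se_y_at_m = _se(maf_m, config.n_out)
    by_m = rng.normal(tri.beta2 * delta_m, se_y_at_m)
    outcome_at_m = SummaryStats("outcome", "binary",
                                _records("rsM", rng, maf_m, by_m, se_y_at_m, config.n_out))

    truth = {"beta1": tri.beta1, "beta2": tri.beta2, "delta": tri.delta,
             "beta3": tri.beta3, "proportion": tri.proportion}
    return TriangleData(taxon_mediator=(taxon_exp, mediator_out),
                        mediator_outcome=(mediator_exp, outcome_at_m),
                        taxon_outcome=(taxon_exp, outcome_at_t),
                        truth=truth)


def simulate_cohort(config: SimulationConfig, weights: dict,
                    rng: Optional[np.random.Generator] = None) -> CohortTable:
    """Generate an individual-level cohort whose hazard is log-linear in the
    wt-GRS built from ``weights`` (variant_id -> per-allele weight)."""
    if config.cohort_n <= 0:
        raise InputError("cohort_n must be positive")
    if not weights:
        raise InputError("simulate_cohort needs a non-empty weight mapping")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.cohort_n
    snp_ids = list(weights)
    k = len(snp_ids)
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, k)
    dosages = rng.binomial(2, maf, size=(n, k)).astype(float)
    w = np.array([weights[v] for v in snp_ids])
    score = dosages @ w

    age = rng.normal(56.7, 8.0, n)
    sex = rng.binomial(1, 0.46, n)
    batch = rng.integers(0, 4, n)
    center = rng.integers(0, 10, n)
    pcs = rng.normal(0.0, 1.0, size=(n, 4))
    covariates = pd.DataFrame({"age": age, "sex": sex.astype(float),
                               "batch": batch, "center": center,
                               "pc1": pcs[:, 0], "pc2": pcs[:, 1],
                               "pc3": pcs[:, 2], "pc4": pcs[:, 3]})

    lp = (math.log(config.true_hr) * score
          + 0.06 * (age - 56.7) / 8.0 + 0.35 * sex + 0.05 * pcs[:, 0])
    hazard = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = (rng.exponential(1.0 / config.censor_rate, n)
                if config.censor_rate > 0 else np.full(n, np.inf))
    t_death = (rng.exponential(1.0 / config.death_rate, n)
               if config.death_rate > 0 else np.full(n, np.inf))
    t_admin = np.full(n, config.followup_years)
    exit_y = np.minimum.reduce([t_event, t_censor, t_death, t_admin])
    event = np.zeros(n, dtype=int)
    event[t_event <= exit_y] = 1
    death_first = (t_death <= exit_y) & (event != 1)
    event[death_first] = 2
    prevalent = rng.random(n) < config.prevalent_frac

    return CohortTable(
        ids=np.array([f"id{i}" for i in range(n)]),
        dosages=dosages, snp_ids=snp_ids, covariates=covariates,
        entry_time=np.zeros(n),
        exit_time=np.round(exit_y * DAYS_PER_YEAR).astype(float),
        event=event, prevalent=prevalent)
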