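"""Individual-level replication: weighted genetic risk scores and
proportional-hazards association with incident events.

A participant's weighted genetic risk score (wt-GRS) for a taxon is the
dosage-weighted sum of that taxon's instrument effect sizes. Prevalent cases
(event on or before recruitment) are excluded; the remaining cohort is fitted
with a Cox proportional hazards model (Efron tie handling) of incident events
on the score, adjusted for age, sex, genotyping batch, assessment centre and
genetic principal components. The proportional-hazards assumption is checked
with the scaled-Schoenfeld-residual test.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

from .exceptions import ConfigurationError, EstimationError, InputError

log = logging.getLogger(__name__)

#: event codes
CENSORED, INCIDENT, COMPETING_DEATH = 0, 1, 2

#: covariate columns treated as categorical codes (one-hot encoded for the fit)
CATEGORICAL_COVARIATES = ("batch", "center")


@dataclass
class CohortTable:
    """Per-individual dosages, covariates, follow-up and event status."""

    ids: np.ndarray
    dosages: np.ndarray          # (n_individuals, n_snps), values in [0, 2]
    snp_ids: list[str]
    covariates: pd.DataFrame
    entry_time: np.ndarray       # days from recruitment
    exit_time: np.ndarray
    event: np.ndarray            # 0 censored, 1 incident event, 2 competing death
    prevalent: np.ndarray        # boolean

    def __post_init__(self):
        n = len(self.ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (n, len(self.snp_ids)):
            raise InputError("dosage matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise InputError("dosages must lie in [0, 2]")
        if np.any(self.entry_time < 0) or np.any(self.exit_time < self.entry_time):
            raise InputError("times must satisfy exit_time >= entry_time >= 0")
        if len(self.covariates) != n:
            raise InputError("covariate table length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(
            ids=self.ids[mask], dosages=self.dosages[mask], snp_ids=self.snp_ids,
            covariates=self.covariates.loc[mask].reset_index(drop=True),
            entry_time=self.entry_time[mask], exit_time=self.exit_time[mask],
            event=self.event[mask], prevalent=self.prevalent[mask])


@dataclass
class GRSAssociation:
    """Cox association of a taxon's wt-GRS with incident events."""

    taxon_id: str
    hr: float
    ci_low: float
    ci_high: float
    pvalue: float
    n: int
    n_events: int
    ph_test_p: float
    log_hr: float = float("nan")
    log_hr_se: float = float("nan")


def compute_wtgrs(cohort: CohortTable, weights: dict) -> np.ndarray:
    """score_i = sum_k w_k * dosage_ik; missing dosages are mean-imputed per SNP."""
    idx = {v: i for i, v in enumerate(cohort.snp_ids)}
    for v in weights:
        if v not in idx:
            raise ConfigurationError(f"weight refers to variant {v!r} with no dosage column")
    cols = [idx[v] for v in weights]
    w = np.array([weights[v] for v in weights], dtype=float)
    dos = cohort.dosages[:, cols].copy()
    n_imputed = int(np.isnan(dos).sum())
    if n_imputed:
        means = np.nanmean(dos, axis=0)
        nan_rows, nan_cols = np.where(np.isnan(dos))
        dos[nan_rows, nan_cols] = means[nan_cols]
        log.info("compute_wtgrs: mean-imputed %d missing dosage value(s)", n_imputed)
    return dos @ w


def exclude_prevalent(cohort: CohortTable) -> CohortTable:
    """Drop participants whose event predates or coincides with recruitment."""
    mask = ~cohort.prevalent.astype(bool)
    n_drop = int((~mask).sum())
    if n_drop:
        log.info("excluded %d prevalent case(s); %d retained", n_drop, int(mask.sum()))
    return cohort.subset(mask)


def fit_ph(cohort: CohortTable, scores: np.ndarray,
           adjust: Sequence[str] = ("age", "sex"), taxon_id: str = "",
           standardize: bool = False, ph_test: bool = True) -> GRSAssociation:
    """Cox proportional-hazards fit of incident events on the wt-GRS.

    Competing deaths (event code 2) are censored, mirroring the primary
    analysis; ``standardize`` rescales the score to unit SD so the HR is per
    SD rather than per score unit. The Schoenfeld p-value tests the
    proportional-hazards assumption for the score term (rank time transform).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(cohort):
        raise InputError("score vector length mismatch")
    duration = (cohort.exit_time - cohort.entry_time).astype(float)
    observed = (cohort.event == INCIDENT).astype(int)
    n_events = int(observed.sum())
    if n_events == 0:
        raise InputError("fit_ph: zero incident events")
    if n_events < 2:
        raise InputError("fit_ph: needs at least 2 incident events")
    if np.std(scores) == 0:
        # no variation: the score cannot be associated with anything
        return GRSAssociation(taxon_id=taxon_id, hr=1.0, ci_low=1.0, ci_high=1.0,
                              pvalue=1.0, n=len(cohort), n_events=n_events,
                              ph_test_p=float("nan"), log_hr=0.0, log_hr_se=float("nan"))
    if standardize:
        scores = scores / np.std(scores, ddof=1)
    df = pd.DataFrame({"duration": np.maximum(duration, 0.5), "event": observed,
                       "score": scores})
    for name in adjust:
        if name not in cohort.covariates.columns:
            raise ConfigurationError(f"fit_ph: covariate {name!r} not in cohort table")
        col = cohort.covariates[name]
        if name in CATEGORICAL_COVARIATES:
            dummies = pd.get_dummies(col.astype("category"), prefix=name, drop_first=True)
            df = pd.concat([df, dummies.astype(float).reset_index(drop=True)], axis=1)
        else:
            df[name] = np.asarray(col, dtype=float)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="duration", event_col="event", batch_mode=True)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise EstimationError(f"fit_ph: partial-likelihood fit failed: {exc}") from exc
    coef = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    p = float(cph.summary.loc["score", "p"])
    ph_p = float("nan")
    if ph_test:
        try:
            ph = proportional_hazard_test(cph, df, time_transform="rank")
            ph_p = float(ph.summary.loc["score", "p"].iloc[0]
                         if hasattr(ph.summary.loc["score", "p"], "iloc")
                         else ph.summary.loc["score", "p"])
        except Exception:
            ph_p = float("nan")
    z = 1.959963984540054
    return GRSAssociation(taxon_id=taxon_id, hr=math.exp(coef),
                          ci_low=math.exp(coef - z * se),
                          ci_high=math.exp(coef + z * se),
                          pvalue=p, n=len(cohort), n_events=n_events,
                          ph_test_p=ph_p, log_hr=coef, log_hr_se=se)
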