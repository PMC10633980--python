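"""Study orchestration: many-exposure screening with FDR control, reverse-
direction MR, sample-overlap bias assessment, and the full multi-stage study.

The screen mirrors the standard design for microbiome-wide MR: per exposure,
select instruments (p-value + MAF filters, LD clumping), harmonize against
the outcome GWAS, estimate the primary effect (IVW for >= 2 instruments,
Wald ratio for one), then control the false discovery rate across all
attempted exposures with the Benjamini-Hochberg step-up procedure. The FDR
denominator counts every attempted exposure — including those yielding no
instruments — because the family of tests is the full taxon panel.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from . import __version__ as _pkg_version
from .cohort import compute_wtgrs, exclude_prevalent, fit_ph
from .estimators import (EstimatorConfig, MREstimate, estimate_all, ivw,
                         wald_ratio)
from .exceptions import ConfigurationError, EstimationError, InputError
from .harmonize import harmonize, retained
from .instruments import filter_candidates, ld_clump, substitute_proxies
from .mediation import mediation_proportion, mvmr_fit, two_step_mr
from .simulate import SimulationConfig, TriangleParams, simulate_cohort, \
    simulate_sumstats, simulate_triangle
from .sumstats import LDMatrix, SummaryStats, harmonized_to_frame, write_results

log = logging.getLogger(__name__)


def bh_fdr(pvalues: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with denominator ``m``.

    ``m`` may exceed the number of observed p-values (tests that produced no
    estimate still count toward the family size); q_(i) = min_{j>=i}
    (m p_(j) / j), capped at 1, mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ConfigurationError(f"bh_fdr: m={m} smaller than number of p-values ({n})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


@dataclass
class ScreenConfig:
    """Thresholds for the screening stage; defaults are the field's standard
    printed values (suggestive 1e-5, MAF 0.01, clump r^2 0.001 within 10 Mb,
    proxy r^2 0.8, FDR 0.05, risk-factor screen 0.005)."""

    p_threshold: float = 1e-5
    eaf_floor: float = 0.01
    clump_r2: float = 0.001
    window_kb: int = 10_000
    proxy_r2: float = 0.8
    fdr_alpha: float = 0.05
    riskfactor_alpha: float = 0.005
    reverse_p_threshold: float = 5e-8
    palindrome_eaf_window: float = 0.08
    sensitivity: str = "significant"   # none | significant | all
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    seed: int = 0


@dataclass
class ScreenResult:
    """One exposure's screening outcome."""

    exposure_id: str
    n_instruments: int
    primary: Optional[MREstimate]
    fdr_q: float = float("nan")
    significant: bool = False
    all_estimates: list = field(default_factory=list)
    status: str = "ok"                 # ok | no_instruments


def _screen_one(exposure: SummaryStats, outcome: SummaryStats,
                ld: Optional[LDMatrix], cfg: ScreenConfig) -> ScreenResult:
    cands = filter_candidates(exposure, cfg.p_threshold, cfg.eaf_floor)
    if not cands:
        return ScreenResult(exposure.trait_id, 0, None, status="no_instruments")
    clumped = ld_clump(cands, ld, cfg.clump_r2, cfg.window_kb, exposure.trait_id)
    insts = clumped.instruments
    missing = [r for r in insts if r.variant_id not in outcome]
    proxy_map = {}
    if missing and ld is not None:
        proxy_map = substitute_proxies(missing, outcome, ld, cfg.proxy_r2)
    resolved = [r for r in insts if r.variant_id in outcome or r.variant_id in proxy_map]
    dropped = len(insts) - len(resolved)
    if dropped:
        log.info("%s: %d instrument(s) unresolvable in outcome; dropped",
                 exposure.trait_id, dropped)
    if not resolved:
        return ScreenResult(exposure.trait_id, 0, None, status="no_instruments")
    harmonized = harmonize(resolved, outcome, cfg.palindrome_eaf_window, proxy_map)
    usable = retained(harmonized)
    if not usable:
        return ScreenResult(exposure.trait_id, 0, None, status="no_instruments")
    binary = outcome.is_binary
    if len(usable) == 1:
        primary = wald_ratio(usable[0], binary=binary)
    else:
        primary = ivw(usable, model=cfg.estimator.ivw_model, binary=binary)[0]
    primary.exposure = exposure.trait_id
    primary.outcome = outcome.trait_id
    res = ScreenResult(exposure.trait_id, len(usable), primary)
    res._harmonized = usable  # cached for the sensitivity battery
    return res


def run_screen(exposures: Sequence[SummaryStats], outcome: SummaryStats,
               ld: Optional[LDMatrix] = None,
               config: Optional[ScreenConfig] = None) -> list[ScreenResult]:
    """Screen many exposures against one outcome with BH-FDR across the panel."""
    if not exposures:
        raise InputError("run_screen: no exposures supplied")
    cfg = config or ScreenConfig()
    results = [_screen_one(exp, outcome, ld, cfg) for exp in exposures]
    scored = [r for r in results if r.primary is not None]
    if scored:
        q = bh_fdr([r.primary.pvalue for r in scored], m=len(exposures))
        for r, qv in zip(scored, q):
            r.fdr_q = float(qv)
            r.significant = bool(qv < cfg.fdr_alpha)
    if cfg.sensitivity != "none":
        for r in results:
            run_batt = (cfg.sensitivity == "all") or r.significant
            if run_batt and r.primary is not None and r.n_instruments >= 1:
                ests = estimate_all(r._harmonized, binary=outcome.is_binary,
                                    config=cfg.estimator)
                for e in ests:
                    e.exposure = r.exposure_id
                    e.outcome = outcome.trait_id
                r.all_estimates = ests
    return results


def run_reverse(outcome_as_exposure: SummaryStats, exposure_as_outcome: SummaryStats,
                ld: Optional[LDMatrix] = None,
                config: Optional[ScreenConfig] = None) -> ScreenResult:
    """Reverse-direction MR: outcome instruments (genome-wide threshold by
    default) against the original exposure, through the same pipeline."""
    cfg = config or ScreenConfig()
    rev_cfg = ScreenConfig(**{**asdict_shallow(cfg), "p_threshold": cfg.reverse_p_threshold,
                              "sensitivity": "none"})
    return _screen_one(outcome_as_exposure, exposure_as_outcome, ld, rev_cfg)


def asdict_shallow(cfg: ScreenConfig) -> dict:
    d = dict(cfg.__dict__)
    d["estimator"] = cfg.estimator
    return d


def assess_overlap_bias(f_bar: float, overlap_fraction: float,
                        confounded_assoc: float,
                        se_estimate: float = 0.02) -> tuple[float, float]:
    """First-order sample-overlap bias and the resulting type-1 error.

    With overlapping exposure/outcome samples the two-sample estimate is
    pulled toward the confounded observational association; to first order
    the expected bias is ``overlap_fraction * confounded_assoc / f_bar``
    (weak-instrument attenuation scale 1/F). The type-1 error of the nominal
    5% test is computed by shifting the estimate's null distribution by the
    bias, in units of ``se_estimate``.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise InputError("overlap_fraction must be in [0, 1]")
    if f_bar <= 0:
        raise InputError("f_bar must be positive")
    bias = overlap_fraction * confounded_assoc / f_bar
    z = bias / se_estimate
    z95 = 1.959963984540054
    type1 = float(sps.norm.sf(z95 - z) + sps.norm.cdf(-z95 - z))
    return float(bias), type1


# ---------------------------------------------------------------------------
# Full-study driver
# ---------------------------------------------------------------------------

DEFAULT_STUDY_CONFIG = {
    "seed": 0,
    "out_dir": "study_out",
    "stages": {"screen": True, "reverse": True, "mediation": True, "cohort": True},
    "thresholds": {"p_threshold": 1e-5, "eaf_floor": 0.01, "clump_r2": 0.001,
                   "window_kb": 10_000, "proxy_r2": 0.8, "fdr_alpha": 0.05,
                   "riskfactor_alpha": 0.005, "reverse_p_threshold": 5e-8},
    "synthetic": {"n_taxa": 20, "n_true": 2, "theta_true": 0.14,
                  "n_snps_range": [3, 12], "triangle": {"beta1": 0.05,
                                                        "beta2": 0.336,
                                                        "delta": 0.123},
                  "cohort_n": 20000, "true_hr": 1.14},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_study(config=None, out_dir=None) -> dict:
    """Execute the full synthetic study end to end and write its report bundle.

    ``config`` is a declarative dict (or a path to a YAML file with the same
    structure); unspecified keys fall back to :data:`DEFAULT_STUDY_CONFIG`.
    Stages run in order screen -> reverse MR -> mediation (incl. MVMR) ->
    cohort GRS; a stage failure is recorded in the manifest and later
    independent stages still run. Outputs (per-stage TSVs, a JSON manifest
    with seeds/thresholds/versions, a run log) are deterministic functions of
    the seed.
    """
    if isinstance(config, (str, Path)):
        import yaml
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge(DEFAULT_STUDY_CONFIG, config or {})
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    thr = cfg["thresholds"]
    scfg = ScreenConfig(p_threshold=thr["p_threshold"], eaf_floor=thr["eaf_floor"],
                        clump_r2=thr["clump_r2"], window_kb=thr["window_kb"],
                        proxy_r2=thr["proxy_r2"], fdr_alpha=thr["fdr_alpha"],
                        riskfactor_alpha=thr["riskfactor_alpha"],
                        reverse_p_threshold=thr["reverse_p_threshold"],
                        estimator=EstimatorConfig(seed=seed))
    syn = cfg["synthetic"]
    rng = np.random.default_rng(seed)
    run_log: list[str] = []
    manifest = {"package_version": _pkg_version, "seed": seed,
                "thresholds": thr, "stages": {}, "toggles": cfg["stages"]}

    # --- build the synthetic study inputs -------------------------------
    n_taxa, n_true = int(syn["n_taxa"]), int(syn["n_true"])
    lo_j, hi_j = syn["n_snps_range"]
    exposures, truths = [], {}
    outcome_records = []
    for t in range(n_taxa):
        theta = float(syn["theta_true"]) if t < n_true else 0.0
        sub = SimulationConfig(n_snps=int(rng.integers(lo_j, hi_j + 1)),
                               theta=theta, seed=seed)
        exp, outc, tr = simulate_sumstats(sub, rng=rng, variant_prefix=f"rsT{t}_")
        exp.trait_id = f"taxon_{t:03d}"
        exposures.append(exp)
        truths[exp.trait_id] = theta
        outcome_records.extend(outc.records)
    outcome = SummaryStats("outcome", "binary", outcome_records)
    run_log.append(f"simulated {n_taxa} taxa ({n_true} causal) against one outcome GWAS")

    results_bundle: dict = {"config": cfg, "truth": truths}

    # --- stage: screen ---------------------------------------------------
    screen_results: list[ScreenResult] = []
    if cfg["stages"]["screen"]:
        try:
            screen_results = run_screen(exposures, outcome, None, scfg)
            rows = [r.primary for r in screen_results if r.primary is not None]
            write_results(rows, out / "screen_primary.tsv")
            sens = [e for r in screen_results for e in r.all_estimates]
            if sens:
                write_results(sens, out / "screen_sensitivity.tsv")
            n_sig = int(sum(r.significant for r in screen_results))
            run_log.append(f"screen: {len(rows)} estimable taxa, {n_sig} FDR-significant")
            manifest["stages"]["screen"] = {"status": "ok", "n_significant": n_sig}
        except Exception as exc:
            manifest["stages"]["screen"] = {"status": "failed", "error": str(exc)}
            run_log.append(f"screen FAILED: {exc}")
    else:
        manifest["stages"]["screen"] = {"status": "disabled"}
    results_bundle["screen"] = screen_results

    # --- stage: reverse MR ----------------------------------------------
    if cfg["stages"]["reverse"] and screen_results:
        try:
            rev_out = []
            for r in screen_results:
                if not r.significant:
                    continue
                exp = next(e for e in exposures if e.trait_id == r.exposure_id)
                # swap roles: the outcome's instruments tested against the taxon
                rev = run_reverse(outcome, exp, None,
                                  ScreenConfig(**{**asdict_shallow(scfg),
                                                  "reverse_p_threshold": thr["reverse_p_threshold"]}))
                if rev.primary is not None:
                    rev.primary.exposure = "outcome"
                    rev.primary.outcome = r.exposure_id
                    rev_out.append(rev.primary)
            if rev_out:
                write_results(rev_out, out / "reverse_mr.tsv")
            manifest["stages"]["reverse"] = {"status": "ok", "n_tested": len(rev_out)}
            run_log.append(f"reverse MR: {len(rev_out)} significant taxa tested")
        except Exception as exc:
            manifest["stages"]["reverse"] = {"status": "failed", "error": str(exc)}
            run_log.append(f"reverse MR FAILED: {exc}")
    else:
        manifest["stages"]["reverse"] = {"status": "disabled" if not cfg["stages"]["reverse"]
                                         else "skipped"}

    # --- stage: mediation ------------------------------------------------
    if cfg["stages"]["mediation"]:
        try:
            tri_cfg = syn["triangle"]
            tri = TriangleParams(beta1=float(tri_cfg["beta1"]),
                                 beta2=float(tri_cfg["beta2"]),
                                 delta=float(tri_cfg["delta"]))
            sub = SimulationConfig(n_snps=10, triangle=tri, seed=seed)
            data = simulate_triangle(sub, rng=rng)
            tm = retained(harmonize([r for r in data.taxon_mediator[0].records],
                                    data.taxon_mediator[1]))
            mo = retained(harmonize([r for r in data.mediator_outcome[0].records],
                                    data.mediator_outcome[1]))
            to = retained(harmonize([r for r in data.taxon_outcome[0].records],
                                    data.taxon_outcome[1]))
            total = ivw(to, binary=True)[0]
            # mediator must itself be a significant risk factor before mediation
            med_est = ivw(mo, binary=True)[0]
            manifest["stages"]["mediation"] = {"status": "ok"}
            if med_est.pvalue <= scfg.riskfactor_alpha:
                steps = two_step_mr(tm, mo, total)
                med = mediation_proportion(steps.beta1, steps.se1, steps.beta2,
                                           steps.se2, steps.beta3, steps.se3,
                                           n_boot=2000, seed=seed)
                bx1 = np.array([h.beta_exp for h in to])
                bx2_lookup = {h.variant_id: h for h in tm}
                X = np.column_stack([
                    bx1,
                    np.array([bx2_lookup[h.variant_id].beta_out for h in to]),
                ])
                mv = mvmr_fit(np.array([h.beta_out for h in to]), X,
                              np.array([h.se_out for h in to]),
                              exposure_ids=["taxon", "mediator"])
                import pandas as pd
                pd.DataFrame([{
                    "taxon": "taxon", "mediator": "mediator",
                    "beta1": med.beta1, "se1": steps.se1,
                    "beta2": med.beta2, "se2": steps.se2,
                    "beta3": med.beta3, "se3": steps.se3,
                    "proportion": med.proportion, "ci_low": med.ci_low,
                    "ci_high": med.ci_high, "pvalue": med.pvalue,
                    "n_boot": med.n_boot, "seed": med.seed,
                }]).to_csv(out / "mediation.tsv", sep="\t", index=False,
                           float_format="%.8g")
                results_bundle["mediation"] = med
                results_bundle["mvmr"] = mv
                run_log.append(f"mediation: proportion {med.proportion:.4f} "
                               f"[{med.ci_low:.4f}, {med.ci_high:.4f}]")
                manifest["stages"]["mediation"]["proportion"] = round(med.proportion, 6)
            else:
                run_log.append("mediation: mediator not significant at the "
                               "risk-factor threshold; skipped")
                manifest["stages"]["mediation"]["status"] = "mediator_not_significant"
        except Exception as exc:
            manifest["stages"]["mediation"] = {"status": "failed", "error": str(exc)}
            run_log.append(f"mediation FAILED: {exc}")
    else:
        manifest["stages"]["mediation"] = {"status": "disabled"}

    # --- stage: cohort GRS -----------------------------------------------
    if cfg["stages"]["cohort"]:
        try:
            import pandas as pd
            sig = [r for r in screen_results if r.significant]
            target = sig[0] if sig else None
            if target is None:
                run_log.append("cohort: no significant taxon; skipped")
                manifest["stages"]["cohort"] = {"status": "no_significant_taxon"}
            else:
                weights = {h.variant_id: h.beta_exp for h in target._harmonized}
                ccfg = SimulationConfig(cohort_n=int(syn["cohort_n"]),
                                        true_hr=float(syn["true_hr"]), seed=seed)
                cohort = simulate_cohort(ccfg, weights, rng=rng)
                cohort = exclude_prevalent(cohort)
                scores = compute_wtgrs(cohort, weights)
                assoc = fit_ph(cohort, scores,
                               adjust=("age", "sex", "batch", "center",
                                       "pc1", "pc2", "pc3", "pc4"),
                               taxon_id=target.exposure_id)
                pd.DataFrame([{
                    "taxon": assoc.taxon_id, "hr": assoc.hr,
                    "ci_low": assoc.ci_low, "ci_high": assoc.ci_high,
                    "pvalue": assoc.pvalue, "n": assoc.n,
                    "n_events": assoc.n_events, "ph_test_p": assoc.ph_test_p,
                }]).to_csv(out / "cohort_grs.tsv", sep="\t", index=False,
                           float_format="%.8g")
                results_bundle["cohort"] = assoc
                run_log.append(f"cohort: HR {assoc.hr:.4f} "
                               f"[{assoc.ci_low:.4f}, {assoc.ci_high:.4f}] "
                               f"({assoc.n_events} events / {assoc.n})")
                manifest["stages"]["cohort"] = {"status": "ok",
                                                "hr": round(assoc.hr, 6)}
        except Exception as exc:
            manifest["stages"]["cohort"] = {"status": "failed", "error": str(exc)}
            run_log.append(f"cohort FAILED: {exc}")
    else:
        manifest["stages"]["cohort"] = {"status": "disabled"}
        run_log.append("cohort stage disabled by config")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(run_log) + "\n")
    results_bundle["manifest"] = manifest
    return results_bundle
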