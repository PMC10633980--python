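"""Instrument selection from an exposure GWAS.

Candidate variants must pass the discovery p-value threshold (suggestive
1e-5 by default, the convention for small microbiome GWAS) and a minor-allele
frequency floor. Survivors are pruned to near-independence by greedy
PLINK-style LD clumping (keep the smallest p-value, remove linked neighbours
within the window, repeat). Instruments absent from the outcome GWAS can be
replaced by LD proxies. Instrument strength is the single-SNP F-statistic
(beta/se)^2; weak instruments (F < 10 or so) bias two-sample MR toward the
confounded association.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .exceptions import InputError
from .sumstats import LDMatrix, SNPAssociation, SummaryStats

log = logging.getLogger(__name__)


@dataclass
class InstrumentSet:
    """Clumping output: the kept instruments plus a per-variant disposition log."""

    exposure_id: str
    instruments: list[SNPAssociation]
    clump_log: dict = field(default_factory=dict)  # variant_id -> disposition string


def filter_candidates(stats: SummaryStats, p_threshold: float = 1e-5,
                      eaf_floor: float = 0.01) -> list[SNPAssociation]:
    """Return records with pvalue < ``p_threshold`` (strict) and
    min(eaf, 1-eaf) > ``eaf_floor``; records with missing eaf are dropped.

    The frequency rule is a minor-allele floor: a variant with eaf 0.995 is as
    nearly monomorphic as one with eaf 0.005 and is equally unusable as an
    instrument.
    """
    if not (0.0 < p_threshold < 1.0) and p_threshold != 1.0:
        raise InputError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if not (0.0 <= eaf_floor < 0.5):
        raise InputError(f"eaf_floor must be in [0, 0.5), got {eaf_floor}")
    kept, n_missing = [], 0
    for rec in stats.records:
        if rec.eaf is None:
            n_missing += 1
            continue
        if rec.pvalue < p_threshold and min(rec.eaf, 1.0 - rec.eaf) > eaf_floor:
            kept.append(rec)
    if n_missing:
        log.info("%s: dropped %d candidate(s) with missing eaf", stats.trait_id, n_missing)
    return kept


def ld_clump(candidates: list[SNPAssociation], ld: Optional[LDMatrix] = None,
             r2_threshold: float = 0.001, window_kb: int = 10_000,
             exposure_id: str = "") -> InstrumentSet:
    """Greedy LD clumping.

    Candidates are ranked by ascending p-value (ties broken by variant id);
    the best remaining variant is kept and every remaining variant on the same
    chromosome within +-``window_kb`` whose r^2 with it is >= ``r2_threshold``
    is removed, until none remain. Pairs absent from ``ld`` count as r^2 = 0,
    so with no LD resource clumping only enforces the physical window together
    with a threshold of r^2 >= 1 never firing — i.e. everything is kept.
    """
    if not candidates:
        raise InputError("ld_clump: empty candidate list")
    if not (0.0 < r2_threshold <= 1.0):
        raise InputError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    for rec in candidates:
        if (rec.chromosome is None or rec.position is None) and (ld is None or rec.variant_id not in ld):
            raise InputError(f"ld_clump: {rec.variant_id} lacks position and is absent from LD data")

    ranked = sorted(candidates, key=lambda r: (r.pvalue, r.variant_id))
    kept: list[SNPAssociation] = []
    clump_log: dict = {}
    remaining = list(ranked)
    window_bp = window_kb * 1000
    while remaining:
        leader = remaining.pop(0)
        kept.append(leader)
        clump_log[leader.variant_id] = "kept"
        survivors = []
        for rec in remaining:
            same_chrom = rec.chromosome == leader.chromosome
            in_window = same_chrom and abs(rec.position - leader.position) <= window_bp
            r2 = ld.r2_between(leader.variant_id, rec.variant_id) if ld is not None else 0.0
            if in_window and r2 >= r2_threshold:
                clump_log[rec.variant_id] = f"removed_by_clump({leader.variant_id})"
            else:
                survivors.append(rec)
        remaining = survivors
    return InstrumentSet(exposure_id=exposure_id, instruments=kept, clump_log=clump_log)


def substitute_proxies(missing: list[SNPAssociation], outcome: SummaryStats,
                       ld: LDMatrix, r2_min: float = 0.8) -> dict:
    """For each instrument absent from the outcome GWAS pick the outcome-present
    variant with maximal r^2 >= ``r2_min`` (ties broken by variant id) on the
    same chromosome; instruments with no qualifying proxy are dropped with a log.

    Returns ``{instrument_id: proxy SNPAssociation from the outcome GWAS}``.
    """
    if not (0.0 < r2_min <= 1.0):
        raise InputError(f"r2_min must be in (0, 1], got {r2_min}")
    mapping: dict = {}
    for inst in missing:
        best_id, best_r2 = None, 0.0
        for cand in outcome.records:
            if cand.variant_id == inst.variant_id:
                continue
            if cand.chromosome != inst.chromosome:
                continue
            r2 = ld.r2_between(inst.variant_id, cand.variant_id)
            if r2 < r2_min:
                continue
            if r2 > best_r2 or (r2 == best_r2 and best_id is not None and cand.variant_id < best_id):
                best_id, best_r2 = cand.variant_id, r2
        if best_id is None:
            log.info("no proxy with r2 >= %.2f for %s; instrument dropped", r2_min, inst.variant_id)
        else:
            mapping[inst.variant_id] = outcome.get(best_id)
    return mapping


def f_statistic(assoc: SNPAssociation) -> float:
    """Single-SNP instrument-strength F ~= (beta/se)^2."""
    if not assoc.se > 0:
        raise InputError(f"{assoc.variant_id}: se must be positive")
    return (assoc.beta / assoc.se) ** 2
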