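"""Align exposure and outcome effects to a common effect allele.

Rules, applied per variant:

1. Outcome alleles equal to the exposure's: keep as is.
2. Outcome alleles swapped: negate the outcome beta and complement its
   frequency (the effect is being re-expressed on the opposite allele).
3. Outcome alleles on the opposite strand (A<->T, C<->G complement):
   complement, then apply rule 1/2.
4. Palindromic variants (allele pair A/T or C/G) cannot be resolved from
   allele labels; the forward strand is inferred from allele frequencies.
   When both frequencies are decisively away from 0.5 the outcome effect is
   oriented so its aligned frequency falls on the same side of 0.5 as the
   exposure's; frequencies inside the ambiguous window (0.42-0.58 by default)
   make inference unsafe and the variant is dropped.

All orientation happens on the outcome side — exposure effects are never
altered, keeping instrument definitions stable across multiple outcomes.
"""
from __future__ import annotations

import logging
import math
from typing import Optional

from scipy import stats as sps

from .exceptions import InputError
from .instruments import f_statistic
from .sumstats import (ACTION_FLIP, ACTION_PALINDROME_DROPPED,
                       ACTION_PALINDROME_INFERRED, ACTION_UNCHANGED,
                       HarmonizedInstrument, SNPAssociation, SummaryStats)

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a: str, b: str) -> bool:
    return COMPLEMENT[a] == b


def retained(insts: list[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """The subset of harmonized pairs usable for estimation."""
    return [h for h in insts if h.retained]


def harmonize(exposure: list[SNPAssociation], outcome: SummaryStats,
              palindrome_eaf_window: float = 0.08,
              proxy_map: Optional[dict] = None) -> list[HarmonizedInstrument]:
    """Harmonize exposure instruments against an outcome GWAS.

    Every exposure record must be resolvable in the outcome, either directly
    or through ``proxy_map`` (instrument id -> outcome-side proxy record, as
    produced by :func:`gutmr.instruments.substitute_proxies`). Dropped
    palindromes stay in the output flagged ``palindromic_dropped``;
    non-reconcilable allele pairs are excluded with a logged reason.
    """
    if not (0.0 <= palindrome_eaf_window < 0.5):
        raise InputError(f"palindrome_eaf_window must be in [0, 0.5), got {palindrome_eaf_window}")
    out: list[HarmonizedInstrument] = []
    for exp in exposure:
        rec = outcome.get(exp.variant_id)
        action_prefix = None
        if rec is None and proxy_map and exp.variant_id in proxy_map:
            rec = proxy_map[exp.variant_id]
            action_prefix = "proxy"
        if rec is None:
            raise InputError(
                f"{exp.variant_id}: absent from outcome GWAS; proxy substitution should have resolved it")
        h = _harmonize_one(exp, rec, palindrome_eaf_window)
        if h is None:
            continue
        if action_prefix == "proxy" and h.retained:
            h = HarmonizedInstrument(
                variant_id=h.variant_id, beta_exp=h.beta_exp, se_exp=h.se_exp,
                beta_out=h.beta_out, se_out=h.se_out, eaf_exp=h.eaf_exp,
                eaf_out=h.eaf_out, action_taken="proxy_substituted", f_stat=h.f_stat)
        out.append(h)
    return out


def _harmonize_one(exp: SNPAssociation, out: SNPAssociation,
                   window: float) -> Optional[HarmonizedInstrument]:
    ea, oa = exp.effect_allele, exp.other_allele
    f = f_statistic(exp)

    def build(beta_out, eaf_out, action):
        return HarmonizedInstrument(
            variant_id=exp.variant_id, beta_exp=exp.beta, se_exp=exp.se,
            beta_out=beta_out, se_out=out.se, eaf_exp=exp.eaf, eaf_out=eaf_out,
            action_taken=action, f_stat=f)

    if _is_palindromic(ea, oa):
        if {out.effect_allele, out.other_allele} != {ea, oa}:
            log.info("%s: incompatible alleles (palindromic exposure); excluded", exp.variant_id)
            return None
        if exp.eaf is None or out.eaf is None:
            return build(out.beta, out.eaf, ACTION_PALINDROME_DROPPED)
        # label-align first, then let frequencies decide the strand
        if out.effect_allele == ea:
            b, fq = out.beta, out.eaf
        else:
            b, fq = -out.beta, 1.0 - out.eaf
        if abs(exp.eaf - 0.5) <= window or abs(fq - 0.5) <= window:
            return build(out.beta, out.eaf, ACTION_PALINDROME_DROPPED)
        if (exp.eaf - 0.5) * (fq - 0.5) < 0:
            b, fq = -b, 1.0 - fq
        return build(b, fq, ACTION_PALINDROME_INFERRED)

    oea, ooa = out.effect_allele, out.other_allele
    if (oea, ooa) == (ea, oa):
        return build(out.beta, out.eaf, ACTION_UNCHANGED)
    if (oea, ooa) == (oa, ea):
        return build(-out.beta, None if out.eaf is None else 1.0 - out.eaf, ACTION_FLIP)
    cea, coa = COMPLEMENT[oea], COMPLEMENT[ooa]
    if (cea, coa) == (ea, oa):
        return build(out.beta, out.eaf, ACTION_UNCHANGED)
    if (cea, coa) == (oa, ea):
        return build(-out.beta, None if out.eaf is None else 1.0 - out.eaf, ACTION_FLIP)
    log.info("%s: non-reconcilable allele pair %s/%s vs %s/%s; excluded",
             exp.variant_id, ea, oa, oea, ooa)
    return None


def harmonize_involution_check(pair: HarmonizedInstrument) -> bool:
    """Re-harmonizing an already-aligned pair must be the identity.

    The pair is re-expressed as exposure/outcome records sharing a
    non-palindromic effect allele and pushed through :func:`harmonize` again;
    returns True iff the betas and frequencies come back unchanged.
    """
    if not pair.retained:
        raise InputError("involution check applies to retained pairs only")

    def pv(beta, se):
        return max(min(2.0 * float(sps.norm.sf(abs(beta / se))), 1.0), 1e-300)

    exp = SNPAssociation(pair.variant_id, "1", 1, "A", "G",
                         pair.eaf_exp, pair.beta_exp, pair.se_exp,
                         pv(pair.beta_exp, pair.se_exp))
    out_rec = SNPAssociation(pair.variant_id, "1", 1, "A", "G",
                             pair.eaf_out, pair.beta_out, pair.se_out,
                             pv(pair.beta_out, pair.se_out))
    res = harmonize([exp], SummaryStats("o", "continuous", [out_rec]))
    if len(res) != 1 or not res[0].retained:
        return False
    h = res[0]
    same = (h.beta_out == pair.beta_out and h.beta_exp == pair.beta_exp
            and h.se_out == pair.se_out and h.se_exp == pair.se_exp)
    if pair.eaf_out is not None:
        same = same and h.eaf_out == pair.eaf_out
    return bool(same)
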