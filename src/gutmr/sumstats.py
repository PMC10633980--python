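"""Data model and delimited-text I/O for GWAS summary statistics and LD information.

The in-memory containers here are consumed by every downstream stage:
:class:`SNPAssociation` is one variant's marginal effect in one GWAS,
:class:`SummaryStats` is one GWAS dataset, :class:`LDMatrix` holds squared
correlations between variants, and :class:`HarmonizedInstrument` is an
exposure/outcome effect pair expressed on a common effect allele.

File formats follow GWAS-SSF conventions (tab-delimited, one header row,
1-based positions) with a user-configurable column map because source GWAS
use heterogeneous headers.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

#: p-values printed as 0 are floored here so -log10(p) stays finite.
P_FLOOR = 1e-300

#: GWAS-SSF-style default header names, remappable per input file.
DEFAULT_COLUMN_MAP = {
    "variant_id": "variant_id",
    "chromosome": "chromosome",
    "position": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pvalue": "p_value",
    "n": "n",
}

_MANDATORY_FIELDS = (
    "variant_id", "chromosome", "position",
    "effect_allele", "other_allele", "beta", "se", "pvalue",
)


@dataclass(frozen=True)
class SNPAssociation:
    """One variant's effect estimate in one GWAS.

    ``beta`` is the per-effect-allele effect on the trait scale (log-odds for
    binary traits). ``eaf`` may be missing (``None``) on the outcome side only;
    the exposure side needs it for the frequency filter and palindrome
    inference.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float
    n: Optional[float] = None

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise InputError(f"{self.variant_id}: effect and other allele are identical")
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise InputError(f"{self.variant_id}: alleles must be in {sorted(VALID_ALLELES)}")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise InputError(f"{self.variant_id}: se must be a finite positive number")
        if not math.isfinite(self.beta):
            raise InputError(f"{self.variant_id}: beta must be finite")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise InputError(f"{self.variant_id}: eaf outside [0, 1]")
        p = self.pvalue
        if p <= 0.0:
            object.__setattr__(self, "pvalue", P_FLOOR)
        elif p > 1.0:
            raise InputError(f"{self.variant_id}: pvalue outside (0, 1]")


@dataclass
class SummaryStats:
    """One GWAS dataset: a trait plus its per-variant associations, unique by id."""

    trait_id: str
    trait_type: str  # "binary" or "continuous"
    records: list[SNPAssociation] = field(default_factory=list)

    def __post_init__(self):
        if self.trait_type not in ("binary", "continuous"):
            raise ConfigurationError(f"trait_type must be binary or continuous, got {self.trait_type!r}")
        self._index = {}
        for rec in self.records:
            if rec.variant_id in self._index:
                raise InputError(f"duplicate variant_id {rec.variant_id} in {self.trait_id}")
            self._index[rec.variant_id] = rec

    @property
    def is_binary(self) -> bool:
        return self.trait_type == "binary"

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def get(self, variant_id: str) -> Optional[SNPAssociation]:
        return self._index.get(variant_id)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class LDMatrix:
    """Squared correlations (r^2) between variants, with optional positions.

    Pairs absent from the matrix are treated as unlinked (r^2 = 0) by callers.
    """

    variant_ids: list[str]
    r2: np.ndarray
    positions: Optional[dict] = None  # variant_id -> (chromosome, position)

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise InputError("r2 matrix shape does not match variant id count")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise InputError("r2 entries outside [0, 1]")
        if not np.allclose(self.r2, self.r2.T, atol=1e-6):
            raise InputError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-6):
            raise InputError("r2 diagonal must be 1")
        self._idx = {v: i for i, v in enumerate(self.variant_ids)}

    def r2_between(self, a: str, b: str) -> float:
        """r^2 between two variants; 0.0 when either is absent, 1.0 for a==b."""
        if a == b:
            return 1.0
        ia, ib = self._idx.get(a), self._idx.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._idx


# Dispositions a harmonized pair can carry.
ACTION_UNCHANGED = "unchanged"
ACTION_FLIP = "allele_flip"
ACTION_PALINDROME_INFERRED = "palindromic_inferred"
ACTION_PALINDROME_DROPPED = "palindromic_dropped"
ACTION_PROXY = "proxy_substituted"


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome effect pair aligned to a common effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None
    action_taken: str = ACTION_UNCHANGED
    f_stat: float = float("nan")

    @property
    def retained(self) -> bool:
        return self.action_taken != ACTION_PALINDROME_DROPPED

    def __post_init__(self):
        if self.retained:
            if not (self.se_exp > 0 and self.se_out > 0):
                raise InputError(f"{self.variant_id}: retained pair needs positive SEs")


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    for sep in ("\t", ",", ";"):
        if sep in header:
            return sep
    return r"\s+"


def read_sumstats(path, column_map: Optional[dict] = None,
                  trait_id: str = "trait", trait_type: str = "continuous") -> SummaryStats:
    """Read a delimited summary-statistics file into a :class:`SummaryStats`.

    ``column_map`` maps the canonical field names (keys of
    :data:`DEFAULT_COLUMN_MAP`) to the file's header names; unmapped fields
    fall back to the GWAS-SSF defaults. Rows with unparseable or invalid
    beta/se are rejected and counted in the log; alleles are upper-cased.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep=_sniff_sep(path))
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty summary-statistics file") from None
    if df.empty:
        raise InputError(f"{path}: summary-statistics file has no data rows")
    for fld in _MANDATORY_FIELDS:
        if cmap[fld] not in df.columns:
            raise ConfigurationError(
                f"{path}: mapped column {cmap[fld]!r} for field {fld!r} not found in header")

    have_eaf = cmap["eaf"] in df.columns
    have_n = cmap["n"] in df.columns
    records, n_rejected = [], 0
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        try:
            eaf = float(d[cmap["eaf"]]) if have_eaf else None
            if eaf is not None and math.isnan(eaf):
                eaf = None
            n = float(d[cmap["n"]]) if have_n and not pd.isna(d[cmap["n"]]) else None
            rec = SNPAssociation(
                variant_id=str(d[cmap["variant_id"]]),
                chromosome=str(d[cmap["chromosome"]]),
                position=int(d[cmap["position"]]),
                effect_allele=str(d[cmap["effect_allele"]]).upper(),
                other_allele=str(d[cmap["other_allele"]]).upper(),
                eaf=eaf,
                beta=float(d[cmap["beta"]]),
                se=float(d[cmap["se"]]),
                pvalue=float(d[cmap["pvalue"]]),
                n=n,
            )
        except (InputError, ValueError, TypeError):
            n_rejected += 1
            continue
        records.append(rec)
    if n_rejected:
        log.info("%s: rejected %d malformed row(s)", path, n_rejected)
    return SummaryStats(trait_id=trait_id, trait_type=trait_type, records=records)


def read_ld(path, format: str = "square") -> LDMatrix:
    """Read an LD table, either a square matrix with an id header row or
    long-format ``id_a, id_b, r2`` triplets (mirrored; self-pairs forced to 1)."""
    if format == "square":
        df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
        ids = [str(c) for c in df.columns]
        mat = df.to_numpy(dtype=float)
        if not np.allclose(mat, mat.T, atol=1e-6):
            raise InputError(f"{path}: square LD matrix asymmetric beyond 1e-6")
        mat = (mat + mat.T) / 2.0
        np.fill_diagonal(mat, 1.0)
        if np.any(mat < 0) or np.any(mat > 1 + 1e-12):
            raise InputError(f"{path}: r2 outside [0, 1]")
        return LDMatrix(variant_ids=ids, r2=np.clip(mat, 0, 1))
    if format == "long":
        df = pd.read_csv(path, sep=_sniff_sep(path))
        for col in ("id_a", "id_b", "r2"):
            if col not in df.columns:
                raise ConfigurationError(f"{path}: long LD format needs column {col!r}")
        if np.any(df["r2"] < 0) or np.any(df["r2"] > 1):
            raise InputError(f"{path}: r2 outside [0, 1]")
        ids = sorted(set(df["id_a"].astype(str)) | set(df["id_b"].astype(str)))
        idx = {v: i for i, v in enumerate(ids)}
        mat = np.zeros((len(ids), len(ids)))
        np.fill_diagonal(mat, 1.0)
        for a, b, r2 in zip(df["id_a"].astype(str), df["id_b"].astype(str), df["r2"]):
            if a == b:
                continue
            mat[idx[a], idx[b]] = r2
            mat[idx[b], idx[a]] = r2
        return LDMatrix(variant_ids=ids, r2=mat)
    raise ConfigurationError(f"unknown LD format {format!r}")


RESULT_COLUMNS = ["exposure", "outcome", "method", "nsnp", "beta", "se",
                  "or_", "ci_low", "ci_high", "pvalue",
                  "q_stat", "q_pvalue", "egger_intercept_p"]


def write_results(estimates, path) -> None:
    """Write a list of :class:`~gutmr.estimators.MREstimate` as a results TSV.

    OR columns are populated only for binary outcomes; floats are serialized
    with 8 significant digits so a round-trip read reproduces them to at least
    the 6 the contract promises.
    """
    if not estimates:
        raise InputError("write_results: empty estimate list")
    rows = []
    for est in estimates:
        rows.append({
            "exposure": est.exposure,
            "outcome": est.outcome,
            "method": est.method,
            "nsnp": est.nsnp,
            "beta": est.beta,
            "se": est.se,
            "or_": est.or_ if est.binary_outcome else np.nan,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "pvalue": est.pvalue,
            "q_stat": np.nan if est.q_stat is None else est.q_stat,
            "q_pvalue": np.nan if est.q_pvalue is None else est.q_pvalue,
            "egger_intercept_p": np.nan if est.intercept_p is None else est.intercept_p,
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def harmonized_to_frame(insts) -> pd.DataFrame:
    """Serialize harmonized pairs (TSV-ready): id, betas, SEs, action, F."""
    return pd.DataFrame({
        "variant_id": [h.variant_id for h in insts],
        "beta_exp": [h.beta_exp for h in insts],
        "se_exp": [h.se_exp for h in insts],
        "beta_out": [h.beta_out for h in insts],
        "se_out": [h.se_out for h in insts],
        "action_taken": [h.action_taken for h in insts],
        "f_stat": [h.f_stat for h in insts],
    })
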