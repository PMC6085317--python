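"""Reading, validation and harmonization of GWAS summary statistics.

Per-stratum association results arrive as delimited text with one row per
variant. Effects may be given directly as a log odds ratio with its standard
error, or as an odds ratio with a 95% confidence interval and/or a P-value;
all are converted to the (beta, se) scale on ingest. The module also hosts
the shared record types used throughout the pipeline and a small locus-level
LD-reference container.

Coordinate convention: positions in summary files are 1-based (the genome
build is carried as metadata, not enforced). BED interval inputs handled
elsewhere are 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

# 97.5th percentile of the standard normal; fixed so CI<->se conversions are
# reproducible to full precision across platforms.
Z_975 = 1.959964

#: default header aliases accepted on ingest (canonical name -> accepted names)
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "snp", "rsid", "markername"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "position", "bp"),
    "effect_allele": ("ea", "effect_allele", "a1"),
    "other_allele": ("oa", "other_allele", "a2"),
    "eaf": ("eaf", "effect_allele_freq", "freq"),
    "beta": ("beta", "logor", "b"),
    "se": ("se", "stderr"),
    "p": ("p", "pval", "p_value"),
    "or": ("or", "odds_ratio"),
    "oci_l": ("oci_l", "or_lci", "ci_lower"),
    "oci_u": ("oci_u", "or_uci", "ci_upper"),
    "info": ("info", "imputation_info", "rsq"),
    "n_cases": ("n_cases", "ncases"),
    "n_controls": ("n_controls", "ncontrols"),
    "stratum_id": ("stratum_id", "study", "stratum"),
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """Input file does not carry the mandatory columns."""


class ValidationError(ValueError):
    """Rows violate record invariants; offending rows are listed."""


class HarmonizationError(ValueError):
    """Allele pair cannot be reconciled with the reference orientation."""


@dataclass
class StratumRecord:
    """One variant's association evidence in one analysis stratum.

    ``beta`` is the per-allele log odds ratio and ``se`` its standard error
    (the tau of downstream formulas). ``info`` is imputation quality in
    [0, 1], 1.0 for directly genotyped variants.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    info: float
    n_cases: int
    n_controls: int
    stratum_id: str
    ambiguous: bool = False

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not 0.0 < self.eaf < 1.0:
            problems.append(f"eaf {self.eaf} outside (0,1)")
        if not self.se > 0:
            problems.append(f"se {self.se} not positive")
        if not 0.0 <= self.info <= 1.0:
            problems.append(f"info {self.info} outside [0,1]")
        if self.n_cases < 1 or self.n_controls < 1:
            problems.append("sample counts must be >= 1")
        if self.effect_allele == self.other_allele:
            problems.append("effect allele equals other allele")
        return problems

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class MetaRecord:
    """Pooled per-variant meta-analysis result."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    z: float
    p: float
    q_stat: float
    i2: float
    het_p: float
    n_strata_used: int
    model: str = "fixed"

    def validate(self) -> list[str]:
        problems = []
        if not 0.0 < self.p <= 1.0:
            problems.append(f"p {self.p} outside (0,1]")
        if not 0.0 <= self.i2 <= 100.0:
            problems.append(f"i2 {self.i2} outside [0,100]")
        if not self.se > 0:
            problems.append("se not positive")
        if self.n_strata_used < 2:
            problems.append("retained records need >= 2 strata")
        return problems


@dataclass
class LDReference:
    """Pairwise genotype correlations for an ordered variant panel.

    ``correlation`` holds r (not r^2); its elementwise square is the usual
    r^2 used for clumping decisions.
    """

    variant_ids: list[str]
    correlation: np.ndarray
    sample_size: int

    def __post_init__(self) -> None:
        r = np.asarray(self.correlation, dtype=float)
        m = len(self.variant_ids)
        if r.shape != (m, m):
            raise ValueError(f"matrix shape {r.shape} does not match {m} variants")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-6):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(np.abs(r) > 1.0 + 1e-8):
            raise ValueError("|r| entries exceed 1")
        self.correlation = r

    def index_of(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = [self.index_of(v) for v in ids]
        return self.correlation[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# effect-scale conversions


def se_from_ci(or_lower: float, or_upper: float) -> float:
    """Standard error of the log OR from a 95% CI on the OR scale."""
    return (math.log(or_upper) - math.log(or_lower)) / (2.0 * Z_975)


def se_from_p(beta: float, p: float) -> float:
    """Standard error recovered from a two-sided P and the point estimate.

    Inverts the Wald test: se = |beta| / Phi^-1(1 - P/2). Undefined for
    beta == 0 or P == 1.
    """
    if p <= 0.0 or p >= 1.0:
        raise ValueError(f"P must be in (0,1), got {p}")
    z = norm.isf(p / 2.0)
    if z <= 0:
        raise ValueError(f"P {p} gives non-positive z")
    return abs(beta) / z


def _resolve_columns(columns: Iterable[str],
                     aliases: Mapping[str, tuple[str, ...]] | None = None
                     ) -> dict[str, str]:
    table = dict(COLUMN_ALIASES)
    if aliases:
        for canon, names in aliases.items():
            table[canon] = tuple(names) + table.get(canon, ())
    lower = {c.lower(): c for c in columns}
    out = {}
    for canon, names in table.items():
        for name in names:
            if name.lower() in lower:
                out[canon] = lower[name.lower()]
                break
    return out


def read_stratum_file(path: str | Path,
                      aliases: Mapping[str, tuple[str, ...]] | None = None,
                      stratum_id: str | None = None,
                      sep: str = "\t",
                      strict: bool = True,
                      ) -> tuple[list[StratumRecord], list[str]]:
    """Read one stratum's summary statistics into validated records.

    The effect may be supplied as ``beta`` + ``se``, as ``or`` with
    ``oci_l``/``oci_u``, or as ``or`` with ``p``; the first available route
    (in that order of preference for se: explicit se, then P-derived, then
    CI-derived) is used. A missing ``info`` column defaults to 1.0, the
    genotyped-array convention.

    Returns ``(records, problems)`` where ``problems`` lists every row that
    failed validation, as human-readable strings. With ``strict=True`` any
    validation failure raises :class:`ValidationError` carrying the same
    list; rows are never silently dropped.
    """
    df = pd.read_csv(path, sep=sep)
    cols = _resolve_columns(df.columns, aliases)

    mandatory = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf"]
    missing = [c for c in mandatory if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    has_beta = "beta" in cols
    has_or = "or" in cols
    if not (has_beta or has_or):
        raise FormatError(f"{path}: need either a beta or an OR column")
    if has_beta and "se" not in cols and "p" not in cols:
        raise FormatError(f"{path}: beta given without se or p")
    if has_or and not ({"oci_l", "oci_u"} <= cols.keys() or "p" in cols):
        raise FormatError(f"{path}: OR given without CI or P")

    records: list[StratumRecord] = []
    problems: list[str] = []
    default_stratum = stratum_id or Path(path).stem
    for i, row in df.iterrows():
        try:
            if has_beta:
                beta = float(row[cols["beta"]])
            else:
                beta = math.log(float(row[cols["or"]]))
            if "se" in cols and pd.notna(row[cols["se"]]):
                se = float(row[cols["se"]])
            elif "p" in cols and pd.notna(row[cols["p"]]) and beta != 0.0:
                se = se_from_p(beta, float(row[cols["p"]]))
            elif {"oci_l", "oci_u"} <= cols.keys():
                se = se_from_ci(float(row[cols["oci_l"]]), float(row[cols["oci_u"]]))
            else:
                raise ValueError("no usable se source")
            rec = StratumRecord(
                variant_id=str(row[cols["variant_id"]]),
                chrom=str(row[cols["chrom"]]),
                pos=int(row[cols["pos"]]),
                effect_allele=str(row[cols["effect_allele"]]).upper(),
                other_allele=str(row[cols["other_allele"]]).upper(),
                eaf=float(row[cols["eaf"]]),
                beta=beta,
                se=se,
                info=float(row[cols["info"]]) if "info" in cols else 1.0,
                n_cases=int(row[cols["n_cases"]]) if "n_cases" in cols else 1,
                n_controls=int(row[cols["n_controls"]]) if "n_controls" in cols else 1,
                stratum_id=str(row[cols["stratum_id"]]) if "stratum_id" in cols
                else default_stratum,
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"row {i}: {exc}")
            continue
        viol = rec.validate()
        if viol:
            problems.append(f"row {i} ({rec.variant_id}): " + "; ".join(viol))
        else:
            records.append(rec)
    if strict and problems:
        raise ValidationError(f"{path}: {len(problems)} invalid rows:\n"
                              + "\n".join(problems))
    return records, problems


def _is_complement_pair(a: tuple[str, str], b: tuple[str, str]) -> bool:
    try:
        return (_COMPLEMENT[a[0]], _COMPLEMENT[a[1]]) == b
    except KeyError:
        return False


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def harmonize_alleles(strata: Mapping[str, list[StratumRecord]],
                      reference: Mapping[str, tuple[str, str]],
                      ambiguity_band: tuple[float, float] = (0.4, 0.6),
                      ) -> dict[str, list[StratumRecord]]:
    """Align every stratum's effect alleles to a common reference orientation.

    Records whose allele pair is swapped relative to the reference (directly
    or on the opposite strand) have beta negated and eaf replaced by 1-eaf.
    Strand-ambiguous A/T and C/G variants with eaf inside ``ambiguity_band``
    are kept but flagged, since their orientation cannot be resolved from
    frequency. An allele pair that is neither equal, swapped, nor a strand
    complement of the reference raises :class:`HarmonizationError`.
    """
    out: dict[str, list[StratumRecord]] = {}
    lo, hi = ambiguity_band
    for sid, records in strata.items():
        harmonized = []
        for rec in records:
            if rec.variant_id not in reference:
                raise HarmonizationError(
                    f"{rec.variant_id}: not present in reference map")
            ref_ea, ref_oa = (a.upper() for a in reference[rec.variant_id])
            pair = (rec.effect_allele, rec.other_allele)
            if pair == (ref_ea, ref_oa) or _is_complement_pair(pair, (ref_ea, ref_oa)):
                new = replace(rec)
            elif pair == (ref_oa, ref_ea) or _is_complement_pair(pair, (ref_oa, ref_ea)):
                new = replace(rec, effect_allele=ref_ea, other_allele=ref_oa,
                              beta=-rec.beta, eaf=1.0 - rec.eaf)
            else:
                raise HarmonizationError(
                    f"{rec.variant_id}: alleles {pair} incompatible with "
                    f"reference ({ref_ea},{ref_oa})")
            if _is_palindromic(rec.effect_allele, rec.other_allele) and lo <= rec.eaf <= hi:
                new.ambiguous = True
            harmonized.append(new)
        out[sid] = harmonized
    return out


# ---------------------------------------------------------------------------
# meta-level file round trip

_META_COLUMNS = ["variant_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se",
                 "z", "p", "q_stat", "i2", "het_p", "n_strata_used", "model"]
_META_FLOAT_FMT = "%.10g"


def write_meta_file(records: Sequence[MetaRecord], path: str | Path) -> None:
    """Write pooled results as TSV with a deterministic column order.

    Floats use a 10-significant-digit shortest representation so that the
    file round-trips through :func:`read_meta_file` to records equal within
    format precision.
    """
    rows = [{
        "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
        "ea": r.effect_allele, "oa": r.other_allele, "eaf": r.eaf,
        "beta": r.beta, "se": r.se, "z": r.z, "p": r.p, "q_stat": r.q_stat,
        "i2": r.i2, "het_p": r.het_p, "n_strata_used": r.n_strata_used,
        "model": r.model,
    } for r in records]
    df = pd.DataFrame(rows, columns=_META_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=_META_FLOAT_FMT)


def read_meta_file(path: str | Path) -> list[MetaRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [MetaRecord(
        variant_id=str(r.variant_id), chrom=str(r.chrom), pos=int(r.pos),
        effect_allele=str(r.ea), other_allele=str(r.oa), eaf=float(r.eaf),
        beta=float(r.beta), se=float(r.se), z=float(r.z), p=float(r.p),
        q_stat=float(r.q_stat), i2=float(r.i2), het_p=float(r.het_p),
        n_strata_used=int(r.n_strata_used), model=str(r.model),
    ) for r in df.itertuples(index=False)]


def read_ld_reference(variants_path: str | Path, matrix_path: str | Path,
                      sample_size: int) -> LDReference:
    """Load an LD reference from a variant list and a square matrix file."""
    ids = [line.strip() for line in Path(variants_path).read_text().splitlines()
           if line.strip()]
    r = np.loadtxt(matrix_path)
    if r.ndim == 0:
        r = r.reshape(1, 1)
    return LDReference(variant_ids=ids, correlation=r, sample_size=sample_size)


def write_ld_reference(ld: LDReference, variants_path: str | Path,
                       matrix_path: str | Path) -> None:
    Path(variants_path).write_text("\n".join(ld.variant_ids) + "\n")
    np.savetxt(matrix_path, ld.correlation, fmt="%.10g")
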