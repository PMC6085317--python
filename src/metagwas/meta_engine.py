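"""Stratified inverse-variance meta-analysis with QC filters and genomic control.

Pools per-stratum log odds ratios by fixed-effects (and optionally
DerSimonian-Laird random-effects) inverse-variance weighting, after the
per-stratum quality filters used in large consortium case-control scans:
minimum imputation info, minimum minor-allele frequency, and a symmetric cap
on implausibly large per-stratum odds ratios. Post-meta filters drop variants
with results in fewer than two strata or with extreme between-stratum
heterogeneity. Genomic-control inflation is summarized by the median-chi2
lambda and its rescaling to a notional 1000-case/1000-control study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .sumstats_io import MetaRecord, StratumRecord

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = 0.4549364231195728


@dataclass
class FilterPolicy:
    """Per-stratum and post-meta exclusion thresholds.

    All comparisons are strict, so boundary values (info = 0.4, MAF = 0.005,
    OR = 3) are retained.
    """

    min_info: float = 0.4
    min_maf: float = 0.005
    max_abs_or: float = 3.0
    min_strata: int = 2
    het_p_exclude: float = 5e-8

    def __post_init__(self) -> None:
        if self.min_info < 0 or self.min_maf <= 0 or self.het_p_exclude <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_abs_or <= 1:
            raise ValueError("max_abs_or must exceed 1")


@dataclass
class InflationResult:
    lambda_raw: float
    lambda_1000: float
    n_cases: int
    n_controls: int
    n_snps_used: int


def apply_stratum_filters(record: StratumRecord,
                          policy: FilterPolicy | None = None
                          ) -> tuple[bool, list[str]]:
    """Decide whether one stratum-level record survives QC.

    Returns ``(keep, reasons)`` where ``reasons`` lists every triggered
    exclusion: ``low_info``, ``low_maf``, ``extreme_or``.
    """
    policy = policy or FilterPolicy()
    reasons = []
    if record.info < policy.min_info:
        reasons.append("low_info")
    if record.maf < policy.min_maf:
        reasons.append("low_maf")
    # compared on the log scale so OR and 1/OR bounds are exactly symmetric
    if abs(record.beta) > np.log(policy.max_abs_or):
        reasons.append("extreme_or")
    return (not reasons), reasons


def ivw_fixed(betas: Sequence[float], ses: Sequence[float]
              ) -> tuple[float, float, float, float]:
    """Fixed-effects inverse-variance pooled estimate.

    Weights are reciprocal squared standard errors; returns
    ``(beta_pooled, se_pooled, z, p)`` with a two-sided normal P.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("ivw_fixed needs at least one stratum")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    w = s ** -2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2.0 * norm.sf(abs(z)))
    return beta, se, float(z), max(p, np.nextafter(0, 1))


def heterogeneity(betas: Sequence[float], ses: Sequence[float]
                  ) -> tuple[float, int, float, float]:
    """Cochran's Q, its degrees of freedom and P, and the I2 percentage."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("heterogeneity needs >= 2 strata")
    w = s ** -2
    beta_pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - beta_pooled) ** 2))
    df = b.size - 1
    het_p = float(chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, het_p, i2


def ivw_random(betas: Sequence[float], ses: Sequence[float]
               ) -> tuple[float, float, float, float]:
    """DerSimonian-Laird random-effects pooled estimate.

    Returns ``(beta_pooled, se_pooled, tau2, p)``. With homogeneous strata
    (Q <= df) tau2 is 0 and the result coincides with :func:`ivw_fixed`.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("ivw_random needs >= 2 strata")
    q, df, _, _ = heterogeneity(b, s)
    w = s ** -2
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (s ** 2 + tau2)
    beta = float(np.sum(w_star * b) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    p = float(2.0 * norm.sf(abs(beta / se)))
    return beta, se, tau2, max(p, np.nextafter(0, 1))


def meta_pipeline(strata: Mapping[str, Sequence[StratumRecord]],
                  policy: FilterPolicy | None = None,
                  model: str = "fixed",
                  ) -> tuple[list[MetaRecord], pd.DataFrame]:
    """Filter, pool and post-filter all variants across strata.

    ``strata`` maps stratum id to its records (already harmonized to a
    common effect-allele orientation). Every exclusion — a stratum record
    failing QC, a variant left in fewer than ``min_strata`` strata, or a
    pooled record with heterogeneity P below the cutoff — is logged in the
    returned audit DataFrame with columns (variant_id, stratum_id, stage,
    reason). Output ordering is by (chrom, pos, variant_id), so results do
    not depend on the iteration order of ``strata``.
    """
    policy = policy or FilterPolicy()
    audit_rows: list[dict] = []
    by_variant: dict[str, list[StratumRecord]] = {}
    for sid in sorted(strata):
        for rec in strata[sid]:
            keep, reasons = apply_stratum_filters(rec, policy)
            if not keep:
                audit_rows.append({"variant_id": rec.variant_id,
                                   "stratum_id": sid, "stage": "stratum",
                                   "reason": "+".join(reasons)})
                continue
            by_variant.setdefault(rec.variant_id, []).append(rec)

    out: list[MetaRecord] = []
    for vid in sorted(by_variant):
        recs = by_variant[vid]
        if len(recs) < policy.min_strata:
            audit_rows.append({"variant_id": vid, "stratum_id": "",
                               "stage": "meta", "reason": "min_strata"})
            continue
        betas = [r.beta for r in recs]
        ses = [r.se for r in recs]
        beta, se, z, p = ivw_fixed(betas, ses)
        q, df, het_p, i2 = heterogeneity(betas, ses)
        if het_p < policy.het_p_exclude:
            audit_rows.append({"variant_id": vid, "stratum_id": "",
                               "stage": "meta", "reason": "heterogeneity"})
            continue
        if model == "random":
            beta, se, _, p = ivw_random(betas, ses)
            z = beta / se
        ns = np.array([r.n_cases + r.n_controls for r in recs], dtype=float)
        eaf = float(np.sum(ns * [r.eaf for r in recs]) / np.sum(ns))
        ref = recs[0]
        out.append(MetaRecord(
            variant_id=vid, chrom=ref.chrom, pos=ref.pos,
            effect_allele=ref.effect_allele, other_allele=ref.other_allele,
            eaf=eaf, beta=beta, se=se, z=z, p=p, q_stat=q, i2=i2,
            het_p=het_p, n_strata_used=len(recs), model=model))
    if not out:
        warnings.warn("no variants shared by >= 2 strata after filtering")
    out.sort(key=lambda r: (r.chrom, r.pos, r.variant_id))
    audit = pd.DataFrame(audit_rows,
                         columns=["variant_id", "stratum_id", "stage", "reason"])
    return out, audit


def lambda_gc(z_scores: Sequence[float] | None = None,
              chi2_stats: Sequence[float] | None = None) -> float:
    """Genomic-control inflation factor: median chi2 over its null median."""
    if chi2_stats is None:
        if z_scores is None:
            raise ValueError("provide z_scores or chi2_stats")
        chi2_stats = np.asarray(z_scores, dtype=float) ** 2
    x = np.asarray(chi2_stats, dtype=float)
    if x.size == 0:
        raise ValueError("no statistics supplied")
    if x.size < 100:
        warnings.warn(f"lambda estimated from only {x.size} variants")
    return float(np.median(x) / CHI2_1_MEDIAN)


def lambda_1000(lambda_raw: float, n_cases: int, n_controls: int) -> float:
    """Rescale an inflation factor to a 1000-case/1000-control study.

    lambda_1000 = 1 + (lambda - 1) * (1/n_cases + 1/n_controls) / (2/1000),
    the standard Freedman rescaling for cross-study comparability.
    """
    if lambda_raw <= 0:
        raise ValueError("lambda_raw must be positive")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("sample counts must be >= 1")
    scale = (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)
    return 1.0 + (lambda_raw - 1.0) * scale


def inflation(meta_records: Iterable[MetaRecord], n_cases: int,
              n_controls: int) -> InflationResult:
    """Lambda and lambda_1000 computed from pooled z statistics."""
    z = np.array([r.z for r in meta_records], dtype=float)
    lam = lambda_gc(z_scores=z)
    return InflationResult(lambda_raw=lam,
                           lambda_1000=lambda_1000(lam, n_cases, n_controls),
                           n_cases=n_cases, n_controls=n_controls,
                           n_snps_used=z.size)
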