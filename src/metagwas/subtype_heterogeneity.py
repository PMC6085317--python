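"""Case-only tests for effect heterogeneity between disease subtypes.

Among cases, regressing the subtype indicator on allele dosage estimates the
difference between subtype-specific case-control log odds ratios (the
controls cancel), so a non-zero case-only coefficient is evidence that a
variant's effect differs by histology. A summary-level contrast of two
subgroup estimates is provided for comparison but is only approximate when
the subgroups share controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact, norm


class SeparationError(RuntimeError):
    """Subtype perfectly separated by dosage; Wald results unavailable."""


@dataclass
class CaseOnlyData:
    """Per-case allele dosage and binary subtype label."""

    dosage: np.ndarray          # in [0, 2]
    subtype: np.ndarray         # 0 = subtype A, 1 = subtype B

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.subtype = np.asarray(self.subtype, dtype=int)
        if self.dosage.shape != self.subtype.shape:
            raise ValueError("dosage and subtype must have equal length")
        if np.any((self.dosage < 0) | (self.dosage > 2)):
            raise ValueError("dosages must lie in [0, 2]")
        if len(np.unique(self.subtype)) < 2:
            raise ValueError("both subtypes must be represented")

    @classmethod
    def from_tsv(cls, path) -> "CaseOnlyData":
        df = pd.read_csv(path, sep="\t")
        labels = sorted(df["subtype"].unique())
        return cls(dosage=df["dosage"].to_numpy(),
                   subtype=(df["subtype"] == labels[1]).to_numpy().astype(int))


@dataclass
class CaseOnlyResult:
    log_or: float
    se: float
    p: float
    n_a: int
    n_b: int
    #: allele-count 2x2 cross-check: (odds ratio, two-sided exact P)
    table_or: float
    table_p: float


def _allele_table(data: CaseOnlyData) -> np.ndarray:
    # collapse dosages to allele counts per subtype (rounded for imputed input)
    counts = np.zeros((2, 2))
    for s in (0, 1):
        d = data.dosage[data.subtype == s]
        eff = float(np.round(d).sum())
        counts[s] = [eff, 2 * len(d) - eff]
    return counts


def case_only_test(data: CaseOnlyData, min_per_subtype: int = 10
                   ) -> CaseOnlyResult:
    """Logistic regression of subtype on dosage among cases.

    Returns the per-allele log OR for membership of subtype B, its Wald
    standard error and two-sided P, plus the hard-call 2x2 exact odds ratio
    and Fisher P as a diagnostic cross-check. Perfect separation raises
    :class:`SeparationError`; the exact 2x2 test remains usable in that
    case.
    """
    n_a = int(np.sum(data.subtype == 0))
    n_b = int(np.sum(data.subtype == 1))
    if min(n_a, n_b) < min_per_subtype:
        warnings.warn(f"only {min(n_a, n_b)} cases in the smaller subtype")
    tab = _allele_table(data)
    # exact cross-check on the transposed [allele x subtype] orientation
    tbl = np.array([[tab[1, 0], tab[1, 1]], [tab[0, 0], tab[0, 1]]])
    if tbl.min() >= 0 and tbl.sum() > 0:
        table_or, table_p = fisher_exact(tbl)
    else:  # pragma: no cover
        table_or, table_p = float("nan"), 1.0

    X = sm.add_constant(data.dosage)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(data.subtype, X).fit(disp=0, maxiter=100)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            raise SeparationError(
                f"perfect separation; exact 2x2 gives OR={table_or:.3g}, "
                f"P={table_p:.3g}") from exc
    if not np.isfinite(fit.bse[1]) or fit.bse[1] > 50:
        raise SeparationError(
            f"(near-)separation; exact 2x2 gives OR={table_or:.3g}, "
            f"P={table_p:.3g}")
    return CaseOnlyResult(log_or=float(fit.params[1]), se=float(fit.bse[1]),
                          p=float(fit.pvalues[1]), n_a=n_a, n_b=n_b,
                          table_or=float(table_or), table_p=float(table_p))


def subgroup_contrast(beta1: float, se1: float, beta2: float, se2: float
                      ) -> tuple[float, float, float]:
    """Approximate heterogeneity test from two subgroup summary estimates.

    z = (beta1 - beta2) / sqrt(se1^2 + se2^2), two-sided P. Assumes the
    subgroup estimates are independent; with shared controls this is only an
    approximation and will generally differ from a case-only test on the
    same data — the result is labeled accordingly.
    """
    diff = beta1 - beta2
    se = float(np.hypot(se1, se2))
    p = float(2.0 * norm.sf(abs(diff) / se)) if se > 0 else 1.0
    warnings.warn("approximate: assumes independent subgroups")
    return diff, se, p
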