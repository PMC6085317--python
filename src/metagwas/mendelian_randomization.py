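"""Two-sample and multivariable Mendelian randomization.

Univariable estimation uses the fixed-effect inverse-variance-weighted (IVW)
combination of per-SNP Wald ratios, algebraically identical to a weighted
regression of outcome effects on exposure effects through the origin with
weights 1/se_outcome^2. Exposure-side standard errors are ignored in the
weighting (the standard two-sample IVW; no measurement-error correction).
Multivariable MR regresses outcome effects jointly on two exposures'
instrument effects, yielding direct effects with a mediator held fixed.
A multiplicative random-effect option inflates standard errors by
sqrt(Q/df) when instrument heterogeneity exceeds its expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .sumstats_io import Z_975


@dataclass
class MRInstrumentTable:
    """Harmonized per-SNP effects on exposure(s) and outcome."""

    snp: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    beta_exposure2: np.ndarray | None = None
    se_exposure2: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("beta_exposure", "se_exposure", "beta_outcome",
                     "se_outcome", "beta_exposure2", "se_exposure2"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))
        if np.any(self.se_outcome <= 0) or np.any(self.se_exposure <= 0):
            raise ValueError("all standard errors must be positive")
        if self.se_exposure2 is not None and np.any(self.se_exposure2 <= 0):
            raise ValueError("all standard errors must be positive")

    def __len__(self) -> int:
        return len(self.snp)

    @property
    def has_mediator(self) -> bool:
        return self.beta_exposure2 is not None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MRInstrumentTable":
        """Columns: snp, bx, bx_se, by, by_se [, bx2, bx2_se]."""
        df = pd.read_csv(path, sep="\t")
        need = {"snp", "bx", "bx_se", "by", "by_se"}
        if not need <= set(df.columns):
            raise ValueError(f"{path}: missing columns {need - set(df.columns)}")
        kw = {}
        if {"bx2", "bx2_se"} <= set(df.columns):
            kw = {"beta_exposure2": df["bx2"].to_numpy(),
                  "se_exposure2": df["bx2_se"].to_numpy()}
        return cls(snp=df["snp"].astype(str).tolist(),
                   beta_exposure=df["bx"].to_numpy(),
                   se_exposure=df["bx_se"].to_numpy(),
                   beta_outcome=df["by"].to_numpy(),
                   se_outcome=df["by_se"].to_numpy(), **kw)


@dataclass
class MREstimate:
    theta: float
    se: float
    p: float
    or_: float
    or_ci: tuple[float, float]
    q_stat: float
    q_df: int
    q_p: float
    model: str
    exposure: int = 1  # which exposure the estimate refers to

    @property
    def ci(self) -> tuple[float, float]:
        return self.or_ci


def _wrap(theta: float, se: float, q: float, df: int, model: str,
          exposure: int = 1) -> MREstimate:
    z = theta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * norm.sf(abs(z)))
    with np.errstate(over="ignore"):
        lo, hi = np.exp(theta - Z_975 * se), np.exp(theta + Z_975 * se)
    return MREstimate(theta=theta, se=se, p=p, or_=float(np.exp(theta)),
                      or_ci=(float(lo), float(hi)),
                      q_stat=q, q_df=df,
                      q_p=float(chi2.sf(q, df)) if df > 0 else float("nan"),
                      model=model, exposure=exposure)


def ivw_mr(table: MRInstrumentTable, random_effects: bool = False) -> MREstimate:
    """Fixed-effect IVW causal estimate for a single exposure.

    theta = sum(bx by / seY^2) / sum(bx^2 / seY^2), se = sum(bx^2/seY^2)^-1/2.
    Cochran's Q over per-SNP Wald ratios is reported; with
    ``random_effects=True`` and Q > df the se is inflated by sqrt(Q/df).
    A single instrument degenerates to the plain Wald ratio (warned).
    """
    bx, by, sy = table.beta_exposure, table.beta_outcome, table.se_outcome
    if len(table) < 1 or np.all(bx == 0):
        raise ValueError("unidentified: no usable instruments")
    if len(table) == 1:
        warnings.warn("single instrument: Wald ratio, no heterogeneity test")
        theta = float(by[0] / bx[0])
        se = float(abs(sy[0] / bx[0]))
        return _wrap(theta, se, 0.0, 0, "ivw_univariable")
    w = sy ** -2
    denom = float(np.sum(w * bx * bx))
    theta = float(np.sum(w * bx * by) / denom)
    se = denom ** -0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    df = len(table) - 1
    if random_effects and q > df:
        se *= np.sqrt(q / df)
    return _wrap(theta, se, q, df, "ivw_univariable")


def multivariable_mr(table: MRInstrumentTable) -> list[MREstimate]:
    """Direct effects of two exposures by weighted least squares.

    Regresses beta_outcome on (beta_exposure, beta_exposure2) without
    intercept, weights 1/se_outcome^2. Returns one estimate per exposure;
    raises on rank deficiency of the weighted design.
    """
    if not table.has_mediator:
        raise ValueError("multivariable MR needs a second exposure")
    n = len(table)
    if n < 3:
        raise ValueError("multivariable MR needs >= 3 instruments")
    X = np.column_stack([table.beta_exposure, table.beta_exposure2])
    y = table.beta_outcome
    w = table.se_outcome ** -2
    # a mediator with (numerically) no instrument effects cannot be adjusted
    # for: the model degenerates to the univariable fit
    scale = np.linalg.norm(X[:, 0]) or 1.0
    if np.linalg.norm(X[:, 1]) < 1e-10 * scale:
        warnings.warn("mediator has no instrument effects; "
                      "returning the univariable estimate")
        uni = ivw_mr(table)
        null = _wrap(0.0, float("inf"), uni.q_stat, uni.q_df,
                     "multivariable", exposure=2)
        null.p = 1.0
        return [_wrap(uni.theta, uni.se, uni.q_stat, uni.q_df,
                      "multivariable", exposure=1), null]
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    xtx = Xw.T @ Xw
    if np.linalg.matrix_rank(xtx) < 2:
        raise ValueError("identifiability error: exposure effects are rank deficient")
    cond = float(np.linalg.cond(xtx))
    if cond > 1e10:
        warnings.warn(f"ill-conditioned exposure matrix (cond = {cond:.2g})")
    cov = np.linalg.inv(xtx)
    theta = cov @ Xw.T @ yw
    resid = yw - Xw @ theta
    q = float(resid @ resid)
    df = n - 2
    return [_wrap(float(theta[k]), float(np.sqrt(cov[k, k])), q, df,
                  "multivariable", exposure=k + 1) for k in range(2)]


def per_unit_or(theta: float, se: float, unit_scale: float = 1.0
                ) -> tuple[float, tuple[float, float]]:
    """Odds ratio (with 95% CI) per ``unit_scale`` units of the exposure."""
    if unit_scale <= 0:
        raise ValueError("unit_scale must be positive")
    t = theta * unit_scale
    s = se * unit_scale
    return float(np.exp(t)), (float(np.exp(t - Z_975 * s)),
                              float(np.exp(t + Z_975 * s)))
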