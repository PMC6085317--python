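"""Familial relative risk decomposition and effective sample sizes.

Under a log-additive risk model, a variant with allele frequency p, log odds
ratio beta (estimated with standard error tau) contributes

    c_j = p_j (1 - p_j) (beta_j^2 - tau_j^2)

to the log familial relative risk, and a set of variants explains
sum_j c_j / ln(lambda) of the FRR lambda (the disease's overall first-degree
familial relative risk; lambda = 2 for endometrial cancer). Subtracting
tau^2 removes the upward bias of the squared estimate, so individual
contributions can legitimately be negative when tau > |beta|; they are kept,
since flooring would bias sums.

Per-variant effective sample sizes N_j = 1 / (2 p_j (1 - p_j) tau_j^2)
convert case-control summary statistics to the weighting needed for
frailty-scale heritability estimation; the resulting h2_f divided by
2 ln(lambda) is the fraction of FRR attributable to all SNPs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass
class FrrInput:
    """Frequency, log OR and its standard error for one variant."""

    variant_id: str
    p: float
    beta: float
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"{self.variant_id}: p must be in (0,1)")
        if self.tau <= 0:
            raise ValueError(f"{self.variant_id}: tau must be positive")


@dataclass
class FrrResult:
    contributions: pd.DataFrame  # variant_id, p, beta, tau, contribution
    total: float                 # sum of contributions (log-FRR scale)
    proportion: float            # total / ln(lambda)
    lambda_frr: float


def frr_contribution(inp: FrrInput) -> float:
    """Per-variant contribution p(1-p)(beta^2 - tau^2); may be negative."""
    c = inp.p * (1.0 - inp.p) * (inp.beta ** 2 - inp.tau ** 2)
    if c < 0:
        warnings.warn(f"{inp.variant_id}: tau exceeds |beta|, "
                      "negative contribution retained")
    return c


def frr_proportion(inputs: Sequence[FrrInput], lambda_frr: float = 2.0) -> FrrResult:
    """Proportion of the familial relative risk explained by a variant set."""
    if lambda_frr <= 1.0:
        raise ValueError("lambda_frr must exceed 1")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for inp in inputs:
            rows.append({"variant_id": inp.variant_id, "p": inp.p,
                         "beta": inp.beta, "tau": inp.tau,
                         "contribution": frr_contribution(inp)})
    df = pd.DataFrame(rows, columns=["variant_id", "p", "beta", "tau",
                                     "contribution"])
    total = float(df["contribution"].sum()) if len(df) else 0.0
    return FrrResult(contributions=df, total=total,
                     proportion=total / math.log(lambda_frr),
                     lambda_frr=lambda_frr)


def effective_n(p: float, tau: float) -> float:
    """Effective sample size N = 1 / (2 p (1-p) tau^2) for one variant."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0,1)")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return 1.0 / (2.0 * p * (1.0 - p) * tau * tau)


def effective_n_table(inputs: Iterable[FrrInput]) -> pd.DataFrame:
    """Per-variant effective sample sizes, ready for LD-score software."""
    return pd.DataFrame([{"variant_id": i.variant_id,
                          "n_eff": effective_n(i.p, i.tau)} for i in inputs],
                        columns=["variant_id", "n_eff"])


def h2f_to_frr_proportion(h2f: float, lambda_frr: float = 2.0) -> float:
    """Fraction of FRR explained by frailty-scale heritability h2_f."""
    if h2f < 0:
        raise ValueError("h2f must be non-negative")
    if lambda_frr <= 1.0:
        raise ValueError("lambda_frr must exceed 1")
    return h2f / (2.0 * math.log(lambda_frr))
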