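"""Synthetic inputs with recorded truth for every pipeline stage.

Generates stratified case-control summary statistics with known per-variant
log odds ratios, individual-level LD blocks (the oracle substrate for
conditional analysis), Mendelian-randomization instrument tables with a
known causal slope and mediated component, case-only genotype sets with a
planted subtype effect, and random feature BEDs. All generators are
deterministic under a fixed seed.

The sampling model for summary statistics is the standard large-sample
approximation for a balanced logistic score test: the variance of the
estimated log OR for variant j in stratum k is

    tau^2_jk = 1 / (2 p_j (1 - p_j) info_jk * n_eff_k),
    n_eff_k  = n_cases_k n_controls_k / (n_cases_k + n_controls_k),

consistent with the effective-sample-size relation used for frailty-scale
heritability when info = 1, and beta-hat is drawn normal around the true
effect. The default configuration emulates a 17-stratum consortium
meta-analysis of roughly 13,000 cases and 109,000 controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sumstats_io import LDReference, StratumRecord

# stratum sizes loosely following a large consortium design: a couple of
# dominant strata and a tail of small ones, totalling ~12.9k cases / 109k
# controls across 17 strata
DEFAULT_STRATUM_SIZES: tuple[tuple[int, int], ...] = (
    (4710, 19438), (2271, 2219), (1280, 8342), (925, 6103), (731, 5087),
    (636, 62853), (606, 6126), (561, 4330), (456, 2372), (424, 558),
    (288, 1440), (272, 2031), (251, 1853), (212, 1621), (187, 1220),
    (161, 980), (120, 872),
)


@dataclass
class SimulationConfig:
    """Knobs for the summary-statistics generator."""

    seed: int = 0
    n_variants: int = 1000
    stratum_sizes: Sequence[tuple[int, int]] = DEFAULT_STRATUM_SIZES
    fraction_causal: float = 0.01
    true_beta_mean: float = 0.0
    true_beta_sd: float = 0.1
    eaf_bounds: tuple[float, float] = (0.05, 0.95)
    info_bounds: tuple[float, float] = (0.7, 1.0)
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_variants < 1 or len(self.stratum_sizes) < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.eaf_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("eaf bounds must lie strictly inside (0,1)")
        if any(nc < 1 or nn < 1 for nc, nn in self.stratum_sizes):
            raise ValueError("stratum sample sizes must be >= 1")

    @property
    def n_strata(self) -> int:
        return len(self.stratum_sizes)


@dataclass
class TruthTable:
    """Ground truth recorded before sampling noise is added."""

    variants: pd.DataFrame  # variant_id, chrom, pos, eaf, true_beta, causal
    mr_theta: float | None = None
    mr_mediated: float | None = None
    subtype_log_or: float | None = None


def _variant_frame(cfg: SimulationConfig, rng: np.random.Generator
                   ) -> pd.DataFrame:
    eaf = rng.uniform(*cfg.eaf_bounds, size=cfg.n_variants)
    causal = rng.random(cfg.n_variants) < cfg.fraction_causal
    beta = np.where(causal,
                    rng.normal(cfg.true_beta_mean, cfg.true_beta_sd,
                               cfg.n_variants), 0.0)
    return pd.DataFrame({
        "variant_id": [f"sim{i:06d}" for i in range(cfg.n_variants)],
        "chrom": "1",
        "pos": np.arange(1, cfg.n_variants + 1) * 1000,
        "eaf": eaf, "true_beta": beta, "causal": causal,
    })


def sampling_tau(eaf: float, info: float, n_cases: int, n_controls: int
                 ) -> float:
    """Closed-form se of the log OR under the balanced score-test model."""
    n_eff = n_cases * n_controls / (n_cases + n_controls)
    return 1.0 / math.sqrt(2.0 * eaf * (1.0 - eaf) * info * n_eff)


def simulate_stratum_sumstats(cfg: SimulationConfig
                              ) -> tuple[dict[str, list[StratumRecord]], TruthTable]:
    """Draw per-stratum summary statistics around known true effects.

    Returns a stratum-id -> records mapping plus the truth table. With
    ``missing_fraction`` > 0, each (variant, stratum) pair is independently
    dropped with that probability, exercising the minimum-strata filter.
    """
    rng = np.random.default_rng(cfg.seed)
    variants = _variant_frame(cfg, rng)
    strata: dict[str, list[StratumRecord]] = {}
    for k, (ncase, nctrl) in enumerate(cfg.stratum_sizes):
        sid = f"stratum{k:02d}"
        info = rng.uniform(*cfg.info_bounds, size=cfg.n_variants)
        keep = rng.random(cfg.n_variants) >= cfg.missing_fraction
        taus = np.array([sampling_tau(e, i, ncase, nctrl)
                         for e, i in zip(variants.eaf, info)])
        betas = rng.normal(variants.true_beta.to_numpy(), taus)
        records = []
        for j in range(cfg.n_variants):
            if not keep[j]:
                continue
            v = variants.iloc[j]
            records.append(StratumRecord(
                variant_id=v.variant_id, chrom=str(v.chrom), pos=int(v.pos),
                effect_allele="A", other_allele="G", eaf=float(v.eaf),
                beta=float(betas[j]), se=float(taus[j]), info=float(info[j]),
                n_cases=ncase, n_controls=nctrl, stratum_id=sid))
        strata[sid] = records
    return strata, TruthTable(variants=variants)


def simulate_ld_block(m: int, rho: float, n_individuals: int,
                      true_betas: Sequence[float], seed: int = 0,
                      eaf: float | Sequence[float] = 0.3,
                      ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, LDReference]:
    """Individual-level LD block with AR(1) latent correlation.

    Latent multivariate Gaussians with correlation rho^|i-j| are thresholded
    at the allele-frequency quantile twice per individual (two haplotypes)
    and summed to dosages; the quantitative phenotype is X beta + N(0,1)
    noise. Returns (genotypes, phenotype, marginal summary stats,
    LDReference from the empirical dosage correlation). This is the oracle
    substrate for the summary-level conditional solver.
    """
    if m < 2:
        raise ValueError("block needs >= 2 variants")
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    if n_individuals < m + 2:
        raise ValueError("joint fit unidentifiable: need n >= m + 2")
    true_betas = np.asarray(true_betas, dtype=float)
    if true_betas.shape != (m,):
        raise ValueError("true_betas must have length m")
    freqs = np.full(m, eaf, dtype=float) if np.isscalar(eaf) \
        else np.asarray(eaf, dtype=float)
    rng = np.random.default_rng(seed)
    corr = rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    chol = np.linalg.cholesky(corr)
    thresh = norm.isf(freqs)
    geno = np.zeros((n_individuals, m))
    for _ in range(2):  # two haplotypes
        latent = rng.standard_normal((n_individuals, m)) @ chol.T
        geno += (latent > thresh).astype(float)
    pheno = geno @ true_betas + rng.standard_normal(n_individuals)

    rows = []
    for j in range(m):
        x = geno[:, j]
        xc = x - x.mean()
        ss = float(xc @ xc)
        b = float(xc @ pheno / ss)
        resid = pheno - pheno.mean() - b * xc
        s2 = float(resid @ resid) / (n_individuals - 2)
        se = math.sqrt(s2 / ss)
        z = b / se
        rows.append({"variant_id": f"ld{j:03d}", "beta": b, "se": se,
                     "z": z, "p": float(2 * norm.sf(abs(z))),
                     "eaf": float(x.mean() / 2.0)})
    sumstats = pd.DataFrame(rows)
    emp_corr = np.corrcoef(geno, rowvar=False)
    ld = LDReference(variant_ids=[f"ld{j:03d}" for j in range(m)],
                     correlation=emp_corr, sample_size=n_individuals)
    return geno, pheno, sumstats, ld


def simulate_mr_instruments(n_snps: int, theta: float,
                            mediated_fraction: float = 0.0,
                            pleiotropy_sd: float = 0.0, seed: int = 0,
                            se_exposure: float = 0.01,
                            se_outcome: float = 0.02,
                            mediator_slope: float = 0.0,
                            ):
    """Two-sample MR instrument table with known causal structure.

    Exposure effects are drawn uniform in [0.02, 0.1] with random sign and
    observed with noise at ``se_exposure``. The outcome effect of SNP i is

        theta * bx_i + mediator_slope * bx2_i + pleiotropy + noise,

    where bx2 (the mediator path, e.g. BMI effects of menarche SNPs) is
    ``mediated_fraction`` * bx_i plus independent variation, so univariable
    IVW recovers the total slope theta + mediator_slope * mediated_fraction
    and multivariable MR the direct slope theta. Returns
    (MRInstrumentTable, TruthTable).
    """
    from .mendelian_randomization import MRInstrumentTable
    if n_snps < 2:
        raise ValueError("need >= 2 instruments")
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(0.02, 0.1, n_snps) * rng.choice([-1, 1], n_snps)
    bx2_true = mediated_fraction * bx_true + 0.02 * rng.standard_normal(n_snps)
    pleio = pleiotropy_sd * rng.standard_normal(n_snps) if pleiotropy_sd else 0.0
    by_true = theta * bx_true + mediator_slope * bx2_true + pleio
    table = MRInstrumentTable(
        snp=[f"iv{i:04d}" for i in range(n_snps)],
        beta_exposure=bx_true + se_exposure * rng.standard_normal(n_snps),
        se_exposure=np.full(n_snps, se_exposure),
        beta_outcome=by_true + se_outcome * rng.standard_normal(n_snps),
        se_outcome=np.full(n_snps, se_outcome),
        beta_exposure2=bx2_true + se_exposure * rng.standard_normal(n_snps),
        se_exposure2=np.full(n_snps, se_exposure))
    truth = TruthTable(variants=pd.DataFrame(), mr_theta=theta,
                       mr_mediated=mediator_slope * mediated_fraction)
    return table, truth


def simulate_case_only(n_cases_a: int, n_cases_b: int, eaf: float,
                       subtype_log_or: float, seed: int = 0):
    """Case genotypes for two subtypes with a planted allele-frequency shift.

    Subtype A dosages are binomial(2, eaf); subtype B uses the frequency
    obtained by shifting the per-allele logit by ``subtype_log_or``. Returns
    (CaseOnlyData, TruthTable).
    """
    from .subtype_heterogeneity import CaseOnlyData
    if min(n_cases_a, n_cases_b) < 10:
        raise ValueError("need >= 10 cases per subtype")
    rng = np.random.default_rng(seed)
    logit_b = math.log(eaf / (1.0 - eaf)) + subtype_log_or
    eaf_b = 1.0 / (1.0 + math.exp(-logit_b))
    dos = np.concatenate([rng.binomial(2, eaf, n_cases_a),
                          rng.binomial(2, eaf_b, n_cases_b)]).astype(float)
    labels = np.concatenate([np.zeros(n_cases_a, dtype=int),
                             np.ones(n_cases_b, dtype=int)])
    truth = TruthTable(variants=pd.DataFrame(), subtype_log_or=subtype_log_or)
    return CaseOnlyData(dosage=dos, subtype=labels), truth


def simulate_feature_bed(n_intervals: int, genome_length: int,
                         mean_width: int, seed: int = 0, chrom: str = "1",
                         path: str | Path | None = None
                         ) -> list[tuple[str, int, int]]:
    """Random sorted non-overlapping-start BED intervals within bounds.

    Widths are geometric with the given mean (minimum 1); intervals are
    clipped to the genome and returned sorted. When ``path`` is given the
    intervals are also written as 3-column BED.
    """
    if genome_length < 1 or mean_width < 1:
        raise ValueError("lengths must be positive")
    rng = np.random.default_rng(seed)
    intervals: list[tuple[str, int, int]] = []
    if n_intervals > 0:
        starts = np.sort(rng.integers(0, genome_length, n_intervals))
        widths = rng.geometric(1.0 / mean_width, n_intervals)
        for s, w in zip(starts, widths):
            e = min(int(s + w), genome_length)
            if e > s:
                intervals.append((chrom, int(s), e))
    if path is not None:
        with open(path, "w") as fh:
            for c, s, e in intervals:
                fh.write(f"{c}\t{s}\t{e}\n")
    return intervals
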