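"""Published endometrial-cancer GWAS lead-SNP summary results.

Printed all-histologies meta-analysis results (effect-allele frequency among
controls, per-allele OR with 95% CI, and P) for the lead SNPs of the
known and newly reported endometrial cancer risk loci, as reported by the
12,906-case / 108,979-control consortium meta-analysis. These serve as
worked-example inputs for the BFDP and familial-relative-risk calculations;
positions are genome build 38.

``KNOWN_LOCI`` lists the previously identified loci (the 14q32.33 / AKT1
SNP rs2498796 did not replicate and is flagged); ``NOVEL_LOCI`` the nine
newly identified loci. ``CONFIRMED_LEADS`` is the 18-SNP union used for the
familial-relative-risk decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class LeadSNP:
    region: str
    variant_id: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    odds_ratio: float
    ci: tuple[float, float]
    p: float
    replicated: bool = True


KNOWN_LOCI: tuple[LeadSNP, ...] = (
    LeadSNP("6p22.3", "rs1740828", 21_648_854, "G", "A", 0.52, 1.15, (1.11, 1.19), 4.2e-16),
    LeadSNP("6q22.31", "rs2747716", 125_687_226, "A", "G", 0.57, 1.10, (1.07, 1.14), 2.9e-10),
    LeadSNP("8q24.21", "rs35286446", 128_433_617, "GAT", "G", 0.58, 1.10, (1.06, 1.13), 3.1e-9),
    LeadSNP("8q24.21", "rs4733613", 128_587_032, "C", "G", 0.12, 1.18, (1.13, 1.24), 7.5e-14),
    LeadSNP("8q24.21", "rs139584729", 128_611_656, "C", "G", 0.98, 1.40, (1.25, 1.58), 2.4e-8),
    LeadSNP("13q22.1", "rs7981863", 73_238_004, "C", "T", 0.72, 1.16, (1.12, 1.20), 2.7e-17),
    LeadSNP("14q32.33", "rs2498796", 104_776_883, "A", "G", 0.30, 1.07, (1.03, 1.11), 6.3e-5,
            replicated=False),
    LeadSNP("15q15.1", "rs937213", 40_029_923, "C", "T", 0.42, 1.09, (1.06, 1.13), 5.1e-9),
    LeadSNP("15q21.2", "rs17601876", 51_261_712, "G", "A", 0.48, 1.12, (1.09, 1.16), 3.3e-14),
    LeadSNP("17q12", "rs11263761", 37_737_784, "A", "G", 0.52, 1.15, (1.12, 1.19), 3.2e-20),
)

NOVEL_LOCI: tuple[LeadSNP, ...] = (
    LeadSNP("1p34.3", "rs113998067", 37_607_755, "C", "T", 0.04, 1.23, (1.14, 1.32), 3.6e-8),
    LeadSNP("2p16.1", "rs148261157", 60_670_444, "A", "G", 0.03, 1.26, (1.16, 1.36), 3.4e-8),
    LeadSNP("9p21.3", "rs1679014", 22_207_038, "T", "C", 0.07, 1.18, (1.12, 1.25), 6.4e-9),
    LeadSNP("11p13", "rs10835920", 32_468_118, "T", "C", 0.38, 1.09, (1.06, 1.13), 1.3e-8),
    LeadSNP("12p12.1", "rs9668337", 26_273_405, "A", "G", 0.74, 1.11, (1.08, 1.15), 1.1e-9),
    LeadSNP("12q24.11", "rs3184504", 111_446_804, "C", "T", 0.52, 1.10, (1.07, 1.14), 1.1e-10),
    LeadSNP("12q24.21", "rs10850382", 114_776_743, "T", "C", 0.31, 1.10, (1.07, 1.14), 3.5e-9),
    LeadSNP("17q11.2", "rs1129506", 31_319_014, "G", "A", 0.38, 1.10, (1.06, 1.13), 4.3e-8),
    LeadSNP("17q21.32", "rs882380", 48_216_874, "A", "C", 0.61, 1.10, (1.06, 1.13), 4.7e-9),
)

#: the 18 confirmed leads used for the total FRR-explained estimate
CONFIRMED_LEADS: tuple[LeadSNP, ...] = tuple(
    s for s in KNOWN_LOCI if s.replicated) + NOVEL_LOCI
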