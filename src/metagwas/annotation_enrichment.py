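"""SNP-feature interval overlap and Fisher enrichment contrasts.

Candidate causal risk SNPs are intersected with epigenomic feature intervals
(histone marks, open chromatin, transcription-factor binding) supplied as
BED-style 0-based half-open intervals; SNP positions are 1-based, so a SNP
at position q overlaps [s, e) iff s <= q-1 < e. Overlap fractions of two SNP
sets (or of one set against two feature conditions) are compared with
Fisher's exact test on the 2x2 overlap table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact


@dataclass
class FeatureSet:
    """Named collection of 0-based half-open genomic intervals."""

    name: str
    intervals: list[tuple[str, int, int]]
    source: str = ""

    def __post_init__(self) -> None:
        bad = [(i, iv) for i, iv in enumerate(self.intervals) if iv[1] >= iv[2]]
        if bad:
            lines = ", ".join(f"line {i}: {iv}" for i, iv in bad[:5])
            raise ValueError(f"{self.name}: malformed intervals ({lines})")
        self.intervals = sorted(self.intervals)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "FeatureSet":
        intervals = []
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path} line {ln}: fewer than 3 BED columns")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(name=name or Path(path).stem, intervals=intervals,
                   source=str(path))


@dataclass
class OverlapSummary:
    snp_set: str
    n_snps: int
    n_overlapping: int
    per_feature: dict[str, int]
    flags: np.ndarray = field(repr=False)  # any-feature flag per SNP

    @property
    def fraction(self) -> float:
        return self.n_overlapping / self.n_snps if self.n_snps else 0.0


def _merge(intervals: Sequence[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted (start, end) pairs; returns parallel start/end arrays."""
    starts, ends = [], []
    for s, e in intervals:
        if ends and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def _feature_flags(snps: Sequence[tuple[str, int]], fs: FeatureSet) -> np.ndarray:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in fs.intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = {c: _merge(sorted(iv)) for c, iv in by_chrom.items()}
    flags = np.zeros(len(snps), dtype=bool)
    for i, (chrom, pos) in enumerate(snps):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        q = pos - 1  # 1-based SNP -> 0-based coordinate
        j = int(np.searchsorted(starts, q, side="right")) - 1
        flags[i] = j >= 0 and q < ends[j]
    return flags


def overlap_snps(snps: Sequence[tuple[str, int]],
                 features: Sequence[FeatureSet],
                 snp_set_name: str = "snps") -> OverlapSummary:
    """Flag each SNP for overlap with each feature set and with their union.

    SNPs are (chrom, 1-based position) pairs. Overlap uses the half-open
    containment rule above, computed by a per-chromosome sorted sweep over
    merged intervals; counts are reported per feature and for the union.
    """
    snps = list(snps)
    per_feature: dict[str, int] = {}
    any_flag = np.zeros(len(snps), dtype=bool)
    for fs in features:
        flags = _feature_flags(snps, fs)
        per_feature[fs.name] = int(flags.sum())
        any_flag |= flags
    return OverlapSummary(snp_set=snp_set_name, n_snps=len(snps),
                          n_overlapping=int(any_flag.sum()),
                          per_feature=per_feature, flags=any_flag)


def enrichment_fisher(a: OverlapSummary, b: OverlapSummary
                      ) -> tuple[float, float, np.ndarray]:
    """Fisher's exact comparison of two overlap fractions.

    Builds [[a_hit, a_miss], [b_hit, b_miss]] and returns the sample odds
    ratio, the two-sided exact P (probability-mass method over the
    hypergeometric support), and the table. Degenerate margins give P = 1
    with a warning.
    """
    if a.n_snps == 0 or b.n_snps == 0:
        raise ValueError("both overlap summaries must be non-empty")
    table = np.array([[a.n_overlapping, a.n_snps - a.n_overlapping],
                      [b.n_overlapping, b.n_snps - b.n_overlapping]])
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        import warnings
        warnings.warn("degenerate margin: no information, P = 1")
        return float("nan"), 1.0, table
    odds, p = fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def condition_contrast(features_stimulated: OverlapSummary,
                       features_unstimulated: OverlapSummary
                       ) -> tuple[float, float, np.ndarray]:
    """Contrast one SNP set's overlap under two feature conditions.

    Same machinery as :func:`enrichment_fisher`; kept as a separate entry
    point so condition contrasts (e.g. estrogen-stimulated vs unstimulated
    chromatin) are labeled as such in reports.
    """
    return enrichment_fisher(features_stimulated, features_unstimulated)
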