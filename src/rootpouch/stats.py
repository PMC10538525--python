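"""Validation and genetics-support statistics.

Covers the tip-count validation R-squared, paired comparisons between
imaging conditions, broad-sense heritability from replicated genotype
phenotypes, and the linkage-block Bonferroni significance threshold for
GWAS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ReplicatedPhenotypes",
    "ValidationResult",
    "GenotypeMatrix",
    "PairedTResult",
    "r_squared",
    "paired_t",
    "heritability",
    "variance_components",
    "tip_validation",
    "count_linkage_blocks",
    "bonferroni_block_threshold",
]


@dataclass
class ReplicatedPhenotypes:
    """Long-format genotype x replicate phenotypes for one trait."""

    genotype: np.ndarray  # genotype id per observation
    value: np.ndarray     # trait value per observation
    trait: str = ""

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype)
        self.value = np.asarray(self.value, float)
        if self.genotype.shape != self.value.shape:
            raise ValueError("genotype and value must have equal length")


@dataclass
class ValidationResult:
    r2_cleaned: float
    r2_uncleaned: float
    n: int
    table: list = field(default_factory=list)  # per-image (truth, cleaned, raw)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages with genomic positions, per chromosome."""

    chrom: np.ndarray      # chromosome id per SNP
    pos: np.ndarray        # bp position per SNP, sorted within chromosome
    dosage: np.ndarray     # (n_snps, n_lines), values in {0,1,2}, NaN = missing

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, np.int64)
        self.dosage = np.asarray(self.dosage, float)
        if len(self.pos) != len(self.chrom) or self.dosage.shape[0] != len(self.pos):
            raise ValueError("chrom, pos and dosage rows must align")
        for ch in np.unique(self.chrom):
            p = self.pos[self.chrom == ch]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions on chromosome {ch!r} are not sorted")


@dataclass
class PairedTResult:
    t: float
    p: float
    mean_diff: float
    degenerate: bool = False


def r_squared(x, y) -> float:
    """Squared Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t-test on the per-pair differences."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    diff = x - y
    md = float(diff.mean())
    if np.std(diff, ddof=1) == 0:
        if md == 0:
            return PairedTResult(t=0.0, p=1.0, mean_diff=0.0)
        return PairedTResult(t=np.inf if md > 0 else -np.inf, p=float("nan"),
                             mean_diff=md, degenerate=True)
    res = _sps.ttest_rel(x, y)
    return PairedTResult(t=float(res.statistic), p=float(res.pvalue), mean_diff=md)


def variance_components(ph: ReplicatedPhenotypes) -> dict:
    """One-way random-effects (method-of-moments) variance components.

    Ve is the within-genotype mean square; Vg = (MS_between - Ve)/r,
    truncated at zero. For unbalanced data r is the harmonic mean of the
    per-genotype replicate counts (flagged with a warning).
    """
    groups, inv = np.unique(ph.genotype, return_inverse=True)
    G = len(groups)
    if G < 2:
        raise ValueError("need at least 2 genotypes")
    counts = np.bincount(inv)
    n = len(ph.value)
    if n == G:
        raise ValueError("no replication: every genotype has one observation")
    means = np.bincount(inv, weights=ph.value) / counts
    grand = float(ph.value.mean())
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((ph.value - means[inv]) ** 2).sum())
    ms_between = ss_between / (G - 1)
    ms_within = ss_within / (n - G)
    if counts.min() == counts.max():
        r = float(counts[0])
    else:
        r = float(len(counts) / (1.0 / counts).sum())
        warnings.warn("unbalanced replication: using harmonic-mean r")
    ve = ms_within
    vg = max((ms_between - ms_within) / r, 0.0)
    return {"Vg": vg, "Ve": ve, "r": r, "G": G}


def heritability(ph: ReplicatedPhenotypes) -> float:
    """Broad-sense heritability H2 = Vg / (Vg + Ve / r), in [0, 1]."""
    vc = variance_components(ph)
    h2 = vc["Vg"] / (vc["Vg"] + vc["Ve"] / vc["r"])
    return float(min(max(h2, 0.0), 1.0))


def tip_validation(truth, cleaned, raw) -> ValidationResult:
    """R-squared of ground-truth tip counts vs cleaned and vs raw counts."""
    truth = np.asarray(truth, float)
    cleaned = np.asarray(cleaned, float)
    raw = np.asarray(raw, float)
    if not (len(truth) == len(cleaned) == len(raw)):
        raise ValueError("count vectors must be aligned")
    if len(truth) < 10:
        raise ValueError("need at least 10 images for validation")
    r2c = r_squared(truth, cleaned)
    r2u = r_squared(truth, raw)
    table = [(float(t), float(c), float(u))
             for t, c, u in zip(truth, cleaned, raw)]
    return ValidationResult(r2_cleaned=r2c, r2_uncleaned=r2u,
                            n=len(truth), table=table)


def _pair_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return 0.0
    aa, bb = a[ok], b[ok]
    if aa.std() == 0 or bb.std() == 0:
        return 0.0
    r = np.corrcoef(aa, bb)[0, 1]
    return float(r * r)


def count_linkage_blocks(gm: GenotypeMatrix, window_bp: int = 200_000,
                         r2_min: float = 0.2) -> int:
    """Greedy left-to-right linkage-block clumping, per chromosome.

    The first unassigned SNP seeds a block; a subsequent SNP joins iff it
    lies within ``window_bp`` of the seed and its squared genotype
    correlation with the seed is >= ``r2_min``; otherwise it seeds a new
    block.
    """
    total = 0
    for ch in np.unique(gm.chrom):
        sel = np.nonzero(gm.chrom == ch)[0]
        seed_idx = None
        for i in sel:
            if seed_idx is None:
                seed_idx = i
                total += 1
                continue
            in_window = gm.pos[i] - gm.pos[seed_idx] <= window_bp
            if in_window and _pair_r2(gm.dosage[seed_idx], gm.dosage[i]) >= r2_min:
                continue
            seed_idx = i
            total += 1
    return total


def bonferroni_block_threshold(alpha: float, n_blocks: int) -> float:
    """Genome-wide -log10 significance threshold, Bonferroni over blocks."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    return float(-np.log10(alpha / n_blocks))
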