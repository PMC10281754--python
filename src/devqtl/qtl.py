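"""Genotype-stratified methylation analysis (mQTL) and methylation-expression
regression (meQTL).

The mQTL model is an additive linear regression of M-values on effect-allele
dosage (0/1/2).  Its headline summary is the genotypic effect (GE): the
methylation difference, in percentage points, between the two homozygote
classes — or, when a homozygote class is too sparse, twice the per-allele
slope on the percentage scale.

The meQTL is an ordinary least-squares regression of CpG M-values on log2
allelic expression ratios from heterozygous donors, summarized by slope, r²
and the slope's p-value, Bonferroni-corrected across the panel by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InsufficientDataError, NotEstimableError
from .measurements import beta_to_m


@dataclass(frozen=True)
class MQTLResult:
    locus_id: int
    cpg_index: int
    tissue: str
    n_by_dosage: tuple[int, int, int]
    slope_m: float          # M-units per effect allele
    p: float
    ge: float               # percentage points, >= 0
    ge_sign: int            # direction of effect-allele association (+1/-1/0)
    p_adj: float | None = None

    @property
    def n(self) -> int:
        return sum(self.n_by_dosage)


@dataclass(frozen=True)
class MeQTLResult:
    locus_id: int
    cpg_index: int
    gene: str
    tissue: str
    n: int
    slope: float            # M-units per log2-ratio unit
    r2: float
    p: float
    p_adj: float | None = None


def _check_design(values, dosages) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(values, dtype=float)
    d = np.asarray(dosages, dtype=float)
    if y.shape != d.shape:
        raise DomainError("mean_betas and dosages must have equal length")
    if y.size < 5:
        raise InsufficientDataError(f"need >= 5 samples, got {y.size}", n=y.size)
    if not set(np.unique(d)) <= {0.0, 1.0, 2.0}:
        raise DomainError("dosages must be 0, 1 or 2")
    if np.unique(d).size < 2:
        raise NotEstimableError("monomorphic dosages: genotype effect not estimable")
    return y, d


def genotypic_effect(mean_betas, dosages) -> tuple[float, int]:
    """GE in percentage points, with the sign of the effect-allele association.

    If both homozygote classes have at least two samples, GE is the absolute
    difference of their mean methylation percentages.  Otherwise it is twice
    the absolute OLS slope of percentage on dosage (extrapolated per-allele
    effect).  Returns ``(ge, sign)``.
    """
    y, d = _check_design(mean_betas, dosages)
    pct = 100.0 * y
    slope = float(stats.linregress(d, pct).slope)
    sign = 0 if slope == 0 else (1 if slope > 0 else -1)
    n0, n2 = int(np.sum(d == 0)), int(np.sum(d == 2))
    if n0 >= 2 and n2 >= 2:
        ge = abs(float(pct[d == 2].mean() - pct[d == 0].mean()))
    else:
        ge = 2.0 * abs(slope)
    return ge, sign


def fit_mqtl(mean_betas, dosages, *, locus_id: int = 0, cpg_index: int = 0,
             tissue: str = "") -> MQTLResult:
    """Additive mQTL fit: OLS of M-values on dosage; p from the slope's t statistic."""
    y, d = _check_design(mean_betas, dosages)
    m = beta_to_m(y)
    fit = stats.linregress(d, m)
    ge, sign = genotypic_effect(y, d)
    n_by = tuple(int(np.sum(d == k)) for k in (0, 1, 2))
    return MQTLResult(locus_id, cpg_index, tissue, n_by,
                      float(fit.slope), float(fit.pvalue), ge, sign)


def fit_meqtl(m_values, log2_ratios, *, locus_id: int = 0, cpg_index: int = 0,
              gene: str = "", tissue: str = "") -> MeQTLResult:
    """OLS of methylation M-values on log2 allelic expression ratios."""
    m = np.asarray(m_values, dtype=float)
    x = np.asarray(log2_ratios, dtype=float)
    if m.shape != x.shape:
        raise DomainError("m_values and log2_ratios must have equal length")
    if m.size < 4:
        raise InsufficientDataError(
            f"need >= 4 heterozygote pairs for meQTL, got {m.size}", n=m.size)
    if np.ptp(x) == 0.0 or np.ptp(m) == 0.0:
        raise NotEstimableError("constant variable: regression not estimable")
    fit = stats.linregress(x, m)
    return MeQTLResult(locus_id, cpg_index, gene, tissue, int(m.size),
                       float(fit.slope), float(fit.rvalue) ** 2, float(fit.pvalue))


def adjust_pvalues(p_list, method: str = "bh") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, p*m).  ``bh``: Benjamini-Hochberg step-up with
    monotonicity enforcement.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise DomainError(f"unknown adjustment method {method!r}")
    return list(multipletests(p, method=key)[1])
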