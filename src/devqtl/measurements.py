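"""QC and transformation of raw molecular measurements.

Pyrosequencing reports methylation as a percentage per CpG, measured in
duplicate; replicates disagreeing by more than 5 percentage points fail QC and
the record is excluded.  Statistical testing runs on M-values,
M = log2(beta / (1 - beta)), which are closer to homoscedastic than beta
values; effect sizes and confidence intervals are reported on the percentage
scale, which is how practitioners read methylation differences.

qPCR expression is normalized to a panel of housekeeping genes and expressed
as 2^-dCt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError

QC_THRESHOLD_PCT = 5.0  # replicate range above this fails QC


@dataclass(frozen=True)
class MethylationRecord:
    """One donor x CpG pyrosequencing measurement (duplicate % values)."""

    donor_id: str
    locus_id: int
    cpg_index: int
    replicate_values: tuple[float, ...]
    qc_pass: bool
    mean_beta: float | None  # proportion in [0, 1]; present iff qc_pass

    @classmethod
    def from_replicates(cls, donor_id: str, locus_id: int, cpg_index: int,
                        values, qc_threshold: float = QC_THRESHOLD_PCT) -> "MethylationRecord":
        ok, mean = replicate_qc(values, qc_threshold)
        return cls(donor_id, locus_id, cpg_index, tuple(float(v) for v in values),
                   ok, None if mean is None else mean / 100.0)


@dataclass(frozen=True)
class DMSResult:
    """Differential methylation between two groups at one CpG."""

    locus_id: int
    cpg_index: int
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_diff: float            # percentage points, group_a - group_b
    ci95: tuple[float, float]   # percentage points
    p: float
    p_adj: float | None = None
    significant: bool | None = None


def replicate_qc(values, qc_threshold: float = QC_THRESHOLD_PCT) -> tuple[bool, float | None]:
    """Apply the replicate-agreement QC rule to 1-3 percentage values.

    Passes iff max - min <= ``qc_threshold`` (a single replicate passes
    vacuously).  Returns ``(qc_pass, mean_pct_or_None)``.
    """
    vals = [float(v) for v in values]
    if not 1 <= len(vals) <= 3:
        raise DomainError(f"expected 1-3 replicate values, got {len(vals)}")
    for v in vals:
        if not 0.0 <= v <= 100.0:
            raise DomainError(f"replicate value {v} outside [0, 100]")
    if max(vals) - min(vals) > qc_threshold:
        return False, None
    return True, float(np.mean(vals))


def beta_to_m(beta, eps: float = 1e-6):
    """Convert a methylation proportion to an M-value, log2(b / (1 - b)).

    ``beta`` is clamped to [eps, 1 - eps] so 0 and 1 map to finite values.
    Accepts scalars or arrays.
    """
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    return float(m) if np.isscalar(beta) or np.ndim(beta) == 0 else m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (away from the clamp region): 2^M / (2^M + 1)."""
    m_arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.power(2.0, -m_arr))
    return float(b) if np.isscalar(m) or np.ndim(m) == 0 else b


def differential_methylation(group_a, group_b, *, locus_id: int = 0, cpg_index: int = 0,
                             label_a: str = "A", label_b: str = "B",
                             alpha: float = 0.05) -> DMSResult:
    """Welch two-sample comparison of mean beta values between two groups.

    The p-value comes from Welch's t on M-values; the effect size and its 95%
    confidence interval are the difference of group means on the percentage
    scale with Welch-Satterthwaite degrees of freedom.  ``p_adj`` is left for
    the caller to fill in across the CpG panel (Benjamini-Hochberg).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError(
            f"need >= 3 QC-passing values per group, got {len(a)} and {len(b)}",
            n_a=len(a), n_b=len(b))

    p = float(stats.ttest_ind(beta_to_m(a), beta_to_m(b), equal_var=False).pvalue)

    pa, pb = 100.0 * a, 100.0 * b
    diff = float(pa.mean() - pb.mean())
    va, vb = pa.var(ddof=1) / len(pa), pb.var(ddof=1) / len(pb)
    se = math.sqrt(va + vb)
    if se == 0.0:
        ci = (diff, diff)
    else:
        df = (va + vb) ** 2 / (va ** 2 / (len(pa) - 1) + vb ** 2 / (len(pb) - 1))
        tcrit = stats.t.ppf(0.975, df)
        ci = (diff - tcrit * se, diff + tcrit * se)
    return DMSResult(locus_id, cpg_index, label_a, label_b, len(a), len(b),
                     diff, ci, p)


def delta_ct_expression(ct_target: float, ct_housekeepers) -> float:
    """Relative expression 2^-dCt, dCt = Ct(target) - mean(Ct(housekeepers))."""
    hk = [float(c) for c in ct_housekeepers]
    if not hk:
        raise DomainError("housekeeper Ct list is empty")
    all_ct = [float(ct_target)] + hk
    if any(not math.isfinite(c) or c <= 0 for c in all_ct):
        raise DomainError("Ct values must be finite and > 0")
    dct = float(ct_target) - float(np.mean(hk))
    return float(2.0 ** (-dct))
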