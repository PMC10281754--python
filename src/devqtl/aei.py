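"""Allelic expression imbalance (AEI) from triplicate pyrosequencing.

A heterozygous donor's cDNA allele-A percentage is converted to an allelic
ratio A/(100-A) and normalized to the same donor's genomic-DNA ratio, which
absorbs assay-specific amplification bias (gDNA is obligately 50:50 at a
heterozygous site).  A normalized ratio of 1 means balanced allelic
expression; departures are tested per gene and tissue against a symmetric
null on the log2 scale with an exact two-sided Wilcoxon signed-rank test.

The exact test is computed from the full distribution of the positive-rank
sum over all 2^n sign assignments, built by a counting recursion on
integer-doubled midranks, so tied magnitudes are handled exactly.  With n
unanimous-direction distinct values the two-sided p is 2/2^n — e.g. 0.0078125
at n = 8 and 0.015625 at n = 7 — which is the smallest p the design can
attain.  Above ``max_exact_n`` the normal approximation with continuity and
tie correction is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, UndefinedTestError

QC_THRESHOLD_PCT = 5.0
MAX_EXACT_N = 25


@dataclass(frozen=True)
class AEIRecord:
    """One heterozygous donor x transcript-SNV triplicate measurement."""

    donor_id: str
    gene: str
    tissue: str
    rsid: str
    cdna_pcts: tuple[float, float, float]
    gdna_pcts: tuple[float, float, float]
    qc_pass: bool
    ratio: float | None        # normalized allelic ratio, > 0; present iff qc_pass
    log2_ratio: float | None


@dataclass(frozen=True)
class GeneAEISummary:
    gene: str
    tissue: str
    n: int
    mean_ratio: float | None
    median_ratio: float | None
    p: float | None
    significant: bool
    note: str = ""


def _triplet(values, name: str) -> tuple[float, float, float]:
    vals = tuple(float(v) for v in values)
    if len(vals) != 3:
        raise DomainError(f"{name}: expected 3 replicate percentages, got {len(vals)}")
    for v in vals:
        if not 0.0 < v < 100.0:
            raise DomainError(f"{name}: allele percentage {v} is degenerate "
                              "(must be strictly inside (0, 100))")
    return vals


def normalize_ratio(cdna_pcts, gdna_pcts, qc_threshold: float = QC_THRESHOLD_PCT,
                    *, donor_id: str = "", gene: str = "", tissue: str = "",
                    rsid: str = "") -> AEIRecord:
    """Build an :class:`AEIRecord` from cDNA and gDNA allele-A triplicates.

    QC fails if either triplicate's range on the percentage scale exceeds
    ``qc_threshold``.  The normalized ratio is the geometric mean of the
    per-replicate cDNA ratios A/(100-A) divided by the geometric mean of the
    gDNA ratios; on the geometric scale an allele relabeling (A <-> B) maps
    the ratio exactly to its reciprocal, which an arithmetic mean of ratios
    would not preserve.
    """
    c = _triplet(cdna_pcts, "cdna_pcts")
    g = _triplet(gdna_pcts, "gdna_pcts")
    qc = (max(c) - min(c) <= qc_threshold) and (max(g) - min(g) <= qc_threshold)
    if qc:
        cr = float(np.exp(np.mean([math.log(v / (100.0 - v)) for v in c])))
        gr = float(np.exp(np.mean([math.log(v / (100.0 - v)) for v in g])))
        ratio = cr / gr
        log2_ratio = math.log2(ratio)
    else:
        ratio = log2_ratio = None
    return AEIRecord(donor_id, gene, tissue, rsid, c, g, qc, ratio, log2_ratio)


def _exact_wplus_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per doubled positive-rank sum.

    Generating-polynomial recursion: product over ranks of (1 + x^rank),
    on the 2x-rank integer lattice so midranks stay exact.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def signed_rank_exact(values, max_exact_n: int = MAX_EXACT_N) -> float:
    """Two-sided Wilcoxon signed-rank p-value against a symmetric null at 0.

    Zeros are dropped before ranking; tied magnitudes receive midranks.  For
    n <= ``max_exact_n`` the p-value is exact (full 2^n distribution via the
    counting recursion); above that, normal approximation with continuity and
    tie corrections.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[x != 0.0]
    n = x.size
    if n == 0:
        raise UndefinedTestError("no non-zero values: signed-rank test undefined")
    ranks = stats.rankdata(np.abs(x))
    w_plus = float(ranks[x > 0].sum())

    if n <= max_exact_n:
        doubled = np.rint(2.0 * ranks).astype(np.int64)
        counts = _exact_wplus_counts(doubled)
        total = 2.0 ** n
        w2 = int(round(2.0 * w_plus))
        cdf = counts[: w2 + 1].sum() / total
        sf = counts[w2:].sum() / total
        return min(1.0, 2.0 * min(cdf, sf))

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    sd = math.sqrt(var)
    if w_plus > mean:
        z = (w_plus - mean - 0.5) / sd
    elif w_plus < mean:
        z = (w_plus - mean + 0.5) / sd
    else:
        z = 0.0
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


def gene_aei_summary(records, gene: str, tissue: str,
                     alpha: float = 0.05) -> GeneAEISummary:
    """Summarize QC-passing records of one gene/tissue: mean and median ratio,
    exact signed-rank p on the log2 ratios, significance at ``alpha``."""
    recs = [r for r in records
            if r.gene == gene and r.tissue == tissue and r.qc_pass]
    if not recs:
        return GeneAEISummary(gene, tissue, 0, None, None, None, False,
                              note="no QC-passing heterozygotes")
    ratios = np.array([r.ratio for r in recs])
    logs = np.array([r.log2_ratio for r in recs])
    try:
        p = signed_rank_exact(logs)
        note = ""
    except UndefinedTestError:
        p = None
        note = "all ratios exactly 1: test undefined, reported non-significant"
    return GeneAEISummary(gene, tissue, len(recs),
                          float(ratios.mean()), float(np.median(ratios)),
                          p, p is not None and p < alpha, note)


def unphased_group_test(het_log2_ratios, hom_log2_ratios) -> float:
    """Two-group comparison for a transcript SNV in linkage equilibrium with
    the association SNV: cDNA log2 ratios of association-SNV heterozygotes vs
    homozygotes, two-sided Mann-Whitney rank-sum p."""
    het = np.asarray(list(het_log2_ratios), dtype=float)
    hom = np.asarray(list(hom_log2_ratios), dtype=float)
    if het.size == 0 or hom.size == 0:
        raise UndefinedTestError("both genotype groups must be non-empty")
    return float(stats.mannwhitneyu(het, hom, alternative="two-sided").pvalue)
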