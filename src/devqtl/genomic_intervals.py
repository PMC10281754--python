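"""Interval algebra for open-chromatin analysis.

Coordinates in this module are BED-style: 0-based, half-open [start, end).
Table-style 1-based point positions (CpGs, SNVs) are converted exactly once,
inside :func:`intersect_points`.

Consensus peaks are defined at base level: a consensus region for a sample
group is a maximal run of bases covered by the peak calls of at least k of the
n samples (the study used k = 4 of 6 fetal and k = 3 of 5 aged samples).  The
base-level definition is deterministic, order-independent and directly
checkable against a per-base oracle.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .errors import DomainError

GROUPS = ("FH", "FK", "AH", "AK")  # fetal/aged hip and knee sample groups


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int   # 0-based inclusive
    end: int     # exclusive
    label: str = ""
    score: float = 0.0

    def __post_init__(self):
        if self.start >= self.end:
            raise DomainError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PeakCollection:
    """One sample's peak calls, merge-normalized (sorted, disjoint per chromosome)."""

    sample_id: str
    group: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise DomainError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        self.intervals = merge_intervals(self.intervals)


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Sort and merge overlapping/adjacent intervals (idempotent normal form)."""
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def consensus_peaks(samples, min_samples: int) -> list[GenomicInterval]:
    """Maximal regions where per-base sample coverage >= ``min_samples``.

    Event sweep over the merged per-sample interval endpoints; each sample
    contributes at most 1 to coverage at any base (its intervals are disjoint
    after normalization).
    """
    samples = list(samples)
    n = len(samples)
    if not 1 <= min_samples <= n:
        raise DomainError(f"min_samples {min_samples} outside [1, {n}]")
    groups = {s.group for s in samples}
    if len(groups) > 1:
        raise DomainError(f"samples span multiple groups {sorted(groups)}")

    events: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for s in samples:
        for iv in s.intervals:
            events[iv.chrom][iv.start] += 1
            events[iv.chrom][iv.end] -= 1

    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        cov = 0
        run_start = None
        for pos in sorted(events[chrom]):
            prev = cov
            cov += events[chrom][pos]
            if prev < min_samples <= cov:
                run_start = pos
            elif prev >= min_samples > cov:
                out.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
    return out


def _overlaps(region: GenomicInterval, intervals: list[GenomicInterval],
              min_overlap_frac: float = 0.0) -> bool:
    """>= 1 bp overlap by default; optionally a fraction of the region's length."""
    need = max(1, math.ceil(min_overlap_frac * len(region)))
    got = 0
    for iv in intervals:
        if iv.chrom != region.chrom:
            continue
        got += max(0, min(region.end, iv.end) - max(region.start, iv.start))
        if got >= need:
            return True
    return False


def classify_shared_unique(fh, fk, ah, ak, min_overlap_frac: float = 0.0
                           ) -> tuple[dict[str, int], list[GenomicInterval]]:
    """Label each region of the merged union of four consensus sets.

    Categories: ``all_four`` (overlaps every set), ``fetal_unique`` (overlaps
    FH or FK but neither aged set), ``aged_unique`` (converse), ``other``.
    Returns (category counts, labeled regions).
    """
    sets = {"FH": list(fh), "FK": list(fk), "AH": list(ah), "AK": list(ak)}
    union = merge_intervals([iv for ivs in sets.values() for iv in ivs])
    counts = {"all_four": 0, "fetal_unique": 0, "aged_unique": 0, "other": 0}
    labeled: list[GenomicInterval] = []
    for region in union:
        hit = {g: _overlaps(region, ivs, min_overlap_frac) for g, ivs in sets.items()}
        if all(hit.values()):
            cat = "all_four"
        elif (hit["FH"] or hit["FK"]) and not (hit["AH"] or hit["AK"]):
            cat = "fetal_unique"
        elif (hit["AH"] or hit["AK"]) and not (hit["FH"] or hit["FK"]):
            cat = "aged_unique"
        else:
            cat = "other"
        counts[cat] += 1
        labeled.append(GenomicInterval(region.chrom, region.start, region.end, cat))
    return counts, labeled


def intersect_points(points, intervals) -> list[tuple]:
    """Intersect 1-based point positions with half-open intervals.

    ``points`` is an iterable of (name, chrom, pos_1based).  A point at
    1-based position p hits [s, e) iff s <= p - 1 < e.  Returns
    ``(name, chrom, pos, [hit intervals])`` per point; unknown chromosomes
    yield empty hit lists.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda v: (v.start, v.end))

    out = []
    for name, chrom, pos in points:
        if pos < 1:
            raise DomainError(f"point {name}: 1-based position {pos} < 1")
        p0 = pos - 1
        hits = [iv for iv in by_chrom.get(chrom, ())
                if iv.start <= p0 < iv.end]
        out.append((name, chrom, pos, hits))
    return out


def state_enrichment(peaks, state_map) -> pd.DataFrame:
    """Per-chromatin-state peak enrichment against genomic background.

    Each peak is assigned the state of maximal base overlap (``unannotated``
    if no state covers it).  For each state: observed = fraction of peaks,
    expected = state's fraction of total annotated genome length,
    fold = observed/expected, p = two-sided exact binomial.
    """
    states = list(state_map)
    state_by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in states:
        state_by_chrom[iv.chrom].append(iv)
    for ivs in state_by_chrom.values():
        ivs.sort(key=lambda v: (v.start, v.end))

    genome_len = sum(len(iv) for iv in states)
    state_len: dict[str, int] = defaultdict(int)
    for iv in states:
        state_len[iv.label] += len(iv)

    assignments: dict[str, int] = defaultdict(int)
    peaks = list(peaks)
    for pk in peaks:
        best, best_ov = "unannotated", 0
        for iv in state_by_chrom.get(pk.chrom, ()):
            ov = min(pk.end, iv.end) - max(pk.start, iv.start)
            if ov > best_ov:
                best, best_ov = iv.label, ov
        assignments[best] += 1

    n = len(peaks)
    rows = []
    for state in sorted(set(state_len) | set(assignments)):
        obs_count = assignments.get(state, 0)
        observed = obs_count / n if n else 0.0
        expected = state_len.get(state, 0) / genome_len if genome_len else 0.0
        fold = observed / expected if expected > 0 else math.inf if observed > 0 else float("nan")
        if n and 0.0 < expected < 1.0:
            p = stats.binomtest(obs_count, n, expected, alternative="two-sided").pvalue
        else:
            p = float("nan")
        rows.append({"state": state, "n_peaks": obs_count, "observed": observed,
                     "expected": expected, "fold": fold, "p": p})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ProxySNV:
    rsid: str
    chrom: str
    pos: int      # 1-based
    ld_r2: float  # LD r^2 with the locus association SNV

    def __post_init__(self):
        if not 0.0 <= self.ld_r2 <= 1.0:
            raise DomainError(f"{self.rsid}: LD r2 {self.ld_r2} outside [0, 1]")


def prioritize_variants(proxies, fh, fk, ah, ak, r2_min: float = 0.8) -> pd.DataFrame:
    """Keep proxies with LD r² > ``r2_min`` that fall in open chromatin, and
    classify each by which consensus sets contain it.

    Timing classes: ``all_tissues`` (all four sets), ``fetal_only`` (fetal
    set(s) only), ``aged_only``, ``partial`` (any other non-empty combination).
    Proxies in no set are excluded — prioritization means intersection with
    open chromatin.
    """
    sets = {"FH": list(fh), "FK": list(fk), "AH": list(ah), "AK": list(ak)}
    rows = []
    for snv in proxies:
        if not snv.ld_r2 > r2_min:
            continue
        containing = [g for g, ivs in sets.items()
                      if intersect_points([(snv.rsid, snv.chrom, snv.pos)], ivs)[0][3]]
        if not containing:
            continue
        in_fetal = any(g in containing for g in ("FH", "FK"))
        in_aged = any(g in containing for g in ("AH", "AK"))
        if len(containing) == 4:
            cls = "all_tissues"
        elif in_fetal and not in_aged:
            cls = "fetal_only"
        elif in_aged and not in_fetal:
            cls = "aged_only"
        else:
            cls = "partial"
        rows.append({"rsid": snv.rsid, "chrom": snv.chrom, "pos": snv.pos,
                     "ld_r2": snv.ld_r2, "class": cls,
                     "containing_sets": ",".join(containing)})
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "ld_r2",
                                       "class", "containing_sets"])


def read_bed(path: str | Path, label_col: bool = False) -> list[GenomicInterval]:
    """Read BED3 (or BED4 with a label in column 4)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        label = str(row[3]) if label_col and len(row) > 3 else ""
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), label))
    return out


def write_bed(intervals, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label:
                cols.append(iv.label)
            fh.write("\t".join(cols) + "\n")
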