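"""Synthetic cohort generator.

Emulates the statistical structure the downstream stages assume, so the whole
pipeline is testable without access to human samples:

* Hardy-Weinberg genotypes at the locus table's effect-allele frequencies;
* genotype-additive methylation on the percentage scale (half the target
  genotypic effect per effect allele) over tissue-specific baselines, with
  small fixed per-CpG offsets, Gaussian technical replicate noise and
  record-level dropout;
* heterozygote-only allelic expression ratios whose log2 mean is linked to
  the donor's methylation M-value through a linear slope (the planted meQTL);
* per-sample open-chromatin interval sets on a toy contig with planted
  shared / fetal-only / aged-only regions;
* qPCR Ct tables with a tissue offset for cartilage marker genes.

Default cohort sizes follow the study design (FL 19, FC 75, AC 139 donors for
molecular assays; 6/6 fetal and 5/5 aged samples for peak sets).  All outputs
are deterministic functions of the spec, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError
from .genomic_intervals import GenomicInterval, PeakCollection
from .locus_config import LocusTable
from .measurements import MethylationRecord, beta_to_m
from .aei import normalize_ratio, AEIRecord

TISSUES = ("FL", "FC", "AC")
PEAK_GROUPS = ("FH", "FK", "AH", "AK")
FETAL_AGE_DAYS = (32, 119)   # developmental age range, days post conception
AGED_AGE_YEARS = (25, 91)
_CLAMP_EPS = 0.01            # keeps latent betas off 0/1 so logits stay finite
TOY_CONTIG = "chrT"
TOY_CONTIG_LEN = 10_000_000


@dataclass
class LocusEffect:
    """Planted effect structure for one locus."""

    baseline_beta: dict[str, float] = field(
        default_factory=lambda: {"FL": 0.60, "FC": 0.45, "AC": 0.55})
    ge_target: dict[str, float] = field(
        default_factory=lambda: {"FL": 10.0, "FC": 30.0, "AC": 15.0})
    aei_log2_mean: dict[str, float] = field(
        default_factory=lambda: {"FL": 0.0, "FC": -0.45, "AC": -0.30})
    meqtl_slope: float = 0.5     # M-value units per log2-ratio unit
    replicate_sd: float = 1.5    # % units, duplicate pyrosequencing noise
    triplicate_sd: float = 1.5   # % units, AEI triplicate noise
    dropout_rate: float = 0.05


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; identical specs (incl. seed)
    produce byte-identical outputs."""

    seed: int = 0
    n_per_tissue: dict[str, int] = field(
        default_factory=lambda: {"FL": 19, "FC": 75, "AC": 139})
    n_per_peak_group: dict[str, int] = field(
        default_factory=lambda: {"FH": 6, "FK": 6, "AH": 5, "AK": 5})
    effects: dict[int, LocusEffect] = field(default_factory=dict)
    cpg_offset_sd: float = 0.03      # beta units, fixed per-CpG shifts
    n_shared_peaks: int = 200
    n_fetal_peaks: int = 120
    n_aged_peaks: int = 150
    peak_width: int = 500
    peak_presence_prob: float = 0.95
    peak_jitter: int = 20            # bp, boundary jitter SD
    marker_delta_ct: float = -2.0    # FC marker Ct shift vs FL (lower = higher expr)

    def __post_init__(self):
        for t, n in {**self.n_per_tissue, **self.n_per_peak_group}.items():
            if n < 0:
                raise DomainError(f"negative sample count for {t}")
        for p in (self.peak_presence_prob,):
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"probability {p} outside [0, 1]")
        for eff in self.effects.values():
            if not 0.0 <= eff.dropout_rate <= 1.0:
                raise DomainError(f"dropout_rate {eff.dropout_rate} outside [0, 1]")
            for b in eff.baseline_beta.values():
                if not 0.0 < b < 1.0:
                    raise DomainError(f"baseline_beta {b} outside (0, 1)")

    def effect(self, locus_id: int) -> LocusEffect:
        return self.effects.get(locus_id, LocusEffect())

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        effects = {int(k): LocusEffect(**v) for k, v in d.pop("effects", {}).items()}
        return cls(effects=effects, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Donor:
    donor_id: str
    tissue: str
    age: float                 # days (fetal tissues) or years (aged)
    sex: str
    dosages: dict[int, int]    # locus_id -> effect-allele count


def simulate_genotypes(eaf: float, n: int, seed: int | np.random.Generator) -> list[int]:
    """i.i.d. Hardy-Weinberg dosages: P(2) = eaf^2, P(1) = 2 eaf (1-eaf), P(0) = (1-eaf)^2."""
    if not 0.0 < eaf < 1.0:
        raise DomainError(f"eaf {eaf} outside (0, 1)")
    if n < 0:
        raise DomainError(f"negative n {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = [(1 - eaf) ** 2, 2 * eaf * (1 - eaf), eaf ** 2]
    return [int(d) for d in rng.choice([0, 1, 2], size=n, p=probs)]


def build_donors(spec: CohortSpec, locus_table: LocusTable) -> list[Donor]:
    """Donor roster with tissue, age, sex and per-locus HWE dosage."""
    rng = np.random.default_rng(spec.seed)
    donors: list[Donor] = []
    for tissue in TISSUES:
        n = spec.n_per_tissue.get(tissue, 0)
        lo, hi = FETAL_AGE_DAYS if tissue in ("FL", "FC") else AGED_AGE_YEARS
        ages = rng.uniform(lo, hi, size=n)
        sexes = rng.choice(["M", "F"], size=n)
        dosage_cols = {
            loc.locus_id: simulate_genotypes(loc.genotyping_snv.eaf, n, rng)
            for loc in locus_table
        }
        for i in range(n):
            donors.append(Donor(
                donor_id=f"{tissue}{i + 1:03d}", tissue=tissue,
                age=float(ages[i]), sex=str(sexes[i]),
                dosages={lid: col[i] for lid, col in dosage_cols.items()}))
    return donors


def _cpg_offsets(spec: CohortSpec, locus_table: LocusTable) -> dict[tuple[int, int], float]:
    """Fixed per-CpG baseline shifts, a deterministic function of the seed."""
    rng = np.random.default_rng(spec.seed + 1)
    return {(c.locus_id, c.cpg_index): float(rng.normal(0.0, spec.cpg_offset_sd))
            for c in locus_table.all_cpgs()}


def simulate_methylation(spec: CohortSpec, donors: list[Donor],
                         locus_table: LocusTable) -> list[MethylationRecord]:
    """Duplicate pyrosequencing measurements per donor x CpG.

    Latent beta = clamp(baseline[tissue] + dosage * ge_target/2 / 100 + CpG
    offset); replicates are 100*beta + N(0, replicate_sd) truncated to
    [0, 100]; records drop out independently with ``dropout_rate``.
    """
    rng = np.random.default_rng(spec.seed + 2)
    offsets = _cpg_offsets(spec, locus_table)
    records: list[MethylationRecord] = []
    for donor in donors:
        for loc in locus_table:
            eff = spec.effect(loc.locus_id)
            base = eff.baseline_beta[donor.tissue]
            ge = eff.ge_target[donor.tissue]
            dosage = donor.dosages[loc.locus_id]
            for cpg in loc.cpgs:
                # draw before the dropout branch so record count never
                # perturbs the stream alignment of later draws
                noise = rng.normal(0.0, eff.replicate_sd, size=2) if eff.replicate_sd > 0 else np.zeros(2)
                drop = rng.random() < eff.dropout_rate
                if drop:
                    continue
                latent = base + dosage * ge / 2.0 / 100.0 + offsets[(loc.locus_id, cpg.cpg_index)]
                latent = float(np.clip(latent, _CLAMP_EPS, 1.0 - _CLAMP_EPS))
                reps = np.clip(100.0 * latent + noise, 0.0, 100.0)
                records.append(MethylationRecord.from_replicates(
                    donor.donor_id, loc.locus_id, cpg.cpg_index, reps))
    return records


def simulate_aei(spec: CohortSpec, donors: list[Donor], locus_table: LocusTable,
                 methylation: list[MethylationRecord]) -> list[AEIRecord]:
    """Triplicate cDNA/gDNA allele percentages for heterozygous donors.

    The donor's log2 allelic ratio is aei_log2_mean[tissue] plus
    meqtl_slope * (donor mean M at the locus - tissue mean M), realized as an
    allele-A percentage with triplicate noise; gDNA triplicates center on 50%.
    """
    rng = np.random.default_rng(spec.seed + 3)
    m_by_donor: dict[tuple[str, int], list[float]] = {}
    for rec in methylation:
        if rec.qc_pass:
            m_by_donor.setdefault((rec.donor_id, rec.locus_id), []).append(
                beta_to_m(rec.mean_beta))
    donor_m = {k: float(np.mean(v)) for k, v in m_by_donor.items()}

    tissue_of = {d.donor_id: d.tissue for d in donors}
    tissue_mean_m: dict[tuple[str, int], float] = {}
    for (donor_id, lid), m in donor_m.items():
        key = (tissue_of[donor_id], lid)
        tissue_mean_m.setdefault(key, [])
    for key in tissue_mean_m:
        vals = [m for (did, lid), m in donor_m.items()
                if (tissue_of[did], lid) == key]
        tissue_mean_m[key] = float(np.mean(vals))

    records: list[AEIRecord] = []
    for donor in donors:
        for loc in locus_table:
            if donor.dosages[loc.locus_id] != 1:
                continue
            eff = spec.effect(loc.locus_id)
            m = donor_m.get((donor.donor_id, loc.locus_id))
            center = tissue_mean_m.get((donor.tissue, loc.locus_id), 0.0)
            m_dev = 0.0 if m is None else m - center
            log2_ratio = eff.aei_log2_mean[donor.tissue] + eff.meqtl_slope * m_dev
            ratio = 2.0 ** log2_ratio
            pct = 100.0 * ratio / (1.0 + ratio)
            cdna = np.clip(pct + rng.normal(0.0, eff.triplicate_sd, size=3), 0.5, 99.5)
            gdna = np.clip(50.0 + rng.normal(0.0, eff.triplicate_sd, size=3), 0.5, 99.5)
            records.append(normalize_ratio(
                cdna, gdna, donor_id=donor.donor_id, gene=loc.genes[0],
                tissue=donor.tissue, rsid=loc.genotyping_snv.rsid))
    return records


def simulate_peak_sets(spec: CohortSpec, seed: int | None = None
                       ) -> tuple[dict[str, list[PeakCollection]], dict[str, list[GenomicInterval]]]:
    """Per-sample peak interval sets with planted shared/fetal/aged regions.

    Returns ``(samples_by_group, truth)`` where ``truth`` maps
    'shared'/'fetal'/'aged' to the planted ground-truth regions on the toy
    contig.  Each sample includes each relevant planted region with
    ``peak_presence_prob``, boundaries jittered by N(0, peak_jitter).
    """
    rng = np.random.default_rng(spec.seed + 4 if seed is None else seed)
    n_total = spec.n_shared_peaks + spec.n_fetal_peaks + spec.n_aged_peaks
    spacing = TOY_CONTIG_LEN // max(1, n_total + 1)
    if spacing <= spec.peak_width + 8 * max(1, spec.peak_jitter):
        raise DomainError("toy contig too crowded for requested peak counts")

    starts = [(i + 1) * spacing for i in range(n_total)]
    order = rng.permutation(n_total)
    classes = (["shared"] * spec.n_shared_peaks + ["fetal"] * spec.n_fetal_peaks
               + ["aged"] * spec.n_aged_peaks)
    truth: dict[str, list[GenomicInterval]] = {"shared": [], "fetal": [], "aged": []}
    planted: list[tuple[str, int, int]] = []
    for idx, cls in zip(order, classes):
        s = starts[idx]
        iv = GenomicInterval(TOY_CONTIG, s, s + spec.peak_width)
        truth[cls].append(iv)
        planted.append((cls, iv.start, iv.end))
    for cls in truth:
        truth[cls].sort()

    groups: dict[str, list[PeakCollection]] = {}
    for group in PEAK_GROUPS:
        wanted = {"shared", "fetal" if group.startswith("F") else "aged"}
        groups[group] = []
        for i in range(spec.n_per_peak_group.get(group, 0)):
            ivs = []
            for cls, s, e in planted:
                present = rng.random() < spec.peak_presence_prob
                j1 = int(round(rng.normal(0.0, spec.peak_jitter))) if spec.peak_jitter else 0
                j2 = int(round(rng.normal(0.0, spec.peak_jitter))) if spec.peak_jitter else 0
                if cls not in wanted or not present:
                    continue
                a, b = s + j1, e + j2
                if a >= b:
                    a, b = s, e
                ivs.append(GenomicInterval(TOY_CONTIG, max(0, a), min(TOY_CONTIG_LEN, b)))
            groups[group].append(PeakCollection(f"{group}{i + 1}", group, ivs))
    return groups, truth


def simulate_marker_expression(spec: CohortSpec, donors: list[Donor]) -> pd.DataFrame:
    """qPCR Ct table for cartilage marker and housekeeping genes.

    Marker genes get ``marker_delta_ct`` added in FC relative to FL, so
    cartilage shows higher marker expression (lower Ct) by construction.
    """
    rng = np.random.default_rng(spec.seed + 5)
    markers = ("COL2A1", "ACAN", "MATN3")
    housekeepers = ("18S", "HPRT1", "GAPDH")
    rows = []
    for donor in donors:
        if donor.tissue not in ("FL", "FC"):
            continue
        for gene in housekeepers:
            rows.append({"donor_id": donor.donor_id, "tissue": donor.tissue,
                         "gene": gene, "role": "housekeeper",
                         "ct": float(20.0 + rng.normal(0.0, 0.2))})
        for gene in markers:
            ct = 26.0 + (spec.marker_delta_ct if donor.tissue == "FC" else 0.0)
            rows.append({"donor_id": donor.donor_id, "tissue": donor.tissue,
                         "gene": gene, "role": "marker",
                         "ct": float(ct + rng.normal(0.0, 0.2))})
    return pd.DataFrame(rows, columns=["donor_id", "tissue", "gene", "role", "ct"])


def methylation_to_frame(records: list[MethylationRecord]) -> pd.DataFrame:
    """Long-format TSV dialect the real-data reader consumes."""
    rows = []
    for r in records:
        for k, v in enumerate(r.replicate_values, start=1):
            rows.append({"donor_id": r.donor_id, "locus": r.locus_id,
                         "cpg_index": r.cpg_index, "replicate": k,
                         "value_pct": v})
    return pd.DataFrame(rows, columns=["donor_id", "locus", "cpg_index",
                                       "replicate", "value_pct"])


def aei_to_frame(records: list[AEIRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for material, pcts in (("cDNA", r.cdna_pcts), ("gDNA", r.gdna_pcts)):
            rows.append({"donor_id": r.donor_id, "gene": r.gene,
                         "tissue": r.tissue, "rsid": r.rsid,
                         "material": material,
                         "rep1": pcts[0], "rep2": pcts[1], "rep3": pcts[2]})
    return pd.DataFrame(rows, columns=["donor_id", "gene", "tissue", "rsid",
                                       "material", "rep1", "rep2", "rep3"])
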