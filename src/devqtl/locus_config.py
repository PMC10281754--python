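"""Locus definition table: the panel of OA risk loci, association SNVs and CpG sites.

The table drives every downstream stage.  It is a flat tab-separated file with
one row per CpG; locus-level columns (SNV, alleles, EAF, genes) are repeated on
every row of a locus block.  A locus may carry more than one association SNV
(semicolon-joined lists in the SNV columns); the first listed is the genotyping
SNV used for dosage coding unless overridden downstream.

Coordinates are stored as printed: 1-based, hg19.  Conversion to half-open
intervals happens in :mod:`devqtl.genomic_intervals`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DomainError, ParseError

COLUMNS = [
    "locus", "rsid", "chrom", "snv_pos", "nea", "ea", "eaf",
    "cpg_index", "cg_id", "cpg_pos", "discovery_p", "genes", "annotation",
]

_NUCLEOTIDES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class AssociationSNV:
    """A GWAS association SNV marking a locus."""

    rsid: str
    chrom: str
    pos: int            # 1-based
    non_effect_allele: str
    effect_allele: str
    eaf: float          # effect-allele frequency, in (0, 1)


@dataclass(frozen=True)
class CpGSite:
    """One investigated CpG within a locus."""

    locus_id: int
    cpg_index: int      # 1-based within locus
    pos: int            # 1-based
    discovery_cg_id: str | None = None
    discovery_p: float | None = None
    region_annotation: str = ""


@dataclass
class Locus:
    locus_id: int
    snvs: list[AssociationSNV]
    genes: list[str]
    cpgs: list[CpGSite] = field(default_factory=list)

    @property
    def genotyping_snv(self) -> AssociationSNV:
        """The SNV used for dosage coding (first listed)."""
        return self.snvs[0]


@dataclass
class LocusTable:
    """The full locus panel: loci in file order, each with its ordered CpGs."""

    loci: list[Locus]

    def __iter__(self) -> Iterable[Locus]:
        return iter(self.loci)

    def locus(self, locus_id: int) -> Locus:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(f"unknown locus_id {locus_id}")

    def all_cpgs(self) -> list[CpGSite]:
        return [c for loc in self.loci for c in loc.cpgs]

    def to_json(self) -> str:
        payload = [
            {
                "locus_id": loc.locus_id,
                "snvs": [vars(s) for s in loc.snvs],
                "genes": loc.genes,
                "cpgs": [vars(c) for c in loc.cpgs],
            }
            for loc in self.loci
        ]
        return json.dumps(payload, indent=2)


def _parse_row(row: pd.Series, line_no: int) -> tuple[int, list[AssociationSNV], list[str], CpGSite]:
    def bad(msg: str) -> ParseError:
        return ParseError(f"line {line_no}: {msg}")

    try:
        locus_id = int(row["locus"])
        cpg_index = int(row["cpg_index"])
        cpg_pos = int(row["cpg_pos"])
    except (TypeError, ValueError) as exc:
        raise bad(f"non-integer locus/cpg_index/cpg_pos ({exc})") from None

    rsids = str(row["rsid"]).split(";")
    poss = str(row["snv_pos"]).split(";")
    neas = str(row["nea"]).split(";")
    eas = str(row["ea"]).split(";")
    eafs = str(row["eaf"]).split(";")
    if not len(rsids) == len(poss) == len(neas) == len(eas) == len(eafs):
        raise bad("SNV list columns have unequal lengths")
    try:
        snvs = [
            AssociationSNV(r, str(row["chrom"]), int(p), n, e, float(f))
            for r, p, n, e, f in zip(rsids, poss, neas, eas, eafs)
        ]
    except ValueError as exc:
        raise bad(f"malformed SNV fields ({exc})") from None

    genes = [g for g in str(row["genes"]).split(";") if g]
    cg = row.get("cg_id")
    cg_id = None if pd.isna(cg) or cg == "" else str(cg)
    dp = row.get("discovery_p")
    disc_p = None if pd.isna(dp) or dp == "" else float(dp)
    cpg = CpGSite(locus_id, cpg_index, cpg_pos, cg_id, disc_p,
                  str(row.get("annotation", "") or ""))
    return locus_id, snvs, genes, cpg


def read_locus_table(path: str | Path) -> LocusTable:
    """Read and validate the locus definition TSV.

    Raises :class:`ParseError` naming the line on malformed rows, and
    :class:`DomainError` if the parsed table violates its invariants
    (e.g. duplicate CpG position).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")

    loci: dict[int, Locus] = {}
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        locus_id, snvs, genes, cpg = _parse_row(row, line_no)
        if locus_id not in loci:
            loci[locus_id] = Locus(locus_id, snvs, genes)
        loci[locus_id].cpgs.append(cpg)

    table = LocusTable(list(loci.values()))
    violations = validate_locus_table(table)
    if violations:
        raise DomainError("invalid locus table: " + "; ".join(violations))
    return table


def write_locus_table(table: LocusTable, path: str | Path) -> None:
    """Write a :class:`LocusTable` back to the flat TSV dialect (round-trips)."""
    rows = []
    for loc in table.loci:
        join = ";".join
        for c in loc.cpgs:
            rows.append({
                "locus": loc.locus_id,
                "rsid": join(s.rsid for s in loc.snvs),
                "chrom": loc.snvs[0].chrom,
                "snv_pos": join(str(s.pos) for s in loc.snvs),
                "nea": join(s.non_effect_allele for s in loc.snvs),
                "ea": join(s.effect_allele for s in loc.snvs),
                "eaf": join(repr(s.eaf) for s in loc.snvs),
                "cpg_index": c.cpg_index,
                "cg_id": c.discovery_cg_id or "",
                "cpg_pos": c.pos,
                "discovery_p": "" if c.discovery_p is None else repr(c.discovery_p),
                "genes": join(loc.genes),
                "annotation": c.region_annotation,
            })
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep="\t", index=False)


def cpg_count(table: LocusTable, locus_id: int | None = None) -> int:
    """Number of CpG sites, optionally restricted to one locus."""
    if locus_id is None:
        return sum(len(loc.cpgs) for loc in table.loci)
    return len(table.locus(locus_id).cpgs)  # KeyError on unknown locus


def validate_locus_table(table: LocusTable) -> list[str]:
    """Check all invariants; returns a list of violation descriptions (empty if valid)."""
    out: list[str] = []
    seen_pos: dict[int, int] = {}
    for loc in table.loci:
        lid = loc.locus_id
        if not loc.genes:
            out.append(f"locus {lid}: genes: gene list must be non-empty")
        for s in loc.snvs:
            if not (0.0 < s.eaf < 1.0):
                out.append(f"locus {lid}: eaf: EAF {s.eaf} outside (0, 1)")
            if s.non_effect_allele not in _NUCLEOTIDES or s.effect_allele not in _NUCLEOTIDES:
                out.append(f"locus {lid}: alleles: must be single nucleotides "
                           f"({s.non_effect_allele}/{s.effect_allele})")
            elif s.non_effect_allele == s.effect_allele:
                out.append(f"locus {lid}: alleles: effect and non-effect allele identical")
            if s.pos < 1:
                out.append(f"locus {lid}: snv_pos: position {s.pos} < 1")
        seen_idx: set[int] = set()
        for c in loc.cpgs:
            if c.pos < 1:
                out.append(f"locus {lid}: cpg_pos: position {c.pos} < 1")
            if c.cpg_index < 1:
                out.append(f"locus {lid}: cpg_index: index {c.cpg_index} < 1")
            if c.cpg_index in seen_idx:
                out.append(f"locus {lid}: cpg_index: duplicate index {c.cpg_index}")
            seen_idx.add(c.cpg_index)
            if c.pos in seen_pos:
                out.append(f"locus {lid}: cpg_pos: position {c.pos} duplicates "
                           f"locus {seen_pos[c.pos]} (uniqueness across table)")
            else:
                seen_pos[c.pos] = lid
    return out


def load_default_table() -> LocusTable:
    """Load the locus panel shipped with the package (seven OA risk loci, 39 CpGs)."""
    with resources.as_file(resources.files("devqtl.data") / "locus_table.tsv") as p:
        return read_locus_table(p)
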