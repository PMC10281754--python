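"""End-to-end orchestration: simulate (or load) -> QC -> differential
methylation -> mQTL/GE -> co-methylation -> AEI -> meQTL -> interval analysis,
with a JSON run manifest that fully determines a rerun.

Every stage writes a TSV into the output directory with a fixed float format,
so identical config + seed gives byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from . import aei as aei_mod
from . import comethylation, genomic_intervals, measurements, qtl, synthetic_cohort
from .locus_config import LocusTable, load_default_table, read_locus_table

_FLOAT_FMT = "%.10g"
_KNOWN_KEYS = {"seed", "outdir", "simulate", "locus_table", "cohort", "qc",
               "stats", "intervals", "inputs"}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    unknown = sorted(set(cfg) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    if not cfg.get("simulate", True) and "inputs" not in cfg:
        raise ConfigError("simulate is false but no 'inputs' section given")
    return cfg


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _qc_methylation(meth_df: pd.DataFrame, qc_threshold: float):
    """Collapse replicate rows to per-(donor, CpG) records via replicate QC."""
    records = []
    grouped = meth_df.groupby(["donor_id", "locus", "cpg_index"], sort=True)
    for (donor, locus, cpg), grp in grouped:
        vals = grp.sort_values("replicate")["value_pct"].tolist()
        records.append(measurements.MethylationRecord.from_replicates(
            donor, int(locus), int(cpg), vals, qc_threshold))
    return records


def run_pipeline(config, outdir: str | Path | None = None) -> dict:
    """Run every stage and write the report bundle.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    cfg = _load_config(config)
    out = Path(outdir or cfg.get("outdir", "devqtl_out"))
    out.mkdir(parents=True, exist_ok=True)

    seed = int(cfg.get("seed", 0))
    qc_cfg = cfg.get("qc", {})
    stats_cfg = cfg.get("stats", {})
    iv_cfg = cfg.get("intervals", {})
    qc_threshold = float(qc_cfg.get("qc_threshold", measurements.QC_THRESHOLD_PCT))
    alpha = float(stats_cfg.get("alpha", 0.05))

    table = (read_locus_table(cfg["locus_table"]) if cfg.get("locus_table")
             else load_default_table())

    spec = synthetic_cohort.CohortSpec.from_dict({"seed": seed, **cfg.get("cohort", {})})
    donors = synthetic_cohort.build_donors(spec, table)
    meth_records = synthetic_cohort.simulate_methylation(spec, donors, table)
    meth_df = synthetic_cohort.methylation_to_frame(meth_records)
    _write(meth_df, out / "methylation_raw.tsv")

    # --- replicate QC ---------------------------------------------------
    records = _qc_methylation(meth_df, qc_threshold)
    tissue_of = {d.donor_id: d.tissue for d in donors}
    qc_df = pd.DataFrame([{
        "donor_id": r.donor_id, "tissue": tissue_of[r.donor_id],
        "locus": r.locus_id, "cpg_index": r.cpg_index,
        "qc_pass": r.qc_pass,
        "mean_beta": np.nan if r.mean_beta is None else r.mean_beta,
    } for r in records])
    _write(qc_df, out / "methylation_qc.tsv")
    passing = qc_df[qc_df.qc_pass]

    # --- mean-beta matrices (heatmap-ready) ------------------------------
    passing = passing.assign(cpg=passing.locus.astype(str) + "." + passing.cpg_index.astype(str))
    wide = passing.pivot_table(index="cpg", columns="tissue", values="mean_beta",
                               aggfunc="mean", observed=True)
    _write(wide.reset_index(), out / "mean_beta_by_tissue.tsv")

    # --- differential methylation: FC vs AC per CpG, BH across panel -----
    dms_rows = []
    for (locus, cpg), grp in passing.groupby(["locus", "cpg_index"], sort=True):
        a = grp[grp.tissue == "FC"].mean_beta.to_numpy()
        b = grp[grp.tissue == "AC"].mean_beta.to_numpy()
        if len(a) < 3 or len(b) < 3:
            continue
        res = measurements.differential_methylation(
            a, b, locus_id=int(locus), cpg_index=int(cpg),
            label_a="FC", label_b="AC", alpha=alpha)
        dms_rows.append({"locus": res.locus_id, "cpg_index": res.cpg_index,
                         "n_FC": res.n_a, "n_AC": res.n_b,
                         "mean_diff_pct": res.mean_diff,
                         "ci_lo": res.ci95[0], "ci_hi": res.ci95[1], "p": res.p})
    dms = pd.DataFrame(dms_rows)
    if len(dms):
        dms["p_adj"] = qtl.adjust_pvalues(dms.p, method=stats_cfg.get("dms_adjust", "bh"))
        dms["significant"] = dms.p_adj < alpha
    _write(dms, out / "dms.tsv")

    # --- mQTL per tissue, BH across the panel within tissue --------------
    dosage_of = {(d.donor_id, lid): dos for d in donors for lid, dos in d.dosages.items()}
    mqtl_rows = []
    for tissue in synthetic_cohort.TISSUES:
        sub = passing[passing.tissue == tissue]
        for (locus, cpg), grp in sub.groupby(["locus", "cpg_index"], sort=True):
            betas = grp.mean_beta.to_numpy()
            dosages = np.array([dosage_of[(d, int(locus))] for d in grp.donor_id])
            try:
                res = qtl.fit_mqtl(betas, dosages, locus_id=int(locus),
                                   cpg_index=int(cpg), tissue=tissue)
            except (qtl.NotEstimableError, qtl.InsufficientDataError):
                continue
            mqtl_rows.append({"locus": res.locus_id, "cpg_index": res.cpg_index,
                              "tissue": tissue, "n": res.n,
                              "slope_m": res.slope_m, "ge": res.ge,
                              "ge_sign": res.ge_sign, "p": res.p})
    mqtl = pd.DataFrame(mqtl_rows)
    if len(mqtl):
        mqtl["p_adj"] = np.nan
        for tissue in mqtl.tissue.unique():
            mask = mqtl.tissue == tissue
            mqtl.loc[mask, "p_adj"] = qtl.adjust_pvalues(
                mqtl.loc[mask, "p"], method=stats_cfg.get("mqtl_adjust", "bh"))
        mqtl["significant"] = mqtl.p_adj < alpha
    _write(mqtl, out / "mqtl.tsv")
    ge_matrix = (mqtl.assign(cpg=mqtl.locus.astype(str) + "." + mqtl.cpg_index.astype(str))
                 .pivot_table(index="cpg", columns="tissue", values="ge", observed=True)
                 if len(mqtl) else pd.DataFrame())
    _write(ge_matrix.reset_index() if len(ge_matrix) else ge_matrix,
           out / "ge_matrix.tsv")

    # --- co-methylation ---------------------------------------------------
    beta_mat = passing.pivot_table(index="donor_id", columns="cpg",
                                   values="mean_beta", observed=True)
    corr = comethylation.correlation_matrix(beta_mat)
    _write(corr.to_frame().reset_index(names="cpg"), out / "comethylation_r.tsv")
    try:
        leaf_order, _ = comethylation.hierarchical_order(corr)
        (out / "comethylation_dendrogram.json").write_text(
            json.dumps({"leaf_order": leaf_order,
                        "merges": comethylation.merge_tree_json(corr)}, indent=2))
    except (comethylation.DomainError, ValueError):
        leaf_order = []  # < 2 clusterable CpGs or missing pairs

    # --- AEI --------------------------------------------------------------
    aei_records = synthetic_cohort.simulate_aei(spec, donors, table, meth_records)
    _write(synthetic_cohort.aei_to_frame(aei_records), out / "aei_raw.tsv")
    aei_rows = []
    for gene in sorted({r.gene for r in aei_records}):
        for tissue in synthetic_cohort.TISSUES:
            s = aei_mod.gene_aei_summary(aei_records, gene, tissue, alpha=alpha)
            aei_rows.append({"gene": gene, "tissue": tissue, "n": s.n,
                             "mean_ratio": s.mean_ratio, "median_ratio": s.median_ratio,
                             "p": s.p, "significant": s.significant, "note": s.note})
    aei_df = pd.DataFrame(aei_rows)
    _write(aei_df, out / "aei_summary.tsv")

    # --- meQTL: per gene across its CpGs, Bonferroni per gene ------------
    log2_by_donor = {(r.donor_id, r.gene): r.log2_ratio
                     for r in aei_records if r.qc_pass}
    meqtl_rows = []
    for loc in table:
        gene = loc.genes[0]
        for tissue in synthetic_cohort.TISSUES:
            for cpg in loc.cpgs:
                sub = passing[(passing.tissue == tissue)
                              & (passing.locus == loc.locus_id)
                              & (passing.cpg_index == cpg.cpg_index)]
                pairs = [(measurements.beta_to_m(b), log2_by_donor[(d, gene)])
                         for d, b in zip(sub.donor_id, sub.mean_beta)
                         if (d, gene) in log2_by_donor]
                if len(pairs) < 4:
                    continue
                m_vals, ratios = zip(*pairs)
                try:
                    res = qtl.fit_meqtl(m_vals, ratios, locus_id=loc.locus_id,
                                        cpg_index=cpg.cpg_index, gene=gene,
                                        tissue=tissue)
                except qtl.NotEstimableError:
                    continue
                meqtl_rows.append({"locus": res.locus_id, "cpg_index": res.cpg_index,
                                   "gene": gene, "tissue": tissue, "n": res.n,
                                   "slope": res.slope, "r2": res.r2, "p": res.p})
    meqtl = pd.DataFrame(meqtl_rows)
    if len(meqtl):
        meqtl["p_adj"] = np.nan
        for gene in meqtl.gene.unique():
            mask = meqtl.gene == gene
            meqtl.loc[mask, "p_adj"] = qtl.adjust_pvalues(
                meqtl.loc[mask, "p"], method="bonferroni")
        meqtl["significant"] = meqtl.p_adj < alpha
    _write(meqtl, out / "meqtl.tsv")

    # --- open-chromatin intervals ----------------------------------------
    groups, truth = synthetic_cohort.simulate_peak_sets(spec)
    consensus = {}
    for group, samples in groups.items():
        n = len(samples)
        k = int(iv_cfg.get("min_samples", {}).get(group,
                4 if group.startswith("F") else 3)) if isinstance(
                    iv_cfg.get("min_samples"), dict) else (4 if group.startswith("F") else 3)
        k = min(k, n) if n else 0
        consensus[group] = (genomic_intervals.consensus_peaks(samples, k)
                            if n else [])
        genomic_intervals.write_bed(consensus[group], out / f"consensus_{group}.bed")
    counts, labeled = genomic_intervals.classify_shared_unique(
        consensus["FH"], consensus["FK"], consensus["AH"], consensus["AK"],
        min_overlap_frac=float(iv_cfg.get("min_overlap_frac", 0.0)))
    genomic_intervals.write_bed(labeled, out / "regions_classified.bed")

    cpg_points = [(f"{c.locus_id}.{c.cpg_index}", f"chr{table.locus(c.locus_id).genotyping_snv.chrom}", c.pos)
                  for c in table.all_cpgs()]
    union = genomic_intervals.merge_intervals(
        [iv for ivs in consensus.values() for iv in ivs])
    cpg_hits = genomic_intervals.intersect_points(cpg_points, union)
    _write(pd.DataFrame([{"cpg": n, "chrom": c, "pos": p, "n_hits": len(h)}
                         for n, c, p, h in cpg_hits]), out / "cpg_open_chromatin.tsv")

    # --- manifest ---------------------------------------------------------
    n_records = len(records)
    n_excluded = int((~qc_df.qc_pass).sum())
    aei_pass = sum(1 for r in aei_records if r.qc_pass)
    manifest = {
        "software_version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "counts": {
            "donors": len(donors),
            "methylation": {"loaded": n_records, "qc_excluded": n_excluded,
                            "tested": n_records - n_excluded},
            "dms": {"tested": int(len(dms)),
                    "significant": int(dms.significant.sum()) if len(dms) else 0},
            "mqtl": {"tested": int(len(mqtl)),
                     "significant": int(mqtl.significant.sum()) if len(mqtl) else 0},
            "aei": {"records_loaded": len(aei_records),
                    "qc_excluded": len(aei_records) - aei_pass,
                    "records_tested": aei_pass,
                    "significant_gene_tissue": int(aei_df.significant.sum()) if len(aei_df) else 0},
            "meqtl": {"tested": int(len(meqtl)),
                      "significant": int(meqtl.significant.sum()) if len(meqtl) else 0},
            "regions": {**counts,
                        "planted_shared": len(truth["shared"]),
                        "planted_fetal": len(truth["fetal"]),
                        "planted_aged": len(truth["aged"])},
            "cpgs_in_open_chromatin": sum(1 for *_x, h in cpg_hits if h),
        },
        "comethylation_leaf_order": leaf_order,
        "outputs": {},
    }
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def render_summary(bundle_dir: str | Path) -> str:
    """Human-readable markdown summary sourced only from the bundle files."""
    out = Path(bundle_dir)
    lines = ["# devqtl run summary", ""]
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        return "\n".join(lines + ["stage missing: manifest.json"])
    manifest = json.loads(manifest_path.read_text())
    counts = manifest.get("counts", {})
    lines += [f"seed: {manifest.get('seed')}",
              f"version: {manifest.get('software_version')}", ""]

    stages = {
        "methylation_qc.tsv": "Methylation QC",
        "dms.tsv": "Differential methylation (FC vs AC)",
        "mqtl.tsv": "mQTL / genotypic effect",
        "aei_summary.tsv": "Allelic expression imbalance",
        "meqtl.tsv": "Methylation-expression QTL",
        "regions_classified.bed": "Open-chromatin region classes",
    }
    for fname, title in stages.items():
        if not (out / fname).exists():
            lines.append(f"## {title}\n\nstage missing: {fname}\n")
            continue
        lines.append(f"## {title}\n")
        key = {"methylation_qc.tsv": "methylation", "dms.tsv": "dms",
               "mqtl.tsv": "mqtl", "aei_summary.tsv": "aei",
               "meqtl.tsv": "meqtl", "regions_classified.bed": "regions"}[fname]
        for k, v in counts.get(key, {}).items():
            lines.append(f"- {k}: {v}")
        if fname == "mqtl.tsv":
            mqtl = pd.read_csv(out / fname, sep="\t")
            if len(mqtl) and "significant" in mqtl:
                per_tissue = mqtl.groupby("tissue").significant.sum()
                for tissue, n_sig in per_tissue.items():
                    lines.append(f"- significant in {tissue}: {int(n_sig)}")
        lines.append("")
    return "\n".join(lines)
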