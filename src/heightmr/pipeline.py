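"""End-to-end orchestration: per-study analysis and cross-study pooling.

``run_all`` drives instrument QC, risk-score construction, one-sample
logistic association (continuous, pooled-tertile and spline), summary-data
IVW with pleiotropy filtering, optional BMI-overlap sensitivity analysis
and gene-set enrichment, then pools study estimates by fixed-effect
meta-analysis.  Every excluded SNP is accounted for with a reason, and the
run manifest records input checksums, thresholds and the package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (
    SUBTYPES,
    grs_association,
    nonlinearity_test,
    tertile_association,
)
from .enrichment import enrichment_frame, overrepresentation, read_gene_map, read_gmt
from .grs import ScoreVector, assign_tertiles, compute_ugrs, compute_wgrs
from .instruments import (
    HarmonizeAction,
    LDTable,
    exclude_bmi_overlap,
    harmonize_alleles,
    load_instruments,
    prune_ld,
    qc_filter,
    read_dosage_tsv,
    read_dosage_vcf,
    substitute_proxies,
)
from .mr import SummaryStats, fixed_effect_meta, ivw_estimate, pleiotropy_filter
from .simulate import _per_snp_logistic
from .assoc import fit_logistic

__all__ = ["StudyInputs", "RunConfig", "PipelineError", "run_study", "run_meta", "run_all"]


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class StudyInputs:
    name: str
    dosage_path: str
    phenotype_path: str
    covariates: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    instrument_path: str
    studies: list[StudyInputs]
    ld_path: str | None = None
    bmi_path: str | None = None
    proxy_path: str | None = None
    gmt_path: str | None = None
    gene_map_path: str | None = None
    # thresholds
    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    ld_r2_max: float = 0.1
    proxy_r2_min: float = 0.9
    pleiotropy_alpha: float = 0.05
    # analysis toggles
    wgrs: bool = True
    ugrs: bool = True
    ivw: bool = True
    tertiles: bool = True
    spline: bool = True
    bmi_sensitivity: bool = False
    enrichment: bool = False
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("at least one study is required")
        for name, v, lo, hi in (
            ("maf_min", self.maf_min, 0.0, 0.5),
            ("call_rate_min", self.call_rate_min, 0.0, 1.0),
            ("hwe_p_min", self.hwe_p_min, 0.0, 1.0),
            ("ld_r2_max", self.ld_r2_max, 0.0, 1.0),
            ("proxy_r2_min", self.proxy_r2_min, 0.0, 1.0),
            ("pleiotropy_alpha", self.pleiotropy_alpha, 0.0, 1.0),
        ):
            if not (lo <= v <= hi):
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {v}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        studies = [StudyInputs(**s) for s in raw.pop("studies")]
        return cls(studies=studies, **raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_genotypes(path: str):
    p = Path(path)
    if p.suffix in (".vcf", ".gz") or p.name.endswith(".vcf.gz"):
        return read_dosage_vcf(p, return_alleles=True)
    return read_dosage_tsv(p), None


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def _subtypes_present(pheno: pd.DataFrame) -> list[str]:
    out = ["all"]
    for st in ("adenocarcinoma", "squamous"):
        if ((pheno["status"] == 1) & (pheno["subtype"] == st)).any():
            out.append(st)
    return out


def run_study(
    config: RunConfig,
    study_index: int,
    tertiles_by_subject: "pd.DataFrame | None" = None,
) -> dict:
    """Run the full per-study analysis and return a JSON-serializable report.

    ``tertiles_by_subject`` carries pooled-tertile categories computed across
    all studies (the default categorization); when absent, tertiles are
    study-local.
    """
    study = config.studies[study_index]
    exclusions: dict[str, str] = {}

    with _stage("load"):
        records = load_instruments(config.instrument_path)
        genotypes, alleles = _read_genotypes(study.dosage_path)
        pheno = pd.read_csv(study.phenotype_path, sep="\t", dtype={"subject_id": str})
        ld = LDTable.from_tsv(config.ld_path) if config.ld_path else LDTable()

    with _stage("proxy"):
        if config.proxy_path:
            proxy_df = pd.read_csv(config.proxy_path, sep="\t", dtype=str)
            mapping = substitute_proxies(
                [r.snp_id for r in records],
                genotypes.snp_ids,
                zip(proxy_df["snp_id"], proxy_df["proxy"], proxy_df["r2"].astype(float)),
                r2_min=config.proxy_r2_min,
            )
        else:
            present = set(genotypes.snp_ids)
            mapping = {r.snp_id: (r.snp_id if r.snp_id in present else None) for r in records}
        for sid, used in mapping.items():
            if used is None:
                exclusions[sid] = "proxy_dropped"
        # rename proxy columns so downstream code sees the instrument ids
        renames = {v: k for k, v in mapping.items() if v is not None and v != k}
        if renames:
            genotypes.snp_ids = [renames.get(s, s) for s in genotypes.snp_ids]
        records = [r for r in records if mapping.get(r.snp_id) is not None]

    with _stage("harmonize"):
        if alleles is not None:
            info = alleles.set_index("snp_id")
            flips: list[str] = []
            kept = []
            for r in records:
                if r.snp_id not in info.index:
                    exclusions[r.snp_id] = "missing_from_genotypes"
                    continue
                row = info.loc[r.snp_id]
                h = harmonize_alleles(
                    r, row["effect_allele"], row["other_allele"], float(row["eaf"])
                )
                if h.action is HarmonizeAction.EXCLUDE:
                    exclusions[r.snp_id] = f"harmonize_{h.reason}"
                    continue
                if h.action is HarmonizeAction.FLIP_DOSAGE:
                    flips.append(r.snp_id)
                kept.append(r)
            if flips:
                genotypes = genotypes.flipped(flips)
            records = kept

    with _stage("qc"):
        control_ids = pheno.loc[pheno["status"] == 0, "subject_id"].tolist()
        sub = genotypes.subset(snp_ids=[r.snp_id for r in records])
        qc = qc_filter(
            sub,
            control_ids,
            maf_min=config.maf_min,
            call_rate_min=config.call_rate_min,
            hwe_p_min=config.hwe_p_min,
        )
        exclusions.update(qc.excluded)
        records = [r for r in records if r.snp_id in set(qc.kept)]

    with _stage("ld_prune"):
        pruned = prune_ld(records, ld, r2_max=config.ld_r2_max)
        for r in records:
            if r not in pruned:
                exclusions[r.snp_id] = "ld"
        records = pruned

    report: dict = {
        "study": study.name,
        "n_cases": int((pheno["status"] == 1).sum()),
        "n_controls": int((pheno["status"] == 0).sum()),
        "n_snps_used": len(records),
        "snp_exclusions": exclusions,
        "analyses": {},
    }

    with _stage("grs"):
        wscores = compute_wgrs(genotypes, records, control_ids=control_ids)
        uscores = compute_ugrs(genotypes, records, control_ids=control_ids)

    subtypes = _subtypes_present(pheno)
    for subtype in subtypes:
        block: dict = {}
        with _stage(f"assoc[{subtype}]"):
            if config.wgrs:
                block["wgrs"] = grs_association(
                    wscores, pheno, study.covariates, subtype
                ).to_dict()
            if config.ugrs:
                block["ugrs"] = grs_association(
                    uscores, pheno, study.covariates, subtype
                ).to_dict()
            if config.tertiles:
                if tertiles_by_subject is not None:
                    cats = tertiles_by_subject
                    tert = _tertiles_from_frame(cats, wscores)
                else:
                    tert = assign_tertiles(wscores)
                ta = tertile_association(tert, pheno, study.covariates, subtype)
                block["tertiles"] = {
                    "Q2": ta.q2.to_dict(),
                    "Q3": ta.q3.to_dict(),
                    "trend": ta.trend.to_dict(),
                }
            if config.spline and subtype == "all":
                nl = nonlinearity_test(wscores, pheno, study.covariates)
                block["nonlinearity"] = {
                    "lrt": nl.statistic,
                    "df": nl.df,
                    "p": nl.p,
                }
        with _stage(f"ivw[{subtype}]"):
            if config.ivw:
                stats = _study_summary_stats(genotypes, pheno, records, subtype)
                if len(stats) >= 3:
                    filt = pleiotropy_filter(stats, alpha=config.pleiotropy_alpha)
                    res = ivw_estimate(
                        filt.kept,
                        snps_excluded=tuple(
                            (sid, "pleiotropy") for sid, _ in filt.excluded
                        ),
                    )
                    cap = filt.cap_reached
                else:
                    res = ivw_estimate(stats)
                    cap = False
                block["ivw"] = res.to_dict()
                block["ivw"]["pleiotropy_cap_reached"] = cap
        report["analyses"][subtype] = block

    if config.bmi_sensitivity and config.bmi_path:
        with _stage("bmi_sensitivity"):
            bmi_ids = [
                line.strip()
                for line in Path(config.bmi_path).read_text().splitlines()
                if line.strip()
            ]
            bmi_records = exclude_bmi_overlap(records, bmi_ids, ld, config.ld_r2_max)
            for r in records:
                if r not in bmi_records and r.snp_id not in exclusions:
                    exclusions[r.snp_id] = "bmi"
            ws = compute_wgrs(genotypes, bmi_records, control_ids=control_ids)
            sens: dict = {
                "n_snps_used": len(bmi_records),
                "wgrs": grs_association(ws, pheno, study.covariates, "all").to_dict(),
            }
            if config.ivw:
                stats = _study_summary_stats(genotypes, pheno, bmi_records, "all")
                filt = pleiotropy_filter(stats, alpha=config.pleiotropy_alpha)
                sens["ivw"] = ivw_estimate(filt.kept).to_dict()
            report["bmi_sensitivity"] = sens
    return report


def _tertiles_from_frame(cats: pd.DataFrame, scores: ScoreVector):
    from .grs import TertileAssignment

    lookup = dict(zip(cats["subject_id"], cats["grs_tertile"]))
    ids = [s for s in scores.subject_ids if s in lookup]
    return TertileAssignment(ids, [lookup[s] for s in ids], (float("nan"), float("nan")))


def _study_summary_stats(genotypes, pheno, records, subtype) -> SummaryStats:
    """Summary statistics with exposure betas from the instrument table."""
    mask = np.ones(len(pheno), dtype=bool)
    if subtype != "all":
        mask = ((pheno["status"] == 0) | (pheno["subtype"] == subtype)).to_numpy()
    y = pheno["status"].to_numpy(dtype=float)[mask]
    snp_ids = [r.snp_id for r in records]
    d = genotypes.subset(snp_ids=snp_ids).dosages[mask]
    # mean-impute missing dosages for the per-SNP outcome scans
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), col_mean[np.newaxis, :], d)
    poly = d.std(axis=0) > 0
    d = d[:, poly]
    used = [r for r, ok in zip(records, poly) if ok]
    by, sy = _per_snp_logistic(y, d)
    bx = np.array([r.beta_height for r in used])
    sx = np.array([r.se_height for r in used])
    return SummaryStats([r.snp_id for r in used], bx, sx, by, sy)


def run_meta(config: RunConfig, study_reports: Sequence[dict]) -> dict:
    """Fixed-effect pooling of every analysis present in all study reports."""
    if not study_reports:
        raise ValueError("no study reports to pool")
    rosters = [set(rep["analyses"].keys()) for rep in study_reports]
    common = set.intersection(*rosters)
    if any(r != common for r in rosters):
        raise ValueError(
            "mismatched analysis rosters across studies: "
            + "; ".join(",".join(sorted(r)) for r in rosters)
        )
    pooled: dict = {}
    for subtype in sorted(common):
        block: dict = {}
        keys = set.intersection(
            *(set(rep["analyses"][subtype].keys()) for rep in study_reports)
        )
        for key in sorted(keys - {"tertiles", "nonlinearity"}):
            est = [
                (rep["analyses"][subtype][key]["beta"]
                 if "beta" in rep["analyses"][subtype][key]
                 else rep["analyses"][subtype][key]["theta"],
                 rep["analyses"][subtype][key]["se"])
                for rep in study_reports
            ]
            block[key] = fixed_effect_meta(est).to_dict()
        if "tertiles" in keys:
            tblock = {}
            for term in ("Q2", "Q3", "trend"):
                est = [
                    (
                        rep["analyses"][subtype]["tertiles"][term]["beta"],
                        rep["analyses"][subtype]["tertiles"][term]["se"],
                    )
                    for rep in study_reports
                ]
                tblock[term] = fixed_effect_meta(est).to_dict()
            block["tertiles"] = tblock
        pooled[subtype] = block
    return pooled


def run_all(config: RunConfig) -> dict:
    """Run every study, pool the results, and write the report tree."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # pooled tertiles need all studies' weighted scores first
    frames = []
    for study in config.studies:
        genotypes, _ = _read_genotypes(study.dosage_path)
        records = load_instruments(config.instrument_path)
        present = [r for r in records if r.snp_id in set(genotypes.snp_ids)]
        pheno = pd.read_csv(study.phenotype_path, sep="\t", dtype={"subject_id": str})
        ctrl = pheno.loc[pheno["status"] == 0, "subject_id"].tolist()
        sv = compute_wgrs(genotypes, present, control_ids=ctrl)
        frames.append(sv.to_frame())
    pooled_scores = pd.concat(frames, ignore_index=True)
    sv_all = ScoreVector(
        pooled_scores["subject_id"].tolist(),
        pooled_scores["grs"].to_numpy(),
        "weighted",
        0,
    )
    tert = assign_tertiles(sv_all)
    tert_frame = tert.to_frame()

    study_reports = [
        run_study(config, i, tertiles_by_subject=tert_frame)
        for i in range(len(config.studies))
    ]
    pooled = run_meta(config, study_reports)
    report = {"studies": study_reports, "pooled": pooled}

    if config.enrichment and config.gmt_path and config.gene_map_path:
        with _stage("enrichment"):
            gene_map = read_gene_map(config.gene_map_path)
            records = load_instruments(config.instrument_path)
            genes = [gene_map[r.snp_id] for r in records if r.snp_id in gene_map]
            rows = overrepresentation(genes, read_gmt(config.gmt_path))
            enrichment_frame(rows).to_csv(
                out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
            )
            report["enrichment"] = [r.to_dict() for r in rows]

    inputs = {"instruments": config.instrument_path}
    for s in config.studies:
        inputs[f"{s.name}_dosages"] = s.dosage_path
        inputs[f"{s.name}_phenotypes"] = s.phenotype_path
    for key, path in (("ld", config.ld_path), ("bmi", config.bmi_path)):
        if path:
            inputs[key] = path
    report["manifest"] = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "maf_min": config.maf_min,
            "call_rate_min": config.call_rate_min,
            "hwe_p_min": config.hwe_p_min,
            "ld_r2_max": config.ld_r2_max,
            "proxy_r2_min": config.proxy_r2_min,
            "pleiotropy_alpha": config.pleiotropy_alpha,
        },
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    tert_frame.to_csv(out / "tertiles.tsv", sep="\t", index=False)
    return report
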