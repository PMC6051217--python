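"""Synthetic two-study case-control data with a known causal structure.

The real genotype data behind this kind of analysis are controlled-access,
so this module generates datasets with the statistical structure the
pipeline assumes and a fully known truth: unlinked instrument SNPs in
Hardy-Weinberg proportions, a polygenic height component explaining a
small, configurable fraction of height variance (default 2%, bracketing
the 1.4%/2.1% a realistic instrument panel achieves), a liability-logistic
disease model with a causal log-odds effect of height, optional shared
confounding and horizontal pleiotropy, case-control ascertainment with
exact quotas, histological subtype labels, and status-independent
covariates.

All generation is a pure function of :class:`SimConfig`, including its
seed; study ``s`` derives its stream from ``seed + s * 10007``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .assoc import fit_logistic
from .instruments import GenotypeMatrix, InstrumentRecord, LDTable
from .mr import SummaryStats

__all__ = [
    "SimConfig",
    "StudySim",
    "SimDataset",
    "simulate_genotypes",
    "simulate_height",
    "simulate_dataset",
    "extract_summary_stats",
    "simulate_summary_stats",
    "pairwise_r2",
    "write_dataset",
]

SUBTYPES = ("adenocarcinoma", "squamous", "other")


@dataclass
class SimConfig:
    """Full generative specification of a synthetic two-study dataset.

    ``theta`` is the causal log-odds ratio of case status per SD of height;
    ``h2_grs`` the fraction of height variance the instruments explain;
    ``confounder_effect`` the loadings of a shared standard-normal
    confounder on height and on the disease liability; ``pleiotropy`` gives
    the first ``n`` SNPs a direct per-allele log-odds effect on the outcome.
    """

    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_grs: float = 0.02
    theta: float = math.log(1.19)
    prevalence: float = 0.10
    n_cases: int = 1500
    n_controls: int = 1500
    n_studies: int = 2
    subtype_probs: tuple[float, float, float] = (0.67, 0.21, 0.12)
    confounder_effect: tuple[float, float] = (0.0, 0.0)
    pleiotropy: tuple[int, float] = (0, 0.0)
    covariate_u_effect: float = 0.0
    n_pcs: int = 3
    ld_block_size: int = 1
    ld_block_r: float = 0.0
    pool_factor: float = 1.4
    gwas_n: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        if not (0.0 <= self.h2_grs < 1.0):
            raise ValueError("h2_grs must lie in [0, 1)")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if abs(sum(self.subtype_probs) - 1.0) > 1e-9 or any(
            p < 0 for p in self.subtype_probs
        ):
            raise ValueError("subtype_probs must be non-negative and sum to 1")
        if self.pleiotropy[0] > self.n_snps:
            raise ValueError("more pleiotropic SNPs than SNPs")
        gh = self.confounder_effect[0]
        if self.h2_grs + gh**2 >= 1.0:
            raise ValueError(
                "h2_grs plus squared confounder height effect must stay below 1 "
                "so height can be scaled to unit variance"
            )


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _draw_dosages(
    n: int,
    mafs: np.ndarray,
    rng: np.random.Generator,
    ld_block_size: int = 1,
    ld_block_r: float = 0.0,
) -> np.ndarray:
    """Dosages in {0,1,2}; optional exchangeable LD within blocks of SNPs.

    With no LD each SNP is Binomial(2, maf) — Hardy-Weinberg proportions in
    linkage equilibrium.  The block mode correlates alleles within a block
    through a Gaussian copula (haplotype-level latent normals with
    exchangeable correlation ``ld_block_r``), giving positive pairwise r2
    that exercises LD pruning.
    """
    m = len(mafs)
    if ld_block_size <= 1 or ld_block_r == 0.0:
        return rng.binomial(2, mafs, size=(n, m)).astype(float)
    thr = norm.ppf(mafs)
    d = np.zeros((n, m))
    r = float(ld_block_r)
    for start in range(0, m, ld_block_size):
        stop = min(start + ld_block_size, m)
        width = stop - start
        for _hap in range(2):
            shared = rng.standard_normal(n)[:, None]
            idio = rng.standard_normal((n, width))
            z = math.sqrt(r) * shared + math.sqrt(1.0 - r) * idio
            d[:, start:stop] += z < thr[start:stop]
    return d


def simulate_genotypes(
    n: int,
    mafs: Sequence[float],
    seed,
    snp_ids: Sequence[str] | None = None,
    subject_prefix: str = "S",
    ld_block_size: int = 1,
    ld_block_r: float = 0.0,
) -> GenotypeMatrix:
    """Genotype matrix of ``n`` subjects at the given effect-allele frequencies."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs >= 1)):
        raise ValueError("mafs must lie strictly in (0, 1)")
    rng = _as_rng(seed)
    d = _draw_dosages(n, mafs, rng, ld_block_size, ld_block_r)
    if snp_ids is None:
        snp_ids = [f"rs{j + 1:04d}" for j in range(len(mafs))]
    subjects = [f"{subject_prefix}{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(subjects, list(snp_ids), d)


def scale_weights(
    betas_raw: np.ndarray, mafs: np.ndarray, h2_grs: float
) -> np.ndarray:
    """Rescale raw per-allele effects so the score explains ``h2_grs`` of height.

    Under linkage equilibrium Var(sum_j w_j x_j) = sum_j w_j^2 2 p_j (1 - p_j).
    """
    betas_raw = np.asarray(betas_raw, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    var_raw = float(np.sum(betas_raw**2 * 2.0 * mafs * (1.0 - mafs)))
    if var_raw == 0:
        if h2_grs > 0:
            raise ValueError("cannot scale all-zero betas to positive h2")
        return betas_raw.copy()
    return betas_raw * math.sqrt(h2_grs / var_raw)


def simulate_height(
    genotypes: GenotypeMatrix,
    betas_raw: Sequence[float],
    h2_grs: float,
    seed,
    mafs: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Height z-scores from a genetic component plus independent noise.

    Raw betas are rescaled so the centered genetic score has variance
    ``h2_grs``; residual variance is ``1 - h2_grs``, giving unit marginal
    height variance.  Returns ``(height, scaled_betas)``.
    """
    rng = _as_rng(seed)
    p = (
        np.asarray(mafs, dtype=float)
        if mafs is not None
        else genotypes.sample_eaf
    )
    w = scale_weights(np.asarray(betas_raw, dtype=float), p, h2_grs)
    g = (genotypes.dosages - 2.0 * p) @ w
    e = rng.standard_normal(genotypes.n_subjects) * math.sqrt(1.0 - h2_grs)
    return g + e, w


def _calibrate_intercept(liability: np.ndarray, prevalence: float) -> float:
    """Bisection for the intercept giving the target population prevalence."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = float(np.mean(expit(mid + liability))) - prevalence
        if abs(f) < 1e-6:
            return mid
        if f > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass
class StudySim:
    """One simulated case-control study."""

    study_index: int
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    height: np.ndarray  # observed height z-scores of the sampled subjects
    intercept: float

    @property
    def control_ids(self) -> list[str]:
        mask = self.phenotypes["status"] == 0
        return self.phenotypes.loc[mask, "subject_id"].tolist()


@dataclass
class SimDataset:
    config: SimConfig
    records: list[InstrumentRecord]
    mafs: np.ndarray
    weights: np.ndarray
    snp_ids: list[str]
    pleio_snp_ids: list[str]
    studies: list[StudySim]

    @property
    def truth(self) -> dict:
        return {
            "theta": self.config.theta,
            "h2_grs": self.config.h2_grs,
            "prevalence": self.config.prevalence,
            "seed": self.config.seed,
            "weights": dict(zip(self.snp_ids, map(float, self.weights))),
            "mafs": dict(zip(self.snp_ids, map(float, self.mafs))),
            "pleiotropic_snps": list(self.pleio_snp_ids),
            "confounder_effect": list(self.config.confounder_effect),
            "study_intercepts": [s.intercept for s in self.studies],
        }


def _draw_instruments(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[InstrumentRecord], np.ndarray, np.ndarray, list[str]]:
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, config.n_snps)
    raw = rng.standard_normal(config.n_snps)
    w = scale_weights(raw, mafs, config.h2_grs)
    snp_ids = [f"rs{j + 1:04d}" for j in range(config.n_snps)]
    records = []
    for j, sid in enumerate(snp_ids):
        se = 1.0 / math.sqrt(config.gwas_n * 2.0 * mafs[j] * (1.0 - mafs[j]))
        z = abs(w[j]) / se
        pval = max(float(2.0 * norm.sf(z)), 5e-324)
        records.append(
            InstrumentRecord(
                snp_id=sid,
                chrom=str(1 + j % 22),
                pos=1_000_000 + 10_000 * j,
                effect_allele="A",
                other_allele="G",
                eaf=float(mafs[j]),
                beta_height=float(w[j]),
                se_height=se,
                pval_height=min(1.0, pval),
                source="east-asian-gws",
            )
        )
    return records, mafs, w, snp_ids


def _simulate_study(
    config: SimConfig,
    study_index: int,
    mafs: np.ndarray,
    weights: np.ndarray,
    snp_ids: list[str],
    pleio_idx: np.ndarray,
) -> StudySim:
    rng = np.random.default_rng(config.seed + study_index * 10007)
    prev = config.prevalence
    pool_n = math.ceil(
        config.pool_factor
        * max(config.n_cases / prev, config.n_controls / (1.0 - prev))
    )
    d = _draw_dosages(pool_n, mafs, rng, config.ld_block_size, config.ld_block_r)
    g = (d - 2.0 * mafs) @ weights
    u = rng.standard_normal(pool_n)
    gh, gy = config.confounder_effect
    evar = 1.0 - config.h2_grs - gh**2
    height = g + gh * u + math.sqrt(evar) * rng.standard_normal(pool_n)
    liability = config.theta * height + gy * u
    n_pleio, delta = config.pleiotropy
    if n_pleio:
        liability = liability + delta * (
            d[:, pleio_idx] - 2.0 * mafs[pleio_idx]
        ).sum(axis=1)
    alpha = _calibrate_intercept(liability, prev)
    status_pool = rng.random(pool_n) < expit(alpha + liability)
    case_pool = np.flatnonzero(status_pool)
    ctrl_pool = np.flatnonzero(~status_pool)
    if len(case_pool) < config.n_cases or len(ctrl_pool) < config.n_controls:
        raise RuntimeError(
            f"population pool exhausted (study {study_index}): "
            f"{len(case_pool)} cases / {len(ctrl_pool)} controls available; "
            "increase pool_factor"
        )
    cases = rng.choice(case_pool, size=config.n_cases, replace=False)
    ctrls = rng.choice(ctrl_pool, size=config.n_controls, replace=False)
    sel = np.concatenate([cases, ctrls])
    n_sel = len(sel)

    subtype = np.array(["control"] * n_sel, dtype=object)
    subtype[: config.n_cases] = rng.choice(
        SUBTYPES, size=config.n_cases, p=config.subtype_probs
    )
    age = rng.normal(60.0, 8.0, n_sel) + config.covariate_u_effect * u[sel]
    sex = rng.integers(0, 2, n_sel).astype(float)
    ever_smoker = rng.random(n_sel) < 0.5
    pack_years = np.where(ever_smoker, rng.gamma(2.0, 10.0, n_sel), 0.0)
    pcs = rng.standard_normal((n_sel, config.n_pcs))

    subject_ids = [f"S{study_index + 1}_{i + 1:06d}" for i in range(n_sel)]
    pheno = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "status": np.r_[
                np.ones(config.n_cases, dtype=int),
                np.zeros(config.n_controls, dtype=int),
            ],
            "subtype": subtype,
            "age": age,
            "sex": sex,
            "pack_years": pack_years,
        }
    )
    for k in range(config.n_pcs):
        pheno[f"pc{k + 1}"] = pcs[:, k]
    genotypes = GenotypeMatrix(subject_ids, snp_ids, d[sel])
    return StudySim(study_index, genotypes, pheno, height[sel], alpha)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate the instrument panel and every study of the dataset."""
    rng = np.random.default_rng(config.seed)
    records, mafs, weights, snp_ids = _draw_instruments(config, rng)
    n_pleio = config.pleiotropy[0]
    pleio_idx = np.arange(n_pleio)
    studies = [
        _simulate_study(config, s, mafs, weights, snp_ids, pleio_idx)
        for s in range(config.n_studies)
    ]
    return SimDataset(
        config=config,
        records=records,
        mafs=mafs,
        weights=weights,
        snp_ids=snp_ids,
        pleio_snp_ids=[snp_ids[j] for j in pleio_idx],
        studies=studies,
    )


def _per_snp_logistic(y: np.ndarray, dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-parameter (intercept + dosage) logistic fits per SNP."""
    y = np.asarray(y, dtype=float)
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    b0 = np.full(m, math.log(y.mean() / (1.0 - y.mean())))
    b1 = np.zeros(m)
    for _ in range(60):
        eta = b0[np.newaxis, :] + d * b1[np.newaxis, :]
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        s00 = w.sum(axis=0)
        s01 = (w * d).sum(axis=0)
        s11 = (w * d * d).sum(axis=0)
        r = y[:, np.newaxis] - mu
        g0 = r.sum(axis=0)
        g1 = (r * d).sum(axis=0)
        det = s00 * s11 - s01**2
        d0 = (s11 * g0 - s01 * g1) / det
        d1 = (s00 * g1 - s01 * g0) / det
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(), np.abs(d1).max()) < 1e-10:
            break
    eta = b0[np.newaxis, :] + d * b1[np.newaxis, :]
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    s00 = w.sum(axis=0)
    s01 = (w * d).sum(axis=0)
    s11 = (w * d * d).sum(axis=0)
    det = s00 * s11 - s01**2
    se1 = np.sqrt(s00 / det)
    return b1, se1


def extract_summary_stats(
    dataset: SimDataset,
    beta_x_source: str = "instruments",
    covariates: Sequence[str] = (),
    subtype_filter: str = "all",
) -> list[SummaryStats]:
    """Per-study per-SNP summary statistics for summary-data MR.

    Outcome effects beta_y come from per-SNP logistic regression of status
    on dosage (optionally covariate-adjusted).  Exposure effects beta_x come
    either from the instrument records — the external-GWAS weights, the
    design this analysis assumes — or, with ``beta_x_source="controls"``,
    from in-sample linear regression of height on dosage among controls
    (useful for diagnostics; note that at modest control counts those
    in-sample effects are weak-instrument noisy).  Monomorphic SNPs in the
    analysis sample are dropped with a warning.
    """
    if beta_x_source not in ("instruments", "controls"):
        raise ValueError("beta_x_source must be 'instruments' or 'controls'")
    out: list[SummaryStats] = []
    rec_by_id = {r.snp_id: r for r in dataset.records}
    for study in dataset.studies:
        pheno = study.phenotypes
        mask = np.ones(len(pheno), dtype=bool)
        if subtype_filter != "all":
            mask = (pheno["status"] == 0) | (pheno["subtype"] == subtype_filter)
            mask = mask.to_numpy()
        y = pheno["status"].to_numpy(dtype=float)[mask]
        d = study.genotypes.dosages[mask]
        snp_ids = list(study.genotypes.snp_ids)

        poly = d.std(axis=0) > 0
        if not poly.all():
            dropped = [s for s, ok in zip(snp_ids, poly) if not ok]
            warnings.warn(
                f"study {study.study_index}: dropping monomorphic SNP(s) "
                + ", ".join(dropped)
            )
        d = d[:, poly]
        snp_ids = [s for s, ok in zip(snp_ids, poly) if ok]

        if covariates:
            b1 = np.empty(d.shape[1])
            se1 = np.empty(d.shape[1])
            covs = pheno.loc[mask, list(covariates)].to_numpy(dtype=float)
            base = np.column_stack([np.ones(len(y)), covs])
            for j in range(d.shape[1]):
                fit = fit_logistic(y, np.column_stack([base, d[:, j]]))
                b1[j], se1[j] = fit.beta[-1], fit.se[-1]
        else:
            b1, se1 = _per_snp_logistic(y, d)

        if beta_x_source == "instruments":
            bx = np.array([rec_by_id[s].beta_height for s in snp_ids])
            sx = np.array([rec_by_id[s].se_height for s in snp_ids])
        else:
            ctrl = (pheno["status"].to_numpy() == 0) & mask
            h = study.height[ctrl]
            dc = study.genotypes.dosages[ctrl][:, poly]
            xc = dc - dc.mean(axis=0)
            hc = h - h.mean()
            sxx = (xc**2).sum(axis=0)
            bx = xc.T @ hc / sxx
            resid = hc[:, np.newaxis] - xc * bx[np.newaxis, :]
            sigma2 = (resid**2).sum(axis=0) / (len(h) - 2)
            sx = np.sqrt(sigma2 / sxx)
        out.append(SummaryStats(snp_ids, bx, sx, b1, se1))
    return out


def simulate_summary_stats(
    n_snps: int,
    theta: float,
    seed,
    maf_range: tuple[float, float] = (0.05, 0.5),
    h2_grs: float = 0.02,
    se_x: float = 0.004,
    se_y: float = 0.01,
    n_outliers: int = 0,
    outlier_delta: float = 0.0,
) -> tuple[SummaryStats, list[str]]:
    """Draw per-SNP summary statistics directly from their sampling model.

    Emulates consortium-scale GWAS summary data: true exposure effects
    scaled to ``h2_grs``, observed effects with the stated standard errors,
    and outcome effects ``theta * beta_x`` plus, for the first
    ``n_outliers`` SNPs, a direct (pleiotropic) outcome effect of
    ``outlier_delta`` per allele with random sign.  Returns the stats and
    the planted outlier ids.
    """
    rng = _as_rng(seed)
    mafs = rng.uniform(*maf_range, n_snps)
    bx_true = scale_weights(rng.standard_normal(n_snps), mafs, h2_grs)
    delta = np.zeros(n_snps)
    if n_outliers:
        signs = rng.choice([-1.0, 1.0], size=n_outliers)
        delta[:n_outliers] = signs * outlier_delta
    bx = bx_true + rng.standard_normal(n_snps) * se_x
    by = theta * bx_true + delta + rng.standard_normal(n_snps) * se_y
    snp_ids = [f"rs{j + 1:04d}" for j in range(n_snps)]
    stats = SummaryStats(
        snp_ids,
        bx,
        np.full(n_snps, se_x),
        by,
        np.full(n_snps, se_y),
    )
    return stats, snp_ids[:n_outliers]


def pairwise_r2(genotypes: GenotypeMatrix, min_r2: float = 0.01) -> LDTable:
    """Empirical pairwise r2 between dosage columns (pairs below ``min_r2`` omitted)."""
    d = genotypes.dosages
    sd = d.std(axis=0)
    ok = sd > 0
    corr = np.corrcoef(d[:, ok], rowvar=False)
    ids = [s for s, k in zip(genotypes.snp_ids, ok) if k]
    table = LDTable()
    m = len(ids)
    for i in range(m):
        for j in range(i + 1, m):
            r2 = float(corr[i, j] ** 2)
            if r2 >= min_r2:
                table.add(ids[i], ids[j], r2)
    return table


def write_dataset(dataset: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact text formats the pipeline reads.

    Produces ``instruments.tsv``, per-study ``study<s>_dosages.tsv`` /
    ``study<s>_phenotypes.tsv`` / ``study<s>_summary.tsv``, ``ld.tsv`` and
    ``truth.json``.  Output is byte-identical across runs for the same
    config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    inst = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in dataset.records],
            "chrom": [r.chrom for r in dataset.records],
            "pos": [r.pos for r in dataset.records],
            "effect_allele": [r.effect_allele for r in dataset.records],
            "other_allele": [r.other_allele for r in dataset.records],
            "eaf": [r.eaf for r in dataset.records],
            "beta": [r.beta_height for r in dataset.records],
            "se": [r.se_height for r in dataset.records],
            "pval": [r.pval_height for r in dataset.records],
            "source": [r.source for r in dataset.records],
        }
    )
    p = outdir / "instruments.tsv"
    inst.to_csv(p, sep="\t", index=False, float_format="%.10g")
    paths["instruments"] = p

    summaries = extract_summary_stats(dataset)
    for study, stats in zip(dataset.studies, summaries):
        s = study.study_index + 1
        dos = pd.DataFrame(
            study.genotypes.dosages,
            columns=study.genotypes.snp_ids,
        )
        dos.insert(0, "subject_id", study.genotypes.subject_ids)
        p = outdir / f"study{s}_dosages.tsv"
        dos.to_csv(p, sep="\t", index=False, float_format="%.10g")
        paths[f"study{s}_dosages"] = p

        p = outdir / f"study{s}_phenotypes.tsv"
        study.phenotypes.to_csv(p, sep="\t", index=False, float_format="%.10g")
        paths[f"study{s}_phenotypes"] = p

        p = outdir / f"study{s}_summary.tsv"
        stats.to_tsv(p)
        paths[f"study{s}_summary"] = p

    ld = (
        pairwise_r2(dataset.studies[0].genotypes)
        if dataset.config.ld_block_size > 1 and dataset.config.ld_block_r > 0
        else LDTable()
    )
    p = outdir / "ld.tsv"
    ld.to_tsv(p)
    paths["ld"] = p

    p = outdir / "truth.json"
    with open(p, "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
    paths["truth"] = p
    return paths
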