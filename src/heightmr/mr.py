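"""Summary-data Mendelian randomization and cross-study pooling.

Given per-SNP exposure effects (height per effect allele, z-score units)
and outcome effects (log-odds of lung cancer per effect allele), this
module forms Wald ratios, combines them with fixed-effect inverse-variance
weighting, screens instruments for horizontal pleiotropy with Cochran's Q,
and pools study-level estimates by fixed-effect meta-analysis.

The IVW estimator uses first-order weights (no exposure-uncertainty term,
the no-measurement-error convention) and no residual over-dispersion
scaling, matching the estimator generation the source analyses of this
design used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .assoc import Z95

__all__ = [
    "SummaryStats",
    "MRResult",
    "MetaResult",
    "PleiotropyFilterResult",
    "wald_ratio",
    "ivw_estimate",
    "cochran_q",
    "pleiotropy_filter",
    "fixed_effect_meta",
]


@dataclass
class SummaryStats:
    """Per-SNP exposure and outcome association estimates."""

    snp_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.snp_ids),):
                raise ValueError(f"{name} length must match snp_ids")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, arr)
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[int] | np.ndarray) -> "SummaryStats":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SummaryStats(
            [self.snp_ids[i] for i in keep],
            self.beta_x[keep],
            self.se_x[keep],
            self.beta_y[keep],
            self.se_y[keep],
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SummaryStats":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
        for col in ("snp_id", "beta_x", "se_x", "beta_y", "se_y"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls(
            df["snp_id"].tolist(),
            df["beta_x"].to_numpy(float),
            df["se_x"].to_numpy(float),
            df["beta_y"].to_numpy(float),
            df["se_y"].to_numpy(float),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta_x": self.beta_x,
                "se_x": self.se_x,
                "beta_y": self.beta_y,
                "se_y": self.se_y,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def wald_ratio(beta_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Single-SNP causal estimate beta_y / beta_x with first-order SE se_y / |beta_x|."""
    if beta_x == 0:
        raise ValueError("beta_x must be non-zero for a Wald ratio")
    if se_y <= 0:
        raise ValueError("se_y must be positive")
    return beta_y / beta_x, se_y / abs(beta_x)


@dataclass(frozen=True)
class MRResult:
    """Causal log-odds estimate per SD of exposure, with heterogeneity."""

    theta: float
    se: float
    p: float
    q: float
    q_df: int
    q_p: float
    snps_used: tuple[str, ...]
    snps_excluded: tuple[tuple[str, str], ...] = ()

    @property
    def or_(self) -> float:
        return float(np.exp(self.theta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.theta - Z95 * self.se)),
            float(np.exp(self.theta + Z95 * self.se)),
        )

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "theta": self.theta,
            "se": self.se,
            "or": self.or_,
            "ci_low": lo,
            "ci_high": hi,
            "p": self.p,
            "q": self.q,
            "q_df": self.q_df,
            "q_p": self.q_p,
            "n_snps": len(self.snps_used),
            "snps_excluded": [list(t) for t in self.snps_excluded],
        }


def ivw_estimate(
    stats: SummaryStats,
    snps_excluded: Sequence[tuple[str, str]] = (),
) -> MRResult:
    """Fixed-effect inverse-variance-weighted causal estimate.

    theta = sum_j bx_j by_j / se_yj^2  /  sum_j bx_j^2 / se_yj^2, the
    precision-weighted combination of per-SNP Wald ratios, equivalently
    weighted least squares of beta_y on beta_x through the origin with
    weights 1/se_y^2.  No residual over-dispersion inflation is applied.
    """
    if len(stats) == 0:
        raise ValueError("need at least one SNP for IVW")
    w = 1.0 / stats.se_y**2
    denom = float(np.sum(stats.beta_x**2 * w))
    if denom == 0:
        raise ValueError("all beta_x are zero")
    theta = float(np.sum(stats.beta_x * stats.beta_y * w) / denom)
    se = denom ** -0.5
    p = float(min(1.0, 2.0 * norm.sf(abs(theta / se))))
    if len(stats) >= 2:
        q, q_df, q_p = cochran_q(stats, theta)
    else:
        q, q_df, q_p = 0.0, 0, 1.0
    return MRResult(theta, se, p, q, q_df, q_p, tuple(stats.snp_ids), tuple(snps_excluded))


def _q_contributions(stats: SummaryStats, theta: float) -> np.ndarray:
    if np.any(stats.beta_x == 0):
        raise ValueError("beta_x must be non-zero for Cochran's Q")
    ratio = stats.beta_y / stats.beta_x
    return (stats.beta_x**2 / stats.se_y**2) * (ratio - theta) ** 2


def cochran_q(stats: SummaryStats, theta: float) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP Wald ratios around ``theta``.

    Excess Q relative to chi-square(J - 1) flags horizontal pleiotropy:
    instruments whose outcome effect is not proportional to their exposure
    effect.
    """
    if len(stats) < 2:
        raise ValueError("need at least 2 SNPs for Cochran's Q")
    q = float(np.sum(_q_contributions(stats, theta)))
    df = len(stats) - 1
    return q, df, float(chi2.sf(q, df))


@dataclass
class PleiotropyFilterResult:
    kept: SummaryStats
    excluded: list[tuple[str, float]]  # (snp_id, Q contribution at removal)
    cap_reached: bool
    final_q_p: float


def pleiotropy_filter(
    stats: SummaryStats,
    alpha: float = 0.05,
    max_remove: int | None = None,
) -> PleiotropyFilterResult:
    """Iterative greedy exclusion of pleiotropic instruments.

    While the Q test rejects at ``alpha``, the SNP with the largest Q
    contribution is removed (ties toward the smaller snp_id) and the IVW
    estimate recomputed.  Removal stops when the Q p-value reaches ``alpha``
    or when ``max_remove`` SNPs (default: 20% of the input, at least 1) have
    been dropped; hitting the cap with p still below ``alpha`` is flagged,
    not fatal.
    """
    if len(stats) < 3:
        raise ValueError("need at least 3 SNPs to filter for pleiotropy")
    if max_remove is None:
        max_remove = max(1, int(math.floor(0.2 * len(stats))))
    current = stats
    excluded: list[tuple[str, float]] = []
    cap_reached = False
    while True:
        res = ivw_estimate(current)
        if res.q_p >= alpha or len(current) < 3:
            break
        if len(excluded) >= max_remove:
            cap_reached = True
            break
        contrib = _q_contributions(current, res.theta)
        top = np.max(contrib)
        ties = [i for i in range(len(current)) if contrib[i] == top]
        drop = min(ties, key=lambda i: current.snp_ids[i])
        excluded.append((current.snp_ids[drop], float(contrib[drop])))
        keep = [i for i in range(len(current)) if i != drop]
        current = current.subset(keep)
    final = ivw_estimate(current)
    return PleiotropyFilterResult(current, excluded, cap_reached, final.q_p)


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effect pooled estimate across studies with heterogeneity."""

    pooled_beta: float
    pooled_se: float
    p: float
    q_between: float
    i2: float
    het_p: float
    n_studies: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.pooled_beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.pooled_beta - Z95 * self.pooled_se)),
            float(np.exp(self.pooled_beta + Z95 * self.pooled_se)),
        )

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "beta": self.pooled_beta,
            "se": self.pooled_se,
            "or": self.or_,
            "ci_low": lo,
            "ci_high": hi,
            "p": self.p,
            "q_between": self.q_between,
            "i2": self.i2,
            "het_p": self.het_p,
            "n_studies": self.n_studies,
        }


def fixed_effect_meta(study_estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """Inverse-variance fixed-effect pooling of (beta, se) study estimates.

    Between-study heterogeneity is summarized by Cochran's Q across studies
    and I^2 = max(0, (Q - (S - 1)) / Q) x 100.
    """
    if len(study_estimates) == 0:
        raise ValueError("need at least one study estimate")
    betas = np.array([b for b, _ in study_estimates], dtype=float)
    ses = np.array([s for _, s in study_estimates], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("study standard errors must be positive")
    w = 1.0 / ses**2
    pooled = float(np.sum(betas * w) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    p = float(min(1.0, 2.0 * norm.sf(abs(pooled / pooled_se))))
    s = len(betas)
    if s > 1:
        q = float(np.sum(w * (betas - pooled) ** 2))
        het_p = float(chi2.sf(q, s - 1))
        i2 = max(0.0, (q - (s - 1)) / q) * 100.0 if q > 0 else 0.0
    else:
        q, het_p, i2 = 0.0, 1.0, 0.0
    return MetaResult(pooled, pooled_se, p, q, i2, het_p, s)
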