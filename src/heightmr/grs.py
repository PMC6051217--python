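"""Genetic risk scores for height and their tertile categorization.

The weighted score GRS_i = sum_j w_j x_ij combines effect-allele dosages
x_ij with per-allele height effects w_j on the z-score scale, so one unit
of the weighted score corresponds to one standard deviation of genetically
predicted height.  The unweighted score is the plain tall-allele count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .instruments import GenotypeMatrix, InstrumentRecord

__all__ = ["ScoreVector", "TertileAssignment", "compute_wgrs", "compute_ugrs", "assign_tertiles"]

TERTILE_LABELS = ("Q1", "Q2", "Q3")


@dataclass
class ScoreVector:
    """Per-subject genetic risk score."""

    subject_ids: list[str]
    score: np.ndarray
    kind: str  # "weighted" | "unweighted"
    n_snps_used: int

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.subject_ids),):
            raise ValueError("score length must match subject list")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids, "grs": self.score})


@dataclass
class TertileAssignment:
    subject_ids: list[str]
    category: list[str]  # Q1 | Q2 | Q3
    cutpoints: tuple[float, float]

    def subset(self, subject_ids: Sequence[str]) -> "TertileAssignment":
        lookup = dict(zip(self.subject_ids, self.category))
        cats = [lookup[str(s)] for s in subject_ids]
        return TertileAssignment([str(s) for s in subject_ids], cats, self.cutpoints)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "grs_tertile": self.category}
        )


def _score(
    genotypes: GenotypeMatrix,
    records: Sequence[InstrumentRecord],
    weights: np.ndarray,
    kind: str,
    control_ids: Sequence[str] | None,
) -> ScoreVector:
    snp_ids = [r.snp_id for r in records]
    try:
        cols = genotypes.snp_index(snp_ids)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    d = genotypes.dosages[:, cols]
    if np.isnan(d).any():
        # mean imputation at 2 x control-sample EAF keeps the score mean intact
        if control_ids is not None:
            ref = genotypes.subset(subject_ids=list(control_ids), snp_ids=snp_ids)
            eaf = ref.sample_eaf
        else:
            with np.errstate(invalid="ignore"):
                eaf = np.nanmean(d, axis=0) / 2.0
        fill = 2.0 * eaf
        d = np.where(np.isnan(d), fill[np.newaxis, :], d)
    score = d @ weights
    return ScoreVector(list(genotypes.subject_ids), score, kind, len(records))


def compute_wgrs(
    genotypes: GenotypeMatrix,
    records: Sequence[InstrumentRecord],
    control_ids: Sequence[str] | None = None,
) -> ScoreVector:
    """Weighted genetic risk score GRS_i = sum_j w_j x_ij.

    Missing dosages are imputed as twice the effect-allele frequency in
    ``control_ids`` (all subjects when not given).  Dosages must already be
    oriented so x counts the instrument's effect (tall) allele.  The score is
    deliberately not re-standardized: its unit is one SD of height.
    """
    w = np.array([r.beta_height for r in records], dtype=float)
    return _score(genotypes, records, w, "weighted", control_ids)


def compute_ugrs(
    genotypes: GenotypeMatrix,
    records: Sequence[InstrumentRecord],
    control_ids: Sequence[str] | None = None,
) -> ScoreVector:
    """Unweighted score: the tall-allele count sum_j x_ij."""
    w = np.ones(len(records), dtype=float)
    return _score(genotypes, records, w, "unweighted", control_ids)


def assign_tertiles(scores: ScoreVector) -> TertileAssignment:
    """Split subjects into thirds of the score distribution.

    Subjects are ranked by score with ties broken by stable input order;
    boundaries fall at ranks ceil(n/3) and ceil(2n/3), so group sizes for
    n = 3k + r are front-loaded (e.g. n = 10 gives 4/3/3).  Cutpoints are the
    scores at the boundary ranks.
    """
    n = len(scores.subject_ids)
    if n < 3:
        raise ValueError(f"need at least 3 subjects to form tertiles, got {n}")
    order = np.argsort(scores.score, kind="stable")
    q1 = math.ceil(n / 3)
    q2 = math.ceil(2 * n / 3)
    category = [""] * n
    for rank, idx in enumerate(order, start=1):
        if rank <= q1:
            category[idx] = "Q1"
        elif rank <= q2:
            category[idx] = "Q2"
        else:
            category[idx] = "Q3"
    sorted_scores = scores.score[order]
    cutpoints = (float(sorted_scores[q1 - 1]), float(sorted_scores[q2 - 1]))
    return TertileAssignment(list(scores.subject_ids), category, cutpoints)
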