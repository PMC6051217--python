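"""Instrument curation for height Mendelian-randomization analyses.

Everything that happens to a SNP before it is allowed to act as an
instrumental variable lives here: loading the height-instrument table,
orienting study dosages so they count the tall allele, Hardy-Weinberg
exact testing in controls, per-SNP quality control (call rate, minor
allele frequency, HWE), proxy substitution for variants missing from a
study, greedy LD pruning to an approximately independent set, and
removal of instruments overlapping body-mass-index loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "InstrumentRecord",
    "GenotypeMatrix",
    "LDTable",
    "HarmonizeAction",
    "Harmonization",
    "QCResult",
    "load_instruments",
    "read_dosage_tsv",
    "read_dosage_vcf",
    "harmonize_alleles",
    "flip_dosage",
    "hwe_test",
    "qc_filter",
    "prune_ld",
    "substitute_proxies",
    "exclude_bmi_overlap",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Required header columns of an instrument TSV, in any order.
INSTRUMENT_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "source",
)


@dataclass(frozen=True)
class InstrumentRecord:
    """One height-associated SNP usable as an instrumental variable.

    ``beta_height`` is the per-effect-allele association with height on the
    z-score scale (the GRS weight w_j); ``eaf`` is the effect-allele
    frequency in the source GWAS population.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta_height: float
    se_height: float
    pval_height: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (0.0 < float(self.eaf) < 1.0):
            raise ValueError(f"{self.snp_id}: eaf must lie in (0, 1), got {self.eaf}")
        if not float(self.se_height) > 0.0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se_height}")
        if not (0.0 < float(self.pval_height) <= 1.0):
            raise ValueError(
                f"{self.snp_id}: p-value must lie in (0, 1], got {self.pval_height}"
            )
        if not np.isfinite(self.beta_height):
            raise ValueError(f"{self.snp_id}: beta must be finite")


def load_instruments(path: str | Path) -> list[InstrumentRecord]:
    """Read an instrument table (TSV) and validate every row.

    The file must carry the columns in :data:`INSTRUMENT_COLUMNS`.  Invalid
    rows raise :class:`ValueError` naming the offending file line (header is
    line 1).  Duplicated ``snp_id`` values are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str, "source": str})
    missing = [c for c in INSTRUMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[InstrumentRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header occupies line 1
        try:
            rec = InstrumentRecord(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                eaf=float(row.eaf),
                beta_height=float(row.beta),
                se_height=float(row.se),
                pval_height=float(row.pval),
                source="" if pd.isna(row.source) else str(row.source),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
        if rec.snp_id in seen:
            raise ValueError(f"{path}, line {line}: duplicate snp_id {rec.snp_id!r}")
        seen.add(rec.snp_id)
        records.append(rec)
    return records


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs effect-allele dosage matrix.

    Dosages are real values in [0, 2]; missing genotypes are ``NaN``.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        d = np.asarray(self.dosages, dtype=float)
        if d.ndim != 2:
            raise ValueError("dosages must be a 2-D array (subjects x SNPs)")
        if d.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {d.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        finite = d[~np.isnan(d)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            raise ValueError("non-missing dosages must lie in [0, 2]")
        self.dosages = d

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing genotypes."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    @property
    def sample_eaf(self) -> np.ndarray:
        """Per-SNP effect-allele frequency estimated from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subject_index(self, subject_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            return np.array([lookup[str(s)] for s in subject_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown subject id {exc.args[0]!r}") from exc

    def snp_index(self, snp_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: j for j, s in enumerate(self.snp_ids)}
        missing = [str(s) for s in snp_ids if str(s) not in lookup]
        if missing:
            raise KeyError(f"SNP(s) absent from genotype matrix: {', '.join(missing)}")
        return np.array([lookup[str(s)] for s in snp_ids], dtype=int)

    def subset(
        self,
        subject_ids: Sequence[str] | None = None,
        snp_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = (
            slice(None) if subject_ids is None else self.subject_index(subject_ids)
        )
        cols = slice(None) if snp_ids is None else self.snp_index(snp_ids)
        subs = self.subject_ids if subject_ids is None else [str(s) for s in subject_ids]
        snps = self.snp_ids if snp_ids is None else [str(s) for s in snp_ids]
        return GenotypeMatrix(subs, snps, self.dosages[rows][:, cols].copy())

    def genotype_counts(
        self, snp_id: str, subject_ids: Sequence[str] | None = None
    ) -> tuple[int, int, int]:
        """Hard genotype counts (hom-effect, het, hom-other) for one SNP.

        Imputed dosages are rounded to the nearest integer genotype;
        missing genotypes are ignored.
        """
        j = self.snp_index([snp_id])[0]
        col = self.dosages[:, j]
        if subject_ids is not None:
            col = col[self.subject_index(subject_ids)]
        col = col[~np.isnan(col)]
        g = np.clip(np.rint(col), 0, 2).astype(int)
        return int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())

    def flipped(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        """Return a copy with the listed SNP columns recoded as ``2 - x``."""
        d = self.dosages.copy()
        cols = self.snp_index(snp_ids)
        d[:, cols] = flip_dosage(d[:, cols])
        return GenotypeMatrix(list(self.subject_ids), list(self.snp_ids), d)


def flip_dosage(dosage: np.ndarray) -> np.ndarray:
    """Recode a dosage to count the opposite allele (``2 - x``; NaN preserved)."""
    return 2.0 - np.asarray(dosage, dtype=float)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a plain dosage matrix: first column ``subject_id``, one column per SNP."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: first column must be 'subject_id'")
    subjects = df["subject_id"].tolist()
    snps = [c for c in df.columns if c != "subject_id"]
    return GenotypeMatrix(subjects, snps, df[snps].to_numpy(dtype=float))


def read_dosage_vcf(path: str | Path, return_alleles: bool = False):
    """Read per-sample dosages from a VCF.

    Dosage of the ALT allele comes from the per-sample ``DS`` FORMAT field
    when present, otherwise from hard genotypes.  Positions are 1-based;
    variants without an ID are keyed ``chrom:pos``.  With
    ``return_alleles=True`` also returns a DataFrame (snp_id, effect_allele,
    other_allele, eaf) where effect_allele is ALT — suitable input for
    :func:`harmonize_alleles`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    alleles: list[tuple[str, str, str]] = []
    for var in vcf:
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ds = None
        try:
            fmt = var.format("DS")
            if fmt is not None:
                ds = np.asarray(fmt, dtype=float).reshape(-1)
        except KeyError:
            ds = None
        if ds is None:
            # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = np.asarray(var.gt_types, dtype=float)
            ds = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
        snp_ids.append(sid)
        cols.append(ds)
        alt = var.ALT[0] if var.ALT else "."
        alleles.append((sid, str(alt).upper(), str(var.REF).upper()))
    gm = GenotypeMatrix(samples, snp_ids, np.column_stack(cols))
    if not return_alleles:
        return gm
    adf = pd.DataFrame(alleles, columns=["snp_id", "effect_allele", "other_allele"])
    adf["eaf"] = gm.sample_eaf
    return gm, adf


class LDTable:
    """Symmetric lookup of pairwise r-squared between SNPs.

    Absent pairs are taken as r2 = 0 (variants on different chromosomes or
    far apart); self-pairs are implicitly 1.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in pairs:
            self.add(a, b, r2)

    def add(self, snp_a: str, snp_b: str, r2: float) -> None:
        r2 = float(r2)
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must lie in [0, 1], got {r2}")
        key = (snp_a, snp_b) if snp_a <= snp_b else (snp_b, snp_a)
        self._r2[key] = r2

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        key = (snp_a, snp_b) if snp_a <= snp_b else (snp_b, snp_a)
        return self._r2.get(key, 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDTable":
        df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        for col in ("snp_a", "snp_b", "r2"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls(zip(df["snp_a"], df["snp_b"], df["r2"].astype(float)))

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted((a, b, r2) for (a, b), r2 in self._r2.items())
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


class HarmonizeAction(str, Enum):
    KEEP = "keep"
    FLIP_DOSAGE = "flip_dosage"
    EXCLUDE = "exclude"


@dataclass(frozen=True)
class Harmonization:
    action: HarmonizeAction
    reason: str = ""


def _is_palindromic(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a) == b


def harmonize_alleles(
    record: InstrumentRecord,
    study_effect_allele: str,
    study_other_allele: str,
    study_eaf: float | None = None,
) -> Harmonization:
    """Decide how a study's dosage must be oriented to count the tall allele.

    Returns ``keep`` when the study's effect allele matches the instrument's,
    ``flip_dosage`` (x' = 2 - x) when the alleles are swapped, resolving
    opposite-strand reports by complementing first.  Strand-ambiguous
    (palindromic A/T or C/G) variants cannot be resolved by alleles alone and
    are oriented by comparing allele frequencies — but only when both
    frequencies are well away from 0.5 (outside [0.42, 0.58]); otherwise the
    variant is excluded.
    """
    ea, oa = record.effect_allele.upper(), record.other_allele.upper()
    sea, soa = study_effect_allele.upper(), study_other_allele.upper()

    if _is_palindromic(ea, oa) and {sea, soa} == {ea, oa}:
        if study_eaf is None:
            return Harmonization(HarmonizeAction.EXCLUDE, "ambiguous_no_eaf")
        if not (record.eaf < 0.42 or record.eaf > 0.58) or not (
            study_eaf < 0.42 or study_eaf > 0.58
        ):
            return Harmonization(HarmonizeAction.EXCLUDE, "ambiguous_eaf_near_half")
        if (record.eaf < 0.5) == (study_eaf < 0.5):
            return Harmonization(HarmonizeAction.KEEP, "ambiguous_eaf_oriented")
        return Harmonization(HarmonizeAction.FLIP_DOSAGE, "ambiguous_eaf_oriented")

    if (sea, soa) == (ea, oa):
        return Harmonization(HarmonizeAction.KEEP)
    if (sea, soa) == (oa, ea):
        return Harmonization(HarmonizeAction.FLIP_DOSAGE)

    # try the opposite strand
    csea = _COMPLEMENT.get(sea)
    csoa = _COMPLEMENT.get(soa)
    if csea is not None and csoa is not None:
        if (csea, csoa) == (ea, oa):
            return Harmonization(HarmonizeAction.KEEP, "strand_complement")
        if (csea, csoa) == (oa, ea):
            return Harmonization(HarmonizeAction.FLIP_DOSAGE, "strand_complement")
    return Harmonization(HarmonizeAction.EXCLUDE, "allele_mismatch")


def hwe_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> float:
    """Exact conditional Hardy-Weinberg equilibrium test.

    P-value is the total probability of heterozygote counts whose conditional
    probability (given the allele counts) does not exceed the observed one.
    Monomorphic sites return 1.
    """
    counts = (int(n_hom_effect), int(n_het), int(n_hom_other))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    na = 2 * counts[0] + counts[1]
    nb = 2 * n - na
    if na == 0 or nb == 0:
        return 1.0
    hets = np.arange(na % 2, min(na, nb) + 1, 2)
    logp = (
        hets * math.log(2.0)
        - gammaln((na - hets) / 2.0 + 1.0)
        - gammaln(hets + 1.0)
        - gammaln((nb - hets) / 2.0 + 1.0)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == counts[1]]
    if obs.size == 0:  # impossible het count given allele totals
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = prob[prob <= obs[0] * (1.0 + 1e-9)].sum()
    return float(min(1.0, p))


@dataclass
class QCResult:
    kept: list[str]
    excluded: dict[str, str]


def qc_filter(
    genotypes: GenotypeMatrix,
    control_ids: Sequence[str],
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-6,
) -> QCResult:
    """Variant-level QC: call rate, minor-allele frequency, HWE in controls.

    A SNP is kept iff call rate >= ``call_rate_min``, MAF >= ``maf_min`` and
    the control-only HWE exact p-value >= ``hwe_p_min`` (thresholds inclusive
    on the keep side).  Each excluded SNP is labelled with the first failing
    check, in the order call_rate, maf, hwe.
    """
    control_ids = [str(s) for s in control_ids]
    if not control_ids:
        raise ValueError("control set is empty")
    genotypes.subject_index(control_ids)  # validates membership
    eaf = genotypes.sample_eaf
    cr = genotypes.call_rate
    kept: list[str] = []
    excluded: dict[str, str] = {}
    for j, sid in enumerate(genotypes.snp_ids):
        if cr[j] < call_rate_min:
            excluded[sid] = "call_rate"
            continue
        maf = min(eaf[j], 1.0 - eaf[j])
        if np.isnan(maf) or maf < maf_min:
            excluded[sid] = "maf"
            continue
        if hwe_test(*genotypes.genotype_counts(sid, control_ids)) < hwe_p_min:
            excluded[sid] = "hwe"
            continue
        kept.append(sid)
    return QCResult(kept, excluded)


def prune_ld(
    records: Sequence[InstrumentRecord], ld: LDTable, r2_max: float = 0.1
) -> list[InstrumentRecord]:
    """Greedy LD pruning to an approximately independent instrument set.

    Candidates are visited in ascending height-GWAS p-value (ties by input
    position); a candidate is kept iff its r2 with every already-kept SNP is
    <= ``r2_max``.  The returned list preserves the input ordering.
    """
    order = sorted(range(len(records)), key=lambda i: (records[i].pval_height, i))
    kept_ids: list[str] = []
    for i in order:
        sid = records[i].snp_id
        if all(ld.r2(sid, k) <= r2_max for k in kept_ids):
            kept_ids.append(sid)
    keep = set(kept_ids)
    return [r for r in records if r.snp_id in keep]


def substitute_proxies(
    requested: Sequence[str],
    available: Sequence[str],
    proxy_table: Iterable[tuple[str, str, float]],
    r2_min: float = 0.9,
) -> dict[str, str | None]:
    """Map each requested SNP to itself, a high-LD proxy, or ``None`` (dropped).

    A SNP present in ``available`` maps to itself.  Otherwise it maps to its
    highest-r2 available proxy with r2 > ``r2_min`` (ties broken toward the
    lexicographically smaller proxy id), else to ``None``.
    """
    avail = set(str(s) for s in available)
    proxies: dict[str, list[tuple[float, str]]] = {}
    for snp, proxy, r2 in proxy_table:
        r2 = float(r2)
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"proxy r2 must lie in [0, 1], got {r2}")
        proxies.setdefault(str(snp), []).append((r2, str(proxy)))
    mapping: dict[str, str | None] = {}
    for snp in (str(s) for s in requested):
        if snp in avail:
            mapping[snp] = snp
            continue
        cands = [
            (r2, p) for r2, p in proxies.get(snp, []) if p in avail and r2 > r2_min
        ]
        if cands:
            # max r2; ties resolved toward the smaller proxy id
            top_r2 = max(r2 for r2, _ in cands)
            mapping[snp] = min(p for r2, p in cands if r2 == top_r2)
        else:
            mapping[snp] = None
    return mapping


def exclude_bmi_overlap(
    records: Sequence[InstrumentRecord],
    bmi_snp_ids: Iterable[str],
    ld: LDTable,
    r2_max: float = 0.1,
) -> list[InstrumentRecord]:
    """Drop instruments that are BMI SNPs or in moderate LD with one.

    Used for the sensitivity analysis that severs the height instrument set
    from body-mass-index loci.
    """
    bmi = [str(s) for s in bmi_snp_ids]
    bmi_set = set(bmi)
    out = []
    for r in records:
        if r.snp_id in bmi_set:
            continue
        if any(ld.r2(r.snp_id, b) > r2_max for b in bmi):
            continue
        out.append(r)
    return out
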