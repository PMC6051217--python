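"""Gene-set over-representation for instrument-mapped genes.

Hypergeometric over-representation of a gene list (the genes the height
instruments fall in or nearest to) against a user-supplied collection such
as KEGG exported in GMT format, with Benjamini-Hochberg false-discovery
control.  The SNP-to-gene mapping is an input, not something this package
computes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentRow",
    "read_gmt",
    "read_gene_map",
    "overrepresentation",
    "bh_adjust",
]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"{self.set_id}: gene set is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.set_id}: duplicate genes within the set")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]
    universe: list[str] | None = None  # explicit background; default is the union

    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out.update(s.genes)
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``set_id, description, gene, gene, ...``.

    Genes duplicated within one line are deduplicated with a warning; lines
    with fewer than three fields raise an error naming the line.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}, line {lineno}: GMT lines need id, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            set_id, desc = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            dup = False
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    dup = True
                    continue
                seen.add(g)
                genes.append(g)
            if dup:
                warnings.warn(
                    f"{path}, line {lineno}: duplicated gene(s) in set {set_id!r} deduplicated"
                )
            sets.append(GeneSet(set_id, desc, tuple(genes)))
    return GeneSetCollection(sets)


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping snp_id to its located/nearest gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: gene map needs two columns (snp_id, gene)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    description: str
    k: int
    gene_ratio: float
    p: float
    q: float
    overlap_genes: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "set_id": self.set_id,
            "description": self.description,
            "k": self.k,
            "gene_ratio": self.gene_ratio,
            "p": self.p,
            "q": self.q,
            "genes": "/".join(self.overlap_genes),
        }


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved.

    q_(i) = min_{j >= i} m p_(j) / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def overrepresentation(
    input_genes: Iterable[str],
    collection: GeneSetCollection,
    universe_size: int | None = None,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``input_genes`` in each set.

    The background defaults to the union of all collection genes (or the
    collection's explicit universe); ``universe_size`` overrides its size.
    For each set, ``k`` is the overlap with the mapped input genes (input
    genes present in at least one set), ``p = P[X >= k]`` for
    ``X ~ Hypergeometric(universe_size, set_size, n_mapped)``, and the gene
    ratio is ``k / n_mapped``.  Rows are sorted by p-value with BH q-values
    across all sets tested.
    """
    input_list = list(dict.fromkeys(str(g) for g in input_genes))
    union = collection.union()
    if collection.universe is not None:
        background = set(collection.universe) | union
    else:
        background = union
    m_univ = universe_size if universe_size is not None else len(background)
    for s in collection.sets:
        if m_univ < len(s.genes):
            raise ValueError(
                f"universe size {m_univ} smaller than set {s.set_id!r} "
                f"({len(s.genes)} genes)"
            )
    mapped = [g for g in input_list if g in union]
    n_mapped = len(mapped)
    mapped_set = set(mapped)

    rows: list[tuple[str, str, int, tuple[str, ...], float]] = []
    for s in collection.sets:
        overlap = tuple(g for g in mapped if g in set(s.genes))
        k = len(overlap)
        if n_mapped == 0:
            p = 1.0
        else:
            p = float(hypergeom.sf(k - 1, m_univ, len(s.genes), n_mapped))
        p = min(1.0, p)
        if p <= 0.0:  # sf underflow; keep strictly inside (0, 1]
            p = 5e-324
        rows.append((s.set_id, s.description, k, overlap, p))
    pvals = [r[4] for r in rows]
    qvals = bh_adjust(pvals)
    out = [
        EnrichmentRow(
            set_id=r[0],
            description=r[1],
            k=r[2],
            gene_ratio=(r[2] / n_mapped) if n_mapped else 0.0,
            p=r[4],
            q=float(q),
            overlap_genes=r[3],
        )
        for r, q in zip(rows, qvals)
    ]
    out.sort(key=lambda row: (row.p, row.set_id))
    return out


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])
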