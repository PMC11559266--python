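"""Diversity and ordination metrics for sample x taxon abundance tables.

Implements, from first principles, the metrics used to characterise
enrichment-culture communities: relative abundance, Shannon entropy
H = -sum p_i ln p_i (nats by default), Bray-Curtis dissimilarity
sum|x_i - y_i| / sum(x_i + y_i), and classical principal coordinate
analysis (PCoA / metric MDS): Gower double-centring of -0.5 * D**2
followed by an eigendecomposition, with coordinates scaled by the square
root of the positive eigenvalues. Negative eigenvalues from non-Euclidean
dissimilarities are retained and reported but excluded from the
coordinates and from proportion-explained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "OrdinationResult",
    "relative_abundance",
    "shannon",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "rarefy",
]


@dataclass
class AbundanceTable:
    """Counts matrix (samples x taxa) with ids and optional group labels."""

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    groups: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (samples x taxa)")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError("counts shape does not match id lists")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.groups is not None and len(self.groups) != len(self.sample_ids):
            raise ValueError("groups length mismatch")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, groups: list[str] | None = None):
        return cls(
            counts=df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
            taxon_ids=[str(c) for c in df.columns],
            groups=groups,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def read_tsv(cls, path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        groups = None
        if "group" in df.columns:
            groups = df["group"].astype(str).tolist()
            df = df.drop(columns="group")
        return cls.from_dataframe(df, groups=groups)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        if self.groups is not None:
            df = df.assign(group=self.groups)
        df.to_csv(path, sep="\t", index_label="sample")


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a dissimilarity matrix."""

    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalues only
    sample_ids: list[str] = field(default_factory=list)


def relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Row-normalised proportions; raises naming the sample on zero rows."""
    sums = table.counts.sum(axis=1)
    for sid, s in zip(table.sample_ids, sums):
        if s <= 0:
            raise ValueError(f"sample {sid!r} has zero total count")
    props = table.counts / sums[:, None]
    return pd.DataFrame(props, index=table.sample_ids, columns=table.taxon_ids)


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy of a counts (or proportions) vector.

    Natural log by default; pass ``base`` (e.g. 2) for other units.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("counts sum to zero")
    p = x[x > 0] / total
    H = float(-(p * np.log(p)).sum())
    if base is not None:
        H /= np.log(base)
    return H


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    denom = (x + y).sum()
    if denom <= 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table: AbundanceTable) -> np.ndarray:
    """Symmetric pairwise Bray-Curtis matrix over the table's samples."""
    n = len(table.sample_ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(table.counts[i], table.counts[j])
    return D


def pcoa(distance_matrix, sample_ids: list[str] | None = None) -> OrdinationResult:
    """Classical PCoA of a symmetric zero-diagonal dissimilarity matrix."""
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J  # Gower double-centring
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > 1e-12
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else evals[pos]
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=evals,
        proportion_explained=prop,
        sample_ids=sample_ids or [str(i) for i in range(n)],
    )


def rarefy(table: AbundanceTable, depth: int, seed: int = 0) -> AbundanceTable:
    """Optional seeded subsampling without replacement to a common depth.

    Not applied by default anywhere in the package; provided for parity
    with amplicon workflows that rarefy before diversity estimates.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros_like(table.counts)
    for i, row in enumerate(table.counts.astype(int)):
        total = row.sum()
        if total < depth:
            raise ValueError(
                f"sample {table.sample_ids[i]!r} has {total} < depth {depth}"
            )
        expanded = np.repeat(np.arange(len(row)), row)
        picked = rng.choice(expanded, size=depth, replace=False)
        out[i] = np.bincount(picked, minlength=len(row))
    return AbundanceTable(
        counts=out,
        sample_ids=table.sample_ids,
        taxon_ids=table.taxon_ids,
        groups=table.groups,
    )
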