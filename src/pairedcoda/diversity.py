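"""Rarefaction, alpha diversity (Shannon, Chao1), Bray-Curtis, PCoA.

Alpha diversity is meant to be computed on tables rarefied to a common depth
(default 3000 reads per sample); Shannon is reported in bits (base 2) by
default, with the base exposed as a parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tabular_io import AbundanceTable


def rarefy(table: AbundanceTable, depth: int = 3000,
           seed: int | None = None) -> AbundanceTable:
    """Subsample each sample to exactly ``depth`` reads without replacement
    (multivariate hypergeometric).  Samples below ``depth`` are dropped with
    a warning; reproducible under a fixed seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    depths = table.depths()
    keep = depths.index[depths >= depth]
    if len(keep) == 0:
        raise ValueError(
            f"rarefaction depth {depth} exceeds every sample's total"
        )
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: "
            f"{dropped}", stacklevel=2)
    rng = np.random.default_rng(seed)
    cols = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        if col.sum() == depth:
            cols[s] = col
        else:
            cols[s] = rng.multivariate_hypergeometric(col, depth)
    out = pd.DataFrame(cols, index=table.counts.index)
    # drop taxa that lost all reads so downstream richness is honest
    out = out.loc[out.sum(axis=1) > 0]
    lin = (table.lineages.reindex(out.index)
           if table.lineages is not None else None)
    return AbundanceTable(out, lin)


def shannon_index(counts, base: float = 2.0) -> float:
    """H = -sum p_i log_base p_i over the non-zero proportions."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("sample with zero total count")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def chao1_index(counts) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2); bias-corrected
    S_obs + F1(F1-1)/(2(F2+1)) when no doubletons are observed."""
    arr = np.asarray(counts)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity_table(table: AbundanceTable,
                          base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon (in ``log base`` units) and Chao1 with the depth
    each was computed at."""
    records = []
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        records.append({
            "sample_id": s,
            "shannon": shannon_index(col, base=base),
            "chao1": chao1_index(col),
            "depth_used": int(col.sum()),
        })
    return pd.DataFrame(records).set_index("sample_id")


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """BC(x, y) = 1 - 2 sum_i min(x_i, y_i) / (sum x + sum y)."""
    arr = table.counts.to_numpy(dtype=float).T
    if np.any(arr.sum(axis=1) == 0):
        raise ValueError("empty sample in Bray-Curtis input")
    dm = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(dm, ids=table.sample_ids)


@dataclass
class PcoaResult:
    """Classical-MDS ordination of a distance matrix.

    ``eigenvalues`` holds the full spectrum (negatives included, reported,
    their axes discarded); ``proportion_explained`` divides the retained
    positive eigenvalues by the positive-eigenvalue total, so the fractions
    sum to <= 1.
    """

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal Coordinate Analysis via the double-centred Gram matrix."""
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * abs(eigvals[0])) if n else 0.0
    positive = eigvals > tol
    negatives = eigvals[eigvals < -tol]
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    pos_total = eigvals[positive].sum()
    explained = (eigvals[positive][:coords.shape[1]] / pos_total
                 if pos_total > 0 else np.array([]))
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=explained,
        negative_eigenvalues=negatives,
    )
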