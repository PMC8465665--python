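"""Compositional transforms and balance machinery.

Microbiome count tables carry only relative information (the sequencing depth
is arbitrary), so analyses here operate on log-ratios of strictly positive
compositions: prevalence filtering, Bayesian-multiplicative zero replacement,
the centred log-ratio (clr) transform, isometric log-ratio balances over
numerator/denominator taxon sets, and the Aitchison distance (Euclidean
distance between clr vectors).

Conventions: compositions are stored as a taxa x samples DataFrame of
proportions (columns sum to 1); natural logarithms throughout; compositions
validated to 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tabular_io import AbundanceTable

__all__ = [
    "closure",
    "prevalence_filter",
    "PrevalenceFilterResult",
    "multiplicative_zero_replacement",
    "clr_transform",
    "Balance",
    "balance_values",
    "sbp_contrast_matrix",
    "aitchison_distance",
]

_COMPOSITION_TOL = 1e-9


def closure(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Rescale each sample (column) to sum to 1."""
    if isinstance(values, pd.DataFrame):
        total = values.sum(axis=0)
        if (total <= 0).any():
            raise ValueError("closure requires positive column sums")
        return values / total
    values = np.asarray(values, dtype=float)
    total = values.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("closure requires positive column sums")
    return values / total


# ---------------------------------------------------------------------------
# Prevalence filter
# ---------------------------------------------------------------------------

@dataclass
class PrevalenceFilterResult:
    table: AbundanceTable
    removed: list[str] = field(default_factory=list)


def prevalence_filter(table: AbundanceTable,
                      rel_ab_threshold: float = 0.01,
                      min_samples: int = 5) -> PrevalenceFilterResult:
    """Keep taxa whose within-sample relative abundance exceeds
    ``rel_ab_threshold`` (strictly) in at least ``min_samples`` samples.

    Defaults: >1% relative abundance in >=5 samples.
    """
    if not (0 < rel_ab_threshold < 1):
        raise ValueError("rel_ab_threshold must lie in (0, 1)")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    rel = table.relative_abundance()
    n_above = (rel > rel_ab_threshold).sum(axis=1)
    keep = n_above >= min_samples
    if not keep.any():
        raise ValueError(
            "prevalence filter removed every taxon; lower rel_ab_threshold "
            f"(={rel_ab_threshold}) or min_samples (={min_samples})"
        )
    removed = list(table.counts.index[~keep])
    return PrevalenceFilterResult(table.subset_taxa(table.counts.index[keep]),
                                  removed)


# ---------------------------------------------------------------------------
# Zero replacement
# ---------------------------------------------------------------------------

def multiplicative_zero_replacement(table: AbundanceTable,
                                    method: str = "GBM",
                                    delta: Optional[float] = None,
                                    ) -> pd.DataFrame:
    """Replace zero counts by small positive proportions, multiplicatively.

    Returns a taxa x samples DataFrame of strictly positive proportions
    (columns sum to 1).  For each sample, the ratios between originally
    non-zero parts are preserved exactly: non-zero parts are rescaled by a
    common factor ``1 - sum(imputed)``.

    method="CZM"
        Count-zero multiplicative: every zero is replaced by ``delta``
        (default ``0.65 / depth`` per sample).
    method="GBM"
        Bayesian-multiplicative with a data-driven geometric prior: the prior
        expectation for part j is the across-sample geometric mean of the
        (0.5-padded) proportions, with per-sample prior strength sqrt(depth),
        so the imputed proportion is ``t_j * s / (depth + s)``.

    Imputed values are capped at 65% of the smallest observed non-zero
    proportion in the sample, so they are always strictly smaller than any
    observed part.
    """
    counts = table.counts.to_numpy(dtype=float)
    depths = counts.sum(axis=0)
    if np.any(depths <= 0):
        raise ValueError("sample with all-zero counts")
    if np.any(counts.sum(axis=1) == 0):
        bad = table.counts.index[counts.sum(axis=1) == 0][0]
        raise ValueError(
            f"taxon {bad!r} is zero in every sample; prevalence-filter first"
        )
    props = counts / depths
    zeros = counts == 0

    if method.upper() == "CZM":
        if delta is None:
            repl = 0.65 / depths  # broadcast per sample
            repl = np.broadcast_to(repl, props.shape).copy()
        else:
            if not (0 < delta < 1):
                raise ValueError("delta must lie in (0, 1)")
            repl = np.full(props.shape, float(delta))
    elif method.upper() == "GBM":
        padded = (counts + 0.5) / (counts + 0.5).sum(axis=0)
        t = np.exp(np.log(padded).mean(axis=1))
        t = t / t.sum()
        s = np.sqrt(depths)
        repl = t[:, None] * (s / (depths + s))[None, :]
    else:
        raise ValueError(f"unknown zero-replacement method {method!r}")

    # keep imputed parts strictly below the smallest observed proportion
    with np.errstate(invalid="ignore"):
        min_obs = np.where(zeros, np.inf, props).min(axis=0)
    cap = 0.65 * min_obs
    repl = np.minimum(repl, cap[None, :])

    out = props.copy()
    out[zeros] = repl[zeros]
    imputed_total = np.where(zeros, repl, 0.0).sum(axis=0)
    if np.any(imputed_total >= 1):
        raise ValueError("imputed mass >= 1; replacement values too large")
    scale = (1.0 - imputed_total)
    out = np.where(zeros, out, props * scale[None, :])
    return pd.DataFrame(out, index=table.counts.index,
                        columns=table.counts.columns)


# ---------------------------------------------------------------------------
# clr / balances / Aitchison distance
# ---------------------------------------------------------------------------

def _check_positive(values: np.ndarray) -> None:
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValueError(
            "composition parts must be strictly positive; "
            "apply zero replacement first"
        )


def clr_transform(composition: pd.DataFrame | pd.Series | np.ndarray):
    """Centred log-ratio: log(part / geometric mean of the sample's parts).

    Accepts a single composition (1-D) or a taxa x samples table; returns the
    same shape.  Output columns sum to 0 (within 1e-9) and the transform is
    invariant to rescaling of the input.
    """
    if isinstance(composition, pd.DataFrame):
        arr = composition.to_numpy(dtype=float)
        _check_positive(arr)
        logs = np.log(arr)
        out = logs - logs.mean(axis=0, keepdims=True)
        return pd.DataFrame(out, index=composition.index,
                            columns=composition.columns)
    arr = np.asarray(composition, dtype=float)
    _check_positive(arr)
    logs = np.log(arr)
    if arr.ndim == 1:
        out = logs - logs.mean()
    else:
        out = logs - logs.mean(axis=0, keepdims=True)
    if isinstance(composition, pd.Series):
        return pd.Series(out, index=composition.index)
    return out


@dataclass(frozen=True)
class Balance:
    """A single numerator/denominator split of the taxa (one ilr contrast)."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ValueError("balance sides must be non-empty")
        if set(self.numerator) & set(self.denominator):
            raise ValueError("numerator and denominator overlap")

    @property
    def coefficient(self) -> float:
        r, s = len(self.numerator), len(self.denominator)
        return float(np.sqrt(r * s / (r + s)))


def balance_values(composition: pd.DataFrame | pd.Series,
                   numerator: Sequence[str],
                   denominator: Sequence[str]):
    """Normalised log contrast b = sqrt(r*s/(r+s)) * ln(g(num)/g(den)).

    ``g`` is the geometric mean; ``r`` and ``s`` are the side sizes.  For a
    taxa x samples DataFrame a per-sample Series is returned; for a single
    composition a float.
    """
    bal = Balance(tuple(numerator), tuple(denominator))
    if isinstance(composition, pd.Series):
        comp = composition.to_frame("x")
        vals = balance_values(comp, numerator, denominator)
        return float(vals.iloc[0])
    missing = (set(bal.numerator) | set(bal.denominator)) - \
        set(composition.index)
    if missing:
        raise KeyError(f"balance taxa not in composition: {sorted(missing)}")
    arr = composition.to_numpy(dtype=float)
    _check_positive(arr)
    logs = np.log(composition.astype(float))
    num_mean = logs.loc[list(bal.numerator)].mean(axis=0)
    den_mean = logs.loc[list(bal.denominator)].mean(axis=0)
    return bal.coefficient * (num_mean - den_mean)


def sbp_contrast_matrix(balances: Sequence[Balance],
                        taxa: Sequence[str]) -> pd.DataFrame:
    """Contrast (psi) matrix of a sequential binary partition.

    Row k holds +sqrt(s/(r(r+s))) on numerator taxa and -sqrt(r/(s(r+s))) on
    denominator taxa of balance k; the ilr coordinates of a composition x are
    ``psi @ clr(x)``.
    """
    psi = pd.DataFrame(0.0, index=range(len(balances)), columns=list(taxa))
    for k, bal in enumerate(balances):
        r, s = len(bal.numerator), len(bal.denominator)
        psi.loc[k, list(bal.numerator)] = np.sqrt(s / (r * (r + s)))
        psi.loc[k, list(bal.denominator)] = -np.sqrt(r / (s * (r + s)))
    return psi


def aitchison_distance(compositions: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distance between clr-transformed samples."""
    clr = clr_transform(compositions)
    dm = squareform(pdist(clr.to_numpy().T, metric="euclidean"))
    return DistanceMatrix(dm, ids=list(compositions.columns))


def distance_matrix_to_tsv(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", float_format="%.10g")
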