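"""Statistical tests for the paired two-group design.

PERMANOVA (free or within-strata restricted permutations), baseline-adjusted
ANCOVA (``after ~ intercept + before + group``), the paired two-timepoint
change test, per-covariate screening models, Welch's t and Benjamini-Hochberg
FDR control.

The two-timepoint mixed model with a subject random intercept is implemented
through its exact equivalence with the paired t-test on within-subject
differences: with exactly two timepoints per subject the group-mean change
test of the random-intercept model and the paired t-test give identical
inference, and the reduction is deterministic and dependency-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "welch_t",
    "WelchResult",
    "paired_change_test",
    "PairedChangeResult",
    "ancova_group_effect",
    "AncovaResult",
    "covariate_linear_model",
    "permanova",
    "PermanovaResult",
]


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    p: float
    df: float
    note: str = ""


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Unequal-variance two-sample t with Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample must have size >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return WelchResult(0.0, 1.0, float(len(x) + len(y) - 2),
                               note="zero variance in both samples")
        return WelchResult(np.inf, 0.0, float(len(x) + len(y) - 2),
                           note="zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.pvalue),
                       float(res.df))


# ---------------------------------------------------------------------------
# Paired two-timepoint change test
# ---------------------------------------------------------------------------

@dataclass
class PairedChangeResult:
    effect: float  # mean within-subject (after - before) change
    p: float
    n: int
    note: str = ""


def paired_change_test(before: Sequence[float], after: Sequence[float],
                       subjects: Optional[Sequence] = None,
                       ) -> PairedChangeResult:
    """Test whether the mean within-subject change differs from zero.

    Equivalent to the two-timepoint subject-random-intercept model (see
    module docstring).  Subjects with a missing member are dropped.
    """
    b = pd.Series(np.asarray(before, dtype=float),
                  index=subjects if subjects is not None else None)
    a = pd.Series(np.asarray(after, dtype=float),
                  index=subjects if subjects is not None else None)
    if subjects is not None:
        common = b.index.intersection(a.index)
        b, a = b.loc[common], a.loc[common]
    mask = b.notna() & a.notna()
    note = ""
    if (~mask).any():
        note = f"dropped {int((~mask).sum())} incomplete pair(s)"
    d = (a[mask] - b[mask]).to_numpy()
    if len(d) < 2:
        raise ValueError("need at least 2 complete pairs")
    effect = float(d.mean())
    if d.std(ddof=1) == 0:
        if effect == 0:
            return PairedChangeResult(0.0, 1.0, len(d),
                                      note=(note + "; " if note else "")
                                      + "zero-variance changes")
        return PairedChangeResult(effect, 0.0, len(d),
                                  note=(note + "; " if note else "")
                                  + "zero-variance non-zero changes")
    res = stats.ttest_rel(a[mask], b[mask])
    return PairedChangeResult(effect, float(res.pvalue), len(d), note)


# ---------------------------------------------------------------------------
# Baseline-adjusted ANCOVA
# ---------------------------------------------------------------------------

@dataclass
class AncovaResult:
    """OLS of ``after ~ intercept + before + group``.

    ``group_coefficient`` is the effect of the non-reference group (reference
    = control), so a positive value means the intervention group ends higher
    at equal baseline.
    """

    group_coefficient: float
    group_p: float
    baseline_coefficient: float
    intercept: float
    n: int
    note: str = ""


def ancova_group_effect(before: Sequence[float], after: Sequence[float],
                        group: Sequence[str],
                        reference: str = "control") -> AncovaResult:
    """Baseline-adjusted group comparison (one record per subject)."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    g = np.asarray(group)
    levels = sorted(set(g.tolist()))
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    if reference not in levels:
        reference = levels[0]
    indicator = (g != reference).astype(float)
    n = len(a)
    if n < 4:
        raise ValueError("need at least 4 subjects for the ANCOVA")
    if np.ptp(b) == 0:
        return AncovaResult(np.nan, np.nan, np.nan, np.nan, n,
                            note="baseline constant; model collinear")
    x = np.column_stack([np.ones(n), b, indicator])
    coef, _, rank, _ = np.linalg.lstsq(x, a, rcond=None)
    if rank < 3:
        return AncovaResult(np.nan, np.nan, np.nan, np.nan, n,
                            note="collinear design")
    resid = a - x @ coef
    dof = n - 3
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    if se[2] == 0:
        p = 1.0 if coef[2] == 0 else 0.0
    else:
        tstat = coef[2] / se[2]
        p = float(2 * stats.t.sf(abs(tstat), dof))
    return AncovaResult(
        group_coefficient=float(coef[2]),
        group_p=p,
        baseline_coefficient=float(coef[1]),
        intercept=float(coef[0]),
        n=n,
    )


# ---------------------------------------------------------------------------
# Per-covariate screening models
# ---------------------------------------------------------------------------

def covariate_linear_model(response: Sequence[float],
                           covariates: pd.DataFrame) -> pd.DataFrame:
    """One simple OLS per covariate with BH correction across covariates.

    Numeric covariates are z-standardised for the fit (the reported
    coefficient is rescaled back to the covariate's original units);
    categorical ones are dummy-coded against their first level.  Constant
    covariates (or categoricals with a single observed level) are skipped
    with a note.
    """
    y = np.asarray(response, dtype=float)
    rows = []
    for name in covariates.columns:
        col = covariates[name]
        note = ""
        scale = 1.0
        if pd.api.types.is_numeric_dtype(col):
            vals = col.to_numpy(dtype=float)
            mask = np.isfinite(vals) & np.isfinite(y)
            if mask.sum() < 3 or np.nanstd(vals[mask]) == 0:
                rows.append({"covariate": name, "coefficient": np.nan,
                             "p": np.nan, "note": "constant or too few values",
                             "tested": False})
                continue
            scale = vals[mask].std(ddof=0)
            x = (vals[mask] - vals[mask].mean()) / scale
            yy = y[mask]
        else:
            levels = [lv for lv in pd.unique(col.dropna())]
            if len(levels) < 2:
                rows.append({"covariate": name, "coefficient": np.nan,
                             "p": np.nan, "note": "single level; skipped",
                             "tested": False})
                continue
            if len(levels) > 2:
                note = f"dummy for {levels[1]!r} vs {levels[0]!r}"
            mask = col.notna().to_numpy() & np.isfinite(y)
            x = (col[mask] == levels[1]).to_numpy(dtype=float)
            yy = y[mask]
        res = stats.linregress(x, yy)
        rows.append({"covariate": name,
                     "coefficient": float(res.slope) / scale,
                     "p": float(res.pvalue), "note": note, "tested": True})
    out = pd.DataFrame(rows).set_index("covariate")
    out["q"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out.drop(columns="tested")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    restricted: bool = False
    note: str = ""


def _group_masks(codes: np.ndarray, n_groups: int) -> list[np.ndarray]:
    return [codes == g for g in range(n_groups)]


def _ss_within(d2: np.ndarray, masks_matrix: np.ndarray,
               group_sizes: np.ndarray) -> np.ndarray:
    """Within-group sum of squared distances for a batch of labelings.

    ``masks_matrix``: (n_perm, n_groups, n) boolean indicators.
    """
    ssw = np.zeros(masks_matrix.shape[0])
    for g in range(masks_matrix.shape[1]):
        m = masks_matrix[:, g, :].astype(float)
        ssw += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * group_sizes[g])
    return ssw


def permanova(dm: DistanceMatrix | np.ndarray,
              grouping: Sequence,
              n_permutations: int = 999,
              seed: int | None = None,
              strata: Optional[Sequence] = None) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F partitions the total sum of squared distances into between- and
    within-group parts; p uses the add-one rule
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.  When ``strata`` is
    given (e.g. subject ids for a paired before/after design), labels are
    permuted only within each stratum.
    """
    if isinstance(dm, DistanceMatrix):
        d = np.asarray(dm.data, dtype=float)
    else:
        d = np.asarray(dm, dtype=float)
    n = d.shape[0]
    labels = np.asarray(list(grouping))
    if len(labels) != n:
        raise ValueError("grouping length must match distance matrix size")
    codes, uniques = pd.factorize(labels)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    if (sizes < 1).any():
        raise ValueError("empty group")

    d2 = d ** 2
    ss_total = d2.sum() / (2.0 * n)

    obs_masks = np.stack(_group_masks(codes, n_groups))[None, :, :]
    ssw_obs = _ss_within(d2, obs_masks, sizes)[0]
    ssb_obs = ss_total - ssw_obs
    dof_b, dof_w = n_groups - 1, n - n_groups
    if dof_w <= 0 or ssw_obs <= 0:
        f_obs = np.inf if ssb_obs > 0 else 0.0
    else:
        f_obs = (ssb_obs / dof_b) / (ssw_obs / dof_w)
    r2 = ssb_obs / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    if strata is None:
        perm_idx = np.argsort(
            rng.random((n_permutations, n)), axis=1)
    else:
        strata_arr = np.asarray(list(strata))
        if len(strata_arr) != n:
            raise ValueError("strata length must match distance matrix size")
        perm_idx = np.tile(np.arange(n), (n_permutations, 1))
        for stratum in pd.unique(strata_arr):
            pos = np.flatnonzero(strata_arr == stratum)
            if len(pos) < 2:
                raise ValueError(
                    f"stratum {stratum!r} has a single sample; cannot permute"
                )
            sub = np.argsort(rng.random((n_permutations, len(pos))), axis=1)
            perm_idx[:, pos] = pos[sub]
    perm_codes = codes[perm_idx]  # (P, n)
    masks = np.stack(
        [perm_codes == g for g in range(n_groups)], axis=1)
    ssw_perm = _ss_within(d2, masks, sizes)
    ssb_perm = ss_total - ssw_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssb_perm / dof_b) / (ssw_perm / dof_w)
    f_perm = np.where(np.isfinite(f_perm), f_perm, np.inf)
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p=float(p),
        n_permutations=n_permutations,
        restricted=strata is not None,
    )
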