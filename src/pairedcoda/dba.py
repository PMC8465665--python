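"""Discriminative balance analysis and the between-group protocol.

This module houses the differential-abundance machinery of the pipeline:

* :func:`dba_select_balances` — discriminative balance analysis (DBA): score
  every two-taxon log-ratio by the standardised difference of its mean
  between two conditions, then greedily accept top-scoring, taxon-disjoint
  balances, optionally growing a side by one taxon when that increases the
  score.  The variant deliberately favours small balances (at most
  ``max_parts_per_side`` taxa per side, default 2).
* :func:`within_group_dba` — DBA on before/after samples of one group, each
  selected balance tested with the paired change test, BH-corrected.
* :func:`aldex_effect` — Dirichlet-clr Monte-Carlo effect sizes in the style
  of ALDEx2: per-sample proportions drawn from Dirichlet(counts + 0.5),
  clr-transformed, between-group difference scaled by within-group
  dispersion, medians across instances.
* :func:`between_group_protocol` — the six-step between-group analysis:
  baseline filtration by Monte-Carlo effect sizes, change-matrix
  construction, DBA on changes, per-balance before/after values,
  baseline-adjusted ANCOVA, BH correction.
* :func:`selbal_like` — greedy forward search for a single balance
  maximising cross-validated AUC, with per-taxon selection reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .coda import Balance, balance_values, multiplicative_zero_replacement
from .inference import (AncovaResult, ancova_group_effect, bh_fdr,
                        paired_change_test)
from .tabular_io import AbundanceTable, StudyDesign, validate_pairing

__all__ = [
    "DbaBalanceResult",
    "dba_select_balances",
    "within_group_dba",
    "aldex_effect",
    "BetweenGroupResult",
    "between_group_protocol",
    "SelbalResult",
    "selbal_like",
]


# ---------------------------------------------------------------------------
# DBA
# ---------------------------------------------------------------------------

@dataclass
class DbaBalanceResult:
    numerator: list[str]
    denominator: list[str]
    values: pd.Series  # per-sample (or per-subject) balance values
    score: float
    p: float = np.nan
    q: float = np.nan
    effect: float = np.nan
    marginal: bool = False
    note: str = ""
    ancova: Optional[AncovaResult] = None


def _standardized_score(vals: np.ndarray, mask_a: np.ndarray,
                        mask_b: np.ndarray) -> float:
    """|mean_A - mean_B| of a balance, over the pooled within-condition SD."""
    a, b = vals[mask_a], vals[mask_b]
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    pooled = ((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1)
    diff = abs(a.mean() - b.mean())
    if pooled == 0:
        return np.inf if diff > 0 else 0.0
    return float(diff / np.sqrt(pooled))


def dba_select_balances(values: pd.DataFrame,
                        labels: Sequence,
                        max_parts_per_side: int = 2,
                        ) -> list[DbaBalanceResult]:
    """Discriminative balance analysis over a strictly positive matrix.

    Every unordered taxon pair is scored by the absolute standardised
    between-condition mean difference of its per-sample log-ratio; pairs are
    accepted greedily under taxon-disjointness and each accepted balance may
    grow by one taxon per step on either side while that raises the score
    (never beyond ``max_parts_per_side`` per side).  Balances are returned
    in acceptance order (descending seed-pair score); the reported score is
    the final, possibly extended, balance's standardised difference.  The
    numerator is oriented so the first condition level (sorted order) has
    the higher mean.  Deterministic under input reordering: ties break on
    sorted taxon names.
    """
    taxa = list(values.index)
    if len(taxa) < 2:
        raise ValueError("DBA needs at least 2 taxa")
    arr = values.to_numpy(dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("DBA requires strictly positive, finite values")
    lab = np.asarray(list(labels))
    levels = sorted(pd.unique(lab).tolist())
    if len(levels) != 2:
        raise ValueError(f"DBA needs exactly two condition levels, got {levels}")
    mask_a, mask_b = lab == levels[0], lab == levels[1]

    logs = np.log(arr)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    mean_diff = logs[:, mask_a].mean(axis=1) - logs[:, mask_b].mean(axis=1)
    cov_a = np.cov(logs[:, mask_a]) if na > 1 else np.zeros((len(taxa),) * 2)
    cov_b = np.cov(logs[:, mask_b]) if nb > 1 else np.zeros((len(taxa),) * 2)
    var_a = np.diag(cov_a)[:, None] + np.diag(cov_a)[None, :] - 2 * cov_a
    var_b = np.diag(cov_b)[:, None] + np.diag(cov_b)[None, :] - 2 * cov_b
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / max(na + nb - 2, 1)
    diff = np.abs(mean_diff[:, None] - mean_diff[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = diff / np.sqrt(pooled)
    scores = np.where(pooled <= 0, np.where(diff > 0, np.inf, 0.0), scores)

    iu, ju = np.triu_indices(len(taxa), k=1)
    pair_scores = scores[iu, ju]
    order = sorted(
        range(len(iu)),
        key=lambda k: (-pair_scores[k],
                       min(taxa[iu[k]], taxa[ju[k]]),
                       max(taxa[iu[k]], taxa[ju[k]])),
    )

    used: set[int] = set()
    results: list[DbaBalanceResult] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if i in used or j in used:
            continue
        # orient: numerator higher in the first condition level
        if mean_diff[i] - mean_diff[j] >= 0:
            num, den = [i], [j]
        else:
            num, den = [j], [i]
        used.update((i, j))
        score = float(pair_scores[k])

        def bal_vals(num_idx: list[int], den_idx: list[int]) -> np.ndarray:
            r, s = len(num_idx), len(den_idx)
            coef = np.sqrt(r * s / (r + s))
            return coef * (logs[num_idx].mean(axis=0)
                           - logs[den_idx].mean(axis=0))

        improved = True
        while improved and (len(num) < max_parts_per_side
                            or len(den) < max_parts_per_side):
            improved = False
            best = (score, None, None)
            candidates = sorted(set(range(len(taxa))) - used,
                                key=lambda c: taxa[c])
            for c in candidates:
                if len(num) < max_parts_per_side:
                    s_num = _standardized_score(
                        bal_vals(num + [c], den), mask_a, mask_b)
                    if s_num > best[0] + 1e-12:
                        best = (s_num, c, "num")
                if len(den) < max_parts_per_side:
                    s_den = _standardized_score(
                        bal_vals(num, den + [c]), mask_a, mask_b)
                    if s_den > best[0] + 1e-12:
                        best = (s_den, c, "den")
            if best[1] is not None:
                score, c, side = best
                (num if side == "num" else den).append(c)
                used.add(c)
                improved = True

        vals = pd.Series(bal_vals(num, den), index=values.columns)
        results.append(DbaBalanceResult(
            numerator=[taxa[i] for i in num],
            denominator=[taxa[i] for i in den],
            values=vals,
            score=score,
        ))
    # results stay in greedy-acceptance order, i.e. descending seed-pair
    # score; post-extension scores are refined in place but do not re-rank
    # (an extension search overfits slightly, so re-sorting on it would let
    # lucky extended balances leapfrog stronger seeds)
    return results


def within_group_dba(table: AbundanceTable, design: StudyDesign, group: str,
                     max_parts_per_side: int = 2,
                     zero_method: str = "GBM",
                     min_depth: int = 1000) -> list[DbaBalanceResult]:
    """DBA on one group's before/after samples with paired significance.

    Balances are selected on zero-replaced proportions with the timepoint as
    condition, then each balance's within-subject change is tested with the
    paired change test and BH-corrected across balances.  Balances with
    0.05 < q < 0.06 are flagged ``marginal``.
    """
    report = validate_pairing(design, table, min_depth=min_depth)
    subjects = [s for s in report.complete_pairs
                if design.group_of(s) == group]
    if len(subjects) < 3:
        raise ValueError(
            f"group {group!r} has {len(subjects)} complete pairs; need >= 3")
    sample_ids = report.paired_samples(design, group=group)
    sub = table.subset_samples(sample_ids)
    props = multiplicative_zero_replacement(sub, method=zero_method)
    tp = design.sample_attribute("timepoint").loc[sample_ids]
    balances = dba_select_balances(props, tp.to_numpy(),
                                   max_parts_per_side=max_parts_per_side)
    before_ids = [report.complete_pairs[s][0] for s in subjects]
    after_ids = [report.complete_pairs[s][1] for s in subjects]
    pvals = []
    for bal in balances:
        res = paired_change_test(
            bal.values.loc[before_ids].to_numpy(),
            bal.values.loc[after_ids].to_numpy(),
            subjects=subjects)
        bal.p = res.p
        bal.effect = res.effect
        bal.note = res.note
        pvals.append(res.p)
    qvals = bh_fdr(pvals)
    for bal, q in zip(balances, qvals):
        bal.q = float(q)
        bal.marginal = 0.05 < bal.q < 0.06
    return balances


# ---------------------------------------------------------------------------
# ALDEx2-style Dirichlet-clr effects
# ---------------------------------------------------------------------------

def aldex_effect(counts: pd.DataFrame | AbundanceTable,
                 labels: Sequence,
                 n_mc_instances: int = 128,
                 seed: int | None = None) -> pd.DataFrame:
    """Monte-Carlo Dirichlet-clr between-group effect sizes per taxon.

    For each instance, per-sample proportions are drawn from
    Dirichlet(counts + 0.5) and clr-transformed.  Pooling the instance x
    sample values per group, ``diff`` is the between-group difference of
    pooled medians, ``disp`` the sqrt of the mean pooled within-group
    variance and ``effect = diff / disp``; the per-instance Welch p is
    averaged across instances and BH-corrected across taxa.
    """
    if isinstance(counts, AbundanceTable):
        counts = counts.counts
    if n_mc_instances < 2:
        raise ValueError("n_mc_instances must be >= 2")
    if n_mc_instances < 16:
        warnings.warn(
            f"n_mc_instances={n_mc_instances} is unstable; use >= 16",
            stacklevel=2)
    lab = np.asarray(list(labels))
    levels = sorted(pd.unique(lab).tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly two labels, got {levels}")
    mask_a, mask_b = lab == levels[0], lab == levels[1]
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if min(na, nb) < 2:
        raise ValueError("each group needs >= 2 samples")

    alpha = counts.to_numpy(dtype=float) + 0.5  # taxa x samples
    n_taxa, n_samples = alpha.shape
    rng = np.random.default_rng(seed)
    # (K, taxa, samples) Dirichlet draws via normalised Gammas
    gammas = rng.standard_gamma(alpha, size=(n_mc_instances, n_taxa,
                                             n_samples))
    gammas /= gammas.sum(axis=1, keepdims=True)
    clr = np.log(gammas)
    clr -= clr.mean(axis=1, keepdims=True)

    xa, xb = clr[:, :, mask_a], clr[:, :, mask_b]
    var_a = xa.var(axis=2, ddof=1)
    var_b = xb.var(axis=2, ddof=1)

    # per-instance Welch test on clr values
    ma, mb = xa.mean(axis=2), xb.mean(axis=2)
    se2 = var_a / na + var_b / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (mb - ma) / np.sqrt(se2)
        df = se2 ** 2 / ((var_a / na) ** 2 / (na - 1)
                         + (var_b / nb) ** 2 / (nb - 1))
    p_k = 2 * stats.t.sf(np.abs(tstat), df)
    p_k = np.where(np.isfinite(p_k), p_k, 1.0)

    # pool instances x samples per group: (K * n_g) values per taxon
    pool_a = np.moveaxis(xa, 1, 0).reshape(n_taxa, -1)
    pool_b = np.moveaxis(xb, 1, 0).reshape(n_taxa, -1)
    diff = np.median(pool_b, axis=1) - np.median(pool_a, axis=1)
    disp = np.maximum(
        np.sqrt((pool_a.var(axis=1, ddof=1)
                 + pool_b.var(axis=1, ddof=1)) / 2.0), 1e-12)
    effect = diff / disp
    p = p_k.mean(axis=0)
    out = pd.DataFrame({
        "diff": diff,
        "disp": disp,
        "effect": effect,
        "p": p,
        "q": bh_fdr(p),
    }, index=counts.index)
    out.attrs["levels"] = levels
    return out


# ---------------------------------------------------------------------------
# Between-group protocol
# ---------------------------------------------------------------------------

@dataclass
class BetweenGroupResult:
    """All artefacts of the six-step between-group analysis, for audit."""

    retained_taxa: list[str]
    effect_before: pd.DataFrame
    effect_after: pd.DataFrame
    change_matrix: Optional[pd.DataFrame]  # taxa x subjects, log-ratios
    balances: list[DbaBalanceResult] = field(default_factory=list)
    subject_group: Optional[pd.Series] = None
    note: str = ""

    @property
    def change_ratios(self) -> Optional[pd.DataFrame]:
        """Display-parity after/before abundance ratios."""
        return None if self.change_matrix is None else np.exp(
            self.change_matrix)


def between_group_protocol(table: AbundanceTable, design: StudyDesign,
                           n_mc_instances: int = 128,
                           seed: int | None = None,
                           max_parts_per_side: int = 2,
                           zero_method: str = "GBM",
                           min_depth: int = 1000) -> BetweenGroupResult:
    """Between-group differential change analysis.

    Steps: (1) Monte-Carlo Dirichlet-clr effects comparing groups at
    *before* and at *after*; keep taxa whose between-group effect magnitude
    is strictly larger after than before (drops baseline-confounded taxa);
    (2) per-subject log(after/before) change matrix on zero-replaced
    proportions for retained taxa; (3) DBA on the changes with group as the
    condition; (4) per-balance before/after values per subject; (5) ANCOVA
    ``after ~ intercept + before + group`` per balance; (6) BH across
    balances.  If no taxa survive step 1 a structured empty result is
    returned rather than raising.
    """
    report = validate_pairing(design, table, min_depth=min_depth)
    subjects = list(report.complete_pairs)
    groups = pd.Series({s: design.group_of(s) for s in subjects})
    if groups.nunique() != 2:
        raise ValueError("need complete pairs in both groups")
    before_ids = [report.complete_pairs[s][0] for s in subjects]
    after_ids = [report.complete_pairs[s][1] for s in subjects]

    ss = np.random.SeedSequence(seed)
    seed_b, seed_a = [int(c.generate_state(1)[0] % (2 ** 31))
                      for c in ss.spawn(2)]
    eff_before = aldex_effect(
        table.subset_samples(before_ids).counts, groups.to_numpy(),
        n_mc_instances=n_mc_instances, seed=seed_b)
    eff_after = aldex_effect(
        table.subset_samples(after_ids).counts, groups.to_numpy(),
        n_mc_instances=n_mc_instances, seed=seed_a)

    retained = list(table.counts.index[
        np.abs(eff_before["effect"].to_numpy())
        < np.abs(eff_after["effect"].to_numpy())])
    if len(retained) == 0:
        return BetweenGroupResult(
            retained_taxa=[], effect_before=eff_before,
            effect_after=eff_after, change_matrix=None,
            subject_group=groups, note="no candidate taxa after filtration")

    all_ids = before_ids + after_ids
    props = multiplicative_zero_replacement(
        table.subset_samples(all_ids), method=zero_method)
    logs = np.log(props)
    change = pd.DataFrame(
        logs[after_ids].to_numpy() - logs[before_ids].to_numpy(),
        index=props.index, columns=subjects).loc[retained]

    if len(retained) < 2:
        return BetweenGroupResult(
            retained_taxa=retained, effect_before=eff_before,
            effect_after=eff_after, change_matrix=change,
            subject_group=groups,
            note="fewer than 2 retained taxa; DBA not applicable")

    balances = dba_select_balances(np.exp(change), groups.to_numpy(),
                                   max_parts_per_side=max_parts_per_side)
    pvals = []
    for bal in balances:
        b_vals = balance_values(props[before_ids], bal.numerator,
                                bal.denominator)
        a_vals = balance_values(props[after_ids], bal.numerator,
                                bal.denominator)
        bal.ancova = ancova_group_effect(
            b_vals.to_numpy(), a_vals.to_numpy(), groups.to_numpy(),
            reference="control")
        bal.p = bal.ancova.group_p
        bal.values = pd.Series(
            a_vals.to_numpy() - b_vals.to_numpy(), index=subjects)
        pvals.append(bal.p)
    qvals = bh_fdr(pvals)
    for bal, q in zip(balances, qvals):
        bal.q = float(q)
        bal.marginal = 0.05 < bal.q < 0.06
    return BetweenGroupResult(
        retained_taxa=retained, effect_before=eff_before,
        effect_after=eff_after, change_matrix=change, balances=balances,
        subject_group=groups)


# ---------------------------------------------------------------------------
# selbal-style forward search
# ---------------------------------------------------------------------------

@dataclass
class SelbalResult:
    numerator: list[str]
    denominator: list[str]
    auc_mean: float
    auc_sd: float
    reproducibility: pd.Series  # per-taxon fraction of fold-selections
    fold_aucs: np.ndarray


def _rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC of ``scores`` for the positive class."""
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = stats.rankdata(scores)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def _pairwise_auc_matrix(logs: np.ndarray, positive: np.ndarray,
                         iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    diffs = logs[iu] - logs[ju]  # (P, n)
    ranks = stats.rankdata(diffs, axis=1)
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    return (ranks[:, positive].sum(axis=1)
            - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _greedy_balance(logs: np.ndarray, positive: np.ndarray,
                    taxa: list[str], max_taxa: int) -> tuple[list[int],
                                                             list[int]]:
    """Forward selection of a balance maximising training AUC."""
    n_taxa = logs.shape[0]
    iu, ju = np.triu_indices(n_taxa, k=1)
    aucs = _pairwise_auc_matrix(logs, positive, iu, ju)
    folded = np.maximum(aucs, 1 - aucs)
    order = sorted(range(len(iu)),
                   key=lambda k: (-folded[k], taxa[iu[k]], taxa[ju[k]]))
    best_k = order[0]
    i, j = int(iu[best_k]), int(ju[best_k])
    if aucs[best_k] >= 0.5:
        num, den = [i], [j]
    else:
        num, den = [j], [i]
    current = float(folded[best_k])

    def bal(num_idx, den_idx):
        r, s = len(num_idx), len(den_idx)
        coef = np.sqrt(r * s / (r + s))
        return coef * (logs[num_idx].mean(axis=0)
                       - logs[den_idx].mean(axis=0))

    while len(num) + len(den) < max_taxa:
        best = (current, None, None)
        for c in sorted(set(range(n_taxa)) - set(num) - set(den),
                        key=lambda c: taxa[c]):
            a_num = _rank_auc(bal(num + [c], den), positive)
            if a_num > best[0] + 1e-9:
                best = (a_num, c, "num")
            a_den = _rank_auc(bal(num, den + [c]), positive)
            if a_den > best[0] + 1e-9:
                best = (a_den, c, "den")
        if best[1] is None:
            break
        current, c, side = best
        (num if side == "num" else den).append(c)
    return num, den


def selbal_like(values: pd.DataFrame, labels: Sequence,
                k_folds: int = 5, n_repeats: int = 20,
                seed: int | None = None,
                max_taxa: int = 4) -> SelbalResult:
    """Cross-validated single-balance selection (selbal-style).

    Within each of ``n_repeats`` stratified ``k_folds`` splits, a balance is
    selected by greedy forward search on the training folds (initialised
    with the taxon pair whose log-ratio maximises training AUC, extended
    while training AUC improves) and scored by rank AUC on the held-out
    fold.  Reports mean +/- sd held-out AUC, per-taxon selection
    reproducibility (fraction of fold-selections containing the taxon), and
    the balance selected on the full data.
    """
    taxa = list(values.index)
    arr = values.to_numpy(dtype=float)
    if np.any(arr <= 0):
        raise ValueError("values must be strictly positive")
    logs = np.log(arr)
    lab = np.asarray(list(labels))
    levels = sorted(pd.unique(lab).tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly two labels, got {levels}")
    positive = lab == levels[1]
    class_counts = np.bincount(positive.astype(int))
    if class_counts.min() < k_folds:
        raise ValueError(
            f"each class needs >= k_folds={k_folds} samples")

    rng = np.random.default_rng(seed)
    fold_aucs: list[float] = []
    selection_counts = pd.Series(0.0, index=taxa)
    n_selections = 0
    for _ in range(n_repeats):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for train_idx, test_idx in skf.split(logs.T, positive):
            num, den = _greedy_balance(logs[:, train_idx],
                                       positive[train_idx], taxa, max_taxa)
            r, s = len(num), len(den)
            coef = np.sqrt(r * s / (r + s))
            test_vals = coef * (logs[np.ix_(num, test_idx)].mean(axis=0)
                                - logs[np.ix_(den, test_idx)].mean(axis=0))
            auc = _rank_auc(test_vals, positive[test_idx])
            if np.isfinite(auc):
                fold_aucs.append(auc)
            for t in num + den:
                selection_counts.iloc[t] += 1
            n_selections += 1
    num, den = _greedy_balance(logs, positive, taxa, max_taxa)
    fold_arr = np.asarray(fold_aucs)
    return SelbalResult(
        numerator=[taxa[i] for i in num],
        denominator=[taxa[i] for i in den],
        auc_mean=float(fold_arr.mean()),
        auc_sd=float(fold_arr.std(ddof=1)) if len(fold_arr) > 1 else 0.0,
        reproducibility=selection_counts / max(n_selections, 1),
        fold_aucs=fold_arr,
    )
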