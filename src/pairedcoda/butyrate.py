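"""Butyrate-production potential statistics.

Two complementary summaries of a community's capacity to make butyrate:

* the producer balance — an ilr balance with the known butyrate-producing
  genera in the numerator and every other taxon in the denominator; and
* pathway potential — a user-supplied pathways x taxa weight matrix applied
  to relative abundances, giving per-sample relative pathway abundances.

Both are compared between intervention and control with the baseline-adjusted
ANCOVA on per-subject before/after values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coda import balance_values, closure, multiplicative_zero_replacement
from .inference import AncovaResult, ancova_group_effect, bh_fdr
from .tabular_io import (AbundanceTable, StudyDesign, _parse_lineage,
                         validate_pairing)

#: Genera treated as the main butyrate producers of the human gut.
DEFAULT_PRODUCERS = (
    "Faecalibacterium", "Eubacterium", "Roseburia", "Ruminococcus",
    "Anaerostipes",
)

#: Genera reported to cooperate with butyrate producers (secondary analysis).
AUXILIARY_PRODUCERS = ("Lactobacillus", "Bifidobacterium")


@dataclass
class ProducerSet:
    """Taxon names designated as producers, matched at genus level.

    Matching is case-insensitive and prefix-dialect aware: a name matches a
    taxon whose id (stripped of any ``g__`` prefix) or lineage genus token
    equals it.  The same genus under two different parent lineages matches
    once per row, and every matching row is included.
    """

    names: tuple[str, ...] = DEFAULT_PRODUCERS
    label: str = "butyrate_producers"

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("producer set must be non-empty")

    def match(self, table: AbundanceTable) -> tuple[list[str], list[str]]:
        """Return (matched taxon ids, unmatched producer names)."""
        wanted = {n.lower(): n for n in self.names}
        matched: list[str] = []
        hit: set[str] = set()
        for taxon in table.taxon_ids:
            keys = {str(taxon).lower().removeprefix("g__")}
            if table.lineages is not None:
                lin = table.lineages.get(taxon)
                if isinstance(lin, str):
                    genus = _parse_lineage(lin)[5]
                    if genus:
                        keys.add(genus.lower())
            found = keys & wanted.keys()
            if found:
                matched.append(taxon)
                hit.update(found)
        unmatched = [wanted[k] for k in wanted if k not in hit]
        return matched, unmatched


def read_producer_set(path: str | Path,
                      label: str = "producers") -> ProducerSet:
    """Read a producer list from a plain-text file, one name per line."""
    names = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    return ProducerSet(tuple(names), label=label)


def producer_balance(compositions: pd.DataFrame,
                     producers: ProducerSet | Sequence[str] = None,
                     table: Optional[AbundanceTable] = None) -> pd.Series:
    """Per-sample producer-vs-rest balance on zero-replaced proportions.

    Numerator = matched producer taxa, denominator = all remaining taxa.
    ``table`` (when given) supplies lineages for genus matching; otherwise
    names are matched against the composition's row labels.
    """
    if producers is None:
        producers = ProducerSet()
    elif not isinstance(producers, ProducerSet):
        producers = ProducerSet(tuple(producers))
    ref = table if table is not None else AbundanceTable(
        pd.DataFrame(1, index=compositions.index,
                     columns=compositions.columns))
    matched, unmatched = producers.match(ref)
    matched = [t for t in matched if t in compositions.index]
    if not matched:
        raise ValueError(
            f"no producer taxon matched; tried {list(producers.names)}")
    rest = [t for t in compositions.index if t not in set(matched)]
    if not rest:
        raise ValueError("every taxon matched the producer set")
    vals = balance_values(compositions, matched, rest)
    vals.attrs["numerator"] = matched
    vals.attrs["unmatched"] = unmatched
    return vals


# ---------------------------------------------------------------------------
# Pathway potential
# ---------------------------------------------------------------------------

@dataclass
class PathwayWeightMatrix:
    """Pathways x taxa non-negative weights (expected pathway copy
    contribution per taxon)."""

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.weights.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("pathway weights must be non-negative")
        if (arr.sum(axis=1) == 0).any():
            bad = self.weights.index[arr.sum(axis=1) == 0][0]
            raise ValueError(f"pathway {bad!r} has no non-zero weight")

    @property
    def pathways(self) -> list[str]:
        return list(self.weights.index)


def read_pathway_weights(path: str | Path) -> PathwayWeightMatrix:
    return PathwayWeightMatrix(pd.read_csv(path, sep="\t", index_col=0))


def pathway_potential(table: AbundanceTable,
                      weights: PathwayWeightMatrix) -> pd.DataFrame:
    """Per-sample relative pathway abundances: weights @ relative abundance,
    renormalised so each sample's pathway profile sums to 1."""
    shared = [t for t in weights.weights.columns if t in table.counts.index]
    if not shared:
        raise ValueError("no overlapping taxa between table and weights")
    rel = table.relative_abundance().loc[shared]
    w = weights.weights[shared].to_numpy(dtype=float)
    raw = w @ rel.to_numpy()
    if np.any(raw.sum(axis=0) == 0):
        raise ValueError("a sample has zero total pathway abundance")
    return pd.DataFrame(closure(raw), index=weights.pathways,
                        columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _paired_frames(design: StudyDesign, table: AbundanceTable,
                   min_depth: int = 1000):
    report = validate_pairing(design, table, min_depth=min_depth)
    subjects = list(report.complete_pairs)
    groups = np.asarray([design.group_of(s) for s in subjects])
    before_ids = [report.complete_pairs[s][0] for s in subjects]
    after_ids = [report.complete_pairs[s][1] for s in subjects]
    return subjects, groups, before_ids, after_ids


def pathway_group_comparison(pathway_abundances: pd.DataFrame,
                             design: StudyDesign,
                             table: AbundanceTable,
                             min_depth: int = 1000) -> pd.DataFrame:
    """Per-pathway baseline-adjusted ANCOVA of after on before + group,
    BH-corrected across pathways."""
    subjects, groups, before_ids, after_ids = _paired_frames(
        design, table, min_depth)
    rows = []
    for pw in pathway_abundances.index:
        res = ancova_group_effect(
            pathway_abundances.loc[pw, before_ids].to_numpy(),
            pathway_abundances.loc[pw, after_ids].to_numpy(),
            groups, reference="control")
        rows.append({"pathway": pw, "group_coefficient": res.group_coefficient,
                     "baseline_coefficient": res.baseline_coefficient,
                     "p": res.group_p, "n": res.n, "note": res.note})
    out = pd.DataFrame(rows).set_index("pathway")
    out["q"] = bh_fdr(out["p"].fillna(1.0).to_numpy())
    return out


def producer_balance_group_test(table: AbundanceTable, design: StudyDesign,
                                producers: ProducerSet | None = None,
                                zero_method: str = "GBM",
                                min_depth: int = 1000) -> AncovaResult:
    """ANCOVA on the producer balance's per-subject before/after values."""
    subjects, groups, before_ids, after_ids = _paired_frames(
        design, table, min_depth)
    sub = table.subset_samples(before_ids + after_ids)
    props = multiplicative_zero_replacement(sub, method=zero_method)
    vals = producer_balance(props, producers, table=sub)
    return ancova_group_effect(
        vals.loc[before_ids].to_numpy(), vals.loc[after_ids].to_numpy(),
        groups, reference="control")
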